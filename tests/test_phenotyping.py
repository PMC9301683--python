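"""Disease/phenotype rule application and comorbidity counting."""

from datetime import date, timedelta

import numpy as np
import pytest

from rhinoreg.errors import ValidationError
from rhinoreg.phenotyping import (
    OTHER_DISEASE_CATEGORIES,
    PhenotypeProfile,
    assign_core_diagnoses,
    build_profile,
    classify_acute_subgroups,
    classify_crs_phenotype,
    count_comorbidities,
)
from rhinoreg.synthetic_ehr import VisitRecord


def _visit(codes=(), note="", pid="p1", vid="v1", d=date(2010, 1, 1)):
    return VisitRecord(pid, vid, d, "ENT", tuple(codes), note)


# ---------------------------------------------------------------------------
# core diagnoses


def test_allergic_asthma_sets_both_flags():
    prof = assign_core_diagnoses({}, [_visit(["J45.0"])])
    assert prof.asthma and prof.allergy


@pytest.mark.parametrize("code", ["J45.0", "J45.1", "J45.9"])
def test_all_asthma_subcodes_qualify(code):
    assert assign_core_diagnoses({}, [_visit([code])]).asthma


def test_immunodeficiency_composite_from_code():
    prof = assign_core_diagnoses({}, [_visit(["D81.9"])])
    assert prof.immunodeficiency and prof.immunodeficiency_or_suspicion


def test_immunodeficiency_suspicion_from_text_only():
    prof = assign_core_diagnoses({"immunodeficiency": True}, [_visit()])
    assert prof.immunodeficiency_or_suspicion and not prof.immunodeficiency


def test_empty_evidence_all_false():
    prof = assign_core_diagnoses({}, [_visit()])
    assert not any(
        getattr(prof, f) for f in ("AR", "NAR", "CRS_any", "CRSwNP", "asthma",
                                   "allergy", "NERD", "diabetes")
    )


def test_mixed_patients_rejected():
    with pytest.raises(ValidationError):
        assign_core_diagnoses({}, [_visit(pid="a"), _visit(pid="b")])


# ---------------------------------------------------------------------------
# CRS phenotype


def _crs_profile(j32: bool, j33: bool) -> PhenotypeProfile:
    prof = PhenotypeProfile(patient_id="p")
    prof.CRS_any = j32 or j33
    prof.CRSwNP = j33
    prof._has_j32 = j32
    return prof


@pytest.mark.parametrize(
    "j32,j33,polyp,crssnp,crswnp",
    [
        (True, False, False, True, False),
        (True, True, False, False, True),
        (False, False, False, False, False),
        (True, False, True, False, False),  # polyp text excludes CRSsNP
        (False, True, False, False, True),
    ],
)
def test_crs_phenotype_rules(j32, j33, polyp, crssnp, crswnp):
    prof = classify_crs_phenotype(_crs_profile(j32, j33), polyp_evidence=polyp)
    assert prof.CRSsNP == crssnp and prof.CRSwNP == crswnp
    assert not (prof.CRSsNP and prof.CRSwNP)


# ---------------------------------------------------------------------------
# acute subgroups

D0 = date(2010, 1, 1)


def _acute(j01_days, j32=False, j33=False, chronic=False, **kw):
    prof = _crs_profile(j32, j33)
    dates = [D0 + timedelta(days=d) for d in j01_days]
    return classify_acute_subgroups(prof, dates, chronic_text_flag=chronic, **kw)


def test_ars_and_rars_overlap_when_gap_short():
    prof = _acute([0, 50])
    assert prof.ARS and prof.RARS


def test_long_gap_blocks_ars_but_not_rars():
    prof = _acute([0, 200])
    assert not prof.ARS and prof.RARS


def test_j33_makes_crswnp_ae_not_crs_ae():
    prof = _acute([0], j33=True)
    assert prof.CRSwNP_AE and not prof.CRS_AE and not prof.ARS
    assert prof.any_CRS_AE


def test_j32_plus_j01_is_crs_ae():
    prof = _acute([0], j32=True)
    assert prof.CRS_AE and not prof.CRSwNP_AE and prof.any_CRS_AE


def test_chronic_text_excludes_acute_groups():
    prof = _acute([0, 30], chronic=True)
    assert not prof.ARS and not prof.RARS


def test_strict_or_reading_keeps_acute_groups_with_codes():
    # literal disjunction: "no codes OR no chronic text" is satisfied by
    # the absent chronic text even when J32 is coded
    prof = _acute([0, 30], j32=True, strict_or=True)
    assert prof.ARS and prof.RARS


def test_any_crs_ae_flag_excluding_crswnp_ae():
    prof = _acute([0], j33=True, include_crswnp_ae=False)
    assert prof.CRSwNP_AE and not prof.any_CRS_AE


def test_more_than_three_j01_visits_blocks_ars():
    prof = _acute([0, 10, 20, 30])
    assert not prof.ARS and prof.RARS


def test_unsorted_dates_rejected():
    prof = _crs_profile(False, False)
    with pytest.raises(ValidationError):
        classify_acute_subgroups(prof, [D0, D0 - timedelta(days=1)], False)


# ---------------------------------------------------------------------------
# comorbidity counting


def test_minimal_profile_counts():
    prof = PhenotypeProfile(patient_id="p", AR=True)
    assert count_comorbidities(prof) == (1, 0, 1, ("0", "1"))


def test_multimorbid_profile_counts():
    prof = PhenotypeProfile(patient_id="p", NAR=True, asthma=True, allergy=True,
                            diabetes=True, cardiovascular=True)
    rhin, other, total, (ob, ab) = count_comorbidities(prof)
    assert (rhin, other, total) == (1, 4, 5)
    assert (ob, ab) == ("≥4", "≥5")


def test_acute_entity_counts_j01_presence_even_with_crs():
    # a patient with J01 + J32 carries both the acute and the CRS entity
    prof = PhenotypeProfile(patient_id="p", CRS_any=True, j01_visit_count=1)
    rhin, *_ = count_comorbidities(prof)
    assert rhin == 2


# ---------------------------------------------------------------------------
# randomized oracle equivalence and monotonicity


def _oracle_flags(codes, j01_days, chronic_text, polyp_text):
    """Independent re-statement of the subgroup clauses for small evidence."""
    has = lambda p: any(c.startswith(p) for c in codes)
    j32, j33 = has("J32"), has("J33")
    k = len(j01_days)
    no_crs = not j32 and not j33 and not chronic_text
    gap_ok = k < 2 or (j01_days[1] - j01_days[0]) <= 90
    return {
        "AR": has("J30"), "NAR": has("J31"), "CRS_any": j32 or j33,
        "CRSwNP": j33, "CRSsNP": j32 and not j33 and not polyp_text,
        "ARS": 1 <= k <= 3 and gap_ok and no_crs,
        "RARS": k >= 2 and no_crs,
        "CRS_AE": k >= 1 and j32 and not j33,
        "CRSwNP_AE": k >= 1 and j33,
    }


_CODE_POOL = ["J30.1", "J31.0", "J32.0", "J33.1", "J45.0", "E11.9", "I10", "M54.5"]


def test_phenotype_rules_match_bruteforce_oracle():
    """10,000 random small evidence sets agree with independent clause evaluation."""
    rng = np.random.default_rng(31)
    for _ in range(10_000):
        codes = {
            _CODE_POOL[i] for i in rng.integers(len(_CODE_POOL), size=rng.integers(0, 7))
        }
        n_j01 = int(rng.integers(0, 5))
        j01_days = sorted(int(d) for d in rng.integers(0, 400, size=n_j01))
        chronic = bool(rng.random() < 0.2)
        polyp = bool(rng.random() < 0.2)

        visits = [_visit(sorted(codes), vid="v0")]
        visits += [
            _visit(["J01.0"], vid=f"j{i}", d=D0 + timedelta(days=d))
            for i, d in enumerate(j01_days)
        ]
        flags = {"chronic_rhinosinusitis": chronic, "nasal_polyps": polyp}
        prof = assign_core_diagnoses(flags, visits)
        prof._has_j32 = any(c.startswith("J32") for c in codes)
        classify_crs_phenotype(prof, polyp_evidence=polyp)
        classify_acute_subgroups(prof, [D0 + timedelta(days=d) for d in j01_days],
                                 chronic_text_flag=chronic)
        expected = _oracle_flags(codes | {"J01.0"} if n_j01 else codes,
                                 j01_days, chronic, polyp)
        for name, want in expected.items():
            assert getattr(prof, name) == want, (name, codes, j01_days, chronic, polyp)


def test_evidence_monotonicity_asymmetry():
    """Adding J33 evidence removes CRSsNP/ARS/RARS but never other flags."""
    visits = [_visit(["J32.0"], vid="v0"), _visit(["J01.0"], vid="v1",
                                                  d=D0 + timedelta(days=30))]
    base = build_profile(visits)
    assert base.CRSsNP and base.CRS_AE
    grown = build_profile(visits + [_visit(["J33.1"], vid="v2",
                                           d=D0 + timedelta(days=60))])
    # exclusion clauses may flip off ...
    assert not grown.CRSsNP and not grown.CRS_AE
    assert grown.CRSwNP and grown.CRSwNP_AE
    # ... but purely accumulative flags never do
    for name in ("AR", "NAR", "CRS_any", "asthma", "NERD", *OTHER_DISEASE_CATEGORIES):
        assert getattr(grown, name) >= getattr(base, name)
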