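"""Patient-level disease and phenotype definitions.

Translates per-patient evidence (ICD-10 codes on visits or written in note
text, plus affirmed keyword concepts) into the analysis variables:

* core diagnoses — AR (J30), NAR (J31), any CRS (J32/J33), CRSwNP (J33),
  asthma (J45 incl. J45.0/J45.1/J45.9), and composites: allergy (J45.0 or
  J30 or affirmed "allergy" text), immunodeficiency (B20 or D80-D84), and
  immunodeficiency-or-suspicion (codes or affirmed "immunodeficiency" text),
  NERD (affirmed keyword concept);
* CRS phenotypes — CRSwNP iff J33; CRSsNP iff J32 with no J33 and no
  affirmed nasal-polyp text evidence (mutually exclusive);
* acute rhinosinusitis subgroups from dated J01 visits — ARS (1-3 J01
  visits, first-to-second gap <= 90 days, no CRS evidence), RARS (>= 2 J01
  visits, no CRS evidence), CRS AE (J01 + J32, no J33), CRSwNP AE
  (J01 + J33), and "any CRS AE" as their union;
* comorbidity counts over the 17 non-rhinitis disease categories with the
  0/1/2/3/>=4 ("other diseases") and 1/2/3/4/>=5 ("any diseases") buckets.

The "no CRS evidence" clause of ARS/RARS is read conjunctively (no J32 AND
no J33 AND no affirmed chronic-rhinosinusitis text), which makes the acute
subgroups disjoint from CRS; ``strict_or=True`` selects the literal
disjunctive reading instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from rhinoreg.dictionary import default_dictionary
from rhinoreg.errors import ValidationError
from rhinoreg.text_extraction import (
    ConceptRule,
    extract_patient_concepts,
    find_icd_codes_in_text,
)

__all__ = [
    "PhenotypeProfile",
    "OTHER_DISEASE_CATEGORIES",
    "collect_codes",
    "assign_core_diagnoses",
    "classify_crs_phenotype",
    "classify_acute_subgroups",
    "count_comorbidities",
    "build_profile",
    "build_profiles",
]

#: the non-rhinitis disease categories entering "other diseases" counts
OTHER_DISEASE_CATEGORIES: tuple[str, ...] = (
    "asthma",
    "allergy",
    "NERD",
    "diabetes",
    "chronic_respiratory_other",
    "obesity",
    "mental",
    "memory",
    "cardiovascular",
    "cancer",
    "musculoskeletal",
    "obstructive_sleep_apnea",
    "mouth_breathing",
    "gastroesophageal_reflux",
    "chronic_otitis_media",
    "tonsil_disease",
    "immunodeficiency_or_suspicion",
)

_FLAG_FIELDS = (
    "AR", "NAR", "CRS_any", "CRSsNP", "CRSwNP", "ARS", "RARS", "CRS_AE",
    "CRSwNP_AE", "any_CRS_AE", "NERD", "asthma", "allergy",
    "immunodeficiency", "immunodeficiency_or_suspicion", "diabetes",
    "chronic_respiratory_other", "obesity", "mental", "memory",
    "cardiovascular", "cancer", "musculoskeletal", "obstructive_sleep_apnea",
    "mouth_breathing", "gastroesophageal_reflux", "chronic_otitis_media",
    "tonsil_disease",
)


@dataclass
class PhenotypeProfile:
    """All boolean phenotype flags and derived comorbidity counts for one patient."""

    patient_id: str
    AR: bool = False
    NAR: bool = False
    CRS_any: bool = False
    CRSsNP: bool = False
    CRSwNP: bool = False
    ARS: bool = False
    RARS: bool = False
    CRS_AE: bool = False
    CRSwNP_AE: bool = False
    any_CRS_AE: bool = False
    NERD: bool = False
    asthma: bool = False
    allergy: bool = False
    immunodeficiency: bool = False
    immunodeficiency_or_suspicion: bool = False
    diabetes: bool = False
    chronic_respiratory_other: bool = False
    obesity: bool = False
    mental: bool = False
    memory: bool = False
    cardiovascular: bool = False
    cancer: bool = False
    musculoskeletal: bool = False
    obstructive_sleep_apnea: bool = False
    mouth_breathing: bool = False
    gastroesophageal_reflux: bool = False
    chronic_otitis_media: bool = False
    tonsil_disease: bool = False
    j01_visit_count: int = 0
    rhinitis_entity_count: int = 0
    other_disease_count: int = 0
    any_disease_count: int = 0
    other_bucket: str = "0"
    any_bucket: str = "1"

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def collect_codes(visits: Sequence) -> set[str]:
    """All ICD-10 codes for a patient: coded fields plus codes written in notes."""
    codes: set[str] = set()
    for v in visits:
        codes.update(c.upper() for c in v.icd_codes)
        if v.note_text:
            codes.update(find_icd_codes_in_text(v.note_text))
    return codes


def _has_prefix(codes: Iterable[str], *prefixes: str) -> bool:
    return any(c.startswith(p) for c in codes for p in prefixes)


def assign_core_diagnoses(
    concept_flags: Mapping[str, bool],
    coded_visits: Sequence,
    patient_id: str | None = None,
) -> PhenotypeProfile:
    """Resolve the code-driven diagnoses and keyword-driven composites.

    ``concept_flags`` are the affirmed-concept booleans from extraction;
    ``coded_visits`` are one patient's visits (codes are re-collected here so
    codes embedded in note text also count).
    """
    pids = {v.patient_id for v in coded_visits}
    if len(pids) > 1:
        raise ValidationError(f"visits span multiple patients: {sorted(pids)}")
    if patient_id is None:
        patient_id = next(iter(pids), "")

    codes = collect_codes(coded_visits)
    prof = PhenotypeProfile(patient_id=patient_id)
    prof.AR = _has_prefix(codes, "J30")
    prof.NAR = _has_prefix(codes, "J31")
    prof.CRS_any = _has_prefix(codes, "J32", "J33")
    prof.CRSwNP = _has_prefix(codes, "J33")
    prof.asthma = _has_prefix(codes, "J45")
    prof.allergy = (
        _has_prefix(codes, "J45.0", "J30") or bool(concept_flags.get("allergy"))
    )
    prof.immunodeficiency = _has_prefix(codes, "B20", "D80", "D81", "D82", "D83", "D84")
    prof.immunodeficiency_or_suspicion = (
        prof.immunodeficiency or bool(concept_flags.get("immunodeficiency"))
    )
    prof.NERD = bool(concept_flags.get("nerd"))
    prof.diabetes = _has_prefix(codes, "E10", "E11", "E12", "E13", "E14") or bool(
        concept_flags.get("diabetes")
    )
    prof.chronic_respiratory_other = _has_prefix(codes, "J40", "J41", "J42", "J43",
                                                 "J44", "J47")
    prof.obesity = _has_prefix(codes, "E66")
    prof.mental = _has_prefix(codes, "F2", "F3", "F4", "F5", "F6")
    prof.memory = _has_prefix(codes, "F00", "F01", "F02", "F03", "G30")
    prof.cardiovascular = _has_prefix(codes, "I1", "I2", "I5", "I6", "I7")
    prof.cancer = _has_prefix(codes, "C")
    prof.musculoskeletal = _has_prefix(codes, "M")
    prof.obstructive_sleep_apnea = _has_prefix(codes, "G47.3")
    prof.mouth_breathing = _has_prefix(codes, "R06.5")
    prof.gastroesophageal_reflux = _has_prefix(codes, "K21")
    prof.chronic_otitis_media = _has_prefix(codes, "H66")
    prof.tonsil_disease = _has_prefix(codes, "J35")
    return prof


def classify_crs_phenotype(profile: PhenotypeProfile, polyp_evidence: bool) -> PhenotypeProfile:
    """Resolve CRSsNP / CRSwNP (mutually exclusive).

    CRSsNP requires a J32 code with no J33 and no affirmed nasal-polyp text
    evidence; CRSwNP follows J33 alone (already set from codes).
    """
    profile.CRSsNP = bool(_j32_flag(profile) and not profile.CRSwNP and not polyp_evidence)
    return profile


def _j32_flag(profile: PhenotypeProfile) -> bool:
    # CRS_any is (J32 or J33); J32 presence is tracked explicitly when built
    # through build_profile.  For manually constructed profiles fall back to
    # CRS_any-and-not-CRSwNP.
    has = getattr(profile, "_has_j32", None)
    if has is None:
        return profile.CRS_any and not profile.CRSwNP
    return bool(has)


def classify_acute_subgroups(
    profile: PhenotypeProfile,
    dated_j01_visits: Sequence[date],
    chronic_text_flag: bool,
    strict_or: bool = False,
    include_crswnp_ae: bool = True,
) -> PhenotypeProfile:
    """Resolve ARS / RARS / CRS AE / CRSwNP AE / any CRS AE.

    ``dated_j01_visits`` are the ascending dates of visits carrying a J01
    code; ``chronic_text_flag`` is the affirmed "chronic rhinosinusitis"
    text mention.  With ``strict_or`` the no-CRS clause is the literal
    disjunction (no J32/J33) OR (no chronic text) instead of the conjunction.
    """
    if list(dated_j01_visits) != sorted(dated_j01_visits):
        raise ValidationError("dated_j01_visits must be sorted ascending")
    k = len(dated_j01_visits)
    has_j32 = _j32_flag(profile)
    no_codes = not profile.CRS_any
    if strict_or:
        no_crs = no_codes or not chronic_text_flag
    else:
        no_crs = no_codes and not chronic_text_flag
    gap_ok = (
        k < 2
        or (dated_j01_visits[1] - dated_j01_visits[0]).days <= 90
    )
    profile.ARS = bool(1 <= k <= 3 and gap_ok and no_crs)
    profile.RARS = bool(k >= 2 and no_crs)
    profile.CRS_AE = bool(k >= 1 and has_j32 and not profile.CRSwNP)
    profile.CRSwNP_AE = bool(k >= 1 and profile.CRSwNP)
    profile.any_CRS_AE = bool(
        profile.CRS_AE or (include_crswnp_ae and profile.CRSwNP_AE)
    )
    return profile


def count_comorbidities(
    profile: PhenotypeProfile,
    other_categories: Sequence[str] = OTHER_DISEASE_CATEGORIES,
) -> tuple[int, int, int, tuple[str, str]]:
    """Derive the comorbidity counts and bucket labels, updating the profile.

    Returns ``(rhinitis_entity_count, other_disease_count, any_disease_count,
    (other_bucket, any_bucket))``.  The rhinitis/rhinosinusitis entities are
    AR, NAR, the acute entity (any J01 visit — so a patient with both J01 and
    a chronic CRS code carries two entities), and any CRS.
    """
    acute = profile.j01_visit_count > 0 or profile.ARS or profile.RARS
    rhinitis = sum([profile.AR, profile.NAR, acute, profile.CRS_any])
    other = sum(bool(getattr(profile, c)) for c in other_categories)
    any_count = rhinitis + other
    other_bucket = str(other) if other < 4 else "≥4"
    any_bucket = str(any_count) if any_count < 5 else "≥5"
    profile.rhinitis_entity_count = rhinitis
    profile.other_disease_count = other
    profile.any_disease_count = any_count
    profile.other_bucket = other_bucket
    profile.any_bucket = any_bucket
    return rhinitis, other, any_count, (other_bucket, any_bucket)


# ---------------------------------------------------------------------------
# end-to-end profile construction


def build_profile(
    visits: Sequence,
    dictionary: Sequence[ConceptRule] | None = None,
    strict_or: bool = False,
    include_crswnp_ae: bool = True,
) -> PhenotypeProfile:
    """Run extraction + all phenotype rules for one patient's visits."""
    if dictionary is None:
        dictionary = default_dictionary()
    flags = extract_patient_concepts(visits, dictionary)
    prof = assign_core_diagnoses(flags, visits)
    codes = collect_codes(visits)
    prof._has_j32 = any(c.startswith("J32") for c in codes)  # type: ignore[attr-defined]
    classify_crs_phenotype(prof, polyp_evidence=bool(flags.get("nasal_polyps")))
    j01_dates = sorted(
        v.date for v in visits if any(c.upper().startswith("J01") for c in v.icd_codes)
        or any(c.startswith("J01") for c in (find_icd_codes_in_text(v.note_text)
                                             if v.note_text else ()))
    )
    prof.j01_visit_count = len(j01_dates)
    classify_acute_subgroups(
        prof,
        j01_dates,
        chronic_text_flag=bool(flags.get("chronic_rhinosinusitis")),
        strict_or=strict_or,
        include_crswnp_ae=include_crswnp_ae,
    )
    count_comorbidities(prof)
    return prof


def build_profiles(
    visits: Sequence,
    dictionary: Sequence[ConceptRule] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Profiles for a whole cohort, one row per patient (indexed by patient_id)."""
    if dictionary is None:
        dictionary = default_dictionary()
    by_patient: dict[str, list] = {}
    for v in visits:
        by_patient.setdefault(v.patient_id, []).append(v)
    rows = []
    for pid in sorted(by_patient):
        pv = sorted(by_patient[pid], key=lambda v: v.date)
        rows.append(build_profile(pv, dictionary, **kwargs).to_dict())
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("patient_id")
    return df
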