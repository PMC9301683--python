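"""Synthetic longitudinal outpatient EHR generator.

Emulates a hospital-registry cohort of rhinitis/rhinosinusitis patients:
patients are sampled at index visits spread uniformly over the months of a
set of index years and followed to a fixed study end date.  Each patient
carries a set of latent disease concepts drawn from configured prevalences
(optionally correlated through pairwise log-odds adjustments); concepts are
planted both as ICD-10 codes on visits and as keyword mentions in synthetic
note text with affirmed / negated / family-history / resolved polarity.
Subsequent visits follow a renewal process with exponential waiting times
whose per-patient rate is a base rate times multiplicative factors for the
patient's concepts — the structure the downstream gap-time Cox stage assumes.

Cohort inclusion requires at least one qualifying upper-airway code
(J30/J31/J32/J33/J01).  The generator enforces this by rejection sampling
with the qualifying prevalences rescaled so that the *conditional* marginal
of each qualifying concept in the accepted cohort equals its configured
value exactly (see :func:`_inclusion_rescale`).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from rhinoreg.dictionary import default_dictionary
from rhinoreg.errors import ConfigError, ValidationError
from rhinoreg.text_extraction import ConceptRule

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "VisitRecord",
    "generate_cohort",
    "render_note",
    "write_cohort",
    "load_patients",
    "load_visits",
]

QUALIFYING_CONCEPTS = ("j30", "j31", "j32", "j33", "j01")

#: concrete ICD-10 codes planted for each code-backed concept
_CODE_POOLS: dict[str, list[str]] = {
    "j30": ["J30.1", "J30.2", "J30.3", "J30.4"],
    "j31": ["J31.0"],
    "j32": ["J32.0", "J32.2", "J32.4", "J32.9"],
    "j33": ["J33.0", "J33.1", "J33.9"],
    "j01": ["J01.0", "J01.9"],
    "asthma": ["J45.1", "J45.9"],  # J45.0 handled via allergic-asthma fraction
    "diabetes": ["E11.9", "E10.9"],
    "chronic_respiratory_other": ["J40", "J42", "J44.9", "J47"],
    "obesity": ["E66.0", "E66.9"],
    "mental": ["F32.9", "F41.1"],
    "memory": ["G30.9", "F03"],
    "cardiovascular": ["I10", "I25.9", "I50.9"],
    "cancer": ["C44.9", "C50.9"],
    "musculoskeletal": ["M54.5", "M17.9"],
    "obstructive_sleep_apnea": ["G47.3"],
    "mouth_breathing": ["R06.5"],
    "gastroesophageal_reflux": ["K21.9"],
    "chronic_otitis_media": ["H66.9"],
    "tonsil_disease": ["J35.0"],
    "immunodeficiency": ["D80.9", "D81.9", "D83.9"],
}

#: generator concept -> dictionary concept whose keyword is mentioned in notes
_KEYWORD_CONCEPT: dict[str, str] = {
    "nerd": "nerd",
    "allergy": "allergy",
    "diabetes": "diabetes",
    "immunodeficiency_suspicion": "immunodeficiency",
    "nasal_polyps": "nasal_polyps",
    "chronic_rhinosinusitis_text": "chronic_rhinosinusitis",
}

#: concepts planted through note text only (no ICD code)
_KEYWORD_ONLY = frozenset(
    {"nerd", "allergy", "immunodeficiency_suspicion", "nasal_polyps",
     "chronic_rhinosinusitis_text"}
)

# Default marginal prevalences emulate the registry cohort's "All patients"
# column: J30 33.5%, J31 27.5%, J32 20.7%, J33 10.9%, J01 27.2%; comorbidity
# marginals likewise.  The allergy keyword (10.4%) and allergic-asthma
# fraction (0.4 of asthma -> J45.0) are back-computed so the derived allergy
# composite (J45.0 or J30 or keyword) lands near 51%; nasal-polyp text (3%)
# so CRSsNP (J32, no J33, no polyp text) lands near 17.9%.
DEFAULT_PREVALENCE: dict[str, float] = {
    "j30": 0.335,
    "j31": 0.275,
    "j32": 0.207,
    "j33": 0.109,
    "j01": 0.272,
    "asthma": 0.444,
    "allergy": 0.104,
    "nerd": 0.039,
    "diabetes": 0.105,
    "chronic_respiratory_other": 0.385,
    "obesity": 0.100,
    "mental": 0.189,
    "memory": 0.025,
    "cardiovascular": 0.357,
    "cancer": 0.101,
    "musculoskeletal": 0.384,
    "obstructive_sleep_apnea": 0.094,
    "mouth_breathing": 0.068,
    "gastroesophageal_reflux": 0.055,
    "chronic_otitis_media": 0.062,
    "tonsil_disease": 0.064,
    "immunodeficiency": 0.005,
    "immunodeficiency_suspicion": 0.017,
    "nasal_polyps": 0.030,
    "chronic_rhinosinusitis_text": 0.020,
}

# Visit-intensity multipliers: chronic sinonasal disease and systemic
# comorbidity raise the outpatient visit rate; purely acute presentations
# (J01) and allergic rhinitis lower it relative to the cohort base rate.
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "j30": 0.80,
    "j31": 1.35,
    "j32": 1.70,
    "j33": 2.20,
    "j01": 0.75,
    "asthma": 1.35,
    "allergy": 1.10,
    "nerd": 1.30,
    "diabetes": 1.15,
    "chronic_respiratory_other": 1.25,
    "obesity": 1.10,
    "mental": 1.15,
    "memory": 1.10,
    "cardiovascular": 1.25,
    "cancer": 1.25,
    "musculoskeletal": 1.25,
    "obstructive_sleep_apnea": 1.25,
    "mouth_breathing": 1.00,
    "gastroesophageal_reflux": 1.10,
    "chronic_otitis_media": 1.10,
    "tonsil_disease": 1.10,
    "immunodeficiency": 1.15,
    "immunodeficiency_suspicion": 1.15,
    "nasal_polyps": 1.00,
    "chronic_rhinosinusitis_text": 1.00,
}

# Comorbidity clustering: pairwise log-odds adjustments among the systemic
# comorbidity concepts.  Edges deliberately avoid the five qualifying code
# concepts so that the inclusion rescaling stays exact; intercepts are
# recalibrated at generation time so configured marginal prevalences are
# preserved under the dependence.  Structure: strong clinically motivated
# pairs (airway-allergy axis, cardiometabolic axis), a high-prevalence
# multimorbidity clique, and a weak background association among all
# remaining comorbidity pairs; weights are calibrated so the "other
# diseases" count distribution approximates the reference cohort's bucket
# proportions (10.4 / 18.0 / 17.6 / 17.0 / 37.0% for 0 / 1 / 2 / 3 / >=4).
_SPECIFIC_LOG_ODDS: dict[tuple[str, str], float] = {
    ("asthma", "chronic_respiratory_other"): 1.35,
    ("asthma", "allergy"): 1.8,
    ("asthma", "nerd"): 3.0,
    ("cardiovascular", "diabetes"): 1.8,
    ("cardiovascular", "obesity"): 1.5,
    ("diabetes", "obesity"): 1.95,
    ("obstructive_sleep_apnea", "obesity"): 1.95,
    ("cardiovascular", "musculoskeletal"): 1.05,
    ("mental", "musculoskeletal"): 0.75,
    ("gastroesophageal_reflux", "obesity"): 1.2,
    ("memory", "cardiovascular"): 1.5,
    ("cancer", "cardiovascular"): 0.75,
    ("immunodeficiency_suspicion", "chronic_respiratory_other"): 1.2,
    ("mental", "memory"): 1.05,
    ("musculoskeletal", "obesity"): 1.05,
}

_COMORBIDITY_CONCEPTS = (
    "asthma", "allergy", "nerd", "diabetes", "chronic_respiratory_other",
    "obesity", "mental", "memory", "cardiovascular", "cancer",
    "musculoskeletal", "obstructive_sleep_apnea", "mouth_breathing",
    "gastroesophageal_reflux", "chronic_otitis_media", "tonsil_disease",
    "immunodeficiency_suspicion",
)

_MULTIMORBIDITY_CLIQUE = (
    "asthma", "allergy", "chronic_respiratory_other", "musculoskeletal",
    "cardiovascular",
)


def _default_log_odds() -> dict[tuple[str, str], float]:
    from itertools import combinations

    lo = dict(_SPECIFIC_LOG_ODDS)
    for a, b in combinations(_COMORBIDITY_CONCEPTS, 2):
        if (a, b) in lo or (b, a) in lo:
            continue
        in_clique = a in _MULTIMORBIDITY_CLIQUE and b in _MULTIMORBIDITY_CLIQUE
        lo[(a, b)] = 1.0 if in_clique else 0.2
    return lo


DEFAULT_LOG_ODDS: dict[tuple[str, str], float] = _default_log_odds()

_DEPARTMENTS = ("ENT", "pulmonology", "allergy", "pulmonology_and_allergy", "other")
_DEPARTMENT_PROBS = (0.62, 0.26, 0.02, 0.02, 0.08)


@dataclass
class CohortConfig:
    """Free parameters of the synthetic cohort.

    Defaults emulate the registry cohort the analysis was designed for:
    n = 5080 patients indexed in 2005/2007/2009/2011/2013 with equal monthly
    samples, followed to 2019-09-30; age at index 33.6 +/- 20.7 years
    (truncated to [0, 100]); 56.1% female; prevalences per
    :data:`DEFAULT_PREVALENCE`.
    """

    n_patients: int = 5080
    seed: int = 0
    study_end: date = date(2019, 9, 30)
    index_years: tuple[int, ...] = (2005, 2007, 2009, 2011, 2013)
    concept_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    comorbidity_log_odds: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_ODDS)
    )
    visit_rate_base: float = 0.18  # expected visits/year before multipliers
    visit_rate_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    note_negation_rate: float = 0.10
    note_family_rate: float = 0.05
    note_resolved_rate: float = 0.05
    age_mean: float = 33.6
    age_sd: float = 20.7
    female_fraction: float = 0.561
    allergic_asthma_fraction: float = 0.40  # share of asthma coded J45.0
    code_per_visit_prob: float = 0.35  # chance each visit repeats a concept code
    distractor_rate: float = 0.10  # non-affirmed mention of an absent concept

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.visit_rate_base <= 0:
            raise ConfigError("visit_rate_base must be > 0")
        if not self.index_years:
            raise ConfigError("index_years must be non-empty")
        for name, p in self.concept_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"concept_prevalence[{name!r}] not in [0, 1]")
        for name in ("note_negation_rate", "note_family_rate", "note_resolved_rate",
                     "female_fraction", "allergic_asthma_fraction",
                     "code_per_visit_prob", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} not in [0, 1]")
        if self.note_negation_rate + self.note_family_rate + self.note_resolved_rate > 1.0:
            raise ConfigError("note polarity rates must sum to <= 1 with affirmed rate")
        for name, m in self.visit_rate_multipliers.items():
            if m <= 0:
                raise ConfigError(f"visit_rate_multipliers[{name!r}] must be > 0")
            if name not in self.concept_prevalence:
                raise ConfigError(
                    f"visit_rate_multipliers[{name!r}] has no concept_prevalence entry"
                )
        for pair, _ in self.comorbidity_log_odds.items():
            for name in pair:
                if name not in self.concept_prevalence:
                    raise ConfigError(
                        f"comorbidity_log_odds concept {name!r} has no concept_prevalence entry"
                    )
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")

    @property
    def note_affirmed_rate(self) -> float:
        return 1.0 - (self.note_negation_rate + self.note_family_rate
                      + self.note_resolved_rate)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a config from YAML or JSON; dates given as ISO strings."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "study_end" in raw and isinstance(raw["study_end"], str):
            raw["study_end"] = date.fromisoformat(raw["study_end"])
        if "index_years" in raw:
            raw["index_years"] = tuple(raw["index_years"])
        if "comorbidity_log_odds" in raw:
            raw["comorbidity_log_odds"] = {
                tuple(k.split(":")): v for k, v in raw["comorbidity_log_odds"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str  # "male" | "female"
    birth_date: date


@dataclass(frozen=True)
class VisitRecord:
    patient_id: str
    visit_id: str
    date: date
    department: str
    icd_codes: tuple[str, ...]
    note_text: str = ""


# ---------------------------------------------------------------------------
# note rendering

_TEMPLATES = {
    "affirmed": [
        "{kw} diagnosis confirmed",
        "ongoing {kw} treatment",
        "{kw} symptoms continue",
    ],
    "negated": [
        "no {kw}",
        "not {kw} according to testing",
        "patient denies {kw}",
    ],
    "family": [
        "mother has {kw}",
        "family history of {kw}",
        "father treated for {kw}",
    ],
    "resolved": [
        "previous {kw} episode",
        "recovered from {kw}",
        "former {kw} diagnosis",
    ],
}

_FILLERS = ["routine control visit", "general condition stable"]


def render_note(
    planted_mentions: Sequence[tuple[str, str]],
    dictionary: Sequence[ConceptRule],
    seed: int,
) -> str:
    """Render a synthetic note containing one keyword per planted mention.

    Each ``(concept_id, polarity)`` pair becomes one sentence embedding one of
    the concept's dictionary keywords in a context template of the requested
    polarity (negation cue, family cue, resolved cue, or none).  Templates and
    keywords are drawn deterministically from ``seed``.
    """
    rules = {r.concept_id: r for r in dictionary}
    rng = np.random.default_rng(seed)
    if not planted_mentions:
        return ""
    sentences = []
    for concept_id, polarity in planted_mentions:
        if concept_id not in rules:
            raise ValidationError(f"unknown concept {concept_id!r}")
        rule = rules[concept_id]
        if not rule.keywords:
            raise ValidationError(f"concept {concept_id!r} has no keywords to render")
        if polarity not in _TEMPLATES:
            raise ValidationError(f"unknown polarity {polarity!r}")
        kw = rule.keywords[rng.integers(len(rule.keywords))]
        template = _TEMPLATES[polarity][rng.integers(len(_TEMPLATES[polarity]))]
        sentences.append(template.format(kw=kw) + ".")
    sentences.append(_FILLERS[rng.integers(len(_FILLERS))] + ".")
    return " ".join(sentences)


# ---------------------------------------------------------------------------
# concept sampling


def _inclusion_rescale(targets: Mapping[str, float]) -> dict[str, float]:
    """Rescale qualifying prevalences so conditional marginals hit targets.

    With independent Bernoulli draws at probability ``c * t_i`` and rejection
    of patients with no qualifying concept, the accepted-cohort marginal of
    concept *i* is ``c * t_i / P(accept)``; choosing ``c`` equal to the
    acceptance probability makes it exactly ``t_i``.  ``c`` solves the fixed
    point ``c = 1 - prod_i(1 - c * t_i)``.  When no solution exists in (0, 1]
    (attainable only for very low total prevalence) the unscaled values are
    used and marginals inflate slightly.
    """
    t = np.array([targets.get(q, 0.0) for q in QUALIFYING_CONCEPTS])
    if t.sum() <= 1.0:
        return {q: targets.get(q, 0.0) for q in QUALIFYING_CONCEPTS}

    def g(c: float) -> float:
        return c - 1.0 + np.prod(1.0 - c * t)

    c = brentq(g, 1e-9, 1.0) if g(1.0) > 0 else 1.0
    return {q: c * targets.get(q, 0.0) for q in QUALIFYING_CONCEPTS}


def _neighbor_map(
    order: Sequence[str], log_odds: Mapping[tuple[str, str], float]
) -> dict[str, list[tuple[str, float]]]:
    """Earlier-in-order neighbours with their log-odds weights, per concept."""
    pos = {name: i for i, name in enumerate(order)}
    nbrs: dict[str, list[tuple[str, float]]] = {name: [] for name in order}
    for (a, b), w in log_odds.items():
        if a not in pos or b not in pos or a == b:
            continue
        late, early = (a, b) if pos[a] > pos[b] else (b, a)
        nbrs[late].append((early, float(w)))
    return nbrs


def _calibrate_intercepts(
    order: Sequence[str],
    probs: Mapping[str, float],
    log_odds: Mapping[tuple[str, str], float],
    n_mc: int = 50_000,
) -> dict[str, float]:
    """Logistic intercepts preserving marginal prevalences under dependence.

    The dependence model is sequential-logistic: concept *i*'s success logit
    is an intercept plus the log-odds weights of its already-sampled earlier
    neighbours.  Intercepts are solved concept by concept so that the
    *marginal* probability equals the configured prevalence, using a Monte
    Carlo prefix sample (internal fixed seed; the result is a deterministic
    function of the configuration).
    """
    nbrs = _neighbor_map(order, log_odds)
    rng = np.random.default_rng(1_234_567)
    states = np.zeros((n_mc, len(order)), dtype=bool)
    idx = {name: i for i, name in enumerate(order)}
    intercepts: dict[str, float] = {}
    for name in order:
        p = probs[name]
        if not nbrs[name] or p <= 0.0 or p >= 1.0:
            intercepts[name] = (
                np.log(p / (1.0 - p)) if 0.0 < p < 1.0 else (np.inf if p >= 1 else -np.inf)
            )
            shift = np.zeros(n_mc)
        else:
            shift = np.zeros(n_mc)
            for other, w in nbrs[name]:
                shift += w * states[:, idx[other]]

            def marginal(a: float) -> float:
                return float(np.mean(1.0 / (1.0 + np.exp(-(a + shift))))) - p

            intercepts[name] = brentq(marginal, -30.0, 30.0)
        prob_vec = 1.0 / (1.0 + np.exp(-(intercepts[name] + shift)))
        states[:, idx[name]] = rng.random(n_mc) < prob_vec
    return intercepts


def _sample_concepts(
    rng: np.random.Generator,
    order: Sequence[str],
    intercepts: Mapping[str, float],
    nbrs: Mapping[str, list[tuple[str, float]]],
) -> set[str]:
    """One draw of the patient's latent concept set (sequential-logistic)."""
    sampled: set[str] = set()
    for name in order:
        eta = intercepts[name]
        for other, w in nbrs[name]:
            if other in sampled:
                eta += w
        if rng.random() < 1.0 / (1.0 + np.exp(-eta)):
            sampled.add(name)
    return sampled


# ---------------------------------------------------------------------------
# cohort generation


def _index_date(rng: np.random.Generator, years: Sequence[int]) -> date:
    year = int(years[rng.integers(len(years))])
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return date(year, month, day)


def _truncnorm_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if 0.0 <= a <= 100.0:
            return a
    return float(np.clip(mean, 0.0, 100.0))


def generate_cohort(
    config: CohortConfig,
    dictionary: Sequence[ConceptRule] | None = None,
) -> tuple[list[PatientRecord], list[VisitRecord]]:
    """Generate the synthetic cohort; deterministic given ``config.seed``.

    Returns ``(patients, visits)``.  Every patient has at least one visit
    carrying a qualifying code from J30/J31/J32/J33/J01 (inclusion
    criterion); visit dates lie within [index date, study_end]; one visit
    per patient-day.
    """
    config.validate()
    if dictionary is None:
        dictionary = default_dictionary()

    order = list(config.concept_prevalence)
    rescaled = _inclusion_rescale(config.concept_prevalence)
    base_probs = {
        name: rescaled.get(name, config.concept_prevalence[name]) for name in order
    }
    nbrs = _neighbor_map(order, config.comorbidity_log_odds)
    if any(config.comorbidity_log_odds.values()):
        intercepts = _calibrate_intercepts(order, base_probs, config.comorbidity_log_odds)
    else:
        intercepts = {
            n: (np.log(p / (1 - p)) if 0 < p < 1 else (np.inf if p >= 1 else -np.inf))
            for n, p in base_probs.items()
        }

    master = int(config.seed) % (2**31)
    patients: list[PatientRecord] = []
    visits: list[VisitRecord] = []

    for i in range(config.n_patients):
        rng = np.random.default_rng([master, i])
        pid = f"P{i:06d}"

        # latent concepts, conditional on >= 1 qualifying concept
        for _ in range(10_000):
            concepts = _sample_concepts(rng, order, intercepts, nbrs)
            if any(q in concepts for q in QUALIFYING_CONCEPTS):
                break
        else:  # pragma: no cover - unreachable with sane configs
            concepts.add("j01")

        sex = "female" if rng.random() < config.female_fraction else "male"
        age = _truncnorm_age(rng, config.age_mean, config.age_sd)
        index = _index_date(rng, config.index_years)
        birth = index - timedelta(days=int(round(age * 365.25)) + 30)
        patients.append(PatientRecord(pid, sex, birth))

        # renewal visit process
        rate = config.visit_rate_base
        for c in concepts:
            rate *= config.visit_rate_multipliers.get(c, 1.0)
        dates = [index]
        current = index
        while True:
            gap = max(1, int(round(rng.exponential(365.25 / rate))))
            current = current + timedelta(days=gap)
            if current > config.study_end:
                break
            dates.append(current)
        n_v = len(dates)

        departments = [
            _DEPARTMENTS[j] for j in rng.choice(
                len(_DEPARTMENTS), size=n_v, p=_DEPARTMENT_PROBS
            )
        ]

        # plant ICD codes: each carried concept appears on >= 1 visit
        codes_per_visit: list[list[str]] = [[] for _ in range(n_v)]
        for c in sorted(concepts):
            if c in _KEYWORD_ONLY:
                continue
            if c == "asthma":
                allergic = rng.random() < config.allergic_asthma_fraction
                pool = ["J45.0"] if allergic else _CODE_POOLS["asthma"]
            else:
                pool = _CODE_POOLS[c]
            if c == "j01":
                # acute episodes: usually a single J01 visit, occasionally more
                m = min(n_v, 1 + int(rng.poisson(0.35)))
                mask = np.zeros(n_v, dtype=bool)
                mask[rng.choice(n_v, size=m, replace=False)] = True
            else:
                mask = rng.random(n_v) < config.code_per_visit_prob
                if not mask.any():
                    mask[rng.integers(n_v)] = True
            for j in np.flatnonzero(mask):
                code = pool[rng.integers(len(pool))]
                if code not in codes_per_visit[j]:
                    codes_per_visit[j].append(code)

        # plant note mentions
        mentions_per_visit: list[list[tuple[str, str]]] = [[] for _ in range(n_v)]
        polar = ["affirmed", "negated", "family", "resolved"]
        polar_p = [config.note_affirmed_rate, config.note_negation_rate,
                   config.note_family_rate, config.note_resolved_rate]
        distract_p = [config.note_negation_rate, config.note_family_rate,
                      config.note_resolved_rate]
        distract_p = (
            [p / sum(distract_p) for p in distract_p] if sum(distract_p) > 0 else None
        )
        for c in sorted(_KEYWORD_CONCEPT):
            kw_concept = _KEYWORD_CONCEPT[c]
            if c in concepts:
                # keyword-only concepts must be recoverable from text alone
                polarity = (
                    "affirmed" if c in _KEYWORD_ONLY
                    else polar[rng.choice(4, p=polar_p)]
                )
                mentions_per_visit[rng.integers(n_v)].append((kw_concept, polarity))
            elif distract_p is not None and rng.random() < config.distractor_rate:
                polarity = ("negated", "family", "resolved")[rng.choice(3, p=distract_p)]
                mentions_per_visit[rng.integers(n_v)].append((kw_concept, polarity))

        for j in range(n_v):
            note_seed = int(rng.integers(2**31))
            text = render_note(mentions_per_visit[j], dictionary, note_seed)
            visits.append(
                VisitRecord(
                    patient_id=pid,
                    visit_id=f"{pid}V{j:04d}",
                    date=dates[j],
                    department=departments[j],
                    icd_codes=tuple(codes_per_visit[j]),
                    note_text=text,
                )
            )

    return patients, visits


# ---------------------------------------------------------------------------
# on-disk formats


def write_cohort(patients: Sequence[PatientRecord], visits: Sequence[VisitRecord],
                 out_dir) -> None:
    """Write patients.csv, visits.csv, and notes.jsonl under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "patients.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "sex", "birth_date"])
        for p in patients:
            w.writerow([p.patient_id, p.sex, p.birth_date.isoformat()])
    with open(out / "visits.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "visit_id", "date", "department", "icd_codes"])
        for v in visits:
            w.writerow([v.patient_id, v.visit_id, v.date.isoformat(),
                        v.department, ";".join(v.icd_codes)])
    with open(out / "notes.jsonl", "w") as fh:
        for v in visits:
            if v.note_text:
                fh.write(json.dumps({"patient_id": v.patient_id,
                                     "visit_id": v.visit_id,
                                     "text": v.note_text}) + "\n")


def load_patients(path) -> list[PatientRecord]:
    with open(path, newline="") as fh:
        return [
            PatientRecord(r["patient_id"], r["sex"], date.fromisoformat(r["birth_date"]))
            for r in csv.DictReader(fh)
        ]


def load_visits(visits_path, notes_path=None) -> list[VisitRecord]:
    """Read visits.csv, optionally merging note texts from notes.jsonl."""
    notes: dict[str, str] = {}
    if notes_path is not None:
        with open(notes_path) as fh:
            for line in fh:
                obj = json.loads(line)
                notes[obj["visit_id"]] = obj["text"]
    out: list[VisitRecord] = []
    with open(visits_path, newline="") as fh:
        for r in csv.DictReader(fh):
            codes = tuple(c for c in r["icd_codes"].split(";") if c)
            out.append(
                VisitRecord(
                    patient_id=r["patient_id"],
                    visit_id=r["visit_id"],
                    date=date.fromisoformat(r["date"]),
                    department=r["department"],
                    icd_codes=codes,
                    note_text=notes.get(r["visit_id"], ""),
                )
            )
    return out
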