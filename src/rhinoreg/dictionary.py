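"""Default concept dictionary for the rhinitis/rhinosinusitis registry analysis.

Keyword lists are populated only where the source keyword sets are public
knowledge in this analysis: diabetes ('diabetes', 'sugar', 'blood sugar',
'insulin'), NERD ('aerd', 'samter', 'aspirin', 'asa'), and the single-term
EHR concepts 'allergy', 'immunodeficiency', 'nasal polyps' / 'polyposis',
and 'chronic rhinosinusitis'.  Every other comorbidity concept ships as an
ICD-10-prefix-only scaffold with an empty keyword list; production use
supplies a full dictionary file (YAML/JSON) via :func:`rhinoreg.text_extraction.load_dictionary`.

ICD-10 prefixes for the comorbidity scaffolds follow the standard chapter
blocks (E66 obesity, F mental, K21 reflux, I circulatory, C neoplasms,
M musculoskeletal, G47.3 obstructive sleep apnoea, H66 chronic otitis media,
J35 tonsil disease, J40-J44/J47 non-asthma chronic lower-respiratory disease).
"""

from __future__ import annotations

from rhinoreg.text_extraction import ConceptRule

__all__ = ["default_dictionary", "DEFAULT_NEGATION_CUES", "DEFAULT_FAMILY_CUES", "DEFAULT_RESOLVED_CUES"]

DEFAULT_NEGATION_CUES = ["no", "not", "without", "denies", "negative", "excluded"]
DEFAULT_FAMILY_CUES = ["mother", "father", "sister", "brother", "family", "parent"]
DEFAULT_RESOLVED_CUES = ["resolved", "healed", "recovered", "previous", "former", "cured"]

# (concept_id, keywords, icd_prefixes)
_ENTRIES: list[tuple[str, list[str], list[str]]] = [
    # qualifying upper-airway diagnosis codes
    ("j30", [], ["J30"]),                     # allergic rhinitis
    ("j31", [], ["J31"]),                     # non-allergic (chronic) rhinitis
    ("j32", [], ["J32"]),                     # chronic sinusitis
    ("j33", [], ["J33"]),                     # nasal polyps (CRSwNP)
    ("j01", [], ["J01"]),                     # acute purulent rhinosinusitis
    # text-derived phenotype evidence
    ("nerd", ["aerd", "samter", "aspirin", "asa"], []),
    ("allergy", ["allergy"], []),
    ("immunodeficiency", ["immunodeficiency"], ["B20", "D80", "D81", "D82", "D83", "D84"]),
    ("nasal_polyps", ["nasal polyps", "polyposis"], []),
    ("chronic_rhinosinusitis", ["chronic rhinosinusitis"], []),
    # comorbidities
    ("asthma", [], ["J45"]),
    ("diabetes", ["diabetes", "sugar", "blood sugar", "insulin"],
     ["E10", "E11", "E12", "E13", "E14"]),
    ("chronic_respiratory_other", [], ["J40", "J41", "J42", "J43", "J44", "J47"]),
    ("obesity", [], ["E66"]),
    ("mental", [], ["F2", "F3", "F4", "F5", "F6"]),
    ("memory", [], ["F00", "F01", "F02", "F03", "G30"]),
    ("cardiovascular", [], ["I1", "I2", "I5", "I6", "I7"]),
    ("cancer", [], ["C"]),
    ("musculoskeletal", [], ["M"]),
    ("obstructive_sleep_apnea", [], ["G47.3"]),
    ("mouth_breathing", [], ["R06.5"]),
    ("gastroesophageal_reflux", [], ["K21"]),
    ("chronic_otitis_media", [], ["H66"]),
    ("tonsil_disease", [], ["J35"]),
]


def default_dictionary(scope_tokens: int = 5) -> list[ConceptRule]:
    """Build the shipped default dictionary with shared context cue lists."""
    return [
        ConceptRule(
            concept_id=cid,
            keywords=list(kws),
            icd_prefixes=list(prefixes),
            negation_cues=list(DEFAULT_NEGATION_CUES),
            family_cues=list(DEFAULT_FAMILY_CUES),
            resolved_cues=list(DEFAULT_RESOLVED_CUES),
            scope_tokens=scope_tokens,
        )
        for cid, kws, prefixes in _ENTRIES
    ]
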