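"""Rule-based information extraction from clinical note text.

Two complementary extraction methods are implemented:

1. **Direct ICD-10 code search** — any token in the note matching the ICD-10
   lexical shape (letter, two digits, optional subcode such as ``J32.0``)
   counts as evidence for the corresponding diagnosis; no context analysis is
   applied to code matches.
2. **Keyword search with rule-based validation** — dictionary keywords are
   located in tokenized sentences and each occurrence is assigned a polarity
   (*affirmed*, *negated*, *family*, *resolved*) from context cues: a negation
   or resolved-status cue fires when it appears in the same sentence at most
   ``scope_tokens`` tokens before the keyword, a family-history cue fires
   anywhere in the sentence.  Precedence is negated > family > resolved >
   affirmed.  Only affirmed mentions count as evidence for a diagnosis.

The engine is language-agnostic: keywords and cues are plain configured
strings, matched token-exact after lowercasing (no stemming).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rhinoreg.errors import ValidationError

__all__ = [
    "ConceptRule",
    "ConceptMention",
    "tokenize",
    "find_icd_codes_in_text",
    "detect_concept",
    "extract_patient_concepts",
    "load_dictionary",
    "dump_mentions",
]

#: ICD-10 lexical shape: letter, two digits, optional "." plus 1-2 characters.
ICD_CODE_RE = re.compile(r"^[a-z][0-9]{2}(?:\.[a-z0-9]{1,2})?$")

# Token scan: code-like tokens (letter + 2 digits + dotted subcode) are kept
# intact so the "." inside "j33.1" is not a sentence boundary; other tokens
# keep internal hyphens; bare ".", "!", "?" and newlines terminate sentences.
_TOKEN_RE = re.compile(
    r"[A-Za-z][0-9]{2}\.[A-Za-z0-9]{1,2}"
    r"|[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*"
    r"|[.!?\n]"
)

_SENTENCE_DELIMS = {".", "!", "?", "\n"}

_POLARITIES = ("affirmed", "negated", "family", "resolved")


@dataclass
class ConceptRule:
    """Dictionary entry driving extraction of one clinical concept.

    A rule must carry at least one keyword or one ICD-10 prefix.  Cue lists
    may be empty; ``scope_tokens`` bounds how far (in tokens, within one
    sentence) a negation or resolved cue may precede a keyword and still
    apply to it.
    """

    concept_id: str
    keywords: list[str] = field(default_factory=list)
    icd_prefixes: list[str] = field(default_factory=list)
    negation_cues: list[str] = field(default_factory=list)
    family_cues: list[str] = field(default_factory=list)
    resolved_cues: list[str] = field(default_factory=list)
    scope_tokens: int = 5

    def __post_init__(self) -> None:
        if not self.keywords and not self.icd_prefixes:
            raise ValidationError(
                f"rule {self.concept_id!r}: keywords and icd_prefixes both empty"
            )
        if self.scope_tokens < 1:
            raise ValidationError(
                f"rule {self.concept_id!r}: scope_tokens must be >= 1"
            )
        self.keywords = [k.lower() for k in self.keywords]
        self.negation_cues = [c.lower() for c in self.negation_cues]
        self.family_cues = [c.lower() for c in self.family_cues]
        self.resolved_cues = [c.lower() for c in self.resolved_cues]


@dataclass(frozen=True)
class ConceptMention:
    """One keyword or in-text code occurrence with its context polarity."""

    concept_id: str
    visit_id: str | None
    matched_text: str
    polarity: str  # affirmed | negated | family | resolved
    source: str  # "keyword" | "code_in_text"

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if self.source == "code_in_text" and self.polarity != "affirmed":
            raise ValidationError("code_in_text mentions are always affirmed")


def tokenize(text: str) -> list[list[str]]:
    """Split ``text`` into sentences of lowercase tokens.

    Sentence boundaries are ``.``, ``!``, ``?`` and newlines; tokens split on
    non-alphanumeric boundaries except internal hyphens, and internal periods
    of code-like tokens (``J33.1``) which are preserved intact.
    """
    sentences: list[list[str]] = []
    current: list[str] = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        if tok in _SENTENCE_DELIMS:
            if current:
                sentences.append(current)
                current = []
        else:
            current.append(tok.lower())
    if current:
        sentences.append(current)
    return sentences


def find_icd_codes_in_text(text: str) -> set[str]:
    """Return every code-shaped token in ``text``, uppercased and deduplicated.

    This is extraction method 1: a code found anywhere in the chart text sets
    the matching disease flag, with no polarity analysis.
    """
    codes: set[str] = set()
    for sentence in tokenize(text):
        for tok in sentence:
            if ICD_CODE_RE.match(tok):
                codes.add(tok.upper())
    return codes


def _find_phrase(sentence: Sequence[str], phrase: Sequence[str]) -> list[int]:
    """Start indices of contiguous occurrences of ``phrase`` in ``sentence``."""
    n, k = len(sentence), len(phrase)
    return [
        i for i in range(n - k + 1) if list(sentence[i : i + k]) == list(phrase)
    ]


def _cue_positions(sentence: Sequence[str], cues: Iterable[str]) -> list[tuple[int, int]]:
    """(start, end-exclusive) spans of every cue occurrence in the sentence."""
    spans: list[tuple[int, int]] = []
    for cue in cues:
        toks = cue.split()
        for start in _find_phrase(sentence, toks):
            spans.append((start, start + len(toks)))
    return spans


def detect_concept(text: str, rule: ConceptRule, visit_id: str | None = None) -> list[ConceptMention]:
    """Locate keyword occurrences of ``rule`` in ``text`` and classify polarity.

    One mention is emitted per keyword occurrence.  A negation or resolved cue
    applies when its last token lies 1..``scope_tokens`` tokens before the
    keyword start within the same sentence; a family cue applies anywhere in
    the sentence.  Precedence: negated > family > resolved > affirmed.
    """
    mentions: list[ConceptMention] = []
    for sentence in tokenize(text):
        neg_spans = _cue_positions(sentence, rule.negation_cues)
        fam_spans = _cue_positions(sentence, rule.family_cues)
        res_spans = _cue_positions(sentence, rule.resolved_cues)
        for kw in rule.keywords:
            kw_toks = kw.split()
            for start in _find_phrase(sentence, kw_toks):
                def _in_scope(spans: list[tuple[int, int]]) -> bool:
                    return any(
                        1 <= start - end + 1 <= rule.scope_tokens
                        for _, end in spans
                        if end <= start
                    )

                if _in_scope(neg_spans):
                    polarity = "negated"
                elif fam_spans:
                    polarity = "family"
                elif _in_scope(res_spans):
                    polarity = "resolved"
                else:
                    polarity = "affirmed"
                mentions.append(
                    ConceptMention(
                        concept_id=rule.concept_id,
                        visit_id=visit_id,
                        matched_text=" ".join(sentence[start : start + len(kw_toks)]),
                        polarity=polarity,
                        source="keyword",
                    )
                )
    return mentions


def _code_matches_prefixes(code: str, prefixes: Iterable[str]) -> bool:
    code = code.upper()
    return any(code == p.upper() or code.startswith(p.upper()) for p in prefixes)


def extract_patient_concepts(
    visits: Sequence,
    dictionary: Sequence[ConceptRule],
) -> dict[str, bool]:
    """Patient-level concept flags from coded visits and note texts.

    A concept is True iff (a) any visit carries — in its coded field or as a
    code written inside the note text — a code matching one of the rule's
    ICD-10 prefixes, or (b) any note yields an affirmed keyword mention.
    Negated, family-history, or resolved mentions alone never set a flag.

    ``visits`` must all belong to one patient.
    """
    patient_ids = {v.patient_id for v in visits}
    if len(patient_ids) > 1:
        raise ValidationError(f"visits span multiple patients: {sorted(patient_ids)}")

    all_codes: set[str] = set()
    for v in visits:
        all_codes.update(c.upper() for c in v.icd_codes)
        if v.note_text:
            all_codes.update(find_icd_codes_in_text(v.note_text))

    flags: dict[str, bool] = {}
    for rule in dictionary:
        hit = any(_code_matches_prefixes(c, rule.icd_prefixes) for c in all_codes)
        if not hit and rule.keywords:
            for v in visits:
                if not v.note_text:
                    continue
                if any(
                    m.polarity == "affirmed"
                    for m in detect_concept(v.note_text, rule, visit_id=v.visit_id)
                ):
                    hit = True
                    break
        flags[rule.concept_id] = hit
    return flags


# ---------------------------------------------------------------------------
# serialization


def load_dictionary(path) -> list[ConceptRule]:
    """Read a concept dictionary from a YAML or JSON file (list of rules)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError("dictionary file must contain a list of rules")
    return [ConceptRule(**entry) for entry in raw]


def dump_mentions(mentions: Iterable[ConceptMention], path) -> None:
    """Write mentions as JSONL, one object per mention."""
    with open(path, "w") as fh:
        for m in mentions:
            fh.write(json.dumps(m.__dict__) + "\n")
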