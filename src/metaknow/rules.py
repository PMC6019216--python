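"""Rule-based components.

Three rule systems live here:

1. **Uncertainty binarization** — the three certainty levels (L1
   possible, L2 probable, L3 certain) collapse to a binary distinction:
   L3 -> Certain, L1/L2 -> Uncertain.

2. **Knowledge Source detection** — rule-only (a learned detector
   overfits the overwhelming Current majority): a sentence is attributed
   to *Other* (background/cited work) iff a citation regex or a
   background-knowledge clue phrase fires, else *Current*.

3. **Hyperdimension inference baseline** — infer the hyperdimensions
   from core meta-knowledge values: an association is New Knowledge iff
   Knowledge Source = Current, certainty = L3 and Knowledge Type is
   Observation or Analysis; it is a Research Hypothesis iff Knowledge
   Type = Analysis and certainty is L1 or L2.  The two rules can never
   fire together (one needs L3, the other L1/L2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List

from .corpus_io import CERTAINTY_LEVELS, MKRecord

__all__ = [
    "SourcePatternSet",
    "binarize_uncertainty",
    "detect_knowledge_source",
    "baseline_new_knowledge",
    "baseline_hypothesis",
]

#: bracketed integer citation lists, e.g. "[12]" or "[3, 4]"
_BRACKET_CITATION = r"\[\d+(,\s*\d+)*\]"
#: author-year parentheticals, e.g. "(Smith et al., 2004)"
_AUTHOR_YEAR = r"\([A-Z][A-Za-z-]+( et al\.)?,? (19|20)\d{2}\)"

_DEFAULT_BACKGROUND_CLUES = [
    "we previously showed",
    "we have previously shown",
    "previously shown",
    "as shown previously",
    "as seen in our former work",
    "our former work",
    "previous studies",
    "previous work",
    "earlier studies",
    "it is known",
    "it is well known",
    "well established",
    "has been reported",
    "has been shown",
    "have been shown",
]


@dataclass
class SourcePatternSet:
    """Citation regexes + background-knowledge clue phrases.

    Default patterns are a documented reconstruction (the exact
    published lists are not reproduced here) and fully replaceable via
    :meth:`from_file`: one pattern per line, ``re:`` prefix for
    regexes, bare lines are literal clue phrases.
    """

    citation_regexes: List[str] = field(
        default_factory=lambda: [_BRACKET_CITATION, _AUTHOR_YEAR]
    )
    background_clues: List[str] = field(
        default_factory=lambda: list(_DEFAULT_BACKGROUND_CLUES)
    )

    def __post_init__(self) -> None:
        if not self.citation_regexes and not self.background_clues:
            raise ValueError("pattern set must contain at least one pattern")
        self._compiled = [re.compile(p) for p in self.citation_regexes]

    @classmethod
    def from_file(cls, source) -> "SourcePatternSet":
        content = source.read() if hasattr(source, "read") else open(source).read()
        regexes, clues = [], []
        for line in content.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("re:"):
                regexes.append(line[3:])
            else:
                clues.append(line.lower())
        return cls(citation_regexes=regexes, background_clues=clues)


def binarize_uncertainty(level: str) -> str:
    """Collapse a certainty level: L3 -> Certain, L1/L2 -> Uncertain."""
    if level == "L3":
        return "Certain"
    if level in ("L1", "L2"):
        return "Uncertain"
    raise ValueError(f"unknown certainty level {level!r}; expected one of {CERTAINTY_LEVELS}")


def detect_knowledge_source(sentence: str, patterns: SourcePatternSet = None) -> str:
    """Classify a sentence's knowledge source as ``Current`` or ``Other``.

    ``Other`` iff any citation regex or background clue fires; the check
    is idempotent and insensitive to surrounding whitespace.
    """
    if patterns is None:
        patterns = SourcePatternSet()
    text = sentence.strip()
    for rx in patterns._compiled:
        if rx.search(text):
            return "Other"
    lowered = text.lower()
    for clue in patterns.background_clues:
        if clue in lowered:
            return "Other"
    return "Current"


def _require(mk: MKRecord, *fields: str) -> None:
    missing = [f for f in fields if getattr(mk, f) is None]
    if missing:
        raise ValueError(f"missing meta-knowledge dimension(s): {', '.join(missing)}")


def baseline_new_knowledge(mk: MKRecord) -> bool:
    """Inference rule: Current source, certain (L3), Observation/Analysis type."""
    _require(mk, "knowledge_source", "certainty", "knowledge_type")
    return (
        mk.knowledge_source == "Current"
        and mk.certainty == "L3"
        and mk.knowledge_type in ("Observation", "Analysis")
    )


def baseline_hypothesis(mk: MKRecord) -> bool:
    """Inference rule: Analysis type with uncertain (L1/L2) certainty."""
    _require(mk, "knowledge_type", "certainty")
    return mk.knowledge_type == "Analysis" and mk.certainty in ("L1", "L2")
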