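"""Clue lexicons: loading, and matching clues inside sentences.

A clue is a word or phrase evidencing a meta-knowledge value ("suggest"
for Uncertainty, "we examined" for an Investigation-type statement).
Lexicons are TSV files with columns::

    pattern <TAB> dimension <TAB> value <TAB> kt_context <TAB> is_regex

``dimension`` is one of KnowledgeType / KnowledgeSource / Uncertainty;
``kt_context`` is a comma list of Knowledge Type values the clue usually
occurs in the context of (feeds the L11–L15 features); ``is_regex``
marks patterns matched as regular expressions against single tokens
(used for citation-style Knowledge Source clues).

Matching is token-based, case-insensitive, longest-match-first and
non-overlapping.  A small default lexicon ships with the package and is
fully user-replaceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

from .corpus_io import KNOWLEDGE_TYPES, Span
from .linguistic import Token

__all__ = [
    "ClueEntry",
    "ClueMatch",
    "ClueLexicon",
    "load_lexicon",
    "default_lexicon",
    "match_clues",
    "nearest_clue",
]

_DIMENSION_VALUES = {
    "KnowledgeType": set(KNOWLEDGE_TYPES),
    "KnowledgeSource": {"Current", "Other"},
    "Uncertainty": {"Certain", "Uncertain"},
}

_BE_FORMS = {"be", "am", "is", "are", "was", "were", "been", "being"}
_HAVE_FORMS = {"have", "has", "had", "having"}
_DO_FORMS = {"do", "does", "did"}


@dataclass(frozen=True)
class ClueEntry:
    """One lexicon entry; ``pattern`` is stored lowercased."""

    pattern: str
    dimension: str
    value: str
    kt_context: frozenset = frozenset()
    is_regex: bool = False

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("clue pattern must be non-empty")
        if self.dimension not in _DIMENSION_VALUES:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.value not in _DIMENSION_VALUES[self.dimension]:
            raise ValueError(
                f"illegal value {self.value!r} for dimension {self.dimension!r}"
            )
        bad = set(self.kt_context) - set(KNOWLEDGE_TYPES)
        if bad:
            raise ValueError(f"illegal kt_context values {sorted(bad)}")

    @property
    def n_words(self) -> int:
        return len(self.pattern.split())

    @property
    def key(self) -> str:
        return f"{self.dimension}:{self.pattern}"


@dataclass(frozen=True)
class ClueMatch:
    """A lexicon entry matched over consecutive sentence tokens.

    Tense/aspect/voice and auxiliary form are heuristic, computed from
    the POS tag of the match head and its left neighbours:
    VBD/VBN -> past; have-form + VBN -> perfect; be-form + VBN ->
    passive; auxiliary iff tagged MD or a form of be/have/do.
    """

    entry: ClueEntry
    span: Span
    token_range: Tuple[int, int]  # inclusive first/last token indices
    tense: str = "present"
    aspect: str = "simple"
    voice: str = "active"
    auxiliary_form: bool = False

    def token_indices(self) -> range:
        return range(self.token_range[0], self.token_range[1] + 1)


class ClueLexicon:
    """Validated, de-duplicated collection of :class:`ClueEntry`."""

    def __init__(self, entries: Iterable[ClueEntry]):
        seen = {}
        for entry in entries:
            seen[(entry.pattern, entry.dimension, entry.value)] = entry
        # deterministic order independent of source file order
        self.entries: List[ClueEntry] = sorted(
            seen.values(), key=lambda e: (e.dimension, e.pattern, e.value)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def for_dimension(self, dimension: str) -> List[ClueEntry]:
        return [e for e in self.entries if e.dimension == dimension]

    def indicator_keys(self) -> List[str]:
        """Stable per-entry keys for the L-N clue indicator block."""
        return sorted({e.key for e in self.entries})


def load_lexicon(source) -> ClueLexicon:
    """Load a TSV lexicon (path, file-like, or raw string content)."""
    if hasattr(source, "read"):
        content = source.read()
    else:
        text = str(source)
        if "\t" in text or "\n" in text or text == "":
            content = text
        else:
            with open(text, "r") as fh:
                content = fh.read()
    entries = []
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise ValueError(f"line {lineno}: expected at least 3 tab-separated columns")
        pattern, dimension, value = cols[0].strip().lower(), cols[1].strip(), cols[2].strip()
        kt_context = frozenset(
            v.strip() for v in (cols[3].split(",") if len(cols) > 3 and cols[3].strip() else [])
        )
        is_regex = len(cols) > 4 and cols[4].strip().lower() in ("1", "true", "yes")
        try:
            entries.append(ClueEntry(pattern, dimension, value, kt_context, is_regex))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return ClueLexicon(entries)


def default_lexicon() -> ClueLexicon:
    """The small lexicon shipped with the package (~20 entries/dimension)."""
    data = resources.files("metaknow.data").joinpath("default_lexicon.tsv").read_text()
    return ClueLexicon(load_lexicon(data).entries)


def _morphosyntax(tokens: Sequence[Token], first: int):
    """Heuristic tense/aspect/voice/auxiliary of the clue starting at ``first``."""
    tok = tokens[first]
    surface = tok.surface.lower()
    tense = "past" if tok.pos in ("VBD", "VBN") else "present"
    aspect, voice = "simple", "active"
    if tok.pos == "VBN":
        for j in range(first - 1, max(first - 3, -1), -1):
            prev = tokens[j].surface.lower()
            if prev in _HAVE_FORMS:
                aspect = "perfect"
                break
            if prev in _BE_FORMS:
                voice = "passive"
                break
            if tokens[j].pos not in ("RB", "RBR", "RBS"):
                break
    auxiliary = tok.pos == "MD" or surface in (_BE_FORMS | _HAVE_FORMS | _DO_FORMS)
    return tense, aspect, voice, auxiliary


def match_clues(
    tokens: Sequence[Token],
    lexicon: ClueLexicon,
    dimensions: Optional[Iterable[str]] = None,
) -> List[ClueMatch]:
    """Find all clue matches in a token sequence.

    Case-insensitive; multi-word patterns match over consecutive tokens;
    longest match wins at each position and matches never overlap.  The
    result is sorted by position and independent of lexicon file order.
    """
    wanted = set(dimensions) if dimensions is not None else None
    entries = [e for e in lexicon if wanted is None or e.dimension in wanted]
    plain = sorted(
        (e for e in entries if not e.is_regex),
        key=lambda e: (-e.n_words, e.pattern, e.dimension),
    )
    regexes = [(e, re.compile(e.pattern)) for e in entries if e.is_regex]

    lowered = [t.surface.lower() for t in tokens]
    matches: List[ClueMatch] = []
    i = 0
    while i < len(tokens):
        hit = None
        for entry in plain:
            words = entry.pattern.split()
            j = i + len(words)
            if j <= len(tokens) and lowered[i:j] == words:
                hit = (entry, i, j - 1)
                break
        if hit is None:
            for entry, rx in sorted(regexes, key=lambda er: er[0].pattern):
                if rx.fullmatch(tokens[i].surface):
                    hit = (entry, i, i)
                    break
        if hit is None:
            i += 1
            continue
        entry, first, last = hit
        tense, aspect, voice, aux = _morphosyntax(tokens, first)
        matches.append(
            ClueMatch(
                entry=entry,
                span=Span(tokens[first].span.start, tokens[last].span.end),
                token_range=(first, last),
                tense=tense,
                aspect=aspect,
                voice=voice,
                auxiliary_form=aux,
            )
        )
        i = last + 1
    return matches


def nearest_clue(
    matches: Sequence[ClueMatch], trigger_index: int
) -> Optional[Tuple[ClueMatch, int]]:
    """The match closest (in tokens) to the trigger; ties broken leftmost.

    Distance is the minimal absolute token distance from the trigger to
    any token of the match — 0 when the clue lies inside the trigger
    phrase.  Returns None when there are no matches.
    """
    if trigger_index < 0:
        raise ValueError("trigger index must be non-negative")
    best = None
    for m in matches:
        first, last = m.token_range
        if first <= trigger_index <= last:
            dist = 0
        else:
            dist = min(abs(trigger_index - first), abs(trigger_index - last))
        if best is None or dist < best[1]:
            best = (m, dist)
    return best
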