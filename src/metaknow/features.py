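"""The seven feature families for meta-knowledge classification.

Feature groups (names follow the field's convention for this task):

- sentence   SE1–SE10  : length and POS-class ratio features
- structural ST1–ST7   : event-structure features
- participant PA1–PA6  : participant POS / nesting features
- lexical    L1–L16 + L-N indicator block : clue-based features
- constituency C1–C7   : clue x-commands trigger/participants
- dependency D1–D6     : clue↔trigger/participant path lengths 1/2/3
- parse_tree PT1–PT4   : theme/cause leaf distances to furthest leaf/root
- mk_extra             : core meta-knowledge values (knowledge source,
  knowledge type, binarized uncertainty), used only by the
  hyperdimension classifiers

Conventions for degenerate inputs: POS ratios with a zero denominator
emit the sentinel -1; missing clue distances emit -1 (L1) or -9999 (L5,
a signed offset); categorical absences emit the string "NONE"; boolean
features default to False.  Relations receive static structural values
(a relation always has exactly one theme-slot and one cause-slot:
arg2/arg1) and are anchored at their first argument for clue-distance
purposes.

Categorical features are one-hot encoded downstream (the model module
uses a DictVectorizer whose vocabulary is frozen on the training split).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from statistics import mean, median
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus_io import Association, Document, Event, Relation, Span
from .lexicon import ClueLexicon, ClueMatch, match_clues, nearest_clue
from .linguistic import (
    LinguisticLayer,
    dep_path_length,
    pos_class,
    same_minimal_scope,
    tree_distance,
    x_commands,
)
from .rules import binarize_uncertainty

__all__ = [
    "GROUPS",
    "FeatureConfig",
    "FeatureVector",
    "sentence_features",
    "structural_features",
    "participant_features",
    "lexical_features",
    "constituency_features",
    "dependency_features",
    "parse_tree_features",
    "mk_extra_features",
    "assemble",
    "vectors_to_frame",
]

GROUPS = (
    "sentence",
    "structural",
    "participant",
    "lexical",
    "constituency",
    "dependency",
    "parse_tree",
    "mk_extra",
)

ABSENT_NUM = -1
ABSENT_OFFSET = -9999  # L5 is a signed offset; sentence lengths never approach this
ABSENT_CAT = "NONE"


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature groups to assemble.

    The default configuration for Knowledge Type uses every group except
    the participant features; the hyperdimension configuration
    additionally appends the mk_extra group.
    """

    sentence: bool = True
    structural: bool = True
    participant: bool = True
    lexical: bool = True
    constituency: bool = True
    dependency: bool = True
    parse_tree: bool = True
    mk_extra: bool = False

    @classmethod
    def all_features(cls) -> "FeatureConfig":
        return cls()

    @classmethod
    def knowledge_type_default(cls) -> "FeatureConfig":
        return cls(participant=False)

    @classmethod
    def hyperdimension(cls) -> "FeatureConfig":
        return cls(participant=False, mk_extra=True)

    @classmethod
    def only(cls, group: str) -> "FeatureConfig":
        if group not in GROUPS:
            raise ValueError(f"unknown feature group {group!r}")
        return cls(**{g: (g == group) for g in GROUPS})

    @classmethod
    def all_except(cls, group: str) -> "FeatureConfig":
        """All seven base groups except ``group`` (mk_extra stays off)."""
        if group not in GROUPS:
            raise ValueError(f"unknown feature group {group!r}")
        kwargs = {g: (g != group) for g in GROUPS}
        kwargs["mk_extra"] = False
        return cls(**kwargs)

    def enabled(self) -> Tuple[str, ...]:
        return tuple(g for g in GROUPS if getattr(self, g))


@dataclass
class FeatureVector:
    """Named features in stable order, with group membership recorded."""

    features: Dict[str, object]
    groups: Dict[str, Tuple[str, ...]]
    config: FeatureConfig

    def to_dict(self) -> Dict[str, object]:
        return dict(self.features)

    def __getitem__(self, name: str):
        return self.features[name]

    def serialize(self) -> str:
        """Deterministic textual form (used for bitwise-identity checks)."""
        return "".join(f"{k}={self.features[k]!r}" for k in self.features)


# ---------------------------------------------------------------------------
# helpers


def _layer_for(assoc: Association, doc: Document) -> LinguisticLayer:
    layer = doc.linguistic.get(assoc.sentence_index)
    if layer is None:
        raise ValueError(
            f"linguistic layer missing for sentence {assoc.sentence_index} "
            f"of document {doc.id!r}"
        )
    return layer


def _require_tree(layer: LinguisticLayer, group: str):
    if layer.tree is None:
        raise ValueError(f"constituency tree missing (needed by {group} features)")
    return layer.tree


def _require_dep(layer: LinguisticLayer, group: str):
    if layer.dep is None:
        raise ValueError(f"dependency graph missing (needed by {group} features)")
    return layer.dep


def token_range_for_span(layer: LinguisticLayer, span: Span) -> List[int]:
    """Indices of tokens whose character spans overlap ``span``."""
    return [t.index for t in layer.tokens if t.span.overlaps(span)]


def head_token(layer: LinguisticLayer, indices: Sequence[int]) -> Optional[int]:
    """Head of a multi-token span: the token whose dependency head lies
    outside the span (fallback: the last token)."""
    if not indices:
        return None
    if len(indices) == 1 or layer.dep is None:
        return indices[-1] if len(indices) > 1 else indices[0]
    inside = set(indices)
    for idx in indices:
        head = layer.dep.head_of(idx)
        if head is None or head not in inside:
            return idx
    return indices[-1]


def _anchor_span(assoc: Association, doc: Document) -> Span:
    """Trigger span of an event; first-argument span of a relation."""
    if assoc.kind == "event":
        return assoc.payload.trigger
    return doc.entity_map()[assoc.payload.arg1].span


def _participant_span(ref: str, doc: Document) -> Optional[Span]:
    ent = doc.entity_map().get(ref)
    if ent is not None:
        return ent.span
    ev = doc.event_map().get(ref)
    if ev is not None:
        return ev.trigger
    raise ValueError(f"unresolved participant reference {ref!r}")


def _theme_cause_refs(assoc: Association) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    if assoc.kind == "event":
        return tuple(assoc.payload.themes), tuple(assoc.payload.causes)
    # relation: arg2 fills the theme slot, arg1 the cause slot
    return (assoc.payload.arg2,), (assoc.payload.arg1,)


def _head_of_ref(ref: Optional[str], assoc: Association, doc: Document,
                 layer: LinguisticLayer) -> Optional[int]:
    if ref is None:
        return None
    span = _participant_span(ref, doc)
    return head_token(layer, token_range_for_span(layer, span))


# ---------------------------------------------------------------------------
# feature families


def sentence_features(layer: LinguisticLayer) -> Dict[str, object]:
    """SE1–SE10: sentence length and pairwise POS-class ratios."""
    tokens = layer.tokens
    out: Dict[str, object] = {}
    out["SE1"] = len(tokens)
    out["SE2"] = (tokens[-1].span.end - tokens[0].span.start) if tokens else 0
    word_lens = [len(t.surface) for t in tokens]
    out["SE3"] = float(mean(word_lens)) if word_lens else float(ABSENT_NUM)
    out["SE4"] = float(median(word_lens)) if word_lens else float(ABSENT_NUM)
    counts = {"noun": 0, "verb": 0, "adjective": 0, "adverb": 0}
    for t in tokens:
        cls = pos_class(t.pos)
        if cls is not None:
            counts[cls] += 1

    def ratio(a: str, b: str) -> float:
        return counts[a] / counts[b] if counts[b] else float(ABSENT_NUM)

    out["SE5"] = ratio("noun", "verb")
    out["SE6"] = ratio("noun", "adjective")
    out["SE7"] = ratio("noun", "adverb")
    out["SE8"] = ratio("verb", "adjective")
    out["SE9"] = ratio("verb", "adverb")
    out["SE10"] = ratio("adjective", "adverb")
    return out


#: static structural values used for binary relations
RELATION_STATIC_ST = {
    "ST1": False, "ST3": False, "ST4": False, "ST5": False, "ST6": 1, "ST7": 1,
}


def structural_features(assoc: Association, doc: Document) -> Dict[str, object]:
    """ST1–ST7: event-structure features (static values for relations)."""
    out: Dict[str, object] = {}
    if assoc.kind == "relation":
        out["ST1"] = RELATION_STATIC_ST["ST1"]
        out["ST2"] = assoc.sentence_index
        for key in ("ST3", "ST4", "ST5", "ST6", "ST7"):
            out[key] = RELATION_STATIC_ST[key]
        return out
    ev: Event = assoc.payload
    event_ids = set(doc.event_map())
    out["ST1"] = any(ref in event_ids for ref in ev.participants)
    out["ST2"] = assoc.sentence_index
    out["ST3"] = any(ev.id in other.participants for other in doc.events if other.id != ev.id)
    out["ST4"] = _trigger_is_np(assoc, doc)
    out["ST5"] = "regulation" in ev.etype.lower()
    out["ST6"] = len(ev.themes)
    out["ST7"] = len(ev.causes)
    return out


def _trigger_is_np(assoc: Association, doc: Document) -> bool:
    """Whether the trigger heads a noun phrase (constituency if present,
    else the POS tag of the trigger head token)."""
    layer = doc.linguistic.get(assoc.sentence_index)
    if layer is None:
        return False
    indices = token_range_for_span(layer, _anchor_span(assoc, doc))
    head = head_token(layer, indices)
    if head is None:
        return False
    if layer.tree is not None:
        leaf = layer.tree.leaf(head)
        parent = layer.tree.parent(leaf)
        if parent is not None:
            return parent.label.split("-")[0] == "NP"
    return pos_class(layer.tokens[head].pos) == "noun"


def participant_features(assoc: Association, doc: Document) -> Dict[str, object]:
    """PA1–PA6: POS and nesting of the first theme/cause."""
    layer = _layer_for(assoc, doc)
    themes, causes = _theme_cause_refs(assoc)
    event_ids = set(doc.event_map())
    out: Dict[str, object] = {}
    th_head = _head_of_ref(themes[0] if themes else None, assoc, doc, layer)
    ca_head = _head_of_ref(causes[0] if causes else None, assoc, doc, layer)
    out["PA1"] = layer.tokens[th_head].pos if th_head is not None else ABSENT_CAT
    out["PA2"] = layer.tokens[ca_head].pos if ca_head is not None else ABSENT_CAT
    out["PA3"] = any(ref in event_ids for ref in themes)
    out["PA4"] = any(ref in event_ids for ref in causes)

    def governor_pos(head: Optional[int]) -> str:
        if head is None or layer.dep is None:
            return ABSENT_CAT
        gov = layer.dep.head_of(head)
        return layer.tokens[gov].pos if gov is not None else ABSENT_CAT

    out["PA5"] = governor_pos(th_head)
    out["PA6"] = governor_pos(ca_head)
    return out


KT_CONTEXT_FLAGS = ("Observation", "Investigation", "Analysis", "Method", "Fact")


def lexical_features(
    assoc: Association,
    doc: Document,
    lexicon: ClueLexicon,
    matches: Optional[List[ClueMatch]] = None,
) -> Dict[str, object]:
    """L1–L16 plus the per-entry L-N clue indicator block."""
    layer = _layer_for(assoc, doc)
    if matches is None:
        matches = match_clues(layer.tokens, lexicon)
    anchor = _anchor_span(assoc, doc)
    trig_range = token_range_for_span(layer, anchor)
    trig_head = head_token(layer, trig_range)

    out: Dict[str, object] = {}
    near = nearest_clue(matches, trig_head) if trig_head is not None else None
    out["L1"] = near[1] if near is not None else ABSENT_NUM
    out["L2"] = bool(matches)
    out["L3"] = near[0].entry.pattern if near else ABSENT_CAT
    out["L4"] = layer.tokens[near[0].token_range[0]].pos if near else ABSENT_CAT
    out["L5"] = (near[0].token_range[0] - trig_head) if near else ABSENT_OFFSET
    out["L6"] = near[0].auxiliary_form if near else False
    trig_set = set(trig_range)
    out["L7"] = any(set(m.token_indices()) & trig_set for m in matches)
    out["L8"] = near[0].tense if near else ABSENT_CAT
    out["L9"] = near[0].aspect if near else ABSENT_CAT
    out["L10"] = near[0].voice if near else ABSENT_CAT
    context = near[0].entry.kt_context if near else frozenset()
    for i, kt in enumerate(KT_CONTEXT_FLAGS, start=11):
        out[f"L{i}"] = kt in context
    out["L16"] = len(matches)
    matched_keys = {m.entry.key for m in matches}
    for key in lexicon.indicator_keys():
        out[f"LN[{key}]"] = key in matched_keys
    return out


def constituency_features(
    assoc: Association,
    doc: Document,
    matches: List[ClueMatch],
) -> Dict[str, object]:
    """C1–C7: x-command relations between clues and trigger/participants."""
    layer = _layer_for(assoc, doc)
    tree = _require_tree(layer, "constituency")
    trig_head = head_token(layer, token_range_for_span(layer, _anchor_span(assoc, doc)))
    themes, causes = _theme_cause_refs(assoc)
    part_heads = [
        h for h in (_head_of_ref(r, assoc, doc, layer) for r in themes + causes)
        if h is not None
    ]
    clue_tokens = [i for m in matches for i in m.token_indices()]

    def any_command(targets: Sequence[int], category: str) -> bool:
        return any(
            x_commands(tree, c, t, category) for c in clue_tokens for t in targets
        )

    trig_targets = [trig_head] if trig_head is not None else []
    out: Dict[str, object] = {}
    for i, cat in enumerate(("S", "VP", "NP"), start=1):
        out[f"C{i}"] = any_command(trig_targets, cat)
    for i, cat in enumerate(("S", "VP", "NP"), start=4):
        out[f"C{i}"] = any_command(part_heads, cat)
    out["C7"] = any(
        same_minimal_scope(tree, c, t, "S") for c in clue_tokens for t in trig_targets
    )
    return out


def dependency_features(
    assoc: Association,
    doc: Document,
    matches: List[ClueMatch],
) -> Dict[str, object]:
    """D1–D6: direct/one-hop/two-hop dependencies (path lengths 1/2/3)."""
    layer = _layer_for(assoc, doc)
    dep = _require_dep(layer, "dependency")
    trig_head = head_token(layer, token_range_for_span(layer, _anchor_span(assoc, doc)))
    themes, causes = _theme_cause_refs(assoc)
    part_heads = [
        h for h in (_head_of_ref(r, assoc, doc, layer) for r in themes + causes)
        if h is not None
    ]
    clue_tokens = [i for m in matches for i in m.token_indices()]

    def lengths(targets: Sequence[int]) -> set:
        return {
            dep_path_length(dep, c, t) for c in clue_tokens for t in targets
        }

    trig_lengths = lengths([trig_head] if trig_head is not None else [])
    part_lengths = lengths(part_heads)
    out: Dict[str, object] = {}
    out["D1"] = 1 in trig_lengths
    out["D2"] = 1 in part_lengths
    out["D3"] = 2 in trig_lengths
    out["D4"] = 2 in part_lengths
    out["D5"] = 3 in trig_lengths
    out["D6"] = 3 in part_lengths
    return out


def parse_tree_features(assoc: Association, doc: Document) -> Dict[str, object]:
    """PT1–PT4: theme/cause head-leaf distances to furthest leaf and root."""
    layer = _layer_for(assoc, doc)
    tree = _require_tree(layer, "parse_tree")
    themes, causes = _theme_cause_refs(assoc)
    th_head = _head_of_ref(themes[0] if themes else None, assoc, doc, layer)
    ca_head = _head_of_ref(causes[0] if causes else None, assoc, doc, layer)
    out: Dict[str, object] = {}
    out["PT1"] = tree_distance(tree, th_head, "furthest_leaf") if th_head is not None else ABSENT_NUM
    out["PT2"] = tree_distance(tree, ca_head, "furthest_leaf") if ca_head is not None else ABSENT_NUM
    out["PT3"] = tree_distance(tree, th_head, "root") if th_head is not None else ABSENT_NUM
    out["PT4"] = tree_distance(tree, ca_head, "root") if ca_head is not None else ABSENT_NUM
    return out


def mk_extra_features(assoc: Association) -> Dict[str, object]:
    """Core meta-knowledge values as features for the hyperdimension task."""
    mk = assoc.mk
    out: Dict[str, object] = {}
    out["MK_source"] = (mk.knowledge_source if mk and mk.knowledge_source else ABSENT_CAT)
    out["MK_type"] = (mk.knowledge_type if mk and mk.knowledge_type else ABSENT_CAT)
    out["MK_uncertainty"] = (
        binarize_uncertainty(mk.certainty) if mk and mk.certainty else ABSENT_CAT
    )
    return out


# ---------------------------------------------------------------------------
# assembly


def assemble(
    assoc: Association,
    doc: Document,
    lexicon: ClueLexicon,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the configured feature groups into one named vector.

    Groups appear in a fixed order (sentence, structural, participant,
    lexical, constituency, dependency, parse_tree, mk_extra) and the
    serialization order of features within each group is stable, so
    identical inputs yield bitwise-identical serializations.
    """
    enabled = config.enabled()
    needs_layer = set(enabled) & {
        "sentence", "participant", "lexical", "constituency", "dependency", "parse_tree"
    }
    layer = _layer_for(assoc, doc) if needs_layer else None
    matches: Optional[List[ClueMatch]] = None
    if set(enabled) & {"lexical", "constituency", "dependency"}:
        matches = match_clues(layer.tokens, lexicon)

    features: Dict[str, object] = {}
    groups: Dict[str, Tuple[str, ...]] = {}

    def add(group: str, values: Dict[str, object]) -> None:
        overlap = set(values) & set(features)
        if overlap:
            raise ValueError(f"duplicate feature names: {sorted(overlap)}")
        features.update(values)
        groups[group] = tuple(values)

    for group in enabled:
        if group == "sentence":
            add(group, sentence_features(layer))
        elif group == "structural":
            add(group, structural_features(assoc, doc))
        elif group == "participant":
            add(group, participant_features(assoc, doc))
        elif group == "lexical":
            add(group, lexical_features(assoc, doc, lexicon, matches))
        elif group == "constituency":
            add(group, constituency_features(assoc, doc, matches))
        elif group == "dependency":
            add(group, dependency_features(assoc, doc, matches))
        elif group == "parse_tree":
            add(group, parse_tree_features(assoc, doc))
        elif group == "mk_extra":
            add(group, mk_extra_features(assoc))
    return FeatureVector(features, groups, config)


def vectors_to_frame(vectors: Sequence[FeatureVector]):
    """Feature vectors as a pandas DataFrame (CSV-ready, stable columns)."""
    import pandas as pd

    return pd.DataFrame([v.to_dict() for v in vectors])
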