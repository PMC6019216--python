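"""Documents with standoff entity/event/relation annotations and meta-knowledge attributes.

The on-disk format is brat standoff: a plain-text ``.txt`` file plus an
``.ann`` file of tab-separated annotation lines (``T`` text-bound spans,
``E`` events, ``R`` binary relations, ``A`` attributes, ``#`` notes).  The
BioNLP-ST split dialect (``.a1`` entities + ``.a2`` events) is accepted by
concatenating the two streams.

Meta-knowledge values attach to events/relations as ``A`` lines, e.g.::

    A1\tKnowledgeType E1 Observation
    A2\tNewKnowledge E1 Yes

Clue spans (which the ``A`` grammar cannot carry) are serialized as brat
note lines ``#1\tClueSpan E1 Uncertainty 10 17`` so files remain loadable
by standard brat tooling.
"""

from __future__ import annotations

import io
import re
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "KNOWLEDGE_TYPES",
    "KNOWLEDGE_SOURCES",
    "CERTAINTY_LEVELS",
    "POLARITIES",
    "MANNERS",
    "Span",
    "Entity",
    "Event",
    "Relation",
    "MKRecord",
    "Association",
    "Document",
    "StandoffError",
    "read_standoff",
    "write_standoff",
    "load_document",
    "as_association_table",
    "segment_sentences",
]

KNOWLEDGE_TYPES = ("Observation", "Investigation", "Analysis", "Method", "Fact", "Other")
KNOWLEDGE_SOURCES = ("Current", "Other")
CERTAINTY_LEVELS = ("L1", "L2", "L3")
POLARITIES = ("Positive", "Negative")
MANNERS = ("High", "Low", "Neutral")

#: attribute-line names understood by the reader, mapped to MKRecord fields
_MK_ATTRIBUTES = {
    "KnowledgeType": "knowledge_type",
    "KnowledgeSource": "knowledge_source",
    "Polarity": "polarity",
    "Manner": "manner",
    "Certainty": "certainty",
    "NewKnowledge": "new_knowledge",
    "ResearchHypothesis": "research_hypothesis",
}

_MK_VALUES = {
    "knowledge_type": KNOWLEDGE_TYPES,
    "knowledge_source": KNOWLEDGE_SOURCES,
    "polarity": POLARITIES,
    "manner": MANNERS,
    "certainty": CERTAINTY_LEVELS,
}


class StandoffError(ValueError):
    """Malformed or inconsistent standoff annotation."""


@dataclass(frozen=True, order=True)
class Span:
    """Character span, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Entity:
    id: str
    etype: str
    span: Span
    surface: str


@dataclass(frozen=True)
class Event:
    """n-ary event: a trigger phrase plus theme/cause participants.

    Participants are references (entity or event ids); event-valued
    participants are kept as references, never flattened.
    """

    id: str
    etype: str
    trigger: Span
    trigger_surface: str
    themes: tuple = ()
    causes: tuple = ()

    @property
    def participants(self) -> tuple:
        return tuple(self.themes) + tuple(self.causes)


@dataclass(frozen=True)
class Relation:
    id: str
    rtype: str
    arg1: str
    arg2: str


@dataclass
class MKRecord:
    """Meta-knowledge values for one association.

    Five core dimensions (knowledge type/source, polarity, manner,
    certainty) plus the two mutually exclusive hyperdimensions.  ``None``
    means unannotated.
    """

    knowledge_type: Optional[str] = None
    knowledge_source: Optional[str] = None
    polarity: Optional[str] = None
    manner: Optional[str] = None
    certainty: Optional[str] = None
    new_knowledge: Optional[bool] = None
    research_hypothesis: Optional[bool] = None
    clue_spans: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, legal in _MK_VALUES.items():
            value = getattr(self, name)
            if value is not None and value not in legal:
                raise ValueError(f"illegal {name} value {value!r}; expected one of {legal}")
        if self.new_knowledge and self.research_hypothesis:
            raise ValueError(
                "mutual exclusivity violated: an association cannot be both "
                "New Knowledge and Research Hypothesis"
            )


@dataclass
class Association:
    """Unified view of an event or relation — the unit that receives MK labels."""

    kind: str  # "event" | "relation"
    payload: Union[Event, Relation]
    sentence_index: int
    mk: Optional[MKRecord] = None

    @property
    def id(self) -> str:
        return self.payload.id


@dataclass
class Document:
    id: str
    text: str
    sentence_spans: list
    entities: list = field(default_factory=list)
    events: list = field(default_factory=list)
    relations: list = field(default_factory=list)
    associations: list = field(default_factory=list)
    #: per-sentence LinguisticLayer, indexed by sentence position (may be absent)
    linguistic: dict = field(default_factory=dict)

    def entity_map(self) -> dict:
        return {e.id: e for e in self.entities}

    def event_map(self) -> dict:
        return {e.id: e for e in self.events}

    def association_map(self) -> dict:
        return {a.id: a for a in self.associations}

    def sentence_of(self, offset: int) -> int:
        """Index of the sentence whose span contains ``offset``."""
        starts = [s.start for s in self.sentence_spans]
        idx = bisect_right(starts, offset) - 1
        return max(idx, 0)

    def sentence_text(self, index: int) -> str:
        span = self.sentence_spans[index]
        return self.text[span.start : span.end]


_SENT_RE = re.compile(r"[^.!?]*[.!?]+(?:\s+|$)|[^.!?]+$", re.S)


def segment_sentences(text: str) -> list:
    """Naive sentence segmentation: split after ./!/? + whitespace.

    Returned spans tile the text in order without overlap.  Used only
    when no sentence-span information is supplied.
    """
    spans = []
    pos = 0
    for m in _SENT_RE.finditer(text):
        if m.end() > m.start():
            spans.append(Span(m.start(), m.end()))
            pos = m.end()
    if not spans and text:
        spans = [Span(0, len(text))]
    return spans


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _natural_key(ann_id: str):
    m = re.match(r"([A-Za-z#]+)(\d+)$", ann_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (ann_id, 0)


def _parse_bool(value: str) -> bool:
    return value in ("Yes", "True", "true", "1")


def read_standoff(
    text_source,
    ann_source,
    doc_id: str = "doc",
    sentence_spans: Optional[Sequence[Span]] = None,
) -> Document:
    """Parse a brat text + annotation stream pair into a :class:`Document`.

    ``text_source`` / ``ann_source`` may be strings or file-like objects.
    Raises :class:`StandoffError` on dangling references, malformed spans,
    or a hyperdimension mutual-exclusivity violation; unknown attribute
    names produce a warning and are kept as opaque extras.
    """
    text = _as_text(text_source)
    ann = _as_text(ann_source)

    entities: dict = {}
    triggers: dict = {}  # T lines referenced as event triggers
    events: dict = {}
    relations: dict = {}
    mk_by_target: dict = {}
    clue_notes: list = []
    event_lines: list = []

    for lineno, raw in enumerate(ann.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag.startswith("T"):
            if len(parts) < 2:
                raise StandoffError(f"line {lineno}: malformed T line")
            header = parts[1].split(" ")
            if len(header) < 3 or ";" in parts[1]:
                raise StandoffError(f"line {lineno}: overlapping or malformed span in {tag}")
            etype = header[0]
            try:
                start, end = int(header[1]), int(header[2])
            except ValueError as exc:
                raise StandoffError(f"line {lineno}: non-integer offsets") from exc
            if not (0 <= start < end <= len(text)):
                raise StandoffError(
                    f"line {lineno}: span [{start}, {end}) outside document of length {len(text)}"
                )
            surface = parts[2] if len(parts) > 2 else text[start:end]
            if surface != text[start:end]:
                raise StandoffError(
                    f"line {lineno}: surface {surface!r} does not match text "
                    f"{text[start:end]!r} at [{start}, {end})"
                )
            entities[tag] = Entity(tag, etype, Span(start, end), surface)
        elif tag.startswith("E"):
            event_lines.append((lineno, tag, parts))
        elif tag.startswith("R"):
            fields = parts[1].split(" ")
            rtype = fields[0]
            args = dict(f.split(":", 1) for f in fields[1:] if ":" in f)
            if "Arg1" not in args or "Arg2" not in args:
                raise StandoffError(f"line {lineno}: relation {tag} must have Arg1 and Arg2")
            relations[tag] = Relation(tag, rtype, args["Arg1"], args["Arg2"])
        elif tag.startswith("A") or tag.startswith("M"):
            fields = parts[1].split(" ")
            if len(fields) < 2:
                raise StandoffError(f"line {lineno}: malformed attribute line")
            attr, target = fields[0], fields[1]
            value = fields[2] if len(fields) > 2 else "Yes"
            rec = mk_by_target.setdefault(target, {})
            if attr in _MK_ATTRIBUTES:
                fname = _MK_ATTRIBUTES[attr]
                if fname in ("new_knowledge", "research_hypothesis"):
                    rec[fname] = _parse_bool(value)
                else:
                    rec[fname] = value
            else:
                warnings.warn(
                    f"line {lineno}: unknown attribute {attr!r}; stored as opaque extra",
                    stacklevel=2,
                )
                rec.setdefault("extras", {})[attr] = value
        elif tag.startswith("#"):
            # note line; ClueSpan notes round-trip MKRecord.clue_spans
            if len(parts) >= 2 and parts[1].startswith("ClueSpan "):
                fields = parts[1].split(" ")
                if len(fields) != 5:
                    raise StandoffError(f"line {lineno}: malformed ClueSpan note")
                _, target, dim, start, end = fields
                clue_notes.append((target, dim, Span(int(start), int(end))))
        else:
            warnings.warn(f"line {lineno}: unknown annotation line {tag!r} skipped", stacklevel=2)

    # resolve events (second pass so forward references to other events work)
    known_event_ids = {tag for _, tag, _ in event_lines}
    for lineno, tag, parts in event_lines:
        fields = parts[1].split(" ")
        etype_ref = fields[0]
        if ":" not in etype_ref:
            raise StandoffError(f"line {lineno}: event {tag} lacks a trigger reference")
        etype, trig_id = etype_ref.split(":", 1)
        if trig_id not in entities:
            raise StandoffError(f"line {lineno}: unresolved reference {trig_id!r} in {tag}")
        trig = entities[trig_id]
        triggers[trig_id] = trig
        themes, causes = [], []
        for f in fields[1:]:
            if ":" not in f:
                continue
            role, ref = f.split(":", 1)
            if ref not in entities and ref not in known_event_ids:
                raise StandoffError(f"line {lineno}: unresolved reference {ref!r} in {tag}")
            if role.rstrip("0123456789") == "Theme":
                themes.append(ref)
            elif role.rstrip("0123456789") == "Cause":
                causes.append(ref)
            else:
                warnings.warn(f"line {lineno}: role {role!r} kept as theme", stacklevel=2)
                themes.append(ref)
        events[tag] = Event(tag, etype, trig.span, trig.surface, tuple(themes), tuple(causes))

    for rel in relations.values():
        for ref in (rel.arg1, rel.arg2):
            if ref not in entities:
                raise StandoffError(f"unresolved reference {ref!r} in {rel.id}")

    _check_no_cycles(events)

    # entities proper = T lines not consumed as event triggers
    plain_entities = [e for tid, e in entities.items() if tid not in triggers]

    spans = list(sentence_spans) if sentence_spans is not None else segment_sentences(text)
    doc = Document(
        id=doc_id,
        text=text,
        sentence_spans=spans,
        entities=sorted(plain_entities, key=lambda e: _natural_key(e.id)),
        events=sorted(events.values(), key=lambda e: _natural_key(e.id)),
        relations=sorted(relations.values(), key=lambda r: _natural_key(r.id)),
    )

    entity_map = doc.entity_map()
    for ev in doc.events:
        mk = _build_mk(mk_by_target.get(ev.id))
        doc.associations.append(
            Association("event", ev, doc.sentence_of(ev.trigger.start), mk)
        )
    for rel in doc.relations:
        mk = _build_mk(mk_by_target.get(rel.id))
        arg1 = entity_map[rel.arg1]
        doc.associations.append(
            Association("relation", rel, doc.sentence_of(arg1.span.start), mk)
        )

    assoc_map = doc.association_map()
    for target, dim, span in clue_notes:
        if target not in assoc_map:
            raise StandoffError(f"unresolved reference {target!r} in ClueSpan note")
        assoc = assoc_map[target]
        if assoc.mk is None:
            assoc.mk = MKRecord()
        assoc.mk.clue_spans.setdefault(dim, []).append(span)
    return doc


def _build_mk(fields: Optional[dict]) -> Optional[MKRecord]:
    if not fields:
        return None
    try:
        return MKRecord(**fields)
    except ValueError as exc:
        raise StandoffError(str(exc)) from exc


def _check_no_cycles(events: Mapping[str, Event]) -> None:
    state: dict = {}

    def visit(eid: str, chain: tuple) -> None:
        if state.get(eid) == "done":
            return
        if state.get(eid) == "active":
            raise StandoffError(f"participant-reference cycle through {eid!r}")
        state[eid] = "active"
        for ref in events[eid].participants:
            if ref in events:
                visit(ref, chain + (eid,))
        state[eid] = "done"

    for eid in events:
        visit(eid, ())


def write_standoff(doc: Document) -> tuple:
    """Serialize a document to ``(text, ann)`` strings.

    Ids are renumbered canonically (entities, then triggers, then events,
    relations, attributes); :func:`read_standoff` on the output recovers a
    document equal to the input up to that renumbering.
    """
    lines = []
    id_map: dict = {}
    t_counter = 0

    for ent in doc.entities:
        t_counter += 1
        new_id = f"T{t_counter}"
        id_map[ent.id] = new_id
        lines.append(f"{new_id}\t{ent.etype} {ent.span.start} {ent.span.end}\t{ent.surface}")

    trigger_ids = {}
    for i, ev in enumerate(doc.events, start=1):
        t_counter += 1
        trig_id = f"T{t_counter}"
        trigger_ids[ev.id] = trig_id
        id_map[ev.id] = f"E{i}"
        lines.append(f"{trig_id}\t{ev.etype} {ev.trigger.start} {ev.trigger.end}\t{ev.trigger_surface}")

    for ev in doc.events:
        args = [f"{ev.etype}:{trigger_ids[ev.id]}"]
        for j, ref in enumerate(ev.themes):
            role = "Theme" if j == 0 else f"Theme{j + 1}"
            args.append(f"{role}:{id_map[ref]}")
        for j, ref in enumerate(ev.causes):
            role = "Cause" if j == 0 else f"Cause{j + 1}"
            args.append(f"{role}:{id_map[ref]}")
        lines.append(f"{id_map[ev.id]}\t{' '.join(args)}")

    for i, rel in enumerate(doc.relations, start=1):
        new_id = f"R{i}"
        id_map[rel.id] = new_id
        lines.append(f"{new_id}\t{rel.rtype} Arg1:{id_map[rel.arg1]} Arg2:{id_map[rel.arg2]}")

    rev_attrs = {v: k for k, v in _MK_ATTRIBUTES.items()}
    a_counter = 0
    n_counter = 0
    for assoc in doc.associations:
        if assoc.mk is None:
            continue
        target = id_map.get(assoc.id)
        if target is None:
            raise StandoffError(f"association {assoc.id!r} lacks a serializable payload")
        mk = assoc.mk
        for fname in ("knowledge_type", "knowledge_source", "polarity", "manner", "certainty"):
            value = getattr(mk, fname)
            if value is not None:
                a_counter += 1
                lines.append(f"A{a_counter}\t{rev_attrs[fname]} {target} {value}")
        for fname in ("new_knowledge", "research_hypothesis"):
            value = getattr(mk, fname)
            if value is not None:
                a_counter += 1
                lines.append(f"A{a_counter}\t{rev_attrs[fname]} {target} {'Yes' if value else 'No'}")
        for attr, value in sorted(mk.extras.items()):
            a_counter += 1
            lines.append(f"A{a_counter}\t{attr} {target} {value}")
        for dim in sorted(mk.clue_spans):
            for span in mk.clue_spans[dim]:
                n_counter += 1
                lines.append(f"#{n_counter}\tClueSpan {target} {dim} {span.start} {span.end}")

    ann = "\n".join(lines) + ("\n" if lines else "")
    return doc.text, ann


def load_document(txt_path, sentence_spans=None) -> Document:
    """Load ``<stem>.txt`` with its sibling ``.ann`` (or ``.a1`` + ``.a2``)."""
    path = Path(txt_path)
    text = path.read_text()
    ann_path = path.with_suffix(".ann")
    if ann_path.exists():
        ann = ann_path.read_text()
    else:
        a1, a2 = path.with_suffix(".a1"), path.with_suffix(".a2")
        ann = (a1.read_text() if a1.exists() else "") + (a2.read_text() if a2.exists() else "")
    return read_standoff(text, ann, doc_id=path.stem, sentence_spans=sentence_spans)


def as_association_table(docs: Iterable[Document]) -> list:
    """All associations across documents in stable (doc id, annotation id) order."""
    rows = []
    for doc in sorted(docs, key=lambda d: d.id):
        rows.extend(sorted(doc.associations, key=lambda a: _natural_key(a.id)))
    return rows
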