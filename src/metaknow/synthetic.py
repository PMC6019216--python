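"""Synthetic fixture corpora with known ground truth.

Generates abstracts of templated pseudo-biomedical sentences, each
carrying one association (an event, or a binary relation in relation
mode) with gold meta-knowledge values, plus a deterministic toy
linguistic layer (POS tags, projective dependency tree, constituency
tree) for every sentence — so the whole pipeline is testable without
any external corpus, tagger or parser.

Latent class priors default to the corpus statistics the method was
developed against: 34.2% New Knowledge and 5.31% Research Hypothesis.
Core meta-knowledge dimensions are sampled *jointly* with the
hyperdimension label so that the rule-based inference baseline is
consistent by construction (New Knowledge instances are always
Current/L3/Observation-or-Analysis; Research Hypotheses are always
Analysis/L1-or-L2; the remainder never satisfies either rule).  With
probability ``clue_fidelity`` a label-consistent clue phrase ("we show
that", "these findings suggest that", "it is known that", ...) is
injected as a sentence prefix; ``noise_rate`` swaps the surface clue
for one from a different class *without* touching the latent label, so
the learnable ceiling is controllable.

The toy linguistic annotator is intentionally simple: it emulates the
structures the features read (embedded clause boundaries, verb-headed
dependencies, NP/VP/SBAR bracketing), not real biomedical parsing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import (
    Association,
    Document,
    Entity,
    Event,
    MKRecord,
    Relation,
    Span,
)
from .linguistic import (
    ConstNode,
    ConstTree,
    DepGraph,
    LinguisticLayer,
    Token,
    VERB_TAGS,
)

__all__ = ["GenConfig", "generate_corpus", "generate_linguistic", "write_corpus"]


# ---------------------------------------------------------------------------
# vocabulary

PROTEINS = ["IL-17", "NF-kappaB", "MCP-1", "STAT3", "CTCF", "TNF-alpha",
            "Spi-1", "Fli-1", "NPTN", "BDP"]
DISEASES = ["psoriasis", "schizophrenia", "inflammation", "atherosclerosis", "GVHD"]

#: content verbs: surface (VBZ), base (VB), event type
VERBS = [
    ("activates", "activate", "positive_regulation"),
    ("inhibits", "inhibit", "negative_regulation"),
    ("regulates", "regulate", "regulation"),
    ("binds", "bind", "binding"),
    ("induces", "induce", "positive_regulation"),
]

NOMINAL_TRIGGERS = [("activation", "positive_regulation"), ("expression", "gene_expression")]

_POS: Dict[str, str] = {
    "we": "PRP", "it": "PRP", "these": "DT", "the": "DT", "and": "CC",
    "data": "NNS", "findings": "NNS", "experiments": "NNS", "hypothesis": "NN",
    "that": "IN", "whether": "IN", "of": "IN", "to": "TO", "using": "VBG",
    "is": "VBZ", "has": "VBZ", "been": "VBN", "were": "VBD",
    "show": "VBP", "found": "VBD", "observed": "VBD", "demonstrate": "VBP",
    "suggest": "VBP", "tested": "VBD", "examined": "VBD", "showed": "VBD",
    "known": "VBN", "shown": "VBN", "performed": "VBN", "related": "VBN",
    "previously": "RB", "may": "MD", ".": ".", ",": ",",
}
for s, b, _ in VERBS:
    _POS[s] = "VBZ"
    _POS[b] = "VB"
for w, _ in NOMINAL_TRIGGERS:
    _POS[w] = "NN"


def _pos_of(word: str) -> str:
    return _POS.get(word, "NN")


# ---------------------------------------------------------------------------
# sentence variants
#
# Each variant: (prefix tokens or None, knowledge_type, knowledge_source,
#                certainty, cite, modal, clue token indices within prefix)

_NK_VARIANTS = [
    (["we", "show", "that"], "Observation", "Current", "L3", False, False, (1,)),
    (["we", "found", "that"], "Observation", "Current", "L3", False, False, (1,)),
    (["we", "observed", "that"], "Observation", "Current", "L3", False, False, (1,)),
    (["these", "data", "demonstrate", "that"], "Analysis", "Current", "L3", False, False, (2,)),
]
_RH_VARIANTS = [
    (["these", "findings", "suggest", "that"], "Analysis", "Current", "L2", False, True, (2,)),
    (["we", "tested", "the", "hypothesis", "that"], "Analysis", "Current", "L1", False, True, (1, 2, 3)),
]
_OTHER_VARIANTS = [
    (["it", "is", "known", "that"], "Fact", "Other", "L3", False, False, (2,)),
    (["it", "has", "been", "shown", "that"], "Observation", "Other", "L3", True, False, (3,)),
    (["we", "previously", "showed", "that"], "Observation", "Other", "L3", False, False, (1, 2)),
    (None, "Other", "Current", "L3", False, False, ()),
    (["we", "examined", "whether"], "Investigation", "Current", "L2", False, True, (1,)),
    (["experiments", "were", "performed", "and"], "Method", "Current", "L3", False, False, (2,)),
]
_ALL_PREFIX_VARIANTS = [v for v in _NK_VARIANTS + _RH_VARIANTS + _OTHER_VARIANTS if v[0]]


@dataclass
class GenConfig:
    """Generator configuration; defaults mirror the study conditions.

    ``p_new_knowledge`` / ``p_research_hypothesis`` are the latent class
    priors (event-corpus defaults 34.2% / 5.31%); ``clue_fidelity`` is
    the probability a label-consistent clue is injected; ``noise_rate``
    flips the surface clue (not the latent label).
    """

    n_documents: int = 150
    sentences_per_document: int = 10
    relation_mode: bool = False
    p_new_knowledge: float = 0.342
    p_research_hypothesis: float = 0.0531
    clue_fidelity: float = 1.0
    noise_rate: float = 0.0
    nested_event_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_new_knowledge", "p_research_hypothesis", "clue_fidelity",
                     "noise_rate", "nested_event_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_new_knowledge + self.p_research_hypothesis > 1.0:
            raise ValueError("class priors must sum to at most 1")
        if self.n_documents < 0 or self.sentences_per_document < 1:
            raise ValueError("corpus dimensions must be positive")


# ---------------------------------------------------------------------------
# toy linguistic annotation


def _clause_boundaries(words: Sequence[str]) -> List[int]:
    return [i for i, w in enumerate(words) if w in ("that", "whether")]


def _toy_dep(words: Sequence[str], tags: Sequence[str]) -> DepGraph:
    """Heuristic projective dependency tree over a template sentence."""
    n = len(words)
    verb_idx = [i for i, t in enumerate(tags) if t in VERB_TAGS]
    root = verb_idx[0] if verb_idx else 0
    heads: Dict[int, int] = {}

    def next_verb_before_boundary(i: int) -> Optional[int]:
        for j in range(i + 1, n):
            if words[j] in ("that", "whether"):
                return None
            if tags[j] in VERB_TAGS:
                return j
        return None

    def prev_verb(i: int) -> Optional[int]:
        for j in range(i - 1, -1, -1):
            if tags[j] in VERB_TAGS:
                return j
        return None

    for i in range(n):
        if i == root:
            continue
        w, t = words[i], tags[i]
        if t in VERB_TAGS:
            heads[i] = prev_verb(i) if prev_verb(i) is not None else root
        elif w in ("that", "whether"):
            nxt = next((j for j in range(i + 1, n) if tags[j] in VERB_TAGS), None)
            heads[i] = nxt if nxt is not None else root
        elif t == "DT" or t in ("JJ",):
            nxt = next((j for j in range(i + 1, n) if tags[j].startswith("NN")), None)
            heads[i] = nxt if nxt is not None else root
        elif w in ("of", "to"):
            prv = next((j for j in range(i - 1, -1, -1) if tags[j].startswith("NN")), None)
            heads[i] = prv if prv is not None else root
        elif t.startswith("NN") or t == "PRP":
            if i > 0 and words[i - 1] in ("of", "to"):
                heads[i] = i - 1
            else:
                nxt = next_verb_before_boundary(i)
                if nxt is not None:
                    heads[i] = nxt
                else:
                    prv = prev_verb(i)
                    heads[i] = prv if prv is not None else root
        elif t == "RB":
            nxt = next((j for j in range(i + 1, n) if tags[j] in VERB_TAGS), None)
            heads[i] = nxt if nxt is not None else root
        else:
            heads[i] = root
    arcs = [(h, d, "dep") for d, h in heads.items()]
    return DepGraph(arcs, root, n)


def _toy_tree(words: Sequence[str], tags: Sequence[str]) -> ConstTree:
    """Heuristic constituency tree: NP/VP chunks, SBAR at that/whether."""

    leaves = [ConstNode(tags[i], word=words[i]) for i in range(len(words))]

    def build_clause(lo: int, hi: int) -> ConstNode:
        """S node over tokens [lo, hi)."""
        s = ConstNode("S")
        i = lo
        verb_at = next((j for j in range(lo, hi) if tags[j] in VERB_TAGS), None)
        # pre-verbal material chunked into one NP (or sits bare)
        if verb_at is not None and verb_at > lo:
            np = ConstNode("NP", children=[leaves[j] for j in range(lo, verb_at)])
            s.children.append(np)
            i = verb_at
        if verb_at is None:
            s.children.append(ConstNode("NP", children=[leaves[j] for j in range(lo, hi)]))
            return s
        vp = ConstNode("VP")
        s.children.append(vp)
        while i < hi:
            w, t = words[i], tags[i]
            if w in ("that", "whether"):
                sbar = ConstNode("SBAR", children=[leaves[i], build_clause(i + 1, hi)])
                vp.children.append(sbar)
                return s
            if t in VERB_TAGS:
                vp.children.append(leaves[i])
                i += 1
            elif w in ("of", "to"):
                j = i + 1
                while j < hi and (tags[j].startswith("NN") or tags[j] == "DT"):
                    if words[j] in ("that", "whether"):
                        break
                    j += 1
                pp = ConstNode("PP", children=[leaves[i]])
                if j > i + 1:
                    pp.children.append(ConstNode("NP", children=[leaves[k] for k in range(i + 1, j)]))
                # attach PP inside the current NP if one is open, else the VP
                tail = vp.children[-1] if vp.children else None
                if tail is not None and tail.label == "NP":
                    wrapper = ConstNode("NP", children=[tail, pp])
                    vp.children[-1] = wrapper
                else:
                    vp.children.append(pp)
                i = j
            else:
                j = i
                while j < hi and tags[j] not in VERB_TAGS and words[j] not in ("that", "whether", "of", "to"):
                    j += 1
                vp.children.append(ConstNode("NP", children=[leaves[k] for k in range(i, j)]))
                i = j
        return s

    n = len(words)
    if n and tags[-1] == ".":
        root = build_clause(0, n - 1)
        root.children.append(leaves[n - 1])
    else:
        root = build_clause(0, n)

    # assign token indices in leaf order
    counter = [0]

    def walk(node: ConstNode) -> None:
        if node.word is not None:
            node.token_index = counter[0]
            counter[0] += 1
            return
        for child in node.children:
            walk(child)

    walk(root)
    return ConstTree(root)


def _make_layer(words: Sequence[str], start_offset: int = 0) -> Tuple[LinguisticLayer, List[Span]]:
    tags = [_pos_of(w) for w in words]
    spans = []
    cursor = start_offset
    for w in words:
        spans.append(Span(cursor, cursor + len(w)))
        cursor = cursor + len(w) + 1
    tokens = [Token(i, spans[i], words[i], tags[i]) for i in range(len(words))]
    layer = LinguisticLayer(tokens, _toy_dep(words, tags), _toy_tree(words, tags))
    return layer, spans


def generate_linguistic(template: str, seed: int = 0) -> LinguisticLayer:
    """Deterministic toy linguistic layer for a template sentence.

    Placeholders ``NOUN`` and ``VERB`` are filled deterministically from
    the generator vocabulary using ``seed``; all other words must carry
    a known POS (unknown words default to NN).
    """
    rng = np.random.default_rng(seed)
    words = []
    for w in template.split():
        if w == "NOUN":
            words.append(PROTEINS[rng.integers(len(PROTEINS))])
        elif w == "VERB":
            words.append(VERBS[rng.integers(len(VERBS))][0])
        else:
            words.append(w)
    return _make_layer(words)[0]


# ---------------------------------------------------------------------------
# corpus generation


def _sample_variant(rng, latent: str, cfg: GenConfig):
    pools = {"nk": _NK_VARIANTS, "rh": _RH_VARIANTS, "other": _OTHER_VARIANTS}
    pool = pools[latent]
    variant = pool[rng.integers(len(pool))]
    prefix, kt, ks, cert, cite, modal, clue_idx = variant
    if rng.random() >= cfg.clue_fidelity:
        prefix, cite, clue_idx = None, False, ()  # clue withheld; label unchanged
    elif cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
        # surface noise: swap in a clue prefix from any class
        wrong = _ALL_PREFIX_VARIANTS[rng.integers(len(_ALL_PREFIX_VARIANTS))]
        prefix, cite, clue_idx = wrong[0], wrong[4], wrong[6]
        modal = wrong[5]
    return prefix, kt, ks, cert, cite, modal, clue_idx


def generate_corpus(cfg: GenConfig) -> List[Document]:
    """Generate a corpus of documents with gold meta-knowledge labels."""
    rng = np.random.default_rng(cfg.seed)
    p_other = 1.0 - cfg.p_new_knowledge - cfg.p_research_hypothesis
    docs: List[Document] = []
    for d in range(cfg.n_documents):
        doc_id = f"synth{d:04d}"
        text_parts: List[str] = []
        sentence_spans: List[Span] = []
        entities: List[Entity] = []
        events: List[Event] = []
        relations: List[Relation] = []
        associations: List[Association] = []
        linguistic: Dict[int, LinguisticLayer] = {}
        offset = 0
        t_count = e_count = r_count = 0

        for s in range(cfg.sentences_per_document):
            latent = rng.choice(["nk", "rh", "other"],
                                p=[cfg.p_new_knowledge, cfg.p_research_hypothesis, p_other])
            prefix, kt, ks, cert, cite, modal, clue_idx = _sample_variant(rng, latent, cfg)

            n1 = PROTEINS[rng.integers(len(PROTEINS))]
            n2_pool = DISEASES if cfg.relation_mode else PROTEINS
            n2 = n2_pool[rng.integers(len(n2_pool))]
            while n2 == n1:
                n2 = n2_pool[rng.integers(len(n2_pool))]

            nested = (not cfg.relation_mode) and (not modal) and rng.random() < cfg.nested_event_rate
            vsurf, vbase, etype = VERBS[rng.integers(len(VERBS))]
            if cfg.relation_mode:
                core = [n1, "is", "related", "to", n2]
            elif nested:
                nom, nom_type = NOMINAL_TRIGGERS[rng.integers(len(NOMINAL_TRIGGERS))]
                core = [n1, vsurf, nom, "of", n2]
            elif modal:
                core = [n1, "may", vbase, n2]
            else:
                core = [n1, vsurf, n2]

            words = list(prefix) if prefix else []
            core_start = len(words)
            words += core
            if cite:
                words.append("[12]")
            words.append(".")

            layer, tok_spans = _make_layer(words, offset)
            sent_text = " ".join(words)
            text_parts.append(sent_text)
            # spans tile the text: each sentence owns its trailing separator
            sentence_spans.append(Span(offset, offset + len(sent_text) + 1))
            linguistic[s] = layer

            # entities
            t_count += 1
            ent1 = Entity(f"T{t_count}", "Target" if cfg.relation_mode else "Protein",
                          tok_spans[core_start], n1)
            n2_idx = core_start + len(core) - 1
            t_count += 1
            ent2 = Entity(f"T{t_count}", "Disease" if cfg.relation_mode else "Protein",
                          tok_spans[n2_idx], n2)
            entities += [ent1, ent2]

            mk = MKRecord(
                knowledge_type=kt,
                knowledge_source=ks,
                certainty=cert,
                polarity="Positive",
                manner="Neutral",
                new_knowledge=(latent == "nk"),
                research_hypothesis=(latent == "rh"),
            )
            if prefix and clue_idx:
                lo = tok_spans[clue_idx[0]].start
                hi = tok_spans[clue_idx[-1]].end
                mk.clue_spans.setdefault("KnowledgeType", []).append(Span(lo, hi))

            if cfg.relation_mode:
                r_count += 1
                rel = Relation(f"R{r_count}", "Target-Disorder", ent1.id, ent2.id)
                relations.append(rel)
                associations.append(Association("relation", rel, s, mk))
            elif nested:
                nom_idx = core_start + 2
                e_count += 1
                inner = Event(f"E{e_count}", nom_type, tok_spans[nom_idx], words[nom_idx],
                              themes=(ent2.id,))
                e_count += 1
                causes = (ent1.id,) if rng.random() < 0.5 else ()
                outer = Event(f"E{e_count}", etype, tok_spans[core_start + 1], vsurf,
                              themes=(inner.id,), causes=causes)
                events += [inner, outer]
                inner_mk = MKRecord(**{f: getattr(mk, f) for f in (
                    "knowledge_type", "knowledge_source", "certainty",
                    "polarity", "manner", "new_knowledge", "research_hypothesis")})
                associations.append(Association("event", inner, s, inner_mk))
                associations.append(Association("event", outer, s, mk))
            else:
                verb_idx = core_start + (2 if modal else 1)
                e_count += 1
                causes = (ent1.id,) if rng.random() < 0.5 else ()
                ev = Event(f"E{e_count}", etype, tok_spans[verb_idx], words[verb_idx],
                           themes=(ent2.id,), causes=causes)
                events.append(ev)
                associations.append(Association("event", ev, s, mk))

            offset += len(sent_text) + 1

        text = " ".join(text_parts)
        # last sentence span must not exceed the text
        spans = []
        for i, sp in enumerate(sentence_spans):
            end = min(sp.end, len(text)) if i == len(sentence_spans) - 1 else sp.end
            spans.append(Span(sp.start, end))
        docs.append(Document(
            id=doc_id, text=text, sentence_spans=spans,
            entities=entities, events=events, relations=relations,
            associations=associations, linguistic=linguistic,
        ))
    return docs


# ---------------------------------------------------------------------------
# serialization of linguistic layers (CLI `synth` output)


def _tree_to_bracketed(node: ConstNode) -> str:
    if node.word is not None:
        return f"({node.label} {node.word})"
    inner = " ".join(_tree_to_bracketed(c) for c in node.children)
    return f"({node.label} {inner})"


def write_corpus(docs: Sequence[Document], outdir) -> None:
    """Write txt + ann + conllu + trees files for each document."""
    from pathlib import Path

    from .corpus_io import write_standoff

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        text, ann = write_standoff(doc)
        (out / f"{doc.id}.txt").write_text(text)
        (out / f"{doc.id}.ann").write_text(ann)
        conllu_blocks, tree_lines = [], []
        for s in sorted(doc.linguistic):
            layer = doc.linguistic[s]
            lines = []
            heads = {dep: h for h, dep, _ in (layer.dep.arcs if layer.dep else [])}
            for tok in layer.tokens:
                if layer.dep is not None and tok.index == layer.dep.root:
                    head = 0
                else:
                    head = heads.get(tok.index, -1) + 1
                lines.append(
                    f"{tok.index + 1}\t{tok.surface}\t_\t_\t{tok.pos}\t_\t{head}\tdep\t_\t_"
                )
            conllu_blocks.append("\n".join(lines))
            if layer.tree is not None:
                tree_lines.append(_tree_to_bracketed(layer.tree.root))
        (out / f"{doc.id}.conllu").write_text("\n\n".join(conllu_blocks) + "\n")
        (out / f"{doc.id}.trees").write_text("\n".join(tree_lines) + "\n")
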