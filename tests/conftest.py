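"""Shared fixtures: hand-built documents, trees, lexicons, random generators."""

import numpy as np
import pytest

from metaknow.corpus_io import read_standoff
from metaknow.linguistic import ConstNode, ConstTree, DepGraph, parse_bracketed
from metaknow.lexicon import ClueLexicon, load_lexicon
from metaknow.synthetic import GenConfig, generate_corpus

# -- a two-sentence document: one nested event pair + one binary relation ----
# sentence 1: an "activation" event (theme NF-kappaB) is itself the theme of
# a "dependent" event whose cause is oxidative stress; sentence 2 links a
# target gene to a disorder.

DOC_TEXT = (
    "The activation of NF-kappaB is dependent on oxidative stress . "
    "NPTN is related to Schizophrenia ."
)

DOC_ANN = """\
T1\tProtein 18 27\tNF-kappaB
T2\tStress 44 60\toxidative stress
T3\tTarget 63 67\tNPTN
T4\tDisease 82 95\tSchizophrenia
T5\tpositive_regulation 4 14\tactivation
T6\tpositive_regulation 31 40\tdependent
E1\tpositive_regulation:T5 Theme:T1
E2\tpositive_regulation:T6 Theme:E1 Cause:T2
R1\tTarget-Disorder Arg1:T3 Arg2:T4
A1\tKnowledgeType E2 Observation
A2\tKnowledgeSource E2 Current
A3\tCertainty E2 L3
A4\tNewKnowledge E2 Yes
"""


@pytest.fixture
def nested_event_doc():
    return read_standoff(DOC_TEXT, DOC_ANN, doc_id="fixture")


@pytest.fixture
def layered_doc(nested_event_doc):
    """The nested-event document with toy linguistic layers attached."""
    from metaknow.synthetic import _make_layer

    doc = nested_event_doc
    for s, span in enumerate(doc.sentence_spans):
        words = doc.text[span.start : span.end].split()
        doc.linguistic[s], _ = _make_layer(words, span.start)
    return doc


FIXTURE_TREE = "(S (NP (NN IL-17)) (VP (VBZ is) (NP (DT a) (NN factor))))"


@pytest.fixture
def four_leaf_tree():
    return parse_bracketed(FIXTURE_TREE)


SMALL_LEXICON_TSV = """\
suggest\tUncertainty\tUncertain\tAnalysis
suggest\tKnowledgeType\tAnalysis\tAnalysis
indicate\tKnowledgeType\tAnalysis\tAnalysis
focused\tKnowledgeType\tInvestigation\tInvestigation
present study\tKnowledgeType\tInvestigation\tInvestigation
tested the hypothesis\tKnowledgeType\tInvestigation\tInvestigation
hypothesis\tUncertainty\tUncertain\tInvestigation
may\tUncertainty\tUncertain
shown\tKnowledgeType\tObservation\tObservation
"""


@pytest.fixture
def small_lexicon() -> ClueLexicon:
    return load_lexicon(SMALL_LEXICON_TSV)


@pytest.fixture(scope="session")
def tiny_corpus():
    """20 documents, ~200 associations, full fidelity, no noise."""
    return generate_corpus(GenConfig(n_documents=20, sentences_per_document=8, seed=11))


@pytest.fixture(scope="session")
def tiny_relation_corpus():
    return generate_corpus(
        GenConfig(n_documents=15, sentences_per_document=8, relation_mode=True, seed=12)
    )


# -- random structure generators for oracle tests ---------------------------

PHRASE_LABELS = ["S", "VP", "NP", "PP", "ADJP"]
POS_LABELS = ["NN", "VBZ", "DT", "JJ", "RB"]


def random_const_tree(rng: np.random.Generator, max_leaves: int = 12) -> ConstTree:
    """Random labelled tree with <= max_leaves preterminal leaves."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    counter = [0]

    def build(n: int, depth: int) -> ConstNode:
        if n == 1 and (depth > 0 and rng.random() < 0.6 or depth > 4):
            node = ConstNode(POS_LABELS[rng.integers(len(POS_LABELS))],
                             word=f"w{counter[0]}")
            counter[0] += 1
            return node
        label = PHRASE_LABELS[rng.integers(len(PHRASE_LABELS))] if depth else "S"
        node = ConstNode(label)
        if n == 1:
            node.children.append(build(1, depth + 1))
            return node
        k = int(rng.integers(2, min(n, 3) + 1))
        cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False)) if k > 1 else []
        parts = np.diff([0] + list(cuts) + [n])
        for part in parts:
            node.children.append(build(int(part), depth + 1))
        return node

    root = build(n_leaves, 0)

    def assign(node: ConstNode, nxt: list) -> None:
        if node.word is not None:
            node.token_index = nxt[0]
            nxt[0] += 1
            return
        for child in node.children:
            assign(child, nxt)

    assign(root, [0])
    return ConstTree(root)


def random_dep_tree(rng: np.random.Generator, max_nodes: int = 12) -> DepGraph:
    """Random dependency tree: each node's head is a uniformly earlier node."""
    n = int(rng.integers(1, max_nodes + 1))
    arcs = [(int(rng.integers(0, i)), i, "dep") for i in range(1, n)]
    return DepGraph(arcs, root=0, n_tokens=n)
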