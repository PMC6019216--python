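"""Per-sentence linguistic annotation and the tree/graph operators the features need.

Linguistic annotation is an *input*: part-of-speech tags, dependency
graphs (CoNLL-U) and constituency trees (one-per-line Penn bracketing)
are produced by external taggers/parsers and consumed here.  An adapter
is any callable ``sentence_text -> LinguisticLayer``; a deterministic toy
adapter for tests lives in :mod:`metaknow.synthetic`.

Operators provided on top of these layers:

- ``x_commands`` — the c-command family restricted to a category: the
  clue leaf's *lowest* ancestor labelled S/VP/NP dominates the target
  leaf (dominance taken as reflexive, so a leaf x-commands itself
  whenever it has an ancestor of the category).
- ``dep_path_length`` — undirected shortest-path length in the
  dependency graph; "direct"/"one-hop"/"two-hop" dependencies map to
  lengths 1/2/3 (intervening-node counts).
- ``tree_distance`` — edge-count distance from a leaf to the root or to
  the furthest other leaf through the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import networkx as nx

from .corpus_io import Span

__all__ = [
    "Token",
    "DepGraph",
    "ConstNode",
    "ConstTree",
    "LinguisticLayer",
    "read_conllu",
    "read_bracketed",
    "parse_bracketed",
    "x_commands",
    "dep_path_length",
    "tree_distance",
    "pos_class",
    "NOUN_TAGS",
    "VERB_TAGS",
    "ADJ_TAGS",
    "ADV_TAGS",
]

NOUN_TAGS = frozenset({"NN", "NNS", "NNP", "NNPS"})
VERB_TAGS = frozenset({"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"})
ADJ_TAGS = frozenset({"JJ", "JJR", "JJS"})
ADV_TAGS = frozenset({"RB", "RBR", "RBS"})


def pos_class(tag: str) -> Optional[str]:
    """Bucket a Penn Treebank tag into noun/verb/adjective/adverb (else None)."""
    if tag in NOUN_TAGS:
        return "noun"
    if tag in VERB_TAGS:
        return "verb"
    if tag in ADJ_TAGS:
        return "adjective"
    if tag in ADV_TAGS:
        return "adverb"
    return None


@dataclass(frozen=True)
class Token:
    index: int
    span: Span
    surface: str
    pos: str


class DepGraph:
    """Single-rooted dependency tree over a token sequence.

    Arcs are ``(head, dependent, label)`` with 0-based token indices.
    Every non-root token has exactly one head; the undirected graph is
    connected and acyclic.
    """

    def __init__(self, arcs: Iterable[Tuple[int, int, str]], root: int, n_tokens: int):
        self.arcs = [(int(h), int(d), str(label)) for h, d, label in arcs]
        self.root = int(root)
        self.n_tokens = int(n_tokens)
        self._validate()
        self._graph = nx.Graph()
        self._graph.add_nodes_from(range(self.n_tokens))
        self._graph.add_edges_from((h, d) for h, d, _ in self.arcs)

    def _validate(self) -> None:
        heads: dict = {}
        for h, d, _ in self.arcs:
            for idx in (h, d):
                if not (0 <= idx < self.n_tokens):
                    raise ValueError(f"token index {idx} out of range (n={self.n_tokens})")
            if d in heads:
                raise ValueError(f"token {d} has multiple heads")
            heads[d] = h
        if self.root in heads:
            raise ValueError(f"root token {self.root} must not have a head")
        missing = set(range(self.n_tokens)) - {self.root} - set(heads)
        if missing:
            raise ValueError(f"tokens without a head: {sorted(missing)}")
        if self.n_tokens > 0 and len(self.arcs) != self.n_tokens - 1:
            raise ValueError("dependency graph is not a tree")

    def head_of(self, index: int) -> Optional[int]:
        """Head token index of ``index`` (None for the root)."""
        for h, d, _ in self.arcs:
            if d == index:
                return h
        return None

    def graph(self) -> nx.Graph:
        return self._graph


@dataclass
class ConstNode:
    """Node of a constituency tree.

    Leaves are the preterminals: ``label`` holds the POS category,
    ``word`` the surface form, ``token_index`` the aligned token.
    """

    label: str
    children: list = field(default_factory=list)
    token_index: Optional[int] = None
    word: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.token_index is not None

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out: list = []
        for child in self.children:
            out.extend(child.leaves())
        return out


class ConstTree:
    """Constituency tree whose leaves align 1:1, in order, with tokens."""

    def __init__(self, root: ConstNode):
        self.root = root
        self.leaves = root.leaves()
        for expect, leaf in enumerate(self.leaves):
            if leaf.token_index != expect:
                raise ValueError(
                    f"leaf order mismatch: leaf {leaf.label!r} has token index "
                    f"{leaf.token_index}, expected {expect}"
                )
        self._parent: dict = {id(root): None}
        self._depth: dict = {id(root): 0}
        stack = [root]
        while stack:
            node = stack.pop()
            for child in node.children:
                self._parent[id(child)] = node
                self._depth[id(child)] = self._depth[id(node)] + 1
                stack.append(child)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def parent(self, node: ConstNode) -> Optional[ConstNode]:
        return self._parent[id(node)]

    def depth(self, node: ConstNode) -> int:
        return self._depth[id(node)]

    def ancestors(self, node: ConstNode) -> list:
        """Path from ``node``'s parent up to the root (nearest first)."""
        out = []
        cur = self.parent(node)
        while cur is not None:
            out.append(cur)
            cur = self.parent(cur)
        return out

    def leaf(self, index: int) -> ConstNode:
        if not (0 <= index < self.n_leaves):
            raise ValueError(f"leaf index {index} out of range (n={self.n_leaves})")
        return self.leaves[index]


@dataclass
class LinguisticLayer:
    """Tokens + dependency graph + constituency tree for one sentence."""

    tokens: List[Token]
    dep: Optional[DepGraph] = None
    tree: Optional[ConstTree] = None

    def __post_init__(self) -> None:
        if self.dep is not None and self.dep.n_tokens != len(self.tokens):
            raise ValueError("dependency graph does not cover the token sequence")
        if self.tree is not None and self.tree.n_leaves != len(self.tokens):
            raise ValueError("constituency tree does not cover the token sequence")


# ---------------------------------------------------------------------------
# readers


def _iter_lines(stream):
    if hasattr(stream, "read"):
        stream = stream.read()
    return str(stream).splitlines()


def read_conllu(stream) -> list:
    """Parse CoNLL-U into one ``(tokens, DepGraph)`` pair per sentence block.

    XPOS (column 5) is used as the Penn tag, falling back to UPOS.
    Multi-word token ranges and empty nodes are skipped.  Token spans are
    synthesized by single-space joining (CoNLL-U carries no offsets).
    """
    sentences = []
    block: list = []

    def flush(block):
        if not block:
            return
        tokens: list = []
        arcs: list = []
        root = None
        cursor = 0
        for lineno, cols in block:
            idx = len(tokens)
            form, xpos, upos = cols[1], cols[4], cols[3]
            pos = xpos if xpos not in ("_", "") else upos
            span = Span(cursor, cursor + len(form))
            cursor = span.end + 1
            tokens.append(Token(idx, span, form, pos))
        for i, (lineno, cols) in enumerate(block):
            try:
                head = int(cols[6])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer head field {cols[6]!r}") from exc
            if head == 0:
                if root is not None:
                    raise ValueError(f"line {lineno}: multiple roots in sentence")
                root = i
            else:
                if not (1 <= head <= len(block)):
                    raise ValueError(f"line {lineno}: head index {head} out of range")
                arcs.append((head - 1, i, cols[7] if len(cols) > 7 else "dep"))
        if root is None:
            raise ValueError("sentence block has no root (head 0) token")
        sentences.append((tokens, DepGraph(arcs, root, len(tokens))))

    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip("\n")
        if not line.strip():
            flush(block)
            block = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            raise ValueError(f"line {lineno}: expected >= 7 tab-separated fields")
        if "-" in cols[0] or "." in cols[0]:
            continue  # multi-word token / empty node
        block.append((lineno, cols))
    flush(block)
    return sentences


def parse_bracketed(text: str) -> ConstTree:
    """Parse one Penn-style bracketed tree, e.g. ``(S (NP (NN x)) ...)``."""
    pos = 0
    n = len(text)
    leaf_counter = [0]

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_node() -> ConstNode:
        nonlocal pos
        skip_ws()
        if pos >= n or text[pos] != "(":
            raise ValueError(f"expected '(' at position {pos}")
        pos += 1
        skip_ws()
        start = pos
        while pos < n and not text[pos].isspace() and text[pos] not in "()":
            pos += 1
        label = text[start:pos]
        if not label:
            raise ValueError(f"missing node label at position {start}")
        node = ConstNode(label)
        skip_ws()
        if pos < n and text[pos] == "(":
            while pos < n and text[pos] == "(":
                node.children.append(parse_node())
                skip_ws()
        else:
            # preterminal: (POS word) — the preterminal itself is the leaf
            start = pos
            while pos < n and not text[pos].isspace() and text[pos] not in "()":
                pos += 1
            word = text[start:pos]
            if not word:
                raise ValueError(f"missing terminal at position {start}")
            node.token_index = leaf_counter[0]
            node.word = word
            leaf_counter[0] += 1
            skip_ws()
        if pos >= n or text[pos] != ")":
            raise ValueError(f"unbalanced brackets: expected ')' at position {pos}")
        pos += 1
        return node

    root = parse_node()
    skip_ws()
    if pos != n:
        raise ValueError(f"trailing content at position {pos}")
    return ConstTree(root)


def read_bracketed(stream) -> list:
    """One Penn bracketed tree per non-empty line."""
    trees = []
    for lineno, line in enumerate(_iter_lines(stream), start=1):
        if not line.strip():
            continue
        try:
            trees.append(parse_bracketed(line.strip()))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return trees


# ---------------------------------------------------------------------------
# operators


def _leaf_ancestors(tree: ConstTree, leaf_index: int) -> list:
    """Ancestors of the preterminal leaf, nearest first."""
    return tree.ancestors(tree.leaf(leaf_index))


def x_commands(tree: ConstTree, clue_leaf: int, target_leaf: int, category: str) -> bool:
    """Whether the clue leaf x-commands the target for X in {S, VP, NP}.

    True iff the lowest ancestor of ``clue_leaf`` labelled ``category``
    dominates ``target_leaf``; dominance is reflexive, so equal leaves
    x-command whenever such an ancestor exists.  Function tags after
    ``-`` are stripped before comparing labels.
    """
    tree.leaf(target_leaf)  # range check
    for anc in _leaf_ancestors(tree, clue_leaf):
        if anc.label.split("-")[0] == category:
            return any(leaf.token_index == target_leaf for leaf in anc.leaves())
    return False


def same_minimal_scope(tree: ConstTree, a_leaf: int, b_leaf: int, category: str = "S") -> bool:
    """Whether two leaves share the same *lowest* ancestor of ``category``."""

    def lowest(leaf_index):
        for anc in _leaf_ancestors(tree, leaf_index):
            if anc.label.split("-")[0] == category:
                return anc
        return None

    la, lb = lowest(a_leaf), lowest(b_leaf)
    return la is not None and la is lb


def dep_path_length(dep: DepGraph, a: int, b: int) -> int:
    """Undirected shortest-path length between two tokens (0 iff a == b)."""
    for idx in (a, b):
        if not (0 <= idx < dep.n_tokens):
            raise ValueError(f"token index {idx} out of range (n={dep.n_tokens})")
    return nx.shortest_path_length(dep.graph(), a, b)


def tree_distance(tree: ConstTree, leaf: int, to: str = "root") -> int:
    """Edge-count distance from a word leaf to the root or the furthest leaf."""
    node = tree.leaf(leaf)
    if to == "root":
        return tree.depth(node)
    if to == "furthest_leaf":
        return max(
            (leaf_to_leaf_distance(tree, leaf, other.token_index) for other in tree.leaves),
            default=0,
        )
    raise ValueError(f"unknown target {to!r}; expected 'root' or 'furthest_leaf'")


def leaf_to_leaf_distance(tree: ConstTree, a: int, b: int) -> int:
    """Path length between two leaves through their lowest common ancestor."""
    if a == b:
        return 0
    na, nb = tree.leaf(a), tree.leaf(b)
    anc_a = {id(x): i for i, x in enumerate([na] + tree.ancestors(na))}
    chain_b = [nb] + tree.ancestors(nb)
    for j, x in enumerate(chain_b):
        if id(x) in anc_a:
            return anc_a[id(x)] + j
    raise ValueError("leaves do not share a root")  # unreachable in a tree
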