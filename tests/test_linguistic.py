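"""Tree/graph operators checked against independent brute-force oracles."""

from collections import deque

import numpy as np
import pytest

from conftest import random_const_tree, random_dep_tree
from metaknow.linguistic import (
    ConstNode,
    DepGraph,
    dep_path_length,
    leaf_to_leaf_distance,
    parse_bracketed,
    read_bracketed,
    read_conllu,
    same_minimal_scope,
    tree_distance,
    x_commands,
)

# ---------------------------------------------------------------------------
# independent oracles (recursive, no parent maps)


def oracle_leaves_under(node: ConstNode) -> set:
    if node.word is not None:
        return {node.token_index}
    out = set()
    for child in node.children:
        out |= oracle_leaves_under(child)
    return out


def oracle_path_to_leaf(node: ConstNode, leaf_index: int):
    """Root-to-leaf node path found by exhaustive search."""
    if node.word is not None:
        return [node] if node.token_index == leaf_index else None
    for child in node.children:
        sub = oracle_path_to_leaf(child, leaf_index)
        if sub is not None:
            return [node] + sub
    return None


def oracle_x_commands(tree, clue_leaf, target_leaf, category) -> bool:
    path = oracle_path_to_leaf(tree.root, clue_leaf)
    ancestors = path[:-1]  # exclude the leaf itself
    for anc in reversed(ancestors):  # lowest first
        if anc.label.split("-")[0] == category:
            return target_leaf in oracle_leaves_under(anc)
    return False


def oracle_bfs_distance(dep: DepGraph, a: int, b: int) -> int:
    adj = {i: set() for i in range(dep.n_tokens)}
    for h, d, _ in dep.arcs:
        adj[h].add(d)
        adj[d].add(h)
    seen, frontier = {a}, deque([(a, 0)])
    while frontier:
        node, dist = frontier.popleft()
        if node == b:
            return dist
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, dist + 1))
    raise AssertionError("graph not connected")


# ---------------------------------------------------------------------------
# readers

CONLLU_3TOK = """\
1\tIL-17\t_\t_\tNN\t_\t2\tnsubj\t_\t_
2\tactivates\t_\t_\tVBZ\t_\t0\troot\t_\t_
3\tNF-kappaB\t_\t_\tNN\t_\t2\tobj\t_\t_
"""


class TestReadConllu:
    def test_three_token_sentence(self):
        [(tokens, dep)] = read_conllu(CONLLU_3TOK)
        assert [t.surface for t in tokens] == ["IL-17", "activates", "NF-kappaB"]
        assert dep.root == 1
        assert len(dep.arcs) == 2
        assert dep.head_of(0) == 1 and dep.head_of(2) == 1

    def test_empty_stream(self):
        assert read_conllu("") == []

    def test_non_integer_head_reports_line(self):
        bad = CONLLU_3TOK.replace("\t0\troot", "\tx\troot")
        with pytest.raises(ValueError, match="line 2"):
            read_conllu(bad)

    def test_head_out_of_range(self):
        bad = CONLLU_3TOK.replace("\t2\tobj", "\t9\tobj")
        with pytest.raises(ValueError, match="out of range"):
            read_conllu(bad)

    def test_multiword_token_lines_skipped(self):
        block = "1-2\tdel\t_\t_\t_\t_\t_\t_\t_\t_\n" + CONLLU_3TOK
        [(tokens, _)] = read_conllu(block)
        assert len(tokens) == 3


class TestReadBracketed:
    def test_four_leaf_fixture(self, four_leaf_tree):
        assert four_leaf_tree.n_leaves == 4
        assert [leaf.word for leaf in four_leaf_tree.leaves] == ["IL-17", "is", "a", "factor"]

    def test_single_leaf(self):
        tree = parse_bracketed("(NP (NN x))")
        assert tree.n_leaves == 1

    def test_unbalanced_brackets_reports_position(self):
        with pytest.raises(ValueError, match="line 1"):
            read_bracketed("(S (NP")

    def test_multiple_lines(self):
        trees = read_bracketed("(NP (NN x))\n\n(S (VP (VB go)))\n")
        assert [t.n_leaves for t in trees] == [1, 1]


# ---------------------------------------------------------------------------
# operators


class TestXCommands:
    def test_same_minimal_s(self, four_leaf_tree):
        # "IL-17" and "factor" sit under the same (only) S
        assert x_commands(four_leaf_tree, 0, 3, "S") is True

    def test_np_does_not_reach_outside(self, four_leaf_tree):
        # "a" is inside the object NP, which excludes the subject
        assert x_commands(four_leaf_tree, 2, 0, "NP") is False
        assert x_commands(four_leaf_tree, 2, 3, "NP") is True

    def test_relative_clause_s_excludes_main_clause(self):
        tree = parse_bracketed(
            "(S (NP (NN X) (SBAR (WHNP (WDT which)) (S (VP (VBZ suggests)))))"
            " (VP (VBZ activates) (NP (NN Y))))"
        )
        # "suggests" (leaf 2): its lowest S is the relative clause
        assert x_commands(tree, 2, 3, "S") is False
        assert x_commands(tree, 2, 1, "S") is False

    def test_leaf_x_commands_itself(self, four_leaf_tree):
        assert x_commands(four_leaf_tree, 2, 2, "NP") is True
        assert x_commands(four_leaf_tree, 0, 0, "S") is True

    def test_leaf_out_of_range(self, four_leaf_tree):
        with pytest.raises(ValueError, match="out of range"):
            x_commands(four_leaf_tree, 0, 9, "S")

    def test_matches_bruteforce_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            tree = random_const_tree(rng, max_leaves=12)
            n = tree.n_leaves
            for _ in range(6):
                a, b = int(rng.integers(n)), int(rng.integers(n))
                cat = ["S", "VP", "NP"][rng.integers(3)]
                assert x_commands(tree, a, b, cat) == oracle_x_commands(tree, a, b, cat)
                checked += 1
        assert checked >= 1000

    def test_same_minimal_scope(self, four_leaf_tree):
        assert same_minimal_scope(four_leaf_tree, 0, 3, "S") is True
        assert same_minimal_scope(four_leaf_tree, 0, 2, "NP") is False


class TestDepPathLength:
    def test_direct_arc(self):
        dep = DepGraph([(0, 1, "obj")], root=0, n_tokens=2)
        assert dep_path_length(dep, 0, 1) == 1

    def test_chain_two(self):
        dep = DepGraph([(0, 2, "x"), (2, 1, "y")], root=0, n_tokens=3)
        assert dep_path_length(dep, 0, 1) == 2

    def test_zero_iff_same(self):
        dep = DepGraph([(0, 1, "x")], root=0, n_tokens=2)
        assert dep_path_length(dep, 1, 1) == 0

    def test_out_of_range(self):
        dep = DepGraph([(0, 1, "x")], root=0, n_tokens=2)
        with pytest.raises(ValueError, match="out of range"):
            dep_path_length(dep, 0, 5)

    def test_matches_bfs_oracle_symmetric_triangle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            dep = random_dep_tree(rng, max_nodes=12)
            n = dep.n_tokens
            a, b, c = (int(rng.integers(n)) for _ in range(3))
            dab = dep_path_length(dep, a, b)
            assert dab == oracle_bfs_distance(dep, a, b)
            assert dab == dep_path_length(dep, b, a)
            assert dab <= dep_path_length(dep, a, c) + dep_path_length(dep, c, b)


class TestTreeDistance:
    def test_fixture_leaf_to_root(self, four_leaf_tree):
        assert tree_distance(four_leaf_tree, 0, "root") == 2

    def test_single_leaf_tree(self):
        tree = parse_bracketed("(NP (NN x))")
        assert tree_distance(tree, 0, "root") == 1
        assert tree_distance(tree, 0, "furthest_leaf") == 0

    def test_furthest_leaf_matches_all_pairs_oracle(self, four_leaf_tree):
        expected = max(
            leaf_to_leaf_distance(four_leaf_tree, 0, j) for j in range(4)
        )
        assert tree_distance(four_leaf_tree, 0, "furthest_leaf") == expected == 5

    def test_root_distance_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tree = random_const_tree(rng)
            for leaf in range(tree.n_leaves):
                assert tree_distance(tree, leaf, "root") >= 1

    def test_unknown_target(self, four_leaf_tree):
        with pytest.raises(ValueError, match="unknown target"):
            tree_distance(four_leaf_tree, 0, "sideways")


class TestDepGraphValidation:
    def test_multiple_heads_rejected(self):
        with pytest.raises(ValueError, match="multiple heads"):
            DepGraph([(0, 1, "a"), (2, 1, "b")], root=0, n_tokens=3)

    def test_headless_token_rejected(self):
        with pytest.raises(ValueError, match="without a head"):
            DepGraph([(0, 1, "a")], root=0, n_tokens=3)
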