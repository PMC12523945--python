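"""p-distance, neighbor joining against additive-tree theory, bootstrap, newick."""

import io

import numpy as np
import pytest

from conftest import make_matrix
from gbtskit.io import MISSING
from gbtskit.phylo import (DistanceMatrix, bootstrap_support, neighbor_joining,
                           newick_string, p_distance, write_newick)
from gbtskit.simulate import PopulationSpec, simulate_cohort


def random_additive_tree(n_taxa, rng):
    """A random binary tree with positive branch lengths and its leaf-to-leaf
    distance matrix (built by path summation, independent of NJ)."""
    names = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, attach remaining taxa to random edges
    nodes = {i: None for i in range(n_taxa)}
    # adjacency: dict node -> dict neighbor -> length
    adj: dict = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def del_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    next_internal = n_taxa
    lengths = lambda: float(rng.uniform(0.5, 3.0))
    add_edge(0, next_internal, lengths())
    add_edge(1, next_internal, lengths())
    add_edge(2, next_internal, lengths())
    next_internal += 1
    for leaf in range(3, n_taxa):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = next_internal
        next_internal += 1
        del_edge(a, b)
        split = float(rng.uniform(0.2, 0.8)) * w
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(leaf, mid, lengths())

    # all-pairs leaf distances by BFS
    d = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n_taxa):
            d[s, t] = dist[t]
    np.fill_diagonal(d, 0.0)

    # bipartition set of the generating tree
    splits = set()
    leaves = frozenset(names)
    for a in adj:
        for b in adj[a]:
            if a < b:
                # side of the split containing a, with edge (a,b) removed
                side = set()
                stack = [a]
                seen = {a, b}
                while stack:
                    u = stack.pop()
                    if u < n_taxa:
                        side.add(names[u])
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                if 1 < len(side) < n_taxa - 1:
                    fs = frozenset(side)
                    other = leaves - fs
                    splits.add(fs if (len(fs), min(fs)) <= (len(other), min(other)) else other)
    canon = set()
    for s in splits:
        other = leaves - s
        canon.add(s if len(s) < len(other) or (len(s) == len(other) and min(s) < min(other)) else other)
    return names, d, canon


class TestPDistance:
    def test_identical_and_opposite_samples(self):
        dos = np.asarray([[0, 0, 0], [0, 0, 0], [2, 2, 2]], dtype=np.int8)
        d = p_distance(make_matrix(dos))
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(10, 100)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.1] = MISSING
        d = p_distance(make_matrix(dos, pos=np.arange(1, 101) * 10))
        for i in range(10):
            for j in range(10):
                ok = (dos[i] != MISSING) & (dos[j] != MISSING)
                want = np.mean(np.abs(dos[i][ok].astype(float) - dos[j][ok]) / 2)
                if i == j:
                    want = 0.0
                assert d.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_disjoint_missingness_rejected(self):
        dos = np.asarray(
            [[0, MISSING], [MISSING, 1], [1, 1]], dtype=np.int8
        )
        with pytest.raises(ValueError, match="share no called loci"):
            p_distance(make_matrix(dos, pos=[10, 20]))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        names = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(ids=names, values=d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        path = tree.path_distances()
        order = [path.ids.index(n) for n in names]
        assert np.allclose(path.values[np.ix_(order, order)], d, atol=1e-9)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 5], [4, 0, 7], [5, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids=["A", "B", "C"], values=d))
        lens = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lens == pytest.approx({"A": 1.0, "B": 3.0, "C": 4.0})

    def test_random_additive_trees_recovered_exactly(self):
        """NJ is consistent on additive matrices: topology and path lengths."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            names, d, splits = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids=names, values=d))
            assert tree.bipartitions() == splits
            path = tree.path_distances()
            order = [path.ids.index(x) for x in names]
            assert np.allclose(path.values[np.ix_(order, order)], d, atol=1e-9)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(4)
        names, d, _ = random_additive_tree(7, rng)
        t1 = neighbor_joining(DistanceMatrix(ids=names, values=d))
        perm = rng.permutation(7)
        t2 = neighbor_joining(
            DistanceMatrix(ids=[names[i] for i in perm],
                           values=d[np.ix_(perm, perm)])
        )
        assert t1.bipartitions() == t2.bipartitions()
        assert np.allclose(t1.path_distances().values,
                           t2.path_distances().values, atol=1e-9)

    def test_agreement_with_skbio_on_random_matrix(self):
        """Independent cross-check: same splits as scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        names, d, _ = random_additive_tree(8, rng)
        d += rng.uniform(0, 0.01, size=d.shape)  # mild non-additive noise
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        ours = neighbor_joining(DistanceMatrix(ids=names, values=d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
        their_splits = set()
        universe = frozenset(names)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                other = universe - side
                their_splits.add(
                    side if len(side) < len(other)
                    or (len(side) == len(other) and min(side) < min(other))
                    else other
                )
        assert ours.bipartitions() == their_splits

    def test_too_few_taxa_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(ids=["A", "B"], values=np.zeros((2, 2))))
        d = np.full((3, 3), np.nan)
        np.fill_diagonal(d, 0)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(ids=list("ABC"), values=d))


class TestBootstrap:
    def test_population_split_strongly_supported(self):
        spec = PopulationSpec(n_pops=2, n_per_pop=10, fst=0.25, n_loci=500,
                              seq_lengths=(100_000,), missing_rate=0.0,
                              qual_low_fraction=0.0, seed=51)
        _, mat, truth = simulate_cohort(spec)
        tree = bootstrap_support(mat, reps=100, seed=1)
        pop1 = frozenset(s for s, g in zip(mat.samples, truth.groups) if g == "pop1")
        counts = {}
        for node in tree.internal_edges():
            below = frozenset(l.name for l in node.leaves())
            counts[below] = node.support
        universe = frozenset(mat.samples)
        match = [
            s for b, s in counts.items()
            if b == pop1 or universe - b == pop1
        ]
        assert match and match[0] >= 0.95

    def test_single_replicate_supports_binary(self, small_cohort):
        _, mat, _ = small_cohort
        sub = mat.take_samples(range(8)).take_loci(np.arange(100))
        tree = bootstrap_support(sub, reps=1, seed=2)
        sups = [n.support for n in tree.internal_edges() if n.support is not None]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_deterministic_given_seed(self, small_cohort):
        _, mat, _ = small_cohort
        sub = mat.take_samples(range(10)).take_loci(np.arange(150))
        t1 = bootstrap_support(sub, reps=20, seed=7)
        t2 = bootstrap_support(sub, reps=20, seed=7)
        assert newick_string(t1) == newick_string(t2)


class TestNewick:
    def test_three_taxon_canonical_form(self):
        d = np.array([[0, 4, 5], [4, 0, 7], [5, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids=["A", "B", "C"], values=d))
        s = newick_string(tree)
        assert s.startswith("(") and s.endswith(");")
        assert "A:1" in s and "B:3" in s and "C:4" in s

    def test_round_trip_preserves_splits_and_lengths(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(6)
        names, d, splits = random_additive_tree(8, rng)
        tree = neighbor_joining(DistanceMatrix(ids=names, values=d))
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        read = dendropy.Tree.get(path=str(path), schema="newick")
        universe = frozenset(names)
        back = set()
        for edge in read.preorder_edge_iter():
            node = edge.head_node
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(side) < len(names) - 1:
                other = universe - side
                back.add(
                    side if len(side) < len(other)
                    or (len(side) == len(other) and min(side) < min(other))
                    else other
                )
        assert back == tree.bipartitions() == splits
        # total tree length preserved to newick precision
        total_written = sum(
            e.length for e in read.preorder_edge_iter() if e.length
        )
        def total(node):
            return node.length + sum(total(c) for c in node.children)
        total_ours = sum(total(c) for c in tree.root.children)
        assert total_written == pytest.approx(total_ours, rel=1e-4)

    def test_labels_with_spaces_quoted(self):
        from gbtskit.phylo import PhyloTree, TreeNode

        t = PhyloTree(root=TreeNode(children=[
            TreeNode(name="sample one", length=1.0),
            TreeNode(name="b", length=2.0),
            TreeNode(name="c", length=3.0),
        ]))
        assert "'sample one':1" in newick_string(t)
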