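"""Individual-level p-distances, neighbor-joining trees, bootstrap, newick.

The p-distance between two diploid unphased individuals is the mean, over
loci called in both, of |g_i - g_j| / 2 -- the allele-sharing mismatch
fraction (0 for identical genotypes, 1 for opposite homozygotes at every
locus).

Neighbor joining follows the Saitou-Nei agglomeration: repeatedly join
the pair minimising Q(i, j) = (n - 2) d(i, j) - r_i - r_j (r = row sums),
with limb lengths from the standard split formula.  Ties are broken by
the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf).  Negative limb estimates are clamped to
zero with the deficit moved to the sibling limb.  The output is an
unrooted tree represented with a trifurcating root node.

Bootstrap support resamples loci with replacement, rebuilds the tree per
replicate, and scores each internal edge of the full-data tree by the
fraction of replicates containing the same leaf bipartition.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io import GenotypeMatrix


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(
                    name + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]) + "\n"
                )


def p_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise mean |dosage difference| / 2 over jointly-called loci."""
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples")
    d = matrix.dosage.astype(float)
    w = matrix.called.astype(float)
    n = matrix.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        joint = w[i] * w  # (n, m)
        shared = joint.sum(axis=1)
        if np.any(shared[np.arange(n) != i] == 0):
            j = int(np.flatnonzero((shared == 0) & (np.arange(n) != i))[0])
            raise ValueError(
                f"samples {matrix.samples[i]} and {matrix.samples[j]} share no called loci"
            )
        diff = np.abs(d[i][None, :] - d) / 2.0
        out[i] = (diff * joint).sum(axis=1) / shared
    out[np.arange(n), np.arange(n)] = 0.0
    return DistanceMatrix(ids=list(matrix.samples), values=0.5 * (out + out.T))


def group_mean_frequency_distance(
    matrix: GenotypeMatrix, locus_weights: np.ndarray | None = None
) -> DistanceMatrix:
    """Breed-level alternative: p-distance between group mean allele freqs.

    ``locus_weights`` (bootstrap multiplicities) reweight the per-locus
    mean; default is uniform.
    """
    idx = matrix.group_indices()
    names = list(idx)
    wloc = (
        np.ones(matrix.n_loci)
        if locus_weights is None
        else np.asarray(locus_weights, dtype=float)
    )
    freqs = []
    for g, ix in idx.items():
        sub = matrix.take_samples(ix)
        called = sub.called
        nc = np.maximum(called.sum(axis=0), 1)
        freqs.append(np.where(called, sub.dosage, 0).sum(axis=0) / (2.0 * nc))
    f = np.vstack(freqs)
    diff = np.abs(f[:, None, :] - f[None, :, :])
    d = (diff * wloc[None, None, :]).sum(axis=2) / wloc.sum()
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=names, values=0.5 * (d + d.T))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = dataclasses.field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclasses.dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each as its smaller/canonical side."""
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                out.add(_canon_split(below, all_leaves))
            return below

        walk(self.root)
        return out

    def internal_edges(self) -> list[TreeNode]:
        """Nodes whose parent edge is internal (non-leaf, non-root)."""
        out = []

        def walk(node: TreeNode) -> None:
            for c in node.children:
                if not c.is_leaf:
                    out.append(c)
                walk(c)

        walk(self.root)
        return out

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf distances along the tree (checks additivity)."""
        names = sorted(self.leaf_names)
        pos = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = [
                {k: v + c.length for k, v in walk(c).items()} for c in node.children
            ]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for na, da in sub[a].items():
                        for nb, db in sub[b].items():
                            d[pos[na], pos[nb]] = d[pos[nb], pos[na]] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self.root)
        return DistanceMatrix(ids=names, values=d)


def _canon_split(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    if len(side) < len(other) or (len(side) == len(other) and min(side) < min(other)):
        return side
    return other


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    n0 = len(dist.ids)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("non-finite distances")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=name) for i, name in enumerate(dist.ids)
    }
    # cluster label for tie-breaks: smallest leaf name in the cluster
    label: dict[int, str] = {i: name for i, name in enumerate(dist.ids)}
    d = {
        (min(i, j), max(i, j)): float(dist.values[i, j])
        for i in range(n0)
        for j in range(i + 1, n0)
    }
    active = list(range(n0))
    next_id = n0

    def D(i: int, j: int) -> float:
        return d[(min(i, j), max(i, j))]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best_q, best_pair = np.inf, None
        for ai in range(n):
            for bi in range(ai + 1, n):
                i, j = active[ai], active[bi]
                q = (n - 2) * D(i, j) - r[i] - r[j]
                key = tuple(sorted((label[i], label[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best_pair is not None
                    and key < best_pair[2]
                ):
                    best_q, best_pair = q, (i, j, key)
        i, j, _ = best_pair  # type: ignore[misc]
        li = 0.5 * D(i, j) + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D(i, j) - li
        # clamp negatives, moving the deficit to the sibling limb
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        nodes[next_id] = new
        label[next_id] = min(label[i], label[j])
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, next_id), max(k, next_id))] = 0.5 * (
                D(i, k) + D(j, k) - D(i, j)
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = sorted(active, key=lambda k: label[k])
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    for k, L in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = L
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def bootstrap_support(
    matrix: GenotypeMatrix,
    reps: int = 1000,
    seed: int = 0,
    distance_fn=p_distance,
) -> PhyloTree:
    """NJ tree on the full data, internal edges annotated with bootstrap support."""
    if matrix.n_samples < 4:
        raise ValueError("need >= 4 samples")
    if reps < 1:
        raise ValueError("need >= 1 replicate")
    tree = neighbor_joining(distance_fn(matrix))
    universe = frozenset(tree.leaf_names)

    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    m = matrix.n_loci
    for _ in range(reps):
        # resampling duplicates loci, so distances are computed on raw arrays
        # (multiplicity weights) rather than via take_loci
        idx = np.sort(rng.integers(0, m, size=m))
        boot = _resampled_distance(matrix, idx, distance_fn)
        bt = neighbor_joining(boot)
        for split in bt.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    def annotate(node: TreeNode, below: frozenset[str]) -> None:
        node.support = counts.get(_canon_split(below, universe), 0) / reps

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(universe) - 1:
            annotate(node, below)
        return below

    walk(tree.root)
    return tree


def _resampled_distance(matrix: GenotypeMatrix, idx: np.ndarray, distance_fn):
    """Distance on a with-replacement locus resample (weights = multiplicities)."""
    counts = np.bincount(idx, minlength=matrix.n_loci).astype(float)
    if distance_fn is group_mean_frequency_distance:
        return group_mean_frequency_distance(matrix, locus_weights=counts)
    if distance_fn is not p_distance:
        raise ValueError("bootstrap supports p_distance or group_mean_frequency_distance")
    d = matrix.dosage.astype(float)
    w = matrix.called.astype(float) * counts[None, :]
    n = matrix.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        joint = matrix.called[i].astype(float) * w
        shared = joint.sum(axis=1)
        diff = np.abs(d[i][None, :] - d) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(shared > 0, (diff * joint).sum(axis=1) / shared, 0.0)
    out[np.arange(n), np.arange(n)] = 0.0
    return DistanceMatrix(ids=list(matrix.samples), values=0.5 * (out + out.T))


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def _quote(name: str) -> str:
    if any(c in name for c in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_string(tree: PhyloTree, with_support: bool = True) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{_quote(node.name)}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        sup = (
            f"{node.support:.3f}"
            if with_support and node.support is not None
            else ""
        )
        return f"({inner}){sup}:{node.length:.6g}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"


def write_newick(tree: PhyloTree, path: str | Path, with_support: bool = True) -> None:
    """Write standard newick (branch lengths to 6 significant digits)."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree, with_support=with_support) + "\n")
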