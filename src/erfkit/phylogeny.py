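"""Distance-based phylogeny: p-distance with pairwise deletion, neighbor
joining with deterministic tie-breaking, and column-resampling bootstrap.

The distance model is the amino-acid p-distance (mismatch fraction over
columns where neither sequence of the pair has a gap). Neighbor joining
uses the Q criterion with Studier-Keppler distance updates; join ties break
by the smallest (i, j) index pair and negative branch-length estimates are
clamped to zero with the deficit recorded. Trees are left unrooted (the
root node of the returned structure is the degree-3 junction of the final
join, a presentation artifact only).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skbio import TreeNode

GAP = "-"


@dataclasses.dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray           # symmetric, zero diagonal
    site_counts: np.ndarray | None = None  # per-pair comparable columns

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m


def _check_alignment(alignment: dict[str, str]) -> np.ndarray:
    if len(alignment) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return np.array([list(s) for s in alignment.values()])


def pdistance_matrix(alignment: dict[str, str],
                     poisson_correction: bool = False) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion.

    For each pair, columns with a gap in either sequence are skipped;
    distance = mismatches / comparable columns. A pair with zero comparable
    columns raises, naming the pair. `poisson_correction` applies
    -ln(1 - p) to each distance."""
    ids = list(alignment)
    arr = _check_alignment(alignment)
    nongap = arr != GAP
    n = len(ids)
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            mism = int((arr[i][both] != arr[j][both]).sum())
            p = mism / m
            if poisson_correction:
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for {ids[i]!r}/{ids[j]!r}")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
            counts[i, j] = counts[j, i] = m
    return DistanceMatrix(ids=ids, matrix=d, site_counts=counts)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ on a DistanceMatrix; returns an unrooted tree whose
    structural root has three children. Deterministic: ties in the Q
    criterion go to the smallest (i, j) pair; negative branch estimates are
    clamped to 0 (deficit stored on the tree as `nj_clamp_deficit`)."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.matrix.copy()
    nodes: list[TreeNode] = []
    for name in dm.ids:
        leaf = TreeNode(name=name)
        nodes.append(leaf)
    clamp_deficit = 0.0

    def _clamp(x: float) -> float:
        nonlocal clamp_deficit
        if x < 0:
            clamp_deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties (to 1e-12) -> smallest (i, j) with i < j
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        cand = cand[cand[:, 0] < cand[:, 1]]
        i, j = min(map(tuple, cand))
        dij = d[i, j]
        li = _clamp(dij / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = _clamp(dij - (dij / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # final 3-way join: closed-form lengths
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    nodes[0].length = _clamp((dab + dac - dbc) / 2)
    nodes[1].length = _clamp((dab + dbc - dac) / 2)
    nodes[2].length = _clamp((dac + dbc - dab) / 2)
    root = TreeNode(children=list(nodes))
    root.nj_clamp_deficit = clamp_deficit
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf names (the
    side not containing the lexicographically smallest leaf)."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    total = set(leaves)
    parts = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = {t.name for t in node.tips()}
        side = total - clade if ref in clade else clade
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(frozenset(side))
    return parts


def nj_tree(alignment: dict[str, str], **kwargs) -> TreeNode:
    return neighbor_joining(pdistance_matrix(alignment, **kwargs))


def bootstrap_support(alignment: dict[str, str], n_replicates: int = 1000,
                      seed: int = 0) -> tuple[TreeNode, dict[frozenset, int]]:
    """Column bootstrap: rebuild NJ per replicate and report each original
    bipartition's replicate frequency as an integer percentage.

    The returned tree is the original NJ tree with internal node names set
    to their support; supports <= 50 are conventionally flagged downstream."""
    if len(alignment) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    rng = np.random.default_rng(seed)
    ids = list(alignment)
    arr = _check_alignment(alignment)
    L = arr.shape[1]
    tree = nj_tree(alignment)
    parts = bipartitions(tree)
    hits = {p: 0 for p in parts}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_aln = {ids[i]: "".join(arr[i, cols]) for i in range(len(ids))}
        rep_parts = bipartitions(nj_tree(rep_aln))
        for p in parts:
            if p in rep_parts:
                hits[p] += 1
    supports = {p: int(round(100.0 * h / n_replicates)) for p, h in hits.items()}
    # annotate internal nodes of the original tree
    leaves = sorted(alignment)
    ref = leaves[0]
    total = set(leaves)
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = {t.name for t in node.tips()}
        side = total - clade if ref in clade else clade
        key = frozenset(side)
        if key in supports:
            node.name = str(supports[key])
    return tree, supports


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize with branch lengths and integer supports as internal node
    labels; skbio's parser round-trips topology, lengths, and supports."""
    text = str(tree).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick(source) -> TreeNode:
    return TreeNode.read(source, format="newick")
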