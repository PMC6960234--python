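"""BIONJ tree construction and nonparametric bootstrap support.

BIONJ is the neighbour-joining variant that propagates a variance estimate
for each distance and merges rows with variance-weighted averaging; on
additive matrices it recovers the generating tree exactly, like classical
NJ, but is more robust to the noisier long distances of real barcode data.
Support values follow Felsenstein's method: alignment columns are resampled
with replacement, the tree is rebuilt per replicate, and each internal edge
of the point-estimate tree is scored by the fraction of replicates whose
tree contains the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .distances import (
    AlignedMarkerSet,
    DistanceMatrix,
    IncomparablePairError,
    SaturationError,
    build_matrix,
    matrix_from_encoded,
)


def bionj(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted BIONJ tree (returned rooted at the final trifurcation).

    Taxa are canonically ordered and Q-criterion ties broken by the
    lexicographically smallest representative leaf of each candidate pair,
    so permuting the input order never changes the result.  Negative branch
    lengths are clamped to zero with the deficit moved to the sibling.
    """
    if len(dm.ids) < 3:
        raise ValueError("BIONJ needs at least 3 taxa")
    if len(set(dm.ids)) != len(dm.ids):
        raise ValueError("duplicate taxon labels")

    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    D = dm.data[np.ix_(order, order)].astype(float).copy()
    V = D.copy()  # BIONJ initialises variances at the distances themselves

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    keys: list[str] = list(ids)  # smallest leaf label per subtree, for tie-breaks
    active = list(range(len(ids)))

    while len(active) > 3:
        r = len(active)
        sub = np.ix_(active, active)
        d = D[sub]
        S = d.sum(axis=1)
        Q = (r - 2) * d - S[:, None] - S[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a, b in np.argwhere(Q <= qmin + 1e-12):
            if a >= b:
                continue
            ka, kb = keys[active[a]], keys[active[b]]
            cand = ((min(ka, kb), max(ka, kb)), int(a), int(b))
            if best is None or cand[0] < best[0]:
                best = cand
        _, a, b = best
        i, j = active[a], active[b]

        bi = 0.5 * d[a, b] + (S[a] - S[b]) / (2 * (r - 2))
        bj = d[a, b] - bi
        if bi < 0:
            bi, bj = 0.0, d[a, b]
        elif bj < 0:
            bi, bj = d[a, b], 0.0

        vij = V[i, j]
        others = [t for t in active if t not in (i, j)]
        if vij > 1e-12 and r > 2:
            lam = 0.5 + (V[j, others].sum() - V[i, others].sum()) / (2 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = TreeNode()
        nodes[i].length, nodes[j].length = float(bi), float(bj)
        parent.extend([nodes[i], nodes[j]])
        new = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))

        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in others:
            dk = lam * (D[i, k] - bi) + (1 - lam) * (D[j, k] - bj)
            D[new, k] = D[k, new] = dk
            V[new, k] = V[k, new] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij
        active = [t for t in active if t not in (i, j)] + [new]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = float(max(0.0, (dab + dac - dbc) / 2))
    nodes[b].length = float(max(0.0, (dab + dbc - dac) / 2))
    nodes[c].length = float(max(0.0, (dac + dbc - dab) / 2))
    root = TreeNode()
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


def tree_path_length(tree: TreeNode, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    return float(tree.find(a).distance(tree.find(b)))


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical internal-edge bipartitions (non-trivial splits only).

    Each bipartition is represented by the side NOT containing the
    lexicographically smallest taxon.
    """
    taxa = frozenset(leaf.name for leaf in tree.tips())
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if anchor in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


@dataclass
class BootstrapResult:
    tree: TreeNode
    support: dict[frozenset[str], float]
    n_completed: int
    n_discarded: int
    discard_log: list[str] = field(default_factory=list)


def bootstrap_support(
    aln: AlignedMarkerSet,
    model: str = "JC69",
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Felsenstein bootstrap on a BIONJ tree.

    Columns are resampled with replacement; replicates whose resampled
    matrix is incomputable (no comparable sites, or saturated under the
    model) are discarded and logged, and the support denominator is the
    number of completed replicates.  Supports are written onto the
    point-estimate tree's internal node names.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = aln.encoded()
    ids = list(aln.ids)
    point_tree = bionj(matrix_from_encoded(ids, enc, model))
    target = bipartitions(point_tree)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    completed = 0
    log: list[str] = []
    length = enc.shape[1]
    for rep in range(n_reps):
        cols = rng.integers(0, length, size=length)
        try:
            rep_tree = bionj(matrix_from_encoded(ids, enc[:, cols], model))
        except (IncomparablePairError, SaturationError) as exc:
            log.append(f"replicate {rep} discarded: {exc}")
            continue
        completed += 1
        found = bipartitions(rep_tree)
        for split in target:
            if split in found:
                counts[split] += 1
    if completed == 0:
        raise RuntimeError("all bootstrap replicates were discarded")
    support = {split: counts[split] / completed for split in target}

    taxa = frozenset(leaf.name for leaf in point_tree.tips())
    anchor = min(taxa)
    for node in point_tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if anchor in side:
            side = taxa - side
        if side in support:
            node.name = f"{support[side]:.2f}"
    return BootstrapResult(point_tree, support, completed, n_reps - completed, log)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
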