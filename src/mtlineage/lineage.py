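"""Clone trees, BCR repertoire clonality, and mtDNA/BCR concordance.

Neighbor joining (Saitou-Nei) is implemented here directly because the tree
contract pins details generic implementations leave open: deterministic
lexicographic tie-breaking when several pairs minimize the Q criterion, and
clamping of negative branch-length estimates to zero with donation of the
deficit to the sibling branch so pairwise path lengths are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class CloneTree:
    """An unrooted clone tree with non-negative branch lengths.

    ``newick`` serializes the topology; ``clamped_branches`` records leaf/node
    names whose NJ branch-length estimate was negative and clamped to zero.
    """

    leaves: list[str]
    newick: str
    clamped_branches: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str, children: list[tuple["_Node", float]] | None = None):
        self.name = name
        self.children = children or []

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{l:.10g}" for c, l in self.children)
        return f"({inner})"


def neighbor_joining(
    dist: pd.DataFrame,
) -> CloneTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion break on the lexicographically smallest leaf-pair
    (current node names); negative branch lengths are clamped to 0 and the
    deficit donated to the sibling so the joined pair's path length equals
    their distance.  NaN entries raise, naming the offending pair.
    """
    labels = [str(c) for c in dist.columns]
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or list(dist.index.astype(str)) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    bad = np.argwhere(np.isnan(d))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"NaN distance between {labels[i]!r} and {labels[j]!r}")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    clamped: list[str] = []
    nodes: list[_Node] = [_Node(name) for name in labels]
    dm = d.copy()

    def _clamp(pair: list[tuple[_Node, float]]) -> list[tuple[_Node, float]]:
        (na, la), (nb, lb) = pair
        if la < 0:
            clamped.append(na.name)
            lb, la = lb + la, 0.0
        if lb < 0:
            clamped.append(nb.name)
            la, lb = la + lb, 0.0
        return [(na, max(la, 0.0)), (nb, max(lb, 0.0))]

    if len(nodes) == 2:
        half = dm[0, 1] / 2.0
        root = _Node("", [(nodes[0], half), (nodes[1], half)])
        return CloneTree(leaves=sorted(labels), newick=root.newick(), clamped_branches=clamped)

    active = list(range(len(nodes)))
    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                if q[ai, bi] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    na, nb = nodes[active[ai]].name, nodes[active[bi]].name
                    key = tuple(sorted((na, nb)))
                    if best is None or key < best[0]:
                        best = (key, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = dij / 2.0 + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        pair = _clamp([(nodes[i], li), (nodes[j], lj)])
        # internal nodes get a deterministic name so later tie-breaks stay stable
        parent = _Node(f"({pair[0][0].name},{pair[1][0].name})", pair)
        # distances from the new node to every remaining active node
        new_row = np.zeros(dm.shape[0] + 1)
        for ci in range(m):
            kidx = active[ci]
            if kidx in (i, j):
                continue
            new_row[kidx] = 0.5 * (dm[i, kidx] + dm[j, kidx] - dij)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = new_row[:-1]
        dm[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # terminal three-node star: closed-form branch lengths
    li = (dm[i, j] + dm[i, k] - dm[j, k]) / 2.0
    lj = (dm[i, j] + dm[j, k] - dm[i, k]) / 2.0
    lk = (dm[i, k] + dm[j, k] - dm[i, j]) / 2.0
    branches = []
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        if length < 0:
            clamped.append(node.name or "internal")
            length = 0.0
        branches.append((node, length))
    root = _Node("", branches)
    return CloneTree(leaves=sorted(labels), newick=root.newick(), clamped_branches=clamped)


def profile_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance on square-root heteroplasmy profiles."""
    x = np.sqrt(profiles.to_numpy(dtype=float))
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    labels = [str(i) for i in profiles.index]
    return pd.DataFrame(d, index=labels, columns=labels)


def nj_tree(
    profiles: pd.DataFrame,
    max_leaves: int = 500,
    seed: int = 0,
) -> CloneTree:
    """Neighbor-joining tree over clone (or cell) heteroplasmy profiles.

    Distance is Euclidean on square-root heteroplasmy.  Profile tables larger
    than ``max_leaves`` rows (per-cell trees) are subsampled, seeded.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if len(profiles) > max_leaves:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(profiles), size=max_leaves, replace=False))
        profiles = profiles.iloc[keep]
    return neighbor_joining(profile_distance(profiles.fillna(0.0)))


# ---------------------------------------------------------------------------
# BCR repertoire


def repertoire_summary(repertoire: pd.DataFrame) -> dict:
    """Clonality report for one sample's AIRR-style clonotype table.

    Cells with a missing clonotype are excluded from all denominators.  The
    dominant clonotype is the largest one; the polyclonal fraction is the
    proportion of assigned cells outside it.
    """
    assigned = repertoire.dropna(subset=["clone_id"])
    n = len(assigned)
    if n == 0:
        raise ValueError("no cells with a clonotype assignment")
    freqs = assigned["clone_id"].value_counts(sort=True) / n
    dominant = str(freqs.index[0])
    spectrum = (
        assigned["clone_id"].value_counts().value_counts().sort_index()
    )  # clone size -> number of clones
    return {
        "n_cells": n,
        "n_clonotypes": int(freqs.size),
        "dominant_clonotype": dominant,
        "dominant_frequency": float(freqs.iloc[0]),
        "polyclonal_fraction": float(1.0 - freqs.iloc[0]),
        "clone_size_spectrum": {int(k): int(v) for k, v in spectrum.items()},
    }


# ---------------------------------------------------------------------------
# mtDNA clone / BCR clonotype concordance


@dataclass
class ConcordanceResult:
    """Agreement between the mtDNA clone partition and BCR clonotypes."""

    contingency: pd.DataFrame  # mtDNA clone x BCR clonotype cell counts
    ari: float
    purity: pd.DataFrame  # per mtDNA clone: majority BCR clonotype + purity
    flows: pd.DataFrame  # long format (mt_clone, bcr_clonotype, n_cells)
    n_cells: int


def clone_concordance(
    mt_labels: pd.Series,
    bcr_labels: pd.Series,
) -> ConcordanceResult:
    """Score concordance between mtDNA clones and BCR clonotypes.

    Both series map cell -> label; the intersection of their cell universes is
    used (its size is reported).  Purity per mtDNA clone is the fraction of
    its cells carrying the majority BCR clonotype.
    """
    cells = mt_labels.index.intersection(bcr_labels.index)
    if len(cells) == 0:
        raise ValueError("no shared cells between mtDNA clones and BCR table")
    mt = mt_labels.loc[cells]
    bcr = bcr_labels.loc[cells]
    contingency = pd.crosstab(mt, bcr)
    contingency.index.name = "mt_clone"
    contingency.columns.name = "bcr_clonotype"
    ari = float(adjusted_rand_score(mt.astype(str), bcr.astype(str)))
    purity_rows = []
    for clone in contingency.index:
        row = contingency.loc[clone]
        purity_rows.append(
            {
                "mt_clone": clone,
                "n_cells": int(row.sum()),
                "majority_bcr": str(row.idxmax()),
                "purity": float(row.max() / row.sum()),
            }
        )
    flows = (
        contingency.stack()
        .rename("n_cells")
        .reset_index()
        .query("n_cells > 0")
        .reset_index(drop=True)
    )
    return ConcordanceResult(
        contingency=contingency,
        ari=ari,
        purity=pd.DataFrame(purity_rows).set_index("mt_clone"),
        flows=flows,
        n_cells=int(len(cells)),
    )
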