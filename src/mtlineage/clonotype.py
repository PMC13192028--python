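"""mtDNA-defined clonotypes: assignment, downsampling stability, dynamics.

Cells are clustered on square-root-transformed heteroplasmy with a cosine
k-nearest-neighbour graph and seeded Leiden community detection, then clusters
are relabelled by decreasing size.  Clusters whose mean profile carries no
variant above ``min_marker_het`` collapse into the background label 0, as do
cells with no heteroplasmy signal at all.  The algorithm is an explicit,
seeded stand-in for clonotype callers in single-cell toolkits; cluster-level
results, not any package's internals, are the contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CloneAssignment:
    """Cells mapped to mtDNA clonotypes.

    ``labels`` maps each cell to a small-integer clone label (0 = background /
    unassigned); ``profiles`` holds per-clone mean heteroplasmy over variants,
    computed over non-missing entries only.
    """

    labels: pd.Series
    profiles: pd.DataFrame

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def n_clones(self) -> int:
        """Number of clones, excluding the background label 0."""
        return int((self.sizes.index != 0).sum())


def call_clonotypes(
    het: pd.DataFrame,
    k: int = 20,
    resolution: float = 1.0,
    min_marker_het: float = 0.02,
    merge_threshold: float = 0.1,
    seed: int = 0,
) -> CloneAssignment:
    """Assign cells to clonotypes from a cells x variants heteroplasmy matrix.

    Missing entries are imputed as 0 for clustering (absence of evidence) but
    excluded from the per-clone mean profiles.  Communities whose mean
    square-root profiles are nearly collinear (cosine distance below
    ``merge_threshold``) are merged: a kNN graph among cells of one clone is
    essentially random, so community detection alone can split clones that
    share the same marker set.  Deterministic given ``seed``.
    """
    filled = het.fillna(0.0)
    x = np.sqrt(filled.to_numpy(dtype=float))
    n = x.shape[0]
    labels = np.zeros(n, dtype=np.int64)

    nonzero = x.sum(axis=1) > 0
    idx = np.flatnonzero(nonzero)
    if idx.size >= 2:
        xs = x[idx]
        kk = min(k, idx.size - 1)
        if kk < k:
            warnings.warn(f"fewer cells than k: reducing k from {k} to {kk}")
        nn = NearestNeighbors(n_neighbors=kk + 1, metric="cosine").fit(xs)
        _, neigh = nn.kneighbors(xs)
        edges = sorted(
            {
                (min(i, j), max(i, j))
                for i, row in enumerate(neigh)
                for j in row[1:]
                if i != j
            }
        )
        g = igraph.Graph(n=idx.size, edges=edges)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
        )
        member = _merge_collinear(np.asarray(part.membership), xs, merge_threshold)
        # relabel by decreasing cluster size, ties by smaller original label
        counts = pd.Series(member).value_counts()
        order = sorted(counts.index, key=lambda c: (-counts[c], c))
        remap = {old: new for new, old in enumerate(order, start=1)}
        labels[idx] = np.array([remap[m] for m in member])

    out = pd.Series(labels, index=het.index, name="clone")
    profiles = clone_profiles(het, out)
    # clusters without a convincing marker collapse into the background
    weak = [
        c
        for c in profiles.index
        if c != 0 and not (profiles.loc[c] >= min_marker_het).any()
    ]
    if weak:
        out = out.replace({c: 0 for c in weak})
        out = _compact_labels(out)
        profiles = clone_profiles(het, out)
    return CloneAssignment(labels=out, profiles=profiles)


def _merge_collinear(member: np.ndarray, x: np.ndarray, threshold: float) -> np.ndarray:
    """Merge communities whose mean vectors are nearly collinear.

    Greedy: repeatedly merge the closest pair below ``threshold`` (cosine on
    community means of the sqrt-heteroplasmy rows), smaller label absorbed
    into larger community (ties by label).  Deterministic.
    """
    member = member.copy()
    while True:
        ids = np.unique(member)
        if ids.size < 2:
            return member
        means = np.vstack([x[member == c].mean(axis=0) for c in ids])
        norms = np.linalg.norm(means, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        cos = 1.0 - (means @ means.T) / np.outer(safe, safe)
        np.fill_diagonal(cos, np.inf)
        cos[norms == 0, :] = np.inf  # zero-profile communities never merge here
        cos[:, norms == 0] = np.inf
        i, j = np.unravel_index(np.argmin(cos), cos.shape)
        if cos[i, j] >= threshold:
            return member
        a, b = ids[i], ids[j]
        sizes = {c: int((member == c).sum()) for c in (a, b)}
        keep, drop = (a, b) if (sizes[a], -a) >= (sizes[b], -b) else (b, a)
        member[member == drop] = keep


def _compact_labels(labels: pd.Series) -> pd.Series:
    """Renumber non-background labels 1..K by decreasing size (ties: old label)."""
    counts = labels[labels != 0].value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    return labels.map(remap)


def clone_profiles(het: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-clone mean heteroplasmy over non-missing entries."""
    rows = {}
    for clone in sorted(labels.unique()):
        cells = labels.index[labels == clone]
        rows[clone] = het.loc[cells].mean(axis=0, skipna=True).fillna(0.0)
    out = pd.DataFrame(rows).T
    out.index.name = "clone"
    return out


@dataclass
class StabilityReport:
    """Partition agreement under cell downsampling."""

    replicates: pd.DataFrame  # fraction, replicate, n_cells, agreement
    threshold: float

    def median_agreement(self) -> pd.Series:
        return self.replicates.groupby("fraction")["agreement"].median()

    def stable(self) -> pd.Series:
        """Stable at a fraction when the median ARI reaches the threshold."""
        return self.median_agreement() >= self.threshold


def downsample_stability(
    het: pd.DataFrame,
    fractions: tuple[float, ...] = (0.75, 0.50),
    n_reps: int = 25,
    threshold: float = 0.7,
    seed: int = 0,
    k: int = 20,
    resolution: float = 1.0,
    min_marker_het: float = 0.02,
    merge_threshold: float = 0.1,
) -> StabilityReport:
    """Re-call clonotypes on random cell subsets and score agreement.

    Agreement per replicate is the adjusted Rand index between re-called
    labels and the full-data labels restricted to retained cells.  Replicates
    leaving fewer than ``2 * k`` cells are skipped and logged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    reference = call_clonotypes(
        het, k=k, resolution=resolution, min_marker_het=min_marker_het,
        merge_threshold=merge_threshold, seed=seed,
    )
    rows = []
    for fraction in fractions:
        n_keep = int(round(fraction * len(het)))
        for rep in range(n_reps):
            if n_keep < 2 * k:
                logger.info(
                    "skipping replicate at fraction %.2f: %d < %d cells",
                    fraction, n_keep, 2 * k,
                )
                continue
            keep = rng.choice(het.index.to_numpy(), size=n_keep, replace=False)
            sub = call_clonotypes(
                het.loc[keep],
                k=k,
                resolution=resolution,
                min_marker_het=min_marker_het,
                merge_threshold=merge_threshold,
                seed=seed,
            )
            agreement = adjusted_rand_score(
                reference.labels.loc[keep].to_numpy(), sub.labels.to_numpy()
            )
            rows.append(
                {
                    "fraction": fraction,
                    "replicate": rep,
                    "n_cells": n_keep,
                    "agreement": float(agreement),
                }
            )
    return StabilityReport(replicates=pd.DataFrame(rows), threshold=threshold)


def match_clones(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame
) -> dict[int, int]:
    """Match clones across samples by nearest mean profile.

    Cosine distance on square-root profiles over the union of variants;
    uniqueness enforced greedily best-first with a deterministic tie-break on
    (distance, label_a, label_b).  Background label 0 is never matched.
    """
    a_labels = [c for c in profiles_a.index if c != 0]
    b_labels = [c for c in profiles_b.index if c != 0]
    if not a_labels or not b_labels:
        return {}
    cols = sorted(set(profiles_a.columns) | set(profiles_b.columns))
    pa = np.sqrt(profiles_a.reindex(columns=cols, fill_value=0.0).loc[a_labels].to_numpy(dtype=float))
    pb = np.sqrt(profiles_b.reindex(columns=cols, fill_value=0.0).loc[b_labels].to_numpy(dtype=float))

    def _cosine(u: np.ndarray, v: np.ndarray) -> float:
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 1.0
        return float(1.0 - np.dot(u, v) / (nu * nv))

    pairs = sorted(
        (( _cosine(pa[i], pb[j]), a, b)
         for i, a in enumerate(a_labels)
         for j, b in enumerate(b_labels)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    matched: dict[int, int] = {}
    used_b: set[int] = set()
    for _, a, b in pairs:
        if a in matched or b in used_b:
            continue
        matched[a] = b
        used_b.add(b)
    return matched


def clone_dynamics(
    assign_a: CloneAssignment,
    assign_b: CloneAssignment,
    clone_map: dict[int, int] | None = None,
    min_cells: int = 10,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Classify matched clones as stable or dynamic between two samples.

    Per clone, a two-sided Fisher exact test on the 2x2 table
    (clone cells, other cells) x (sample A, sample B), BH-corrected across
    testable clones; *dynamic* requires q <= alpha and a frequency fold change
    of at least ``fc_threshold`` in either direction.  Clones below
    ``min_cells`` in both samples, and unmatched clones, are not testable.
    """
    if clone_map is None:
        clone_map = match_clones(assign_a.profiles, assign_b.profiles)
    n_a, n_b = len(assign_a.labels), len(assign_b.labels)
    sizes_a, sizes_b = assign_a.sizes, assign_b.sizes
    rows = []
    for a in sorted(c for c in assign_a.profiles.index if c != 0):
        b = clone_map.get(a)
        ca = int(sizes_a.get(a, 0))
        cb = int(sizes_b.get(b, 0)) if b is not None else 0
        freq_a, freq_b = ca / n_a, cb / n_b
        fc = (freq_b + pseudocount) / (freq_a + pseudocount)
        testable = b is not None and max(ca, cb) >= min_cells
        if testable:
            _, p = stats.fisher_exact(
                [[ca, n_a - ca], [cb, n_b - cb]], alternative="two-sided"
            )
        else:
            p = np.nan
        rows.append(
            {
                "clone_a": a,
                "clone_b": b if b is not None else -1,
                "cells_a": ca,
                "cells_b": cb,
                "freq_a": freq_a,
                "freq_b": freq_b,
                "fold_change": fc,
                "p": p,
                "testable": testable,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    big_fc = (out["fold_change"] >= fc_threshold) | (
        out["fold_change"] <= 1.0 / fc_threshold
    )
    out["class"] = np.where(
        ~out["testable"],
        "not_testable",
        np.where((out["q"] <= alpha) & big_fc, "dynamic", "stable"),
    )
    return out


def subclone_summary(assignments: dict[str, CloneAssignment]) -> pd.DataFrame:
    """Per-sample subclone count and clone-size diversity (background excluded)."""
    rows = []
    for sample, assign in assignments.items():
        sizes = assign.sizes
        sizes = sizes[sizes.index != 0].to_numpy(dtype=float)
        n = len(sizes)
        if n == 0:
            rows.append(
                {"sample": sample, "n_subclones": 0, "entropy": 0.0,
                 "normalized_entropy": 0.0, "gini": 0.0}
            )
            continue
        p = sizes / sizes.sum()
        entropy = float(-(p * np.log(p)).sum())
        norm_entropy = entropy / np.log(n) if n > 1 else 0.0
        sorted_sizes = np.sort(sizes)
        cum = np.cumsum(sorted_sizes)
        gini = float(
            (n + 1 - 2 * (cum / cum[-1]).sum()) / n
        ) if n > 1 else 0.0
        rows.append(
            {
                "sample": sample,
                "n_subclones": n,
                "entropy": entropy,
                "normalized_entropy": norm_entropy,
                "gini": gini,
            }
        )
    return pd.DataFrame(rows)
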