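import numpy as np
import pandas as pd
import pytest

from mtlineage.counts import BaseCountTensor
from mtlineage.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated population (no fragments), seed 7."""
    config = SimulationConfig(seed=7)
    sample, truth = simulate_population(config, with_fragments=False)
    return config, sample, truth


@pytest.fixture()
def tiny_tensor():
    """A 3-cell, 2-position tensor with hand-computable counts.

    Position 5 (ref A): cell0 10xA(5+/5-) + 2xG(1+/1-); cell1 20xA; cell2 0.
    Position 9 (ref C): cell0 8xC; cell1 4xC + 4xT(2+/2-); cell2 6xT(3+/3-).
    """
    counts = np.zeros((3, 2, 4, 2), dtype=np.int64)
    A, C, G, T = 0, 1, 2, 3
    counts[0, 0, A] = (5, 5)
    counts[0, 0, G] = (1, 1)
    counts[1, 0, A] = (10, 10)
    counts[0, 1, C] = (4, 4)
    counts[1, 1, C] = (2, 2)
    counts[1, 1, T] = (2, 2)
    counts[2, 1, T] = (3, 3)
    return BaseCountTensor(
        barcodes=["c0", "c1", "c2"],
        positions=np.array([5, 9]),
        ref_bases=np.array(["A", "C"]),
        counts=counts,
    )


def brute_force_heteroplasmy(tensor, vids, min_coverage=5):
    """Independent oracle: per-entry loop over the raw count array."""
    from mtlineage.genome import BASES, parse_variant_id

    out = np.full((tensor.n_cells, len(vids)), np.nan)
    for j, vid in enumerate(vids):
        pos, _ref, alt = parse_variant_id(vid)
        pi = list(tensor.positions).index(pos)
        bi = BASES.index(alt)
        for i in range(tensor.n_cells):
            total = int(tensor.counts[i, pi].sum())
            if total >= min_coverage:
                out[i, j] = tensor.counts[i, pi, bi].sum() / total
    return pd.DataFrame(out, index=pd.Index(tensor.barcodes, name="cell"), columns=vids)


def brute_force_bh(pvalues):
    """Step-up BH adjusted p-values by direct enumeration."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def brute_force_ks_d(a, b):
    """Sup distance of empirical CDFs by a double loop over pooled values."""
    pooled = np.concatenate([a, b])
    best = 0.0
    for x in pooled:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {k: comb(row1, k) * comb(n - row1, col1 - k) / denom for k in range(lo, hi + 1)}
    cutoff = pmf[a] * (1 + 1e-7)
    return sum(v for v in pmf.values() if v <= cutoff)


def brute_force_ari(x, y):
    """Adjusted Rand index by explicit pair counting."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = x.size
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_x = x[i] == x[j]
            same_y = y[i] == y[j]
            if same_x and same_y:
                ss += 1
            elif same_x:
                sd += 1
            elif same_y:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


def random_additive_tree(rng, n_leaves):
    """A random binary tree over named leaves; returns (distance frame, newick-free truth).

    Distances are exactly additive, built by joining random subtrees with
    positive branch lengths.
    """
    names = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    depth = {i: {i: 0.0} for i in range(n_leaves)}
    active = list(range(n_leaves))
    splits = []
    nxt = n_leaves
    while len(active) > 1:
        i, j = rng.choice(active, size=2, replace=False)
        li, lj = rng.uniform(0.5, 3.0, 2)
        for a in depth[i]:
            for b in depth[j]:
                dist[a, b] = dist[b, a] = depth[i][a] + li + depth[j][b] + lj
        splits.append(frozenset(depth[i]))
        splits.append(frozenset(depth[j]))
        depth[nxt] = {a: d + li for a, d in depth[i].items()} | {
            b: d + lj for b, d in depth[j].items()
        }
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    frame = pd.DataFrame(dist, index=names, columns=names)
    return frame
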