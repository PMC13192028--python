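"""Variant-level two-sample heteroplasmy shift machinery.

Two complementary screens between paired samples (e.g. HC-MBL vs matched
CLL): a mean-level screen (Wilcoxon rank-sum with BH correction, flagged only
beyond an absolute 1.5-fold change of mean heteroplasmy) and a distribution-
level screen (two-sample Kolmogorov-Smirnov with BH correction, gated on cell
counts of at least 100).  Q-Q curves expose the shape of any shift, and the
same Wilcoxon machinery classifies compartment enrichment/depletion between
physiologic and monoclonal B cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Pseudocount applied to mean heteroplasmies before fold changes.
FC_PSEUDOCOUNT = 1e-4


def _column_vectors(het: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        str(col): het[col].dropna().to_numpy(dtype=float) for col in het.columns
    }


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration for small, tie-free vectors; otherwise the tie-corrected
    normal approximation (heteroplasmy vectors are heavily tied at 0).
    """
    small = len(a) <= 25 and len(b) <= 25
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not ties else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def mean_shift_screen(
    het_a: pd.DataFrame,
    het_b: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean-heteroplasmy shift screen between two samples.

    Fold change is (mean_B + eps)/(mean_A + eps); a variant is flagged
    ``shifted_mean`` when BH q <= alpha AND the fold change is >= fc_threshold
    or <= 1/fc_threshold.  Variants absent (no non-missing cells) in one
    sample are ``not_testable`` and excluded from the BH family.
    """
    vec_a, vec_b = _column_vectors(het_a), _column_vectors(het_b)
    variants = sorted(set(vec_a) | set(vec_b))
    rows = []
    for vid in variants:
        a = vec_a.get(vid, np.array([]))
        b = vec_b.get(vid, np.array([]))
        testable = a.size > 0 and b.size > 0
        mean_a = float(a.mean()) if a.size else np.nan
        mean_b = float(b.mean()) if b.size else np.nan
        if testable:
            fc = (mean_b + FC_PSEUDOCOUNT) / (mean_a + FC_PSEUDOCOUNT)
            p = _wilcoxon_p(a, b)
        else:
            fc, p = np.nan, np.nan
        rows.append(
            {
                "variant_id": vid,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fc,
                "wilcoxon_p": p,
                "testable": testable,
            }
        )
    out = pd.DataFrame(rows).set_index("variant_id")
    out["wilcoxon_q"] = np.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        out.loc[mask, "wilcoxon_q"] = multipletests(
            out.loc[mask, "wilcoxon_p"], method="fdr_bh"
        )[1]
    big_fc = (out["fold_change"] >= fc_threshold) | (
        out["fold_change"] <= 1.0 / fc_threshold
    )
    out["class"] = np.where(
        ~out["testable"],
        "not_testable",
        np.where((out["wilcoxon_q"] <= alpha) & big_fc, "shifted_mean", "stable"),
    )
    return out


def ks_shift_test(
    het_a: pd.DataFrame,
    het_b: pd.DataFrame,
    min_cells: int = 100,
    alpha: float = 0.05,
    gate: str = "both",
) -> pd.DataFrame:
    """Distribution-shift screen: two-sample KS with BH over gated variants.

    ``gate="both"`` (default) requires at least ``min_cells`` non-missing
    cells in each sample; ``gate="any"`` requires it in at least one, the
    literal reading of the cell-count rule.  Non-testable variants are
    excluded from the BH family.  P-values are asymptotic.
    """
    if gate not in ("both", "any"):
        raise ValueError("gate must be 'both' or 'any'")
    vec_a, vec_b = _column_vectors(het_a), _column_vectors(het_b)
    variants = sorted(set(vec_a) | set(vec_b))
    rows = []
    for vid in variants:
        a = vec_a.get(vid, np.array([]))
        b = vec_b.get(vid, np.array([]))
        if gate == "both":
            testable = a.size >= min_cells and b.size >= min_cells
        else:
            testable = (a.size >= min_cells or b.size >= min_cells) and min(
                a.size, b.size
            ) > 0
        if testable:
            res = stats.ks_2samp(a, b, method="asymp")
            d, p = float(res.statistic), float(res.pvalue)
        else:
            d, p = np.nan, np.nan
        rows.append(
            {
                "variant_id": vid,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "ks_D": d,
                "ks_p": p,
                "testable_ks": testable,
            }
        )
    out = pd.DataFrame(rows).set_index("variant_id")
    out["ks_q"] = np.nan
    mask = out["testable_ks"].to_numpy()
    if mask.any():
        out.loc[mask, "ks_q"] = multipletests(out.loc[mask, "ks_p"], method="fdr_bh")[1]
    out["class"] = np.where(
        ~out["testable_ks"],
        "not_testable",
        np.where(out["ks_q"] <= alpha, "shifted_distribution", "stable"),
    )
    return out


def combine_shift_results(
    mean_screen: pd.DataFrame, ks_screen: pd.DataFrame
) -> pd.DataFrame:
    """Join both screens into one table with a combined classification.

    Classes: ``stable``, ``shifted_mean``, ``shifted_distribution``,
    ``shifted_both``, ``not_testable`` (not testable by either screen).
    """
    out = mean_screen.drop(columns=["class"]).join(
        ks_screen.drop(columns=["n_a", "n_b", "class"]), how="outer"
    )
    mean_hit = (mean_screen["class"] == "shifted_mean").reindex(out.index, fill_value=False)
    ks_hit = (ks_screen["class"] == "shifted_distribution").reindex(out.index, fill_value=False)
    any_testable = out["testable"].fillna(False) | out["testable_ks"].fillna(False)
    combined = np.select(
        [
            mean_hit & ks_hit,
            mean_hit,
            ks_hit,
            any_testable,
        ],
        ["shifted_both", "shifted_mean", "shifted_distribution", "stable"],
        default="not_testable",
    )
    out["class"] = combined
    return out


@dataclass
class QQCurve:
    """Paired empirical quantiles of two heteroplasmy samples."""

    variant_id: str
    probs: np.ndarray
    quantiles_a: np.ndarray
    quantiles_b: np.ndarray

    @property
    def max_deviation(self) -> float:
        """Largest vertical distance from the identity line."""
        return float(np.max(np.abs(self.quantiles_b - self.quantiles_a)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "prob": self.probs,
                "quantile_a": self.quantiles_a,
                "quantile_b": self.quantiles_b,
            }
        )


def qq_curve(
    a: np.ndarray,
    b: np.ndarray,
    n_quantiles: int = 100,
    variant_id: str = "",
) -> QQCurve:
    """Empirical quantiles of both samples on a shared probability grid.

    Linear (type-7) interpolation; both inputs need at least two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("qq_curve needs at least 2 values per sample")
    probs = np.linspace(0.0, 1.0, n_quantiles)
    qa = np.quantile(a, probs)  # numpy default is type-7 linear interpolation
    qb = np.quantile(b, probs)
    return QQCurve(variant_id=variant_id, probs=probs, quantiles_a=qa, quantiles_b=qb)


def compartment_enrichment(
    het_physiologic: pd.DataFrame,
    het_monoclonal: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Classify variants as shared, enriched or depleted in the monoclonal
    compartment relative to physiologic B cells.

    Enriched: BH q <= alpha and fold change (monoclonal/physiologic)
    >= fc_threshold; depleted: q <= alpha and fold change <= 1/fc_threshold;
    otherwise shared.  Variants with fewer than ``min_cells`` covered cells in
    either compartment are reported shared with ``not_powered`` set.
    """
    screen = mean_shift_screen(
        het_physiologic, het_monoclonal, fc_threshold=fc_threshold, alpha=alpha
    )
    powered = (screen["n_a"] >= min_cells) & (screen["n_b"] >= min_cells)
    significant = screen["wilcoxon_q"] <= alpha
    cls = np.select(
        [
            powered & significant & (screen["fold_change"] >= fc_threshold),
            powered & significant & (screen["fold_change"] <= 1.0 / fc_threshold),
        ],
        ["enriched", "depleted"],
        default="shared",
    )
    out = screen.drop(columns=["class"]).copy()
    out["not_powered"] = ~powered
    out["class"] = cls
    return out
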