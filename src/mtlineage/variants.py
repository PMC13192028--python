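"""mtDNA variant calling: heteroplasmy, quality filters, burden, genotyping.

High-confidence variants are retained when they are present in more than 4
cells, show a variance-to-mean ratio of per-cell heteroplasmy above 0.01 and a
strand concordance above 0.65, are not homoplasmic across compartments, and are
not on the artifact blacklist (310T>C by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import BaseCountTensor
from .genome import BASES, parse_variant_id, variant_id

logger = logging.getLogger(__name__)

#: Variants excluded a priori as recurrent sequencing artifacts.
DEFAULT_BLACKLIST = frozenset({"310T>C"})


@dataclass(frozen=True)
class VariantCall:
    """Filter statistics for one candidate variant.

    ``strand_concordance`` is the Pearson correlation between per-cell plus-
    and minus-strand alternate-read counts over covered, detected cells; it is
    ``-inf`` when undefined (fewer than two detected cells, or a constant
    strand vector), which conservatively fails the concordance filter.
    """

    variant_id: str
    n_cells_detected: int
    mean_heteroplasmy: float
    vmr: float
    strand_concordance: float
    pass_filters: bool = False
    fail_reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_heteroplasmy <= 1.0:
            raise ValueError("mean_heteroplasmy outside [0, 1]")
        if self.vmr < 0:
            raise ValueError("vmr must be non-negative")
        if self.pass_filters != (len(self.fail_reasons) == 0) and self.pass_filters:
            raise ValueError("pass_filters requires empty fail_reasons")


def compute_heteroplasmy(
    tensor: BaseCountTensor,
    variant_ids: Sequence[str],
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Cells x variants allele-fraction matrix.

    Entry = (alt+ + alt-)/(total+ + total-) at the variant's position; NaN
    when total coverage is below ``min_coverage``.  A variant whose ALT equals
    the stored reference base is rejected.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    coverage = tensor.coverage()
    columns = {}
    for vid in variant_ids:
        pos, ref, alt = parse_variant_id(vid)
        if tensor.ref_base(pos) != ref:
            raise ValueError(
                f"{vid}: REF {ref} does not match reference base "
                f"{tensor.ref_base(pos)} at position {pos}"
            )
        plus, minus = tensor.allele_counts(pos, alt)
        total = coverage[:, tensor.position_index(pos)].astype(float)
        alt_total = (plus + minus).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            het = np.where(total > 0, alt_total / np.maximum(total, 1), 0.0)
        het = np.where(total >= min_coverage, het, np.nan)
        columns[vid] = het
    return pd.DataFrame(columns, index=pd.Index(tensor.barcodes, name="cell"))


def discover_variants(tensor: BaseCountTensor, min_alt_reads: int = 1) -> list[str]:
    """Candidate variants: every non-reference base with at least
    ``min_alt_reads`` reads (both strands summed) in at least one cell."""
    totals = tensor.counts.sum(axis=3)  # (N, P, 4)
    out = []
    for pi, pos in enumerate(tensor.positions):
        ref = str(tensor.ref_bases[pi])
        for bi, base in enumerate(BASES):
            if base == ref:
                continue
            if (totals[:, pi, bi] >= min_alt_reads).any():
                out.append(variant_id(int(pos), ref, base))
    return out


def variant_statistics(
    tensor: BaseCountTensor,
    vid: str,
    detection_threshold: float = 0.01,
    min_coverage: int = 5,
) -> VariantCall:
    """Compute the three filter statistics for one variant.

    A cell is *covered* when position coverage >= ``min_coverage`` and
    *detected* when additionally heteroplasmy >= ``detection_threshold``.
    VMR is sample variance (n-1 denominator) over mean of per-cell
    heteroplasmy across covered cells (0 when the mean is 0).
    """
    pos, _ref, alt = parse_variant_id(vid)
    het = compute_heteroplasmy(tensor, [vid], min_coverage=min_coverage)[vid].to_numpy()
    covered = ~np.isnan(het)
    het_cov = het[covered]
    detected = covered & (np.nan_to_num(het, nan=0.0) >= detection_threshold)
    n_detected = int(detected.sum())

    if het_cov.size == 0 or het_cov.mean() == 0:
        mean_het, vmr = (float(het_cov.mean()) if het_cov.size else 0.0), 0.0
    else:
        mean_het = float(het_cov.mean())
        var = float(het_cov.var(ddof=1)) if het_cov.size > 1 else 0.0
        vmr = var / mean_het

    plus, minus = tensor.allele_counts(pos, alt)
    p, m = plus[detected].astype(float), minus[detected].astype(float)
    if n_detected < 2 or p.std() == 0 or m.std() == 0:
        concordance = float("-inf")
    else:
        concordance = float(np.corrcoef(p, m)[0, 1])

    return VariantCall(
        variant_id=vid,
        n_cells_detected=n_detected,
        mean_heteroplasmy=mean_het,
        vmr=vmr,
        strand_concordance=concordance,
    )


def call_variants(
    tensor: BaseCountTensor,
    variant_ids: Sequence[str] | None = None,
    detection_threshold: float = 0.01,
    min_coverage: int = 5,
    min_alt_reads: int = 1,
) -> list[VariantCall]:
    """Statistics for every candidate (or supplied) variant."""
    if variant_ids is None:
        variant_ids = discover_variants(tensor, min_alt_reads=min_alt_reads)
    return [
        variant_statistics(tensor, vid, detection_threshold, min_coverage)
        for vid in variant_ids
    ]


def filter_variants(
    calls: Iterable[VariantCall],
    blacklist: frozenset[str] | set[str] = DEFAULT_BLACKLIST,
    homoplasmy_cutoff: float = 0.9,
    min_cells: int = 4,
    vmr_threshold: float = 0.01,
    concordance_threshold: float = 0.65,
    compartment_means: Mapping[str, Sequence[float]] | None = None,
) -> list[VariantCall]:
    """Apply the high-confidence filters, annotating each failure.

    Pass requires n_cells_detected strictly > ``min_cells``, VMR strictly >
    ``vmr_threshold``, strand concordance strictly > ``concordance_threshold``,
    id not blacklisted, and not homoplasmic.  A variant counts as homoplasmic
    when its mean heteroplasmy is >= ``homoplasmy_cutoff`` in *every*
    compartment (``compartment_means`` maps variant id to per-compartment
    means; without it the overall mean is treated as a single compartment).
    """
    out = []
    for call in calls:
        reasons: set[str] = set()
        if call.n_cells_detected <= min_cells:
            reasons.add("n_cells")
        if not call.vmr > vmr_threshold:
            reasons.add("vmr")
        if not call.strand_concordance > concordance_threshold:
            reasons.add("strand_concordance")
        if call.variant_id in blacklist:
            reasons.add("blacklist")
        if compartment_means is not None and call.variant_id in compartment_means:
            means = list(compartment_means[call.variant_id])
        else:
            means = [call.mean_heteroplasmy]
        if means and min(means) >= homoplasmy_cutoff:
            reasons.add("homoplasmic")
        out.append(
            replace(call, pass_filters=not reasons, fail_reasons=frozenset(reasons))
        )
    return out


def passing_ids(calls: Iterable[VariantCall]) -> list[str]:
    return [c.variant_id for c in calls if c.pass_filters]


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": c.variant_id,
            "n_cells_detected": c.n_cells_detected,
            "mean_heteroplasmy": c.mean_heteroplasmy,
            "vmr": c.vmr,
            "strand_concordance": c.strand_concordance,
            "pass": c.pass_filters,
            "fail_reasons": ",".join(sorted(c.fail_reasons)),
        }
        for c in calls
    ]
    return pd.DataFrame(rows).set_index("variant_id")


def mutation_burden(
    het: pd.DataFrame,
    groups: pd.Series,
    coverage: pd.Series,
    n_downsample: int = 100,
    het_threshold: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Depth-normalized mutation counts per (donor, cell-type) group.

    Each group is down-sampled without replacement to ``n_downsample`` cells;
    the number of variants with mean heteroplasmy above ``het_threshold``
    within the sampled cells is divided by the group's mean per-cell mtDNA
    coverage relative to the cohort mean.  Groups with fewer cells than
    ``n_downsample`` are skipped and logged.
    """
    rng = np.random.default_rng(seed)
    cohort_mean_cov = float(coverage.mean())
    rows = []
    for group, cells in groups.groupby(groups).groups.items():
        cells = list(cells)
        if len(cells) < n_downsample:
            logger.info("skipping group %s: %d < %d cells", group, len(cells), n_downsample)
            continue
        sampled = list(rng.choice(np.array(cells, dtype=object), size=n_downsample, replace=False))
        sub = het.loc[sampled]
        n_variants = int((sub.mean(axis=0, skipna=True) > het_threshold).sum())
        rel_depth = float(coverage.loc[sampled].mean()) / cohort_mean_cov
        rows.append(
            {
                "group": group,
                "n_cells": len(cells),
                "n_variants": n_variants,
                "relative_depth": rel_depth,
                "burden": n_variants / rel_depth if rel_depth > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recurrence_table(
    donor_variants: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict]:
    """Number of donors carrying each passing variant, plus cohort totals.

    A variant is *non-recurrent* when it appears in exactly one donor.
    """
    if not donor_variants:
        raise ValueError("at least one donor required")
    counts: dict[str, int] = {}
    for _donor, vids in donor_variants.items():
        for vid in set(vids):
            counts[vid] = counts.get(vid, 0) + 1
    table = (
        pd.DataFrame(
            {"variant_id": list(counts), "n_donors": list(counts.values())}
        )
        .sort_values(["n_donors", "variant_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    n_total = len(table)
    n_nonrec = int((table["n_donors"] == 1).sum())
    summary = {
        "n_variants": n_total,
        "n_non_recurrent": n_nonrec,
        "fraction_non_recurrent": n_nonrec / n_total if n_total else np.nan,
        "max_recurrence": int(table["n_donors"].max()) if n_total else 0,
    }
    return table, summary


def genotype_cells(
    counts: pd.DataFrame,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-cell somatic genotype from targeted amplicon read counts.

    ``counts`` needs columns ``mutant_reads`` and ``wildtype_reads``.  A cell
    is called only with at least ``min_reads`` total reads; it is *mutant*
    when strictly more reads support the mutant allele, otherwise *wildtype*
    (ties are wildtype).
    """
    mut = counts["mutant_reads"].to_numpy()
    wt = counts["wildtype_reads"].to_numpy()
    if (mut < 0).any() or (wt < 0).any():
        raise ValueError("negative read counts")
    total = mut + wt
    call = np.where(
        total < min_reads, "unassigned", np.where(mut > wt, "mutant", "wildtype")
    )
    out = counts.copy()
    out["call"] = call
    return out
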