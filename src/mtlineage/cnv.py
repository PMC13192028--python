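"""Sliding-window copy-number inference from single-cell chromatin fragments.

Overlapping genome bins (10 Mb, step 2 Mb by default) are filled with
per-cell fragment counts; the target population's depth-normalized per-bin
mean is compared with a reference cell population (e.g. T cells) as a
standardized deviation z-score, and maximal runs of consistently deviant bins
become gain/loss segment calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 10_000_000
DEFAULT_STEP = 2_000_000


def make_bins(
    chrom_sizes: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Overlapping bins tiling each contig: 0-based half-open, fixed step.

    Terminal bins shorter than ``bin_size`` are kept and flagged; their counts
    are length-normalized downstream.
    """
    if bin_size <= 0 or step <= 0 or step > bin_size:
        raise ValueError("need 0 < step <= bin_size")
    rows = []
    for chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        for start in range(0, size, step):
            end = min(start + bin_size, size)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "terminal": end - start < bin_size,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GenomeBinMatrix:
    """Cells x overlapping genome bins fragment counts."""

    bins: pd.DataFrame  # chrom, start, end, terminal
    barcodes: list[str]
    counts: np.ndarray  # (n_cells, n_bins) int64
    n_skipped_fragments: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.barcodes), len(self.bins)):
            raise ValueError("counts shape does not match barcodes x bins")
        if (self.counts < 0).any():
            raise ValueError("negative fragment counts")

    @property
    def cell_depth(self) -> np.ndarray:
        """Total binned fragments per cell (overlap-inflated but consistent)."""
        return self.counts.sum(axis=1)

    def subset_cells(self, barcodes: list[str]) -> "GenomeBinMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = [index[b] for b in barcodes]
        return GenomeBinMatrix(
            bins=self.bins, barcodes=list(barcodes), counts=self.counts[rows]
        )


def bin_fragments(
    fragments: pd.DataFrame,
    barcodes: list[str],
    chrom_sizes: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    step: int = DEFAULT_STEP,
) -> GenomeBinMatrix:
    """Count fragments into overlapping bins by fragment midpoint.

    A fragment is counted once in every bin containing its midpoint
    (``(start + end) // 2``), so each fragment contributes to exactly
    ``bin_size / step`` interior bins.  Fragments on contigs absent from
    ``chrom_sizes`` or with unknown barcodes are skipped (count logged).
    """
    bins = make_bins(chrom_sizes, bin_size=bin_size, step=step)
    fragments = fragments.reset_index(drop=True)
    cell_index = {b: i for i, b in enumerate(barcodes)}
    n_cells, n_bins = len(barcodes), len(bins)
    counts = np.zeros((n_cells, n_bins), dtype=np.int64)

    # first bin row of each chromosome, for offsetting midpoint // step
    chrom_offset = {}
    for chrom in chrom_sizes:
        rows = bins.index[bins["chrom"] == chrom]
        chrom_offset[chrom] = (int(rows[0]), len(rows))

    skipped = 0
    weights = (
        fragments["count"].to_numpy()
        if "count" in fragments.columns
        else np.ones(len(fragments), dtype=np.int64)
    )
    n_overlap = bin_size // step  # bins covering one midpoint
    for chrom, group_idx in fragments.groupby("chrom", sort=False).groups.items():
        if chrom not in chrom_offset:
            skipped += len(group_idx)
            continue
        sub = fragments.loc[group_idx]
        cells = sub["barcode"].map(cell_index)
        known = cells.notna().to_numpy()
        skipped += int((~known).sum())
        if not known.any():
            continue
        cells_arr = cells.to_numpy()[known].astype(np.int64)
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)[known]
        w = weights[group_idx][known] if "count" in fragments.columns else np.ones(known.sum(), dtype=np.int64)
        offset, n_chrom_bins = chrom_offset[chrom]
        last = mids // step  # index (within chrom) of last bin starting at/before mid
        for back in range(n_overlap):
            j = last - back
            ok = (j >= 0) & (j < n_chrom_bins)
            if not ok.any():
                continue
            np.add.at(counts, (cells_arr[ok], offset + j[ok]), w[ok])
    if skipped:
        logger.info("skipped %d fragments on unknown contigs/barcodes", skipped)
    return GenomeBinMatrix(
        bins=bins, barcodes=list(barcodes), counts=counts, n_skipped_fragments=skipped
    )


@dataclass
class CNVProfile:
    """Per-bin deviation of a target population from its reference."""

    bins: pd.DataFrame
    zscores: np.ndarray  # per-bin population z; NaN where masked
    cell_z: np.ndarray  # (n_target_cells, n_bins) per-cell z for plotting
    segments: pd.DataFrame  # chrom, start, end, direction, mean_z, n_bins

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["z"] = self.zscores
        return out


def cnv_deviation(
    target: GenomeBinMatrix,
    reference: GenomeBinMatrix,
    min_ref_cells: int = 50,
    min_bins: int = 5,
    z_threshold: float = 3.0,
) -> CNVProfile:
    """Standardized deviation of target bin counts versus a reference population.

    Every cell is scaled to a consistent sequencing depth, where a cell's
    depth is its *median* bin count (terminal bins length-normalized first).
    The median bin is copy-neutral as long as aberrant bins are a minority,
    so a large gain does not deflate neutral bins the way total-count
    normalization would.  Per bin with reference mean mu and SD sigma of the
    normalized counts, the population score is
    ``z = (mean target - mu) / (sigma / sqrt(n_target))``.  Bins with sigma=0
    are masked.  Segments are maximal runs of at least ``min_bins``
    consecutive bins with |z| >= ``z_threshold`` and consistent sign.
    """
    if not target.bins.equals(reference.bins):
        raise ValueError("target and reference use different bin sets")
    if len(reference.barcodes) < min_ref_cells:
        raise ValueError(
            f"reference has {len(reference.barcodes)} cells < min_ref_cells={min_ref_cells}"
        )
    bins = target.bins
    bin_len = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    full = float(bin_len.max())
    length_scale = full / bin_len  # length-normalize terminal bins

    def _length_normalized(mat: GenomeBinMatrix) -> np.ndarray:
        return mat.counts * length_scale[None, :]

    def _cell_depth(scaled: np.ndarray) -> np.ndarray:
        depth = np.median(scaled, axis=1)
        depth[depth <= 0] = np.nan
        return depth

    t_scaled = _length_normalized(target)
    r_scaled = _length_normalized(reference)

    def _zscores(neutral: np.ndarray):
        """Normalize depths on ``neutral`` bins only, then score every bin."""
        t_depth = _cell_depth(t_scaled[:, neutral])
        r_depth = _cell_depth(r_scaled[:, neutral])
        median_depth = float(np.nanmedian(np.concatenate([t_depth, r_depth])))
        t_norm = t_scaled * (median_depth / t_depth)[:, None]
        r_norm = r_scaled * (median_depth / r_depth)[:, None]
        mu = np.nanmean(r_norm, axis=0)
        sigma = np.nanstd(r_norm, axis=0, ddof=1)
        n_target = np.sum(~np.isnan(t_norm[:, 0]))
        t_mean = np.nanmean(t_norm, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (t_mean - mu) / (sigma / np.sqrt(max(n_target, 1)))
            cell_z = (t_norm - mu[None, :]) / sigma[None, :]
        z[sigma == 0] = np.nan
        cell_z[:, sigma == 0] = np.nan
        return z, cell_z

    # two passes: aberrant bins found in pass 1 are excluded from the per-cell
    # depth estimate, removing the compositional bias large events induce
    n_bins = len(bins)
    z, cell_z = _zscores(np.ones(n_bins, dtype=bool))
    neutral = ~np.isnan(z) & (np.abs(z) < z_threshold)
    if neutral.sum() >= max(5, n_bins // 5):
        z, cell_z = _zscores(neutral)

    segments = _call_segments(bins, z, min_bins=min_bins, z_threshold=z_threshold)
    return CNVProfile(bins=bins, zscores=z, cell_z=cell_z, segments=segments)


def _call_segments(
    bins: pd.DataFrame, z: np.ndarray, min_bins: int, z_threshold: float
) -> pd.DataFrame:
    rows = []
    for chrom in bins["chrom"].unique():
        idx = bins.index[bins["chrom"] == chrom].to_numpy()
        signs = np.where(
            np.isnan(z[idx]), 0, np.sign(z[idx]) * (np.abs(z[idx]) >= z_threshold)
        ).astype(int)
        start = None
        for i, s in enumerate(np.append(signs, 0)):
            if start is not None and (i == len(signs) or s != signs[start]):
                run = idx[start:i]
                if len(run) >= min_bins and signs[start] != 0:
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(bins.loc[run[0], "start"]),
                            "end": int(bins.loc[run[-1], "end"]),
                            "direction": "gain" if signs[start] > 0 else "loss",
                            "mean_z": float(np.nanmean(z[run])),
                            "n_bins": len(run),
                        }
                    )
                start = None
            if start is None and i < len(signs) and s != 0:
                start = i
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "mean_z", "n_bins"]
    )
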