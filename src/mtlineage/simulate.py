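"""Ground-truthed synthetic single-cell mtDNA data.

The generator realizes the statistical structure the downstream analysis
assumes: clonal populations carrying marker mtDNA mutations at heterogeneous
founding heteroplasmies, per-cell heteroplasmy dispersion from stochastic
mitochondrial segregation (a single Beta draw per cell with concentration
``dispersion_c``, the marginal of a per-division binomial genealogy),
negative-binomial position coverage, binomial strand splitting (fair for
genuine variants, biased for artifacts), near-homoplasmic germline variants,
injected longitudinal heteroplasmy shifts, planted chromosomal gains/losses in
a synthetic nuclear genome, and clone-linked BCR clonotype labels.

Everything is reproducible byte-for-byte given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts import BaseCountTensor
from .genome import BASES, MT_GENOME_LENGTH, synthetic_reference, variant_id

GERMLINE_HETEROPLASMY = 0.995
MAX_SHIFTED_HETEROPLASMY = 0.95

# Scaled-down nuclear genome: enough contigs that any single planted event
# covers only a minority of 10-Mb windows, as real chromosomal events do.
DEFAULT_GENOME = {
    "chr1": 100_000_000,
    "chr2": 90_000_000,
    "chr3": 80_000_000,
    "chr4": 70_000_000,
    "chr5": 60_000_000,
    "chr6": 50_000_000,
}

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic sample (or a matched pair)."""

    n_cells: int = 1000
    n_clones: int = 5
    polyclonal_fraction: float = 0.2
    markers_per_clone: int = 3
    founding_heteroplasmy_range: tuple[float, float] = (0.05, 0.4)
    dispersion_c: float = 50.0
    n_germline_variants: int = 3
    n_artifact_variants: int = 3
    artifact_heteroplasmy_range: tuple[float, float] = (0.03, 0.10)
    mean_depth: float = 100.0
    depth_dispersion: float = 2.0
    strand_bias_artifact: float = 0.05
    injected_shifts: dict[str, float] = field(default_factory=dict)
    planted_cnvs: tuple[tuple[str, int, int, int], ...] = ()
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    mean_fragments_per_cell: float = 5000.0
    fragment_length: int = 150
    coverage_multipliers: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def n_variants(self) -> int:
        return (
            self.n_clones * self.markers_per_clone
            + self.n_germline_variants
            + self.n_artifact_variants
        )

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_clones <= 0:
            raise ValueError("n_cells and n_clones must be positive")
        if not 0.0 <= self.polyclonal_fraction <= 1.0:
            raise ValueError("polyclonal_fraction outside [0, 1]")
        lo, hi = self.founding_heteroplasmy_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founding_heteroplasmy_range must lie within (0, 1)")
        lo, hi = self.artifact_heteroplasmy_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("artifact_heteroplasmy_range must lie within (0, 1)")
        if self.dispersion_c <= 0:
            raise ValueError("dispersion_c must be positive")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")
        if not 0.0 <= self.strand_bias_artifact <= 1.0:
            raise ValueError("strand_bias_artifact outside [0, 1]")
        if min(self.markers_per_clone, self.n_germline_variants, self.n_artifact_variants) < 0:
            raise ValueError("variant counts must be non-negative")
        # distinct positions are sampled without replacement, so a collision
        # between marker and germline/artifact positions is only possible when
        # the request exceeds the genome
        if self.n_variants() > MT_GENOME_LENGTH - 1:
            raise ValueError("more variants requested than mtDNA positions available")
        for chrom, start, end, copy in self.planted_cnvs:
            if chrom not in self.genome:
                raise ValueError(f"planted CNV on unknown contig {chrom}")
            if not 0 <= start < end <= self.genome[chrom]:
                raise ValueError(f"planted CNV interval invalid: {chrom}:{start}-{end}")
            if copy not in (1, 3):
                raise ValueError("copy number must be 1 or 3 (diploid baseline 2)")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated population (or matched pair)."""

    clone_labels: pd.Series  # cell -> true clone (0 = polyclonal background)
    variants: pd.DataFrame  # id -> class, clone, founding_h (+ founding_h_b when paired)
    shifts: dict[str, float]
    cnv_segments: tuple[tuple[str, int, int, int], ...]
    bcr_clonotypes: pd.Series  # cell -> true BCR clonotype
    clone_labels_b: pd.Series | None = None
    bcr_clonotypes_b: pd.Series | None = None


@dataclass
class SimulatedSample:
    tensor: BaseCountTensor
    clone_labels: pd.Series
    repertoire: pd.DataFrame  # AIRR-style: cell_id, clone_id, junction_aa
    fragments: pd.DataFrame  # chrom, start, end, barcode, count (0-based half-open)


def _make_structure(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the variant table shared by all samples of one population."""
    ref = synthetic_reference()
    n_var = config.n_variants()
    positions = np.sort(rng.choice(np.arange(1, MT_GENOME_LENGTH + 1), size=n_var, replace=False))
    classes = (
        ["marker"] * (config.n_clones * config.markers_per_clone)
        + ["germline"] * config.n_germline_variants
        + ["artifact"] * config.n_artifact_variants
    )
    order = rng.permutation(n_var)  # decouple class from genomic position
    lo, hi = config.founding_heteroplasmy_range
    alo, ahi = config.artifact_heteroplasmy_range
    rows = []
    marker_i = 0
    for slot, pos in zip(order, positions):
        cls = classes[slot]
        ref_base = str(ref[pos - 1])
        alt = rng.choice([b for b in BASES if b != ref_base])
        if cls == "marker":
            clone = marker_i % config.n_clones + 1
            marker_i += 1
            h = rng.uniform(lo, hi)
        elif cls == "germline":
            clone, h = 0, GERMLINE_HETEROPLASMY
        else:
            clone, h = 0, rng.uniform(alo, ahi)
        rows.append(
            {
                "variant_id": variant_id(int(pos), ref_base, str(alt)),
                "position": int(pos),
                "ref": ref_base,
                "alt": str(alt),
                "class": cls,
                "clone": clone,
                "founding_h": float(h),
            }
        )
    frame = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    return frame.set_index("variant_id")


def _latent_heteroplasmy(
    variants: pd.DataFrame,
    clone_labels: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    founding_col: str = "founding_h",
) -> np.ndarray:
    """Per-cell latent heteroplasmy: Beta(h*c, (1-h)*c) around each founding h."""
    n, v = len(clone_labels), len(variants)
    c = config.dispersion_c
    latent = np.zeros((n, v))
    for j, (_vid, row) in enumerate(variants.iterrows()):
        h = row[founding_col]
        if row["class"] == "marker":
            members = clone_labels == row["clone"]
            k = int(members.sum())
            if k:
                latent[members, j] = rng.beta(h * c, (1 - h) * c, size=k)
        elif row["class"] == "germline":
            latent[:, j] = h
        else:  # artifact: present in every cell at low heteroplasmy
            latent[:, j] = rng.beta(h * c, (1 - h) * c, size=n)
    return latent


def _simulate_fragments(
    barcodes: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-cell chromatin fragments; Poisson rate scales with local copy number."""
    segments: list[tuple[str, int, int, int]] = []
    for chrom, size in config.genome.items():
        events = sorted(
            [(s, e, c) for ch, s, e, c in config.planted_cnvs if ch == chrom]
        )
        cursor = 0
        for s, e, c in events:
            if s > cursor:
                segments.append((chrom, cursor, s, 2))
            segments.append((chrom, s, e, c))
            cursor = e
        if cursor < size:
            segments.append((chrom, cursor, size, 2))
    total_len = sum(config.genome.values())
    rate_per_bp = config.mean_fragments_per_cell / total_len  # at diploid copy
    n = len(barcodes)
    chroms, starts, cells = [], [], []
    for chrom, s, e, copy in segments:
        lam = rate_per_bp * (e - s) * copy / 2.0
        per_cell = rng.poisson(lam, size=n)
        total = int(per_cell.sum())
        if total == 0:
            continue
        mids = rng.integers(s, e, size=total)
        chroms.append(np.full(total, chrom, dtype=object))
        starts.append(mids)
        cells.append(np.repeat(np.arange(n), per_cell))
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
    mids = np.concatenate(starts)
    start = np.maximum(mids - config.fragment_length // 2, 0)
    frame = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": start,
            "end": start + config.fragment_length,
            "barcode": np.array(barcodes, dtype=object)[np.concatenate(cells)],
            "count": 1,
        }
    )
    return frame.sort_values(["chrom", "start", "end", "barcode"]).reset_index(drop=True)


def _junction(rng: np.random.Generator) -> str:
    return "C" + "".join(rng.choice(_AMINO_ACIDS, size=11)) + "W"


def _realize_sample(
    variants: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    prefix: str,
    founding_col: str = "founding_h",
    with_fragments: bool = True,
) -> SimulatedSample:
    n, v = config.n_cells, len(variants)
    barcodes = [f"{prefix}BC{i:05d}" for i in range(n)]

    # clone membership: a fixed polyclonal background plus uniform clone draws
    labels = np.zeros(n, dtype=np.int64)
    n_background = int(round(config.polyclonal_fraction * n))
    order = rng.permutation(n)
    clonal = order[n_background:]
    labels[clonal] = rng.integers(1, config.n_clones + 1, size=clonal.size)

    latent = _latent_heteroplasmy(variants, labels, config, rng, founding_col)

    theta = config.depth_dispersion
    mean_depth = np.full(v, config.mean_depth)
    for j, pos in enumerate(variants["position"]):
        if int(pos) in config.coverage_multipliers:
            mean_depth[j] *= config.coverage_multipliers[int(pos)]
    p_nb = theta / (theta + mean_depth)
    coverage = rng.negative_binomial(theta, p_nb, size=(n, v))

    alt = rng.binomial(coverage, latent)
    strand_p = np.where(
        variants["class"].to_numpy() == "artifact", config.strand_bias_artifact, 0.5
    )
    alt_plus = rng.binomial(alt, strand_p)
    ref_reads = coverage - alt
    ref_plus = rng.binomial(ref_reads, 0.5)

    positions = variants["position"].to_numpy()
    ref_idx = np.array([BASES.index(b) for b in variants["ref"]])
    alt_idx = np.array([BASES.index(b) for b in variants["alt"]])
    counts = np.zeros((n, v, 4, 2), dtype=np.int64)
    cols = np.arange(v)
    counts[:, cols, alt_idx, 0] = alt_plus
    counts[:, cols, alt_idx, 1] = alt - alt_plus
    counts[:, cols, ref_idx, 0] += ref_plus
    counts[:, cols, ref_idx, 1] += ref_reads - ref_plus
    tensor = BaseCountTensor(
        barcodes=barcodes,
        positions=positions,
        ref_bases=variants["ref"].to_numpy(),
        counts=counts,
    )

    # BCR: the clone's clonotype for monoclonal cells, singletons otherwise
    junctions = {c: _junction(rng) for c in range(1, config.n_clones + 1)}
    clone_ids, junction_aa = [], []
    for i, lab in enumerate(labels):
        if lab == 0:
            clone_ids.append(f"IGH-S{i:05d}")
            junction_aa.append(_junction(rng))
        else:
            clone_ids.append(f"IGH-{lab:02d}")
            junction_aa.append(junctions[lab])
    repertoire = pd.DataFrame(
        {"cell_id": barcodes, "clone_id": clone_ids, "junction_aa": junction_aa}
    )

    # fragments are drawn last, so skipping them leaves all other draws intact
    if with_fragments:
        fragments = _simulate_fragments(barcodes, config, rng)
    else:
        fragments = pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
    clone_labels = pd.Series(labels, index=pd.Index(barcodes, name="cell"), name="clone")
    return SimulatedSample(tensor, clone_labels, repertoire, fragments)


def simulate_population(
    config: SimulationConfig,
    with_fragments: bool = True,
) -> tuple[SimulatedSample, SyntheticTruth]:
    """Simulate one clonal single-cell population with full ground truth.

    ``with_fragments=False`` skips the chromatin fragment file (the slowest
    part) without perturbing any other draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants = _make_structure(config, rng)
    sample = _realize_sample(variants, config, rng, prefix="", with_fragments=with_fragments)
    truth = SyntheticTruth(
        clone_labels=sample.clone_labels,
        variants=variants,
        shifts=dict(config.injected_shifts),
        cnv_segments=tuple(config.planted_cnvs),
        bcr_clonotypes=pd.Series(
            sample.repertoire["clone_id"].to_numpy(),
            index=pd.Index(sample.repertoire["cell_id"], name="cell"),
            name="bcr_clonotype",
        ),
    )
    return sample, truth


def simulate_paired_timepoints(
    config: SimulationConfig,
    with_fragments: bool = False,
) -> tuple[SimulatedSample, SimulatedSample, SyntheticTruth]:
    """Two samples from the same clone structure, with shifts injected in B.

    Sample B is regenerated from the same founding heteroplasmies except for
    the variants listed in ``injected_shifts`` (id -> mean multiplier, clipped
    at 0.95); unshifted variants share identical generating parameters, so an
    empty shift list makes A and B exchangeable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants = _make_structure(config, rng)
    for vid in config.injected_shifts:
        if vid not in variants.index:
            raise ValueError(f"injected shift on unknown variant {vid}")
    variants = variants.copy()
    founding_b = variants["founding_h"].copy()
    for vid, mult in config.injected_shifts.items():
        founding_b.loc[vid] = min(
            variants.loc[vid, "founding_h"] * mult, MAX_SHIFTED_HETEROPLASMY
        )
    variants["founding_h_b"] = founding_b

    rng_a, rng_b = rng.spawn(2)
    sample_a = _realize_sample(
        variants, config, rng_a, prefix="A-", with_fragments=with_fragments
    )
    sample_b = _realize_sample(
        variants, config, rng_b, prefix="B-", founding_col="founding_h_b",
        with_fragments=with_fragments,
    )
    truth = SyntheticTruth(
        clone_labels=sample_a.clone_labels,
        variants=variants,
        shifts=dict(config.injected_shifts),
        cnv_segments=tuple(config.planted_cnvs),
        bcr_clonotypes=pd.Series(
            sample_a.repertoire["clone_id"].to_numpy(),
            index=pd.Index(sample_a.repertoire["cell_id"], name="cell"),
            name="bcr_clonotype",
        ),
        clone_labels_b=sample_b.clone_labels,
        bcr_clonotypes_b=pd.Series(
            sample_b.repertoire["clone_id"].to_numpy(),
            index=pd.Index(sample_b.repertoire["cell_id"], name="cell"),
            name="bcr_clonotype",
        ),
    )
    return sample_a, sample_b, truth


def reference_population(config: SimulationConfig, seed: int | None = None) -> SimulatedSample:
    """A copy-neutral companion population (e.g. T cells) for CNV referencing.

    Same genome and fragment depth, no clonal structure, no planted CNVs.
    """
    ref_config = replace(
        config,
        planted_cnvs=(),
        n_clones=1,
        polyclonal_fraction=1.0,
        seed=config.seed if seed is None else seed,
    )
    sample, _ = simulate_population(ref_config)
    sample = replace_barcode_prefix(sample, "REF-")
    return sample


def replace_barcode_prefix(sample: SimulatedSample, prefix: str) -> SimulatedSample:
    mapping = {b: prefix + b for b in sample.tensor.barcodes}
    tensor = BaseCountTensor(
        barcodes=[mapping[b] for b in sample.tensor.barcodes],
        positions=sample.tensor.positions.copy(),
        ref_bases=sample.tensor.ref_bases.copy(),
        counts=sample.tensor.counts.copy(),
    )
    clone_labels = sample.clone_labels.rename(index=mapping)
    repertoire = sample.repertoire.assign(
        cell_id=sample.repertoire["cell_id"].map(mapping)
    )
    fragments = sample.fragments.assign(
        barcode=sample.fragments["barcode"].map(mapping)
    )
    return SimulatedSample(tensor, clone_labels, repertoire, fragments)
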