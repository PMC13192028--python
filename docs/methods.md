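# Methods

This note documents the models, estimators and numerical choices behind
`mtlineage`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The data model

The raw substrate is a per-cell, per-mtDNA-position, per-base, per-strand
read-count tensor (the layout mgatk-style callers emit). Heteroplasmy of a
variant in a cell is the allele fraction

    h = (alt+ + alt-) / (total+ + total-),

treated as *missing* (not zero) when position coverage is below
`min_coverage` (default 5 reads). Missingness and zero are kept distinct
throughout: stored heteroplasmy matrices carry an explicit coverage mask,
clustering imputes missing as 0 (absence of evidence), and per-clone mean
profiles average over covered cells only. Mitochondrial coordinates are
1-based (variant ids like `7161G>A`); nuclear fragments and bins are 0-based
half-open (BED convention).

## High-confidence variant filters

A candidate variant passes when all of the following hold:

| filter | default | rationale |
| --- | --- | --- |
| cells detected | > 4 | a cell detects a variant at coverage ≥ 5 and h ≥ 1% |
| variance/mean ratio of per-cell h | > 0.01 | genuine clonal variation, not uniform noise |
| strand concordance | > 0.65 | Pearson r of per-cell (+) vs (−) alternate-read counts over detected cells |
| homoplasmy | mean h < 0.9 in at least one compartment | near-homoplasmic germline variants carry no lineage signal |
| blacklist | `310T>C` excluded | recurrent technical artifact |

Undefined strand correlations (fewer than two detected cells, or a constant
strand vector) are assigned −∞ and therefore fail — conservative artifact
handling. VMR uses the sample variance (n−1) of per-cell heteroplasmy, the
scale on which the 0.01 cutoff is meaningful, and is 0 when the mean is 0.
Filter statistics are computed on cells pooled across a donor's longitudinal
samples; per-compartment means feed the homoplasmy rule when a donor has
both physiologic and monoclonal samples.

Per-cell "presence" is not uniquely defined by the filter conventions above;
both knobs (`min_coverage`, `detection_threshold`) are exposed. The
normalized mutation burden follows the downsampling convention: each
(donor, cell type) group is sampled without replacement to 100 cells, the
number of variants with mean h > 1% is counted, and the count is divided by
the group's mean per-cell mtDNA coverage relative to the cohort mean.

Targeted amplicon genotyping calls a cell mutant only with ≥ 10 reads at the
locus and strictly more mutant than wildtype reads; ties are wildtype.

## Clonotype assignment and stability

Cells are embedded as √h vectors (the square root stabilizes the variance of
small allele fractions), connected in a cosine k-nearest-neighbour graph
(k = 20) and partitioned with Leiden community detection (RB-configuration,
resolution 1.0, fixed seed). Two deterministic post-passes follow:

1. **Collinearity merge** — communities whose mean √h profiles have cosine
   distance < 0.1 are merged greedily. Within one clone all cells share a
   marker set, so the kNN graph among them is essentially a random regular
   graph, and community detection alone splits such clones; the merge
   restores one cluster per distinct marker profile and makes the separable
   case exactly recoverable.
2. **Background collapse** — clusters whose mean profile has no variant at
   ≥ 2% heteroplasmy, and cells with no signal at all, take label 0.

Labels are renumbered 1..K by decreasing size. The whole procedure is an
explicit, seeded algorithm; it reproduces cluster-level results of
clonotype callers in single-cell toolkits without copying any particular
implementation, and the cluster-level output contract — not the algorithm's
internals — is what the tests pin down.

Stability of a sample's clonotype definitions is measured by re-calling
clonotypes on random subsets of 75% and 50% of cells (25 replicates by
default; 5 in the acceptance experiments) and computing the adjusted Rand
index against the full-data labels restricted to the retained cells. A
sample is "stable at fraction f" when the median ARI is ≥ 0.7. ARI is the
standard chance-corrected partition agreement; the threshold is a
documented stand-in since no published metric accompanies the reported
stability percentages.

Between timepoints, clones are matched by nearest mean profile (cosine on
√h, greedy best-first, deterministic tie-breaks), and each matched clone is
tested with a two-sided Fisher exact test on (clone cells, other cells) ×
(sample A, sample B), BH-corrected. "Dynamic" requires q ≤ 0.05 *and* a
frequency fold change ≥ 1.5 (or ≤ 1/1.5), mirroring the variant-level
1.5-fold convention; clones under 10 cells in both samples are not testable.

## Heteroplasmy shift screens

Per variant, with non-missing per-cell heteroplasmies a and b from the two
samples:

- **Mean screen** — two-sided Wilcoxon rank-sum (exact enumeration for
  tie-free vectors up to n = 25, tie-corrected normal approximation
  otherwise — heteroplasmy vectors are heavily tied at 0), BH across all
  variants present in both samples; flagged beyond q ≤ 0.05 with fold change
  (mean_b + ε)/(mean_a + ε) ≥ 1.5 or ≤ 1/1.5, ε = 10⁻⁴.
- **KS screen** — two-sample Kolmogorov–Smirnov (asymptotic p), BH across
  the *gated* variants only, so the two screens have different denominators
  by design. The cell-count gate defaults to ≥ 100 non-missing cells in
  *both* samples (`gate="both"`); the literal "either sample" reading is
  available as `gate="any"`. The conservative default avoids one-sided KS
  tests on tiny samples, which are underpowered and unstable.
- **Q-Q curves** — empirical quantiles of both samples on a shared
  probability grid (type-7 linear interpolation, 100 points), with the
  maximum vertical deviation from the identity line reported.

Sample means are unweighted over cells with non-missing values; a
coverage-weighted alternative is a documented variation. Compartment
enrichment applies the mean screen with fold change oriented toward the
monoclonal compartment: enriched (q ≤ 0.05, FC ≥ 1.5), depleted
(q ≤ 0.05, FC ≤ 1/1.5), otherwise shared; compartments under 10 covered
cells are reported shared with a `not_powered` flag.

## Sliding-window CNV inference

Fragments are counted into overlapping 10-Mb bins with 2-Mb step, each
fragment assigned by its midpoint so it contributes once to every covering
bin (midpoint assignment avoids double-length bias at bin edges). Terminal
bins are kept, flagged, and length-normalized. The deviation score versus a
reference population (≥ 50 cells, e.g. T cells):

1. scale each cell to a consistent depth, where a cell's depth is its
   *median* length-normalized bin count — the median bin is copy-neutral as
   long as aberrant bins are a minority, so a large gain does not
   compositionally deflate neutral bins the way total-count normalization
   does;
2. two passes: bins flagged at |z| ≥ 3 in pass one are excluded from the
   depth estimate before recomputing, removing the residual bias unbalanced
   events induce on the median;
3. per bin, with reference mean μ and SD σ of normalized counts and target
   mean t̄ over n cells, the population score is z = (t̄ − μ)/(σ/√n); bins
   with σ = 0 are masked. A per-cell z matrix is also emitted for plotting.

Segments are maximal runs of ≥ 5 consecutive bins with |z| ≥ 3 and
consistent sign. Under the null with equal target/reference sizes the score
has variance ≈ 2 (both means are estimated), which the run-length and
threshold defaults absorb comfortably. The exact deviation formula is this
package's own, since only the binning scheme and the idea of a
depth-normalized deviation from a T-cell reference are fixed conventions.

## Trees, repertoire, concordance

Neighbor joining is implemented directly (Saitou–Nei): ties in the
Q-criterion break on the lexicographically smallest leaf-name pair, negative
branch-length estimates are clamped to 0 with the deficit donated to the
sibling branch (preserving the joined pair's path length), and the tree
serializes to Newick. On additive matrices the reconstruction is exact; the
test suite cross-checks topology against an independent NJ implementation.
Clone trees use Euclidean distance on √h mean profiles; per-cell trees
subsample to ≤ 500 cells, seeded. Whether such trees are best built on cells
or clones is left open by the conventions this follows; clone-level trees
are the default because profile means are far less noisy.

Repertoire clonality per sample: dominant clonotype frequency, polyclonal
fraction (cells outside the dominant clonotype; cells without a heavy-chain
clonotype are excluded from denominators), richness, and the clone-size
spectrum. mtDNA/BCR concordance reports the contingency table, adjusted
Rand index, and per-mtDNA-clone majority-BCR purity, plus a long-format
table ready for alluvial plotting.

## The synthetic-data generator

The generator realizes exactly the structure the analysis assumes, with
ground truth for every entity. Defaults are the package's study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| n_cells / n_clones | 1000 / 5 | cells per sample, planted clones |
| polyclonal_fraction | 0.2 | background cells outside any clone |
| markers_per_clone | 3 | clone-private marker variants |
| founding h range | (0.05, 0.4) | uniform founding heteroplasmies |
| dispersion c | 50 | Beta concentration of per-cell h |
| germline / artifact variants | 3 / 3 | near-homoplasmic (h≈0.995) / strand-biased |
| strand_bias_artifact | 0.05 | P(alternate read on + strand) for artifacts |
| mean depth / NB size θ | 100 / 2 | negative-binomial per-cell-position coverage |
| fragments per cell | 5000 | diploid-genome fragment depth |
| genome | 6 contigs, 450 Mb | scaled-down nuclear genome |

Per cell and marker of its clone, latent heteroplasmy is drawn
Beta(hc, (1−h)c) — the marginal dispersion that stochastic mitochondrial
segregation produces, modeled as a single draw rather than an explicit
per-division genealogy because downstream analysis only consumes the
marginal, at far lower cost. Coverage is NB(mean 100, size 2): the strong
overdispersion (CV ≈ 0.7) reflects how variable per-cell mtDNA coverage is
in fixed-cell chromatin assays, and it is what gives genuine low-h variants
enough between-cell alternate-read variance for the strand-concordance
statistic to be informative. Alternate reads are Binomial(coverage, h),
split across strands Binomial(alt, 0.5) for genuine variants and
Binomial(alt, 0.05) for artifacts — making the concordance filter testable
by construction. Fragments are Poisson per genome segment with rate
proportional to segment length × copy/2; planted events use copy 1 or 3
against the diploid baseline. The 6-contig genome keeps any single planted
event a realistic minority of 10-Mb windows, as on a real genome. BCR
clonotypes equal the clone's clonotype for clonal cells and unique
singletons for background cells. Paired timepoints share all generating
parameters except variants listed in `injected_shifts` (founding-h
multipliers, clipped at 0.95); an empty list makes the samples exchangeable.

Identical config + seed reproduces every output byte-for-byte (fragment
generation is drawn last, so skipping it perturbs nothing else).

What the generator does **not** emulate: doublets, read-level errors and
chimeras, position-dependent coverage along the mitochondrial genome
(a multiplier hook exists but is off by default), contaminating ambient
DNA, nuclear-mitochondrial (nuMT) misalignment, clone phylogenies with
nested marker sharing, or BCR somatic hypermutation. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to every artifact of real assays.

## Problem sizes and determinism

The test-suite experiments run at desk scale, chosen once: 100 seeds for the
filter rates, 20 paired cohorts of 500 variants × 300 cells for null FDR
control, 100 seeds for KS power, 20 simulations of 1000 cells for clonotype
recovery, a 20-sample graded-noise cohort (c from 30 down to 0.3, 200 cells,
5 replicates per fraction) for the stability ordering, 20 seeds of 500 cells
/ 5000 fragments for CNV recovery, and all 316,251 2×2 tables with n ≤ 50
for Fisher exactness. `scripts/acceptance.py` re-measures the same
quantities at moderately smaller seed counts (30/10/50/10/20/5/5/50/10) so a
full reproduction completes in a few minutes; every random draw in the
script derives from the single `--seed` argument. The pipeline driver is
byte-deterministic for a fixed seed: manifests carry input hashes and
parameters but no timestamps or absolute paths.

## Known limitations

- The clonotype algorithm is a documented stand-in; on data clustered by a
  different community-detection implementation, cluster *boundaries* may
  differ even where cluster-level conclusions agree.
- The stability threshold (median ARI ≥ 0.7) and the stable/dynamic clone
  criterion (Fisher q ≤ 0.05 ∧ |FC| ≥ 1.5) are explicit conventions for
  quantities whose original definitions are not published.
- KS p-values are asymptotic; at the 100-cell gate this is accurate, but
  exact p-values would differ slightly near the gate with `gate="any"`.
- CNV segments are bin-resolution calls (≥ 10 Mb events); no allele-specific
  or breakpoint-level inference is attempted.
- The homoplasmy exclusion generalizes a cohort-specific variant list into a
  rule (mean h ≥ 0.9 in every compartment); other cohorts may need the
  explicit blacklist extended.
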