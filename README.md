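# mtlineage

Single-cell lineage tracing from mitochondrial DNA mutations, for studies of
clonal evolution in blood malignancies (e.g. the monoclonal B cell
lymphocytosis → chronic lymphocytic leukemia continuum) profiled with
mtscATAC-seq-style assays.

Because each cell carries hundreds of mitochondrial genomes that mutate ~10×
faster than nuclear DNA and segregate stochastically at division, the
per-cell allele fraction of an mtDNA mutation — its **heteroplasmy**
h = alt reads / total reads — acts as an endogenous lineage barcode.
`mtlineage` implements the analysis stack built on that idea:

- **Variant calling with quality filters** from per-cell, per-base,
  per-strand read counts (mgatk-style tables). A variant is high-confidence
  when it is detected in > 4 cells, its per-cell heteroplasmy has
  variance-to-mean ratio > 0.01, its alternate reads correlate between DNA
  strands (Pearson r > 0.65; strand-biased artifacts fail this), it is not
  near-homoplasmic in every compartment, and it is not on the artifact
  blacklist (310T>C).
- **Clonotype assignment**: cells are clustered on √h with a cosine kNN graph
  and seeded Leiden communities, followed by a profile-collinearity merge;
  stability is quantified by re-clustering random 75%/50% cell subsets and
  scoring the adjusted Rand index against the full-data partition.
- **Heteroplasmy shift testing between serial samples**: a mean-level screen
  (Wilcoxon rank-sum, Benjamini–Hochberg FDR, flagged only beyond an absolute
  1.5-fold change) and a distribution-level screen (two-sample
  Kolmogorov–Smirnov with BH correction, gated at ≥ 100 cells), plus Q-Q
  curves; the same machinery classifies compartment enrichment/depletion
  between physiologic and monoclonal B cells.
- **Clone dynamics**: clones matched across timepoints by profile, Fisher
  exact test on frequencies with BH correction and the 1.5-fold convention.
- **Sliding-window CNV inference** from chromatin fragment counts in
  overlapping 10-Mb bins (2-Mb step) as standardized deviation z-scores
  versus a T-cell reference population.
- **Neighbor-joining clone trees** (exact Saitou–Nei, Newick output) and
  **BCR repertoire concordance** (contingency, ARI, per-clone purity).
- A **ground-truthed synthetic-data generator** covering all of the above:
  beta-binomial heteroplasmy dispersion, negative-binomial coverage,
  binomial strand splitting with artifact bias, injected longitudinal shifts,
  planted chromosomal gains/losses, and clone-linked BCR clonotypes.

## Worked example

Simulate a matched sample pair in which one marker mutation's founding
heteroplasmy is tripled in the later sample, then run the core pipeline:

```python
import mtlineage as mt
from mtlineage.simulate import SimulationConfig, simulate_paired_timepoints
from sklearn.metrics import adjusted_rand_score

config = SimulationConfig(n_cells=500, injected_shifts={"475A>C": 3.0}, seed=11)
sample_a, sample_b, truth = simulate_paired_timepoints(config)

calls = mt.filter_variants(mt.call_variants(sample_a.tensor))
passing = mt.passing_ids(calls)
print(f"{len(passing)} of {len(calls)} candidate variants pass the filters")

het_a = mt.compute_heteroplasmy(sample_a.tensor, passing)
het_b = mt.compute_heteroplasmy(sample_b.tensor, passing)

assign = mt.call_clonotypes(het_a, seed=11)
ari = adjusted_rand_score(truth.clone_labels.to_numpy(), assign.labels.to_numpy())
print(f"{assign.n_clones} mtDNA clonotypes recovered (ARI vs truth: {ari:.2f})")

screen = mt.combine_shift_results(
    mt.mean_shift_screen(het_a, het_b), mt.ks_shift_test(het_a, het_b)
)
print(screen.loc[["475A>C"], ["mean_a", "mean_b", "fold_change",
                              "wilcoxon_q", "ks_q", "class"]].round(4))
```

Output:

```
13 of 21 candidate variants pass the filters
5 mtDNA clonotypes recovered (ARI vs truth: 1.00)
            mean_a  mean_b  fold_change  wilcoxon_q    ks_q                 class
variant_id
475A>C      0.0687  0.1419       2.0641      0.8943  0.0003  shifted_distribution
```

All 3 germline and 3 strand-biased artifact variants are removed by the
filters, the 5 planted clones are recovered exactly, and the injected shift
is the only variant flagged. Note the division of labor: the shift lives in
one subclone (~16% of cells), so the cohort-level rank test is diluted by the
zero-heteroplasmy majority, while the distribution-level KS screen detects it
decisively — the reason distribution testing complements the mean screen.

The same stages are available from the shell via the `mtlin` CLI
(`mtlin simulate | call-variants | clonotype | stability | dynamics |
shift-test | cnv | tree | concordance | run`); `mtlin run` chains everything
over a YAML sample sheet and writes a JSON manifest, byte-reproducibly for a
fixed seed.

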