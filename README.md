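# chas

Cell-type deconvolution of bulk brain H3K27ac ChIP-seq profiles.

Histone acetylation at H3K27 marks active enhancers and promoters and is
strongly cell-type specific, so a bulk-tissue H3K27ac profile is a mixture
of the signals of the constituent cell types. Shifts in cellular
composition (e.g. neuronal loss in neurodegeneration) therefore confound
bulk differential-acetylation analyses. `chas` infers cellular composition
from bulk peaks and counts using a cell-sorted reference panel (typically
astrocytes, microglia, neurons and oligodendrocytes), for epigenomics
researchers analysing bulk brain ChIP-seq cohorts.

Two independent algorithms are provided:

1. **Cell-type scores.** Bulk peaks are annotated to every reference cell
   type they overlap by ≥ 1 bp; a peak is *cell-type specific* when it is
   annotated to a single cell type x and covers ≥ 50% (configurable) of one
   of that cell type's reference peaks, giving the peak set P_x. With
   counts converted to CPM and each peak standardized by its maximum
   across samples (s_{p,y} ∈ [0, 1], max_y s_{p,y} = 1),

       CHAS_{x,y} = (1 / |P_x|) Σ_{p ∈ P_x} s_{p,y}  ∈ [0, 1]

   — a per-sample rank proxy for the abundance of cell type x (scores are
   not constrained to sum to 1 across cell types).

2. **Matrix-factorization proportions (CHAS-MF).** On consensus peaks
   (merged union of bulk and reference peaks), length- and
   library-normalized bulk CPM is modelled as b ≈ R p with p ≥ 0 and
   Σ p ≤ 1, where R holds per-cell-type median normalized reference CPM.
   The fit runs on *signature peaks* only (top cell type ≥ 5× any other),
   weighted by inverse signal variability w_p = 1 / (1 + v_p) with v_p
   half the CPM range across reference samples, and solves

       p_y = argmin Σ_p w_p (b_{p,y} − Σ_x R_{p,x} p_{x,y})²,
             p ≥ 0, Σ p ≤ 1,

   exactly (weighted NNLS, with support enumeration on the Σ p = 1 face).
   The slack 1 − Σ p is reported as "other" — cell types missing from the
   reference.

A pseudobulk simulator (`chas.synthetic`) generates reference panels and
multinomial mixtures of known composition for validation, and
`chas.enrichment` tests whether cell-type-specific peaks are
over-represented among differentially acetylated regions (hypergeometric
test, Benjamini–Hochberg FDR).

## Worked example

Simulate 49 pseudobulk samples of known composition and recover it:

```python
from chas import (standard_benchmark, annotate_peaks, annotation_summary,
                  compute_scores, score_truth_correlation, deconvolve)

bench = standard_benchmark(seed=1)                # 4 cell types, depth 1e6
ann = annotate_peaks(bench.bulk_peaks, bench.panel)
print(annotation_summary(ann))
scores = compute_scores(bench.bulk_counts, ann)
print(score_truth_correlation(scores, bench.truth.proportions))
```

```
                  count  fraction
category
astrocytes          500     0.227
microglia           500     0.227
neurons             500     0.227
oligodendrocytes    500     0.227
multiple            200     0.091
other                 0     0.000
                     rho    p
cell_type
astrocytes        0.9988  0.0
microglia         0.9994  0.0
neurons           0.9982  0.0
oligodendrocytes  0.9986  0.0
```

Every synthetic bulk peak annotates to exactly one cell type (the 200
shared peaks are "multiple"), and the scores rank the 49 samples almost
perfectly for each cell type (Spearman ρ ≥ 0.998 here). Absolute
proportions come from the constrained least-squares fit:

```python
est = deconvolve(bench.bulk_peaks, bench.bulk_counts, bench.panel,
                 bench.ref_counts, ref_count_peaks=bench.bulk_peaks)
print(est.proportions.head(3).round(3))
```

```
         astrocytes  microglia  neurons  oligodendrocytes  other
sample1       0.168      0.124    0.472             0.236    0.0
sample2       0.089      0.144    0.458             0.310    0.0
sample3       0.177      0.088    0.478             0.257    0.0
```

Rows are per-sample proportions on the simplex; "other" ≈ 0 because the
reference covers every cell type in the mixture. Against the known truth
the mean absolute error is ≤ 0.003 per cell type on this benchmark.

The same steps are available from the shell: `chas simulate`,
`chas annotate`, `chas score`, `chas deconvolve`, `chas enrich`
(see `chas --help`).

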