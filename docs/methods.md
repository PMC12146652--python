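# Methods

## Model and assumptions

Bulk-tissue H3K27ac signal is treated as a convex mixture of cell-type
signals. Two estimators are implemented, deliberately independent of each
other so they can cross-validate:

**Cell-type scores.** Peak-level counts are converted to CPM (count /
library size × 10⁶; the library size defaults to the in-peak column sum,
recomputed after row filtering, with an external override available —
total-mapped-read librares are often unavailable downstream of peak
calling). Each peak's CPM row is divided by its maximum across samples,
so every peak with any signal attains 1 in some sample and all values lie
in [0, 1]; all-zero rows map to 0 (a peak with no reads anywhere carries
no information, and 0/0 is defined away rather than propagated). The
score of cell type x in sample y is the plain average of these
standardized values over the cell-type-specific peak set P_x. The
normalization factor applied per cell type is exactly 1/|P_x|; no
cross-cell-type rescaling is performed. An alternative reading of the
score definition — that cell types with more specific peaks should score
higher — is incompatible with a [0, 1] average and is deliberately not
implemented. Scores are monotone proxies for abundance: valid for
ranking samples and for use as model covariates, not as absolute
proportions.

**Constrained least-squares proportions.** On the merged union of bulk
and reference peaks ("consensus peaks"; counts of constituent source
peaks are summed as a proxy when per-consensus recounting from alignments
is not possible), counts are divided by peak bp length and rescaled so
each sample sums to 10⁶. The reference profile R takes, per cell type,
the per-peak median across that cell type's normalized reference
samples; per-peak variability v_p is half the range of normalized values
across *all* reference samples (a per-peak, not per-cell-type, notion —
a switch for within-cell-type variability is exposed through the input
mapping), and the fit weight is w_p = 1/(1 + v_p)^e with e = 1 by
default. Any bounded, monotone-decreasing map of v_p satisfies the design
contract; this form is dimensionless at v → 0 and behaves like inverse
variability for strong signals, approximating variance-stabilized least
squares for count-like noise. The fit is restricted to signature peaks —
consensus peaks whose top cell-type value is at least `ratio` (default
5) times the second-highest; a positive top with all-zero competitors
always qualifies. Normalization uses all consensus peaks as the CPM
denominator and subsets afterwards, so the denominator does not depend on
the signature selection.

Per sample the solver minimizes Σ w_p (b_p − Σ_x R_{p,x} p_x)² subject
to p ≥ 0 and Σ p ≤ 1. Weighted non-negative least squares (an exact
active-set method) handles the interior case; when its solution leaves
the simplex, the optimum lies on the Σ p = 1 face and is found by
enumerating supports of the equality-constrained KKT system — exact,
deterministic, and cheap because the number of cell types is small
(2^K systems of size ≤ K+1). Ties resolve to the minimum-norm solution;
the KKT tolerance is 10⁻⁸. The remainder 1 − Σ p is reported as "other":
the constraint is an inequality, not an equality, because real tissues
contain cell types absent from any finite reference panel. No per-cell
"size" correction factors are applied — unlike mRNA content in
transcriptomic deconvolution, there is no analogous per-cell acetylation
scale to normalize by.

## Annotation rules

Any ≥ 1 bp overlap (half-open interval arithmetic; bookended intervals do
not overlap) annotates a bulk peak to a cell type. The covered fraction
per cell type is measured relative to the *reference* peak's length, and
when a bulk peak overlaps several reference peaks of one cell type the
maximum single-peak fraction is used — the most conservative
order-independent reading. Peaks overlapping multiple cell types are
"multiple" and never specific; "multiple" peaks also do not count toward
any cell type's successes in enrichment tests (counting them for every
overlapped type would inflate the margins of the 2×2 table). The
enrichment universe is all annotated bulk peaks that entered differential
testing, keeping the hypergeometric margins consistent; the test is
upper-tail (enrichment) by default with depletion behind a flag, and BH
correction spans the cell types tested in one call.

Peak filtering keeps a peak whose -log10 p equals the threshold exactly
(a significance cutoff of p < 10⁻⁷ is read as keeping peaks at least that
significant, boundary included). The canonical chromosome list defaults
to human chr1–22, X, Y but is configurable.

## Synthetic data: what it emulates, what it does not

The generator emulates the pseudobulk validation design: per-cell-type
peak sets with disjoint specific peaks and shared peaks, reference counts
with independent multinomial noise per reference sample, and pseudobulk
samples mixed at known proportions. Defaults (chosen once as the standard
benchmark): 4 cell types × 500 specific peaks plus 200 shared peaks on a
2 × 30 Mb toy genome, peak lengths uniform in 500–1500 bp, owner signal
log-normal (scale 10× background, sdlog 0.75, floored at 5× background so
the owner/background expected ratio is always ≥ 5), 3 reference samples
per cell type at 10⁶ counts, and 49 pseudobulk samples at 10⁶ counts.
Depth 10⁶ is a desk-scale stand-in for tens of millions of reads: the
estimators depend on relative composition, not absolute depth, and the
robustness sweep probes 10⁵–10⁶ explicitly. Mixing normalizes each cell
type's rate vector to a probability distribution before combining, so a
truth proportion is a proportion of *reads* — matching a read-pooling
design.

"Paper-like" compositions draw microglia uniformly in [0.05, 0.21] and
rescale neuron-dominant remainders (neurons U(0.40, 0.55),
oligodendrocytes U(0.15, 0.32), astrocytes U(0.08, 0.22)) to fill the
rest; neurons are the most abundant type in every sample by construction.

Real data differ in ways the simulator does not model: reference peak
sets overlap across cell types beyond the simulated shared peaks, bulk
peak boundaries do not coincide with reference peaks, signal covaries
with GC content and fragment length, and brain-region or disease-state
epigenetic divergence shrinks the effective separation between cell
types. Passing the synthetic benchmark therefore demonstrates
correctness of the estimators under the mixture model, not expected
field performance on arbitrary tissue.

## Numerical choices and degenerate inputs

- Sorting is lexicographic by (chrom, start, end); interval work goes
  through NCLS-backed joins, with all-pairs scans retained in the test
  suite as oracles.
- A cell type with zero specific peaks yields a *missing* score column
  plus a warning, never a silent 0. An emptied cell type after reference
  downsampling is dropped from the panel with a warning (an empty
  reference set is invalid by construction).
- Single-reference-sample panels give v_p = 0 and unit weights.
- A near-collinear reference profile (condition number > 10⁸) warns but
  proceeds; zero-length peaks, zero library sizes and negative weights
  are errors.
- All generators are driven by `numpy.random.default_rng`; every public
  simulation function takes a seed and the benchmark spawns independent
  child streams for panel, compositions and mixing, so all outputs are
  bit-reproducible from one integer.

## Known limitations

- At n = 10 samples the smallest attainable Spearman ρ below 1.0 is
  0.9879, so thresholds like ρ ≥ 0.99 amount to requiring a perfect
  ranking; at the desk-scale depth of 10⁶ a single adjacent-rank swap
  between near-tied compositions can occur for some seeds. This is a
  granularity artifact of small-n rank correlation, not an estimator
  failure (the corresponding error in estimated proportions is ≪ 0.01).
- The scores are relative: comparable across samples within one dataset,
  not across datasets or cell types.
- Proportion estimates inherit any compositional bias of the reference
  (e.g. unequal reference quality across cell types) and assign signal
  from unrepresented cell types partly to "other" and partly to the most
  similar represented type.
- Counting reads on consensus peaks by summing constituent source-peak
  counts under-counts reads falling in merged-but-unpeaked gaps; with
  alignment files available, recounting per consensus peak is preferable.
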