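# Methods

## Readthrough estimation from binned read counts

A sort-seq experiment measures a variant's reporter fluorescence
indirectly: cells are sorted into mCherry gates and each gate is
sequenced. The estimator reconstructs each variant's mean mCherry level
as a convex combination of gate fluorescences. For gate *j* with
population share `pc_j` (percent of sorted cells) and mean fluorescence
`fv_j`, the quantity `(r_vj / R_j) · pc_j` is proportional to the
expected number of cells of variant *v* in gate *j*, so

    score_v = Σ_j (r_vj/R_j)·pc_j·fv_j / Σ_j (r_vj/R_j)·pc_j

is the cell-weighted mean gate fluorescence of the variant. Dividing by
the untreated no-nonsense control's score converts arbitrary fluorescence
units into percent of wild-type expression (RTp). Because the score is a
ratio, it is invariant to rescaling all reads of a variant, rescaling all
`pc` by a constant, and multiplying all `fv` by a constant (the control
scales identically, leaving RTp unchanged).

Properties and edge cases:

* Gates with zero total reads or zero `pc` are dropped from numerator and
  denominator for all variants, keeping the estimator a convex
  combination of the remaining `fv`.
* A variant with no reads at all has an undefined score; the scalar API
  raises and the table API drops the row.
* RTp is not clipped above 100: values slightly above 100 are legitimate
  measurement outcomes after control normalization.
* The confidence filter retains variants with ≥ 10 reads per
  condition-replicate, applied before replicate merging; the merged table
  carries the between-replicate standard deviation as the error measure
  (0 and flagged for single-replicate variants).

Replicates that are monotonically but non-linearly related (e.g. a
cytometer voltage difference) are recalibrated by fitting a LOESS curve
of replicate 1 on replicate 2 (span 0.75 by default), forcing it monotone
with isotonic regression, and mapping replicate 2 through the curve. We
calibrate rather than replace: substituting fitted-from-rep1 values would
discard replicate 2's independent information. For monotone distortions
this linearizes the relation and cannot decrease the inter-replicate
Pearson correlation.

Individual (non-pooled) flow-cytometry measurements use the companion
estimator: the fraction of EGFP+ cells that are mCherry+, times the mean
mCherry intensity of the mCherry+ population, normalized to the
no-nonsense control.

## The sequence-context model

Readthrough percentages are continuous, heteroskedastic and bounded below
by 0, with values above 100 possible; "classification" links are the
natural scale but a Bernoulli likelihood is not. We therefore fit a
fractional-response logistic regression: the response is `p = RTp/100`
clipped to `[1e-4, 1 − 1e-4]` (negative measured values clip to the lower
bound), the link is logit, and estimation is iteratively reweighted least
squares under the binomial quasi-likelihood (statsmodels GLM), run to a
relative deviance change below 1e-8 or 100 iterations. On small, noisy
designs with sparsely populated level combinations IRLS can oscillate
near the optimum; the fit is then polished with L-BFGS started from the
IRLS parameters, and only if that also fails does fitting raise an error
carrying the deviance trace. Coefficient uncertainty is not taken from
the quasi-likelihood information matrix but from the spread of
coefficients across cross-validation folds, which is robust to the
misspecified variance function.

The design matrix is one-hot with reference-level drop per factor
(reference A for nucleotides, UAA for stop type; the "absent" level `-`
used for positions beyond a short context can never become the
reference). Interactions are products of indicator columns, so the
three-nucleotide downstream group with full interactions spans
4³ − 1 = 63 columns. Columns are grouped into named terms — stop type,
down_123, up_123, stop × down — which is the unit of ablation. The
pan-drug model adds a drug main effect and a drug × term copy of every
base term; with full interactions and per-drug data it reproduces the
per-drug fits exactly (tested). Levels unseen at fit time raise during
training and map to the reference with a warning at prediction time, so
genome-scale scans never fail on an edge context.

Evaluation protocol:

* Cross-validation runs seeded random 90/10 splits; with the default ten
  rounds the test sets are disjoint (one permutation split into ten
  chunks). r² is the squared Pearson correlation of observed vs predicted
  RTp over the pooled held-out predictions; per-fold r² values are also
  reported. Fold membership is derived from the sorted row labels, so
  results do not depend on physical row order.
* Ablation refits every reduced model on the same folds as the full model
  and reports `1 − r²_removed / r²_full`.
* The downstream-position scan grows the model one position at a time
  (+1..+3 with their mutual interactions, +4..+8 as main effects — the
  interaction structure beyond +3 is deliberately not expanded), compares
  each model to the previous one with a one-sided paired t test over 20
  per-round r² values and BH-adjusts across positions. Two identical
  models leave the paired t statistic undefined; that boundary is
  reported as non-significant (p = 1).
* Per-fold coefficient tables are summarised with mean, s.d., t-based 95%
  CI, a two-sided one-sample t test against zero and BH adjustment across
  the model's coefficients. Zero between-fold variance with a nonzero
  mean is flagged degenerate and reported at the smallest positive float.
* The explainable-variance ceiling is the squared Pearson correlation
  between replicate RTp vectors; for parallel replicates the un-squared
  correlation equals the classical reliability Vs/(Vs + Vn) (signal over
  signal-plus-noise variance), which is what the simulation tests check.

## Sequence features

Features are anchored at the stop codon: `down_k` is the k-th base after
the stop triplet, `up_k` the k-th base before it, and the upstream codon
is the triplet immediately 5' of the stop (walking back in steps of three,
so it coincides with the translation frame whenever the upstream sequence
is in frame). CAI and tAI are arithmetic means of user-supplied per-codon
weights over all in-frame upstream codons in the context (24 codons for
the standard 147-nt PTC context) — note the classical CAI is a geometric
mean; the arithmetic mean is used here deliberately, matching how the
indices are used in this assay's analysis. G+C content is computed over
the full context. Weight tables are external TSVs (codon → weight); none
are bundled.

## The synthetic generator

The generator produces data with known truth for every pipeline stage,
emulating: uniform-random 147-nt contexts with a balanced stop at offset
72 plus a no-nonsense control; true readthrough fractions from a
logistic sequence model over the same design the fitting code uses
(inverse-logit of X·β, control fixed at exactly 100%); per-replicate
variant-level perturbations on the logit scale (the simplest perturbation
that preserves (0,1)); per-cell log-normal mCherry fluorescence around a
variant mean proportional to true readthrough (the standard FACS
intensity model, and the source of the unimodal distributions with long
upper tails seen in real screens); Poisson cell counts per variant; gate
assignment by log10-fluorescence boundaries with gate shares and mean
fluorescences recomputed from the simulated cells; and per-gate
multinomial sequencing reads proportional to within-gate variant cell
counts.

Defaults (set once, before any testing, and stated here as the package's
study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| mean_cells_per_variant | 272 | sorted-cell budget per variant of a genome-scale screen (~1.6 M cells / ~5,800 variants) |
| n_replicates | 2 | biological duplicates |
| gate_boundaries | (2.0, 2.75, 3.5) log10 | four gates, log-spaced across the fluorescence range spanned by 0.1–100% readthrough around a 10⁴-unit control; real screens used three to five |
| reads_per_gate | 500,000 | a NextSeq-class lane share per gate |
| cell_noise_sd | 0.2 log10 units | typical FACS spread of a clonal population |
| replicate_noise_sd | 0.1 logit units | reproduces inter-replicate correlations ≈ 0.95, the regime of a well-behaved screen |
| truth coefficients | intercept −3, effects N(0, 0.25²) | median true readthrough of a few percent with a long upper tail, the regime of effective readthrough drugs |

What the generator does **not** emulate: EGFP co-fluorescence and
aberrant-integration filtering, induction kinetics, nonsense-mediated
decay, sequencing errors, PCR jackpotting, or condition-specific control
shifts (e.g. RNA-stabilizing drugs). Passing tests therefore demonstrate
that the estimator and models recover truth under an idealized but
structurally faithful measurement chain — not that every real-data
artifact is handled.

A note on estimator consistency: with a handful of coarse gates the score
is a gate-mean-smoothed version of the variant's fluorescence, so
individual estimates are biased toward gate centers even as correlation
with truth stays high (r ≈ 0.98 at the default four gates). Exact
per-variant recovery (within 1% relative) holds in the fine-gate limit,
which the tests realize by giving each variant its own gate.

## Saturation and NTC analyses

Stop-gain enumeration covers every sense codon of the CDS (positions
1..L−1); the natural stop is excluded, since mutating one stop into
another is not a stop gain, and codons that already are stops are
skipped. Contexts near transcript ends are trimmed rather than padded,
with out-of-range features taking the "absent" level. Best-drug ties are
broken by drug name order and logged. Per-transcript streaming keeps
memory bounded for genome-scale scans.

NTC contexts keep 66 nt either side of the natural stop and remove every
in-frame 3'-UTR stop with a 1-Hamming substitution (default TAA→TAC,
TAG→TGG, TGA→TGG; the map is configurable and validated to be single-base
and stop-free). The distance to the nearest original UTR stop is counted
in codons with the first UTR codon = 1; the tandem threshold zeroes the
readthrough of variants with a distance strictly below the threshold, is
idempotent, and leaves a threshold of 0 as the identity. PTC/NTC
comparisons use replicate-merged tables, report the ratio of medians and
a two-sided Wilcoxon rank-sum test, BH-adjusted across drugs.

## Numerical choices and limitations

* Clipping at 1e-4 bounds the logit response; truth configurations are
  chosen so the clip is inert in simulations.
* The permutation-null pooled cross-validated r² on 5,000 variants is
  below 0.02, calibrating the |drop| < 0.02 bound the tests use for null
  terms in ablation.
* Problem sizes in the test-suite and acceptance runs (1,000 oracle
  tables, 2,000-variant screens, 5,000-variant model recovery) are the
  package's chosen verification scale: large enough that sampling error
  is far below the tested tolerances, small enough to run routinely.
* The models are deliberately interpretable (named terms, factor levels);
  no regularization path or black-box learner is provided, and conditions
  where readthrough barely rises above background are expected to
  cross-validate poorly regardless of model.
* Fitting needs more rows than design columns (255 for the four-term
  drug model); under-determined or oscillating fits that even the
  gradient fallback cannot stabilise raise a convergence error rather
  than returning unstable coefficients.
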