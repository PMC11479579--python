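# Methods

## Model

All engines address the same estimation problem. A bulk matrix
**X** (features × samples; non-negative expression values, or β-values in
[0, 1]) is modeled as a proportion-weighted mixture of K cell-type profiles,

    X ≈ T · A,    T ∈ R^{F×K},  A ∈ R^{K×S},

with every column of **A** on the probability simplex (entries ≥ 0, summing
to 1), **T ≥ 0**, and additionally **T ∈ [0, 1]** when the input is
methylation (a mixture of β-values is a β-value, and so are the underlying
cell-type profiles). Both factors are estimated from **X** alone; only K is
supplied. Estimates are identified at best up to a permutation of
components, which is why evaluation uses Hungarian matching of proportion
rows (maximizing summed Pearson correlation) before computing errors.

## Identifiability: when can the truth be recovered?

The constraints (A simplex, T ≥ 0) do **not** identify the factorization in
general. If (T, A) reproduces X exactly, so does (T M⁻¹, M A) for any
invertible M with column sums one such that M A ≥ 0 and T M⁻¹ ≥ 0 — a
continuum of "widened-simplex" solutions whose extent is governed by how far
the data sit from the constraint boundaries. Two boundary conditions shrink
this set to a point:

* **pure (marker) features** — rows of T supported on a single component —
  pin the solution on the T side; and
* **boundary samples** — samples at or near a vertex of the proportion
  simplex (purified cell populations) — pin it on the A side.

Alternating constrained least squares converges, empirically, to a solution
that stretches the estimated simplex until a constraint binds; when the
true proportions include purified samples the binding solution *is* the
truth, and the noiseless recovery error drops from ~5e-2 to the solver
tolerance (~1e-6 or below). Designed benchmark mixtures (reconstituted
mixes of purified cell populations) have exactly this structure, which is
what the simulator's `n_pure_samples_per_component` and
`marker_background=0` options emulate. The exact-recovery tests use one
purified sample per component and pure-support markers; with proportions
drawn purely from Dirichlet(1) the same algorithms still achieve small
errors (MAE well under 0.05 at K=6 with 36 samples) but cannot do better
than the identifiability slack, which scales with the smallest proportion
entries in the cohort.

## Engines

**nmf.** Block coordinate descent on ‖X − T·A‖²_F: the T-block solves a
non-negative (box-constrained for methylation) least-squares problem per
feature, the A-block a simplex-constrained least-squares problem per
sample. The sum-to-one constraint is enforced *inside* the A update rather
than by post-hoc renormalization: exact compensation of a per-column
rescaling of A is impossible on the T side (T can only absorb
per-component scales), and enforcing the constraint in the update keeps
every block step an exact constrained minimization, hence a monotonically
non-increasing RSS trace. After convergence (relative RSS change < `tol`,
default 1e-6, or `max_iter` = 500) the profile matrix is re-estimated in
one shot as T = X·A⁺ (Moore–Penrose) and negative entries are clamped to
zero (clipped to [0, 1] for methylation). The trace reported is the
stage-1 trace; the post-clamp residual is in the diagnostics.

**edec.** The same alternation specialized to β-values: T box-constrained
to [0, 1], A simplex-constrained, stopping when the absolute RSS change
falls below `rss_diff_stop` (1e-10) or after `max_its` (2000) iterations;
`n_restarts` (5) random Dirichlet initializations are run and the lowest
final RSS kept. All randomness flows from the single seed.

**ica.** Features are row-centered and FastICA (scikit-learn, logcosh,
unit-variance whitening) extracts K independent source components over
features. Each component is reoriented so that its largest-|weight| entry
is positive (ties → smallest row index; the operation is idempotent). The
`n_markers` (30) features with largest positive weight are markers, and a
per-sample abundance score is the weight-weighted mean of the marker rows
of the *original* matrix. Scores are made into proportions by per-sample
renormalization (negative scores — possible on general input — are clamped
to zero first and counted in diagnostics; a non-positive column total is an
error naming the sample). This renormalization is a presentation choice:
the underlying method yields abundance scores, not proportions, and can be
disabled (`renormalize=False`). A structural limitation worth knowing: on
*exactly* proportion-constrained mixtures the row-centered data have rank
K−1, so K requested independent components cannot all be genuine; ICA is
at its best when sources are independent and heavy-tailed and the mixing
is not exactly simplex-bound.

**cam_lite.** A simplified convex-geometry corner search. Feature rows are
scaled to sum one, projecting each feature into the simplex of sample
composition, where rows proportional to a single component's proportions
are corners of the data's convex hull. K-means (5·K clusters, seeded)
summarizes the cloud; every K-subset of centers is scored by the total
squared residual of the remaining centers under their best convex
combination of the subset, and the minimizing subset is taken as the
corners. The chosen corner rows estimate the proportion rows only up to a
positive per-row scale (each was row-normalized), so the scales are
recovered by non-negative least squares against the column-sum-to-one
constraint (min ‖Cᵀd − 1‖, d ≥ 0) before the final column renormalization —
without this step the corner rows' differing masses bias A by several
percent even on noiseless data. T follows by per-feature non-negative
least squares. The exhaustive subset search bounds K at 6
(C(30, 6) ≈ 6·10⁵ subsets) and K·cluster_factor at 60.

### Constrained least-squares primitives

Both recurring subproblems exploit a shared small Gram matrix. Simplex
columns are solved by an exact active-set method on the K-variable QP (the
equality stays in the KKT system; the dual-feasibility threshold is looser
than the primal drop threshold to preclude cycling on variables whose
optimum is zero), with a batched all-free solve handling the interior
columns in one shot. Box-constrained rows are solved by vectorized cyclic
coordinate descent over all rows simultaneously; every coordinate update
is an exact 1-D minimization, so the objective never increases — this is
what makes the engines' RSS traces provably non-increasing — and warm
starts across outer iterations keep the cost low. Monotonicity of
`rss_trace` is asserted in tests with a 1e-9 slack *relative to the initial
RSS* (an expression-scale RSS is ~1e6–1e9; absolute 1e-9 is below the
float64 resolution of the residual computation itself).

## Choosing K

`scree()` reports the eigenvalues of the feature covariance (features as
variables; `center=True`, `scale=False` by default) and an automatic elbow:
the k maximizing (λ_k − λ_{k+1}) / (λ_{k+1} − λ_min + 1e-12) over
k ≤ min(10, S−1). The eigenvalue table is the primary output; the suggestion
is advisory.

For proportion-constrained mixtures the plain elbow is systematically
wrong, in both centerings: the centered data matrix has rank K−1 (centered
proportion rows sum to zero — K components span a (K−1)-dimensional affine
subspace), and the uncentered spectrum is dominated by the grand-mean
eigenvalue, whose k=1 drop ratio swamps the component gap about half the
time. `simplex_mixture=True` therefore locates the elbow on the centered
spectrum and adds one — the endmember-counting rule of convex mixture
analysis. On simulated six-component mixtures this recovers K=6 in ~100%
of seeds; the pipeline's automatic-K path uses it.

## Interpretation

Per component, features are ranked by their coordinate on the component's
profile column (descending; ties broken lexicographically by gene id for
determinism). For methylation, CpG scores are first aggregated to genes by
the per-gene maximum — a gene counts as contributing if at least one of its
CpGs does; unmapped CpGs are dropped and counted in logs.

The test is chosen from the tie structure of the scores: if the fraction
of distinct values is at least 30% (boundary inclusive) the ordering is
deemed reliable and preranked **GSEA** runs; otherwise **ORA**.

*GSEA.* The enrichment score is the maximum deviation from zero of the
weighted Kolmogorov–Smirnov running sum (increment |score|^p / Σ_members
|score|^p at members, p = 1 by default; decrement 1/(N−n) at non-members).
The null redraws member positions uniformly `n_perm` (1000) times, seeded,
with permutations shared across sets of equal size. The p-value is
(1 + #{same-side null with |ES_null| ≥ |ES|}) / (1 + #{same-side null});
conditioning *both* counts on the sign side keeps the null uniform
(dividing by all permutations would halve the scale and double the false
positive rate — measured 0.10 instead of 0.05 at the nominal 5% level).

*ORA.* Selection = top ⌈20%·N⌉ genes (ceiling); universe = every gene in
the ranking. The p-value is the exact hypergeometric upper tail
P(overlap ≥ observed), verified against exhaustive enumeration of all
selections on small universes; the statistic is the sample odds ratio.

p-values are BH-adjusted within each method's pool across all components
of a run. Gene sets are read from GMT; sets with fewer than 3 members
(after universe intersection, for GSEA) are dropped or skipped with a log
entry.

## Simulator

`simulate_expression` draws a log-normal baseline per gene (meanlog 5,
sdlog 1 — a realistic CV spread for feature selection), plants disjoint
blocks of `n_markers_per_component` marker genes whose baseline is
multiplied by `fold_change` (8) in their component only
(`marker_background=0` makes markers pure-support), draws proportions from
Dirichlet(1) (optionally replacing leading samples by purified
endmembers), and applies multiplicative log-normal noise of log-sd
`noise_sd`. `simulate_methylation` draws Beta(0.3, 0.3) profiles (bimodal,
as β-values are), plants anchor CpGs (0.95 on-component / 0.05 off),
allocated in whole synthetic genes (3 CpGs/gene) so planted sets stay
disjoint at gene level, and adds Gaussian noise clipped back to [0, 1].
Defaults (K=6, 2000 features, 36 samples, 5% noise) mirror a six-cell-type
benchmark mixture. Everything is a deterministic function of the seed.

What the simulator does *not* emulate: read-count sampling noise (negative
binomial dispersion), batch effects, probe cross-reactivity, correlated
marker structure, or cell types with overlapping marker programs. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated mixture model, not performance on any particular real cohort.

## Problem sizes and numerical choices

Test and acceptance runs use 150–2000 features, 8–36 samples, K ≤ 6 —
small enough for the whole suite to run in minutes on one CPU while still
exercising the benchmark-scale six-component case. Degenerate inputs are
errors with named offenders (duplicate ids, non-numeric cells, zero-signal
samples, out-of-range β-values, constant matrices, all-zero weight
columns); features with zero mean are excluded from CV ranking (logged),
and a rank-deficient A at NMF convergence produces a diagnostic warning
while the pseudoinverse remains defined. CSV round trips preserve 12+
significant digits; rerunning any pipeline with the same config and seed
reproduces every CSV byte-for-byte.

## Known limitations

* Exact recovery requires the identifiability conditions above; on
  boundary-free cohorts all reference-free methods share a bias floor.
* `cam_lite` is a deliberately simplified corner search, not a full convex
  analysis of mixtures implementation (no dimension reduction, no margin
  denoising); its K ≤ 6 bound comes from exhaustive subset scoring.
* The NMF here is plain alternating constrained least squares; no sparsity
  penalty is imposed on profiles.
* GSEA p-values are permutation-based and hence granular at 1/(1+n_perm);
  adjusted values saturate accordingly when many sets are strongly
  enriched.
* The ICA proportion renormalization is a convention, not an estimate of
  absolute cell fractions.
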