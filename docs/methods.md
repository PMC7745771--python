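# Methods

This note documents the statistical procedures implemented in `rhoshrink`,
the choices made where definitions in the literature are loose or
conflicting, and what the synthetic-data experiments do and do not show.

## Data model and containers

The raw object is a count matrix `W` (n samples × p taxa, non-negative
integers); canonical orientation is samples-in-rows and all readers
normalize to it. Sample depth is the row sum `m_j`. Filtering follows the
usual survey protocol: samples whose depth falls at or below a depth
quantile are dropped first (default: the 10th percentile, type-7
linear-interpolation quantile, strict inequality), then taxa present in
fewer than a fraction of the retained samples (default 30%). Both the
quantile convention and the order (samples before taxa) are fixed and
configurable. Note that the depth arm is not idempotent by construction:
re-filtering recomputes the quantile on the retained depths. The
shuffled-null construction permutes each taxon column independently across
samples, which destroys every pairwise association while preserving all
per-taxon marginals exactly; a whole-row shuffle would preserve
associations and could not serve as a null.

## Normalizations

All eight schemes map counts to a real matrix of identical shape with IDs
carried through. A pseudocount (default 1) is applied internally only by
the methods that take logarithms or require positivity — `clr`, `rle`,
`vst` — and is configurable; `tss`, `css`, `com`, `wren` and `asinh`
consume raw counts and map zeros to zeros (`asinh(0) = 0` before
centering).

- **tss** divides each row by its depth (rows sum to 1).
- **css** divides by the cumulative sum of counts up to a data-driven
  stable quantile, times N (default 1000). Per-sample quantiles are taken
  on the grid l/p (type-7, zeros included in the sorted vector); their
  instability is δ_l = med_j |q_l^(j) − med_j q_l^(j)|, and the reference
  level is the smallest l with δ_{l+1} − δ_l ≥ 0.1 δ_l (requiring
  δ_l > 0 so that a run of all-zero quantiles cannot trigger the rule),
  falling back to the median (0.5) quantile when no level is stable. The
  published descriptions of this search are compressed and differ between
  sources; the contract implemented here is pinned by a step-by-step
  oracle test.
- **com** rescales every sample to the minimum depth and floors to
  integers.
- **rle** uses median-of-ratios factors against the per-taxon geometric
  mean; factors are normalized to geometric mean 1 and the global factor
  is their arithmetic mean (arithmetic, not geometric, deliberately).
- **asinh** is elementwise log(w + √(w²+1)) followed by per-taxon mean
  centering. Centering per taxon rather than globally is the natural
  choice when the next step is a column-wise association estimate (and is
  correlation-invariant anyway).
- **wren** computes the compositional scale factor
  η_j⁻¹ = (1/p) Σ_i e_i y_ji / ȳ_i from sample proportions y and their
  across-sample means ȳ. Unit weights (e ≡ 1) are the default and the
  tested contract; a `w2-approx` flag offers a moment-based weighting
  (inverse empirical variance of the proportion ratios) as a rough
  stand-in for full hurdle-model weights, which are out of scope. Taxa
  with zero mean proportion must be filtered upstream.
- **vst**: size factors are median-of-ratios; per-taxon variances of the
  normalized counts are corrected for shot noise (z_i = μ_i · mean(1/s)),
  and the remaining *excess* variance is smoothed by lowess in log-log
  space, made monotone non-decreasing, and extrapolated linearly in
  log-log coordinates. The variance used by the transform is
  v(μ) = μ·mean(1/s) + v_excess(μ), so for pure counting (Poisson) noise
  the excess is negligible and v(μ) ≈ μ. The transform is the integral
  u(w) = ∫₀^w dμ/√v(μ), evaluated by trapezoid quadrature after the
  substitution μ = t², which removes the integrable singularity at zero
  and makes the Poisson closed form u(w) = 2√w exact at grid points
  (2000-point grid up to the maximum count). An affine calibration
  (default on) maps u so that large counts track log₂ of size-factor
  normalized counts, fitted on the upper quartile of counts.
- **clr** is log(w/geometric-mean-of-row); rows sum to zero, and the
  identity clr(w) = log w − rowmean(log w) is tested.

## Association estimators

Sample covariance uses the unbiased (n−1) denominator; Pearson correlation
is the diagonally rescaled covariance. The symmetric proportionality ρ_p
operates on clr-transformed data and is computed in its covariance form
2s_ik/(s_ii+s_kk), with the variance form asserted equal in tests. The
difference from clr correlation is only the denominator: geometric vs
arithmetic mean of the two variances.

Shrinkage follows the Schäfer–Strimmer scheme with the identity
correlation target and the median-variance target. With standardized data
z and per-observation products w_ik^(j) = z_ji z_jk,

- λ₁\* = Σ_{i≠k} V̂(r_ik) / Σ_{i≠k} r_ik², where
  r_ik = n/(n−1)·w̄_ik and V̂(r_ik) = n/(n−1)³ · Σ_j (w_ik^(j) − w̄_ik)²;
- λ₂\* shrinks variances toward v = median(s_11…s_pp) analogously from
  the centered squares.

Both are clipped to [0,1]; a degenerate denominator (all correlations
zero) yields λ = 1 by convention. The vectorized implementation is pinned
to a literal double-loop transcription of these equations at 1e−10.

The shrunk correlation is r\*_ik = (1−λ₁)r_ik. The shrunk covariance uses
the *unshrunk* variances in the off-diagonal rescaling
(s\*_ik = r\*_ik √(s_ii s_kk)) and the shrunk variances
s\*_ii = λ₂v + (1−λ₂)s_ii on the diagonal; this asymmetric convention is
deliberate (variants differ on it), and a `consistent_diagonal` flag
provides the alternative. The shrinkage proportionality is
ρ\* = 2s\*_ik/(s\*_ii+s\*_kk) with diagonal 1. With λ₁=λ₂=0 it equals ρ_p
to machine precision; with λ₁=1 all off-diagonals vanish. ρ\* values are
clipped to [−1,1]; for auto-estimated intensities the clip is inactive on
all test data, but extreme manual (λ₁, λ₂) combinations with heterogeneous
variances could otherwise exceed the range. Note that
shrinkage-correlation equals diagonally-rescaled shrinkage-covariance only
when λ₂ = 0.

## Comparing association matrices

Frobenius distance is the entrywise 2-norm of the difference; spectral
distance is the operator 2-norm (largest singular value of the
difference) — one printed variant squares-roots this quantity, available
behind `literal_sqrt`; CMD is 1 − tr(RR′)/(‖R‖_F‖R′‖_F) ∈ [0,1]. CMD is
not a metric (no triangle inequality) and is exempt from that axiom.
Distances are computed on full matrices including the diagonal, which
cancels for same-metric comparisons. MDS is classical/Torgerson
(deterministic up to rotation/reflection), not stress-minimizing. Moment
summaries use the strictly-upper-triangle values with biased
(population-style) central moments; kurtosis is not excess; constant
off-diagonals yield NaN sentinels for skewness/kurtosis rather than an
exception.

For the consistency experiment, the distance of each subsample estimate to
a fixed large-sample reference is the primary aggregation; mean pairwise
distance among same-size replicates is also emitted, since figure captions
and text in the literature use both readings.

## Downstream analysis

Spectral clustering builds the affinity A = 1 − √((1−R)/2), sparsifies it
to a symmetric k-nearest-neighbor graph (k = 2, union rule — an edge
survives if either endpoint claims it; the union keeps the graph connected
at small k and is configurable to mutual), and eigendecomposes the
symmetric normalized Laplacian L = I − D^{−1/2}AD^{−1/2}. Some sources
print the exponents of D as +1/2; that form is read as a typo since it
contradicts the standard spectral-clustering construction. k defaults to
the number of connected components of the affinity graph; k-means on the
leading k eigenvectors uses a fixed seed and 25 restarts; zero-degree
nodes become singleton clusters. Spectral-gap diagnostics (eigenvalues and
gaps) are exported so either model-selection rule can be inspected.

Hierarchical clustering applies Ward's method to √((1−R)/2) and cuts the
tree into k flat clusters (default 10). Cluster purity is the effective
number of rank labels, exp(Shannon entropy)/[number of distinct labels],
averaged unweighted over clusters. Because the effective number of a
*balanced* mixture equals the label count, purity is 1 both for pure and
perfectly uniform clusters; it penalizes unbalanced mixtures only. The
synthetic purity comparisons therefore use unequal block sizes.
Unclassified taxa form their own category rather than being dropped.

Relevance networks keep the top-k pairs by |association| (default 2000),
with exact ties at the boundary broken lexicographically by taxon-pair ID
for determinism. Assortativity is Newman's categorical coefficient on a
taxonomic rank (genus by default); modularity maximization is fast-greedy
(Clauset–Newman–Moore) on the unweighted skeleton — the ranking-then-
thresholding construction already encodes the weights — with a weighted
variant behind a flag. The consensus network is the exact edge
intersection across input networks, together with the full
inclusion-exclusion (Venn) overlap table.

## Synthetic data generator

The generative family is logistic-normal-multinomial: latent log
abundances are multivariate normal with a prescribed correlation structure
C and heavy-tailed base means; softmax maps them to a composition; counts
are multinomial at a log-normal library size; extra zeros are applied
post-multinomial as independent per-taxon masking (so post-masking depths
are approximate; pre-masking depths are also returned). Because
clr(softmax(a)) = a − mean(a) exactly, the clr covariance of the latent
composition is GΣG with G the centering projector, and both the clr
correlation and the proportionality implied by it are available in closed
form as recovery targets.

Defaults, chosen once as desk-scale analogues of filtered gut-survey data:
p = 100 taxa in 10 equal correlation blocks (within-block 0.6,
between-block 0) — a *sparse* latent structure, with under 10% of taxon
pairs carrying signal; base log-abundance means drawn from N(0, 2²)
(heavy-tailed abundance distribution); library sizes log-normal(μ=9,
σ=0.6), i.e. a median depth near 8000 spanning roughly an order of
magnitude; zero inflation off by default and configurable up to survey-like
levels. Cluster-recovery scenarios use a narrower abundance spread (2.0 →
1.5) so that every planted taxon retains enough coverage to be
identifiable; with the wider spread the rarest taxa are zero-truncated
below recoverability at any sample size, which is a realistic failure mode
of count data but makes a planted-partition oracle vacuous. Taxonomy is
generated aligned to the latent blocks (one family/genus per block, five
ranks populated), with an optional label-noise fidelity parameter.

What the generator does *not* emulate: amplification bias, batch effects,
overdispersion beyond the logistic-normal term, taxon-specific sequencing
efficiency, and the extreme sparsity (60–85% zeros) of unfiltered survey
tables — the last is reachable by raising the base-abundance spread and
zero-inflation but is not the default. Passing tests therefore demonstrate
correctness of the estimators and the qualitative sample-size phenomena,
not calibration to any particular real survey.

## Consistency experiment

The workflow engine crosses normalizations with estimators (`cor`,
`cor-shrink`, `rho`, `rho-shrink`; proportionality pairs only with clr,
and requesting it without clr is a configuration error) over a grid of
subsample sizes with replicates. The reference estimate is computed from
one fixed subsample at the reference size (configurable conceptually to a
mean-of-replicates). Every random draw derives from the single root seed
recorded in the manifest; reruns are byte-identical, and cells already
written to the output directory are reloaded rather than recomputed.
Failures in one grid cell are recorded and do not abort the run. Outputs
are tidy TSVs (distances, moments, intensities, MDS coordinates, labeled
association matrices with JSON sidecars) bound by `manifest.json`.

Problem sizes used by the test suite and the acceptance script — reference
n = 5000 with subsamples 25–250 at p = 100, ten replicates for intensity
trajectories, twenty for null-skewness and generator-fidelity checks —
were chosen as the smallest sizes at which the qualitative phenomena
(shrinkage gain for n < p, λ decay, positive null skewness, block
recovery) are stable across seeds.

## Known limitations

- The Wrench `w2-approx` weighting is a moment heuristic, not the
  hurdle-model weight estimation of the original method; unit weights are
  the tested contract.
- css numerics follow one concrete reading of a compressed published
  description; other implementations may select a different reference
  quantile on the same data.
- ρ\* is not guaranteed PSD-compatible or range-bounded for arbitrary
  manual intensity pairs (values are clipped); auto-estimated intensities
  behave well empirically.
- The purity score cannot distinguish a balanced mixed cluster from a pure
  one; treat it as a measure of label concentration, not accuracy.
- BIOM support covers the JSON dialect only (not HDF5).
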