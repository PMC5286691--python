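# Methods

## Kinetic model and estimation

mRNA decay after transcription blockade is modelled as first-order:
A(t) = A₀·e^(−kt), so natural-log intensities are affine in time and the
decay constant is estimable by linear regression. Each gene is fit
independently by OLS to

    ln I = μ + α_rep + γ_cond + β_P·t·1[cond=P] + β_CI7·t·1[cond=CI7] + ε

* `α_rep` — biological-replicate intercept. A replicate is one cell batch
  measured in both states, so replicate enters as a blocking factor crossed
  with condition (a single intercept per replicate id, no replicate-specific
  slopes).
* `γ_cond` — condition intercept, absorbing state-dependent baseline
  abundance.
* `β_c` — per-condition slope of ln intensity in time; k_c = −β_c in min⁻¹
  on the natural-log scale. Half-life = ln 2 / k for k > 0; non-positive k̂
  (apparent increase after shut-off) is retained un-clipped — clipping would
  bias the decay difference — and its half-life is reported as undefined
  (NaN).

With all genes sharing one design, the fits are computed in a single
vectorized least-squares pass; genes with missing values fall back to
per-gene fits and are marked unfittable when any (condition, replicate)
series retains fewer than 3 distinct time points or the reduced design is
rank-deficient.

Two nested F-tests per gene:

* **Fit filter** (joint time effect): full model vs the model with both
  slopes removed. "Poor fit to log-linear decay" is operationalized as
  absence of a resolvable time trend (p > α, default α = 0.05). The
  alternative reading — a residual lack-of-fit test — cannot be
  distinguished from the available description; the time-effect form was
  chosen because it is computable from the stated predictors alone and
  directly screens the flat/non-decaying profiles that defeat the model.
* **Interaction** (condition × time): full model vs a single shared slope.
  Benjamini–Hochberg adjustment is applied over filter-passing genes only
  (the filter decision uses the orthogonal time-main-effect contrast);
  differential stability is called at q ≤ 0.05.

Per-replicate decay constants used for clustering come from independent
simple regressions of ln I on t within each (condition, replicate) series,
not from the joint model, so each heatmap column is a self-contained
determination.

Optional spike-in normalization divides every sample by its spike-in median
intensity. Since a global per-sample scale enters only the intercepts, this
changes no slope, F-statistic or p-value; it matters only when intensities
are compared across samples directly.

## The lfdr-shrunken decay metric

The raw difference Δ = k_P − k_CI7 (positive = stabilized with quiescence)
is noisy for the large majority of genes with no true stability change. The
interaction p-values are modelled as a two-component beta-uniform mixture

    f(p) = π₀ + (1 − π₀)·a·p^(a−1),   0 < a < 1,

fit by maximum likelihood (Nelder–Mead over a logit parametrization, a
fixed 2×2 grid of starts, best likelihood wins — deterministic). The local
false discovery rate lfdr(p) = π₀ / f(p), clipped to [0, 1], is the
posterior probability of "no change" given p, and the shrunken metric is
Δ·(1 − lfdr). The multiplicative form realizes "pull non-significant
comparisons towards zero" while preserving sign and the |Δ| ranking at
equal lfdr. Degenerate input (all p identical) yields lfdr = 1 everywhere
with a warning; below ~50 p-values the mixture fit is flagged unstable.
An alternative metric ln(k_P/k_CI7) (defined only when both constants are
positive) is available behind a flag; the plain difference is the default
because it remains defined for non-positive estimates.

For display alongside expression values, shrunken deltas are linearly
rescaled by max|log2fc| / max|shrunken| over the displayed subset (an
all-zero vector maps to zeros).

## Profile clustering

Differential genes (by default) contribute rows of per-replicate decay
constants (P replicates, then CI7), mean-centered and sign-flipped so
positive = slower decay than the gene's own mean rate. Euclidean k-means
(scikit-learn, default k = 2, best of 10 restarts, seeded) clusters the
rows; clusters are then relabeled canonically by ascending centroid mean
over the CI7 columns, so cluster 1 is always "faster decay in CI7"
(destabilized with quiescence) independent of the seed. No criterion-based
selection of k is performed; k = 2 reflects the two-direction structure of
a differential contrast and is configurable.

## Gene-set tests

* **Rank-sum**: two-sided Wilcoxon rank-sum of shrunken deltas (a flag
  switches to raw Δ) in-set vs out-of-set; exact Mann–Whitney null when
  min(n₁, n₂) ≤ 10 and the values are tie-free, otherwise the normal
  approximation with tie-corrected variance (no continuity correction).
  BH across sets; direction from the in-set vs out-of-set median. The
  default universe is all filter-passing genes; a `differential` universe
  mode restricts to called genes, since the tested universe is a genuine
  analysis choice.
* **Chi-squared direction test**: Pearson chi-squared (1 df, continuity
  correction off by default) on (member / non-member) × (Δ > 0 / Δ ≤ 0);
  degenerate margins are rejected by name.
* **Hypergeometric over-representation** of a term within a cluster
  (upper tail, BH across terms) stands in for external GO tooling; it is a
  generic over-representation test, not a reproduction of any specific
  tool's statistic.

## Synthetic data generator

The generator emulates the shut-off microarray design: default time points
0/120/240/480 min, two conditions (P, CI7) × two biological replicates,
lognormal baseline half-lives, lognormal initial abundances, multiplicative
noise (additive Gaussian on ln intensities, default SD 0.2), per-replicate
batch offsets (default SD 0.1) shared by both conditions of a batch, and
non-decaying spike-in rows carrying the same offsets and noise.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `halflife_log_mean` | ln 240 (median 4 h) | centre of the decay range an 8-h shut-off window resolves; consistent with transcription-inhibitor half-life estimates in cultured cells |
| `halflife_log_sd` | 0.75 | ±2 SD spans ≈ 50 min–18 h |
| `frac_differential` | 0.06 | of order the observed fraction of retained genes with a stability change in this experimental system |
| `differential_log2_effect` | 1.0 | two-fold rate change, applied symmetrically in log space (k_CI7 = k_P·2^(±effect)), sign randomized per gene so Δ is sign-balanced |
| `frac_nonexponential` | 0.40 | roughly the fraction of probes a fit filter removes in such experiments; split 50/50 flat vs biphasic — the two shapes defeat a log-linear fit differently (no slope vs lack of fit). Biphasic genes decay 4× faster before the second time point and 4× slower after, and many still carry enough time trend to pass a time-effect filter, so the realized filtered fraction is below `frac_nonexponential`. |
| `noise_sd`, `replicate_effect_sd` | 0.2, 0.1 | study-condition noise used throughout validation |
| `spikein_level`, `n_spikeins` | 1000, 10 | constant-abundance controls for per-sample normalization |

Intensities are not truncated by default; an optional `detection_floor`
censors values below background to mimic threshold filtering.

What the generator does **not** emulate: probe-level/dye effects, image
artifacts, correlated noise across genes, partially degraded RNA,
transcription leakage under inhibition, and gene-length or sequence
effects. Passing recovery tests on this generator therefore demonstrates
correctness of the estimation and testing machinery under the stated
kinetic model, not robustness to every failure mode of real array data.

Planted gene sets draw from differential genes of one stability direction
(topped up uniformly if the pool is small); null sets are uniform draws.
Simulated expression ratios couple a configurable fraction of differential
genes' log2(CI7/P) sign to their stabilization direction; the rest are
independent N(0, lfc_sd²).

## Numerical choices

* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; identical configuration gives bit-identical outputs, and file
  readers parse floats in round-trip mode so persisted stages re-run to
  identical checksums.
* F-statistics are clipped at 0 against round-off; model ranks come from
  the least-squares solve, so rank-deficient designs reduce degrees of
  freedom instead of crashing.
* p-values are clipped to [1e-15, 1] inside the mixture likelihood to keep
  the a−1 power finite at p = 0.
* BH adjustment uses statsmodels `multipletests(method="fdr_bh")`.

## Validation design and known limitations

Statistical behaviour is validated end-to-end on the generator: exact
recovery at zero noise (<1e-9), ~8–9% median relative error on k at the
study noise level, nominal type-I rate of the fit filter on flat profiles,
uniform null interaction p-values, FDR control under the global null
(false-call gene fraction ≤ 5%; the per-run probability of zero calls is
the Simes level, ≈95%, so individual 20-run windows fluctuate around
19/20), ≥5-fold shrinkage of null-gene deltas, top-ranked recovery of a
planted target family with calibrated null sets, and adjusted Rand ≥ 0.8
against planted directions for profile clustering (typical draw ≈ 0.9).

Limitations: genes are fit independently with no variance pooling or
empirical-Bayes moderation; biphasic decay is simulated but never fitted
(single-slope model by design); the lfdr is computed on interaction
p-values, one of several defensible inputs; gene identifiers are matched
exactly (no aliasing); and reproducing the original experiment's probe
counts requires its primary intensity data, which ship separately from this
package.
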