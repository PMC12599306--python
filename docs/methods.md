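# Methods

## The composition–function landscape model

A community is the obligate degrader plus a subset S of p nondegrader
strains; its measured function v(S) is the area under a blank-corrected
resorufin fluorescence time course (RFU·h), a proxy for aerobic aniline
metabolism. All statistics operate on replicate means per composition:
each unique composition contributes one landscape point, so the design
counts quoted throughout (28 three-member combinations, 163 test
compositions, …) are composition counts, not well counts. Replicate-level
pairing of edge differences would be arbitrary, since replicates of the two
endpoint compositions are unrelated wells.

Richness counts the implicit degrader: a "two-member" community is the
degrader plus one nondegrader. The degrader never appears as a model
feature; membership vectors cover only the p nondegraders, in fixed panel
order.

## Empirical statistics

**Functional effect.** Δᵢ(S) = v̄(S∪{i}) − v̄(S) for every background S with
both endpoints observed (128 per strain when p=8 and the landscape is
complete). Incomplete landscapes yield the observable subset of edges, with
n reported.

**Shapley value.** φᵢ = Σ_{S⊆N∖{i}} |S|!(p−1−|S|)!/p! Δᵢ(S), computed by
subset weighting in O(p·2^p). This equals the average marginal contribution
over all p! assembly orderings; the package also ships the explicit
orderings oracle (guarded at p ≤ 9) and the test suite verifies equality to
1e-10 on random landscapes. Shapley computation refuses incomplete
landscapes because exactness is then impossible. Efficiency
(Σφᵢ = v̄(full) − v̄(degrader alone)) holds to machine precision by
construction and is asserted in tests.

**Functional interaction.** Iᵢⱼ = mean(Δᵢ(S) | j∈S) − mean(Δᵢ(S) | j∉S),
with a two-sided Welch t-test treating backgrounds as independent
observations (64 vs 64 at p=8). For fixed focal i each composition mean
enters exactly one edge, so the per-background effects are independent
under i.i.d. replicate noise and the test is calibrated (verified by a
1000-landscape null simulation; empirical rate ≈ 0.044 at α = 0.05).
Welch rather than pooled-variance is used because it is the default
two-sided t-test convention in R, and the variances are not assumed equal.
No multiplicity correction is applied by default — significant-pair counts
are reported on raw P values — with Benjamini–Hochberg available as an
option. On complete landscapes Iᵢⱼ = Iⱼᵢ exactly (both reduce to the same
averaged second difference); the tests assert this symmetry.

**Growth–function correlation.** Per strain, Pearson r between Δgrowth and
Δfunction across its edges, two-sided P, star-coded (*** <.001, ** <.01,
* <.05). Fewer than 3 usable edges or zero variance in either delta flags
the strain instead of reporting a number.

**Global epistasis.** Per strain, OLS of Δᵢ(S) on v̄(S). A negative slope is
the canonical pattern: positive effects on low-function backgrounds,
negative on high-function ones.

## Synthetic-data generator

The generator targets the statistical structure the analysis assumes, not
ecological mechanism (no consumer–resource or Lotka–Volterra dynamics):

v*(S) = β₀ + Σ_{i∈S} βᵢ + Σ_{i<j∈S} γᵢⱼ, replicates add N(0, σ²).

It is pairwise by default (an optional third-order hook exists, off by
default) so that ground truth is identifiable by the pairwise empirical
statistics: closed forms are φ*ᵢ = βᵢ + ½Σⱼγᵢⱼ and I*ᵢⱼ = γᵢⱼ, both
verified against the estimators to 1e-10 on noiseless data. Noise is
homoscedastic Gaussian per replicate — the simplest model consistent with
replicate scatter in this kind of plate assay and sufficient for
power/recovery studies.

**Study-scale preset** (`study_preset`): p=8, 4 replicates per composition
(the 2^8 × 4 design), with AUC-scale magnitudes: β₀ = 2·10⁴ RFU·h,
βᵢ ~ N(0, 6·10³), each pair carrying an interaction with probability 0.46
of size N(0, 6·10³), replicate noise σ = 1.5·10³. The replicate noise SD is
not an empirically reported quantity; it was fixed at a quarter of the
main-effect SD so that single effects are well resolved at n=4 replicates,
as in the motivating assay. The interaction scale equals the main-effect
scale and the 0.46 density matches the observed fraction of significant
pairs in communities of this kind; together they reproduce the hallmark
phenomenology — strain effects that flip sign across backgrounds, roughly
a dozen significant pairs, a large gap between two-member- and
three-member-trained prediction — and make the pairwise ground truth
identifiable from 3–4-member training data, which a substantially weaker
interaction scale does not.

**Growth coupling.** Growth AUC is g₀ + Σ_{i∈S} δᵢ (+ optional pairwise
growth interactions γᵍ) + N(0, σ_g²). The function channel's effective main
effect of strain i is κᵢδᵢ + βᵢ (βᵢ acting as the growth-independent
residual), and growth interactions are inherited into the function channel
scaled by the pair-mean κ. With uniform κ, zero residuals and γᵍ present,
every strain's functional effect is exactly proportional to its growth
effect (r = 1); κᵢ = 0 decouples a strain. A purely additive growth
landscape makes each strain's growth effect constant across backgrounds,
so the per-strain correlation is degenerate and flagged — γᵍ is what gives
the correlation analysis within-strain variance to work with.

**Global-epistasis fixture.** v*(S) = baseline + scale·(1+λ)^|S| yields
Δᵢ(S) = λ·v*(S) − λ·baseline exactly for every strain and any assembly
order, giving the regression an exact oracle (slope λ, intercept
−λ·baseline). A naive recursive construction v(S∪i) = v(S)(1+λ) + aᵢ is
order-inconsistent and was rejected.

**Plate time courses.** Per well, RFU(t) = drift(t) + A_S·logistic(t) with
drift linear in t, sampled every 10 min over 72 h (433 points); A_S is
chosen so the blank-corrected trapezoidal AUC equals the target landscape
value, making the feature-extraction round-trip exact up to integration
error. Blank wells carry the drift alone (plus optional read noise).

## Feature extraction

Blank correction subtracts the per-channel, per-time-point mean (optionally
median) of the blank wells; blanks are then removed, which also guards
against double correction (a second pass fails for lack of blanks). AUC is
the trapezoidal integral over the full common time window with the time
axis in hours; readings are not smoothed and negative corrected values are
not clipped, because correction can legitimately produce them and clipping
would bias low-activity wells upward. Every step (blank statistic, window)
is configurable; the detailed AUC recipe of the motivating assay is not
fully specified publicly, so the simplest defensible estimator is used.

## Bottom-up prediction

Random-forest regression on presence/absence features with classic
regression defaults: 500 trees, mtry = max(1, ⌊p/3⌋), unlimited depth; no
tuning. Training sets are the unique compositions at the chosen richness
levels; subsampling draws ⌊fraction·n⌋ compositions without replacement
(25% of 28 → 7, of 56 → 14). Evaluation is Pearson r between predicted and
observed replicate-mean function over the pooled 5–9-member compositions
(163 at p=8). Leakage control follows the single-point-removal rule: a test
composition that is also in the (subsampled) training set gets its
prediction from a refit excluding exactly that composition; all other test
compositions use the full-training-set model. Each repeat re-seeds both the
subsampling and the forest; the suite reports mean ± SD over repeats and
the median-performance repeat, defined as the (n//2 + 1)-th ascending order
statistic (the 51st of 100), ties broken by repeat index.

## Model interpretation

Partial dependence forces the feature(s) to each {0,1} grid value,
averages predictions over the reference rows (the model's own training
design matrix, there being no separate reference population), and centers
by the empirically-weighted grid mean. Friedman's H for a pair is
H = sqrt(Σ_rows[PDⱼₖ − PDⱼ − PDₖ]² / Σ_rows PDⱼₖ²), reported on the square
root scale; a joint-PD second moment below 1e-12 maps to H = 0 to avoid
0/0 on near-constant models. H is invariant to affine transformations of
the model output and is exactly 0 for additive models (asserted
analytically; forests fitted to additive noiseless data stay ≤ 0.05).
Exact numerical parity with any particular R implementation's grid or
normalization details is not claimed.

Permutation importance is the mean MSE increase after shuffling one
column, over k seeded permutations (default 50) or over all n! distinct
permutations when exhaustive (guarded at 8 rows); the enumerated worked
example (importance 0.5 for the active feature of y = x₁ on the balanced
4-row design) is asserted exactly.

Comparison with the empirical metrics correlates importance with |φ|
(Pearson and Spearman) and H with |I| over the 28 pairs. Absolute
interaction strength is the default because H is unsigned; comparing
against the signed strength is exposed as an option since the intended
convention in the motivating analysis is ambiguous.

## Problem sizes and numerical choices

Simulation-backed checks use sizes chosen to make their Monte-Carlo error
small relative to the asserted margins: 100 random landscapes (p ≤ 6) for
the Shapley oracle equivalence, 1000 null landscapes at p = 4 for test
calibration, 20–30 repeats for regime suites in tests and the acceptance
script (the full 100-repeat protocol is the library default), and 20–25
landscapes per replicate level for consistency RMSEs. Exact identities
(Shapley oracle agreement, efficiency, noiseless recovery) are asserted at
1e-10; analytic interpretation values at 1e-6 or machine precision.

## Known limitations

- The generator is pairwise and homoscedastic; it does not emulate
  heteroscedastic plate noise, well-position effects, batch/plate effects
  or higher-order epistasis, so passing tests demonstrate correctness of
  the estimators under the assumed structure, not robustness to real-data
  artifacts.
- Shapley computation requires a complete landscape; no sampled
  approximation is provided (the framework targets panels of ≤ ~10
  strains).
- Friedman's H on forests trained from few rows (e.g. the 8 two-member
  compositions) is estimation-noise dominated; that is the expected and
  documented behaviour, not a defect — two-member data cannot inform joint
  dependences.
- Growth analyses require the growth channel; without it they are skipped
  with a warning rather than an error.
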