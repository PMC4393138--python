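# Methods

`paleosel` quantifies which species-level properties predicted survival
through a stepwise marine extinction event, from two kinds of raw data:
per-sample conodont-element counts in several deep cores, and the
cores' downhole gamma-ray logs. This note records the statistical
definitions the package implements, the conventions it fixes where the
underlying procedures leave freedom, what the synthetic generator does
and does not emulate, and known limitations.

## Data model and orientation

A *sample* is one horizon in one core: depth (m, measured downhole),
gamma-ray intensity (μR/h, optionally missing), and one non-negative
element count per species. Series are always oriented oldest-first
(deepest-first), because depth is the time axis; every statistic below
is either orientation-symmetric (Hurst, skewness, Lomb power) or
defined on that fixed orientation, so the contract is reproducible
either way. Blank count cells mean "species absent" (0); a blank gamma
cell means "not logged" and propagates as missing into the habitat
metrics only. Cores are treated independently; no cross-core datum
alignment is attempted.

Two derived windows matter throughout:

* the **range window** of a species in a core — all samples from its
  first to its last appearance, inclusive, zeros kept;
* the **trimmed range** — the samples strictly between the first and
  last appearance (both endpoints removed). Under this reading a
  trimmed series such as `XX000X0XX` is already the object the
  occupancy rates are defined on.

The **longest series** of a species is its longest range window across
cores (length in samples); ties break toward the larger total element
count, then the lexicographically smaller core id. The Hurst and
spectral exponents and the occupancy rates are computed on this single
series (rates on its trimmed interior) rather than averaged over
cores, so they describe the best-sampled local history of the species.

## The ten predictors

1. **Mean abundance ā** — arithmetic mean of all positive counts
   pooled over cores. Zeros inside the range record non-detection and
   are excluded.
2. **Averaged variation coefficient CV̄** — within each core, the
   positive samples form a subsequence; every consecutive pair (a, b)
   contributes CV2 = sd/mean with the n−1 standard deviation, i.e.
   |a−b|/(√2·mean). CV̄ is the grand mean of all pairs over all cores.
   Pairing only adjacent positive samples factors out series length
   (each pair spans the shortest resolvable interval) and the ratio
   form factors out absolute abundance. Pairs never span cores.
3. **Hurst exponent H** — on the longest series, zeros included:
   RS = (1/S_T)·[max_k Σ_{j≤k}(a_j−ā) − min_k Σ_{j≤k}(a_j−ā)] with S_T
   the maximum-likelihood (n-denominator) standard deviation, and
   H = ln(RS)/ln(T) with T the sample count. H ≈ 0.5 is uncorrelated;
   larger is persistent. Undefined (NaN) for constant series or T < 3.
4. **Spectral exponent ν** — the classical variance-normalized Lomb
   periodogram of the longest series against depth (suited to uneven
   sampling), on a fixed grid from 1/span to the pseudo-Nyquist
   frequency n/(2·span) in steps of 1/(oversample·span), oversample 1
   by default; then ν = −slope of the OLS fit of ln(power+1) on
   ln(frequency+1). The +1 offsets avoid exaggerating logs of small
   values but make ν depend on the frequency units, which are
   therefore fixed to cycles per meter. Higher ν = redder dynamics.
   Because the spectrum is demeaned and variance-normalized, ν is
   invariant to shifting or rescaling counts; it is *not* invariant to
   relabelling depth units.
5. **Abundance skewness G(a)** — adjusted Fisher–Pearson skewness
   G1 = g1·√(n(n−1))/(n−2) of the pooled positive counts (plain g1 is
   available by option). Needs ≥3 positive counts and nonzero
   variance.
6–7. **Apparent extirpation E(t) and colonization I(t)** — on the
   trimmed longest series, with t = samples−1 intervals, z zero
   samples, ε positive→zero transitions, i zero→positive transitions
   and n(t) the final count: E = ε/(t+1−z) if n(t)=0 else ε/(t−z);
   I = i/(z−1) if n(t)=0 else i/z. Zero denominators yield NaN rather
   than 0, so such species drop out of models that use these rates —
   this is the package's operationalization of the varying
   per-predictor sample sizes seen in practice.
8–10. **Habitat affinity γ̄, σ(γ), G(γ)** — mean, sample (n−1) standard
   deviation and adjusted-G1 skewness of the gamma values at the
   species' positive occurrences, pooled over cores; samples without a
   gamma reading are skipped. Gamma tracks clay/organic content and so
   proxies water depth; γ̄ is the preferred depth, σ(γ) the occupied
   breadth, G(γ) the shape of the occupied-depth distribution. Each
   metric requires progressively more data (1, 2, 3 values) and is NaN
   below that.

A **Taylor's-law fit** (σ²(a) = c·āᵇ over sliding three-positive-sample
windows, stride 1, OLS on the log-log pairs) is provided as a
diagnostic of the mean–variance scaling that motivates CV̄; it is not
one of the ten predictors.

## Selectivity models

All model fitting is complete-case per fit, so n varies by model; the
per-fit n is always reported and logged.

* **Bivariate screen** — survival (0/1) is regressed on each predictor
  separately by maximum-likelihood logit (statsmodels). A predictor is
  a candidate when its slope's Wald p < α, default α = 0.1. No
  multiple-testing correction is applied at this exploratory stage;
  the screen's type-I rate is verified by simulation in the test
  suite. Separation is flagged (|β| > 15 or a separation error) and
  flagged fits are never promoted to candidates.
* **Effect size** — Tjur's coefficient of discrimination D: mean
  fitted survival probability among survivors minus that among
  victims.
* **Model ranking** — the table is culled to rows complete in *all*
  candidates, every candidate subset of size ≥ 2 is fitted, and models
  are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting the
  intercept. Akaike weights ω_i = exp(−Δ_i/2)/Σexp(−Δ_j/2) are
  renormalized over the models actually fitted (a subset too large
  for the culled n is skipped with a warning). Percent deviance
  explained is 100·(1 − residual/null deviance).
* **Group comparisons** — pooled-variance Student's t for
  survivor-vs-victim predictor means; Pearson r (pairwise-complete)
  for predictor intercorrelations.
* **Regression tree** — greedy recursive partitioning of the 0/1
  response with the ANOVA (within-node sum of squares) criterion.
  Controls mirror the defaults of classic recursive-partitioning
  software: minsplit 20, minbucket 7, cp 0.01 (a split must reduce
  relative error by ≥ cp, measured against the root sum of squares).
  Thresholds are midpoints between adjacent observed values. Rows
  missing the split variable are excluded from evaluating splits on
  that variable and routed down the majority child afterwards —
  simpler than surrogate splits, and a documented potential deviation
  from software that uses them. No cross-validation pruning is done;
  the tree reported is the fitted tree. Tree deviance explained is
  100·(1 − Σ(y−P_leaf)²/Σ(y−ȳ)²) on the fitting data.

The numerical conventions that required a choice: the n−1 standard
deviation in CV2 and σ(γ) but the maximum-likelihood S_T inside RS
(each as its definition states); natural logs throughout (H is
base-invariant as a ratio of logs); Wald rather than likelihood-ratio
p-values per coefficient; and NaN (never an exception) as the contract
for statistically undefined predictor values.

## Synthetic data

The generator emulates the structure the analysis assumes, at the
scale of the motivating survey: five cores of 22–36 samples at ~1.5 m
(jittered) spacing, 34 species by default. Gamma logs are a per-core
baseline (graded 8–22 μR/h across cores to mimic a depth gradient)
plus a gentle downhole trend, an abrupt 4 μR/h drop in the upper 40%
of samples (a regression event), and Gaussian noise, floored at 0.
Species occupancy follows a two-state persistence chain (stay 0.75,
colonize 0.45) modulated by a Gaussian affinity kernel on gamma
(tolerance 6 μR/h); positive counts are 1 + negative binomial
(dispersion 1, lognormal species means) whose log-mean carries colored
noise built by spectral synthesis with per-species exponent ν_gen ∈
[0, 2], so both ν and G(a) are steerable and the counts show
Taylor's-law-like overdispersion. Survival is Bernoulli on a logistic
link over z-scored computed predictors (defaults: intercept 0.2,
β(γ̄) = −1, β(G(a)) = +1 — a habitat-driven, skewness-assisted
regime). All randomness flows from one seed through deterministic,
process-stable substreams; a fixed config is bit-reproducible.

What the generator does **not** emulate: lithology and biofacies
structure, taphonomic time-averaging, correlated sampling effort,
inter-species interactions, and any spatial structure beyond the
gamma gradient. Passing recovery tests therefore show the estimators
and model stack behave correctly under the stated generating process,
not that real assemblage data satisfy that process.

## Problem sizes in tests

Simulation-based tests use sizes chosen to make their statistical
assertions stable: 1000 replicates for the screen's type-I rate
(±2%), 200 replicates at n = 1000 for logistic slope recovery, 300
species for screen power at |β| = 1, 100 series per noise color for
the ν-ordering checks, and exhaustive enumeration of all binary
presence patterns up to length 10 for the occupancy rates. The
end-to-end synthetic workflow is exercised at the survey scale
(34 species) where individual predictor identities are noise-dominated
by design; identity-recovery assertions are made only at the larger
sizes.

## Limitations

* Per-coefficient inference is Wald-based and can be optimistic at
  n ≈ 30; the screen's α = 0.1 is exploratory by construction.
* Element counts are treated as directly comparable across species
  (equal element numbers per animal) and samples (equal sample mass);
  violations act as extra noise.
* ν depends on the fixed Lomb grid and the +1 offsets; comparisons are
  meaningful only within one convention, which the package pins down.
* The tree is reported unpruned and its leaf probabilities are
  training-sample means; they are descriptive, not cross-validated.
* Missing-value routing in the tree is majority-rule, not surrogate
  splits.
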