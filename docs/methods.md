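# Methods

## Measurement model

Each clinical sample i (of n) carries a latent concentration
τ_i ~ Uniform(c_l, c_u).  Device A reports x_ir = τ_i + h_ir and device B
reports y_ir = ξ_i + v_ir for replicates r = 1..R, where ξ_i = β₀ + β₁τ_i
and the errors are independent zero-mean normals with repeatability SDs
σ_X and σ_Y.  SDs are parameterized as CV × mid-interval concentration.
The model assumes the samples and both devices are stable over the
study; drift is out of scope.

## The DINS measure and its estimator

Regressing y on x by OLS over the nR pairs, the mean estimated
prediction-error variance over the observed design collapses to
S_P² = S²(nR+2)/nR with S² = RSS/(nR−2).  The estimator is

    ζ̂ = S_P² / (σ̂²_Y + β̂₁² σ̂²_X),

with σ̂² the pooled within-sample replicate variances (mean over samples
of the per-sample unbiased variance).  Under identical nonselectivity
profiles S² estimates σ²_Y + β₁²σ²_X and ζ̂ ≈ 1; any nonselectivity
difference adds variance to the numerator only.

Conventions and choices:

- **Residual-variance divisor** nR − 2 (OLS with intercept), the
  conventional unbiased choice.
- **Role assignment.**  Measurement error in the predictor attenuates
  β̂₁, so the device with the *smaller pooled variance* is the predictor;
  x and y are interchanged when σ̂²_X > σ̂²_Y, ties keep the given order.
  The rule operates on variances, not CVs.
- **Unbalanced data.**  Missing cells are allowed: pooled variances skip
  samples with < 2 non-missing replicates on that device (the mean runs
  over contributing samples), and nR is the count of complete (x, y)
  pairs entering the fit.  With balanced data this reduces to the
  textbook formulas.  Missingness ≤ 5% has negligible effect (see the
  sensitivity tests).
- **Simplified form.**  ζ̂ = S_P²/(σ̂²_X + σ̂²_Y) assumes β̂₁ ≈ 1; it is
  biased up for β̂₁ < 1 and down for β̂₁ > 1.  The advisory
  `simplified_form_applicable` accepts β̂₁ ∈ [0.75, 1.25], or
  β̂₁ ∈ [0.5, 2] when the CV ratio is ≤ 1/4 or ≥ 4.  The full form is
  the package default everywhere.
- All quantities are unit-free ratios; ζ̂ is invariant to a common
  rescaling of both devices.

## Cluster bootstrap

Replicates of one sample are a cluster; resampling draws n samples with
replacement and keeps each drawn sample's replicates intact.  Duplicated
samples get fresh ids so the resampled design has exactly n clusters and
nR rows — the estimator's degrees of freedom are preserved.  Roles are
re-assigned on every resample.  Intervals are percentile (BPCI) at the
requested level, computed as type-7 quantiles of the replicate vector;
no bias correction or acceleration is applied.  Reported kurtosis is
non-excess (normal = 3) and the MAD is scaled for consistency with the
SD under normality.  Resamples with a degenerate design are redrawn up
to 10·B attempts; a result with > 10% failures is marked unstable.

The percentile interval's finite-sample coverage at n = 25 clusters is
a little below nominal (the acceptance suite measures ≈ 92–93% for a
nominal 95% interval under the null); this is inherent to percentile
intervals with few clusters, not a calibration knob of the package.

## Simulation scenarios

1. **No DINS, homoskedastic** — the null; the basis for thresholds.
2. **Heteroskedastic null** — error SDs step linearly with the rank of
   τ_i: the sample of rank j gets SD·(1 + j(η−1)/n), so the top of the
   interval carries η times the base SD.  The rule is rank-based (n
   equally spaced steps), not interpolated on concentration.
3. **Random DINS** — each sample is affected with probability p
   (affected count Binomial(n, p)); affected samples' y-replicates share
   one upward shift m·base with m = m_max·Beta(2, 2) and
   base = √(σ²_X + σ²_Y).  Beta(2, 2) is a symmetric default for the
   relocation magnitude; the exact shape is not pinned down by the
   reference, so ordering properties (monotonicity in p and m_max), not
   exact percentiles, are asserted for this scenario.
4. **Systematic DINS** — deterministic ramp over a quantile window
   [l, u] with l = 0 or u = 1: at quantile position s of the interval
   the shift is m_max·(s−l)/(1−l)·base (mirrored for bottom-anchored
   windows), largest at the extreme of the concentration range.
5. **General DINS** — summarized only by M, the average relative
   increase in pointwise prediction-interval widths, with the exact law
   ζ̂ = (1+M)²·ζ̂₀.

Two realizations of scenario 5 coexist deliberately.  The
*distribution engine* (`simulate_zeta_distribution`) applies the scaling
law to null draws — this is exact, matches how the reference percentiles
relate scenario 5 to the null, and keeps thresholds self-consistent
(`zeta_upper(M)/zeta_upper(0) = (1+M)²` algebraically).  The *data-level*
generator (`apply_general_dins`, used by `simulate_comparison` to
synthesize DINS-affected datasets for power studies) relocates each
sample by a zero-mean normal with variance ((1+M)²−1)(σ²_Y+β₁²σ²_X);
this reproduces the scaling of E[S²] but its ζ̂ upper tail is heavier
than the scaled null (a per-sample random shift adds between-sample
variability), so data synthesized this way are flagged *more* often than
the nominal rate at their own M — conservative for power checks, and the
reason thresholds use the scaled route.

### Nuisance parameters

The device CVs and the concentration interval barely move ζ̂ in the bulk
of its distribution, but the far right tail is sensitive to
high-CV/narrow-interval combinations (strong slope attenuation).
Reference-percentile runs therefore draw, per dataset, each device CV
uniformly from [0.1%, 10%] and the interval uniformly from {[5,10],
[2,10], [500,750], [70,1600]} — the CV range and interval set studied
for this model.  This randomization is the default for
`zeta_upper`/look-up-table simulation and for the acceptance runs;
dataset-level simulation defaults to fixed CVs of 1% on [5, 90].

### Sensitivity variants

Latent concentrations can instead follow normal, log-normal or
location-scale t (df 5 or 15) laws, located/scaled so their 1% and 99%
quantiles match the uniform's; errors can be location-scale t scaled to
the target SD.  Missingness is MAR (uniform cell blanking) or MNAR
(blanking probability proportional to the value's within-column rank,
mean probability equal to the requested fraction).

What the generator does *not* emulate: reproducibility components
exceeding repeatability (day, calibration or lot effects between the
replicate sets), drift over the study, value-rounding to reporting
precision, and correlated errors between devices.  Passing tests
therefore show the machinery is correct under the stated model, not that
real studies are free of those effects; in particular, when replicates
span conditions beyond repeatability, ζ̂ rises for reasons other than
nonselectivity and the tolerance M should be set larger.

## Decision procedure

For a tolerance M (decimal internally; the CLI accepts percent) and the
post-screening design (n, R): simulate the null ζ̂ distribution, take its
99th percentile (type-7, the same convention as the bootstrap), scale by
(1+M)².  The observed ζ̂ is computed on the raw or log scale — whichever
lands closer to 1; the log scale is the standard variance-stabilizer for
the proportional-SD heteroskedasticity common in these instruments and
is only considered when all values are positive.  The pair is flagged
iff ζ̂ strictly exceeds the threshold, so at most 1% of pairs whose true
inflation is within M are flagged.  Thresholds come from a shipped or
user-built look-up table when it covers (n, R, M) exactly; otherwise a
fresh simulation (2×10⁵ replicates by default) is authoritative.  The
choice of M is the user's: it encodes how much prediction-interval
inflation the application tolerates, and should be inflated further when
the replicate structure captures more than repeatability variance.

### Outlier screen

Before estimation, each sample's replicates are tested per device with
the studentized range: w = range/(pooled within-sample SD), compared to
the studentized range distribution with the pooled degrees of freedom.
The requested alpha (default 0.01) is family-wise, split Bonferroni over
all per-sample-per-device tests, so clean data keep all samples ~99% of
the time while a gross replicate error (tens of SDs) is caught with
near-certainty.  Flagged samples are removed whole from both devices.

## Numerical conventions

- Quantiles: numpy default (type 7) everywhere.
- RNG: numpy `default_rng`; one root seed per run, per-design substreams
  spawned via `SeedSequence` where several simulations share a seed.
- Monte Carlo sizes: reference percentiles use 2×10⁵ replicates per
  condition (the package's chosen precision/runtime balance; the
  resulting 99th-percentile Monte Carlo SE is ≈ 0.005–0.01), property
  checks 5×10⁴, thresholds inside the decision procedure 2×10⁵.
- Degenerate inputs raise typed errors: fewer than 3 complete pairs or a
  constant predictor (`DegenerateDesignError`), no replicated sample
  (`InsufficientReplicationError`), both pooled variances zero
  (`DomainError`).  Ties in role assignment keep the user's order.

## Known limitations

- The estimator inherits OLS endogeneity bias when *both* devices' error
  variances are large relative to Var(τ) and similar to each other; role
  swapping mitigates only the asymmetric case.
- Percentile-bootstrap undercoverage at small n (above).
- Scenario-3/4 relocation shapes (Beta(2, 2); deterministic ramp) are
  reasonable defaults, not uniquely determined; scenario-3 percentiles
  should be read as ordering statements.
- Thresholds depend on the null simulation's nuisance distribution; the
  shipped randomization reproduces the reference table, but a laboratory
  with tight knowledge of its CVs and measuring interval may prefer
  fixed-nuisance thresholds for its own design.
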