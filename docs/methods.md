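# Methods

## Scope

The package implements copy-number "accounting" for screening a
single-species biomaterial for undeclared bulking agents. It assumes the
assay target is absent from any plausible adulterant and that the screen's
job is binary triage: samples indistinguishable from pure reference
material pass; everything else goes to confirmatory analysis. Droplet
calling from raw fluorescence is included only as minimal plumbing (a
two-means threshold); production calling should use a dedicated rain-aware
algorithm, and rain exists here only as a simulator nuisance.

## Poisson quantification

With `positives` of `total` droplets positive, the mean copies per droplet
is the maximum-likelihood estimate λ̂ = −ln((total−positives)/total) under
the binomial likelihood with positive probability 1−e^(−λ); a test checks
the closed form against brute-force likelihood maximization. The reaction
total is cm = λ̂·Vs/Vp with Vs = 20 µL, Vp = 0.00085 µL by default
(droplet-generator geometry; both are configurable).

Uncertainty on λ̂ is a normal approximation on the negative fraction
(p̂ ± z·SE) mapped through −ln and clipped at zero — adequate at the ≥10⁴
droplets of a typical well, where the binomial is effectively Gaussian.
All-negative wells are valid (λ̂ = 0); all-positive wells are flagged
saturated and refused downstream, never imputed. Replicate wells of a
sample are pooled by summing counts, which preserves the Poisson
likelihood, rather than by averaging per-well estimates.

## Genome forecast

Expected copies are ce = DNA(ng)·1000·n·x/(2·1C) with n the target copies
per monoploid genome, x the ploidy and 1C the monoploid weight in pg. The
shipped saffron entry (n = 2/3, x = 3, 1C = 7.87 pg) yields
1000/7.87 ≈ 127.06 copies/ng. The published genome bookkeeping for saffron
is internally tense — a "haploid" weight of 5.9 pg is quoted alongside the
7.87 pg monoploid weight (7.87 = 5.9·4/3), and the target copy number is
described both per haploid and per monoploid genome. Only the
(n = 2/3, x = 3, 1C = 7.87) reading reproduces the 127 copies/ng that the
rest of the method is built on, so that is what ships; the formula is
implemented exactly as written and the tension is documented rather than
resolved. Other species enter through a CSV registry whose copy-number
field parses rational strings ("2/3") exactly.

## Weighted calibration and prediction interval

Pure reference samples give pairs (ce, cm). The pipeline's error sources —
pipetting, fluorometric mass quantification, biological variation in
copies per ng — are multiplicative, so residual spread grows roughly in
proportion to ce. The fit is therefore WLS of cm on ce with weights
1/ce^γ, γ = 2 by default (constant CV). γ is user-settable, and a
two-stage empirical estimate (log squared OLS residuals regressed on
log ce) is provided as a diagnostic; no claim is made that the variance
model is exact, and the resulting intervals are approximate by
construction. An intercept is included by default (a through-origin option
exists); quantiles are Student-t with n−2 (through origin: n−1) degrees of
freedom.

The 95% prediction interval at ce is
ŷ(ce) ± t·sqrt(σ̂²·ce^γ + Var(ŷ(ce))). The fit itself is delegated to
statsmodels' WLS; the interval is evaluated in closed form from the stored
coefficients and covariance, and is cross-checked against statsmodels'
prediction machinery in the test suite. If the lower bound is non-positive
(possible at very small ce), it is clamped to a machine-epsilon-scaled
value and the sample is flagged "below quantification range" instead of
receiving a purity value, because the purity statistic divides by the
lower bound.

## Purity and classification

Purity is 1 inside the interval (inclusive bounds), cm/lCe below it, and
cm/uCe above it. The upper branch's denominator is a genuine ambiguity in
the method's published formulation; dividing by uCe is the default because
it makes purity continuous (→1) as cm approaches the interval from above,
and the alternative lCe denominator — available via
`upper_denominator="lce"` — only inflates above-interval values without
ever changing which side of the acceptance band a sample lands on.

Classification: purity in [0.80, 1.20] (inclusive) is non-suspicious;
otherwise suspicious, tiered into a high band (0.70–0.80 or >1.20, where
confirmatory data usually still shows the declared species dominant) and a
low band (<0.70, where substitution is likely). Purity is a fraction
internally and a percentage in reports.

The simplified population rule drops the constant terms and screens the
ratio cm/DNA(ng) against mean ± z·SD (z = 1.96) bounds estimated from
authentic samples; with a market mean of 143 and SD of 40 copies/ng the
lower bound is 64.6 (~65). The CLI requires an explicit rule file rather
than shipping such population values as silent defaults, since the rule is
only valid after in-house verification on authentic material.

## Simulator

The generator emulates the statistical structure the method assumes:

- **Partitioning**: positives ~ Binomial(n_droplets, 1−e^(−λ)) with
  n_droplets = 15,000 per well by default (a typical accepted-droplet
  count) and duplicate wells per sample.
- **Fluorometry**: template mass is measured with mean-one lognormal noise,
  5% CV per read, averaged over 4 reads — the usual fluorometric protocol.
  The measured (not true) mass feeds the ce forecast, so calibration and
  screening carry realistic quantification error.
- **Pipetting**: an independent 3% CV lognormal factor on the mass actually
  loaded.
- **Population**: authentic samples draw true copies-per-ng from a normal
  distribution truncated at zero (default mean 143, CV 10% in the shipped
  experiments); template masses are log-uniform over a configurable range
  (5–15 ng for routine wells; 8–800 ng in the calibration experiments so
  expected copies span 10³–10⁵).
- **Admixture**: a bulking agent at mass fraction w with relative DNA
  extractability r leaves the fraction f = (1−w)/((1−w)+w·r) of the
  template target-bearing; the adulterant carries no target. The preset
  ratios (safflower 20, wheat 1, capsicum 0.3) are illustrative round
  numbers for scenario testing, not measured yields.

All randomness flows from one integer seed; identical configurations give
byte-identical outputs. Multiplicative noise placement is deliberate: it
generates exactly the heteroskedasticity the weighted calibration exists
to handle. The simulator does not model amplitude-level PCR kinetics,
inhibition, DNA degradation, or between-batch drift, so passing tests
demonstrate the statistical machinery is correct under the stated error
model — not that real instruments meet that model.

## Numerical choices and problem sizes

- Threshold calling is strictly-greater-than; the auto threshold is the
  midpoint of a deterministic two-means split, and an unseparated
  (unimodal) amplitude distribution warns and calls all droplets negative.
- Interval and band boundaries are inclusive everywhere; the boundaries
  have measure zero under any continuous error model, so the convention is
  immaterial in practice and chosen for readability.
- The shipped coverage experiment uses 72 calibration samples (duplicate
  wells pooled) and 2000 evaluation samples — large enough that the
  binomial error on a 95% coverage estimate is ~0.5 points, small enough
  to run in seconds. Conditional on one 72-point calibration, empirical
  coverage still varies by a couple of points across realizations because
  σ̂ carries ~8.5% relative error at 70 degrees of freedom; this is a
  property of prediction intervals, not an implementation artifact.
- Reports format values to 4 significant digits and are byte-stable across
  re-runs; model files are JSON with the full coefficient covariance so a
  reloaded model reproduces intervals exactly.

## Known limitations

- Sensitivity to low admixture levels depends strongly on the adulterant's
  extractability and on the width of the calibration interval; under the
  default 10% population CV, 5% bulking by a poorly extracting agent is
  generally not detectable, and claims at that level should be validated
  with in-house reference mixtures.
- The λ interval ignores droplet-volume variation and subsampling of the
  reaction into droplets beyond the binomial model.
- The calibration assumes the reference material is pure; contaminated
  references shift the line and silently recalibrate "purity".
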