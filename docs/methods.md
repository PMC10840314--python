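# Methods

This note records the models, algorithms, defaults and design choices
behind `saskit`, in the spirit of a package's statistical reference
documentation.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and uncertainty propagation

A profile is (q, I, σ) with strictly increasing q and 1-σ uncertainties; a
series is a frame-ordered stack of profiles on one shared q grid (relative
grid tolerance 10⁻⁸, chosen to survive text round trips).  All profile
arithmetic assumes independent Gaussian errors: averaging n profiles gives
σ = √(Σσᵢ²)/n, subtraction adds in quadrature.  Two-column text files (no
σ) are ingested with σ = 1 and flagged, so downstream weighted fits degrade
to unweighted ones rather than inventing a noise model.

The final subtracted profile of a series is computed as
average(unsubtracted sample frames) − average(buffer frames).  Averaging
already-subtracted frames would treat the shared buffer noise as
independent: for k sample frames the naive route reports
σ² = Σσ_f²/k² + σ_buf²/k, while the correct value is
Σσ_f²/k² + σ_buf² — the buffer term does not average down because it is
the *same* draw in every frame.  The subtract-after-averaging profile
carries the honest (larger) uncertainty.

## CorMap similarity testing

Under the null hypothesis that two profiles measure the same curve, each
sign of their pointwise difference is an independent fair Bernoulli trial.
The statistic is the longest same-sign run C; the p-value is the exact tail
probability that n fair trials contain a run ≥ C.  Sequences with all runs
≤ m are counted through compositions of n into parts ≤ m via the
sliding-window recurrence c(k) = 2c(k−1) − c(k−1−m), carried out in Python
big integers, so the result is exact at any n the package encounters
(validated to n = 10⁴).  Exactly zero differences break runs; a comparison
whose differences are all zero returns C = 0 and p = 1, since exact
equality only arises from duplicated data.  No multiple-testing correction
is applied inside the pairwise comparison; callers that scan many
windows/regions apply Bonferroni themselves.

## Guinier analysis

The fit is the weighted least-squares line of ln I versus q² over a point
window, with weights (I/σ)² (the delta-method variance of ln I).  Profiles
without usable σ (all zero, e.g. noiseless synthetic curves) fall back to
counting-statistics weights w = I (σ ∝ √I) with residual-scaled
covariance; this is the physically consistent default in ln-space and
matters for reference curves, where uniform ln-space weights overweight the
high-q end of the window.  Rg = √(−3·slope); a non-negative slope (e.g.
inter-particle repulsion) yields a flagged failure result, never an
exception.

Two uncertainties are reported and the larger one is the headline value:

* **fit uncertainty** — from the parameter covariance (assumes accurate σ);
* **range uncertainty** — for manual fits, the standard deviation of
  Rg/I(0) over sub-ranges of the selected window (starts advanced by 0..s,
  ends retracted by 0..s with s = min(10, window/4); sub-ranges shorter than
  max(5, window/2) excluded; at most 500 by uniform subsampling — bounded,
  deterministic and symmetric; sub-ranges never extend beyond the selected
  window, since the end points are presumed to exclude unusable data).  For
  automated fits, the standard deviation of Rg/I(0) over all candidate
  windows scoring ≥ 90% of the winner, i.e. the spread the search itself
  observed.

The automatic range search proceeds in three progressively relaxed stages,
each scanning every window inside a low-q search region.  The region is
bounded at q·Rg = 1.35 (stage 3: 1.6), found iteratively since Rg is not
known a priori (fit the first 20 points, re-bound, repeat ≤ 10 times).
Stage acceptance constraints (defaults, all configurable):

| stage | min window | r² ≥ | qmax·Rg | qmin·Rg ≤ |
|-------|-----------|------|---------|-----------|
| 1 | max(10, 5% of region) | 0.96 | 1.00–1.35 | 0.65 |
| 2 | 7 | 0.92 | 1.00–1.35 | 0.65 |
| 3 | 7 | 0.90 | ≤ 1.45 | 1.00 |

Valid windows are scored
0.6·r² + 0.1·(1 − |1.3 − qmax·Rg|/1.3) + 0.1·max(0, 1 − qmin·Rg/0.65)
+ 0.2·(window/region); ties break toward lower start then longer window,
making the search fully deterministic.  All windows are fitted in O(1)
each via prefix sums of the weighted moments.

Known bias: the Guinier approximation itself overestimates a sphere's Rg
by ~1–2% for windows reaching qRg ≈ 1.0–1.35, and underestimates a Debye
coil's by ~2% at qRg ≤ 0.8.  These are properties of the approximation,
not the fitter; the tests bracket them explicitly.

## Molecular weight

Both concentration-independent estimators need ∫qI dq and ∫q²I dq from
q = 0, below the first measured point; the missing head is integrated
analytically under the Guinier form with the fitted Rg and I(0) (closed
forms, the q² case via erf), and the measured part by the trapezoid rule.

* Correlation volume: Vc = I(0)/∫₀^qmax qI dq, QR = Vc²/Rg; the
  protein/RNA mass laws are calibrated with QR in nm³ (division by 10³
  from Å³), giving MW = QR/0.1231 kDa (protein) or (QR/0.00934)^0.808
  (RNA).  Default cutoff qmax = min(0.3 Å⁻¹, q_last), inside the
  convergence regime for globular particles; configurable.
* Porod volume: Q = ∫₀^qmax q²I dq, Vp = 2π²I(0)/Q, MW = Vp·ρ_app with
  apparent density 1/1.66 Da Å⁻³.  A linear qmax-correction hook exists
  but ships off, since its coefficients are calibration inputs.
* Concentration methods are pure proportionalities on I(0)/c against a
  reference record or an absolute-scale constant.

All constants assume q in 1/Å; 1/nm data must be q-rescaled first.

## Bayesian IFT

The transform I(q) = 4π∫₀^Dmax P(r) sinc(qr) dr is discretized on an
N = 100 point r grid (trapezoid weights; configurable), giving I = A·p.
The solution maximizes −χ²/2 − αS with the quadratic smoothness penalty
S = Σⱼ (pⱼ − (pⱼ₋₁+pⱼ₊₁)/2)², with ghost zeros beyond both grid ends so
the prior matrix is positive definite.  p(0) = 0 is always imposed;
p(Dmax) = 0 only when requested.  Non-negativity is deliberately *not*
imposed: the Dmax diagnostics below need to see negative tail excursions.
Because both terms are quadratic the maximizer is one linear solve and the
evidence is a Gaussian integral:

log E = −χ²/2 − αS + ½ log det(2αB) − ½ log det(H + 2αB)

with H the χ² Hessian, both restricted to the free coordinates.
Determinants are computed from Cholesky factors (a scale-robust
positive-definiteness check; the symmetrized posterior matrix is used).
χ² is reported per data point.

`bift_auto` maximizes the evidence over a 15-point log-α grid spanning ±7
decades around the trace-balance point α₀ = tr(H)/tr(2B) (a scale-aware
anchor: absolute α values are meaningless across intensity scales),
crossed with an 8-point Dmax grid on [2Rg, 4Rg] from a quick Guinier
estimate, followed by one local refinement pass in each variable.  The
whole search is deterministic, and equivariant under intensity rescaling.

Monte Carlo errors re-solve at fixed (α, Dmax) on profiles perturbed by
zero-mean Gaussian noise of the profile's own σ; p_err is the per-bin
standard deviation over replicates, seeded and reproducible.  Note that at
a strongly smoothing α the fixed-α response to σ is sublinear (the
effective regularization grows as σ²); linear scaling of p_err with σ
holds where the error budget sits in data-determined modes.

### Automatic Dmax refinement

Starting from the evidence-optimal Dmax (or an explicit start), the
*unconstrained* (free-endpoint) P(r) is recomputed while Dmax moves in
1 Å steps.  Tail diagnostics over the last 20% of the r grid, as fractions
of the P(r) peak (defaults, configurable):

* **overestimated** — ≥ 2 sign changes with mean |P| < 5% of peak
  (a tail oscillating about zero), or min P < −2% of peak (a negative dip,
  the repulsion signature);
* **underestimated** — endpoint P(Dmax) > 2% of peak.

An underestimated Dmax truncates real density and therefore *also* rings
the tail negative, so the underestimation branch takes precedence when
both criteria fire; for a genuinely overestimated Dmax the endpoint is ~0
and the precedence is moot.  The total change is capped at ±50% of the
start so pathological (e.g. aggregated) data cannot walk the estimate away
indefinitely.  The 5% oscillation threshold was set during development on
the reference sphere: at Dmax 10% too large the tail still carries ~4%
mean amplitude of real density, which a 1% threshold fails to classify.

## LC-series analysis

The scattergram defaults to total intensity per frame (best at exposing
low-/high-q artefacts); mean, q-window and single-q variants exist.  Peaks
are found on a 5-frame moving average with a prominence floor of 5 median
absolute deviations of the raw trace's first difference (a smoothing-free
noise estimate); peak bases are where the trace returns to 99.5% of the
prominence below the apex — *not* the lowest point toward the series edge,
which would swallow the flat regions the buffer search needs.

**Buffer validity** (in order, short-circuiting, so a report lists only
executed tests): (1) no scattergram trend — Spearman rank correlation
versus frame over the window and both halves, Bonferroni ×3, fail below
corrected p = 0.01; (2) profile similarity — CorMap of every window frame
against the first over the full q range and the lowest/highest 20% of q
(fouling shows at low q, drift at high q), Bonferroni over all
comparisons, corrected p < 0.01 fails; (3) a single significant SVD
component.

**Sample validity** adds, before the shared similarity/SVD tests: all
frames must have Rg and MW values; no Rg or MW trend (Spearman,
Bonferroni ×2); similarity is tested after least-squares scaling of each
profile to the first (concentration varies across a peak); and averaging
the full range must not lose signal-to-noise against the best
descending-S/N prefix of its frames (tolerance factor 0.999), where
S/N := mean over q of I/σ of the averaged profile.

**SVD rank**: the stack (q on rows, frames on columns) is whitened per q
channel by the RMS σ of that channel over the selected frames.
Element-wise I/σ normalization is *not* used: it rescales every frame
differently and provably bends an exactly rank-k stack into k+1 smooth
components (a single-species peak then reads as rank 2).  A component is
significant when its singular value exceeds twice the median of the
trailing half of the spectrum and both singular vectors have non-centered
lag-1 autocorrelation > 0.6 — noise vectors decorrelate, real spectral
and elution shapes do not.

**Searches**: the buffer search scans windows of shrinking width (initial
min(30, largest non-peak gap), minimum 10, shrink ×0.75, step = width/2)
left-to-right over the frames outside every peak's base-to-base span,
returning the first valid window.  The sample search scans inside the
strongest peak (initial = base-to-base width, minimum 3) in
centered-first order.  Both are deterministic.  Note the known failure
mode of buffer-first ordering: a long flat region that contains a weak
eluting component can pass all three tests; the validity report exists so
the user can inspect what was accepted.

**Baselines** operate on subtracted data and never touch the stored
frames.  Linear: an independent straight line in frame number per q
channel through the start/end range means, applied between the ranges
(optionally extrapolated to all frames).  Integral (capillary fouling): a
non-negative correction accumulating in proportion to the above-baseline
intensity, b ← d·cumsum(max(I−b,0))/Σ_[start..end] max(I−b,0) with
d(q) = max(0, mean_end − mean_start), iterated to a 10⁻⁴·max(d) fixed
point (≤ 100 iterations; non-convergence is flagged, not raised) and
clamped monotone non-decreasing in frame.  Sliding Rg/MW traces use a
centered 5-frame window (odd widths only) and leave NaN gaps on frames
without a valid Guinier fit; they are recomputed after any baseline
correction.

A note on the trend tests: consecutive sliding-window trace values share
frames, so the Spearman test on short windows is anti-conservative; in
practice this makes the sample search conservative (it rejects some
acceptable apex windows and settles on a slightly narrower one), which is
the safe direction.

## Synthetic data

The generator produces what the analysis assumes: one or more species with
analytic form factors (solid sphere; Debye Gaussian coil as a second,
spectrally distinct shape), Gaussian elution concentration profiles, a
featureless buffer background (constant plus decaying exponential in q),
and Gaussian noise with counting-like σ = scale·√I — Gaussian rather than
Poisson, matching the weighted-least-squares assumptions of every
downstream fit.  The per-series noise scale is set so the strongest
component's apex frame has a requested mean S/N (30 in the reference
presets; q grid 0.008–0.35 Å⁻¹, 200 points, 100 frames).  Drift injection
adds m·frame·g(q) (linear) or a cumulative non-negative fouling term
proportional to elution intensity (integral), with g(q) = exp(−q/0.1).

Truth records label buffer frames (component signal ≤ 10⁻⁴ of apex) and
pure sample frames (species purity ≥ 99% with ≥ 1% of apex signal),
enabling exact scoring of range selections.

What the generator does *not* emulate — and hence what passing tests do
not establish about measured data: inter-particle structure factors,
radiation damage, non-Gaussian/correlated detector noise, imperfect buffer
matching, q-calibration errors, and tailing (non-Gaussian) elution peaks.

## Numerical and degenerate-input policy

Validation failures of caller inputs raise `ValidationError`; data-quality
outcomes (non-negative Guinier slope, failed BIFT solve, no valid window)
return flagged result objects so series-scale loops never die on a bad
frame.  All stochastic steps take explicit seeds; every search is
deterministic given data and configuration.  Every constant above lives in
`AutoGuinierConfig`, `BiftConfig`, `SeriesConfig` or `RunConfig`, which
serialize to a single JSON file and reject unknown keys.

Problem sizes in the test and acceptance suites (50 Guinier replicates, 10
BIFT/pipeline replicates, 100-frame series, exhaustive CorMap enumeration
to n = 12) are the package's reference study conditions.

## Known limitations

* Single-component analysis only: overlapping species are *detected*
  (SVD rank, Rg trends) but not deconvolved; no EFA/REGALS-style
  factorization is included.
* The evidence search brackets Dmax by [2Rg, 4Rg], which can clip very
  elongated particles before refinement widens it.
* MW constants are protein/RNA empirical laws; other polymer classes need
  user calibration.
* The integral baseline assumes monotone accumulation; transient fouling
  that clears mid-run violates its model.
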