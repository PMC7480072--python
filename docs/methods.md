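# Methods

## The measurement problem

The contrast sensitivity function (CSF) — sensitivity S(f) = 1/threshold
contrast as a function of spatial frequency f — is clinically informative in
amblyopia but tedious to measure in young children. `popcsf` models a
gamified tablet test in which drifting Gabor patches appear on screen and
the child presses ("pops") the ones they can see, while a Bayesian adaptive
procedure (QUEST+) chooses each patch's contrast and spatial frequency to be
maximally informative about the child's CSF.

## CSF model

A truncated log-parabola with three parameters plus a lapse rate:

    log10 S(f) = log10 Gmax                                    f <= Fmax
    log10 S(f) = log10 Gmax
                 - log10(2) * ((log10 f - log10 Fmax) / (log10(2^beta)/2))^2
                                                               f >  Fmax

* `Gmax` — peak gain (dimensionless sensitivity; threshold contrast is the
  Michelson fraction 1/S).
* `Fmax` — peak spatial frequency, cycles/degree (cpd).
* `beta` — bandwidth: full width at half maximum, in octaves.  One checks
  directly that S(Fmax * 2^(beta/2)) = Gmax/2.
* `lapse` — the probability of missing an arbitrarily visible target.

There is no low-frequency fall-off: the function is flat at `Gmax` below the
peak. The test presents nothing below ~1.8 cpd, so a low-frequency
truncation parameter would be unidentifiable; the model deliberately omits
it. Hypotheses with threshold contrast above 1 (unreachably weak) are legal;
the psychometric function simply stays near the guess rate there.

Detection follows a Weibull psychometric function on **linear** contrast:

    p(hit | c, f) = gamma + (1 - gamma - lapse) * (1 - exp(-(c/alpha(f))^s))

with fixed slope s = 3, guess rate gamma = 0.05, and lapse fitted over the
discrete set {0.05, 0.1, 0.2}. Whether the slope is meant on a linear or
log contrast axis is a genuine ambiguity; linear is the simplest reading and
is exposed as configuration (`PsychometricSpec.slope`), not hard-coded.

## QUEST+ engine

Inference is grid-based. The live grids are:

* stimuli: 15 Michelson contrasts log-spaced 0.01%–100% x 10 spatial
  frequencies log-spaced 0.019–0.125 cycles/pixel (1.8–11.7 cpd at the
  nominal 500 mm viewing distance) — 150 stimuli;
* hypotheses: 15 Gmax log-spaced 3–300 x 10 Fmax log-spaced 1–10 x
  9 beta linearly spaced 1–9 x 3 lapse values — 4050 points, uniform prior
  (a prior from an earlier assessment can be injected and is renormalized).

After each Hit or Miss the posterior is multiplied by p(hit) or 1 − p(hit)
and renormalized. False alarms (presses with no stimulus nearby) carry no
stimulus information and are rejected by the update with an explicit error;
callers log them but never feed them to the engine.

Stimulus selection minimizes the expected posterior Shannon entropy
p(Hit)·H(post|Hit) + p(Miss)·H(post|Miss) over the stimulus grid, the
standard QUEST+ criterion. Exact ties (within 1e−12 relative) are broken by
a seeded uniform draw, so sessions are reproducible given a seed. All
likelihoods are precomputed in one (150 x 4050) table; a selection step is a
few vectorized passes over that table (~10 ms on one core).

Point estimates are posterior means, taken in log10 space for the
log-spaced Gmax and Fmax grids (back-transformed) and linearly for beta and
lapse. Log-space expectation is the convention consistent with log-spaced
grids; it reproduces the geometric grid midpoint under a uniform posterior.

## Geometry

Pixels-per-degree uses the *full-width average* convention: total horizontal
pixels divided by the total subtended angle 2·atan(width/2d). On the default
tablet (12.3", 2736 x 1824) at 500 mm this gives 93.88 px/deg, which jointly
reproduces the worked conversions 0.019 cpp → 1.8 cpd, 0.125 cpp → 11.7 cpd
and 52 px → 0.55°. The per-pixel central-tangent alternative (91.8 px/deg)
is available behind `convention="central"` but is *not* consistent with
those three values simultaneously.

The 99%-energy diameter of the Gabor envelope uses the two-sided 1-D normal
quantile convention, 2·Φ⁻¹(0.995)·SD = 2.83° for SD 0.55°. A strict 2-D
radial-energy calculation (energy ∝ squared envelope) gives 2.36° and is
available as `convention="radial_2d"`.

Viewing-distance traces are looked up by last observation carried forward
(LOCF): at camera rates near 29 Hz the lookup error is at most ~35 ms of
head motion, and LOCF never uses future information. An empty or missing
trace falls back to the nominal distance.

## Session simulator

The simulator reproduces the game loop at frame resolution (60 Hz):

* **Appearance.** With N Gabors on screen, a new one appears each frame
  with probability 1/(60·(N+1)), clamped to 0 at the 5-Gabor cap. The
  (N+1) reading keeps the rate finite on an empty screen and inversely
  proportional to the number already present; the literal 1/(60·N) form is
  available as a config switch with N=0 mapped to 1/60.
* **Detection.** Each appearing Gabor gets its (contrast, frequency) from
  QUEST+ on the current posterior. The observer detects it with the Weibull
  probability at their *true* CSF, evaluated at the cpd implied by their
  current simulated viewing distance — while the engine only ever sees the
  nominal-distance cpd, exactly the mismatch the post-hoc refit corrects.
* **Timing.** Hits occur after a log-normal latency (median 0.8 s, sigma
  0.5 in log units — invented, config-exposed), truncated at the 7 s
  response window (6 s visible + 1 s grace); undetected Gabors become
  Misses at the window's end. Trials enter the posterior in scoring order.
* **False alarms.** A homogeneous Poisson process at the observer's rate
  (default 2/min, bracketing the observed per-eye medians of 1.8 and 2.2).
  They decrement the score (floor at zero) but never touch the posterior:
  with a fixed seed, switching the FA process on or off leaves the
  posterior bit-identical, because the random streams are split per
  subsystem.
* **Distance drift.** A Gaussian random walk (step SD 4 mm per 29 Hz
  sample) reflected at [300, 900] mm around the 500 mm nominal — chosen to
  span the observed spread of real sessions (median ~531 mm, IQR roughly
  378–755 mm); an emulation target, not a fit.
* **Motion is not simulated.** Gabor kinematics never enter the
  psychophysical model; position matters only through the hit-radius rule,
  so presses are reduced to detection events, with an optional 2-D Gaussian
  positional error to exercise the 221 px radius.

Sessions stop after ~30 hits (the clinical practice) or a trial cap.

## Post-hoc refit and summaries

`refit_session` reruns the Bayes product on an enlarged grid (40 x 40 x 9 x
3) with each trial's frequency recomputed from its cycles/pixel value and
the LOCF distance at stimulus offset. The product is accumulated in log
space and exponentiated once, so trial order is irrelevant by construction;
with a constant nominal-distance trace and live-size grids it reproduces the
live posterior to ~1e−13.

`aucsf` integrates max(log10 S, 0) over log10 f by the trapezoid rule on a
200-point log-spaced grid, default band 1–15 cpd (the refit stimulus
domain; the band is configuration because nothing pins it down externally).
Integrating in log-log coordinates makes the area invariant to frequency
rescaling; flooring at 0 discards sub-unity sensitivities (moot on-grid,
where Gmax >= 3). For a flat CSF the closed form log10(Gmax)·log10(fhi/flo)
holds to float precision. `hf_cutoff_sensitivity` is log10 S at the band's
top. Summaries are computed from the posterior-mean parameters (a point
estimate), not the posterior expectation of the summary.

## Synthetic cohorts

`generate_cohort` draws paired-eye subjects:

* fellow-eye CSF: Gmax log-normal, median 80, SD 0.15 log10 units; Fmax
  log-normal, median 3 cpd, SD 0.12; beta normal(3, 0.8) clipped to [1, 9];
  lapse 0.05 — a plausible healthy-child profile (the population is not
  externally fixed; these are package defaults).
* acuity: amblyopic-eye logMAR uniform within its severity band (mild
  0.2–0.3, moderate 0.3–0.6, severe 0.6–1.0; classes cut at 0.3/0.6 on the
  worse eye); fellow eye near-normal (uniform 0–0.1) capped to keep the
  interocular gap >= 0.2 logMAR.
* effect model: the amblyopic eye loses `gmax_slope` (default 1.0) log10
  units of Gmax and `fmax_slope` (default 0.5) log10 units of Fmax per
  logMAR of interocular difference, plus N(0, 0.05) log10 noise. Zero
  slopes give the null model with exchangeable eyes.

What the generator does *not* emulate: attention lapses that drift within a
session, strabismic vs anisometropic subtype differences, learning effects
across eyes, non-stationary false-alarm rates, and any dependence of
response latency on stimulus visibility. Passing cohort-level tests
therefore demonstrates that the pipeline detects effects *of the generative
kind*, not that real pediatric data will show them at the same strength.

## Statistics

Case-control: paired Wilcoxon signed-rank on amblyopic vs fellow AUCSF, per
severity stratum and overall. Dose: Kruskal-Wallis on AUCSF ratio across
severity classes, and Spearman rank correlation of AUCSF ratio vs the
acuity ratio (1+logMAR_amblyopic)/(1+logMAR_fellow). False-alarm rates are
compared between eyes with the paired signed-rank test. All tests are
scipy.stats with `method="auto"`, which uses the exact small-sample null
when sizes permit and the asymptotic approximation otherwise. Degenerate
strata (all-zero differences, constant ratios) are flagged in the report
rather than raised.

## Numerical choices

* Posterior mass is strictly positive throughout a session (likelihoods are
  bounded inside (0, 1)); entropy sums use `xlogy` so injected priors with
  exact zeros are still safe.
* An update that annihilates the posterior raises a degeneracy error (CLI
  exit code 3) rather than renormalizing garbage.
* Selection ties are resolved at 1e−12 relative tolerance with a seeded
  draw; every stochastic entry point takes an explicit seed and there is no
  hidden global RNG state.
* Grid values are matched by 1e−9 relative closeness when looking up
  precomputed likelihood rows; off-grid stimuli (the refit path) are
  computed on demand.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` size their simulations so a full
run stays interactive on a single core: parameter recovery uses 50 (tests)
or 30 (script) simulated observers checkpointed at 30/60/100/120 trials of
one continuing session; the end-to-end cohort pipeline uses 60 (tests) or
24 (script) subjects with both eyes simulated and refitted; null
calibration of the paired test uses 500 replicate cohorts of n=200 (tests)
or 200 of n=100 (script), built from generated cohorts with analytic AUCSF
plus independent per-eye measurement noise — the calibration of the test
statistic does not depend on running the adaptive engine per replicate.

## Known limitations

* The engine is strictly grid-based; posterior means inherit edge bias for
  true parameters at grid boundaries (visible as the larger recovery error
  for Fmax near 1 or 10 cpd).
* Fmax below the 1.8 cpd stimulus floor is only weakly identifiable — a
  property of the test design, faithfully reproduced.
* The simulator's latency, drift, and cohort-effect parameters are
  plausible defaults, not fitted quantities; conclusions about power at
  other parameter settings require re-running the generator at those
  settings.
* Live inference deliberately ignores viewing distance (it is corrected
  post hoc); sessions with extreme sustained drift will show live/refit
  disagreement, which is the intended signal, not an error.
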