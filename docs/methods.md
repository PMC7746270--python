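# Methods

`motionprior` implements a complete, synthetic-data-driven analysis of a
motion-direction estimation task with biased stimulus statistics: task
simulation, Bayesian observer models of percept formation, behavioural
summary statistics, maximum-likelihood model fitting, and model
comparison. This note records the models, the numerical choices, and the
places where the design was genuinely open.

## Task model

A session has 567 trials in four randomly interleaved contrast
conditions: 167 zero-contrast (no stimulus), 90 low-contrast trials whose
luminance follows a 2-up/1-down staircase, 243 on a 4-up/1-down
staircase, and 67 high-contrast trials at a fixed 1.76 cd/m² above
background. Stimulus trials move at 0°, ±16°, ±32°, ±48° or ±64°
relative to a central reference, with ±32° shown on 58% of stimulus
trials, the other predetermined directions on 36%, and fully random
directions on 6%. The over-representation of ±32° is the statistical
structure the observer is assumed to internalize as a bimodal prior.

Direction allocation is exact-count rather than Bernoulli (58% of 400 =
232 trials at ±32°, 116 per sign; 24 random trials; 144 spread as evenly
as possible over the seven remaining predetermined directions with the
4-trial remainder assigned by a seeded draw), so the designed
percentages hold exactly on every seed and are directly testable.

Staircases step multiplicatively on luminance (default factor 1.2)
within bounds [0.01, 1.76] cd/m²; the level drops only after the rule's
run of consecutive correct detections and rises after any single miss.
Step size, starting level and bounds are explicit configuration knobs:
standard adaptive-psychophysics defaults, not reported task values. The
2/1 and 4/1 rules converge near 71% and 84% correct respectively, and
against a fixed logistic detection function the simulated level series
stabilizes within roughly 100 trials, which the test suite checks as a
variance contrast between the first and last 100 low-contrast trials.

## Observer models

All angles are degrees. A von Mises "width" σ maps to concentration
κ = 1/σ_rad² (the Gaussian-approximation convention); densities are per
degree. All circular densities live on a uniform 1° grid over
[−180°, 180°); integrals over the sensed direction are discrete sums on
that grid and convolutions are circular.

Per trial with true direction θ_act:

1. a sensed direction θ_s ~ V(θ_act, σ_s) captures trial-to-trial
   sensory variability;
2. the observer multiplies the likelihood V(θ_s, σ_s) with an acquired
   bimodal prior p_prior(θ) = ½[V(−θ_p, σ_p) + V(θ_p, σ_p)];
3. the percept θ_perc is the circular mean (resultant argument) of the
   posterior — the arithmetic mean is ill-defined on the circle;
4. with probability α_p the percept is instead a lapse: a draw from the
   prior (BAYES_P and the variable-precision variants) or uniform
   (BAYES);
5. the reported estimate adds motor noise: θ_est ~ V(θ_perc, σ_m).

The response density marginalizes θ_s on the grid:

p(θ_est | θ_act) = (1−α_p) Σ_j p(θ_s_j | θ_act) V(θ_est; μ(θ_s_j), σ_m)
                 + α_p · L(θ_est),

with L the prior convolved with V(0, σ_m) for prior-based lapses and
1/360 for uniform ones. Variants: BAYES_P and BAYES use a scalar σ_s
(4 free parameters each); BAYES_varmin uses one σ_s at ±32° and one
elsewhere (5); BAYES_var one σ_s per direction magnitude
{0, 16, 32, 48, 64} (8). Random-direction trials take the σ_s of the
nearest magnitude. σ_m is never fitted; it is estimated from
high-contrast trials (below).

The non-Bayesian ADD class mixes a prior-only response route (taken with
probability w_prior) with a likelihood-only route instead of multiplying
the densities. Four concrete forms are implemented — the prior route
either samples the prior or reports one of the two modes at random,
crossed with uniform vs. prior-based lapses. These four forms are
canonical reconstructions of the strategy class, not transcriptions of a
published table, and results involving them should be read with that
caveat.

Numerics worth knowing:

- The percept map μ(θ_s) for all grid θ_s at once is a circular
  cross-correlation evaluated by FFT; where FFT round-off floods
  resultants many orders below the peak (sensed directions far from both
  prior modes under narrow widths), those entries are recomputed in log
  space. A genuinely zero posterior resultant raises an error.
- Halving the grid spacing moves response-distribution circular means by
  under 0.05° in the operating regime (tested); σ values below ~2° are
  outside the trustworthy regime of the 1° grid, which is why fit bounds
  stop there.
- Model-level "attraction" is summarized by the location parameter of a
  von-Mises-plus-uniform mixture fitted to the response density — the
  same summary the behavioural analysis applies to samples. The raw
  circular mean of the response distribution is *not* a useful attraction
  measure here: the marginal response distribution is bimodal (an
  opposite-mode lobe always exists), which drags the circular mean toward
  the centre even for stimuli at a prior mode. With large σ_s the
  posterior-mean reading itself collapses percepts toward 0° (the
  resultant of a near-symmetric bimodal posterior), so attraction toward
  the *nearest* mode is a moderate-noise phenomenon, roughly σ_s ≲ 15°
  and σ_p between ~8° and ~30° for θ_p = 32°. Tests assert it there.

## Synthetic observers

`simulate_session` generates complete sessions from any parameterized
observer. Estimation responses on low-contrast trials follow the
generative chain above exactly (percepts interpolated circularly from the
grid percept map). Everything else is deliberately descriptive — material
for the behavioural summaries, with no theoretical claim attached:

- Detection is logistic in log-luminance (threshold 0.1 cd/m², slope 2.5
  per log-unit), with a ×1.5 odds boost at ±32° to emulate better
  detection at expected directions. Staircases advance trial-by-trial on
  these outcomes.
- High-contrast trials are generated as veridical percept + motor noise
  (+ lapses). This is the premise that makes σ_m estimable from
  high-contrast errors; it also means high-contrast behaviour carries no
  information about σ_s or the prior.
- Zero-contrast trials are "detected" at a false-alarm rate of 0.15; a
  detected (hallucination) trial yields an estimate drawn from the prior
  with probability 0.7 and uniformly otherwise, plus motor noise. These
  two knobs were chosen once to land the hallucination probability ratio
  in the 2–3 range and are emulation targets, not mechanisms.
- Reaction times are lognormal (log-mean 0, log-sd 0.3, i.e. median 1 s)
  with a −0.1 log-unit shift at ±32°; 2% of estimates are omitted to
  emulate the finite response window.

The default observer — used by the analysis drivers and the
behavioural-signature tests — is BAYES_P with θ_p = 32°, σ_p = 15°,
σ_s = 12°, α_p = 0.1, σ_m = 8°. The moderate σ_s puts it in the regime
where attraction at ±16° is toward the modes and summary magnitudes are
realistic (per-direction variability 11–19°, attraction at ±64° around
+13°, median p_ratio ≈ 3).

What passing tests on these observers does and does not show: they
validate the pipeline (the statistics recover what the generator put in),
not claims about human data. In particular, a scalar-σ_s BAYES_P
generator produces fitted per-direction variability that *decreases*
monotonically with attraction strength — variability at ±48°/±64° comes
out at or below the ±32° value, unlike the empirical pattern in such
tasks, where variability rises again at far directions. Reproducing that
rise requires direction-dependent sensory precision (the var variants) or
mechanisms outside these models. Tests therefore assert the contrasts a
BAYES_P world genuinely produces: variability at ±32° below 0° and ±16°,
detection best at ±32°, attraction toward the modes at ±16/±48/±64°.

## Behavioural statistics

- **QC**: a session fails if high-contrast detection ≤ 70%, high-contrast
  circular RMSE of estimation error ≥ 30°, or low-contrast detection
  < 50%.
- **Error mixture**: per-direction bias/variability/lapse come from the
  MLE of (1−α)·V(μ, σ) + α/360 on wrapped errors, fitted by L-BFGS-B from
  a fixed 9-point start grid (data circular mean × three widths × three
  lapse levels), bounds μ ∈ [−180, 180], σ ∈ [0.5, 120], α ∈ [0, 1].
  Strata under 10 usable trials are flagged, not fitted.
- **Folding**: low-contrast estimation statistics use trials with a
  response and a "seen" report; negative directions fold onto positive
  magnitudes with error signs mirrored. The 0° stratum, where "toward the
  modes" has no sign, is symmetrized (each error pooled with its mirror),
  which makes the output exactly invariant under mirroring a session and
  pins its bias near 0 by construction.
- **p_ratio**: the circle is treated as 11 bins of 32° centred on the
  predetermined direction lattice; the two bins at ±32° are targets, a
  hit is a circular distance ≤ 16° to the nearest mode, and the ratio is
  the average per-target-bin hit probability × 11. Uniform-by-bin
  responding gives exactly 1; all-mass-on-targets gives 5.5. The 11 × 32°
  = 352° layout leaves an 8° sliver opposite the reference that is
  assigned to the nearest (non-target) bin — an interpretation, flagged
  as such. An empty input yields an undefined (NaN) result, not 0.
- **Learning dynamics**: overlapping windows (default 110 trials, step
  55) carry a cheap attraction index — the mean signed error toward the
  nearest prior mode at non-±32° predetermined directions, excluding 0°
  where the sign is undefined — plus detection and RT contrasts at ±32°
  vs. elsewhere. A full mixture fit per window would be unstable at these
  window sizes; the cheap estimator is a deliberate deviation and is
  validated as flat on stationary observers.

## Fitting and model comparison

σ_m is the mixture-fit σ on high-contrast errors (≥ 20 usable trials);
the uniform component absorbs lapses, though same-mode prior lapses can
inflate it slightly. Model likelihoods use low-contrast trials with an
estimate and a "seen" report, staircases pooled; the density of each
observed estimate is evaluated exactly (no response-grid interpolation).

Optimization is bounded L-BFGS-B from a fixed 12-point Latin-square start
grid (per-dimension level midpoints in seeded permutations); optionally
only the best few starts by raw NLL are polished (`polish_top`), which the
recovery harnesses use to keep hundreds of fits affordable. Bounds:
θ_p ∈ [5°, 80°], σ_p ∈ [2°, 120°], σ_s ∈ [2°, 80°], α_p ∈ [0, 0.5],
w_prior ∈ [0, 1]. Fits are deterministic given data and settings. BIC is
k·ln(n) + 2·NLL with k the variant's free-parameter count. Note σ_p is
unidentifiable above roughly 40–60°: a prior that wide is effectively
flat, the likelihood surface is flat in σ_p, and fitted values there
should be read as "uninformative prior", not as estimates.

Random-effects comparison approximates each subject × model log evidence
as −BIC/2 and runs the standard variational Dirichlet scheme over model
frequencies; exceedance probabilities come from 10⁵ seeded Dirichlet
draws; the Bayes omnibus risk (from the variational free energy against
the null of exchangeable frequencies) shrinks them toward 1/K to give
protected exceedance probabilities. Against a converged
importance-sampling oracle the scheme is accurate (< 0.01) for tied,
mildly heterogeneous and well-separated evidences, but underestimates the
exceedance of close-but-not-tied models by up to ~0.04 — a known property
of the variational approximation, worth remembering when PXPs near a tie
are interpreted.

Recovery harnesses simulate → refit → tabulate. Parameter recovery on 20
full-length (567-trial) BAYES_P observers spanning θ_p ∈ [20, 45],
σ_p ∈ [8, 30], σ_s ∈ [8, 25], α_p ∈ [0.02, 0.2] yields Spearman ρ ≈ 0.9
for θ_p and ≈ 0.85 for σ_s with median absolute errors of ~2.5° (θ_p),
~10% (σ_p), ~5% (σ_s) and ~0.015 (α_p) — the quantities the acceptance
tests recompute. Model recovery between the two lapse-route variants
(BAYES_P vs. BAYES) uses cohorts of 10 subjects; per-subject BIC gaps of
~30–60 in favour of the generating model make both comparison methods
reliable identifiers at that scale.

## Problem sizes used by the test suite

The suite keeps everything single-CPU-friendly by choice of scale, not by
weakening checks: oracle equivalence uses 10⁶-draw forward simulations at
five parameter sets; parameter recovery 20 observers × 567 trials; model
recovery 20 cohorts × 10 subjects with the two 4-parameter variants and
screened-start fitting; behavioural signatures pool 20 sessions.

## Known limitations

- Prior *acquisition* is not modelled: the generative prior is static,
  matching how the models are fitted; learning-dynamics outputs on
  synthetic data are flat by construction.
- Detection, hallucination and RT mechanisms are emulations; only the
  estimation chain is the theory.
- The ADD variants are reconstructions (above).
- Group-level inference (ANOVAs, Bayes factors, rank tests) is out of
  scope; the pipeline stops at per-session summaries and cohort-level
  model comparison.
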