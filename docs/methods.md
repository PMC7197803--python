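# Methods

## The experiment the package models

Fifteen observers judged the orientation of a low-contrast probe grating
by rotating a response bar (an adjustment task). Five conditions: a
probe-only control; two controls showing a superposition of two orthogonal
oblique gratings (−45° and +45°) for 33 or 200 ms; and two test conditions
in which the superposition collapses to a *single* sustained grating at one
of the two obliques before the probe appears. Thirteen probe orientations
(−90°…+90° in 15° steps) × 8 repeats gives 104 judgments per condition per
observer; the two endpoint labels denote the same physical orientation
measured twice, which is why labels and physical angles are kept distinct.
The phenomenon of interest is a rare illusory report of the *removed*
orientation — orthogonal to the probe — occurring almost exclusively at
probes parallel to the sustained grating ("adapted" probes, ±45°), more
often after the 200 ms than the 33 ms switch, and in roughly half the
observers.

## Circular arithmetic

Gratings are axial: θ and θ + 180° are the same stimulus. All angles are
reduced to the half-open interval (−90°, +90°] (−90° folds to +90°), and
every judgment enters the analysis as the signed circular offset
Δ = canonicalize(response − probe). Orthogonality is the unique
maximal-distance case |Δ| = 90°. Canonicalization is idempotent and
exactly periodic; offsets of ±90°-labelled probes coincide by
construction.

## Error criterion

The control reference is the mean μ and SD σ (ddof = 1) of the pooled
offsets of all three control conditions (n = 4680); a trial is an error
iff the circular distance of its offset from μ exceeds k·σ with k = 4 (a
named, configurable constant). Moments are computed on the raw empirical
offsets — no kernel density step is needed for a mean and an SD. Two
centering modes are reported side by side:

* `pooled` (default) — offsets pooled as-is. The oblique bias (below)
  inflates σ by its between-orientation variance.
* `per_orientation` — each offset is first centered by its probe label's
  mean control offset; this removes the bias component and can only
  shrink σ (variance decomposition), giving a stricter threshold.

Degenerate inputs raise: fewer than 2 control trials, or σ = 0.
Classification also flags `near_orthogonal` trials
(circular |Δ − 90°| ≤ k·σ), the subset entering the CDF comparison.
Because thresholds sit near 30° ≪ 45°, near-orthogonal implies error.

## Resampling procedures

All three procedures accept a seed, are bit-reproducible, and sort their
input on a stable key before sampling so results are independent of row
order. Empirical p-values are reported both as raw frequencies and in the
add-one convention (1 + #extreme)/(1 + n), which bounds p ≥ 1/(1 + n) —
the resolution floor implied by reporting "p < 10⁻⁶ at 10⁶ shuffles".

**Bootstrap count nulls.** The 240 adapted-probe trials of a test
condition are resampled with replacement and reclassified against the
*fixed* original reference (re-fitting the reference per resample is a
defensible alternative; fixed is the default because the reference comes
from controls that are not being resampled). Unit `trial` draws 240
trials i.i.d., making the count exactly Binomial(240, k/240) — the oracle
used in the tests; unit `participant` draws 15 observers with all their
adapted trials, preserving the within-observer clustering of errors. Both
units are first-class. Tail probabilities are exposed as P(X = k),
P(X ≤ k) and P(X ≥ k) because "probability to obtain k error counts" is
ambiguous between them. On cohorts reconstructed from the reported counts
alone, the trial-unit bootstrap reproduces two of the three printed tail
probabilities (P(X ≤ 8 | mean 20) ≈ 0.0015; P(X ≥ 20 | mean 8) ≈ 0.0002,
values the 03 driver computes); the third printed value (≈ 0.0003 for
"1 error or less" under mean 8) is an order of magnitude below the
trial-unit binomial value (≈ 0.003), consistent with an unstated
resampling unit or selection — the discrepancy is surfaced, not resolved.

**Shuffle test.** Error status is a property of the trial, computed once
from the true probe/response pairing; shuffles permute probe labels
within each condition × sustained-grating panel and re-count errors
sitting at adapted labels. (Re-classifying after permutation would count
every veridical response paired with a distant label as an "error" and
invert the test.) The adapted label set defaults to both obliques
{−45°, +45°}, so a single error lands there with probability
16/104 = 2/13 under exchangeability — the hypergeometric oracle in the
test suite. The statistic sums over panels; the permutation is
implemented as a row-wise permutation of the adapted-label mask, which is
distributionally identical to permuting labels.

**CDF distance test.** Near-orthogonal error offsets are centered by
circularly subtracting 90°; control offsets by subtracting their pooled
mean. The reference CDF is the empirical CDF of *all* centered control
offsets; each of n_resamples draws of n_cases control offsets (with
replacement) yields an empirical CDF whose mean absolute vertical
distance to the reference, over a fixed symmetric grid of 201 points
spanning ±4 control SD, forms the null sample; p is the fraction of
resamples at least as distant as the error CDF. A fixed grid keeps
distances comparable across resamples. Two centering policies: the
default re-centers every resample (and the error sample) at its own mean,
matching a "all distributions centered at 0°" protocol — this makes the
test a *shape/scale* comparison, blind to pure location shifts by
construction; the global mode centers only once and retains location
sensitivity. Type-I calibration (rejection rate ≈ α under the null) holds
in the default mode because error sample and resamples are treated
identically; the power property against a gross 3-SD shift is a
global-mode statement. Fewer than 2 error cases raises an
insufficient-data signal, which the pipeline records as a skipped stage.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
it is the package's stand-in for the experiment, with defaults fixed at
the study's reported values:

| parameter | default | rationale |
|---|---|---|
| response_noise_sd | 5° | 4·SD ≈ 20–35° stays well below 45°, keeping the orthogonal cluster separable |
| bias_amplitude | 6.8° | maximum mean oblique bias reported |
| bias_heterogeneity_sd | 6.2° | between-observer SD reported with that maximum |
| illusion_rate_200 / 33 | 0.083 / 0.033 | observed error fractions at adapted probes |
| control_illusion_rate | 2/4680 | two errors in all control trials |
| susceptible_fraction | 7/15 | observers who showed the illusion at all |
| orthogonal_jitter_sd | = response_noise_sd | illusory percepts scatter like veridical ones |

The oblique bias is modelled as amplitude·sin(4θ) — the simplest smooth
form that vanishes at cardinal and oblique orientations and repels
judgments from the cardinal axes; only the maximum magnitude is
constrained by data. Illusion occurrence is Bernoulli per trial with no
history dependence (no sequential structure is reported). Susceptible
observers are drawn without replacement to hit exactly
round(fraction × 15) = 7. The illusion rates are *marginal* over all
adapted-probe trials; since only susceptible observers can show the
illusion, the within-susceptible per-trial probability is
rate / susceptible_fraction (≈ 0.178 and 0.071), and a configuration
error is raised if that exceeds 1. The within-susceptible rate is
otherwise unconstrained by the study, which reports no per-observer
rates. On illusory trials the sustained grating is set parallel to the
probe (the context in which the illusion is reported to occur);
non-illusory test trials get a random ±45° grating.

What the generator does **not** emulate: reaction times, sequential or
learning effects, observer-specific illusion rates beyond the
susceptible/insusceptible split, the masking noise patch, and —
important for interpreting the CDF stage — the fact that real illusory
responses presumably carry the same observer-level idiosyncrasies as
veridical ones. Planted orthogonal jitter equals the *per-trial* noise
SD, whereas pooled control offsets also contain between-observer and
between-orientation variance (pooled SD ≈ 8.4° vs 5°); on synthetic
cohorts the CDF comparison can therefore legitimately flag a scale
difference that matched real data would not show. Passing tests
demonstrate the procedures' calibration and oracle agreement, not that
real data would produce any particular p-value.

**Exact-count reconstruction.** For statistics that depend only on the
reported error counts (the bootstrap means), `reconstruct_reported_counts`
plants exactly k orthogonal trials per test condition into a
zero-illusion background whose Gaussian components are truncated (noise
at 3 SD, observer bias at 2 SD, jitter at 3 SD), bounding every veridical
offset ≈ 33° below the fitted 4·SD threshold ≈ 34–35°; a deterministic
repair pass removes the (expected ≪ 1) residual exceedances at adapted
test probes. The classifier then finds exactly the requested counts by
construction, for any seed.

## Toy decision model

A deliberately minimal competition model of the proposed mechanism, not
used in any quantitative claim: representation amplitude
R(d) = exp(−d/τ_adapt) (adaptation of the sustained orientation, τ_adapt
= 800 ms), error amplitude E(d) = g·(1 − exp(−d/τ_off)) (duration-
dependent off-response, τ_off = 300 ms, attenuated by feedback to the
surviving fraction g); independent Gaussian noise (SD 0.367) on each; the
larger noisy amplitude wins if it clears a threshold (0.10), an error-unit
win reporting the orthogonal orientation. A fully explained-away error
signal (g = 0, hence E = 0) carries no activity and cannot win on noise
alone. The exponential forms are the simplest monotone choices; the
competition is one-shot (no accumulator) because no temporal decision
data exist. The error signal can alternatively be read out as the
amplitude difference max(off − R, 0) via `error_signal="difference"`;
the off-response form is the default. Given the fixed timescales and
threshold, g and the noise SD were calibrated once by Monte-Carlo
root-finding (2 × 10⁶ common-random-number trials per evaluation) so the
illusion rate hits 3.3% at 33 ms and 8.3% at 200 ms; only the qualitative
increase with duration is a structural property.

## Problem sizes and numerics

Default iteration counts are 10⁵ for bootstrap and shuffle and 10⁴ for
CDF resamples, with every procedure accepting larger values (the study
used 10⁶); at 10⁵ iterations the Monte-Carlo SE of a bootstrap mean count
is ≈ 0.013 errors. Resampling is chunked (10⁴ × 240 index blocks; 5 × 10³
permutation rows) to bound memory. Sample SDs use ddof = 1 throughout.
Percentiles are numpy's default linear interpolation. The acceptance
script derives independent child seeds for reconstruction and each
bootstrap from the single command-line seed via `SeedSequence.spawn`.

## Known limitations

* The deposited trial-level data set is not bundled; analyses of it run
  through the column-map CSV adapter, whose schema must be supplied by
  the user because the published layout is not described.
* The exact statistic behind the study's joint shuffle p-value and its
  resampling unit for the printed tail probabilities are under-specified;
  the package exposes every defensible reading side by side rather than
  picking one silently.
* The decision model is a cartoon: two signal channels, one decision,
  no hierarchy, no biological parameter claims.
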