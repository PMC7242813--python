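# Methods

This package re-implements, as a tested pipeline, the analysis of identified
motor-neuron recruitment during *Aplysia californica* swallowing under
mechanical load: extracting unit spike trains from multichannel nerve/EMG
recordings, converting them to bursts with instantaneous-firing-frequency
(IFF) thresholds, segmenting the force record of loaded swallows into five
behavioral stages, normalizing swallows onto a common timeline, and running
a paired statistical battery on per-animal condition means. Because the
study's raw recordings are not shipped here, a synthetic-data generator with
full ground truth stands in for them; every downstream stage is validated
against that ground truth.

## Spike detection

Spikes are "window discriminated": local extrema on a channel whose
amplitude lies in a closed per-unit range and whose time lies in a closed
window. Identified buccal motor neurons are separable this way because
their relative spike amplitudes per nerve are stereotyped (B3 largest on
BN2, B6/B9 medium, B38 medium-small; B8a/b largest on RN; B4/B5 largest on
BN3; the I2 EMG reflects B31/B32 and B61/B62). Choices the verbal procedure
leaves open, and how this implementation fixes them:

- A *peak* is a strict local extremum over a 1 ms refractory neighborhood;
  ties on flat tops break to the earliest sample.
- A peak matching the amplitude windows of two units is assigned to the
  unit whose window center is nearer, with a warning. Multiple OR-combined
  windows per unit are allowed (spike collisions change apparent amplitude
  for B8a/b and B4/B5).
- The I2 EMG channel is low-pass filtered at 100 Hz before detection. The
  filter is a 4th-order Butterworth applied forward-backward so peak times
  are not shifted; the design frequency is pre-warped by
  (√2−1)^(−1/(2·order)) ≈ 1.116 so the combined two-pass response is −3 dB
  at the nominal cutoff.

Amplitude windows are always user/config input (they had to be set per
recording in the original work); for synthetic data, defaults place window
boundaries at midpoints between adjacent template amplitudes per channel.

## Burst identification

For each spike train the IFF is the reciprocal of each interspike interval
(ISI), assigned to that interval. A candidate burst begins at the first
spike of the first ISI whose IFF reaches the unit's start threshold and
ends at the later spike of the last consecutive ISI at or above the end
threshold (boundary equality stays in-burst; "dropping below" is strict).
Scanning resumes after each candidate. Candidates shorter than 0.5 s or
with fewer than three spikes are discarded; the survivors within one
annotated swallow cycle are merged into a single burst spanning the entire
set of spikes (muscles here are low-pass filters, so force is plausibly
maintained across short gaps in firing). Discard-before-merge is the
default order; the opposite order is available via
`filter_and_merge(..., order="merge-then-discard")` for sensitivity
analysis. Default thresholds (start/end Hz): B38 8/5, I2 10/5, B8a/b 3/3,
B6/B9 10/5, B3 8/2, B4/B5 3/3; per-unit overrides are config.

The mean burst rate is (n_spikes − 1)/duration. B3 and B6/B9 are combined
into a functional retractor pool: the pool bursts when either member does,
spanning the earlier start to the later end, with the union of member
spikes counted in the span. The smoothed rate estimate is a sum of
unit-mass Gaussian kernels (σ = 200 ms) centered on each spike, truncated
at ±5σ (mass loss < 10⁻⁶), evaluated on a 100 Hz grid.

## Force segmentation

Loaded swallows are segmented by five events: (1) end of the preceding
swallow's rapid force decrease at a temporarily stable intermediate level,
(2) start of the final drop to the minimum, (3) start of the rapid rise
(retraction onset), (4) start of force deceleration near the maximum,
(5) start of the rapid terminal decrease. Stages I–V (partial force
maintenance, force dip, force rise, force maintenance, major force drop)
lie between consecutive events; stage V runs to event 1 of the next cycle.
When the force decays smoothly to its minimum, events 1–2 are indistinct
and stage I is undefined.

The original events were placed manually; manual annotations (CSV) remain
the authoritative input here. The automatic detector is a documented
heuristic: the force is smoothed with a 100 ms moving average,
differentiated, and classified into rapid-rise / rapid-fall / plateau runs
by a slope threshold expressed as a fraction of the cycle's force range
(default 0.18 s⁻¹ of range — above the maintenance-stage creep, below the
slowest genuine drop); runs shorter than 150 ms are demoted to plateau so
noise excursions cannot shift genuine run boundaries. Event 3/4 are the
boundaries of the rise run with the largest gain; event 5 starts the first
fall after it. The stage-I plateau must last ≥ 0.4 s at a level between
0.15 and 0.6 of the range above the minimum (ruling out both the
force-minimum dwell and pauses high on the preceding drop); its boundaries
give events 1–2. These defaults were chosen and adjusted against the
synthetic suite only and are not claimed to be canonical for real force
records. On that suite at default noise, all five events fall within 50 ms
of ground truth for ≥ 99% of swallows, and the presence/absence of stage I
is classified correctly throughout.

## Time normalization and aggregation

Loaded swallows are warped by an exact piecewise-linear map taking each
stage boundary to a common target boundary; each stage is stretched or
compressed by its target/source duration ratio. Swallows lacking stage I
contribute nothing before event 3 (their warp domain starts there, and
earlier bursts are dropped, with the count reported). Unloaded swallows,
which have no force record, are rescaled uniformly so inward-movement
start/end align. After warping, pointwise medians and quartiles
(linear-interpolation "type 7" convention — the study does not state one;
this choice is configurable) of force and smoothed-rate traces and of burst
start/stop times are computed on a 100 Hz grid, then the timeline is
rescaled so each stage has the median duration observed across swallows.
Burst-timing quartiles are computed after that final rescale, on the final
timeline; whether the original analysis did so before or after is not
stated.

## Statistics

All tests operate on per-animal condition means (n = 5 animals in the
study's tables):

- One-tailed paired t (direction: increase under load), df = n − 1.
- Shapiro–Wilk on the differences gates every t test; p < 0.05 routes to a
  one-tailed exact Wilcoxon signed-rank, computed by enumerating all 2ⁿ
  sign assignments with W = sum of positive-difference ranks (midranks on
  ties, still enumerated exactly; zero differences dropped with a warning).
- Cohen's d = mean difference / pooled SD of the condition means,
  √((var_U + var_L)/2). This pooled variant reproduces all published d
  values; d_z is available but non-default.
- Bivariate measure groups (protraction: B38 + I2; retraction: B8a/b +
  B3/B6/B9) use a paired Hotelling's T² = n·d̄ᵀS⁻¹d̄ with
  F = (n−p)/(p(n−1))·T² on (p, n−p) df; significant groups are followed by
  post hoc paired t tests at a Bonferroni-corrected 0.05/2 = 0.025.
- Ordinary least squares R² and two-sided slope p (scipy) for
  duration–duration regressions.

Statistics recomputed from the published per-animal means (rounded to two
decimals) match the published statistics to ~1% for t and d and ~3% for the
retraction Hotelling T² (its small covariance determinant amplifies
rounding); the published T²/F pair itself confirms the (n−p)/(p(n−1)) = 3/8
conversion exactly.

## Synthetic-data generator

The generator emulates the study's conditions, not its biophysics. Each
session is a sequence of swallow cycles with log-normally jittered stage
durations (defaults: loaded stages I–V = 1.2, 0.8, 1.5, 2.0, 1.5 s, a ~7 s
cycle; unloaded latent phases 1.2, 0.8, 1.0, 1.0, 1.4 s, a ~5.4 s cycle
with 2 s of inward movement — chosen once from the study's behavioral
summary ranges). Per cycle, each unit fires one burst anchored to a stage
boundary: B38 and I2 in stage I (protraction); B8a/b, B4/B5, B6/B9, and B3
end-anchored in stage IV (retraction) so duration jitter never spills into
the next analysis window. B3 and B6/B9 share one realized span per cycle
(a synchronized retractor pool). Spikes are quasi-regular with uniform
jitter, time-rescaled through an optional rate profile, with the first and
last spike pinned to the burst boundaries so the realized span equals the
configured duration exactly and the realized mean burst rate is
round(rate·duration)/duration. Under load the retraction templates add
Δduration = +1.0 s (B4/B5: +0.8 s) and the pool members add Δrate = +3 Hz
each (+6 Hz summed); protraction templates are unchanged. Animal-level
heterogeneity perturbs baselines (duration SD 0.25 s, rate SD 15% of the
template rate) and the effects themselves (duration-effect SD 0.40 s,
rate-effect SD 1.65 Hz per member), with the effect SDs matched to the
spread implied by the study's published between-animal difference SEMs.

Spikes render as a fixed biphasic waveform (2 ms for nerve units, 12 ms for
the EMG so it survives the 100 Hz pre-filter) scaled by the unit amplitude,
plus white Gaussian channel noise (nerve/EMG SD 0.02 of the largest unit,
force SD 0.5 mN). Spikes of different units on a shared channel are nudged
to ≥ 2.4 ms separation — just beyond the waveform support — so waveforms
never merge; overlap decomposition is explicitly out of scope for the
detector. The loaded force channel is piecewise linear through the
five-stage keypoints (intermediate plateau ≈ 30 mN, maximum ≈ 100 mN,
minimum ≈ 2 mN, per-cycle log-normal amplitude jitter); flagged swallows
(default 7/39, the study's observed fraction) fall smoothly to the minimum
with no intermediate plateau. All randomness flows from one seed;
regeneration is bit-identical.

What the generator does not emulate — and what passing tests therefore do
not show about real data: biophysical spike shapes and electrode noise
spectra, amplitude drift, true spike collisions and superposition, bursts
that straddle cycle boundaries, missing units (B3 is generated in both
conditions by default, although the study found it mostly silent without
load — pool-level quantities are then defined in every swallow; configs may
disable it), and real force-record idiosyncrasies (the automatic event
detector is tuned to this generator only).

## Validation experiments

Two simulation studies qualify the pipeline end to end (both seeded, both
run by `scripts/acceptance.py`):

- *Effect recovery.* 50 replicates of a 5-animal study (4 swallows per
  condition per animal) are generated, measured by the full
  detect-and-burst pipeline, and reduced to mean paired differences. The
  95% CI of the across-replicate mean covers the configured +1.0 s
  retractor-burst prolongation and the configured +6 Hz pool-rate increase.
  The rate effect is recovered as the sum of member mean burst rates: the
  union-count pool statistic (n_union − 1)/span differs from it by exactly
  1/span — a fencepost from pooling two boundary-pinned trains — so its
  expected shift under a duration change is attenuated by
  (1/span_L − 1/span_U) ≈ 0.2 Hz; both statistics are computed, and the
  member-sum is the one whose configured effect is exact. The replicate
  sizes (50 × 5 × 8 swallows) keep the experiment at ~15 s on one CPU.
- *Type-I calibration.* 10⁴ null paired tables at n = 5 give a one-tailed
  paired-t rejection rate within Monte-Carlo error of the nominal 5%.

## Known limitations

- The automatic force-event detector is a stand-in for manual annotation;
  its slope-fraction defaults are generator-specific.
- The exact Wilcoxon enumerates 2ⁿ assignments and is limited to n ≤ 25.
- Cross-swallow aggregation assumes each unit bursts at most once per
  cycle, as the burst-merging rule guarantees within a cycle window.
- Statistics recomputed from rounded summary tables cannot reproduce the
  original unrounded results beyond ~2–3 significant figures; tolerances in
  the test suite reflect that.
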