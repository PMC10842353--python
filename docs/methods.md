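# Methods

## The forward model

One bouton's fluorescence is simulated at `sampling_rate` (default 10
frames/s) as

```
F(t) = F0 · [1 + u_E(t)·E(t) + u_S(t)·S(t) + u_B(t)·b(t)] + ε(t)
```

**Transients.** `E` and `S` superpose unit-peak difference-of-exponential
kernels `k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r)`. The kernel was chosen because its
two parameters map directly onto the rise/decay comparisons the pipeline
reports. Evoked events occur at stimulus times with probability `p_evoked`
(default 0.95 — detection likelihoods near 1 with occasional failures);
spontaneous events are a homogeneous Poisson process (default
0.03 events/min, the middle of the reported 0.01–0.05 band). Amplitudes are
lognormal (means 1.5 and 0.8 ΔF/F₀, CV 0.3 — spontaneous events are the
smaller class). Rise constants are 0.05 s (evoked) and 0.25 s
(spontaneous); both classes share `τ_d = 0.7 s`, a slow-sensor decay. Under
elevated external Ca²⁺, `ca_scale` multiplies the evoked amplitude and the
micro-opening rate.

**Baseline.** The resting elevation is shot noise from stochastic
single-channel openings: default 5000 openings/s of amplitude 0.001 ΔF/F₀
lasting `τ_shot = 0.1 s`. Because the micro-events are sub-frame at 10 Hz,
the superposition is realised exactly as per-frame Poisson counts scaled by
`shot_amp·τ_shot/dt` (time-averaged within the frame), giving mean
elevation `μ_b = shot_rate·shot_amp·τ_shot = 0.5` and per-frame SD ≈ 0.022
ΔF/F₀. This one mechanism yields the paired signature the pipeline must
detect: blocking the channels lowers the absolute trace level *and* its
noise SD together, which is how a genuine baseline reduction is
distinguished from passive decay. The parameters were set so that the
baseline elevation is large (50% of F0) while its frame-to-frame noise
stays small enough that the 3-SD event rule retains a negligible
false-positive floor (see below).

**Bleaching.** Each class rides on its own sensor pool with unbleached
fraction `u_p ∈ [0,1]` obeying
`du_p/dt = −k_bleach·duty_p·u_p + k_exchange·(1−u_p)`. `duty_p` is the
pool's fluorescent duty cycle — only fluorescent sensors can bleach:
evoked pool `p_evoked·(kernel area)/ISI ≈ 0.08` when stimulated, else 0;
spontaneous pool `λ_spont·(kernel area) ≈ 6×10⁻⁴` always (their rarity is
why they resist bleaching); baseline pool `shot_rate·shot_amp·τ_shot·ca_scale
= 0.5` always; elevated K⁺ saturates all three to 1. Bleach light acts only
in epochs flagged `illumination="bleach"`; exchange with an infinite
unbleached reservoir acts everywhere. The update is the exact exponential
solution per epoch (no Euler drift), so `u_p` respects its bounds for any
step size. `k_bleach = 0.04 /s` makes 30 min of stimulated bleaching
deplete the evoked pool to ~5% (enough to push amplitudes to the detection
threshold, as observed post-bleach), and `k_exchange = 0.01 /min` makes
recovery reach ~95% after 5 h in the dark, matching the reported recovery
time course. The illumination duty within a stimulated bleach epoch
(continuous vs pulsed light) is not constrained by the protocols, so it is
exposed as `stim_bleach_duty` (default 1, continuous).

**Movies.** `render_movie` places each trace as a unit-mass 2-D Gaussian
punctum (default optics 0.25 µm/px, PSF σ 0.5 µm — with these, 99% of a
punctum's mass falls inside a 3-µm circle) with optional Poisson photon
noise and Gaussian read noise, to exercise ROI extraction end to end.

## What the generator emulates, and what it does not

It emulates: 10-Hz traces of sparse boutons; stimulus-locked and Poisson
spontaneous transients; an elevated noisy baseline; epoch-structured
protocols (before → treatment/bleach → recovery → after); use-dependent
bleaching with slow reservoir exchange; treatments as parameter scalings
(VGCC blockade scales `p_evoked` and `shot_rate`; ryanodine scales
`λ_spont`; vehicle is the identity); cohorts with a silent majority
(`silent_fraction` draws ROIs with no spontaneous source).

It does not emulate: sensor binding kinetics or Ca²⁺ buffering (kernels are
phenomenological); spatial nanodomain geometry (pools are abstract
compartments); stage drift or focus changes; correlated noise across ROIs;
bouton-to-bouton parameter heterogeneity beyond the silent/active split.
Passing tests therefore demonstrate that the pipeline recovers known
effects under this idealised noise model — not that it is robust to
motion, bleed-through or optical artifacts in real movies.

## Detection pipeline: numerical choices

* **Background subtraction** fits a line to the 10th percentiles of tiled
  30-s windows and removes *slope only*, preserving the absolute level for
  baseline quantification. Traces shorter than one window are rejected.
* **Smoothing** is one pass of a centered 3-frame moving average (the
  smallest window consistent with "up to three points"); edges shrink.
* **Moving baseline** is the trailing 4-s mean excluding the current frame,
  expanding at the trace start.
* **Noise SD scope.** σ is a global robust estimate (MAD × 1.4826) of the
  residuals of the *unsmoothed* detrended trace around its moving baseline,
  with detected events (padded by one baseline window — the trailing mean
  carries an event's tail that long) and 1 s post-stimulus masked out.
  Detection runs on the smoothed trace against `3σ`. With σ taken from the
  raw trace, the threshold is an effective ~5 smoothed-noise SDs and the
  false-positive floor on Gaussian noise is below 0.01 events/min
  (measured: 0 events in 500 simulated minutes), far under the reported
  spontaneous band; had σ been taken from the smoothed trace, the same rule
  would produce ~0.5 false events/min, which is incompatible with
  detecting 0.01–0.05 events/min. The noise estimate runs slightly hot on
  stimulus-dense recordings (baseline tails of frequent evoked events),
  which is conservative.
* **Event state machine.** An event opens at the first frame with
  `trace − baseline > 3σ`, freezes the baseline at its onset value (a
  trailing mean would otherwise absorb the event and truncate its
  amplitude), peaks at the running maximum, and closes when the trace falls
  within 1σ of the frozen baseline. Events with onsets closer than 0.5 s
  merge (earliest onset, largest peak). Classification uses a left-closed
  window `[t_stim, t_stim + 0.3 s)`; frame `i` covers `[i/rate,(i+1)/rate)`
  and stimulus times are compared against frame start times. A trace with
  zero estimated σ is rejected with a diagnostic rather than thresholded.
* **Kinetics.** Amplitude is peak minus frozen baseline, reported in ΔF and
  ΔF/F₀ (a `kinetics_on_raw` switch reads amplitudes off the unsmoothed
  trace, avoiding the ~7–10% attenuation the 3-point smoother applies to
  sub-second transients at 10 Hz). Rise time is 20→80% of amplitude with
  linear interpolation, using the last upward crossings before the peak.
  Decay τ is a least-squares single-exponential fit over
  `[peak, min(peak+2 s, next onset)]`, *starting where the trace first
  falls to 90% of peak*: anchoring the fit at the peak itself provably
  folds rise-time differences into the decay estimate (a slow-rise kernel's
  post-peak plateau masquerades as slower decay even noise-free), defeating
  the known equal-decay construction. Fits whose τ exceeds 2.5× the fit
  window are flat-segment artifacts and fall back to time-to-half-amplitude;
  events peaking at the trace end are flagged and excluded from decay
  summaries. Rise/decay estimates are accurate to better than 10% when the
  sampling interval resolves the kernel; at 10 Hz a 50-ms rise reads as
  ~0.18 s, so cross-class *comparisons* (orderings) are meaningful at 10 Hz
  while absolute sub-frame rise times are not.
* **ROI extraction.** Local maxima on a σ=1 px Gaussian-smoothed average
  projection, above mean + 2 SD (the acceptance criterion for a maximum is
  not otherwise constrained; k=2 is the default and a parameter), accepted
  greedily in descending intensity with ≥3 µm pairwise separation; exact
  intensity ties break in row-major pixel order. Circular 3-µm ROIs contain
  all pixels whose centers lie within the radius; coordinates are 0-based
  (x = column, y = row), origin top-left. Drift is not corrected beyond the
  slack a 3-µm ROI provides; recorded as a limitation.

## Epoch comparison, susceptibility and recovery

Treatment effects are after/before ratios: for the Ca²⁺ sensor, each ROI's
after-value is divided by the coverslip mean of before-values (per-synapse
normalization is unstable when events are this sparse); for the glutamate
sensor, synapse-by-synapse so all normalized before-values are 1, with
zero-denominator ROIs excluded and counted. The per-synapse count ratio
`E[X_after/X_before | X_before>0]` carries a small upward Jensen bias at
finite counts (~+2 points at 30 expected events per synapse); ratios are
reported as computed, uncorrected.

Bleach susceptibility always compares a bleach arm with a matched
imaging-time control arm. Evoked metrics are measured in stimulated
recordings, spontaneous and baseline metrics in separate unstimulated ones
(as the live protocols do) — in a single stimulated recording,
near-threshold evoked responses with late onsets would leak into the
spontaneous counts. Analysis epochs are kept at ~10 min around the bleach:
with exchange at 0.01/min, longer post-bleach epochs visibly recover
within the measurement itself. Each class is called susceptible when
*both* members of its metric pair (amplitude + likelihood/frequency for
the event classes; level + noise SD for baseline) fall below the control
ratio by more than a 10-percentage-point margin; requiring agreement keeps
the call robust to sparse-count noise, an undefined amplitude (no events
left) counts as complete loss, and the margin stands in for the
significance tests the matrix is based on in the live experiments (it is a
configuration knob, and the full ratio table is always reported).

Recovery fractions are per-duration metric ratios against the pre-bleach
epoch; the single-rate exchange model predicts
`u(t) = 1 − (1−u₀)e^(−k_x t)`, which the measured baseline-level fractions
follow within Monte-Carlo error and the evoked likelihood satisfies at the
5-h point (≥95% of pre-bleach).

## Problem sizes

Desk-scale experiment sizes were chosen so each check's Monte-Carlo error
is small against its assertion band: detector-vs-reference equivalence on
1,000 random 60-s traces; false-positive control on 500 one-minute noise
traces per arm; planted-event recovery over 200 seeded traces; the
susceptibility matrix from 120 stimulated plus 500 unstimulated sessions
per arm and protocol (10-min epochs, 30-min bleach); recovery at 0, 1 and
5 h with 40 sessions per duration; pharmacology endpoints from 8,400
(ryanodine), 100×60 stimuli (VGCC/evoked) and 900 (glutamate) ROIs per
arm. The full test suite runs in ~2 minutes and the endpoint script in
~1 minute on one CPU.

## Known limitations

* Absolute rise times at 10 Hz are resolution-limited (see above).
* The false-positive floor, while negligible under the default noise
  model, scales with any unmodelled heavy-tailed noise.
* The susceptibility margin (10 points) and the both-metrics rule are
  deterministic stand-ins for inferential statistics; the package exports
  tidy tables for any external stats tool and deliberately implements no
  hypothesis tests.
* Bouton independence: ROIs share no reservoir, so cross-synapse exchange
  effects (superpool mixing between neighbours) are not represented.
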