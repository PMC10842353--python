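"""Unit and property tests for preprocessing and event detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import boutoncalc as bc
from boutoncalc.config import ConfigError, DetectionParams
from boutoncalc.detect import DegenerateTraceError

from _reference import ref_detect

RATE = 10.0


def planted_trace(n, events, sigma=1.0, rng=None, tau_r=0.1, tau_d=0.5,
                  rate=RATE):
    """Gaussian-noise trace with unit-peak kernels planted at (t, amp)."""
    y = np.zeros(n)
    t = np.arange(n) / rate
    for t0, amp in events:
        m = t >= t0
        y[m] += amp * bc.kernel(t[m] - t0, tau_r, tau_d)
    if sigma > 0:
        y += (rng or np.random.default_rng(0)).normal(0, sigma, n)
    return y


# ---------------------------------------------------------------------------
# smooth
# ---------------------------------------------------------------------------

def test_smooth_window_one_is_identity(rng):
    y = rng.normal(size=100)
    np.testing.assert_array_equal(bc.smooth(y, 1), y)


def test_smooth_impulse_arithmetic():
    np.testing.assert_allclose(bc.smooth([0, 0, 3, 0, 0], 3), [0, 1, 1, 1, 0])


def test_smooth_even_window_rejected():
    with pytest.raises(ConfigError):
        bc.smooth(np.zeros(10), 4)


def test_smooth_reduces_white_noise_sd_by_sqrt3(rng):
    y = rng.normal(size=200_000)
    interior = bc.smooth(y, 3)[1:-1]
    assert abs(interior.std() - 1 / np.sqrt(3)) < 0.01


# ---------------------------------------------------------------------------
# moving_baseline
# ---------------------------------------------------------------------------

def test_baseline_constant():
    b = bc.moving_baseline(np.full(100, 7.0), RATE)
    np.testing.assert_allclose(b, 7.0)


def test_baseline_step_reaches_plateau_after_window():
    """Step 0 -> 1 at frame k: the trailing 4-s baseline first equals 1
    exactly 40 frames later at 10 Hz."""
    k = 100
    y = np.concatenate([np.zeros(k), np.ones(200)])
    b = bc.moving_baseline(y, RATE, 4.0)
    assert b[k + 39] < 1.0
    assert b[k + 40] == pytest.approx(1.0)
    assert np.allclose(b[k + 40:], 1.0)


def test_baseline_ramp_lag():
    """Trailing mean of a unit-per-frame ramp lags by (w+1)/2 frames."""
    y = np.arange(400, dtype=float)
    b = bc.moving_baseline(y, RATE, 4.0)
    lag = y[50:] - b[50:]
    np.testing.assert_allclose(lag, (40 + 1) / 2)


# ---------------------------------------------------------------------------
# subtract_background
# ---------------------------------------------------------------------------

def test_detrend_zero_slope_unchanged(rng):
    y = np.full(1200, 50.0)
    np.testing.assert_allclose(bc.subtract_background(y, RATE), y, atol=1e-9)


def test_detrend_recovers_known_slope(rng):
    m = 0.05  # units/s
    noise = rng.normal(0, 1.0, 6000)
    t = np.arange(6000) / RATE
    det = bc.subtract_background(100.0 + m * t + noise, RATE)
    fit = np.polyfit(t, det, 1)[0]
    assert abs(fit) < 0.05 * m
    # the value at t=0 (absolute level) is retained
    assert abs(det[:100].mean() - 100.0) < 1.0


def test_detrend_preserves_event_amplitudes(rng):
    """Planted amplitudes survive linear drift removal within 5%."""
    events = [(20.0, 10.0), (60.0, 8.0), (100.0, 12.0)]
    flat = planted_trace(1200, events, sigma=0.3, rng=np.random.default_rng(5))
    t = np.arange(1200) / RATE
    drifting = flat + 0.05 * t
    params = DetectionParams()
    amps = {}
    for name, y in (("flat", flat), ("drift", bc.subtract_background(drifting, RATE))):
        evs = bc.detect_events(y, RATE, params, sigma=0.3)
        amps[name] = sorted(e.amplitude_df for e in evs)
    assert len(amps["flat"]) == len(amps["drift"]) == 3
    for a, b in zip(amps["flat"], amps["drift"]):
        assert abs(a - b) / a < 0.05


def test_detrend_short_trace_rejected():
    with pytest.raises(ConfigError):
        bc.subtract_background(np.zeros(200), RATE)  # < one 30-s window


# ---------------------------------------------------------------------------
# estimate_noise_sd
# ---------------------------------------------------------------------------

def test_noise_sd_pure_gaussian(rng):
    y = rng.normal(0, 1.0, 6000)
    assert 0.94 < bc.estimate_noise_sd(y, RATE) < 1.06


def test_noise_sd_constant_trace_is_zero():
    assert bc.estimate_noise_sd(np.full(200, 3.0), RATE) == 0.0


def test_noise_sd_event_masking(rng):
    clean = rng.normal(0, 1.0, 6000)
    sd_clean = bc.estimate_noise_sd(clean, RATE)
    events = [(i * 60.0 + 7.0, 20.0) for i in range(10)]
    y = planted_trace(6000, events, sigma=0) + clean
    evs = bc.detect_events(y, RATE, sigma=sd_clean)
    from boutoncalc.detect import _exclusion_mask

    mask = _exclusion_mask(6000, RATE, evs, event_pad_s=4.0)
    sd_masked = bc.estimate_noise_sd(y, RATE, exclusion_mask=mask)
    assert abs(sd_masked - sd_clean) / sd_clean < 0.05


def test_noise_sd_too_few_frames():
    with pytest.raises(ConfigError):
        bc.estimate_noise_sd(np.zeros(30), RATE)


# ---------------------------------------------------------------------------
# detect_events
# ---------------------------------------------------------------------------

def test_flat_trace_no_events():
    assert bc.detect_events(np.zeros(600), RATE, sigma=1.0) == []


def test_degenerate_trace_rejected():
    with pytest.raises(DegenerateTraceError):
        bc.detect_events(np.zeros(600), RATE)


def test_single_planted_event_onset_accuracy():
    """A 10-sigma kernel at t=20 s gives one spontaneous event with onset
    within 0.2 s of truth."""
    y = planted_trace(600, [(20.0, 10.0)], sigma=1.0,
                      rng=np.random.default_rng(1))
    evs = bc.detect_events(y, RATE, sigma=1.0)
    assert len(evs) == 1
    assert evs[0].klass == "spontaneous"
    assert abs(evs[0].onset_s - 20.0) <= 0.2


def test_evoked_window_classification():
    """Onset inside [t_stim, t_stim+0.3) is evoked; at +0.5 s spontaneous."""
    y1 = planted_trace(600, [(30.1, 10.0)], sigma=0.0)
    evs = bc.detect_events(y1, RATE, stim_times=[30.0], sigma=1.0)
    assert [e.klass for e in evs] == ["evoked"]
    assert evs[0].stim_index == 0
    y2 = planted_trace(600, [(30.5, 10.0)], sigma=0.0)
    evs = bc.detect_events(y2, RATE, stim_times=[30.0], sigma=1.0)
    assert [e.klass for e in evs] == ["spontaneous"]


def test_merge_gap_controls_splitting():
    """Two threshold crossings 0.4 s apart merge at the default 0.5-s gap
    but stay separate at a 0.2-s gap (single-frame spikes so the first
    event ends before the second begins)."""
    y = np.zeros(600)
    y[200] = 10.0
    y[204] = 10.0
    merged = bc.detect_events(y, RATE, DetectionParams(), sigma=1.0)
    split = bc.detect_events(y, RATE, DetectionParams(merge_gap=0.2), sigma=1.0)
    assert len(merged) == 1
    assert len(split) == 2


def test_amplitude_linearity():
    """Doubling the planted amplitude doubles amplitude_df within 5%."""
    a1 = planted_trace(600, [(20.0, 20.0)], sigma=0.0)
    a2 = planted_trace(600, [(20.0, 40.0)], sigma=0.0)
    e1 = bc.detect_events(a1, RATE, sigma=1.0)[0]
    e2 = bc.detect_events(a2, RATE, sigma=1.0)[0]
    assert abs(e2.amplitude_df / e1.amplitude_df - 2.0) < 0.05


def test_order_invariance():
    """Detection has no history dependence beyond the merge gap: permuting
    well-separated events in time permutes detections only."""
    rng = np.random.default_rng(9)
    noise = rng.normal(0, 1.0, 900)
    times = [15.0, 40.0, 70.0]
    amps = [8.0, 12.0, 10.0]
    base = planted_trace(900, list(zip(times, amps)), sigma=0) + noise
    perm = planted_trace(900, list(zip(times, [10.0, 8.0, 12.0])), sigma=0) + noise
    d1 = {round(e.onset_s): e.amplitude_df for e in
          bc.detect_events(base, RATE, sigma=1.0)}
    d2 = {round(e.onset_s): e.amplitude_df for e in
          bc.detect_events(perm, RATE, sigma=1.0)}
    assert set(d1) == set(d2) == {15, 40, 70}
    # each detection matches its planted amplitude up to smoothing
    # attenuation and local noise, regardless of the surrounding sequence
    for detected, planted in [(d1, dict(zip(times, amps))),
                              (d2, dict(zip(times, [10.0, 8.0, 12.0])))]:
        for t0, amp in planted.items():
            assert abs(detected[round(t0)] - 0.93 * amp) < 2.0


@given(seed=st.integers(0, 10_000))
def test_reference_equivalence_property(seed):
    """The production detector agrees with the naive frame-by-frame
    reference on random short traces (full chain incl. noise estimate)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1.0, 300)
    n_ev = rng.integers(0, 3)
    for _ in range(n_ev):
        y += planted_trace(300, [(rng.uniform(5, 25), rng.uniform(4, 15))],
                           sigma=0)
    stims = [10.0, 20.0]
    got = [(e.onset_frame, e.peak_frame, e.end_frame, e.klass)
           for e in bc.detect_events(y, RATE, stim_times=stims)]
    want = [(o, p, e, k) for o, p, e, k, _, _ in
            ref_detect(y, RATE, stim_times=stims)]
    assert got == want


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def test_kinetics_match_dense_numerical_oracle():
    """At adequate sampling, rise (20-80%) and decay (exp tau) estimates of
    an ideal tau_r=0.05/tau_d=0.5 kernel fall within 10% of values computed
    by dense numerical evaluation of the kernel."""
    rate = 200.0
    tau_r, tau_d = 0.05, 0.5
    t = np.arange(int(30 * rate)) / rate
    y = 10.0 * bc.kernel(t - 5.0, tau_r, tau_d)
    evs = bc.detect_events(y, rate, DetectionParams(), sigma=0.05)
    assert len(evs) == 1
    ev = evs[0]
    # dense numerical 20-80% rise of the kernel itself
    td = np.linspace(0, 2.0, 2_000_001)
    k = bc.kernel(td, tau_r, tau_d)
    peak = np.argmax(k)
    t20 = td[np.searchsorted(k[:peak], 0.2)]
    t80 = td[np.searchsorted(k[:peak], 0.8)]
    assert abs(ev.rise_s - (t80 - t20)) / (t80 - t20) < 0.10
    assert abs(ev.decay_s - tau_d) / tau_d < 0.10


def test_step_event_rise_below_frame_interval():
    y = np.zeros(600)
    y[300:] = 10.0
    params = DetectionParams(kinetics_on_raw=True)
    evs = bc.detect_events(y, RATE, params, sigma=1.0)
    assert len(evs) == 1
    assert evs[0].rise_s <= 0.1


def test_decay_flagged_at_trace_end():
    y = np.zeros(600)
    y[-2:] = 10.0
    evs = bc.detect_events(y, RATE, sigma=1.0)
    assert len(evs) == 1
    assert evs[0].decay_flagged or evs[0].decay_s is None


# ---------------------------------------------------------------------------
# summarize_synapse
# ---------------------------------------------------------------------------

def test_summary_examples():
    evs = []
    for i in range(20):
        evs.append(bc.DetectedEvent(onset_s=i * 10.0, peak_s=i * 10.0 + 0.2,
                                    klass="evoked", amplitude_df=5.0,
                                    amplitude_dff=0.05, stim_index=i))
    s = bc.summarize_synapse(evs, duration_s=200.0, n_stimuli=20)
    assert s.evoked_likelihood == 1.0
    spont = [bc.DetectedEvent(onset_s=t, peak_s=t + 0.3, klass="spontaneous",
                              amplitude_df=3.0, amplitude_dff=0.03)
             for t in (10.0, 200.0, 400.0)]
    s = bc.summarize_synapse(spont, duration_s=600.0, n_stimuli=0)
    assert s.evoked_likelihood is None
    assert s.spont_frequency == pytest.approx(0.3)
    assert s.active
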