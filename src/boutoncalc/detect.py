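"""Event detection on fluorescence traces.

The procedure mirrors the standard unbiased 10-Hz workflow: linear
background subtraction, a light (3-point) smoothing pass, a trailing 4-s
moving-average baseline, and a threshold of 3 trace-noise SDs for event
onsets.  Events whose onsets fall within 0.3 s after a stimulus are classed
as evoked; everything else is spontaneous.

Conventions that matter for reproducibility:

* the noise SD is a global robust estimate (MAD x 1.4826) of the residuals
  of the *unsmoothed* detrended trace around its moving baseline, with
  detected events and 1 s after each stimulus masked out;
* detection runs on the smoothed trace against ``threshold_sd`` times that
  raw-noise SD (an effective ~5 smoothed-noise SDs at the default 3-point
  window, which keeps the false-positive floor orders of magnitude below
  reported spontaneous event rates);
* during an event the moving baseline is frozen at its onset value so a
  transient cannot absorb itself into its own baseline;
* frame ``i`` covers ``[i/rate, (i+1)/rate)``; stimulus times are compared
  against frame start times, and the evoked window is ``[t, t + 0.3)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import ConfigError, DetectionParams, StimulusSchedule


class DegenerateTraceError(ValueError):
    """Raised when a trace has zero estimated noise (nothing to threshold)."""


@dataclass
class DetectedEvent:
    """One detected transient with its kinetic estimates."""

    onset_s: float
    peak_s: float
    klass: str                      # "evoked" | "spontaneous"
    amplitude_df: float             # camera units above frozen baseline
    amplitude_dff: float            # dF/F relative to frozen baseline
    rise_s: float | None = None     # 20 -> 80% of peak
    decay_s: float | None = None    # exponential tau from peak
    stim_index: int | None = None
    onset_frame: int = -1
    peak_frame: int = -1
    end_frame: int = -1
    baseline_f: float = float("nan")
    decay_flagged: bool = False     # peak too close to trace end for a fit


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def subtract_background(trace, rate: float, window_s: float = 30.0) -> np.ndarray:
    """Remove the linear drift component of a trace.

    A straight line is least-squares fitted to the 10th percentiles of
    tiled ``window_s`` windows and only its *slope* is removed; the fitted
    value at t = 0 is retained so the absolute baseline level survives for
    downstream baseline quantification.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ConfigError("trace must be one-dimensional")
    if y.size < 100:
        raise ConfigError("background subtraction needs >= 100 frames")
    w = int(round(window_s * rate))
    n_win = y.size // w
    if n_win < 1:
        raise ConfigError(
            f"trace shorter than one {window_s}-s percentile window"
        )
    tiles = y[: n_win * w].reshape(n_win, w)
    lows = np.percentile(tiles, 10, axis=1)
    centers = (np.arange(n_win) + 0.5) * w / rate
    if n_win >= 2:
        slope = np.polyfit(centers, lows, 1)[0]
    else:
        slope = 0.0
    t = np.arange(y.size) / rate
    return y - slope * t


def smooth(trace, window: int = 3) -> np.ndarray:
    """Centered moving average; edges use shrunken windows."""
    if window % 2 == 0:
        raise ConfigError("smooth window must be odd")
    y = np.asarray(trace, dtype=float)
    if window == 1:
        return y.copy()
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(y)))
    i = np.arange(y.size)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, y.size)
    return (c[hi] - c[lo]) / (hi - lo)


def moving_baseline(trace, rate: float, window_s: float = 4.0) -> np.ndarray:
    """Trailing mean over the previous ``window_s`` seconds.

    The current frame is excluded; the window expands from the start of the
    trace, and the first frame's baseline is the frame itself.
    """
    y = np.asarray(trace, dtype=float)
    w = int(round(window_s * rate))
    if w < 2:
        raise ConfigError("baseline window must span >= 2 frames")
    c = np.concatenate(([0.0], np.cumsum(y)))
    i = np.arange(y.size)
    lo = np.maximum(i - w, 0)
    cnt = np.maximum(i - lo, 1)
    b = (c[i] - c[lo]) / cnt
    if y.size:
        b[0] = y[0]
    return b


def _exclusion_mask(
    n: int,
    rate: float,
    events: list[DetectedEvent] | None,
    stim_times=(),
    post_stim_s: float = 1.0,
    event_pad_s: float = 0.0,
) -> np.ndarray:
    """True inside event extents (plus ``event_pad_s``) or 1 s post-stimulus.

    When the mask feeds a residual-based noise estimate, pad events by the
    baseline window: the trailing mean carries an event's tail for one
    window beyond its extent.
    """
    mask = np.zeros(n, dtype=bool)
    pad = int(math.ceil(event_pad_s * rate))
    for ts in stim_times:
        lo = int(math.floor(ts * rate))
        hi = min(n, int(math.ceil((ts + post_stim_s) * rate)))
        mask[max(lo, 0):hi] = True
    for ev in events or ():
        mask[max(ev.onset_frame, 0): min(ev.end_frame + pad, n)] = True
    return mask


def estimate_noise_sd(
    trace,
    rate: float,
    baseline_window_s: float = 4.0,
    exclusion_mask=None,
) -> float:
    """Robust SD (MAD x 1.4826) of trace residuals around the moving baseline."""
    y = np.asarray(trace, dtype=float)
    resid = y - moving_baseline(y, rate, baseline_window_s)
    if exclusion_mask is not None:
        resid = resid[~np.asarray(exclusion_mask, dtype=bool)]
    if resid.size < 50:
        raise ConfigError("noise estimation needs >= 50 unmasked frames")
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


# ---------------------------------------------------------------------------
# Detection state machine
# ---------------------------------------------------------------------------

def _first_below(y: np.ndarray, start: int, level: float, chunk: int = 512) -> int:
    """Index of the first element >= start with y < level (len(y) if none)."""
    n = y.size
    i = start
    while i < n:
        j = min(n, i + chunk)
        block = y[i:j] < level
        if block.any():
            return i + int(np.argmax(block))
        i = j
    return n


def _raw_events(y: np.ndarray, b: np.ndarray, sigma: float,
                params: DetectionParams) -> list[tuple[int, int, int, float]]:
    """(onset, peak, end, frozen_baseline) tuples, in temporal order."""
    thr = params.threshold_sd * sigma
    end_thr = params.end_threshold_sd * sigma
    cand = np.flatnonzero((y - b) > thr)
    out = []
    pos = 0
    for i in cand:
        if i < pos:
            continue
        fb = b[i]
        end = _first_below(y, i + 1, fb + end_thr)
        peak = i + int(np.argmax(y[i:max(end, i + 1)]))
        out.append((int(i), int(peak), int(end), float(fb)))
        pos = end
    return out


def detect_events(
    trace,
    rate: float,
    params: DetectionParams | None = None,
    stim_times=(),
    sigma: float | None = None,
    raw_trace=None,
    with_kinetics: bool = True,
) -> list[DetectedEvent]:
    """Detect transients on a detrended trace and classify them.

    ``trace`` is the detrended, *unsmoothed* trace in camera units; the
    smoothing pass of ``params.smooth_window`` frames is applied here.  The
    noise SD defaults to the raw-residual robust estimate (recomputed with
    event masking after a first pass).  ``raw_trace`` optionally supplies
    the unsmoothed trace for kinetics when ``params.kinetics_on_raw``.
    """
    params = params or DetectionParams()
    y_raw = np.asarray(trace, dtype=float)
    y = smooth(y_raw, params.smooth_window)
    b = moving_baseline(y, rate, params.baseline_window)

    if sigma is None:
        sigma = estimate_noise_sd(y_raw, rate, params.baseline_window)
        # second pass: mask a provisional detection so large events do not
        # inflate the noise estimate
        try:
            prov = _finalize(y, b, y_raw, sigma, rate, params, stim_times,
                             with_kinetics=False)
        except DegenerateTraceError:
            prov = []
        if prov or stim_times:
            mask = _exclusion_mask(y.size, rate, prov, stim_times,
                                   event_pad_s=params.baseline_window)
            if (~mask).sum() >= 50:
                sigma = estimate_noise_sd(
                    y_raw, rate, params.baseline_window, exclusion_mask=mask
                )
    return _finalize(y, b, y_raw, sigma, rate, params, stim_times,
                     with_kinetics=with_kinetics)


def _finalize(y, b, y_raw, sigma, rate, params, stim_times,
              with_kinetics: bool = True) -> list[DetectedEvent]:
    if sigma <= 0 or not np.isfinite(sigma):
        raise DegenerateTraceError(
            "estimated noise SD is zero; the 3-SD rule is undefined on a "
            "degenerate trace"
        )
    raw = _raw_events(y, b, sigma, params)

    # merge by onset gap; keep earliest onset & frozen baseline, largest peak
    merged: list[tuple[int, int, int, float]] = []
    gap = params.merge_gap * rate
    for onset, peak, end, fb in raw:
        if merged and onset - merged[-1][0] < gap:
            o0, p0, e0, fb0 = merged[-1]
            best = p0 if y[p0] >= y[peak] else peak
            merged[-1] = (o0, best, max(e0, end), fb0)
        else:
            merged.append((onset, peak, end, fb))

    kin_trace = y_raw if params.kinetics_on_raw else y
    events = []
    for onset, peak, end, fb in merged:
        t_on = onset / rate
        stim_index = None
        for j, ts in enumerate(stim_times):
            if ts <= t_on < ts + params.evoked_window:
                stim_index = j
                break
        ev = DetectedEvent(
            onset_s=t_on,
            peak_s=peak / rate,
            klass="evoked" if stim_index is not None else "spontaneous",
            amplitude_df=float(kin_trace[peak] - fb),
            amplitude_dff=float((kin_trace[peak] - fb) / fb) if fb != 0 else float("nan"),
            stim_index=stim_index,
            onset_frame=onset,
            peak_frame=peak,
            end_frame=end,
            baseline_f=fb,
        )
        events.append(ev)
    if with_kinetics:
        for idx, ev in enumerate(events):
            nxt = events[idx + 1].onset_frame if idx + 1 < len(events) else None
            _estimate_kinetics(ev, kin_trace, rate, params, next_onset=nxt)
    return events


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def _estimate_kinetics(ev: DetectedEvent, y: np.ndarray, rate: float,
                       params: DetectionParams, next_onset: int | None) -> None:
    """Fill rise and decay estimates of a detected event in place."""
    fb = ev.baseline_f
    peak = ev.peak_frame
    amp = y[peak] - fb
    if amp <= 0:
        ev.rise_s = None
        ev.decay_s = None
        return

    # rise: last upward crossings of 20% and 80% of amplitude before the peak
    lo_level = fb + 0.2 * amp
    hi_level = fb + 0.8 * amp
    start = peak
    floor = max(0, peak - int(round(10 * rate)))
    while start > floor and y[start - 1] > lo_level:
        start -= 1
    start = max(floor, start - 1)  # include the frame below the 20% level
    seg = y[start:peak + 1]
    t_seg = np.arange(start, peak + 1) / rate
    t20 = t_seg[0]
    t80 = t_seg[-1]
    for k in range(len(seg) - 1):
        if seg[k] <= lo_level <= seg[k + 1]:
            t20 = _interp_crossing(t_seg[k], t_seg[k + 1], seg[k], seg[k + 1], lo_level)
        if seg[k] <= hi_level <= seg[k + 1]:
            t80 = _interp_crossing(t_seg[k], t_seg[k + 1], seg[k], seg[k + 1], hi_level)
    ev.rise_s = max(0.0, float(t80 - t20))

    # decay: single-exponential fit over min(peak + 2 s, next onset),
    # starting where the trace first falls to 90% of peak so that slow-rise
    # kernels' post-peak plateau does not masquerade as a slower decay
    stop = min(y.size, peak + int(round(2.0 * rate)) + 1)
    if next_onset is not None:
        stop = min(stop, next_onset)
    start_fit = peak
    level90 = fb + 0.9 * amp
    while start_fit < stop - 3 and y[start_fit] > level90:
        start_fit += 1
    seg = y[start_fit:stop] - fb
    if seg.size < 3 or peak >= y.size - 1:
        ev.decay_s = None
        ev.decay_flagged = True
        return
    t = np.arange(seg.size) / rate
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            t, seg, p0=(float(amp), 0.5),
            bounds=((0, 1e-4), (np.inf, np.inf)), maxfev=200,
        )
        tau = float(popt[1])
        # a 2-s window cannot resolve taus far beyond its own length; such
        # fits are flat-segment artifacts, not decays
        if tau > 2.5 * (t[-1] - t[0] + 1.0 / rate):
            raise RuntimeError("decay fit outside resolvable range")
        ev.decay_s = tau
    except Exception:
        # fallback: time to half amplitude
        half = 0.5 * amp
        ev.decay_s = None
        for k in range(seg.size - 1):
            if seg[k] >= half >= seg[k + 1]:
                ev.decay_s = float(
                    _interp_crossing(t[k], t[k + 1], seg[k], seg[k + 1], half)
                )
                break


# ---------------------------------------------------------------------------
# Per-synapse summary
# ---------------------------------------------------------------------------

@dataclass
class SynapseSummary:
    roi_id: str
    evoked_likelihood: float | None   # None when the epoch has no stimuli
    spont_frequency: float            # events / min
    n_evoked: int
    n_spont: int
    mean_amp_evoked_df: float
    mean_amp_spont_df: float
    mean_amp_evoked_dff: float
    mean_amp_spont_dff: float
    active: bool
    baseline_level: float = float("nan")
    noise_sd: float = float("nan")


def summarize_synapse(
    events: list[DetectedEvent],
    duration_s: float,
    n_stimuli: int,
    roi_id: str = "roi",
) -> SynapseSummary:
    """Reduce one ROI's detected events to the standard per-synapse metrics."""
    evoked = [e for e in events if e.klass == "evoked"]
    spont = [e for e in events if e.klass == "spontaneous"]
    if n_stimuli > 0:
        hit_stims = {e.stim_index for e in evoked}
        likelihood = len(hit_stims) / n_stimuli
    else:
        likelihood = None
    freq = len(spont) / (duration_s / 60.0)

    def _mean(vals):
        return float(np.mean(vals)) if vals else float("nan")

    return SynapseSummary(
        roi_id=roi_id,
        evoked_likelihood=likelihood,
        spont_frequency=freq,
        n_evoked=len(evoked),
        n_spont=len(spont),
        mean_amp_evoked_df=_mean([e.amplitude_df for e in evoked]),
        mean_amp_spont_df=_mean([e.amplitude_df for e in spont]),
        mean_amp_evoked_dff=_mean([e.amplitude_dff for e in evoked]),
        mean_amp_spont_dff=_mean([e.amplitude_dff for e in spont]),
        active=len(spont) > 0,
    )
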