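"""Naive frame-by-frame reference implementation of the detection rules.

Deliberately slow and literal: every quantity is recomputed from its
definition (window means via explicit slices, the event state machine as a
per-frame walk).  Used as the independent oracle for the production
detector and for the false-positive Monte-Carlo.
"""

from __future__ import annotations

import numpy as np

from boutoncalc.config import DetectionParams


def ref_smooth(y: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        lo = max(0, i - half)
        hi = min(y.size, i + half + 1)
        out[i] = float(np.mean(y[lo:hi]))
    return out


def ref_trailing_baseline(y: np.ndarray, w: int) -> np.ndarray:
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        lo = max(0, i - w)
        out[i] = float(np.mean(y[lo:i])) if i > lo else float(y[0])
    return out


def ref_noise_sd(y_raw: np.ndarray, rate: float, params: DetectionParams,
                 mask=None) -> float:
    b = ref_trailing_baseline(y_raw, int(round(params.baseline_window * rate)))
    resid = y_raw - b
    if mask is not None:
        resid = resid[~mask]
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def _ref_state_machine(y, b, sigma, params, rate):
    thr = params.threshold_sd * sigma
    end_thr = params.end_threshold_sd * sigma
    n = y.size
    raw = []
    i = 0
    while i < n:
        if y[i] - b[i] > thr:
            onset = i
            fb = b[i]
            j = i + 1
            while j < n and not (y[j] - fb < end_thr):
                j += 1
            peak = onset
            for k in range(onset, max(j, onset + 1)):
                if y[k] > y[peak]:
                    peak = k
            raw.append((onset, peak, j, fb))
            i = j
        else:
            i += 1
    # merge onsets closer than the merge gap
    merged = []
    for onset, peak, end, fb in raw:
        if merged and onset - merged[-1][0] < params.merge_gap * rate:
            o0, p0, e0, fb0 = merged[-1]
            best = p0 if y[p0] >= y[peak] else peak
            merged[-1] = (o0, best, max(e0, end), fb0)
        else:
            merged.append((onset, peak, end, fb))
    return merged


def _classify(onset_frame, rate, stim_times, window):
    t_on = onset_frame / rate
    for j, ts in enumerate(stim_times):
        if ts <= t_on < ts + window:
            return "evoked", j
    return "spontaneous", None


def ref_detect(trace, rate, params: DetectionParams | None = None,
               stim_times=(), sigma=None):
    """Full naive detection chain; returns (onset, peak, end, class, amp) tuples."""
    params = params or DetectionParams()
    y_raw = np.asarray(trace, dtype=float)
    y = ref_smooth(y_raw, params.smooth_window)
    w = int(round(params.baseline_window * rate))
    b = ref_trailing_baseline(y, w)
    if sigma is None:
        sigma = ref_noise_sd(y_raw, rate, params)
        prov = _ref_state_machine(y, b, sigma, params, rate)
        if prov or stim_times:
            mask = np.zeros(y.size, dtype=bool)
            for ts in stim_times:
                lo = int(np.floor(ts * rate))
                hi = min(y.size, int(np.ceil((ts + 1.0) * rate)))
                mask[max(lo, 0):hi] = True
            pad = int(np.ceil(params.baseline_window * rate))
            for onset, _, end, _ in prov:
                mask[onset:min(end + pad, y.size)] = True
            if (~mask).sum() >= 50:
                sigma = ref_noise_sd(y_raw, rate, params, mask)
    out = []
    for onset, peak, end, fb in _ref_state_machine(y, b, sigma, params, rate):
        klass, stim_index = _classify(onset, rate, stim_times,
                                      params.evoked_window)
        out.append((onset, peak, end, klass, float(y[peak] - fb), stim_index))
    return out
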