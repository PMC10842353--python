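"""Baseline Ca2+ quantification, epoch comparison and photobleaching analysis.

Covers the measurements behind treatment comparisons (baseline level and
trace-noise SD before vs after a drug), the use-dependent photobleaching
susceptibility matrix (bleach at rest / with stimulation / with elevated
K+, each against a matched no-bleach imaging-time control), and the
fluorescence recovery time course after bleaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    BoutonSimConfig,
    ConfigError,
    DetectionParams,
    Epoch,
    StimulusSchedule,
    regular_stims,
)
from .detect import (
    DetectedEvent,
    SynapseSummary,
    _exclusion_mask,
    detect_events,
    estimate_noise_sd,
    subtract_background,
    summarize_synapse,
)
from .simulate import simulate_trace

SIGNAL_CLASSES = ("evoked", "spontaneous", "baseline")
PROTOCOLS = ("rest", "stim", "highk")

# metric pair per class; a class is called susceptible only when every
# defined member of its pair drops beyond the margin (an undefined
# amplitude - no detectable events left - counts as complete loss)
_CLASS_METRICS = {
    "evoked": ("evoked_amplitude", "evoked_likelihood"),
    "spontaneous": ("spont_amplitude", "spont_frequency"),
    "baseline": ("baseline_level", "noise_sd"),
}

METRICS = (
    "evoked_likelihood",
    "evoked_amplitude",
    "spont_frequency",
    "spont_amplitude",
    "baseline_level",
    "noise_sd",
)


# ---------------------------------------------------------------------------
# Per-epoch analysis
# ---------------------------------------------------------------------------

def baseline_level(
    trace,
    rate: float,
    events: list[DetectedEvent] | None = None,
    stim_times=(),
    post_stim_s: float = 1.0,
) -> tuple[float, int]:
    """Mean fluorescence during minimal-to-no transient activity.

    Averages the (slope-detrended) trace over frames outside detected event
    extents and outside ``[t_stim, t_stim + 1 s]`` windows.  Returns the
    level together with the number of frames used.
    """
    y = np.asarray(trace, dtype=float)
    mask = _exclusion_mask(y.size, rate, events, stim_times, post_stim_s)
    n_free = int((~mask).sum())
    if n_free < 50:
        raise ConfigError("baseline level needs >= 50 event-free frames")
    return float(y[~mask].mean()), n_free


def analyze_epoch(
    segment,
    rate: float,
    stim_times=(),
    params: DetectionParams | None = None,
    roi_id: str = "roi",
    with_kinetics: bool = True,
) -> tuple[list[DetectedEvent], SynapseSummary]:
    """Run the full detection pipeline on one imaging epoch of one ROI."""
    params = params or DetectionParams()
    seg = np.asarray(segment, dtype=float)
    det = subtract_background(seg, rate, params.detrend_window)
    events = detect_events(det, rate, params, stim_times=stim_times,
                           with_kinetics=with_kinetics)
    mask = _exclusion_mask(seg.size, rate, events, stim_times,
                           event_pad_s=params.baseline_window)
    summary = summarize_synapse(
        events, seg.size / rate, len(stim_times), roi_id=roi_id
    )
    if (~mask).sum() >= 50:
        summary.noise_sd = estimate_noise_sd(
            det, rate, params.baseline_window, exclusion_mask=mask
        )
        summary.baseline_level = baseline_level(det, rate, events, stim_times)[0]
    return events, summary


def summaries_frame(summaries: list[SynapseSummary]) -> pd.DataFrame:
    """Tidy per-ROI metric table from a list of synapse summaries."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "roi_id": s.roi_id,
                "evoked_likelihood": (
                    np.nan if s.evoked_likelihood is None else s.evoked_likelihood
                ),
                "evoked_amplitude": s.mean_amp_evoked_df,
                "n_evoked": s.n_evoked,
                "spont_frequency": s.spont_frequency,
                "spont_amplitude": s.mean_amp_spont_df,
                "n_spont": s.n_spont,
                "baseline_level": s.baseline_level,
                "noise_sd": s.noise_sd,
                "active": s.active,
            }
        )
    return pd.DataFrame(rows).set_index("roi_id")


# ---------------------------------------------------------------------------
# Epoch comparison (treatment effects)
# ---------------------------------------------------------------------------

def compare_epochs(
    before: pd.DataFrame,
    after: pd.DataFrame,
    mode: str = "gcamp",
    metrics=METRICS,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Normalized after/before effect table for matched ROI sets.

    ``gcamp`` mode divides each ROI's after-value by the coverslip mean of
    the before-values (sparse event counts make per-synapse normalization
    unstable); ``iglusnfr`` mode normalizes synapse by synapse so every
    normalized before-value is 1.  ROIs with a zero or undefined
    denominator are excluded; their count is returned.
    """
    if mode not in ("gcamp", "iglusnfr"):
        raise ConfigError("mode must be 'gcamp' or 'iglusnfr'")
    if not before.index.equals(after.index):
        raise ConfigError("before/after tables must cover the same ROIs")
    metrics = [m for m in metrics if m in before.columns and m in after.columns]
    ratios = pd.DataFrame(index=before.index, columns=metrics, dtype=float)
    n_excluded = 0
    for m in metrics:
        if mode == "gcamp":
            denom = before[m].mean(skipna=True)
            if not np.isfinite(denom) or denom == 0:
                ratios[m] = np.nan
                n_excluded += len(before)
            else:
                ratios[m] = after[m] / denom
        else:
            denom = before[m]
            bad = (~np.isfinite(denom)) | (denom == 0)
            n_excluded += int(bad.sum())
            ratios[m] = after[m] / denom.where(~bad)
    return ratios, ratios.mean(skipna=True), n_excluded


def pooled_metrics(df: pd.DataFrame) -> dict[str, float]:
    """Cohort-level metrics: event-count-weighted amplitude means, plain
    means for likelihood, frequency, level and noise."""
    out: dict[str, float] = {}
    for m in ("evoked_likelihood", "spont_frequency", "baseline_level", "noise_sd"):
        out[m] = float(df[m].mean(skipna=True)) if m in df else float("nan")

    def _pooled_amp(amp_col: str, n_col: str) -> float:
        if amp_col not in df or n_col not in df:
            return float("nan")
        ok = df[n_col] > 0
        if not ok.any():
            return float("nan")
        return float(
            (df.loc[ok, amp_col] * df.loc[ok, n_col]).sum() / df.loc[ok, n_col].sum()
        )

    out["evoked_amplitude"] = _pooled_amp("evoked_amplitude", "n_evoked")
    out["spont_amplitude"] = _pooled_amp("spont_amplitude", "n_spont")
    return out


# ---------------------------------------------------------------------------
# Bleach protocols
# ---------------------------------------------------------------------------

def bleach_schedule(
    kind: str,
    before_s: float = 1800.0,
    bleach_s: float = 1800.0,
    after_s: float = 1800.0,
    recovery_s: float = 0.0,
    stim_interval: float = 10.0,
    bleach_on: bool = True,
    first_stim: float = 5.0,
    measure_stimulated: bool = True,
) -> StimulusSchedule:
    """Protocol: before -> bleach (or sham) -> [dark recovery] -> after.

    ``kind`` selects what happens during the bleach epoch: ``rest`` (no
    stimulation), ``stim`` (stimuli continue during bleaching) or ``highk``
    (elevated-K+ perfusion).  ``bleach_on=False`` builds the matched
    imaging-time control with identical structure but no bleaching light.
    ``measure_stimulated=False`` leaves the before/after recordings
    unstimulated, as in dedicated spontaneous-activity measurements.
    """
    if kind not in PROTOCOLS:
        raise ConfigError(f"unknown bleach protocol {kind!r}")
    t1 = before_s
    t2 = t1 + bleach_s
    t3 = t2 + recovery_s
    t4 = t3 + after_s
    stims: list[float] = []
    if measure_stimulated:
        stims += regular_stims(first_stim, before_s, stim_interval)
    if kind == "stim":
        stims += regular_stims(t1 + first_stim, t2, stim_interval)
    if measure_stimulated:
        stims += regular_stims(t3 + first_stim, t4, stim_interval)
    illum = "bleach" if bleach_on else "imaging"
    epochs = [
        Epoch("before", 0.0, t1, "imaging", stimulated=measure_stimulated),
        Epoch(
            "bleach", t1, t2, illum,
            stimulated=kind == "stim", highk=kind == "highk",
        ),
    ]
    if recovery_s > 0:
        epochs.append(Epoch("recovery", t2, t3, "dark"))
    epochs.append(Epoch("after", t3, t4, "imaging",
                        stimulated=measure_stimulated))
    return StimulusSchedule(stims, epochs)


def run_bleach_cohort(
    config: BoutonSimConfig,
    kind: str,
    n_roi: int,
    seed: int,
    before_s: float = 1800.0,
    bleach_s: float = 1800.0,
    after_s: float = 1800.0,
    recovery_s: float = 0.0,
    bleach_on: bool = True,
    params: DetectionParams | None = None,
    with_kinetics: bool = False,
    measure_stimulated: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort under one bleach protocol and analyze both epochs.

    Returns (before, after) per-ROI metric tables.
    """
    sched = bleach_schedule(
        kind, before_s, bleach_s, after_s, recovery_s,
        stim_interval=config.stim_interval, bleach_on=bleach_on,
        measure_stimulated=measure_stimulated,
    )
    cfg = config.replace(duration=sched.duration)
    rng = np.random.default_rng(seed)
    rate = cfg.sampling_rate
    params = params or DetectionParams()
    ep_before = sched.epochs[0]
    ep_after = sched.epochs[-1]
    rows_b, rows_a = [], []
    for i in range(n_roi):
        trace, _ = simulate_trace(cfg, sched, rng)
        for ep, rows in ((ep_before, rows_b), (ep_after, rows_a)):
            lo = int(round(ep.start * rate))
            hi = int(round(ep.end * rate))
            stims = [t - ep.start for t in sched.stims_in(ep.start, ep.end)]
            _, summ = analyze_epoch(
                trace[lo:hi], rate, stims, params, roi_id=f"roi_{i:04d}",
                with_kinetics=with_kinetics,
            )
            rows.append(summ)
    return summaries_frame(rows_b), summaries_frame(rows_a)


_EVOKED_COLS = ["evoked_likelihood", "evoked_amplitude", "n_evoked"]
_SPONT_COLS = ["spont_frequency", "spont_amplitude", "n_spont",
               "baseline_level", "noise_sd"]


def run_protocol_arm(
    config: BoutonSimConfig,
    kind: str,
    seed: int,
    n_roi_evoked: int = 100,
    n_roi_spont: int = 100,
    bleach_on: bool = True,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One arm of a bleach experiment, measured the way the live protocols
    are: evoked metrics from stimulated recordings, spontaneous and
    baseline metrics from separate unstimulated recordings.

    Mixing them in a single stimulated recording would let near-threshold
    evoked responses with late onsets leak into the spontaneous counts.
    Returns merged (before, after) metric tables.
    """
    be, ae = run_bleach_cohort(
        config, kind, n_roi_evoked, seed, bleach_on=bleach_on,
        measure_stimulated=True, **kwargs,
    )
    bs, as_ = run_bleach_cohort(
        config, kind, n_roi_spont, seed + 1, bleach_on=bleach_on,
        measure_stimulated=False, **kwargs,
    )
    before = pd.concat([be[_EVOKED_COLS], bs[_SPONT_COLS]],
                       keys=("evoked", "spont"))
    after = pd.concat([ae[_EVOKED_COLS], as_[_SPONT_COLS]],
                      keys=("evoked", "spont"))
    return before, after


# ---------------------------------------------------------------------------
# Susceptibility matrix
# ---------------------------------------------------------------------------

@dataclass
class SusceptibilityResult:
    ratios: pd.DataFrame       # (protocol, arm) x metric after/before ratios
    delta: pd.DataFrame        # class x protocol: bleach ratio - control ratio
    susceptible: pd.DataFrame  # class x protocol: bool
    margin: float


def bleach_susceptibility(
    sessions: dict[str, dict[str, tuple[pd.DataFrame, pd.DataFrame]]],
    margin: float = 0.10,
) -> SusceptibilityResult:
    """Classify each signal class's sensitivity to each bleach protocol.

    ``sessions[protocol][arm] = (before, after)`` per-ROI metric tables,
    with arms ``bleach`` and ``control`` (matched imaging time, no bleach
    light).  For every metric the cohort after/before ratio is computed in
    both arms; a class is susceptible under a protocol when both members
    of its metric pair (fluorescence output: amplitude or baseline level;
    counting: likelihood, frequency or noise SD) fall below the control
    ratio by more than ``margin``.  Requiring the pair to agree keeps the
    call robust when sparse spontaneous counts make a single ratio noisy;
    when bleaching leaves no detectable events, the undefined amplitude
    counts as complete loss and the counting metric decides.
    """
    ratio_rows = {}
    for proto, arms in sessions.items():
        if "control" not in arms or "bleach" not in arms:
            raise ConfigError(f"protocol {proto!r} needs bleach and control arms")
        for arm, (before, after) in arms.items():
            pb, pa = pooled_metrics(before), pooled_metrics(after)
            ratio_rows[(proto, arm)] = {
                m: (pa[m] / pb[m] if pb.get(m) not in (0,) and np.isfinite(pb[m])
                    else float("nan"))
                for m in METRICS
            }
    ratios = pd.DataFrame(ratio_rows).T
    ratios.index = pd.MultiIndex.from_tuples(ratios.index, names=["protocol", "arm"])

    protos = [p for p in PROTOCOLS if p in sessions] + [
        p for p in sessions if p not in PROTOCOLS
    ]
    delta = pd.DataFrame(index=list(SIGNAL_CLASSES), columns=protos, dtype=float)
    flags = pd.DataFrame(index=list(SIGNAL_CLASSES), columns=protos, dtype=bool)
    for proto in protos:
        rb = ratios.loc[(proto, "bleach")]
        rc = ratios.loc[(proto, "control")]
        for cls, pair in _CLASS_METRICS.items():
            deltas = []
            for metric in pair:
                d = rb[metric] - rc[metric]
                if not np.isfinite(d):
                    # bleach-arm metric undefined (no events left) while the
                    # control is defined: complete loss of that readout
                    d = -1.0 if np.isfinite(rc[metric]) else float("nan")
                deltas.append(d)
            defined = [d for d in deltas if np.isfinite(d)]
            delta.loc[cls, proto] = deltas[0] if np.isfinite(deltas[0]) else (
                defined[0] if defined else float("nan")
            )
            flags.loc[cls, proto] = bool(
                defined and all(d < -margin for d in defined)
            )
    return SusceptibilityResult(ratios, delta, flags, margin)


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------

def recovery_curve(
    durations_min,
    metrics_at: list[dict[str, float]],
    pre: dict[str, float],
    metrics=("evoked_likelihood", "evoked_amplitude", "baseline_level"),
) -> pd.DataFrame:
    """Recovery fractions (metric / pre-bleach metric) vs recovery time."""
    durations = list(durations_min)
    if len(durations) != len(metrics_at):
        raise ConfigError("need one metric dict per recovery duration")
    if any(b <= a for a, b in zip(durations, durations[1:])):
        raise ConfigError("recovery durations must be strictly increasing")
    rows = []
    for d, vals in zip(durations, metrics_at):
        row = {"recovery_min": d}
        for m in metrics:
            denom = pre.get(m)
            row[m] = (
                vals.get(m, float("nan")) / denom
                if denom and np.isfinite(denom) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("recovery_min")


def predicted_unbleached(t_min, u0: float, k_exchange_per_min: float):
    """Closed-form single-rate recovery: u(t) = 1 - (1 - u0) e^{-k_x t}."""
    t = np.asarray(t_min, dtype=float)
    return 1.0 - (1.0 - u0) * np.exp(-k_exchange_per_min * t)
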