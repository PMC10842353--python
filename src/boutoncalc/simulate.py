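"""Generative model of presynaptic bouton fluorescence.

Three signal classes ride on a resting fluorescence level ``F0``:

* evoked transients, time-locked to field stimuli with per-stimulus response
  probability ``p_evoked`` and fast rise;
* spontaneous transients, a homogeneous Poisson process with slower rise;
* an elevated, noisy baseline built from high-rate sub-frame micro-openings
  of voltage-gated Ca2+ channels (shot noise), which contributes both a mean
  shift and extra trace variance.

Each class is carried by its own sensor pool with unbleached fraction
``u_p``.  Photobleaching is use dependent: only sensors that are fluorescent
during bleach illumination can be bleached, so each pool bleaches at
``k_bleach`` times its fluorescent duty cycle, while all pools exchange with
an unbleached reservoir at ``k_exchange``:

    du_p/dt = -k_bleach * duty_p * u_p + k_exchange * (1 - u_p)

integrated exactly (no Euler drift).  The observed trace is

    F(t) = F0 * (1 + u_E*E(t) + u_S*S(t) + u_B*b(t)) + eps(t)

with transient kernels k(t) = (exp(-t/tau_d) - exp(-t/tau_r)) normalized to
unit peak, b(t) the shot-noise baseline, and eps Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BoutonSimConfig, ConfigError, Epoch, StimulusSchedule

POOLS = ("evoked", "spont", "baseline")


# ---------------------------------------------------------------------------
# Transient kernel
# ---------------------------------------------------------------------------

def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of the difference-of-exponentials kernel."""
    if not 0 < tau_rise < tau_decay:
        raise ConfigError("kernel requires 0 < tau_rise < tau_decay")
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(
        tau_decay / tau_rise
    )


def _kernel_norm(tau_rise: float, tau_decay: float) -> float:
    tp = kernel_peak_time(tau_rise, tau_decay)
    return math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)


def kernel(t, tau_rise: float, tau_decay: float):
    """Unit-peak transient kernel evaluated at times ``t`` (s, from onset)."""
    t = np.asarray(t, dtype=float)
    norm = _kernel_norm(tau_rise, tau_decay)
    out = (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm
    return np.where(t >= 0, out, 0.0)


def kernel_area(tau_rise: float, tau_decay: float) -> float:
    """Integral of the unit-peak kernel (s); the transient's time occupancy."""
    return (tau_decay - tau_rise) / _kernel_norm(tau_rise, tau_decay)


def mu_baseline(config: BoutonSimConfig) -> float:
    """Mean shot-noise baseline elevation in dF/F0 units."""
    return config.shot_rate * config.ca_scale * config.shot_amp * config.tau_shot


# ---------------------------------------------------------------------------
# Use-dependent bleaching
# ---------------------------------------------------------------------------

def duty_cycles(epoch: Epoch, config: BoutonSimConfig) -> np.ndarray:
    """Fluorescent duty cycle of the (evoked, spont, baseline) pools.

    Elevated K+ saturates everything; otherwise the evoked pool is only
    fluorescent around stimuli, the spontaneous pool for the tiny fraction
    of time occupied by its rare transients, and the baseline pool at the
    resting occupancy set by the micro-opening process.
    """
    if epoch.highk:
        return np.ones(3)
    d_e = 0.0
    if epoch.stimulated:
        occ = config.p_evoked * kernel_area(config.tau_rise_evoked, config.tau_decay)
        d_e = min(1.0, occ / config.stim_interval)
    d_s = min(
        1.0,
        (config.lambda_spont / 60.0)
        * kernel_area(config.tau_rise_spont, config.tau_decay),
    )
    d_b = min(
        1.0,
        config.shot_rate * config.shot_amp * config.tau_shot * config.ca_scale,
    )
    return np.array([d_e, d_s, d_b])


def _bleach_duty(epoch: Epoch, config: BoutonSimConfig) -> np.ndarray:
    """Effective bleaching duty: pool duty gated by bleach illumination."""
    if epoch.illumination != "bleach":
        return np.zeros(3)
    duty = duty_cycles(epoch, config)
    if epoch.stimulated:
        duty = duty * config.stim_bleach_duty
    return duty


def apply_bleach_step(u, duty, dt: float, config: BoutonSimConfig) -> np.ndarray:
    """Advance unbleached fractions by ``dt`` seconds (exact exponential).

    ``duty`` is the per-pool fluorescent duty under bleach illumination;
    pass zeros for epochs without bleaching light.  Exchange with the
    unbleached reservoir acts in every epoch.
    """
    u = np.asarray(u, dtype=float)
    duty = np.asarray(duty, dtype=float)
    if dt <= 0:
        raise ConfigError("dt must be positive")
    if u.shape != duty.shape:
        raise ConfigError("u and duty must have matching shapes")
    if np.any((u < 0) | (u > 1)) or np.any((duty < 0) | (duty > 1)):
        raise ConfigError("u and duty must lie in [0, 1]")
    k_x = config.k_exchange / 60.0
    a = config.k_bleach * duty + k_x
    u_inf = np.divide(k_x, a, out=np.ones_like(a), where=a > 0)
    return np.where(a > 0, u_inf + (u - u_inf) * np.exp(-a * dt), u)


@dataclass(frozen=True)
class _PoolSegment:
    """Closed-form unbleached-fraction trajectory within one epoch."""

    start: float
    end: float
    u0: np.ndarray      # (3,) at epoch start
    a: np.ndarray       # (3,) decay rate /s
    u_inf: np.ndarray   # (3,) asymptote

    def u_at(self, t) -> np.ndarray:
        """u for times within this segment; t may be scalar or array."""
        dt = np.asarray(t, dtype=float) - self.start
        return self.u_inf + (self.u0 - self.u_inf) * np.exp(
            -self.a * np.expand_dims(dt, -1)
        )

    @property
    def u_end(self) -> np.ndarray:
        return self.u_at(self.end)


def pool_trajectory(
    schedule: StimulusSchedule,
    config: BoutonSimConfig,
    u0=(1.0, 1.0, 1.0),
) -> list[_PoolSegment]:
    """Piecewise closed-form u_p(t) across all epochs of a schedule."""
    k_x = config.k_exchange / 60.0
    segs: list[_PoolSegment] = []
    u = np.asarray(u0, dtype=float)
    for ep in schedule.epochs:
        duty = _bleach_duty(ep, config)
        a = config.k_bleach * duty + k_x
        u_inf = np.divide(k_x, a, out=u.copy(), where=a > 0)
        seg = _PoolSegment(ep.start, ep.end, u.copy(), a, u_inf)
        segs.append(seg)
        u = seg.u_end
    return segs


def u_at(segments: list[_PoolSegment], t: float) -> np.ndarray:
    for seg in segments:
        if seg.start <= t < seg.end:
            return seg.u_at(t)
    if math.isclose(t, segments[-1].end):
        return segments[-1].u_end
    raise ConfigError(f"time {t} outside simulated schedule")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueEvent:
    time: float           # onset, s
    klass: str            # "evoked" | "spontaneous"
    amplitude: float      # drawn dF/F0, before bleach scaling
    amplitude_effective: float  # dF/F0 actually added (scaled by u_pool)
    stim_index: int | None = None


@dataclass
class GroundTruth:
    """Truth channel emitted alongside every simulated trace."""

    events: list[TrueEvent]
    pool_segments: list[_PoolSegment]
    baseline_mean_dff: float     # mean shot elevation, dF/F0, unbleached
    config: BoutonSimConfig = field(repr=False, default=None)

    def u(self, t: float) -> np.ndarray:
        return u_at(self.pool_segments, t)

    def epoch_u(self) -> list[tuple[float, float, np.ndarray, np.ndarray]]:
        return [(s.start, s.end, s.u0, s.u_end) for s in self.pool_segments]

    def true_baseline_level(self, t: float) -> float:
        """Expected event-free fluorescence (camera units) at time t."""
        u_b = self.u(t)[2]
        return self.config.f0 * (1.0 + u_b * self.baseline_mean_dff)


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(size)
    if cv == 0:
        return np.full(size, mean)
    s2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def _add_kernel(sig: np.ndarray, t0: float, amp: float, tau_r: float,
                tau_d: float, rate: float) -> None:
    n = sig.shape[0]
    i0 = int(math.floor(t0 * rate))
    span = int(math.ceil(8.0 * tau_d * rate)) + 2
    i1 = min(n, i0 + span)
    if i1 <= max(i0, 0):
        return
    idx = np.arange(max(i0, 0), i1)
    sig[idx] += amp * kernel(idx / rate - t0, tau_r, tau_d)


def simulate_trace(
    config: BoutonSimConfig,
    schedule: StimulusSchedule,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate one bouton's fluorescence trace plus its ground truth.

    Returns the trace in camera units (length ``duration*sampling_rate``)
    and a :class:`GroundTruth` carrying the planted events and the
    unbleached-fraction trajectory of the three pools.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if schedule.duration - config.duration > 1e-9:
        raise ConfigError(
            f"schedule extends to {schedule.duration}s beyond the configured "
            f"duration {config.duration}s"
        )
    rate = config.sampling_rate
    dt = 1.0 / rate
    n = int(round(config.duration * rate))
    t_frames = np.arange(n) / rate

    segments = pool_trajectory(schedule, config)
    u = np.ones((n, 3))
    for seg in segments:
        lo = int(math.ceil(seg.start * rate - 1e-9))
        hi = min(n, int(math.ceil(seg.end * rate - 1e-9)))
        if hi > lo:
            u[lo:hi] = seg.u_at(t_frames[lo:hi])

    events: list[TrueEvent] = []
    e_sig = np.zeros(n)
    s_sig = np.zeros(n)

    def _u_of(ts: float, pool: int) -> float:
        return float(u[min(n - 1, int(ts * rate)), pool])

    # evoked: Bernoulli(p_evoked) per stimulus, lognormal amplitude
    stims = [t for t in schedule.stim_times if t < config.duration]
    if stims:
        hits = rng.random(len(stims)) < config.p_evoked
        amps = _lognormal(
            rng, config.a_evoked_mean * config.ca_scale, config.a_evoked_cv,
            len(stims),
        )
        for j, (ts, hit) in enumerate(zip(stims, hits)):
            if not hit:
                continue
            _add_kernel(e_sig, ts, amps[j], config.tau_rise_evoked,
                        config.tau_decay, rate)
            events.append(TrueEvent(ts, "evoked", amps[j],
                                    amps[j] * _u_of(ts, 0), j))

    # spontaneous: homogeneous Poisson at lambda_spont events/min
    lam = config.lambda_spont / 60.0 * config.duration
    n_spont = rng.poisson(lam) if lam > 0 else 0
    if n_spont:
        times = np.sort(rng.uniform(0.0, config.duration, n_spont))
        amps = _lognormal(rng, config.a_spont_mean, config.a_spont_cv, n_spont)
        for ts, amp in zip(times, amps):
            _add_kernel(s_sig, ts, amp, config.tau_rise_spont,
                        config.tau_decay, rate)
            events.append(TrueEvent(float(ts), "spontaneous", float(amp),
                                    float(amp * _u_of(ts, 1))))

    events.sort(key=lambda e: e.time)

    # baseline: per-frame Poisson micro-opening counts (sub-frame events,
    # time-averaged within each frame)
    mu_b = mu_baseline(config)
    if config.shot_rate > 0 and config.shot_amp > 0:
        counts = rng.poisson(config.shot_rate * config.ca_scale * dt, n)
        b_sig = counts * (config.shot_amp * config.tau_shot / dt)
    else:
        b_sig = np.zeros(n)

    # sustained elevation during high-K+ perfusion
    highk_elev = np.zeros(n)
    for ep in schedule.epochs:
        if ep.highk:
            lo = int(math.ceil(ep.start * rate - 1e-9))
            hi = min(n, int(math.ceil(ep.end * rate - 1e-9)))
            highk_elev[lo:hi] = (
                u[lo:hi, 0] * config.a_evoked_mean * config.ca_scale
                + u[lo:hi, 1] * config.a_spont_mean
            )

    dff = u[:, 0] * e_sig + u[:, 1] * s_sig + u[:, 2] * b_sig + highk_elev
    trace = config.f0 * (1.0 + dff)

    # dark epochs: excitation off, only read noise reaches the camera
    for ep in schedule.epochs:
        if ep.illumination == "dark":
            lo = int(math.ceil(ep.start * rate - 1e-9))
            hi = min(n, int(math.ceil(ep.end * rate - 1e-9)))
            trace[lo:hi] = 0.0

    if config.sigma_noise > 0:
        trace = trace + rng.normal(0.0, config.sigma_noise, n)

    truth = GroundTruth(events, segments, mu_b, config)
    return trace, truth


def simulate_cohort(
    config: BoutonSimConfig,
    schedule: StimulusSchedule,
    n_roi: int,
    seed: int | None = None,
    silent_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Simulate ``n_roi`` independent boutons under one protocol.

    ``silent_fraction`` of ROIs are drawn with no spontaneous source
    (lambda_spont = 0), emulating the large silent majority seen in
    spontaneous-activity recordings.  Returns a tidy trace table (column
    ``time_s`` plus one column per ROI, camera units) and per-ROI truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.sampling_rate
    n = int(round(config.duration * rate))
    data = {"time_s": np.arange(n) / rate}
    truths = []
    silent = rng.random(n_roi) < silent_fraction
    cfg_silent = config.replace(lambda_spont=0.0) if silent_fraction else None
    for i in range(n_roi):
        cfg = cfg_silent if silent[i] else config
        tr, gt = simulate_trace(cfg, schedule, rng)
        data[f"roi_{i:04d}"] = tr
        truths.append(gt)
    return pd.DataFrame(data), truths


def apply_treatment(
    config: BoutonSimConfig, treatment: str, block_fraction: float = 0.0
) -> BoutonSimConfig:
    """Encode a pharmacological treatment as a parameter scaling.

    ``vgcc`` (channel-blocking toxins) scales the per-stimulus response
    probability and the micro-opening rate by ``1 - block_fraction``;
    ``ryanodine`` scales the spontaneous event rate; ``dmso`` (vehicle) is
    the identity.
    """
    if not 0.0 <= block_fraction <= 1.0:
        raise ConfigError("block_fraction must lie in [0, 1]")
    keep = 1.0 - block_fraction
    if treatment == "vgcc":
        return config.replace(
            p_evoked=config.p_evoked * keep, shot_rate=config.shot_rate * keep
        )
    if treatment == "ryanodine":
        return config.replace(lambda_spont=config.lambda_spont * keep)
    if treatment == "dmso":
        return config
    raise ConfigError(f"unknown treatment {treatment!r}")


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def render_movie(
    traces: np.ndarray,
    centers_um: list[tuple[float, float]],
    pixel_size_um: float = 0.25,
    psf_sigma_um: float = 0.5,
    shape: tuple[int, int] | None = None,
    photon_scale: float = 0.0,
    read_noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces as diffraction-limited puncta in an image stack.

    Each punctum is a unit-mass 2-D Gaussian times its trace value, so the
    integrated (noise-free) pixel mass of a punctum is proportional to the
    trace.  ``photon_scale`` > 0 adds Poisson photon noise (counts per
    fluorescence unit); ``read_noise`` adds Gaussian camera noise.

    Returns ``(stack, centers_px)`` with centers as (x, y) pixel
    coordinates, origin at the top-left pixel center.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] != len(centers_um):
        raise ConfigError("need one trace column per punctum center")
    if rng is None:
        rng = np.random.default_rng(0)
    centers_px = np.array(centers_um, dtype=float) / pixel_size_um
    sigma_px = psf_sigma_um / pixel_size_um
    if shape is None:
        pad = int(math.ceil(6 * sigma_px)) + 2
        h = int(math.ceil(centers_px[:, 1].max())) + pad
        w = int(math.ceil(centers_px[:, 0].max())) + pad
        shape = (h, w)
    h, w = shape
    if np.any(centers_px[:, 0] > w - 1) or np.any(centers_px[:, 1] > h - 1) or \
            np.any(centers_px < 0):
        raise ConfigError("punctum centers fall outside the field of view")
    d2 = (
        (centers_px[:, None, 0] - centers_px[None, :, 0]) ** 2
        + (centers_px[:, None, 1] - centers_px[None, :, 1]) ** 2
    )
    np.fill_diagonal(d2, np.inf)
    min_sep_px = 3.0 / pixel_size_um
    if np.any(d2 < min_sep_px**2):
        raise ConfigError("punctum centers must be >= 3 um apart")

    yy, xx = np.mgrid[0:h, 0:w]
    psfs = np.empty((len(centers_um), h, w))
    for p, (cx, cy) in enumerate(centers_px):
        g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))
        psfs[p] = g / g.sum()
    stack = np.tensordot(traces, psfs, axes=(1, 0))
    if photon_scale > 0:
        stack = rng.poisson(np.clip(stack, 0, None) * photon_scale) / photon_scale
    if read_noise > 0:
        stack = stack + rng.normal(0.0, read_noise, stack.shape)
    return stack, centers_px
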