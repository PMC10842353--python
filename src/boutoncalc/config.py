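"""Configuration types for the bouton simulator and the detection pipeline.

All timing is in seconds, rates in the units stated per field, and
fluorescence in arbitrary camera units relative to the resting level ``F0``.
Configs round-trip through JSON so that every run can be reproduced from its
serialized configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

EPOCH_LABELS = ("before", "treatment", "bleach", "after", "recovery", "highk")
ILLUMINATIONS = ("imaging", "bleach", "dark")


class ConfigError(ValueError):
    """Raised when a configuration or schedule fails validation."""


@dataclass(frozen=True)
class Epoch:
    """One contiguous segment of a recording protocol.

    ``illumination`` distinguishes normal imaging light, full-intensity
    bleaching light (neutral-density filter removed) and darkness (shutter
    closed, e.g. during overnight recovery). ``stimulated`` marks epochs in
    which field stimuli are delivered; ``highk`` marks perfusion of elevated
    (90 mM) K+, which drives all signal classes at saturating duty.
    """

    label: str
    start: float
    end: float
    illumination: str = "imaging"
    stimulated: bool = False
    highk: bool = False

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ConfigError(f"unknown epoch label {self.label!r}")
        if self.illumination not in ILLUMINATIONS:
            raise ConfigError(f"unknown illumination {self.illumination!r}")
        if not (self.end > self.start >= 0):
            raise ConfigError(
                f"epoch {self.label!r} must have 0 <= start < end, "
                f"got [{self.start}, {self.end}]"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StimulusSchedule:
    """Stimulus times plus the ordered epoch structure of a protocol.

    Epochs must be non-overlapping, ordered, and cover ``[0, duration]``
    without gaps; stimulus times must be strictly increasing.
    """

    stim_times: tuple[float, ...]
    epochs: tuple[Epoch, ...]

    def __init__(self, stim_times: Sequence[float], epochs: Sequence[Epoch]):
        object.__setattr__(self, "stim_times", tuple(float(t) for t in stim_times))
        object.__setattr__(self, "epochs", tuple(epochs))
        self._validate()

    def _validate(self) -> None:
        if not self.epochs:
            raise ConfigError("schedule needs at least one epoch")
        if abs(self.epochs[0].start) > 1e-9:
            raise ConfigError("first epoch must start at t=0")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if abs(b.start - a.end) > 1e-9:
                raise ConfigError(
                    f"epochs must tile the recording: {a.label} ends at {a.end} "
                    f"but {b.label} starts at {b.start}"
                )
        ts = self.stim_times
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigError("stim_times must be strictly increasing")
        if ts and (ts[0] < 0 or ts[-1] >= self.duration):
            raise ConfigError("stim_times must lie within [0, duration)")

    @property
    def duration(self) -> float:
        return self.epochs[-1].end

    def epoch_at(self, t: float) -> Epoch:
        for ep in self.epochs:
            if ep.start <= t < ep.end:
                return ep
        if math.isclose(t, self.duration):
            return self.epochs[-1]
        raise ConfigError(f"time {t} outside schedule [0, {self.duration}]")

    def stims_in(self, start: float, end: float) -> tuple[float, ...]:
        return tuple(t for t in self.stim_times if start <= t < end)

    def to_dict(self) -> dict:
        return {
            "stim_times": list(self.stim_times),
            "epochs": [dataclasses.asdict(e) for e in self.epochs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(d.get("stim_times", []), [Epoch(**e) for e in d["epochs"]])

    @classmethod
    def single_epoch(
        cls,
        duration: float,
        label: str = "before",
        stim_interval: float | None = None,
        first_stim: float = 5.0,
        highk: bool = False,
    ) -> "StimulusSchedule":
        """A one-epoch imaging schedule, optionally with periodic stimuli."""
        stims: list[float] = []
        stimulated = stim_interval is not None
        if stimulated:
            t = first_stim
            while t < duration:
                stims.append(t)
                t += stim_interval
        ep = Epoch(label, 0.0, duration, "imaging", stimulated, highk)
        return cls(stims, [ep])


def regular_stims(start: float, end: float, interval: float = 10.0) -> list[float]:
    """Stimulus times at fixed intervals within [start, end)."""
    out = []
    t = start
    while t < end:
        out.append(round(t, 9))
        t += interval
    return out


@dataclass
class BoutonSimConfig:
    """Generative parameters of one simulated presynaptic bouton.

    The forward model superimposes three signal classes on a resting level
    ``F0``: stimulus-locked evoked transients, Poisson spontaneous
    transients, and a noisy elevated baseline produced by high-rate
    sub-frame micro-openings of voltage-gated Ca2+ channels. Each class is
    carried by its own sensor pool whose unbleached fraction evolves under
    use-dependent photobleaching and slow exchange with an unbleached
    reservoir.
    """

    sampling_rate: float = 10.0       # frames / s
    duration: float = 600.0           # s
    pool_fractions: tuple[float, float, float] = (0.3, 0.2, 0.5)  # E, S, B
    p_evoked: float = 0.95            # per-stimulus response probability
    a_evoked_mean: float = 1.5        # dF/F0 lognormal mean
    a_evoked_cv: float = 0.3
    a_spont_mean: float = 0.8         # dF/F0 lognormal mean
    a_spont_cv: float = 0.3
    tau_rise_evoked: float = 0.05     # s
    tau_rise_spont: float = 0.25      # s
    tau_decay: float = 0.7            # s
    lambda_spont: float = 0.03        # events / min
    stim_interval: float = 10.0       # s, nominal inter-stimulus interval
    shot_rate: float = 5000.0         # micro-openings / s
    shot_amp: float = 0.001           # dF/F0 per micro-opening
    tau_shot: float = 0.1             # s, micro-opening duration (<= frame)
    f0: float = 100.0                 # resting fluorescence, camera units
    sigma_noise: float = 3.0          # additive Gaussian SD, camera units
    k_bleach: float = 0.04            # /s, bleach rate of a fluorescent sensor
    k_exchange: float = 0.01          # /min, pool exchange with reservoir
    ca_scale: float = 1.0             # elevated-Ca2+ multiplier (A_evoked, shot_rate)
    stim_bleach_duty: float = 1.0     # illumination duty within a stimulated bleach epoch
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pf = self.pool_fractions
        if len(pf) != 3 or any(f < 0 for f in pf):
            raise ConfigError("pool_fractions must be 3 nonnegative values")
        if abs(sum(pf) - 1.0) > 1e-9:
            raise ConfigError("pool_fractions must sum to 1")
        if not 0.0 <= self.p_evoked <= 1.0:
            raise ConfigError("p_evoked must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        nonneg = (
            "a_evoked_mean a_evoked_cv a_spont_mean a_spont_cv tau_rise_evoked "
            "tau_rise_spont tau_decay lambda_spont shot_rate shot_amp tau_shot "
            "f0 sigma_noise k_bleach k_exchange ca_scale"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.stim_bleach_duty <= 1.0:
            raise ConfigError("stim_bleach_duty must lie in [0, 1]")
        if self.stim_interval <= 0:
            raise ConfigError("stim_interval must be positive")
        if self.tau_decay <= max(self.tau_rise_evoked, self.tau_rise_spont):
            raise ConfigError("tau_decay must exceed both rise time constants")

    def replace(self, **kw) -> "BoutonSimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool_fractions"] = list(self.pool_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BoutonSimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        d = dict(d)
        if "pool_fractions" in d:
            d["pool_fractions"] = tuple(d["pool_fractions"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class DetectionParams:
    """Parameters of the event-detection procedure.

    Defaults follow the standard 10-Hz analysis: a 3-frame smoothing pass, a
    trailing 4-s moving-average baseline, a 3-SD detection threshold and a
    0.3-s window for time-locking evoked events to stimuli.
    """

    smooth_window: int = 3        # frames, odd
    baseline_window: float = 4.0  # s
    threshold_sd: float = 3.0
    evoked_window: float = 0.3    # s, closed-left / open-right
    merge_gap: float = 0.5        # s
    end_threshold_sd: float = 1.0
    detrend_window: float = 30.0  # s, tile size for percentile detrending
    kinetics_on_raw: bool = False

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd and >= 1")
        for name in (
            "baseline_window threshold_sd evoked_window merge_gap "
            "end_threshold_sd detrend_window"
        ).split():
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown detection-parameter keys: {sorted(extra)}")
        return cls(**d)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def dump_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
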