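"""Factorial probe-indentation stimulus design and trial rendering.

The stimulus is a circular probe indented into the skin following a
ramp-and-hold profile; once the plateau is reached a sinusoid is superimposed,
emulating classical vibrotactile psychophysics setups. Four features vary
factorially: probe size (mm), ramp amplitude (mm), ramp-up time (s) and
vibration frequency (Hz). The full grid yields 800 unique conditions.

Per-trial "motor noise" jitters the probe location, the sine amplitude and the
ramp amplitude, each uniformly within a stated half-width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIZES_MM",
    "AMPLITUDES_MM",
    "RAMP_TIMES_S",
    "FREQUENCIES_HZ",
    "StimulusFeatures",
    "MotorNoiseSpec",
    "StimulusTrace",
    "build_design",
    "design_table",
    "render_trial",
]

# Feature grids (probe size is interpreted as probe *radius* in mm).
SIZES_MM: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
AMPLITUDES_MM: tuple[float, ...] = (0.3, 0.6, 0.9, 1.2)
RAMP_TIMES_S: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
FREQUENCIES_HZ: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 130.0, 160.0, 200.0)

#: Base amplitude of the superimposed sinusoid (mm). Not a grid feature; the
#: per-trial motor noise jitters it by +-0.05 mm.
BASE_SINE_AMPLITUDE_MM: float = 0.1


@dataclass(frozen=True)
class StimulusFeatures:
    """One cell of the factorial stimulus design."""

    size_mm: float
    ramp_amplitude_mm: float
    ramp_time_s: float
    frequency_hz: float

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.size_mm, self.ramp_amplitude_mm, self.ramp_time_s, self.frequency_hz)


@dataclass(frozen=True)
class MotorNoiseSpec:
    """Uniform jitter half-widths emulating motor noise during active touch."""

    location_jitter_mm: float = 0.3
    sine_amplitude_jitter_mm: float = 0.05
    ramp_amplitude_jitter_mm: float = 0.1

    def __post_init__(self) -> None:
        for name in ("location_jitter_mm", "sine_amplitude_jitter_mm", "ramp_amplitude_jitter_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative half-width")

    @classmethod
    def zero(cls) -> "MotorNoiseSpec":
        return cls(0.0, 0.0, 0.0)


@dataclass
class StimulusTrace:
    """A rendered single-trial indentation time series."""

    dt_s: float
    depth_mm: np.ndarray
    probe_center_cm: float
    probe_size_mm: float
    trial_duration_s: float
    features: StimulusFeatures
    sine_amplitude_mm: float = 0.0
    sine_amplitude_clamped: bool = False

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.depth_mm.size) * self.dt_s


def build_design(
    sizes_mm: Sequence[float] = SIZES_MM,
    amplitudes_mm: Sequence[float] = AMPLITUDES_MM,
    ramp_times_s: Sequence[float] = RAMP_TIMES_S,
    frequencies_hz: Sequence[float] = FREQUENCIES_HZ,
) -> list[StimulusFeatures]:
    """Enumerate the factorial design, size-major / frequency-minor.

    With the default grids this yields the full 4 x 4 x 5 x 10 = 800 condition
    set.
    """
    return [
        StimulusFeatures(float(s), float(a), float(r), float(f))
        for s in sizes_mm
        for a in amplitudes_mm
        for r in ramp_times_s
        for f in frequencies_hz
    ]


def design_table(design: Sequence[StimulusFeatures]) -> pd.DataFrame:
    """Design as a DataFrame with a stable ``condition_id`` column."""
    return pd.DataFrame(
        {
            "condition_id": np.arange(len(design)),
            "size_mm": [f.size_mm for f in design],
            "ramp_amplitude_mm": [f.ramp_amplitude_mm for f in design],
            "ramp_time_s": [f.ramp_time_s for f in design],
            "frequency_hz": [f.frequency_hz for f in design],
        }
    )


def render_trial(
    features: StimulusFeatures,
    noise: MotorNoiseSpec | None = None,
    duration_s: float = 0.5,
    dt_s: float = 1e-4,
    rng: np.random.Generator | int | None = None,
    base_sine_amplitude_mm: float = BASE_SINE_AMPLITUDE_MM,
) -> StimulusTrace:
    """Render one trial's probe trajectory with motor-noise jitter.

    The trace ramps linearly to the (jittered) ramp amplitude over
    ``ramp_time_s``, holds with a superimposed sinusoid, and ramps back down
    over the same duration at the end of the trial. The sinusoid starts at
    phase zero when the plateau is reached and stops when the ramp-down
    begins. Depth is clipped at zero.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration_s and dt_s must be positive")
    if duration_s <= 2 * features.ramp_time_s:
        raise ValueError("duration_s must exceed twice the ramp time")
    if dt_s > 1.0 / (10.0 * max(FREQUENCIES_HZ)):
        raise ValueError("dt_s too coarse to resolve the highest sine frequency")
    if noise is None:
        noise = MotorNoiseSpec.zero()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    loc_jit_cm = rng.uniform(-noise.location_jitter_mm, noise.location_jitter_mm) / 10.0 \
        if noise.location_jitter_mm > 0 else 0.0
    amp_jit = rng.uniform(-noise.ramp_amplitude_jitter_mm, noise.ramp_amplitude_jitter_mm) \
        if noise.ramp_amplitude_jitter_mm > 0 else 0.0
    sine_jit = rng.uniform(-noise.sine_amplitude_jitter_mm, noise.sine_amplitude_jitter_mm) \
        if noise.sine_amplitude_jitter_mm > 0 else 0.0

    plateau_mm = features.ramp_amplitude_mm + amp_jit
    sine_amp = base_sine_amplitude_mm + sine_jit
    clamped = False
    if sine_amp < 0:
        sine_amp = 0.0
        clamped = True

    n = int(round(duration_s / dt_s))
    t = np.arange(n) * dt_s
    ramp = features.ramp_time_s
    t_down = duration_s - ramp

    depth = np.full(n, plateau_mm)
    up = t < ramp
    depth[up] = plateau_mm * t[up] / ramp
    down = t >= t_down
    depth[down] = plateau_mm * (duration_s - t[down]) / ramp

    if features.frequency_hz > 0 and sine_amp > 0:
        hold = (~up) & (~down)
        depth[hold] = plateau_mm + sine_amp * np.sin(
            2 * np.pi * features.frequency_hz * (t[hold] - ramp)
        )

    np.clip(depth, 0.0, None, out=depth)

    return StimulusTrace(
        dt_s=dt_s,
        depth_mm=depth,
        probe_center_cm=loc_jit_cm,
        probe_size_mm=features.size_mm,
        trial_duration_s=duration_s,
        features=features,
        sine_amplitude_mm=sine_amp,
        sine_amplitude_clamped=clamped,
    )
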