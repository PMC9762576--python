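"""Phenomenological simulator of tactile afferent populations on a line.

Three mechanoreceptive afferent classes are modelled, each terminating along a
line radiating outwards from the probe contact site:

* **SA1** (slowly adapting type 1): small receptive fields, sustained response
  to static indentation plus low-frequency dynamic sensitivity, so spikes
  align to a superimposed vibration.
* **RA** (rapidly adapting): medium receptive fields, velocity-driven
  (onset/offset bursts, flutter-range locking), no static response.
* **PC** (Pacinian): very large receptive fields, acceleration-driven with a
  high-frequency passband and a saturating drive, insensitive to static depth
  and — by construction — to probe size.

Each afferent's drive is a spatially attenuated, rectified combination of the
indentation depth and its (band-filtered) derivatives; spikes are produced by
a leaky integrate-and-fire mechanism with Gaussian per-spike threshold noise
and an absolute refractory period. Class parameters are calibration constants
chosen to satisfy qualitative response properties, not fitted claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._seeds import (
    STREAM_NEURAL,
    STREAM_STIMULUS,
    child_rng,
    class_index,
    density_key,
)
from .stimuli import MotorNoiseSpec, StimulusFeatures, StimulusTrace, design_table, render_trial

__all__ = [
    "AfferentClassParams",
    "AfferentPopulation",
    "SpikeDataset",
    "DEFAULT_CLASS_PARAMS",
    "default_params",
    "place_population",
    "drive",
    "generate_spikes",
    "simulate_dataset",
]

DENSITY_RANGE = (1.0, 140.0)
LINE_LENGTH_CM = {"SA1": 1.0, "RA": 1.0, "PC": 5.0}


@dataclass(frozen=True)
class AfferentClassParams:
    """Response parameters of one afferent class.

    Gains are in drive units per mm (static), per mm/s (velocity) and per
    mm/s^2 (acceleration); the drive unit is defined by ``threshold`` = 1
    being the nominal spiking threshold.
    """

    class_label: str
    rf_length_constant_cm: float
    static_gain: float
    velocity_gain: float
    acceleration_gain: float
    #: (low, high) corner frequencies in Hz of the band filter applied to the
    #: signed depth derivatives before rectification; None disables a corner.
    bandpass: tuple[float | None, float | None] = (None, None)
    threshold: float = 1.0
    threshold_noise_sd: float = 0.1
    refractory_s: float = 0.002
    membrane_tau_s: float = 0.005
    #: Half-saturation constant of the dynamic drive (None = linear).
    drive_saturation: float | None = None
    #: If True (SA1/RA) spatial attenuation is measured from the probe *edge*
    #: so that probe size changes recruitment; if False (PC) from the probe
    #: center, making the drive independent of probe size.
    edge_referenced: bool = True
    line_length_cm: float = 1.0


DEFAULT_CLASS_PARAMS: Mapping[str, AfferentClassParams] = {
    "SA1": AfferentClassParams(
        class_label="SA1",
        rf_length_constant_cm=0.10,
        static_gain=2.0,
        velocity_gain=0.05,
        acceleration_gain=0.0,
        bandpass=(None, 50.0),
        threshold_noise_sd=0.15,
        refractory_s=0.005,
        membrane_tau_s=0.005,
        edge_referenced=True,
        line_length_cm=1.0,
    ),
    "RA": AfferentClassParams(
        class_label="RA",
        rf_length_constant_cm=0.8,
        static_gain=0.0,
        velocity_gain=0.12,
        acceleration_gain=0.0,
        bandpass=(None, 60.0),
        threshold_noise_sd=0.15,
        refractory_s=0.0025,
        membrane_tau_s=0.004,
        drive_saturation=2.5,
        edge_referenced=True,
        line_length_cm=1.0,
    ),
    "PC": AfferentClassParams(
        class_label="PC",
        rf_length_constant_cm=100.0,
        static_gain=0.0,
        velocity_gain=0.0,
        acceleration_gain=6e-4,
        bandpass=(None, None),
        threshold_noise_sd=0.15,
        refractory_s=0.003,
        membrane_tau_s=0.002,
        drive_saturation=1.3,
        edge_referenced=False,
        line_length_cm=5.0,
    ),
}


def default_params(class_label: str) -> AfferentClassParams:
    """Default calibration for one of the SA1/RA/PC classes."""
    try:
        return DEFAULT_CLASS_PARAMS[class_label]
    except KeyError:
        raise ValueError(f"unknown afferent class {class_label!r}") from None


@dataclass
class AfferentPopulation:
    """Afferents of one class placed along a line at a given areal density.

    The areal density (afferents/cm^2) maps to a line count through a 1-cm
    wide strip: ``N = round(density * line_length_cm)``.
    """

    class_label: str
    density_per_cm2: float
    line_length_cm: float
    positions_cm: np.ndarray

    @property
    def n_afferents(self) -> int:
        return self.positions_cm.size


def place_population(
    class_label: str,
    density_per_cm2: float,
    line_length_cm: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> AfferentPopulation:
    """Place ``round(density * length)`` afferents evenly along the line.

    A seeded positional dither (< 1/4 of the spacing) breaks the regularity;
    positions radiate outward from the origin (the probe contact site).
    """
    lo, hi = DENSITY_RANGE
    if not (lo <= density_per_cm2 <= hi):
        raise ValueError(f"density must lie in [{lo}, {hi}] afferents/cm^2")
    if line_length_cm is None:
        line_length_cm = LINE_LENGTH_CM.get(class_label, 1.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = max(1, int(round(density_per_cm2 * line_length_cm)))
    spacing = line_length_cm / n
    centers = (np.arange(n) + 0.5) * spacing
    dither = rng.uniform(-0.25 * spacing, 0.25 * spacing, size=n)
    positions = np.clip(centers + dither, 0.0, line_length_cm)
    return AfferentPopulation(class_label, float(density_per_cm2), float(line_length_cm), positions)


def _band_filter(x: np.ndarray, band: tuple[float | None, float | None], fs: float) -> np.ndarray:
    """Apply the class band filter (2nd-order Butterworth) to a signed signal."""
    lo, hi = band
    if lo is None and hi is None:
        return x
    nyq = fs / 2.0
    if lo is not None and hi is not None:
        sos = signal.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    elif hi is not None:
        sos = signal.butter(2, hi / nyq, btype="lowpass", output="sos")
    else:
        sos = signal.butter(2, lo / nyq, btype="highpass", output="sos")
    return signal.sosfilt(sos, x, axis=-1)


def drive_profile(params: AfferentClassParams, trace: StimulusTrace) -> np.ndarray:
    """Spatially unattenuated drive g(t) shared by all afferents of a class."""
    depth = trace.depth_mm
    dt = trace.dt_s
    fs = 1.0 / dt
    g = np.zeros_like(depth)
    if params.static_gain:
        g = g + params.static_gain * depth
    dyn = np.zeros_like(depth)
    if params.velocity_gain:
        vel = np.gradient(depth, dt)
        dyn = dyn + params.velocity_gain * np.abs(_band_filter(vel, params.bandpass, fs))
    if params.acceleration_gain:
        acc = np.gradient(np.gradient(depth, dt), dt)
        dyn = dyn + params.acceleration_gain * np.abs(_band_filter(acc, params.bandpass, fs))
    if params.drive_saturation is not None:
        dyn = params.drive_saturation * dyn / (params.drive_saturation + dyn)
    g = g + dyn
    np.clip(g, 0.0, None, out=g)
    return g


def spatial_weights(
    pop: AfferentPopulation, params: AfferentClassParams, trace: StimulusTrace
) -> np.ndarray:
    """Exponential distance attenuation w(x) = exp(-x / rf_length_constant).

    For edge-referenced classes (SA1, RA) the distance is measured from the
    probe edge, so larger probes recruit afferents farther along the line;
    for PC it is measured from the probe center, independent of probe size.
    """
    if params.edge_referenced:
        radius_cm = trace.probe_size_mm / 10.0
        dist = np.maximum(0.0, pop.positions_cm - trace.probe_center_cm - radius_cm)
    else:
        dist = np.abs(pop.positions_cm - trace.probe_center_cm)
    return np.exp(-dist / params.rf_length_constant_cm)


def drive(
    pop: AfferentPopulation, params: AfferentClassParams, trace: StimulusTrace
) -> np.ndarray:
    """Per-afferent non-negative drive time series, shape (N, T)."""
    g = drive_profile(params, trace)
    w = spatial_weights(pop, params, trace)
    return w[:, None] * g[None, :]


def _lif_spike_times(
    drive_arr: np.ndarray,
    dt: float,
    params: AfferentClassParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Leaky integrate-and-fire over the trailing time axis.

    ``drive_arr`` has shape (..., T). Returns (unit_flat_index, spike_time_s)
    arrays, where the flat index runs over the leading axes in C order. The
    threshold is redrawn (Gaussian noise around the nominal threshold) after
    every spike of each unit; an absolute refractory period is enforced.
    """
    lead_shape = drive_arr.shape[:-1]
    T = drive_arr.shape[-1]
    flat = drive_arr.reshape(-1, T)
    n_units = flat.shape[0]

    v = np.zeros(n_units)
    refr_steps = max(1, int(round(params.refractory_s / dt)))
    refr = np.zeros(n_units, dtype=np.int64)
    thr = params.threshold + params.threshold_noise_sd * rng.standard_normal(n_units)
    alpha = dt / params.membrane_tau_s

    idx_out: list[np.ndarray] = []
    t_out: list[np.ndarray] = []
    for t in range(T):
        v += alpha * (flat[:, t] - v)
        active = refr == 0
        fired = active & (v >= thr)
        if fired.any():
            k = np.nonzero(fired)[0]
            idx_out.append(k)
            t_out.append(np.full(k.size, (t + 1) * dt))
            v[k] = 0.0
            refr[k] = refr_steps
            thr[k] = params.threshold + params.threshold_noise_sd * rng.standard_normal(k.size)
        np.maximum(refr - 1, 0, out=refr)

    if idx_out:
        unit_idx = np.concatenate(idx_out)
        times = np.concatenate(t_out)
    else:
        unit_idx = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    del lead_shape
    return unit_idx, times


def generate_spikes(
    drive_arr: np.ndarray,
    params: AfferentClassParams,
    dt_s: float,
    seed: int | np.random.Generator | None = None,
) -> list[np.ndarray] | np.ndarray:
    """Spike times from a drive series via noisy-threshold LIF.

    ``drive_arr`` may be 1-D (one afferent; returns an array of spike times)
    or 2-D (N, T) (returns a list of N arrays). Zero drive yields no spikes.
    Identical seed implies identical spikes.
    """
    if np.any(drive_arr < 0):
        raise ValueError("drive must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.atleast_2d(np.asarray(drive_arr, dtype=float))
    unit_idx, times = _lif_spike_times(arr, dt_s, params, rng)
    out = [np.sort(times[unit_idx == i]) for i in range(arr.shape[0])]
    if np.asarray(drive_arr).ndim == 1:
        return out[0]
    return out


@dataclass
class SpikeDataset:
    """Spike times of one population across all trials of a design.

    Stored as flat parallel arrays (trial index, afferent index, spike time)
    for efficient binning and perturbation; ``labels`` maps each trial to its
    stimulus condition.
    """

    class_label: str
    density_per_cm2: float
    population: AfferentPopulation
    n_trials: int
    duration_s: float
    trial_idx: np.ndarray
    aff_idx: np.ndarray
    times: np.ndarray
    labels: pd.DataFrame  # columns: trial, condition_id, size_mm, ramp_amplitude_mm, ramp_time_s, frequency_hz

    @property
    def n_afferents(self) -> int:
        return self.population.n_afferents

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spike_train(self, trial: int, afferent: int) -> np.ndarray:
        m = (self.trial_idx == trial) & (self.aff_idx == afferent)
        return np.sort(self.times[m])

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            class_label=np.array(self.class_label),
            density=np.array(self.density_per_cm2),
            positions=self.population.positions_cm,
            line_length=np.array(self.population.line_length_cm),
            n_trials=np.array(self.n_trials),
            duration=np.array(self.duration_s),
            trial_idx=self.trial_idx,
            aff_idx=self.aff_idx,
            times=self.times,
            labels=self.labels.to_records(index=False),
        )

    @classmethod
    def from_npz(cls, path) -> "SpikeDataset":
        with np.load(path, allow_pickle=False) as z:
            labels = pd.DataFrame(z["labels"])
            pop = AfferentPopulation(
                str(z["class_label"]), float(z["density"]), float(z["line_length"]), z["positions"]
            )
            return cls(
                class_label=str(z["class_label"]),
                density_per_cm2=float(z["density"]),
                population=pop,
                n_trials=int(z["n_trials"]),
                duration_s=float(z["duration"]),
                trial_idx=z["trial_idx"],
                aff_idx=z["aff_idx"],
                times=z["times"],
                labels=labels,
            )


def _nonsize_key(f: StimulusFeatures) -> tuple[int, int, int]:
    """Condition key excluding probe size (common random numbers across sizes)."""
    return (
        int(round(f.ramp_amplitude_mm * 1000)),
        int(round(f.ramp_time_s * 100000)),
        int(round(f.frequency_hz)),
    )


def render_design_traces(
    design: Sequence[StimulusFeatures],
    noise: MotorNoiseSpec,
    n_trials: int,
    master_seed: int,
    duration_s: float = 0.5,
    dt_s: float = 1e-4,
) -> dict[tuple[int, int], StimulusTrace]:
    """Render every (condition, trial) trace once; shared across classes.

    Trial randomness is keyed by the condition's non-size features, so
    conditions differing only in probe size see identical jitter draws and
    identical depth traces.
    """
    traces: dict[tuple[int, int], StimulusTrace] = {}
    for ci, f in enumerate(design):
        key = _nonsize_key(f)
        for trial in range(n_trials):
            rng = child_rng(master_seed, STREAM_STIMULUS, *key, trial)
            traces[(ci, trial)] = render_trial(f, noise, duration_s, dt_s, rng)
    return traces


def simulate_dataset(
    design: Sequence[StimulusFeatures],
    populations: Sequence[tuple[AfferentPopulation, AfferentClassParams]],
    n_trials: int,
    noise: MotorNoiseSpec,
    master_seed: int,
    duration_s: float = 0.5,
    dt_s: float = 1e-4,
    traces: dict[tuple[int, int], StimulusTrace] | None = None,
) -> dict[str, SpikeDataset]:
    """Simulate every population's response to every (condition, trial).

    Per-trial RNG streams are derived deterministically from ``master_seed``;
    neural-noise streams are keyed by (class, density, non-size condition,
    trial) so that, for a given class, rasters are identical across probe
    sizes by construction.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if traces is None:
        traces = render_design_traces(design, noise, n_trials, master_seed, duration_s, dt_s)

    out: dict[str, SpikeDataset] = {}
    table = design_table(list(design))
    for pop, params in populations:
        cls_i = class_index(pop.class_label)
        dens_k = density_key(pop.density_per_cm2)
        tr_list: list[np.ndarray] = []
        aff_list: list[np.ndarray] = []
        time_list: list[np.ndarray] = []
        rows = []
        global_trial = 0
        for ci, f in enumerate(design):
            key = _nonsize_key(f)
            # batch all trials of this condition through the LIF together
            drives = np.empty((n_trials, pop.n_afferents, traces[(ci, 0)].depth_mm.size))
            for trial in range(n_trials):
                drives[trial] = drive(pop, params, traces[(ci, trial)])
            # threshold-noise draws must not depend on batch composition:
            # run each trial with its own keyed RNG
            for trial in range(n_trials):
                try:
                    rng = child_rng(master_seed, STREAM_NEURAL, cls_i, dens_k, *key, trial)
                    unit_idx, times = _lif_spike_times(drives[trial], dt_s, params, rng)
                except Exception as exc:  # pragma: no cover - context for debugging
                    raise RuntimeError(
                        f"simulation failed at condition {ci}, trial {trial}"
                    ) from exc
                tr_list.append(np.full(times.size, global_trial + trial, dtype=np.int64))
                aff_list.append(unit_idx)
                time_list.append(times)
            for trial in range(n_trials):
                rows.append(
                    {
                        "trial": global_trial + trial,
                        "condition_id": int(table.loc[ci, "condition_id"]),
                        "size_mm": f.size_mm,
                        "ramp_amplitude_mm": f.ramp_amplitude_mm,
                        "ramp_time_s": f.ramp_time_s,
                        "frequency_hz": f.frequency_hz,
                    }
                )
            global_trial += n_trials
        out[pop.class_label] = SpikeDataset(
            class_label=pop.class_label,
            density_per_cm2=pop.density_per_cm2,
            population=pop,
            n_trials=global_trial,
            duration_s=duration_s,
            trial_idx=np.concatenate(tr_list) if tr_list else np.empty(0, dtype=np.int64),
            aff_idx=np.concatenate(aff_list) if aff_list else np.empty(0, dtype=np.int64),
            times=np.concatenate(time_list) if time_list else np.empty(0),
            labels=pd.DataFrame(rows),
        )
    return out
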