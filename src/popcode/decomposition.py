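"""Binning and non-negative matrix factorization of population spike trains.

Single-trial spatiotemporal responses are binned (2 ms default) into a matrix
``R`` of shape M x (T*N) — M trials, T time bins, N afferents, with an
afferent-major / time-minor layout of the flattened axis — and decomposed as

    R = H W + residuals,

where ``W`` (K x T*N) holds non-negative spatiotemporal modules and ``H``
(M x K) the per-trial activation coefficients. Module count selection sweeps
K upward until the explained-variance gain per added module falls below a
tolerance (default 1 percentage point), averages the resulting saturation
levels across densities of a class, and takes the minimal K reaching that
class-level threshold.

A spatial-only control decomposition factorizes whole-trial spike counts into
spatial modules and projects each time bin onto them, yielding K_space * T
coefficients per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .afferents import SpikeDataset

__all__ = [
    "ResponseMatrix",
    "NMFModel",
    "SplitSpec",
    "ModuleSelection",
    "bin_raster",
    "fit_nmf",
    "explained_variance",
    "select_num_modules",
    "project",
    "spatial_nmf",
    "make_split",
]

DEFAULT_BIN_WIDTH_S = 0.002


@dataclass
class ResponseMatrix:
    """Binned spike counts, shape M x (T*N), column index = afferent*T + bin."""

    R: np.ndarray
    n_time_bins: int
    n_afferents: int
    bin_width_s: float

    @property
    def n_trials(self) -> int:
        return self.R.shape[0]

    def as_3d(self) -> np.ndarray:
        """View as (M, N, T)."""
        return self.R.reshape(self.n_trials, self.n_afferents, self.n_time_bins)


@dataclass
class NMFModel:
    """Fitted non-negative factorization R ~= H W."""

    W: np.ndarray  # K x (T*N)
    H: np.ndarray  # M x K
    K: int
    explained_variance: float
    fit_seed: int | None = None


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split fractions for module selection vs analysis."""

    selection_fraction: float = 0.25
    analysis_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.selection_fraction + self.analysis_fraction - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def bin_raster(
    dataset: SpikeDataset,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    trial_duration_s: float | None = None,
) -> ResponseMatrix:
    """Bin spike times into per-(trial, afferent, bin) counts.

    Total spike count is conserved; spikes outside [0, duration] are an error.
    A spike at exactly the trial end falls into the last bin.
    """
    duration = dataset.duration_s if trial_duration_s is None else trial_duration_s
    T = int(round(duration / bin_width_s))
    if abs(T * bin_width_s - duration) > 1e-9:
        raise ValueError("bin width must divide the trial duration")
    if dataset.times.size and (dataset.times.min() < 0 or dataset.times.max() > duration + 1e-12):
        raise ValueError("spike times outside [0, trial duration]")
    M = dataset.n_trials
    N = dataset.n_afferents
    bins = np.minimum((dataset.times / bin_width_s).astype(np.int64), T - 1)
    flat = dataset.trial_idx * (N * T) + dataset.aff_idx * T + bins
    counts = np.bincount(flat, minlength=M * N * T).astype(float)
    return ResponseMatrix(counts.reshape(M, N * T), T, N, bin_width_s)


def explained_variance(R: np.ndarray, H: np.ndarray, W: np.ndarray) -> float:
    """1 - ||R - HW||_F^2 / ||R||_F^2 (1.0 for an all-zero R, by convention)."""
    denom = float(np.sum(R * R))
    if denom == 0.0:
        return 1.0
    resid = R - H @ W
    return 1.0 - float(np.sum(resid * resid)) / denom


def fit_nmf(
    R: ResponseMatrix | np.ndarray,
    K: int,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> NMFModel:
    """Frobenius-loss NMF with seeded random non-negative initialization.

    Uses scikit-learn's coordinate-descent solver. Warns (without raising) if
    the solver hits ``max_iter`` before reaching ``tol``.
    """
    X = R.R if isinstance(R, ResponseMatrix) else np.asarray(R, dtype=float)
    if K < 1 or K > min(X.shape):
        raise ValueError("K must satisfy 1 <= K <= min(M, T*N)")
    if not np.any(X):
        # degenerate all-zero input: perfect reconstruction with zero modules
        return NMFModel(
            W=np.zeros((K, X.shape[1])), H=np.zeros((X.shape[0], K)), K=K,
            explained_variance=1.0, fit_seed=seed,
        )
    nmf = NMF(
        n_components=K,
        init="random",
        random_state=seed,
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        H = nmf.fit_transform(X)
    W = nmf.components_
    return NMFModel(W=W, H=H, K=K, explained_variance=explained_variance(X, H, W), fit_seed=seed)


@dataclass
class ModuleSelection:
    """Outcome of the variance-saturation module-count selection."""

    class_threshold: float
    k_per_density: dict[float, int]
    saturation_levels: dict[float, float]
    ev_curves: dict[float, list[float]]
    unreachable: list[float]


def _ev_curve(X: np.ndarray, k_max: int, seed: int | None, tol_gain: float) -> tuple[list[float], int]:
    """Explained variance for K = 1..k_stop, stopping once the gain < tol_gain."""
    evs: list[float] = []
    prev = 0.0
    k_sat = 1
    k_max = min(k_max, min(X.shape))
    for K in range(1, k_max + 1):
        ev = fit_nmf(X, K, seed=seed).explained_variance
        evs.append(ev)
        gain = ev - prev
        if gain < tol_gain:
            k_sat = max(1, K - 1)
            return evs, k_sat
        prev = ev
        k_sat = K
    return evs, k_sat


def select_num_modules(
    R_by_density: Mapping[float, "ResponseMatrix | np.ndarray"],
    variance_saturation_tol: float = 0.01,
    seed: int | None = 0,
    k_max: int = 20,
) -> ModuleSelection:
    """Select the module count per density via the saturation protocol.

    Per density, K is swept upward until the explained-variance gain from one
    added module drops below ``variance_saturation_tol``; the explained
    variance at that point is the density's saturation level. Saturation
    levels are averaged across densities into a class-level threshold, and the
    final K per density is the minimal K whose explained variance reaches that
    threshold. Densities that cannot reach the threshold within ``k_max``
    modules are flagged and assigned their saturation K.
    """
    curves: dict[float, list[float]] = {}
    sat_levels: dict[float, float] = {}
    sat_k: dict[float, int] = {}
    for dens, R in R_by_density.items():
        X = R.R if isinstance(R, ResponseMatrix) else np.asarray(R, dtype=float)
        evs, k_sat = _ev_curve(X, k_max, seed, variance_saturation_tol)
        curves[dens] = evs
        sat_k[dens] = k_sat
        sat_levels[dens] = evs[k_sat - 1]
    threshold = float(np.mean(list(sat_levels.values())))

    k_final: dict[float, int] = {}
    unreachable: list[float] = []
    for dens, evs in curves.items():
        reached = [k + 1 for k, ev in enumerate(evs) if ev >= threshold]
        if reached:
            k_final[dens] = reached[0]
        else:
            # extend the sweep beyond the saturation stop if needed
            X = R_by_density[dens]
            X = X.R if isinstance(X, ResponseMatrix) else np.asarray(X, dtype=float)
            k = len(evs)
            found = None
            while k < min(k_max, min(X.shape)):
                k += 1
                ev = fit_nmf(X, k, seed=seed).explained_variance
                evs.append(ev)
                if ev >= threshold:
                    found = k
                    break
            if found is None:
                unreachable.append(dens)
                k_final[dens] = sat_k[dens]
            else:
                k_final[dens] = found
    return ModuleSelection(threshold, k_final, sat_levels, curves, unreachable)


def project(R: ResponseMatrix | np.ndarray, W: np.ndarray) -> np.ndarray:
    """Per-trial non-negative least-squares fit of fixed modules.

    Solves ``min_{h >= 0} ||r - W^T h||`` independently for every trial row;
    deterministic (no random initialization).
    """
    X = R.R if isinstance(R, ResponseMatrix) else np.asarray(R, dtype=float)
    if X.shape[1] != W.shape[1]:
        raise ValueError("column dimension of R must match W")
    A = W.T  # (T*N, K)
    H = np.empty((X.shape[0], W.shape[0]))
    for i in range(X.shape[0]):
        H[i], _ = nnls(A, X[i])
    return H


@dataclass
class SpatialNMFResult:
    """Spatial-control decomposition: spatial modules + per-bin coefficients."""

    W_space: np.ndarray      # K_space x N
    H_count: np.ndarray      # M x K_space (whole-trial counts projection)
    H_t: np.ndarray          # M x (K_space * T), bin-major per module
    K_space: int
    explained_variance: float


def spatial_nmf(
    R: ResponseMatrix,
    K: int | None = None,
    seed: int | None = 0,
    variance_saturation_tol: float = 0.01,
    k_max: int = 20,
) -> SpatialNMFResult:
    """Spatial NMF control: factorize whole-trial counts, project each bin.

    Whole-trial spike counts ``R_count`` (M x N) are factorized into spatial
    modules ``W_space``; each 2-ms population vector is then projected
    (non-negative least squares) onto those modules, giving K_space * T
    activation coefficients per trial.
    """
    R3 = R.as_3d()  # (M, N, T)
    R_count = R3.sum(axis=2)  # (M, N)
    if K is None:
        sel = select_num_modules({0.0: R_count}, variance_saturation_tol, seed=seed, k_max=k_max)
        K = sel.k_per_density[0.0]
    model = fit_nmf(R_count, K, seed=seed)
    W_space = model.W  # (K, N)
    M, N, T = R3.shape
    A = W_space.T  # (N, K)
    H_t = np.empty((M, K, T))
    for m in range(M):
        for t in range(T):
            H_t[m, :, t], _ = nnls(A, R3[m, :, t])
    return SpatialNMFResult(
        W_space=W_space,
        H_count=model.H,
        H_t=H_t.reshape(M, K * T),
        K_space=K,
        explained_variance=model.explained_variance,
    )


def make_split(
    condition_ids: np.ndarray,
    selection_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (by condition id) split into selection and analysis sets.

    Returns boolean masks (selection_mask, analysis_mask). Every condition is
    represented in both sets; with ``c`` trials of a condition, ``round(c *
    selection_fraction)`` (at least 1, at most c-1) go to the selection set.
    """
    condition_ids = np.asarray(condition_ids)
    rng = np.random.default_rng(seed)
    sel = np.zeros(condition_ids.size, dtype=bool)
    for cid in np.unique(condition_ids):
        idx = np.nonzero(condition_ids == cid)[0]
        if idx.size < 2:
            raise ValueError(f"condition {cid} has fewer than 2 trials; cannot split")
        n_sel = int(round(idx.size * selection_fraction))
        n_sel = min(max(n_sel, 1), idx.size - 1)
        chosen = rng.choice(idx, size=n_sel, replace=False)
        sel[chosen] = True
    return sel, ~sel
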