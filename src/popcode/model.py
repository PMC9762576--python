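"""Model/Results interface tying simulation output to information estimates.

:class:`PopulationCodingModel` is built from one or more simulated afferent
populations responding to the same stimulus design. ``fit()`` runs the full
estimation chain — 25/75 stratified split, per-class spatiotemporal NMF with
variance-saturation module selection, projection of the analysis set onto the
selected modules, multinomial decoding of each stimulus feature, and plugin
mutual information from the decoder confusion matrix — repeated across NMF
instantiations to quantify the dispersion induced by the random
initialization. The returned :class:`PopulationCodingResults` carries the
per-instantiation estimates, aggregates, a ``summary()`` table, the
complementarity/redundancy decomposition, and perturbation re-evaluation
(spatial shuffle / temporal jitter) against the frozen modules and decoders.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import (
    STREAM_DECODER,
    STREAM_NMF,
    STREAM_PERTURB,
    STREAM_SPLIT,
    child_int_seed,
    child_rng,
    class_index,
    density_key,
)
from .afferents import SpikeDataset
from .decoding import DEFAULT_C_GRID, DecoderModel, confusion_matrix, train_decoder
from .decomposition import (
    ResponseMatrix,
    bin_raster,
    fit_nmf,
    make_split,
    project,
    select_num_modules,
)
from .information import (
    complementary_information,
    mutual_information,
    redundant_information,
    stimulus_entropy,
)
from .perturbation import PerturbationSpec, evaluate_perturbed, jitter_spikes, shuffle_afferents

__all__ = ["PopulationCodingModel", "PopulationCodingResults", "FEATURE_COLUMNS"]

#: Decodable stimulus features and their label-table columns.
FEATURE_COLUMNS: dict[str, str] = {
    "size": "size_mm",
    "amplitude": "ramp_amplitude_mm",
    "ramp_time": "ramp_time_s",
    "frequency": "frequency_hz",
}
_FEATURE_INDEX = {f: i for i, f in enumerate(FEATURE_COLUMNS)}


def _set_key(class_set: Sequence[str]) -> int:
    return sum(2 ** class_index(c) for c in class_set)


def _set_name(class_set: Sequence[str]) -> str:
    return "+".join(class_set)


@dataclass
class _ClassFit:
    """Per-class fitted state kept for perturbation re-evaluation."""

    dataset: SpikeDataset
    R75: ResponseMatrix
    K: int
    variance_threshold: float | None
    W: list[np.ndarray]          # per instantiation
    H75: list[np.ndarray]        # per instantiation
    explained_variance: list[float]


class PopulationCodingModel:
    """Population-coding information model over simulated afferent datasets.

    Parameters
    ----------
    datasets
        Mapping of class label to :class:`SpikeDataset`. All datasets must
        share the same trial structure (condition ids per trial).
    bin_width_s
        Spike-count bin width (2 ms default).
    n_instantiations
        Number of NMF instantiations (random initializations) over which the
        dispersion of the information estimates is measured.
    selection_fraction
        Fraction of trials used for module-count selection and module
        fitting; the remainder (the analysis set) is projected, split 50/50
        stratified into decoder train/test halves.
    variance_thresholds
        Optional per-class explained-variance thresholds (e.g. computed
        across densities by :func:`popcode.decomposition.select_num_modules`);
        if absent, each class's threshold is its own saturation level.
    class_sets
        Class combinations to decode; defaults to all singles, pairs and the
        full set. Joint sets concatenate the per-class activation
        coefficients trial-wise.
    """

    def __init__(
        self,
        datasets: Mapping[str, SpikeDataset],
        *,
        bin_width_s: float = 0.002,
        n_instantiations: int = 10,
        selection_fraction: float = 0.25,
        C_grid: Sequence[float] = DEFAULT_C_GRID,
        variance_saturation_tol: float = 0.01,
        k_max: int = 20,
        variance_thresholds: Mapping[str, float] | None = None,
        fixed_k: Mapping[str, int] | None = None,
        class_sets: Sequence[Sequence[str]] | None = None,
        features: Sequence[str] | None = None,
        nmf_max_iter: int = 500,
    ) -> None:
        if not datasets:
            raise ValueError("need at least one dataset")
        self.datasets = dict(datasets)
        labels0 = next(iter(self.datasets.values())).labels
        for ds in self.datasets.values():
            if not np.array_equal(ds.labels["condition_id"].values, labels0["condition_id"].values):
                raise ValueError("datasets must share the same trial/condition structure")
        self.labels = labels0.reset_index(drop=True)
        self.bin_width_s = bin_width_s
        self.n_instantiations = n_instantiations
        self.selection_fraction = selection_fraction
        self.C_grid = tuple(C_grid)
        self.variance_saturation_tol = variance_saturation_tol
        self.k_max = k_max
        self.variance_thresholds = dict(variance_thresholds or {})
        self.fixed_k = dict(fixed_k or {})
        self.nmf_max_iter = nmf_max_iter

        classes = list(self.datasets)
        if class_sets is None:
            class_sets = [(c,) for c in classes]
            if len(classes) > 1:
                class_sets += [tuple(s) for r in range(2, len(classes) + 1)
                               for s in combinations(classes, r)]
        self.class_sets = [tuple(s) for s in class_sets]
        for s in self.class_sets:
            for c in s:
                if c not in self.datasets:
                    raise ValueError(f"class set {s} references unknown class {c!r}")

        if features is None:
            features = [
                f for f, col in FEATURE_COLUMNS.items()
                if self.labels[col].nunique() >= 2
            ]
        self.features = list(features)

    # ------------------------------------------------------------------
    def fit(self, master_seed: int = 0) -> "PopulationCodingResults":
        """Run the full split/NMF/decode/information chain."""
        cond = self.labels["condition_id"].values
        split_seed = child_int_seed(master_seed, STREAM_SPLIT)
        sel_mask, ana_mask = make_split(cond, self.selection_fraction, seed=split_seed)
        ana_idx = np.nonzero(ana_mask)[0]
        train_seed = child_int_seed(master_seed, STREAM_SPLIT, 1)
        tr_rel, te_rel = make_split(cond[ana_idx], 0.5, seed=train_seed)

        class_fits: dict[str, _ClassFit] = {}
        for cls, ds in self.datasets.items():
            R = bin_raster(ds, self.bin_width_s)
            R25 = ResponseMatrix(R.R[sel_mask], R.n_time_bins, R.n_afferents, R.bin_width_s)
            R75 = ResponseMatrix(R.R[ana_mask], R.n_time_bins, R.n_afferents, R.bin_width_s)
            cls_i = class_index(cls)
            dens_k = density_key(ds.density_per_cm2)
            sel_seed = child_int_seed(master_seed, STREAM_NMF, cls_i, dens_k, 9999)
            if cls in self.fixed_k:
                K = int(self.fixed_k[cls])
                thr = self.variance_thresholds.get(cls)
            elif cls in self.variance_thresholds:
                thr = float(self.variance_thresholds[cls])
                K = self._k_for_threshold(R25, thr, sel_seed)
            else:
                sel = select_num_modules(
                    {ds.density_per_cm2: R25},
                    self.variance_saturation_tol,
                    seed=sel_seed,
                    k_max=self.k_max,
                )
                K = sel.k_per_density[ds.density_per_cm2]
                thr = sel.class_threshold
            W_list, H_list, ev_list = [], [], []
            for j in range(self.n_instantiations):
                seed_j = child_int_seed(master_seed, STREAM_NMF, cls_i, dens_k, j)
                m = fit_nmf(R25, K, seed=seed_j, max_iter=self.nmf_max_iter)
                W_list.append(m.W)
                H_list.append(project(R75, m.W))
                ev_list.append(m.explained_variance)
            class_fits[cls] = _ClassFit(ds, R75, K, thr, W_list, H_list, ev_list)

        labels_ana = self.labels.iloc[ana_idx].reset_index(drop=True)
        decoders: dict[tuple[str, tuple[str, ...], int], DecoderModel] = {}
        rows = []
        for feature in self.features:
            col = FEATURE_COLUMNS[feature]
            y = labels_ana[col].values
            n_out = int(pd.unique(y).size)
            for cs in self.class_sets:
                dens_keys = [density_key(self.datasets[c].density_per_cm2) for c in cs]
                for j in range(self.n_instantiations):
                    H = np.hstack([class_fits[c].H75[j] for c in cs])
                    dseed = child_int_seed(
                        master_seed, STREAM_DECODER,
                        _FEATURE_INDEX.get(feature, 9), _set_key(cs), *dens_keys, j,
                    )
                    model = train_decoder(H[tr_rel], y[tr_rel], self.C_grid, seed=dseed)
                    cm = confusion_matrix(model, H[te_rel], y[te_rel])
                    I = mutual_information(cm)
                    decoders[(feature, cs, j)] = model
                    rows.append(
                        {
                            "feature": feature,
                            "class_set": _set_name(cs),
                            "densities": "/".join(
                                f"{c}:{self.datasets[c].density_per_cm2:g}" for c in cs
                            ),
                            "density": (
                                self.datasets[cs[0]].density_per_cm2 if len(cs) == 1 else np.nan
                            ),
                            "perturbation": "none",
                            "instantiation": j,
                            "K": "+".join(str(class_fits[c].K) for c in cs),
                            "C": model.C,
                            "n_outcomes": n_out,
                            "I_bits": I,
                            "I_norm": I / stimulus_entropy(n_out),
                        }
                    )

        return PopulationCodingResults(
            model=self,
            master_seed=master_seed,
            table=pd.DataFrame(rows),
            class_fits=class_fits,
            decoders=decoders,
            selection_mask=sel_mask,
            analysis_mask=ana_mask,
            train_mask=tr_rel,
            test_mask=te_rel,
            labels_analysis=labels_ana,
        )

    def _k_for_threshold(self, R25: ResponseMatrix, threshold: float, seed: int) -> int:
        prev = 0.0
        k_cap = min(self.k_max, min(R25.R.shape))
        for K in range(1, k_cap + 1):
            ev = fit_nmf(R25, K, seed=seed, max_iter=self.nmf_max_iter).explained_variance
            if ev >= threshold:
                return K
            if ev - prev < self.variance_saturation_tol and K > 1:
                return K  # saturated below threshold; flagged via threshold bookkeeping
            prev = ev
        return k_cap


@dataclass
class PopulationCodingResults:
    """Fitted estimates plus the frozen state needed for perturbations."""

    model: PopulationCodingModel
    master_seed: int
    table: pd.DataFrame
    class_fits: dict[str, _ClassFit]
    decoders: dict[tuple[str, tuple[str, ...], int], DecoderModel]
    selection_mask: np.ndarray
    analysis_mask: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    labels_analysis: pd.DataFrame

    # -- aggregation ----------------------------------------------------
    def info(self, feature: str, class_set: Sequence[str] | str) -> tuple[float, float]:
        """(mean, sd) of I_bits across instantiations for one cell."""
        name = class_set if isinstance(class_set, str) else _set_name(class_set)
        sub = self.table[
            (self.table.feature == feature)
            & (self.table.class_set == name)
            & (self.table.perturbation == "none")
        ]
        if sub.empty:
            raise KeyError(f"no results for feature={feature!r}, class_set={name!r}")
        return float(sub.I_bits.mean()), float(sub.I_bits.std(ddof=0))

    def aggregate(self) -> pd.DataFrame:
        """Mean/SD of information across NMF instantiations per cell."""
        g = self.table.groupby(["feature", "class_set", "densities", "perturbation"], sort=True)
        out = g.agg(
            I_bits_mean=("I_bits", "mean"),
            I_bits_sd=("I_bits", lambda s: s.std(ddof=0)),
            I_norm_mean=("I_norm", "mean"),
            n_outcomes=("n_outcomes", "first"),
        ).reset_index()
        return out

    def summary(self) -> str:
        """Human-readable summary table of the fitted information estimates."""
        agg = self.aggregate()
        lines = [
            "Population coding information estimates",
            f"  instantiations: {self.model.n_instantiations}   "
            f"bin width: {self.model.bin_width_s * 1000:g} ms   "
            f"master seed: {self.master_seed}",
            "",
            f"{'feature':<10} {'classes':<12} {'densities':<22} {'perturb':<18} "
            f"{'I (bits)':>10} {'SD':>8} {'I/H(S)':>8}",
        ]
        for _, r in agg.iterrows():
            lines.append(
                f"{r.feature:<10} {r.class_set:<12} {r.densities:<22} {r.perturbation:<18} "
                f"{r.I_bits_mean:>10.4f} {r.I_bits_sd:>8.4f} {r.I_norm_mean:>8.4f}"
            )
        ks = ", ".join(f"{c}: K={cf.K}" for c, cf in self.class_fits.items())
        lines += ["", f"NMF modules per class: {ks}"]
        return "\n".join(lines)

    # -- complementarity ------------------------------------------------
    def complementarity(self, features: Sequence[str] | None = None) -> pd.DataFrame:
        """Complementary/redundant decomposition per reference class.

        For each feature, instantiation and reference class present in the
        fitted class sets, computes I_comp = I_all - I_others and
        I_red = I_ref + I_others - I_all, where "all" is the full fitted
        class set and "others" the complement of the reference class.
        """
        classes = [cs[0] for cs in self.model.class_sets if len(cs) == 1]
        full = tuple(c for c in self.model.datasets if c in classes)
        if len(full) < 2:
            raise ValueError("complementarity needs at least two classes")
        feats = list(features) if features is not None else self.model.features
        t = self.table[self.table.perturbation == "none"]
        rows = []
        for feature in feats:
            for j in range(self.model.n_instantiations):
                sub = t[(t.feature == feature) & (t.instantiation == j)]
                by_set = dict(zip(sub.class_set, sub.I_bits))
                all_name = _set_name(full)
                if all_name not in by_set:
                    continue
                I_all = by_set[all_name]
                for ref in full:
                    others = tuple(c for c in full if c != ref)
                    others_name = _set_name(others)
                    if ref not in by_set or others_name not in by_set:
                        continue
                    I_ref = by_set[ref]
                    I_others = by_set[others_name]
                    I_comp = complementary_information(I_all, I_others)
                    I_red = redundant_information(I_ref, I_others, I_all)
                    rows.append(
                        {
                            "feature": feature,
                            "instantiation": j,
                            "reference_class": ref,
                            "I_ref": I_ref,
                            "I_others": I_others,
                            "I_all": I_all,
                            "I_comp": I_comp,
                            "I_red": I_red,
                            "comp_fraction": I_comp / I_ref if I_ref > 0 else np.nan,
                        }
                    )
        return pd.DataFrame(rows)

    # -- perturbations --------------------------------------------------
    def evaluate_perturbation(
        self,
        spec: PerturbationSpec,
        classes: Sequence[str] | None = None,
        features: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Re-evaluate information on perturbed data with frozen W + decoder.

        Perturbations act on single-class populations: the analysis-set
        response matrix of each class is shuffled (spatial) or its spike
        times jittered (temporal), projected onto the original modules of
        each instantiation, and decoded with the frozen decoder.
        """
        classes = list(classes) if classes is not None else list(self.class_fits)
        feats = list(features) if features is not None else self.model.features
        rows = []
        for cls in classes:
            cf = self.class_fits[cls]
            cls_i = class_index(cls)
            dens_k = density_key(cf.dataset.density_per_cm2)
            if spec.kind == "spatial_shuffle":
                rng = child_rng(self.master_seed, STREAM_PERTURB, cls_i, dens_k, spec.seed, 0)
                R_pert = shuffle_afferents(cf.R75, rng)
            else:
                w = float(spec.jitter_half_width_ms)
                if w == 0.0:
                    R_pert = cf.R75
                else:
                    rng = child_rng(
                        self.master_seed, STREAM_PERTURB, cls_i, dens_k, spec.seed,
                        int(round(w * 1000)),
                    )
                    jittered = jitter_spikes(cf.dataset, w, rng)
                    R_full = bin_raster(jittered, self.model.bin_width_s)
                    R_pert = ResponseMatrix(
                        R_full.R[self.analysis_mask],
                        R_full.n_time_bins,
                        R_full.n_afferents,
                        R_full.bin_width_s,
                    )
            for feature in feats:
                col = FEATURE_COLUMNS[feature]
                y = self.labels_analysis[col].values
                for j in range(self.model.n_instantiations):
                    if (feature, (cls,), j) not in self.decoders:
                        continue
                    res = evaluate_perturbed(
                        R_pert,
                        cf.W[j],
                        self.decoders[(feature, (cls,), j)],
                        y,
                        self.test_mask,
                        feature=feature,
                        class_set=(cls,),
                        density=cf.dataset.density_per_cm2,
                        perturbation_tag=spec.tag,
                        instantiation=j,
                    )
                    rows.append(
                        {
                            "feature": feature,
                            "class_set": cls,
                            "densities": f"{cls}:{cf.dataset.density_per_cm2:g}",
                            "density": cf.dataset.density_per_cm2,
                            "perturbation": spec.tag,
                            "instantiation": j,
                            "K": str(cf.K),
                            "C": self.decoders[(feature, (cls,), j)].C,
                            "n_outcomes": res.n_outcomes,
                            "I_bits": res.I_bits,
                            "I_norm": res.I_normalized,
                        }
                    )
        return pd.DataFrame(rows)
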