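"""Experiment orchestration: the simulate -> decompose -> decode -> inform grid.

A :class:`ExperimentConfig` declares the stimulus grid, the afferent density
grid per class, the preset density combinations at which multi-class
information is computed, perturbation settings, and all estimation
parameters. :func:`run_experiment` executes every grid cell, persists
per-cell artifacts (spike datasets as NPZ, information tables as CSV,
manifest and summary as JSON) under an output directory, and is resumable at
cell granularity: deleting one cell's output and re-running recomputes only
that cell. All randomness derives hierarchically from ``master_seed``.

Density presets for the human palm and finger follow microneurography
estimates (afferents/cm^2): palm SA1 10 / RA 25 / PC 10; finger SA1 30 /
RA 40 / PC 10; fingertip SA1 70 / RA 140 / PC 25.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from ._seeds import STREAM_PLACEMENT, child_rng, class_index, density_key
from .afferents import (
    DEFAULT_CLASS_PARAMS,
    SpikeDataset,
    place_population,
    render_design_traces,
    simulate_dataset,
)
from .decomposition import ResponseMatrix, bin_raster, make_split, select_num_modules
from ._seeds import STREAM_SPLIT, child_int_seed
from .information import InfoCurve, compare_strategies, saturation_density
from .model import PopulationCodingModel
from .perturbation import STANDARD_JITTER_WIDTHS_MS, PerturbationSpec
from .stimuli import (
    AMPLITUDES_MM,
    FREQUENCIES_HZ,
    RAMP_TIMES_S,
    SIZES_MM,
    MotorNoiseSpec,
    build_design,
    design_table,
)

__all__ = [
    "PALM_DENSITIES",
    "FINGER_DENSITIES",
    "FINGERTIP_DENSITIES",
    "ExperimentConfig",
    "paper_profile",
    "desk_profile",
    "micro_profile",
    "run_experiment",
    "report",
]

log = logging.getLogger("popcode")

PALM_DENSITIES: dict[str, float] = {"SA1": 10.0, "RA": 25.0, "PC": 10.0}
FINGER_DENSITIES: dict[str, float] = {"SA1": 30.0, "RA": 40.0, "PC": 10.0}
FINGERTIP_DENSITIES: dict[str, float] = {"SA1": 70.0, "RA": 140.0, "PC": 25.0}

_CLASSES = ("SA1", "RA", "PC")


def _log_spaced_densities(n: int = 16, lo: float = 1.0, hi: float = 140.0) -> list[float]:
    return [float(x) for x in np.round(np.geomspace(lo, hi, n), 2)]


@dataclass
class ExperimentConfig:
    """Full description of one experiment run."""

    # stimulus grid
    sizes_mm: tuple[float, ...] = SIZES_MM
    amplitudes_mm: tuple[float, ...] = AMPLITUDES_MM
    ramp_times_s: tuple[float, ...] = RAMP_TIMES_S
    frequencies_hz: tuple[float, ...] = FREQUENCIES_HZ
    n_trials: int = 40
    duration_s: float = 0.5
    dt_s: float = 1e-4
    # motor noise half-widths (mm)
    location_jitter_mm: float = 0.3
    sine_amplitude_jitter_mm: float = 0.05
    ramp_amplitude_jitter_mm: float = 0.1
    # density grid per class and the preset for multi-class analyses
    densities: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {c: tuple(_log_spaced_densities()) for c in _CLASSES}
    )
    combo_densities: dict[str, float] | None = field(default_factory=lambda: dict(FINGER_DENSITIES))
    # estimation parameters
    bin_width_s: float = 0.002
    n_instantiations: int = 50
    selection_fraction: float = 0.25
    variance_saturation_tol: float = 0.01
    k_max: int = 20
    nmf_max_iter: int = 500
    features: tuple[str, ...] | None = None
    # perturbations
    perturb: bool = True
    perturb_classes: tuple[str, ...] | None = None
    perturb_features: tuple[str, ...] | None = None
    jitter_widths_ms: tuple[float, ...] = STANDARD_JITTER_WIDTHS_MS
    perturb_densities: dict[str, float] | None = None  # default: top grid density per class
    # density-vs-class strategy comparison (double the best class's density
    # vs add another class); needs baseline and doubled densities simulated
    compare_strategies: bool = False
    strategy_baseline: float = 10.0
    master_seed: int = 0

    # ------------------------------------------------------------------
    def noise(self) -> MotorNoiseSpec:
        return MotorNoiseSpec(
            self.location_jitter_mm, self.sine_amplitude_jitter_mm, self.ramp_amplitude_jitter_mm
        )

    def design(self):
        return build_design(self.sizes_mm, self.amplitudes_mm, self.ramp_times_s, self.frequencies_hz)

    def classes(self) -> list[str]:
        return list(self.densities)

    def perturb_density_of(self, cls: str) -> float:
        if self.perturb_densities and cls in self.perturb_densities:
            return self.perturb_densities[cls]
        return max(self.densities[cls])

    def required_densities(self) -> dict[str, list[float]]:
        """All (class, density) cells that must be simulated."""
        req = {c: sorted(set(d)) for c, d in self.densities.items()}
        if self.combo_densities:
            for c, d in self.combo_densities.items():
                if c in req and d not in req[c]:
                    req[c].append(d)
        if self.compare_strategies:
            for c in req:
                for d in (self.strategy_baseline, 2 * self.strategy_baseline):
                    if d not in req[c]:
                        req[c].append(d)
        return {c: sorted(v) for c, v in req.items()}

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        d["densities"] = {c: list(v) for c, v in self.densities.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        for k in (
            "sizes_mm", "amplitudes_mm", "ramp_times_s", "frequencies_hz",
            "jitter_widths_ms", "perturb_classes", "perturb_features", "features",
        ):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        if "densities" in d:
            d["densities"] = {c: tuple(v) for c, v in d["densities"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def paper_profile(master_seed: int = 0) -> ExperimentConfig:
    """Full-scale conditions: 800 stimuli, 40 trials, 16 densities/class,
    50 NMF instantiations. Long-running; intended for cluster-scale use."""
    return ExperimentConfig(master_seed=master_seed, compare_strategies=True)


def desk_profile(master_seed: int = 0) -> ExperimentConfig:
    """Reduced conditions that run on one CPU in minutes.

    Keeps the full probe-size axis (the spatial feature), two ramp
    amplitudes, and frequencies {0, 80, 120} Hz — a pair whose discrimination
    rests on spike timing at 2-ms resolution plus the static case; two
    densities per class chosen so every class contributes 5 and 40 afferents
    (PC afferents lie on a 5-cm line); 20 trials and 5 NMF instantiations.
    """
    return ExperimentConfig(
        sizes_mm=(1.0, 2.0, 3.0, 4.0),
        amplitudes_mm=(0.3, 1.2),
        ramp_times_s=(0.03,),
        frequencies_hz=(0.0, 80.0, 120.0),
        n_trials=20,
        densities={"SA1": (5.0, 40.0), "RA": (5.0, 40.0), "PC": (1.0, 8.0)},
        combo_densities={"SA1": 40.0, "RA": 40.0, "PC": 8.0},
        n_instantiations=5,
        k_max=12,
        perturb=True,
        perturb_features=("size", "frequency"),
        master_seed=master_seed,
    )


def micro_profile(master_seed: int = 0) -> ExperimentConfig:
    """Smoke-test conditions: a handful of stimuli and afferents; seconds."""
    return ExperimentConfig(
        sizes_mm=(1.0, 4.0),
        amplitudes_mm=(0.6,),
        ramp_times_s=(0.03,),
        frequencies_hz=(0.0, 40.0),
        n_trials=8,
        densities={"SA1": (5.0,), "RA": (5.0,), "PC": (1.0,)},
        combo_densities={"SA1": 5.0, "RA": 5.0, "PC": 1.0},
        n_instantiations=1,
        k_max=6,
        perturb=True,
        perturb_features=("size",),
        jitter_widths_ms=(2.0,),
        master_seed=master_seed,
    )


# ----------------------------------------------------------------------
# persistence helpers

_INFO_COLUMNS = [
    "feature", "class_set", "densities", "density", "perturbation",
    "instantiation", "K", "C", "n_outcomes", "I_bits", "I_norm",
]


def _cell_name(cls: str, density: float) -> str:
    return f"{cls}_d{density:g}"


def _write_info_csv(df: pd.DataFrame, path: Path) -> None:
    df = df[_INFO_COLUMNS].sort_values(_INFO_COLUMNS[:6]).reset_index(drop=True)
    df.to_csv(path, index=False)


def _sim_cell(
    cfg: ExperimentConfig, outdir: Path, cls: str, density: float, traces, resume: bool
) -> SpikeDataset:
    path = outdir / "sim" / f"{_cell_name(cls, density)}.npz"
    if resume and path.exists():
        return SpikeDataset.from_npz(path)
    pop = place_population(
        cls, density,
        seed=child_rng(cfg.master_seed, STREAM_PLACEMENT, class_index(cls), density_key(density)),
    )
    ds = simulate_dataset(
        cfg.design(), [(pop, DEFAULT_CLASS_PARAMS[cls])], cfg.n_trials, cfg.noise(),
        cfg.master_seed, cfg.duration_s, cfg.dt_s, traces=traces,
    )[cls]
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_npz(path)
    return ds


def _class_selection(
    cfg: ExperimentConfig, outdir: Path, cls: str, datasets: Mapping[float, SpikeDataset], resume: bool
) -> dict:
    """Cross-density module-count selection for one class (cached as JSON)."""
    path = outdir / "nmf" / f"selection_{cls}.json"
    if resume and path.exists():
        return json.loads(path.read_text())
    cond = next(iter(datasets.values())).labels["condition_id"].values
    sel_mask, _ = make_split(cond, cfg.selection_fraction, seed=child_int_seed(cfg.master_seed, STREAM_SPLIT))
    R25 = {}
    for dens, ds in datasets.items():
        R = bin_raster(ds, cfg.bin_width_s)
        R25[dens] = ResponseMatrix(R.R[sel_mask], R.n_time_bins, R.n_afferents, R.bin_width_s)
    sel_seed = child_int_seed(cfg.master_seed, STREAM_PLACEMENT, 5000 + class_index(cls))
    sel = select_num_modules(R25, cfg.variance_saturation_tol, seed=sel_seed, k_max=cfg.k_max)
    payload = {
        "class": cls,
        "threshold": sel.class_threshold,
        "k_per_density": {f"{d:g}": int(k) for d, k in sel.k_per_density.items()},
        "saturation_levels": {f"{d:g}": float(v) for d, v in sel.saturation_levels.items()},
        "unreachable": [f"{d:g}" for d in sel.unreachable],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return payload


def _model_for(
    cfg: ExperimentConfig,
    datasets: Mapping[str, SpikeDataset],
    selections: Mapping[str, dict],
    class_sets=None,
) -> PopulationCodingModel:
    fixed_k = {}
    thresholds = {}
    for cls, ds in datasets.items():
        sel = selections[cls]
        thresholds[cls] = sel["threshold"]
        key = f"{ds.density_per_cm2:g}"
        if key in sel["k_per_density"]:
            fixed_k[cls] = sel["k_per_density"][key]
    return PopulationCodingModel(
        datasets,
        bin_width_s=cfg.bin_width_s,
        n_instantiations=cfg.n_instantiations,
        selection_fraction=cfg.selection_fraction,
        variance_saturation_tol=cfg.variance_saturation_tol,
        k_max=cfg.k_max,
        variance_thresholds=thresholds,
        fixed_k=fixed_k,
        class_sets=class_sets,
        features=cfg.features,
        nmf_max_iter=cfg.nmf_max_iter,
    )


def _perturb_specs(cfg: ExperimentConfig) -> list[PerturbationSpec]:
    specs = [PerturbationSpec("spatial_shuffle")]
    specs += [PerturbationSpec("temporal_jitter", w) for w in cfg.jitter_widths_ms]
    return specs


def run_experiment(
    config: ExperimentConfig, outdir: str | Path, resume: bool = True, through: str = "all"
) -> Path:
    """Execute the experiment grid, persisting artifacts under ``outdir``.

    ``through`` limits execution to a stage prefix: "simulate", "analyze",
    "report" or "all". Per-cell failures are logged and skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, outdir, resume, through)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(cfg: ExperimentConfig, outdir: Path, resume: bool, through: str) -> Path:
    import sklearn

    manifest = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "popcode_version": _pkg_version,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    design_table(cfg.design()).to_csv(outdir / "design.csv", index=False)

    # ---- simulate ----------------------------------------------------
    log.info("rendering stimulus traces")
    traces = render_design_traces(
        cfg.design(), cfg.noise(), cfg.n_trials, cfg.master_seed, cfg.duration_s, cfg.dt_s
    )
    sims: dict[str, dict[float, SpikeDataset]] = {}
    for cls, dens_list in cfg.required_densities().items():
        sims[cls] = {}
        for dens in dens_list:
            log.info("simulate %s at %g afferents/cm^2", cls, dens)
            sims[cls][dens] = _sim_cell(cfg, outdir, cls, dens, traces, resume)
    del traces
    if through == "simulate":
        return outdir

    # ---- analyze -----------------------------------------------------
    selections = {
        cls: _class_selection(cfg, outdir, cls, sims[cls], resume) for cls in sims
    }
    cells_dir = outdir / "cells"
    cells_dir.mkdir(exist_ok=True)
    specs = _perturb_specs(cfg) if cfg.perturb else []

    for cls, by_dens in sims.items():
        for dens, ds in by_dens.items():
            if dens not in cfg.densities.get(cls, ()) and dens != cfg.perturb_density_of(cls):
                continue
            cell_path = cells_dir / f"single_{_cell_name(cls, dens)}.csv"
            if resume and cell_path.exists():
                continue
            try:
                log.info("analyze single-class cell %s d=%g", cls, dens)
                model = _model_for(cfg, {cls: ds}, selections)
                res = model.fit(cfg.master_seed)
                parts = [res.table]
                if specs and dens == cfg.perturb_density_of(cls) and (
                    cfg.perturb_classes is None or cls in cfg.perturb_classes
                ):
                    feats = [
                        f for f in (cfg.perturb_features or model.features)
                        if f in model.features
                    ]
                    for spec in specs:
                        parts.append(res.evaluate_perturbation(spec, classes=[cls], features=feats))
                _write_info_csv(pd.concat(parts, ignore_index=True), cell_path)
            except Exception:
                log.exception("cell single %s d=%g failed; skipping", cls, dens)

    if cfg.combo_densities and len(sims) > 1:
        combo_path = cells_dir / "combo.csv"
        comp_path = cells_dir / "combo_complementarity.csv"
        if not (resume and combo_path.exists() and comp_path.exists()):
            try:
                log.info("analyze combined-class cell at %s", cfg.combo_densities)
                datasets = {c: sims[c][d] for c, d in cfg.combo_densities.items() if c in sims}
                model = _model_for(cfg, datasets, selections)
                res = model.fit(cfg.master_seed)
                _write_info_csv(res.table, combo_path)
                comp = res.complementarity()
                comp.sort_values(["feature", "reference_class", "instantiation"]).to_csv(
                    comp_path, index=False
                )
            except Exception:
                log.exception("combined-class cell failed; skipping")

    if cfg.compare_strategies:
        _strategy_cells(cfg, outdir, sims, selections, resume)

    _collect(cfg, outdir)
    if through in ("analyze",):
        return outdir

    # ---- report ------------------------------------------------------
    if through in ("all", "report"):
        report(outdir)
    return outdir


def _strategy_cells(cfg, outdir, sims, selections, resume) -> None:
    """Pairwise class cells at the strategy baseline density."""
    cells_dir = outdir / "cells"
    base = cfg.strategy_baseline
    classes = list(sims)
    for a, b in [(x, y) for i, x in enumerate(classes) for y in classes[i + 1:]]:
        path = cells_dir / f"pair_{a}_{b}_base{base:g}.csv"
        if resume and path.exists():
            continue
        try:
            datasets = {a: sims[a][base], b: sims[b][base]}
            model = _model_for(cfg, datasets, selections, class_sets=[(a, b)])
            res = model.fit(cfg.master_seed)
            _write_info_csv(res.table, path)
        except Exception:
            log.exception("strategy pair cell %s+%s failed; skipping", a, b)
    for cls in classes:
        for dens in (base, 2 * base):
            path = cells_dir / f"single_{_cell_name(cls, dens)}.csv"
            if resume and path.exists():
                continue
            try:
                model = _model_for(cfg, {cls: sims[cls][dens]}, selections)
                res = model.fit(cfg.master_seed)
                _write_info_csv(res.table, path)
            except Exception:
                log.exception("strategy single cell %s d=%g failed; skipping", cls, dens)


def _collect(cfg: ExperimentConfig, outdir: Path) -> None:
    """Merge per-cell CSVs into info.csv / complementarity.csv / summary.json."""
    cells = sorted((outdir / "cells").glob("*.csv"))
    info_parts = []
    comp = None
    for p in cells:
        if p.name == "combo_complementarity.csv":
            comp = pd.read_csv(p)
        else:
            info_parts.append(pd.read_csv(p))
    if not info_parts:
        return
    info = pd.concat(info_parts, ignore_index=True)
    info = info.drop_duplicates(subset=_INFO_COLUMNS[:6]).reset_index(drop=True)
    _write_info_csv(info, outdir / "info.csv")
    if comp is not None:
        comp.to_csv(outdir / "complementarity.csv", index=False)

    summary: dict = {"saturation_densities": {}, "strategies": {}}
    singles = info[(info.perturbation == "none") & info.density.notna()]
    for (feature, cls), sub in singles.groupby(["feature", "class_set"]):
        if "+" in cls:
            continue
        g = sub.groupby("density").I_bits.agg(["mean", lambda s: s.std(ddof=0)])
        g.columns = ["mean", "sd"]
        g = g.sort_index()
        grid = [d for d in g.index if d in cfg.densities.get(cls, ())]
        if len(grid) >= 3:
            curve = InfoCurve(
                feature, cls,
                np.array(grid), g.loc[grid, "mean"].values, g.loc[grid, "sd"].values,
                n_outcomes=int(sub.n_outcomes.iloc[0]),
            )
            summary["saturation_densities"].setdefault(feature, {})[cls] = saturation_density(curve)
    if cfg.compare_strategies:
        summary["strategies"] = _strategy_verdicts(cfg, info)
    if comp is not None and not comp.empty:
        fr = comp.groupby(["feature", "reference_class"]).comp_fraction.mean()
        summary["mean_complementary_fraction"] = {
            f"{f}/{c}": (None if pd.isna(v) else round(float(v), 6)) for (f, c), v in fr.items()
        }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))


def _strategy_verdicts(cfg: ExperimentConfig, info: pd.DataFrame) -> dict:
    base = cfg.strategy_baseline
    out = {}
    none = info[info.perturbation == "none"]
    for feature in none.feature.unique():
        sub = none[none.feature == feature]
        singles_base = {
            r.class_set: r.I_bits
            for _, r in sub[(sub.density == base)].groupby("class_set").I_bits.mean().reset_index().iterrows()
        }
        singles_base = {c: v for c, v in singles_base.items() if "+" not in c}
        if not singles_base:
            continue
        most = max(singles_base, key=lambda c: (singles_base[c], c))
        doubled = sub[(sub.class_set == most) & (sub.density == 2 * base)].I_bits.mean()
        pairs = {}
        for other in singles_base:
            if other == most:
                continue
            names = {f"{most}+{other}", f"{other}+{most}"}
            pr = sub[sub.class_set.isin(names) & (sub.densities.str.contains(f":{base:g}"))]
            if not pr.empty:
                pairs[other] = float(pr.I_bits.mean())
        if np.isnan(doubled) or not pairs:
            continue
        v = compare_strategies(feature, base, singles_base[most], float(doubled), pairs, most)
        out[feature] = {
            "most_informative": v.most_informative,
            "gain_double": round(v.gain_double, 6),
            "gains_add": {c: round(g, 6) for c, g in v.gains_add.items()},
            "verdict": v.describe(),
        }
    return out


# ----------------------------------------------------------------------
# reporting


def report(outdir: str | Path) -> list[Path]:
    """Render figures and tables from a completed run archive."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    info_path = outdir / "info.csv"
    if not info_path.exists():
        raise FileNotFoundError(f"{info_path} not found; run the analysis first")
    info = pd.read_csv(info_path)
    rep = outdir / "report"
    rep.mkdir(exist_ok=True)
    made: list[Path] = []

    summary = {}
    if (outdir / "summary.json").exists():
        summary = json.loads((outdir / "summary.json").read_text())

    # info vs density curves
    singles = info[(info.perturbation == "none") & info.density.notna()]
    singles = singles[~singles.class_set.str.contains("\\+")]
    features = sorted(singles.feature.unique())
    if features:
        fig, axes = plt.subplots(1, len(features), figsize=(4 * len(features), 3.2), squeeze=False)
        for ax, feature in zip(axes[0], features):
            sub = singles[singles.feature == feature]
            for cls, g in sub.groupby("class_set"):
                agg = g.groupby("density").I_norm.agg(["mean", "std"]).sort_index()
                ax.errorbar(agg.index, agg["mean"], yerr=agg["std"].fillna(0), label=cls, marker="o")
                sat = summary.get("saturation_densities", {}).get(feature, {}).get(cls)
                if sat is not None:
                    ax.axvline(sat, ls=":", alpha=0.4)
            ax.set_xscale("log")
            ax.set_title(feature)
            ax.set_xlabel("density (afferents/cm$^2$)")
            ax.set_ylabel("I / H(S)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        p = rep / "info_vs_density.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        made.append(p)

    # complementarity fractions
    comp_path = outdir / "complementarity.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        if not comp.empty:
            fig, ax = plt.subplots(figsize=(6, 3.2))
            piv = comp.groupby(["feature", "reference_class"]).comp_fraction.mean().unstack()
            piv.plot.bar(ax=ax)
            ax.set_ylabel("complementary fraction of class info")
            ax.set_ylim(0, 1)
            fig.tight_layout()
            p = rep / "complementarity.png"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            made.append(p)

    # perturbation losses
    pert = info[info.perturbation != "none"]
    if not pert.empty:
        rows = []
        for (feature, cls, tag), g in pert.groupby(["feature", "class_set", "perturbation"]):
            base = info[
                (info.feature == feature) & (info.class_set == cls)
                & (info.perturbation == "none") & (info.densities == g.densities.iloc[0])
            ]
            if base.empty or base.I_bits.mean() <= 0:
                continue
            rows.append(
                {
                    "feature": feature,
                    "class_set": cls,
                    "perturbation": tag,
                    "relative_loss": 1 - g.I_bits.mean() / base.I_bits.mean(),
                }
            )
        if rows:
            loss = pd.DataFrame(rows)
            loss.to_csv(rep / "perturbation_losses.csv", index=False)
            fig, axes = plt.subplots(
                1, loss.feature.nunique(), figsize=(4 * loss.feature.nunique(), 3.2), squeeze=False
            )
            for ax, (feature, g) in zip(axes[0], loss.groupby("feature")):
                piv = g.pivot(index="class_set", columns="perturbation", values="relative_loss")
                piv.plot.bar(ax=ax)
                ax.set_title(feature)
                ax.set_ylabel("information loss (fraction)")
            fig.tight_layout()
            p = rep / "perturbation_losses.png"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            made.append(p)

    # strategy table
    if summary.get("strategies"):
        rows = [
            {"feature": f, **{k: v for k, v in d.items() if k != "gains_add"}}
            for f, d in summary["strategies"].items()
        ]
        pd.DataFrame(rows).to_csv(rep / "strategies.csv", index=False)
        made.append(rep / "strategies.csv")
    return made
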