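"""Confusion-matrix mutual information and its decomposition across classes.

The plugin estimate

    I(S; S_hat) = sum_{s, s_hat} p(s, s_hat) log2[ p(s, s_hat) / (p(s) p(s_hat)) ]

computed from the decoder's empirical confusion matrix is a data-robust lower
bound on the information the population activity carries about the stimulus;
it is reported both in bits and normalized by the stimulus entropy
H(S) = log2(S_n). No bias correction is applied: compressing responses to a
single decoded label per trial is itself the bias-control strategy.

Complementary information of a reference class-set is the gain from adding it
to the remaining classes; redundant information is the overlap, and the two
sum exactly to the reference class's own information:

    I_comp(S, ref) = I(S, all) - I(S, others)
    I_red(S, ref)  = I(S, ref) + I(S, others) - I(S, all)
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .decoding import ConfusionMatrix

__all__ = [
    "InfoResult",
    "InfoCurve",
    "StrategyVerdict",
    "mutual_information",
    "stimulus_entropy",
    "complementary_information",
    "redundant_information",
    "saturation_density",
    "compare_strategies",
]


@dataclass
class InfoResult:
    """Mutual information for one (feature, class-set, density) combination."""

    feature: str
    class_set: tuple[str, ...]
    density: float | dict[str, float] | None
    I_bits: float
    n_outcomes: int
    perturbation: str = "none"
    instantiation: int | None = None

    @property
    def I_normalized(self) -> float:
        return self.I_bits / stimulus_entropy(self.n_outcomes)


def mutual_information(cm: ConfusionMatrix | np.ndarray) -> float:
    """Plugin MI (bits) between presented and decoded stimulus labels."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm, dtype=float)
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p = counts / total
    ps = p.sum(axis=1, keepdims=True)
    ps_hat = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / (ps * ps_hat)
        terms = np.where(p > 0, p * np.log2(ratio), 0.0)
    return float(terms.sum())


def stimulus_entropy(S_n: int) -> float:
    """H(S) = log2(S_n) bits for S_n equiprobable stimulus values."""
    if S_n < 2:
        raise ValueError("need at least 2 stimulus values")
    return float(np.log2(S_n))


def complementary_information(I_all: float, I_others: float) -> float:
    """Information the reference class adds beyond the remaining classes."""
    return I_all - I_others


def redundant_information(I_ref: float, I_others: float, I_all: float) -> float:
    """Overlap between the reference class's information and the others'.

    Satisfies ``complementary + redundant == I_ref`` exactly.
    """
    return I_ref + I_others - I_all


@dataclass
class InfoCurve:
    """Information as a function of innervation density for one feature/class."""

    feature: str
    class_label: str
    densities: np.ndarray
    mean_info: np.ndarray
    sd_info: np.ndarray | None = None
    n_outcomes: int | None = None

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.mean_info = np.asarray(self.mean_info, dtype=float)
        if self.sd_info is not None:
            self.sd_info = np.asarray(self.sd_info, dtype=float)
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")

    @property
    def asymptote(self) -> float:
        return float(self.mean_info[-1])


def saturation_density(curve: InfoCurve, tolerance: float | None = None) -> float:
    """Smallest density whose information reaches the high-density asymptote.

    The asymptote is the mean information at the highest density. If no
    tolerance is given it defaults to max(SD across NMF instantiations at the
    top density, 2% of the stimulus entropy) — the curve must then carry
    ``sd_info`` or ``n_outcomes``. Returns the top density when no earlier
    point qualifies.
    """
    if curve.densities.size < 3:
        raise ValueError("need at least 3 densities to define a saturation point")
    if tolerance is None:
        candidates = []
        if curve.sd_info is not None:
            candidates.append(float(curve.sd_info[-1]))
        if curve.n_outcomes is not None:
            candidates.append(0.02 * stimulus_entropy(curve.n_outcomes))
        if not candidates:
            raise ValueError("tolerance not given and curve has no sd_info/n_outcomes")
        tolerance = max(candidates)
    target = curve.asymptote - tolerance
    for d, i in zip(curve.densities, curve.mean_info):
        if i >= target:
            return float(d)
    return float(curve.densities[-1])


@dataclass
class StrategyVerdict:
    """Outcome of the double-density vs add-a-class comparison for a feature."""

    feature: str
    most_informative: str
    baseline_density: float
    I_baseline: float
    gain_double: float
    gains_add: dict[str, float]
    winner: str
    tie: bool = False

    def describe(self) -> str:
        if self.tie:
            return f"{self.feature}: tie between strategies"
        if self.winner == "double":
            return f"{self.feature}: increase density of {self.most_informative} population"
        return f"{self.feature}: add {self.winner} population"


def compare_strategies(
    feature: str,
    baseline_density: float,
    I_baseline: float,
    I_doubled: float,
    I_combined: dict[str, float],
    most_informative: str,
    tie_tol: float = 1e-12,
) -> StrategyVerdict:
    """Compare information gains: doubling density vs adding another class.

    ``I_baseline`` is the most informative class at the baseline density,
    ``I_doubled`` the same class at twice the baseline, and ``I_combined``
    maps each other class label to the joint information of (most informative
    at baseline + that class at baseline).
    """
    gain_double = I_doubled - I_baseline
    gains_add = {cls: I - I_baseline for cls, I in I_combined.items()}
    best_add_cls = min(gains_add, key=lambda c: (-gains_add[c], c))
    best_add = gains_add[best_add_cls]
    if abs(best_add - gain_double) <= tie_tol:
        winner, tie = "tie", True
    elif gain_double > best_add:
        winner, tie = "double", False
    else:
        winner, tie = best_add_cls, False
    return StrategyVerdict(
        feature=feature,
        most_informative=most_informative,
        baseline_density=baseline_density,
        I_baseline=I_baseline,
        gain_double=gain_double,
        gains_add=gains_add,
        winner=winner,
        tie=tie,
    )
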