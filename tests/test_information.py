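"""Mutual information, its decomposition, saturation and strategy comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from popcode.information import (
    InfoCurve,
    compare_strategies,
    complementary_information,
    mutual_information,
    redundant_information,
    saturation_density,
    stimulus_entropy,
)


def _plugin_mi_oracle(counts):
    """Independent direct evaluation of the plugin MI sum (base 2)."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    I = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / total
            if p > 0:
                ps = counts[i].sum() / total
                psh = counts[:, j].sum() / total
                I += p * np.log2(p / (ps * psh))
    return I


class TestMutualInformation:
    def test_perfect_decoding_reaches_stimulus_entropy(self):
        assert mutual_information(np.eye(4) * 25) == pytest.approx(2.0, abs=1e-12)

    def test_independent_rows_carry_zero_information(self):
        cm = np.outer([10, 30], [5, 15])
        assert mutual_information(cm) == pytest.approx(0.0, abs=1e-12)

    def test_mixed_two_by_two_matches_hand_oracle(self):
        cm = np.array([[30, 10], [10, 30]])
        assert mutual_information(cm) == pytest.approx(_plugin_mi_oracle(cm), abs=1e-12)
        assert mutual_information(cm) == pytest.approx(0.18872, abs=1e-4)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros((3, 3)))

    @given(
        arrays(np.int64, (4, 4), elements=st.integers(0, 50)).filter(lambda a: a.sum() > 0)
    )
    def test_plugin_mi_bounded_by_entropy_and_matches_oracle(self, counts):
        I = mutual_information(counts)
        assert -1e-9 <= I <= np.log2(4) + 1e-9
        assert I == pytest.approx(_plugin_mi_oracle(counts), abs=1e-9)


class TestEntropy:
    @pytest.mark.parametrize("n,expected", [(4, 2.0), (10, np.log2(10)), (5, np.log2(5))])
    def test_equiprobable_entropy(self, n, expected):
        assert stimulus_entropy(n) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_outcome_count_rejected(self):
        with pytest.raises(ValueError):
            stimulus_entropy(1)


class TestDecomposition:
    def test_complementary_is_joint_minus_others(self):
        assert complementary_information(1.2, 0.9) == pytest.approx(0.3)
        assert complementary_information(1.0, 1.0) == 0.0

    def test_redundant_example(self):
        assert redundant_information(0.5, 0.8, 1.0) == pytest.approx(0.3)
        assert redundant_information(0.4, 0.6, 1.0) == pytest.approx(0.0)

    @given(
        st.floats(0, 3, allow_nan=False),
        st.floats(0, 3, allow_nan=False),
        st.floats(0, 3, allow_nan=False),
    )
    def test_complementary_plus_redundant_equals_reference(self, i_ref, i_others, i_all):
        comp = complementary_information(i_all, i_others)
        red = redundant_information(i_ref, i_others, i_all)
        assert comp + red == pytest.approx(i_ref, abs=1e-12)


class TestSaturation:
    def test_example_curve_saturates_at_ten(self):
        curve = InfoCurve("size", "SA1", [1, 5, 10, 20, 40], [0.2, 0.5, 0.79, 0.80, 0.80])
        assert saturation_density(curve, tolerance=0.02) == 10

    def test_flat_curve_saturates_at_lowest_density(self):
        curve = InfoCurve("size", "PC", [1, 5, 10], [0.5, 0.5, 0.5])
        assert saturation_density(curve, tolerance=0.01) == 1

    def test_strictly_increasing_curve_saturates_at_top(self):
        curve = InfoCurve("size", "SA1", [1, 5, 10], [0.1, 0.4, 0.9])
        assert saturation_density(curve, tolerance=0.01) == 10

    def test_default_tolerance_uses_dispersion_and_entropy(self):
        curve = InfoCurve(
            "size", "SA1", [1, 5, 10], [0.75, 0.78, 0.80],
            sd_info=[0.01, 0.01, 0.05], n_outcomes=4,
        )
        # tolerance = max(0.05, 0.02*2 bits) = 0.05 -> first density qualifies
        assert saturation_density(curve) == 1

    def test_too_few_densities_rejected(self):
        curve = InfoCurve("size", "SA1", [1, 5], [0.2, 0.4])
        with pytest.raises(ValueError):
            saturation_density(curve, tolerance=0.01)

    def test_non_increasing_densities_rejected(self):
        with pytest.raises(ValueError):
            InfoCurve("size", "SA1", [5, 1, 10], [0.1, 0.2, 0.3])


class TestStrategies:
    def test_adding_a_class_wins_when_gain_larger(self):
        v = compare_strategies(
            "frequency", 10.0, I_baseline=1.0, I_doubled=1.1,
            I_combined={"SA1": 1.3, "RA": 1.2}, most_informative="PC",
        )
        assert v.winner == "SA1" and not v.tie
        assert "add SA1" in v.describe()

    def test_doubling_wins_for_spatial_feature(self):
        v = compare_strategies(
            "size", 10.0, I_baseline=1.0, I_doubled=1.5,
            I_combined={"RA": 1.2}, most_informative="SA1",
        )
        assert v.winner == "double"
        assert "increase density of SA1" in v.describe()

    def test_equal_gains_reported_as_tie(self):
        v = compare_strategies(
            "size", 10.0, I_baseline=1.0, I_doubled=1.2,
            I_combined={"RA": 1.2}, most_informative="SA1",
        )
        assert v.tie
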