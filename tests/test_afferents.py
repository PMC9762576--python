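"""Afferent placement, drive computation and spike generation."""

import numpy as np
import pytest

from popcode.afferents import (
    DEFAULT_CLASS_PARAMS,
    drive,
    generate_spikes,
    place_population,
    simulate_dataset,
)
from popcode.stimuli import MotorNoiseSpec, StimulusFeatures, build_design, render_trial


def _trace(size=2.0, amp=0.6, ramp=0.03, freq=0.0, seed=0, noise=None):
    return render_trial(
        StimulusFeatures(size, amp, ramp, freq), noise or MotorNoiseSpec.zero(), rng=seed
    )


class TestPlacement:
    @pytest.mark.parametrize(
        "cls,density,expected_n,expected_len",
        [("SA1", 30.0, 30, 1.0), ("PC", 10.0, 50, 5.0), ("RA", 1.0, 1, 1.0)],
    )
    def test_strip_convention_count(self, cls, density, expected_n, expected_len):
        pop = place_population(cls, density, seed=0)
        assert pop.n_afferents == expected_n
        assert pop.line_length_cm == expected_len
        assert pop.positions_cm.min() >= 0
        assert pop.positions_cm.max() <= pop.line_length_cm

    def test_positions_roughly_even_with_bounded_dither(self):
        pop = place_population("SA1", 20.0, seed=1)
        spacing = 1.0 / 20
        centers = (np.arange(20) + 0.5) * spacing
        assert np.abs(pop.positions_cm - centers).max() < 0.25 * spacing + 1e-12

    @pytest.mark.parametrize("density", [0.5, 150.0])
    def test_density_outside_range_rejected(self, density):
        with pytest.raises(ValueError):
            place_population("SA1", density)


class TestDrive:
    def test_ra_has_no_static_response_during_hold(self):
        pop = place_population("RA", 10.0, seed=0)
        d = drive(pop, DEFAULT_CLASS_PARAMS["RA"], _trace(freq=0.0))
        hold = d[:, 1000:4000]  # 0.1-0.4 s
        assert hold.max() < 0.05 * d.max()

    def test_pc_ignores_static_depth(self):
        pop = place_population("PC", 5.0, seed=0)
        lo = drive(pop, DEFAULT_CLASS_PARAMS["PC"], _trace(amp=0.3, freq=0.0))
        hi = drive(pop, DEFAULT_CLASS_PARAMS["PC"], _trace(amp=1.2, freq=0.0))
        # static depth quadrupled; PC hold drive stays ~0 either way
        assert lo[:, 1000:4000].max() < 1e-6
        assert hi[:, 1000:4000].max() < 1e-6

    def test_pc_drive_independent_of_probe_size(self):
        pop = place_population("PC", 5.0, seed=0)
        d1 = drive(pop, DEFAULT_CLASS_PARAMS["PC"], _trace(size=1.0, freq=80.0))
        d4 = drive(pop, DEFAULT_CLASS_PARAMS["PC"], _trace(size=4.0, freq=80.0))
        assert np.array_equal(d1, d4)

    def test_sa1_recruitment_grows_with_probe_size(self):
        pop = place_population("SA1", 30.0, seed=0)
        p = DEFAULT_CLASS_PARAMS["SA1"]
        d1 = drive(pop, p, _trace(size=1.0)).mean(axis=1)
        d4 = drive(pop, p, _trace(size=4.0)).mean(axis=1)
        assert (d4 >= d1 - 1e-12).all() and d4.sum() > d1.sum()

    def test_drive_non_negative(self):
        for cls in ("SA1", "RA", "PC"):
            pop = place_population(cls, 5.0, seed=0)
            d = drive(pop, DEFAULT_CLASS_PARAMS[cls], _trace(freq=120.0))
            assert (d >= 0).all()


class TestSpikes:
    def test_zero_drive_produces_no_spikes(self):
        out = generate_spikes(np.zeros(5000), DEFAULT_CLASS_PARAMS["PC"], 1e-4, seed=0)
        assert out.size == 0

    def test_pc_phase_locks_to_strong_200hz_drive(self):
        # one rectified lobe per cycle -> vector strength at 200 Hz
        t = np.arange(0, 0.5, 1e-4)
        drive_arr = 3.0 * np.clip(np.sin(2 * np.pi * 200 * t), 0, None)
        spikes = generate_spikes(drive_arr, DEFAULT_CLASS_PARAMS["PC"], 1e-4, seed=0)
        assert spikes.size > 20
        phases = 2 * np.pi * 200 * spikes
        vs = np.abs(np.mean(np.exp(1j * phases)))
        assert vs > 0.8

    def test_sa1_sustained_firing_is_regular(self):
        drive_arr = np.full(5000, 1.5)
        spikes = generate_spikes(drive_arr, DEFAULT_CLASS_PARAMS["SA1"], 1e-4, seed=0)
        assert spikes.size > 10
        isi = np.diff(spikes)
        assert isi.std() / isi.mean() < 1.0  # CV of ISI below Poisson

    def test_refractory_period_respected(self):
        drive_arr = np.full(5000, 50.0)
        for cls in ("SA1", "RA", "PC"):
            p = DEFAULT_CLASS_PARAMS[cls]
            spikes = generate_spikes(drive_arr, p, 1e-4, seed=3)
            assert np.diff(spikes).min() >= p.refractory_s - 1e-12

    def test_same_seed_same_spikes(self):
        rng_drive = np.random.default_rng(0).uniform(0, 2, size=(3, 5000))
        a = generate_spikes(rng_drive, DEFAULT_CLASS_PARAMS["RA"], 1e-4, seed=9)
        b = generate_spikes(rng_drive, DEFAULT_CLASS_PARAMS["RA"], 1e-4, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes(np.full(100, -1.0), DEFAULT_CLASS_PARAMS["RA"], 1e-4)


class TestSimulateDataset:
    @pytest.fixture(scope="class")
    def tiny(self):
        design = build_design((1.0, 4.0), (0.6,), (0.03,), (0.0, 120.0))
        pops = [
            (place_population("SA1", 5.0, seed=0), DEFAULT_CLASS_PARAMS["SA1"]),
            (place_population("PC", 1.0, seed=0), DEFAULT_CLASS_PARAMS["PC"]),
        ]
        return design, simulate_dataset(design, pops, 3, MotorNoiseSpec(), master_seed=5)

    def test_trial_count_and_labels(self, tiny):
        design, out = tiny
        ds = out["SA1"]
        assert ds.n_trials == len(design) * 3
        assert (ds.labels.groupby("condition_id").size() == 3).all()

    def test_spike_times_sorted_within_window_and_refractory(self, tiny):
        _, out = tiny
        for ds in out.values():
            assert ds.times.min() >= 0 if ds.times.size else True
            assert ds.times.max() <= ds.duration_s + 1e-12 if ds.times.size else True
            p = DEFAULT_CLASS_PARAMS[ds.class_label]
            for trial in (0, 5):
                for aff in range(ds.n_afferents):
                    st = ds.spike_train(trial, aff)
                    if st.size > 1:
                        assert np.diff(st).min() >= p.refractory_s - 1e-12

    def test_rerun_is_bitwise_identical(self, tiny):
        design, out = tiny
        pops = [(place_population("SA1", 5.0, seed=0), DEFAULT_CLASS_PARAMS["SA1"])]
        again = simulate_dataset(design, pops, 3, MotorNoiseSpec(), master_seed=5)["SA1"]
        assert np.array_equal(again.times, out["SA1"].times)
        assert np.array_equal(again.trial_idx, out["SA1"].trial_idx)

    def test_pc_rasters_identical_across_probe_sizes(self, tiny):
        _, out = tiny
        ds = out["PC"]
        lab = ds.labels
        for freq in lab.frequency_hz.unique():
            a_trials = lab[(lab.size_mm == 1.0) & (lab.frequency_hz == freq)].trial.values
            b_trials = lab[(lab.size_mm == 4.0) & (lab.frequency_hz == freq)].trial.values
            for ta, tb in zip(a_trials, b_trials):
                for aff in range(ds.n_afferents):
                    assert np.array_equal(ds.spike_train(ta, aff), ds.spike_train(tb, aff))

    def test_pc_rate_increases_with_frequency(self, tiny):
        _, out = tiny
        ds = out["PC"]
        lab = ds.labels
        def mean_count(freq):
            trials = set(lab[lab.frequency_hz == freq].trial)
            return sum(np.isin(ds.trial_idx, list(trials))) / max(len(trials), 1)
        assert mean_count(120.0) > mean_count(0.0) + 10

    def test_npz_roundtrip(self, tiny, tmp_path):
        _, out = tiny
        ds = out["SA1"]
        path = tmp_path / "ds.npz"
        ds.to_npz(path)
        back = type(ds).from_npz(path)
        assert np.array_equal(back.times, ds.times)
        assert back.labels.equals(ds.labels)
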