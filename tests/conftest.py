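import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popcode.pipeline import desk_profile, micro_profile, run_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MASTER_SEED = 1


@pytest.fixture(scope="session")
def micro_run(tmp_path_factory):
    """A completed micro-scale experiment archive (seconds to run)."""
    out = tmp_path_factory.mktemp("micro_run")
    run_experiment(micro_profile(MASTER_SEED), out, through="analyze")
    return out


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """A completed desk-scale experiment archive (a few minutes to run).

    Desk conditions: full probe-size axis, two ramp amplitudes, vibration
    frequencies 0/80/120 Hz, 20 trials, two densities per class, five NMF
    instantiations, perturbations for size and frequency.
    """
    out = tmp_path_factory.mktemp("desk_run")
    run_experiment(desk_profile(MASTER_SEED), out, through="analyze")
    return out


@pytest.fixture(scope="session")
def fitted_micro_model():
    """A fitted PopulationCodingModel on micro-scale simulated data."""
    from popcode.model import PopulationCodingModel
    from popcode.pipeline import micro_profile
    from popcode.afferents import DEFAULT_CLASS_PARAMS, place_population, simulate_dataset

    cfg = micro_profile(MASTER_SEED)
    design = cfg.design()
    pops = [
        (place_population(cls, dens[0], seed=7), DEFAULT_CLASS_PARAMS[cls])
        for cls, dens in cfg.densities.items()
    ]
    datasets = simulate_dataset(
        design, pops, cfg.n_trials, cfg.noise(), cfg.master_seed, cfg.duration_s, cfg.dt_s
    )
    model = PopulationCodingModel(
        datasets, n_instantiations=1, k_max=4, features=["size", "frequency"]
    )
    return model.fit(MASTER_SEED)
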