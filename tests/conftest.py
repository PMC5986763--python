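"""Shared fixtures: a tiny fast world for unit tests and the full
scaled-down study (50 cells, 5 chains x 5,000 accepted per model) shared by
the acceptance tests so the expensive calibrations run once."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soilcarbon as sc
from soilcarbon.forcing import monthly_to_daily
from soilcarbon.synthetic import truth_vector

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# --- tiny world for unit tests ---------------------------------------------


@pytest.fixture(scope="session")
def tiny_config():
    return sc.SyntheticConfig(n_cells=8, spinup_years=3, scenario_years=2,
                              seed=1234)


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return sc.make_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_models(tiny_world):
    return sc.build_models(tiny_world)


@pytest.fixture(scope="session")
def column():
    return sc.column_layout()


# --- scaled-down study for the acceptance criteria --------------------------

STUDY_SEED = 3           # master calibration seed
MEMBER_SEED = 11         # posterior draw seed for the projection ensembles
N_ACCEPT = 5_000
BURN_IN = 500
N_CHAINS = 5
N_MEMBERS = 200


@pytest.fixture(scope="session")
def study_world():
    # warming-dominated scenario: +5 degC and -2 % litter per century, so the
    # conventional model's carbon loss is sign-definite for any Q10 >= 1
    return sc.make_world(sc.SyntheticConfig(litter_trend=-2.0))


@pytest.fixture(scope="session")
def study_models(study_world):
    return sc.build_models(study_world)


@pytest.fixture(scope="session")
def study_truths(study_world, study_models):
    return {kind: truth_vector(study_world, model)
            for kind, model in study_models.items()}


@pytest.fixture(scope="session")
def study_calibrations(study_world, study_models):
    """CalibrationResult per model kind at the recovery-study settings."""
    results = {}
    for kind, model in study_models.items():
        obs = sc.make_observations(study_world, model)
        results[kind] = sc.calibrate(model, obs, n_chains=N_CHAINS,
                                     n_accept=N_ACCEPT, burn_in=BURN_IN,
                                     seed=STUDY_SEED)
    return results


@pytest.fixture(scope="session")
def study_ensembles(study_world, study_models, study_calibrations):
    """200-member projection ensembles per model kind (spread/sensitivity)."""
    ensembles = {}
    for kind, model in study_models.items():
        thetas = sc.sample_posterior(study_calibrations[kind].posterior,
                                     n=N_MEMBERS, seed=MEMBER_SEED)
        scenario = study_world.scenario
        if kind == "mimics":
            scenario = monthly_to_daily(scenario)
        ensembles[kind] = sc.run_ensemble(model, thetas, scenario)
    return ensembles


@pytest.fixture(scope="session")
def constant_forcing_factory():
    """Build a constant (time-invariant) monthly ForcingSeries for n cells."""

    def build(n_cells=1, n_years=1, temperature=10.0, litter=400.0,
              water=0.8, oxygen=0.9, nitrogen=0.85, sand=0.4, clay=0.25,
              layer_temperature=None):
        months = n_years * 12
        column = sc.column_layout()
        time = (np.arange(months) + 0.5) / 12.0
        ones = np.ones((n_cells, months))
        t_col = temperature * ones
        if layer_temperature is None:
            t_layers = np.broadcast_to(
                t_col[:, None, :], (n_cells, column.n_layers, months)).copy()
        else:
            t_layers = np.asarray(layer_temperature) * np.ones(
                (n_cells, column.n_layers, months))
        return sc.ForcingSeries(
            time=time,
            temperature=t_col,
            temperature_layers=t_layers,
            water=water * ones,
            oxygen=oxygen * ones,
            nitrogen=nitrogen * ones,
            litter=litter * ones,
            sand=sand * np.ones(n_cells),
            clay=clay * np.ones(n_cells),
            resolution="monthly",
        )

    return build
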