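"""Synthetic world generator: grid, texture, forcing, biomass, observations.

Emulates the statistical structure of the study's global inputs at desk
scale: a latitudinal temperature gradient with a permafrost partition (the
coldest fraction of cells), spatially varying sand/clay texture, seasonal
soil temperature with depth-damped amplitude and an optional century-scale
warming trend, positive litter inputs with an optional trend, exogenous
water/oxygen/nitrogen scalars, a microbial biomass map, and log-normally
distributed pseudo-observations of steady-state soil carbon.

Everything is reproducible from a :class:`SyntheticConfig` and its seed;
downstream calibration and projection run end-to-end from this module's
output alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import SIGMA_FACTOR, ObservationSet, observation_layout
from .conventional import ConventionalModel
from .forcing import ForcingSeries
from .grid import N_LAYERS, Grid, column_layout
from .mimics import MimicsModel
from .vertical import VerticalModel

__all__ = ["SyntheticConfig", "World", "make_world", "make_observations",
           "build_models"]

_DAMPING_DEPTH = 1.5  # m; e-folding of the seasonal temperature wave


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Trends are per century: ``temperature_trend`` in degC/100yr applied
    linearly over the scenario, ``litter_trend`` in %/100yr.  ``noise_sd``
    is the log-space standard deviation of observation noise (smaller than
    the assumed observation sigma, keeping the likelihood conservative).
    """

    n_cells: int = 50
    permafrost_fraction: float = 0.25
    seed: int = 20_240_101
    noise_sd: float = 0.25
    spinup_years: int = 20
    scenario_years: int = 95  # 2005 -> 2100
    temperature_trend: float = 5.0   # degC per century (high-emission scenario)
    litter_trend: float = 5.0        # percent per century
    resolution: str = "monthly"
    truth: dict = field(default_factory=dict)  # model kind -> parameter vector

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if not np.isfinite(self.temperature_trend) or not np.isfinite(self.litter_trend):
            raise ValueError("trends must be finite")


@dataclass(frozen=True)
class World:
    """A generated study domain: grid + column + forcing + biomass."""

    grid: Grid
    column: object
    spinup: ForcingSeries
    scenario: ForcingSeries
    microbial_biomass: np.ndarray
    config: SyntheticConfig


def _layer_temperature(t_surface_mean, amplitude, frac_year, nodes, trend_per_year,
                       years_elapsed):
    """(cells, layers, time) soil temperature with depth damping and lag."""
    damp = np.exp(-nodes / _DAMPING_DEPTH)  # (L,)
    phase = 2.0 * np.pi * frac_year[None, None, :] - (nodes / _DAMPING_DEPTH)[None, :, None]
    seasonal = amplitude[:, None, None] * damp[None, :, None] * np.sin(phase)
    trend = trend_per_year * years_elapsed[None, None, :]
    return t_surface_mean[:, None, None] + seasonal + trend


def _forcing(cfg, rng, static, n_years, t0, trend_on, interannual_sd):
    """Assemble a monthly ForcingSeries for ``n_years`` starting at ``t0``."""
    n = cfg.n_cells
    months = n_years * 12
    time = t0 + (np.arange(months) + 0.5) / 12.0
    frac_year = (np.arange(months) % 12 + 0.5) / 12.0
    years_elapsed = (np.arange(months) + 0.5) / 12.0
    t_trend = (cfg.temperature_trend / 100.0) if trend_on else 0.0
    temp_layers = _layer_temperature(static["t_mean"], static["amplitude"],
                                     frac_year, static["nodes"], t_trend,
                                     years_elapsed)
    if interannual_sd > 0:
        # one anomaly per (cell, year), repeated over months and layers
        anom = rng.normal(0.0, interannual_sd, size=(n, n_years))
        temp_layers = temp_layers + np.repeat(anom, 12, axis=1)[:, None, :]
    w = static["thickness"] / static["thickness"].sum()
    temp_col = np.einsum("l,nlt->nt", w, temp_layers)
    litter = np.broadcast_to(static["litter"][:, None], (n, months)).copy()
    # mild litterfall seasonality with an exactly preserved annual mean
    litter = litter * (1.0 + 0.3 * np.sin(2.0 * np.pi * frac_year)[None, :])
    if trend_on and cfg.litter_trend != 0.0:
        litter = litter * (1.0 + cfg.litter_trend / 100.0 / 100.0 * years_elapsed)
    ones = np.ones((n, months))
    return ForcingSeries(
        time=time,
        temperature=temp_col,
        temperature_layers=temp_layers,
        water=static["water"][:, None] * ones,
        oxygen=static["oxygen"][:, None] * ones,
        nitrogen=static["nitrogen"][:, None] * ones,
        litter=litter,
        sand=static["sand"],
        clay=static["clay"],
        resolution="monthly",
    )


def make_world(cfg: SyntheticConfig) -> World:
    """Generate the full synthetic study domain, reproducible by seed.

    Permafrost cells are exactly ``floor(permafrost_fraction * n_cells)``
    coldest cells; temperatures carry a seasonal cycle (depth-damped for
    the layered fields) plus the configured linear century trend in the
    scenario window only.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    column = column_layout()

    latitude = np.sort(rng.uniform(5.0, 75.0, size=n))
    longitude = rng.uniform(-180.0, 180.0, size=n)
    area = 1e10 * rng.uniform(0.8, 1.2, size=n)
    t_mean = 28.0 - 0.55 * latitude + rng.normal(0.0, 1.5, size=n)
    n_pf = int(np.floor(cfg.permafrost_fraction * n))
    permafrost = np.zeros(n, dtype=bool)
    if n_pf > 0:
        permafrost[np.argsort(t_mean)[:n_pf]] = True
    grid = Grid(cell_ids=np.arange(n), latitude=latitude, longitude=longitude,
                area=area, land=np.ones(n, dtype=bool), permafrost=permafrost)

    sand = rng.uniform(0.1, 0.9, size=n)
    clay = (1.0 - sand) * rng.uniform(0.2, 0.6, size=n)
    static = {
        "t_mean": t_mean,
        "amplitude": 6.0 + 10.0 * latitude / 75.0,
        "litter": np.clip(150.0 + 18.0 * (t_mean + 12.0)
                          + rng.normal(0.0, 40.0, size=n), 80.0, None),
        "water": rng.uniform(0.45, 0.95, size=n),
        "oxygen": rng.uniform(0.75, 1.0, size=n),
        "nitrogen": rng.uniform(0.7, 1.0, size=n),
        "sand": sand,
        "clay": clay,
        "nodes": column.nodes,
        "thickness": column.thickness,
    }
    spinup = _forcing(cfg, rng, static, cfg.spinup_years, t0=1985.0,
                      trend_on=False, interannual_sd=0.4)
    scenario = _forcing(cfg, rng, static, cfg.scenario_years, t0=2005.0,
                        trend_on=True, interannual_sd=0.0)
    biomass = np.clip(80.0 + 0.35 * static["litter"]
                      + rng.normal(0.0, 10.0, size=n), 30.0, None)
    return World(grid=grid, column=column, spinup=spinup, scenario=scenario,
                 microbial_biomass=biomass, config=cfg)


def build_models(world: World) -> dict:
    """The three decomposition models bound to one synthetic world."""
    return {
        "conventional": ConventionalModel(world.grid, world.spinup),
        "vertical": VerticalModel(world.grid, world.spinup, world.column),
        "mimics": MimicsModel(world.grid, world.spinup, world.microbial_biomass),
    }


def truth_vector(world: World, model) -> np.ndarray:
    """The truth parameter vector for a model (configured or space default)."""
    theta = world.config.truth.get(model.kind)
    if theta is None:
        return model.space.defaults.copy()
    return model.space.validate(np.asarray(theta, dtype=float))


def make_observations(world: World, model, noise_sd=None, seed=None,
                      truth=None) -> ObservationSet:
    """Steady-state pseudo-observations under the truth parameters.

    Z = log(steady-state stock) + eps with eps ~ N(0, noise_sd); the assumed
    observation error follows the sigma = 0.5 * Z rule.  Raises if the
    truth parameters are infeasible, naming the offending cells.
    """
    cfg = world.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    seed = cfg.seed + 7 if seed is None else seed
    theta = truth_vector(world, model) if truth is None else model.space.validate(truth)
    preds = model.log_predicted_stocks(theta)
    if preds is None:
        raise ValueError(
            f"truth parameters infeasible for {model.kind} model "
            f"(check transfer fractions / quadratic roots on this world)")
    rng = np.random.default_rng(seed)
    z = preds + rng.normal(0.0, noise_sd, size=len(preds))
    sigma = SIGMA_FACTOR * z
    if np.any(sigma <= 0):
        bad = np.flatnonzero(sigma <= 0)
        raise ValueError(f"non-positive sigma for observation rows {bad.tolist()}")
    layout = observation_layout(model.kind, world.grid)
    return ObservationSet(
        cell_index=np.array([r[0] for r in layout]),
        z=z,
        sigma=sigma,
        interval=np.array([(r[1], r[2]) for r in layout]),
        source=tuple(r[3] for r in layout),
    )
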