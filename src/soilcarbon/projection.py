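"""Posterior-ensemble forward projection and sensitivity analysis.

Parameter sets drawn from the calibrated posterior each get a steady-state
initial condition S_i (under spin-up mean forcing) and a forward run
through the scenario forcing; the ensemble of annual global-total soil
carbon trajectories yields confidence-interval fans and Pearson
correlations of the outcomes (final stock and Delta C) against parameters
and initial conditions.

Reported soil carbon is the sum of the soil organic matter pools (the
microbial model's biomass pools are state variables but are not counted in
the soil C stock).  Global totals are sum(stock * area) in Pg C (1e15 g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "sample_posterior",
    "global_total",
    "cell_totals",
    "EnsembleRun",
    "run_ensemble",
    "ci_trajectory",
    "sensitivity_correlations",
]


def sample_posterior(archive, n=1000, seed=0, replace=True):
    """Draw ``n`` parameter vectors from the post-burn-in posterior.

    ``archive`` may be a ChainArchive, a CalibrationResult (chains pooled),
    or a plain (N, P) array.  Draws are uniform with replacement by
    default; without replacement and n equal to the archive length the
    result is a permutation.
    """
    if hasattr(archive, "posterior"):
        post = archive.posterior
    else:
        post = np.asarray(archive, dtype=float)
    if post.ndim != 2 or len(post) == 0:
        raise ValueError("posterior archive is empty or malformed")
    if not replace and n > len(post):
        raise ValueError("cannot draw more than the archive length without replacement")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(post), size=n, replace=replace)
    return post[idx]


def global_total(stocks, grid):
    """Global soil C in Pg from per-cell stocks (g C m-2) and cell areas."""
    stocks = np.asarray(stocks, dtype=float)
    area = np.asarray(grid.area, dtype=float)
    if stocks.shape[-1] != len(area):
        raise ValueError("stocks do not match the grid")
    if not np.all(np.isfinite(area)):
        raise ValueError("missing cell area")
    return stocks @ area * 1e-15


def cell_totals(model, states):
    """Per-cell soil C stock (g C m-2) from a model's state array.

    ``states`` has the model's trailing pool axes: (..., n, 3) conventional,
    (..., n, L, 3) vertical, (..., n, 5) microbial (SOM pools only counted).
    """
    if model.kind == "conventional":
        return states.sum(axis=-1)
    if model.kind == "vertical":
        return states.sum(axis=(-2, -1))
    if model.kind == "mimics":
        return states[..., :3].sum(axis=-1)
    raise ValueError(f"unknown model kind: {model.kind}")


@dataclass
class EnsembleRun:
    """One posterior member's projection."""

    member: int
    theta: np.ndarray
    si_total: float          # initial-condition global total, Pg C
    trajectory: np.ndarray   # annual global totals, Pg C (start year .. end year)
    valid: bool = True
    start_stocks: np.ndarray = None  # per-cell stocks at start, g C m-2
    end_stocks: np.ndarray = None    # per-cell stocks at the end year

    @property
    def delta_c(self) -> float:
        """C(end) - C(start), Pg C."""
        return float(self.trajectory[-1] - self.trajectory[0])


def run_ensemble(model, thetas, scenario, grid=None):
    """Project every parameter vector through the scenario forcing.

    Each member starts from its own steady state under the model's spin-up
    mean forcing; members whose steady state is infeasible, or whose run
    produces non-finite totals, are flagged invalid and excluded from the
    batched simulation (their trajectories are NaN).

    Returns a list of :class:`EnsembleRun`; the trajectory holds the initial
    total followed by year-end totals (96 values for a 95-year scenario).
    """
    grid = grid if grid is not None else model.grid
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    m = len(thetas)
    states0, valid = [], np.ones(m, dtype=bool)
    for i, theta in enumerate(thetas):
        x0 = model.try_steady_state(theta)
        if x0 is None:
            valid[i] = False
            logger.warning("member %d: infeasible steady state; excluded", i)
            states0.append(None)
        else:
            states0.append(x0)
    idx = np.flatnonzero(valid)
    n_years = round(scenario.n_steps * scenario.dt)
    n = grid.n_cells
    trajectories = np.full((m, n_years + 1), np.nan)
    stocks_start = np.full((m, n), np.nan)
    stocks_end = np.full((m, n), np.nan)
    if idx.size:
        x0 = np.stack([states0[i] for i in idx], axis=0)
        states = model.simulate_ensemble(thetas[idx], scenario, x0)
        per_cell = cell_totals(model, states)  # (m_valid, Y+1, n)
        totals = global_total(per_cell, grid)  # (m_valid, Y+1)
        blown = ~np.all(np.isfinite(totals), axis=1)
        if np.any(blown):
            for j in np.flatnonzero(blown):
                logger.warning("member %d: non-finite trajectory; excluded", idx[j])
            valid[idx[blown]] = False
        trajectories[idx] = totals
        stocks_start[idx] = per_cell[:, 0]
        stocks_end[idx] = per_cell[:, -1]
    runs = []
    for i, theta in enumerate(thetas):
        si = trajectories[i, 0] if valid[i] else np.nan
        runs.append(EnsembleRun(member=i, theta=theta, si_total=float(si),
                                trajectory=trajectories[i], valid=bool(valid[i]),
                                start_stocks=stocks_start[i],
                                end_stocks=stocks_end[i]))
    return runs


def ci_trajectory(runs, level=0.95):
    """Empirical (lower, median, upper) quantile trajectories across members.

    For the default level the bounds are the 2.5% and 97.5% quantiles per
    year.  Invalid members are excluded; at least two valid members are
    required.
    """
    traj = np.stack([r.trajectory for r in runs if r.valid], axis=0) \
        if any(r.valid for r in runs) else np.empty((0, 0))
    if len(traj) < 2:
        raise ValueError("need at least 2 valid ensemble members")
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(traj, alpha, axis=0)
    median = np.quantile(traj, 0.5, axis=0)
    upper = np.quantile(traj, 1.0 - alpha, axis=0)
    return lower, median, upper


def sensitivity_correlations(runs, param_names, include_si=True, extra=None):
    """Pearson correlations of parameters (and S_i) with projection outcomes.

    Returns a DataFrame indexed by regressor with columns ``final_c`` and
    ``delta_c``.  A regressor with zero variance across members yields NaN
    (marked undefined, not dropped).  ``extra`` maps extra regressor names
    to per-member arrays (e.g. a deliberately outcome-independent nuisance
    variable for null checks).
    """
    valid = [r for r in runs if r.valid]
    if len(valid) < 3:
        raise ValueError("need at least 3 valid ensemble members")
    thetas = np.stack([r.theta for r in valid], axis=0)
    final_c = np.array([r.trajectory[-1] for r in valid])
    delta_c = np.array([r.delta_c for r in valid])
    regressors = {name: thetas[:, i] for i, name in enumerate(param_names)}
    if include_si:
        regressors["S_i"] = np.array([r.si_total for r in valid])
    if extra:
        for name, values in extra.items():
            v = np.asarray(values, dtype=float)
            if len(v) == len(runs):
                v = v[[r.valid for r in runs]]
            regressors[name] = v

    def _corr(x, y):
        # a constant regressor can carry a rounding-level std; treat any
        # spread below machine precision of the values as zero variance
        def _degenerate(v):
            return np.std(v) <= 1e-12 * max(np.max(np.abs(v)), 1e-300)
        if _degenerate(x) or _degenerate(y):
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    rows = {name: {"final_c": _corr(x, final_c), "delta_c": _corr(x, delta_c)}
            for name, x in regressors.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
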