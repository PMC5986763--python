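"""Three-pool Century-type soil carbon model.

Pools: X1 (fast/labile), X2 (slow), X3 (passive), in g C m-2.  Dynamics

    X'(t) = R + F * xi(t) * K * X(t)

with litter input R (g C m-2 yr-1), transfer matrix F (diagonal -1,
off-diagonal transfer fractions f_ij from donor pool j to receiver i,
respired fraction 1 - sum_i f_ij), baseline turnover K = diag(k1, k2, k3)
(1/yr) and scalar environmental modifier xi (product of temperature, water,
oxygen and nitrogen scalars).  f21 depends on texture:
f21 = 1 - t - f31 with t = t1 - t2 * (1 - sand), sand as a fraction.

The analytic steady state is X_ss = -(F xi K)^{-1} R; time stepping is
explicit Euler at a monthly step with automatic sub-stepping when the
fastest turnover would make the step unstable.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import InfeasibleParameterError
from .grid import temperature_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "f21_fraction",
    "build_transfer_matrix",
    "conv_rhs",
    "conv_steady_state",
    "conv_step",
    "ConventionalModel",
]

N_POOLS = 3
_EULER_LIMIT = 0.5  # max xi*k*dt per explicit Euler substep


def f21_fraction(t1, t2, f31, sand):
    """Fast -> slow transfer fraction, f21 = 1 - (t1 - t2*(1 - sand)) - f31."""
    return 1.0 - (t1 - t2 * (1.0 - np.asarray(sand, dtype=float))) - f31


def build_transfer_matrix(p, sand):
    """Assemble the 3x3 transfer matrix F for one cell.

    ``p`` is a mapping with keys t1, t2, f31, f12, f32, f13.  Raises
    :class:`InfeasibleParameterError` when the derived f21 leaves [0, 1].
    """
    if not 0.0 <= sand <= 1.0:
        raise ValueError("sand fraction must lie in [0, 1]")
    f21 = float(f21_fraction(p["t1"], p["t2"], p["f31"], sand))
    if not 0.0 <= f21 <= 1.0:
        raise InfeasibleParameterError(f"f21 = {f21:.4f} outside [0, 1]")
    return np.array(
        [
            [-1.0, p["f12"], p["f13"]],
            [f21, -1.0, 0.0],
            [p["f31"], p["f32"], -1.0],
        ]
    )


def conv_rhs(x, r, f_matrix, k, xi):
    """Pool tendencies dX/dt = R + F (xi K X), g C m-2 yr-1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("pool carbon must be non-negative")
    if xi < 0:
        raise ValueError("environmental modifier must be non-negative")
    return np.asarray(r, dtype=float) + f_matrix @ (xi * np.asarray(k) * x)


def conv_steady_state(p, sand, k, xi, r):
    """Analytic steady state X_ss = -(F xi K)^{-1} R for one cell.

    Raises :class:`InfeasibleParameterError` for a singular system or a
    negative steady state.
    """
    f_matrix = build_transfer_matrix(p, sand)
    a = f_matrix * (xi * np.asarray(k, dtype=float))[None, :]
    try:
        x_ss = np.linalg.solve(a, -np.asarray(r, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise InfeasibleParameterError("singular steady-state system") from exc
    if np.any(x_ss < 0):
        raise InfeasibleParameterError("negative steady state")
    return x_ss


def conv_step(x, r, f_matrix, k, xi, dt=1.0 / 12.0):
    """Advance one explicit Euler step of length ``dt`` (years).

    Returns ``(x_next, respired)`` where ``respired`` is the heterotrophic
    respiration over the step, so that sum(x_next) - sum(x) equals
    dt*sum(r) - respired exactly (carbon balance).  Sub-steps automatically
    when xi*k*dt exceeds the stability guard; negative pools are clipped to
    zero with a logged warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float).copy()
    k = np.asarray(k, dtype=float)
    n_sub = max(1, math.ceil(float(np.max(xi * k)) * dt / _EULER_LIMIT))
    h = dt / n_sub
    resp_frac = -f_matrix.sum(axis=0)  # 1 - sum_i f_ij per donor pool
    respired = 0.0
    for _ in range(n_sub):
        flux = xi * k * x
        respired += h * float(resp_frac @ flux)
        x = x + h * (np.asarray(r, dtype=float) + f_matrix @ flux)
        if np.any(x < 0):
            logger.warning("negative pool clipped to zero in conv_step")
            x = np.clip(x, 0.0, None)
    return x, respired


class ConventionalModel:
    """Vectorized conventional model bound to a grid and spin-up forcing.

    The steady state uses the time-mean environmental modifier and litter
    input over the spin-up series; the modifier mean is recomputed per
    parameter vector because the temperature scalar depends on Q10.

    Parameters
    ----------
    grid : Grid
    spinup : ForcingSeries
        Climatological forcing used for steady-state (initial-condition)
        calculations.
    litter_split : length-3 fractions
        Allocation of total litter input among (fast, slow, passive); the
        default routes everything to the fast pool.
    """

    kind = "conventional"
    n_pools = N_POOLS

    def __init__(self, grid, spinup, litter_split=(1.0, 0.0, 0.0)):
        from .params import conventional_space

        split = np.asarray(litter_split, dtype=float)
        if split.shape != (3,) or np.any(split < 0) or not np.isclose(split.sum(), 1.0):
            raise ValueError("litter_split must be 3 non-negative fractions summing to 1")
        self.grid = grid
        self.space = conventional_space()
        self.litter_split = split
        self.sand = np.asarray(spinup.sand, dtype=float)
        # spin-up summaries reused by every likelihood evaluation
        self._t_spin = spinup.temperature  # (n, S)
        self._sc_spin = spinup.water * spinup.oxygen * spinup.nitrogen
        self._litter_mean = spinup.litter.mean(axis=1)  # (n,) g C m-2 yr-1

    # -- parameter unpacking -------------------------------------------------

    def _unpack(self, thetas):
        """Return parameters as (M, P) columns dict from (P,) or (M, P)."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return {name: thetas[:, i] for i, name in enumerate(self.space.names)}

    def transfer_matrices(self, thetas):
        """(M, n_cells, 3, 3) transfer matrices; infeasible f21 -> NaN rows."""
        p = self._unpack(thetas)
        m = p["t1"].shape[0]
        n = self.grid.n_cells
        f21 = f21_fraction(p["t1"][:, None], p["t2"][:, None],
                           p["f31"][:, None], self.sand[None, :])  # (M, n)
        f = np.zeros((m, n, 3, 3))
        f[..., 0, 0] = f[..., 1, 1] = f[..., 2, 2] = -1.0
        f[..., 0, 1] = p["f12"][:, None]
        f[..., 0, 2] = p["f13"][:, None]
        f[..., 1, 0] = f21
        f[..., 2, 0] = p["f31"][:, None]
        f[..., 2, 1] = p["f32"][:, None]
        bad = (f21 < 0) | (f21 > 1)
        if np.any(bad):
            f[bad] = np.nan
        return f

    def mean_xi(self, q10):
        """Time-mean environmental modifier per cell, shape (M, n_cells)."""
        q10 = np.atleast_1d(np.asarray(q10, dtype=float))
        ts = temperature_scalar(q10[:, None, None], self._t_spin[None, :, :])
        return (ts * self._sc_spin[None, :, :]).mean(axis=2)

    # -- steady state --------------------------------------------------------

    def steady_state(self, theta):
        """Steady-state pools (n_cells, 3) under spin-up mean forcing.

        Raises :class:`InfeasibleParameterError` if any cell is infeasible.
        """
        x = self.try_steady_state(theta)
        if x is None:
            raise InfeasibleParameterError("infeasible conventional steady state")
        return x

    def try_steady_state(self, theta):
        """As :meth:`steady_state` but returns None instead of raising."""
        p = self._unpack(theta)
        f = self.transfer_matrices(theta)[0]  # (n, 3, 3)
        if np.any(np.isnan(f)):
            return None
        k = np.stack([p["k1"], p["k2"], p["k3"]], axis=1)[0]  # (3,)
        xi = self.mean_xi(p["Q10"])[0]  # (n,)
        r = self._litter_mean[:, None] * self.litter_split[None, :]  # (n, 3)
        a = f * (xi[:, None, None] * k[None, None, :])
        try:
            x_ss = np.linalg.solve(a, -r[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(x_ss)) or np.any(x_ss < 0):
            return None
        return x_ss

    # -- observation mapping -------------------------------------------------

    def log_predicted_stocks(self, theta):
        """Natural log of the per-cell total stock, or None if infeasible.

        The conventional model has no depth axis: its total is compared
        against the 0-1 m aggregate in non-permafrost cells and the 0-3 m
        aggregate in permafrost cells.
        """
        x_ss = self.try_steady_state(theta)
        if x_ss is None:
            return None
        totals = x_ss.sum(axis=1)
        if np.any(totals <= 0):
            return None
        return np.log(totals)

    # -- forward simulation --------------------------------------------------

    def simulate_ensemble(self, thetas, forcing, x0):
        """Advance an ensemble through a forcing series; annual year-end states.

        Parameters
        ----------
        thetas : (M, P) parameter vectors
        forcing : ForcingSeries (monthly)
        x0 : (M, n_cells, 3) initial pools

        Returns
        -------
        states : (M, n_years + 1, n_cells, 3)
            ``states[:, 0]`` is the initial condition; subsequent entries are
            year-end states.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        p = self._unpack(thetas)
        m = thetas.shape[0]
        n = self.grid.n_cells
        dt = forcing.dt
        steps_per_year = round(1.0 / dt)
        n_years = forcing.n_steps // steps_per_year
        f = self.transfer_matrices(thetas)  # (M, n, 3, 3)
        if np.any(np.isnan(f)):
            raise InfeasibleParameterError("infeasible transfer fraction in ensemble")
        k = np.stack([p["k1"], p["k2"], p["k3"]], axis=1)  # (M, 3)
        q10 = p["Q10"]
        x = np.array(x0, dtype=float)
        if x.shape != (m, n, 3):
            raise ValueError(f"x0 must have shape {(m, n, 3)}")
        out = np.empty((m, n_years + 1, n, 3))
        out[:, 0] = x
        sc = forcing.water * forcing.oxygen * forcing.nitrogen  # (n, T)
        kmax = k.max()
        for t in range(forcing.n_steps):
            ts = temperature_scalar(q10[:, None], forcing.temperature[None, :, t])
            xi = ts * sc[None, :, t]  # (M, n)
            r = forcing.litter[:, t, None] * self.litter_split[None, :]  # (n, 3)
            n_sub = max(1, math.ceil(float(xi.max() * kmax) * dt / _EULER_LIMIT))
            h = dt / n_sub
            for _ in range(n_sub):
                flux = xi[..., None] * k[:, None, :] * x  # (M, n, 3)
                x = x + h * (r[None] + np.einsum("mnij,mnj->mni", f, flux))
            np.clip(x, 0.0, None, out=x)
            if (t + 1) % steps_per_year == 0:
                out[:, (t + 1) // steps_per_year] = x
        return out
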