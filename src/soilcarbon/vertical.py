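"""Vertically resolved soil carbon model (10 layers x 3 pools = 30 pools).

Within each layer the decomposition cascade is the conventional three-pool
model; layers exchange carbon by diffusion (cryoturbation in permafrost
soils), discretized as a finite-volume tridiagonal operator with zero-flux
top and bottom boundaries:

    X'(t) = R + F * xi(t) * K * X(t) + Tr * X(t)

State ordering is layer-major with the pool index fastest,
``[X_{1,1}, X_{2,1}, X_{3,1}, ..., X_{3,10}]`` (pool m, layer n).  Pools are
stored as per-layer mass (g C m-2); diffusion acts on concentration
(g C m-3), so the transport coefficients divide by layer thickness — with
unequal layers a mass-based operator would not conserve carbon.

The environmental modifier per layer multiplies the column scalars by a
depth attenuation r_z = exp(-z / z_t) evaluated at the layer node, with
e-folding depth z_t.  The analytic steady state is
X_ss = -(F xi K + Tr)^{-1} R.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import InfeasibleParameterError, InvalidParameterError
from .grid import N_LAYERS, temperature_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "depth_scalar",
    "build_transport_layers",
    "build_transport",
    "vert_rhs",
    "vert_steady_state",
    "aggregate_depth",
    "VerticalModel",
]

N_POOLS = 3
_EULER_LIMIT = 0.5


def depth_scalar(z, z_t):
    """Depth attenuation of decomposition, exp(-z / z_t), in (0, 1]."""
    if np.any(np.asarray(z_t) <= 0):
        raise InvalidParameterError("e-folding depth z_t must be positive")
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    return np.exp(-z / np.asarray(z_t, dtype=float))


def build_transport_layers(d, column):
    """Finite-volume diffusion operator between layers, shape (10, 10).

    Acts on the vector of per-layer masses of a single pool.  The exchange
    across the interface between layers i and i+1 moves mass at rate
    ``D / (dz_node * dz_layer)`` (dz_node = node distance), giving zero
    column sums (what leaves a layer arrives at its neighbours) and zero
    flux through the top and bottom boundaries.
    """
    if d < 0:
        raise ValueError("diffusivity must be non-negative")
    h = column.thickness
    dzn = np.diff(column.nodes)
    n = column.n_layers
    tr = np.zeros((n, n))
    for i in range(n - 1):
        down = d / (dzn[i] * h[i])      # leaves layer i toward i+1
        up = d / (dzn[i] * h[i + 1])    # leaves layer i+1 toward i
        tr[i, i] -= down
        tr[i + 1, i] += down
        tr[i + 1, i + 1] -= up
        tr[i, i + 1] += up
    return tr


def build_transport(d, column):
    """Block-tridiagonal 30x30 transport matrix (all three pools diffused)."""
    return np.kron(build_transport_layers(d, column), np.eye(N_POOLS))


def vert_rhs(x, r, f_layer, k, xi_layers, tr):
    """Tendencies dX/dt = R + F xi K X + Tr X on the 30-vector state.

    ``f_layer`` is the 3x3 within-layer transfer matrix (shared by all
    layers), ``xi_layers`` the per-layer environmental modifier (including
    the depth scalar), ``tr`` the 30x30 transport matrix.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_LAYERS * N_POOLS,):
        raise ValueError("state must be a 30-vector")
    if np.any(x < 0):
        raise ValueError("pool carbon must be non-negative")
    xl = x.reshape(N_LAYERS, N_POOLS)
    flux = np.asarray(xi_layers, dtype=float)[:, None] * np.asarray(k, dtype=float) * xl
    decomp = flux @ np.asarray(f_layer).T
    return np.asarray(r, dtype=float) + decomp.ravel() + tr @ x


def vert_steady_state(r, f_layer, k, xi_layers, tr):
    """Analytic steady state X_ss = -(F xi K + Tr)^{-1} R (30-vector).

    Raises :class:`InfeasibleParameterError` on a singular system or a
    negative solution.
    """
    xi_layers = np.asarray(xi_layers, dtype=float)
    k = np.asarray(k, dtype=float)
    blocks = xi_layers[:, None, None] * np.asarray(f_layer)[None] * k[None, None, :]
    a = np.zeros((N_LAYERS, N_POOLS, N_LAYERS, N_POOLS))
    idx = np.arange(N_LAYERS)
    a[idx, :, idx, :] = blocks
    a = a.reshape(N_LAYERS * N_POOLS, N_LAYERS * N_POOLS) + tr
    try:
        x_ss = np.linalg.solve(a, -np.asarray(r, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise InfeasibleParameterError("singular steady-state system") from exc
    if np.any(x_ss < 0):
        raise InfeasibleParameterError("negative steady state")
    return x_ss


def aggregate_depth(x, column, interval):
    """Total carbon (g C m-2) within a depth interval [top, bottom).

    ``x`` is the state as (10, 3) per-layer pool masses or a flat 30-vector.
    Layers partially covered by the interval are pro-rated by the thickness
    fraction inside it.  An interval that misses the column entirely returns
    zero with a warning.
    """
    top, bottom = interval
    x = np.asarray(x, dtype=float).reshape(N_LAYERS, N_POOLS)
    if top >= column.total_depth:
        logger.warning("depth interval %s does not intersect the column", interval)
        return 0.0
    w = column.layer_overlap(top, bottom)
    return float(w @ x.sum(axis=1))


class VerticalModel:
    """Vectorized vertically resolved model bound to a grid and forcing.

    Permafrost cells use diffusivity D2 throughout the column, others D1.
    Total litter input is distributed over layers proportionally to
    exp(-z_node / z_t) (re-using the e-folding depth) and routed to the fast
    pool by default.

    Observation aggregation: one 0-1 m value per non-permafrost cell; three
    independent values (0-1, 1-2, 2-3 m) per permafrost cell.
    """

    kind = "vertical"
    n_pools = N_POOLS

    INTERVALS_NONPF = ((0.0, 1.0),)
    INTERVALS_PF = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0))

    def __init__(self, grid, spinup, column, litter_split=(1.0, 0.0, 0.0)):
        from .params import vertical_space

        split = np.asarray(litter_split, dtype=float)
        if split.shape != (3,) or np.any(split < 0) or not np.isclose(split.sum(), 1.0):
            raise ValueError("litter_split must be 3 non-negative fractions summing to 1")
        self.grid = grid
        self.column = column
        self.space = vertical_space()
        self.litter_split = split
        self.sand = np.asarray(spinup.sand, dtype=float)
        self._t_spin = spinup.temperature_layers  # (n, L, S)
        self._sc_spin = spinup.water * spinup.oxygen  # (n, S); no nitrogen scalar
        self._litter_mean = spinup.litter.mean(axis=1)
        # unit-diffusivity transport (linear in D), as (10,10) layer operator
        self._tr_unit = build_transport_layers(1.0, column)
        self._tr_unit30 = np.kron(self._tr_unit, np.eye(N_POOLS))
        self._tr_rate_max = float(np.max(-np.diag(self._tr_unit)))

    # -- helpers -------------------------------------------------------------

    def _unpack(self, thetas):
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return {name: thetas[:, i] for i, name in enumerate(self.space.names)}

    def _f_matrices(self, p):
        """(M, n, 3, 3) within-layer transfer matrices; NaN marks infeasible."""
        from .conventional import f21_fraction

        m = p["t1"].shape[0]
        n = self.grid.n_cells
        f21 = f21_fraction(p["t1"][:, None], p["t2"][:, None],
                           p["f31"][:, None], self.sand[None, :])
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

    def _diffusivity(self, p):
        """(M, n) per-cell diffusivity: D2 in permafrost cells, else D1."""
        pf = np.asarray(self.grid.permafrost, dtype=bool)
        return np.where(pf[None, :], p["D2"][:, None], p["D1"][:, None])

    def _litter_profile(self, zt):
        """(M, L) normalized exp(-z/z_t) litter allocation over layers."""
        w = depth_scalar(self.column.nodes[None, :], np.atleast_1d(zt)[:, None])
        return w / w.sum(axis=1, keepdims=True)

    def mean_xi(self, q10, zt):
        """(M, n, L) time-mean modifier incl. the depth scalar at nodes."""
        q10 = np.atleast_1d(np.asarray(q10, dtype=float))
        ts = temperature_scalar(q10[:, None, None, None],
                                self._t_spin[None, :, :, :])  # (M, n, L, S)
        base = (ts * self._sc_spin[None, :, None, :]).mean(axis=3)
        rz = depth_scalar(self.column.nodes[None, :], np.atleast_1d(zt)[:, None])
        return base * rz[:, None, :]

    # -- steady state --------------------------------------------------------

    def try_steady_state(self, theta):
        """Per-cell steady state (n, L, 3) or None if infeasible."""
        p = self._unpack(theta)
        f = self._f_matrices(p)[0]  # (n, 3, 3)
        if np.any(np.isnan(f)):
            return None
        if p["zt"][0] <= 0:
            return None
        k = np.array([p["k1"][0], p["k2"][0], p["k3"][0]])
        xi = self.mean_xi(p["Q10"], p["zt"])[0]  # (n, L)
        d = self._diffusivity(p)[0]  # (n,)
        profile = self._litter_profile(p["zt"])[0]  # (L,)
        n = self.grid.n_cells
        r = (self._litter_mean[:, None, None] * profile[None, :, None]
             * self.litter_split[None, None, :])  # (n, L, 3)
        blocks = xi[:, :, None, None] * f[:, None, :, :] * k[None, None, None, :]
        a = np.zeros((n, N_LAYERS, N_POOLS, N_LAYERS, N_POOLS))
        idx = np.arange(N_LAYERS)
        a[:, idx, :, idx, :] = np.moveaxis(blocks, 1, 0)
        a = a.reshape(n, 30, 30)
        a += d[:, None, None] * self._tr_unit30[None]
        try:
            x_ss = np.linalg.solve(a, -r.reshape(n, 30)[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(x_ss)) or np.any(x_ss < 0):
            return None
        return x_ss.reshape(n, N_LAYERS, N_POOLS)

    def steady_state(self, theta):
        x = self.try_steady_state(theta)
        if x is None:
            raise InfeasibleParameterError("infeasible vertical steady state")
        return x

    # -- observation mapping -------------------------------------------------

    def observation_rows(self):
        """Ordered (cell_index, top, bottom) rows of the assimilation layout."""
        rows = []
        pf = np.asarray(self.grid.permafrost, dtype=bool)
        for c in range(self.grid.n_cells):
            for top, bottom in (self.INTERVALS_PF if pf[c] else self.INTERVALS_NONPF):
                rows.append((c, top, bottom))
        return rows

    def log_predicted_stocks(self, theta):
        """Log predicted stock per observation row, or None if infeasible."""
        x_ss = self.try_steady_state(theta)
        if x_ss is None:
            return None
        layer_totals = x_ss.sum(axis=2)  # (n, L)
        rows = self.observation_rows()
        preds = np.empty(len(rows))
        for i, (c, top, bottom) in enumerate(rows):
            w = self.column.layer_overlap(top, bottom)
            preds[i] = w @ layer_totals[c]
        if np.any(preds <= 0):
            return None
        return np.log(preds)

    # -- forward simulation --------------------------------------------------

    def simulate_ensemble(self, thetas, forcing, x0):
        """Advance an ensemble; returns (M, n_years + 1, n, L, 3) states."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        p = self._unpack(thetas)
        m = thetas.shape[0]
        n = self.grid.n_cells
        dt = forcing.dt
        steps_per_year = round(1.0 / dt)
        n_years = forcing.n_steps // steps_per_year
        f = self._f_matrices(p)  # (M, n, 3, 3)
        if np.any(np.isnan(f)):
            raise InfeasibleParameterError("infeasible transfer fraction in ensemble")
        k = np.stack([p["k1"], p["k2"], p["k3"]], axis=1)  # (M, 3)
        d = self._diffusivity(p)  # (M, n)
        rz = depth_scalar(self.column.nodes[None, :], p["zt"][:, None])  # (M, L)
        profile = self._litter_profile(p["zt"])  # (M, L)
        x = np.array(x0, dtype=float)
        if x.shape != (m, n, N_LAYERS, N_POOLS):
            raise ValueError(f"x0 must have shape {(m, n, N_LAYERS, N_POOLS)}")
        out = np.empty((m, n_years + 1, n, N_LAYERS, N_POOLS))
        out[:, 0] = x
        sc = forcing.water * forcing.oxygen  # (n, T)
        kmax = float(k.max())
        tr_rate = float(d.max()) * self._tr_rate_max
        for t in range(forcing.n_steps):
            ts = temperature_scalar(p["Q10"][:, None, None],
                                    forcing.temperature_layers[None, :, :, t])
            xi = ts * sc[None, :, None, t] * rz[:, None, :]  # (M, n, L)
            r = (forcing.litter[None, :, None, t] * profile[:, None, :])[..., None] \
                * self.litter_split  # (M, n, L, 3)
            n_sub = max(1, math.ceil((float(xi.max()) * kmax + tr_rate) * dt / _EULER_LIMIT))
            h = dt / n_sub
            for _ in range(n_sub):
                flux = xi[..., None] * k[:, None, None, :] * x  # (M, n, L, 3)
                decomp = np.einsum("mnij,mnlj->mnli", f, flux)
                transport = d[:, :, None, None] * np.einsum(
                    "lq,mnqp->mnlp", self._tr_unit, x)
                x = x + h * (r + decomp + transport)
            np.clip(x, 0.0, None, out=x)
            if (t + 1) % steps_per_year == 0:
                out[:, (t + 1) // steps_per_year] = x
        return out
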