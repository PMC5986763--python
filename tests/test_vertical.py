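"""Vertically resolved model: transport operator, steady state, aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import soilcarbon as sc
from soilcarbon.conventional import build_transfer_matrix, conv_steady_state
from soilcarbon.errors import InfeasibleParameterError, InvalidParameterError
from soilcarbon.grid import N_LAYERS
from soilcarbon.vertical import (VerticalModel, aggregate_depth,
                                 build_transport, build_transport_layers,
                                 depth_scalar, vert_rhs, vert_steady_state)

P_CONV = {"t1": 0.85, "t2": 0.68, "f31": 0.005, "f12": 0.4185,
          "f32": 0.0315, "f13": 0.45}
K_DEFAULT = np.array([7.3, 0.2, 0.0045])


@pytest.fixture(scope="module")
def equal_column():
    return sc.SoilColumn(np.full(N_LAYERS, 0.3))


class TestDepthScalar:
    def test_oracle_values(self):
        assert depth_scalar(0.0, 0.5) == pytest.approx(1.0)
        assert depth_scalar(1.0, 0.5) == pytest.approx(np.exp(-2.0))
        assert depth_scalar(0.5, 0.5) == pytest.approx(np.exp(-1.0))

    def test_monotone_decreasing(self, column):
        s = depth_scalar(column.nodes, 0.5)
        assert np.all(np.diff(s) < 0)

    def test_rejects_nonpositive_efolding(self):
        with pytest.raises(InvalidParameterError):
            depth_scalar(1.0, 0.0)


class TestTransport:
    def test_zero_column_sums(self, column):
        tr = build_transport_layers(3e-4, column)
        np.testing.assert_allclose(tr.sum(axis=0), 0.0, atol=1e-14)

    def test_block_operator_zero_column_sums(self, column):
        tr = build_transport(3e-4, column)
        assert tr.shape == (30, 30)
        np.testing.assert_allclose(tr.sum(axis=0), 0.0, atol=1e-14)

    def test_zero_diffusivity_is_zero_operator(self, column):
        np.testing.assert_array_equal(build_transport_layers(0.0, column), 0.0)

    def test_negative_diffusivity_rejected(self, column):
        with pytest.raises(ValueError):
            build_transport_layers(-1e-4, column)

    def test_two_box_exchange_rate(self, equal_column):
        # equal layers of thickness h: the difference between neighbouring
        # layers decays at 2 d / h^2 in an isolated pair
        d, h = 2e-3, 0.3
        tr = build_transport_layers(d, equal_column)
        assert tr[1, 0] == pytest.approx(d / (h * h))
        assert tr[0, 1] == pytest.approx(d / (h * h))
        # an isolated pair with that exchange rate damps the difference
        # mode at 2 d / h^2
        pair = np.array([[-d / h**2, d / h**2], [d / h**2, -d / h**2]])
        np.testing.assert_allclose(np.sort(np.linalg.eigvals(pair).real),
                                   [-2 * d / h**2, 0.0], atol=1e-12)

    def test_conserves_and_flattens(self, column):
        # pure diffusion: total mass conserved, concentration flattens
        rng = np.random.default_rng(0)
        x = rng.uniform(10.0, 500.0, N_LAYERS)
        tr = build_transport_layers(2e-2, column)
        sol = solve_ivp(lambda _, y: tr @ y, (0.0, 5000.0), x,
                        method="BDF", rtol=1e-10, atol=1e-10)
        final = sol.y[:, -1]
        assert final.sum() == pytest.approx(x.sum(), rel=1e-8)
        conc = final / column.thickness
        assert conc.std() / conc.mean() < 1e-5

    def test_eigenvalues_nonpositive_with_single_zero(self, column):
        tr = build_transport_layers(1e-3, column)
        ev = np.sort(np.linalg.eigvals(tr).real)
        assert ev[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(ev[:-1] < 0)


class TestVertSteadyState:
    def _setup(self, d=3e-4, zt=0.5):
        column = sc.column_layout()
        f = build_transfer_matrix(P_CONV, 0.5)
        xi = 0.6 * depth_scalar(column.nodes, zt)
        tr = build_transport(d, column)
        profile = depth_scalar(column.nodes, zt)
        profile = profile / profile.sum()
        r = np.zeros((N_LAYERS, 3))
        r[:, 0] = 400.0 * profile
        return column, f, xi, tr, r.ravel()

    def test_rhs_zero_at_steady_state(self):
        column, f, xi, tr, r = self._setup()
        x_ss = vert_steady_state(r, f, K_DEFAULT, xi, tr)
        rhs = vert_rhs(x_ss, r, f, K_DEFAULT, xi, tr)
        np.testing.assert_allclose(rhs, 0.0, atol=1e-8)

    def test_matches_long_integration(self):
        column, f, xi, tr, r = self._setup()
        x_ss = vert_steady_state(r, f, K_DEFAULT, xi, tr)
        a = np.zeros((30, 30))
        for j in range(30):
            e = np.zeros(30)
            e[j] = 1.0
            a[:, j] = vert_rhs(e, np.zeros(30), f, K_DEFAULT, xi, tr)
        # the deep passive pool equilibrates over ~1e5 yr (tiny depth-
        # attenuated turnover); BDF covers the long horizon in few steps
        sol = solve_ivp(lambda _, y: r + a @ y, (0.0, 5e6), np.zeros(30),
                        method="BDF", rtol=1e-10, atol=1e-6)
        np.testing.assert_allclose(sol.y[:, -1], x_ss, rtol=1e-3)

    def test_reduces_to_conventional_without_transport(self):
        # D -> 0 and depth scalar -> 1: each layer is an independent
        # conventional model driven by its litter share
        column = sc.column_layout()
        f = build_transfer_matrix(P_CONV, 0.5)
        xi = np.full(N_LAYERS, 0.6)
        tr = np.zeros((30, 30))
        shares = column.thickness / column.total_depth
        r = np.zeros((N_LAYERS, 3))
        r[:, 0] = 400.0 * shares
        x_ss = vert_steady_state(r.ravel(), f, K_DEFAULT, xi, tr)
        x_ss = x_ss.reshape(N_LAYERS, 3)
        for layer in range(N_LAYERS):
            expected = conv_steady_state(P_CONV, 0.5, K_DEFAULT, 0.6,
                                         r[layer])
            np.testing.assert_allclose(x_ss[layer], expected, rtol=1e-9)

    def test_infeasible_negative_raises(self):
        column, f, xi, tr, r = self._setup()
        with pytest.raises(InfeasibleParameterError):
            vert_steady_state(-r, f, K_DEFAULT, xi, tr)


class TestAggregateDepth:
    def test_full_column_total(self, column):
        x = np.arange(30, dtype=float).reshape(N_LAYERS, 3)
        total = aggregate_depth(x, column, (0.0, column.total_depth))
        assert total == pytest.approx(x.sum())

    def test_prorates_partial_layers(self, equal_column):
        x = np.ones((N_LAYERS, 3))
        # 0-0.45 m covers layer 1 fully (0.3 m) and half of layer 2
        assert aggregate_depth(x, equal_column, (0.0, 0.45)) == pytest.approx(4.5)

    def test_interval_below_column_returns_zero(self, column):
        x = np.ones((N_LAYERS, 3))
        assert aggregate_depth(x, column, (50.0, 51.0)) == 0.0


class TestVerticalModel:
    def test_steady_state_matches_reference(self, tiny_world):
        model = VerticalModel(tiny_world.grid, tiny_world.spinup,
                              tiny_world.column)
        theta = model.space.defaults
        x = model.steady_state(theta)
        p = model.space.to_dict(theta)
        xi = model.mean_xi(np.array([p["Q10"]]), np.array([p["zt"]]))[0]
        k = np.array([p["k1"], p["k2"], p["k3"]])
        profile = model._litter_profile(np.array([p["zt"]]))[0]
        pf = np.asarray(tiny_world.grid.permafrost, bool)
        f = build_transfer_matrix(p, model.sand[0])
        c = 0
        d = p["D2"] if pf[c] else p["D1"]
        tr = build_transport(d, tiny_world.column)
        r = np.zeros((N_LAYERS, 3))
        r[:, 0] = model._litter_mean[c] * profile
        expected = vert_steady_state(r.ravel(), f, k, xi[c], tr)
        np.testing.assert_allclose(x[c].ravel(), expected, rtol=1e-8)

    def test_observation_rows_counts(self, tiny_world):
        model = VerticalModel(tiny_world.grid, tiny_world.spinup,
                              tiny_world.column)
        rows = model.observation_rows()
        pf = np.asarray(tiny_world.grid.permafrost, bool)
        assert len(rows) == (~pf).sum() + 3 * pf.sum()
        for c, top, bottom in rows:
            assert bottom > top
            assert (top, bottom) in {(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)}

    def test_log_predicted_stocks_are_interval_aggregates(self, tiny_world):
        model = VerticalModel(tiny_world.grid, tiny_world.spinup,
                              tiny_world.column)
        theta = model.space.defaults
        preds = model.log_predicted_stocks(theta)
        x = model.steady_state(theta)
        for i, (c, top, bottom) in enumerate(model.observation_rows()):
            expected = aggregate_depth(x[c], tiny_world.column, (top, bottom))
            assert preds[i] == pytest.approx(np.log(expected), rel=1e-10)

    def test_permafrost_cells_use_d2(self, tiny_world):
        model = VerticalModel(tiny_world.grid, tiny_world.spinup,
                              tiny_world.column)
        pf = np.asarray(tiny_world.grid.permafrost, bool)
        assert pf.any() and (~pf).any()
        theta = model.space.defaults.copy()
        base = model.steady_state(theta)
        theta[model.space.index("D1")] *= 3.0
        moved = model.steady_state(theta)
        # non-permafrost cells respond to D1, permafrost cells do not
        assert not np.allclose(moved[~pf], base[~pf])
        np.testing.assert_allclose(moved[pf], base[pf], rtol=1e-12)

    def test_steady_start_constant_forcing_is_flat(self, constant_forcing_factory):
        spin = constant_forcing_factory(n_cells=2, n_years=1)
        scen = constant_forcing_factory(n_cells=2, n_years=3)
        grid = sc.Grid(cell_ids=np.arange(2), latitude=np.zeros(2),
                       longitude=np.zeros(2), area=np.full(2, 1e10),
                       land=np.ones(2, bool),
                       permafrost=np.array([False, True]))
        model = VerticalModel(grid, spin, sc.column_layout())
        theta = model.space.defaults
        x0 = model.steady_state(theta)
        states = model.simulate_ensemble(theta[None], scen, x0[None])
        drift = np.abs(states[0, -1] / x0 - 1.0)
        assert drift.max() < 1e-3

    @given(st.integers(min_value=0, max_value=500))
    def test_conservation_of_rhs(self, seed):
        # column total tendency = input - respiration; transport cancels
        rng = np.random.default_rng(seed)
        column = sc.column_layout()
        f = build_transfer_matrix(P_CONV, 0.5)
        xi = rng.uniform(0.1, 1.0, N_LAYERS)
        tr = build_transport(rng.uniform(0.0, 1e-3), column)
        x = rng.uniform(0.0, 1000.0, 30)
        r = np.zeros(30)
        r[::3] = rng.uniform(0.0, 100.0, N_LAYERS)
        rhs = vert_rhs(x, r, f, K_DEFAULT, xi, tr)
        resp_frac = -f.sum(axis=0)
        flux = xi[:, None] * K_DEFAULT[None, :] * x.reshape(N_LAYERS, 3)
        respiration = float((flux * resp_frac[None, :]).sum())
        assert rhs.sum() == pytest.approx(r.sum() - respiration, rel=1e-10)
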