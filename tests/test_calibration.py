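"""Calibration machinery: observations, likelihood, sampler, diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilcarbon as sc
from soilcarbon.calibration import (CalibrationResult, ChainArchive,
                                    _reflect, calibrate, gelman_rubin,
                                    log_likelihood, mh_run,
                                    observation_layout, propose)
from soilcarbon.synthetic import make_observations, truth_vector


def _obs(n=3, z=None):
    z = np.full(n, 8.0) if z is None else np.asarray(z, float)
    return sc.ObservationSet(
        cell_index=np.arange(n), z=z, sigma=0.5 * z,
        interval=np.tile([0.0, 1.0], (n, 1)), source=("tag",) * n)


class TestObservationSet:
    def test_n_obs(self):
        assert _obs(4).n_obs == 4

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            sc.ObservationSet(cell_index=np.arange(2), z=np.ones(2),
                              sigma=np.array([0.5, 0.0]),
                              interval=np.tile([0.0, 1.0], (2, 1)),
                              source=("a", "b"))

    def test_rejects_inconsistent_lengths(self):
        with pytest.raises(ValueError):
            sc.ObservationSet(cell_index=np.arange(3), z=np.ones(2),
                              sigma=np.ones(2),
                              interval=np.tile([0.0, 1.0], (2, 1)),
                              source=("a", "b"))


class TestObservationLayout:
    def test_row_counts_per_kind(self, tiny_world):
        grid = tiny_world.grid
        pf = np.asarray(grid.permafrost, bool)
        assert len(observation_layout("conventional", grid)) == grid.n_cells
        assert len(observation_layout("mimics", grid)) == grid.n_cells
        n_vert = len(observation_layout("vertical", grid))
        assert n_vert == (~pf).sum() + 3 * pf.sum()

    def test_conventional_depths_follow_permafrost(self, tiny_world):
        grid = tiny_world.grid
        pf = np.asarray(grid.permafrost, bool)
        for c, top, bottom, tag in observation_layout("conventional", grid):
            assert top == 0.0
            assert bottom == (3.0 if pf[c] else 1.0)
            assert tag == ("permafrost" if pf[c] else "non-permafrost")

    def test_unknown_kind_raises(self, tiny_world):
        with pytest.raises(ValueError):
            observation_layout("bucket", tiny_world.grid)


class TestLogLikelihood:
    def test_zero_at_perfect_fit(self, tiny_world, tiny_models):
        model = tiny_models["conventional"]
        theta = truth_vector(tiny_world, model)
        preds = model.log_predicted_stocks(theta)
        obs = sc.ObservationSet(
            cell_index=np.arange(len(preds)), z=preds, sigma=0.5 * preds,
            interval=np.tile([0.0, 1.0], (len(preds), 1)),
            source=("t",) * len(preds))
        assert log_likelihood(theta, obs, model) == pytest.approx(0.0)

    def test_matches_gaussian_formula(self, tiny_world, tiny_models):
        model = tiny_models["conventional"]
        obs = make_observations(tiny_world, model)
        theta = model.space.defaults
        preds = model.log_predicted_stocks(theta)
        expected = -np.sum((obs.z - preds) ** 2 / (2.0 * obs.sigma**2))
        assert log_likelihood(theta, obs, model) == pytest.approx(expected)

    def test_infeasible_gives_minus_inf(self, tiny_world, tiny_models):
        model = tiny_models["conventional"]
        obs = make_observations(tiny_world, model)
        theta = model.space.defaults.copy()
        theta[model.space.index("t1")] = 0.0
        theta[model.space.index("t2")] = 1.0
        assert log_likelihood(theta, obs, model) == -np.inf

    def test_layout_mismatch_raises(self, tiny_world, tiny_models):
        model = tiny_models["conventional"]
        with pytest.raises(ValueError):
            log_likelihood(model.space.defaults, _obs(n=1), model)


class TestProposal:
    @given(st.integers(min_value=0, max_value=1000))
    def test_stays_inside_box(self, seed):
        space = sc.conventional_space()
        rng = np.random.default_rng(seed)
        theta = space.sample(rng)
        for _ in range(5):
            theta = propose(theta, space, rng)
            assert space.contains(theta)

    @given(st.integers(min_value=0, max_value=1000))
    def test_displacement_bounded_by_step(self, seed):
        space = sc.conventional_space()
        rng = np.random.default_rng(seed)
        theta = space.sample(rng)
        new = propose(theta, space, rng, step_divisor=5.0)
        # reflection can only shorten the displacement, never lengthen it
        assert np.all(np.abs(new - theta) <= 0.5 * space.width / 5.0 + 1e-12)

    def test_reflect_identity_inside(self):
        lo, hi = np.zeros(2), np.ones(2)
        x = np.array([0.3, 0.9])
        np.testing.assert_allclose(_reflect(x, lo, hi), x)

    def test_reflect_mirrors_overshoot(self):
        lo, hi = np.zeros(1), np.ones(1)
        np.testing.assert_allclose(_reflect(np.array([1.2]), lo, hi), [0.8])
        np.testing.assert_allclose(_reflect(np.array([-0.2]), lo, hi), [0.2])


class TestMhRun:
    def _quad_loglik(self, space):
        mid = 0.5 * (space.lower + space.upper)
        return lambda t: float(-np.sum(((t - mid) / space.width) ** 2) * 50.0)

    def test_accepted_only_storage_has_no_duplicates(self):
        space = sc.conventional_space()
        arc = mh_run(self._quad_loglik(space), space, n_accept=200,
                     burn_in=10, seed=1)
        assert arc.samples.shape == (200, space.n_params)
        diffs = np.abs(np.diff(arc.samples, axis=0)).sum(axis=1)
        assert np.all(diffs > 0)

    def test_every_iteration_storage_repeats_on_rejection(self):
        space = sc.conventional_space()
        arc = mh_run(self._quad_loglik(space), space, n_accept=100,
                     burn_in=10, seed=1, store_every_iteration=True)
        diffs = np.abs(np.diff(arc.samples, axis=0)).sum(axis=1)
        assert np.any(diffs == 0)  # at least one rejection duplicated

    def test_acceptance_rate_consistent(self):
        space = sc.conventional_space()
        arc = mh_run(self._quad_loglik(space), space, n_accept=150,
                     burn_in=10, seed=3)
        assert arc.acceptance_rate == pytest.approx(150 / arc.n_proposals)
        assert 0.0 < arc.acceptance_rate <= 1.0

    def test_deterministic_by_seed(self):
        space = sc.conventional_space()
        ll = self._quad_loglik(space)
        a = mh_run(ll, space, n_accept=50, burn_in=5, seed=42)
        b = mh_run(ll, space, n_accept=50, burn_in=5, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_infeasible_initial_raises(self):
        space = sc.conventional_space()
        with pytest.raises(ValueError):
            mh_run(lambda t: -np.inf, space, n_accept=10, burn_in=1, seed=0,
                   initial=space.defaults)

    def test_burn_in_must_be_shorter(self):
        space = sc.conventional_space()
        with pytest.raises(ValueError):
            mh_run(self._quad_loglik(space), space, n_accept=10, burn_in=10,
                   seed=0)

    def test_samples_concentrate_near_mode(self):
        space = sc.conventional_space()
        mid = 0.5 * (space.lower + space.upper)
        arc = mh_run(self._quad_loglik(space), space, n_accept=2000,
                     burn_in=200, seed=7)
        post_mean = arc.posterior.mean(axis=0)
        assert np.all(np.abs(post_mean - mid) < 0.1 * space.width)


class TestChainArchive:
    def test_posterior_drops_burn_in(self):
        arc = ChainArchive(samples=np.arange(20.0).reshape(10, 2),
                           log_likelihoods=np.zeros(10), burn_in=3,
                           param_names=("a", "b"), seed=0, step_divisor=5.0)
        assert arc.posterior.shape == (7, 2)
        np.testing.assert_array_equal(arc.posterior[0], [6.0, 7.0])

    def test_csv_round_trip(self, tmp_path):
        samples = np.random.default_rng(0).uniform(size=(12, 3))
        arc = ChainArchive(samples=samples,
                           log_likelihoods=-np.arange(12.0), burn_in=2,
                           param_names=("a", "b", "c"), seed=9,
                           step_divisor=5.0, n_proposals=40)
        path = tmp_path / "chain.csv"
        arc.save_csv(path)
        back = ChainArchive.load_csv(path, burn_in=2)
        np.testing.assert_allclose(back.samples, samples)
        np.testing.assert_allclose(back.log_likelihoods, arc.log_likelihoods)
        assert back.param_names == ("a", "b", "c")

    def test_rejects_burn_in_too_long(self):
        with pytest.raises(ValueError):
            ChainArchive(samples=np.zeros((5, 2)),
                         log_likelihoods=np.zeros(5), burn_in=5,
                         param_names=("a", "b"), seed=0, step_divisor=5.0)


class TestGelmanRubin:
    def test_identical_chains_at_lower_bound(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(1, 1000, 2))
        chains = np.repeat(one, 4, axis=0)
        n = 1000
        np.testing.assert_allclose(gelman_rubin(chains),
                                   np.sqrt((n - 1) / n), rtol=1e-12)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(5, 5000, 3))
        gr = gelman_rubin(chains)
        assert np.all(gr > 0.999) and np.all(gr < 1.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 500, 1))
        chains += np.arange(4.0)[:, None, None] * 3.0  # disjoint chain means
        assert gelman_rubin(chains)[0] > 1.1

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((5, 10)))
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 10, 2)))

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            gelman_rubin(np.zeros((3, 10, 1)))


class TestCalibrate:
    def test_small_run_structure_and_determinism(self, tiny_world, tiny_models):
        model = tiny_models["conventional"]
        obs = make_observations(tiny_world, model)
        res = calibrate(model, obs, n_chains=2, n_accept=120, burn_in=20,
                        seed=5)
        assert isinstance(res, CalibrationResult)
        assert res.posterior.shape == (2 * 100, model.space.n_params)
        assert res.gr.shape == (model.space.n_params,)
        res2 = calibrate(model, obs, n_chains=2, n_accept=120, burn_in=20,
                         seed=5)
        np.testing.assert_array_equal(res.posterior, res2.posterior)

    def test_summary_layout(self, tiny_world, tiny_models):
        model = tiny_models["conventional"]
        obs = make_observations(tiny_world, model)
        res = calibrate(model, obs, n_chains=2, n_accept=60, burn_in=10,
                        seed=6)
        df = res.summary(space=model.space)
        assert list(df.columns) == ["name", "lower", "upper", "default",
                                    "mean", "sd", "GR"]
        assert len(df) == model.space.n_params
        assert np.all(df["mean"] >= df["lower"]) and np.all(df["mean"] <= df["upper"])
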