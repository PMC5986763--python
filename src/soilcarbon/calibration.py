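"""Bayesian calibration: observation operator, likelihood, Metropolis-Hastings.

Observations are natural logs of soil carbon stocks per (cell, depth
interval); their assumed standard deviation is sigma = 0.5 * Z (a
deliberately conservative error on the log observation Z).  Priors are
uniform over the parameter bounds, so the Metropolis ratio reduces to the
likelihood ratio; proposals perturb every coordinate by a uniform step of
width (upper - lower) / D (D = 5 by default) and are reflected at the
bounds, which preserves detailed balance for the symmetric proposal.

By convention a chain stores *accepted* samples only
(duplicated states between acceptances are not stored) and runs until the
requested number of acceptances; standard every-iteration storage is
available via ``store_every_iteration=True``.  Convergence is assessed with
the Gelman-Rubin potential scale reduction over K parallel chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationSet",
    "observation_layout",
    "log_likelihood",
    "propose",
    "mh_run",
    "ChainArchive",
    "gelman_rubin",
    "calibrate",
    "CalibrationResult",
]

SIGMA_FACTOR = 0.5  # sigma = 0.5 * Z per log-observation


@dataclass(frozen=True)
class ObservationSet:
    """Log soil-carbon observations aligned with a model's assimilation rows.

    ``z`` holds ln(observed stock in g C m-2); ``sigma`` the per-observation
    standard deviation; ``interval`` the (top, bottom) depth bounds in m;
    ``source`` a tag such as "non-permafrost", "permafrost" or
    "microbial-domain".
    """

    cell_index: np.ndarray
    z: np.ndarray
    sigma: np.ndarray
    interval: np.ndarray
    source: tuple

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("observation sigma must be positive")
        n = len(self.z)
        if not (len(self.cell_index) == len(self.sigma) == len(self.interval)
                == len(self.source) == n):
            raise ValueError("inconsistent observation arrays")

    @property
    def n_obs(self) -> int:
        return len(self.z)


def observation_layout(kind, grid):
    """Ordered (cell, top, bottom, source) assimilation rows for a model kind.

    conventional: one aggregate per cell, 0-1 m in non-permafrost cells and
    0-3 m in permafrost cells.  vertical: 0-1 m per non-permafrost cell and
    independent 0-1, 1-2, 2-3 m values per permafrost cell.  mimics: 0-1 m
    everywhere (explicit 1-m-depth parameterization).
    """
    pf = np.asarray(grid.permafrost, dtype=bool)
    rows = []
    for c in range(grid.n_cells):
        tag = "permafrost" if pf[c] else "non-permafrost"
        if kind == "conventional":
            rows.append((c, 0.0, 3.0 if pf[c] else 1.0, tag))
        elif kind == "vertical":
            intervals = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)) if pf[c] else ((0.0, 1.0),)
            rows.extend((c, top, bottom, tag) for top, bottom in intervals)
        elif kind == "mimics":
            rows.append((c, 0.0, 1.0, "microbial-domain"))
        else:
            raise ValueError(f"unknown model kind: {kind}")
    return rows


def log_likelihood(theta, obs: ObservationSet, model):
    """Gaussian log-likelihood of log-stock residuals; -inf when infeasible.

    Returns -sum((Z_i - pred_i)^2 / (2 sigma_i^2)); the maximum value 0 is
    attained only at a perfect fit.  A parameter vector whose steady state
    fails (negative pools, infeasible transfer fraction, no quadratic root)
    contributes -inf rather than raising.
    """
    preds = model.log_predicted_stocks(theta)
    if preds is None:
        return -np.inf
    if len(preds) != obs.n_obs:
        raise ValueError("observation set does not match the model layout")
    resid = obs.z - preds
    return float(-np.sum(resid**2 / (2.0 * obs.sigma**2)))


def _reflect(x, lower, upper):
    """Reflect coordinates into [lower, upper] (step sizes < interval width)."""
    width = upper - lower
    y = np.mod(x - lower, 2.0 * width)
    return lower + np.minimum(y, 2.0 * width - y)


def propose(theta_old, space, rng, step_divisor=5.0):
    """Symmetric uniform random-walk proposal with boundary reflection.

    Each coordinate moves by r * (upper - lower) / D with r ~ U(-0.5, 0.5);
    coordinates leaving the prior box are reflected back inside.
    """
    r = rng.uniform(-0.5, 0.5, size=space.n_params)
    theta_new = theta_old + r * space.width / step_divisor
    return _reflect(theta_new, space.lower, space.upper)


@dataclass
class ChainArchive:
    """Accepted samples of one Metropolis-Hastings chain plus metadata."""

    samples: np.ndarray  # (n_accept, P)
    log_likelihoods: np.ndarray
    burn_in: int
    param_names: tuple
    seed: int
    step_divisor: float
    n_proposals: int = 0
    field_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.burn_in >= len(self.samples):
            raise ValueError("burn-in must be shorter than the chain")

    @property
    def acceptance_rate(self) -> float:
        return len(self.samples) / max(self.n_proposals, 1)

    @property
    def posterior(self) -> np.ndarray:
        """Samples with the burn-in discarded."""
        return self.samples[self.burn_in:]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.param_names))
        df.insert(0, "log_likelihood", self.log_likelihoods)
        df.insert(0, "iteration", np.arange(len(self.samples)))
        return df

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, burn_in, seed=0, step_divisor=5.0):
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c not in ("iteration", "log_likelihood"))
        return cls(samples=df[list(names)].to_numpy(),
                   log_likelihoods=df["log_likelihood"].to_numpy(),
                   burn_in=burn_in, param_names=names, seed=seed,
                   step_divisor=step_divisor, n_proposals=len(df))


def mh_run(loglik, space, n_accept, burn_in, seed, step_divisor=5.0,
           initial=None, store_every_iteration=False, max_proposals=None,
           low_rate_window=2000):
    """Run one Metropolis-Hastings chain until ``n_accept`` acceptances.

    ``loglik`` maps a parameter vector to a log-likelihood (may be -inf).
    The chain starts at ``initial`` (default: a uniform prior draw) and uses
    the acceptance rule u < exp(logL_new - logL_old) with u ~ U(0, 1); with
    the uniform prior this is the full Metropolis criterion.  By default
    only accepted states are stored (see module docstring).  A window with
    acceptance below 0.1% triggers a diagnostic warning reporting the best
    log-likelihood seen in the window.
    """
    if n_accept <= burn_in:
        raise ValueError("n_accept must exceed burn_in")
    rng = np.random.default_rng(seed)
    if initial is None:
        theta = space.sample(rng)
        logl = loglik(theta)
        tries = 0
        while not np.isfinite(logl):
            theta = space.sample(rng)
            logl = loglik(theta)
            tries += 1
            if tries > 10000:
                raise RuntimeError("could not find a feasible starting point")
    else:
        theta = space.validate(initial)
        logl = loglik(theta)
        if not np.isfinite(logl):
            raise ValueError("initial point has -inf log-likelihood")
    if max_proposals is None:
        max_proposals = 1000 * n_accept
    samples = [theta.copy()]
    logls = [logl]
    n_proposals = 0
    window_accepts = 0
    window_best = -np.inf
    while len(samples) <= n_accept:
        theta_new = propose(theta, space, rng, step_divisor)
        logl_new = loglik(theta_new)
        n_proposals += 1
        window_best = max(window_best, logl_new)
        accept = np.log(rng.random()) < logl_new - logl
        if accept:
            theta, logl = theta_new, logl_new
            window_accepts += 1
            samples.append(theta.copy())
            logls.append(logl)
        elif store_every_iteration:
            samples.append(theta.copy())
            logls.append(logl)
        if n_proposals % low_rate_window == 0:
            if window_accepts / low_rate_window < 0.001:
                logger.warning(
                    "acceptance below 0.1%% over the last %d proposals "
                    "(best logL in window: %.3g)", low_rate_window, window_best)
            window_accepts = 0
            window_best = -np.inf
        if n_proposals >= max_proposals:
            raise RuntimeError(
                f"exceeded {max_proposals} proposals before {n_accept} acceptances")
    return ChainArchive(
        samples=np.asarray(samples[1:]),  # drop the start; store acceptances
        log_likelihoods=np.asarray(logls[1:]),
        burn_in=burn_in,
        param_names=space.names,
        seed=int(seed),
        step_divisor=step_divisor,
        n_proposals=n_proposals,
    )


def gelman_rubin(chains):
    """Gelman-Rubin potential scale reduction per parameter.

    ``chains`` has shape (K, N, P): K >= 2 parallel chains of N >= 2 samples.
    Computes the between-chain variance B, within-chain variance W and

        GR = sqrt((W (N-1)/N + B/N) / W)

    which is bounded below by sqrt((N-1)/N) and ~1 at convergence.  Raises
    if any parameter has zero within-chain variance.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3:
        raise ValueError("chains must have shape (K, N, P)")
    k, n, _ = chains.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 chains of at least 2 samples")
    chain_means = chains.mean(axis=1)            # (K, P)
    grand_means = chain_means.mean(axis=0)       # (P,)
    b = n / (k - 1) * np.sum((chain_means - grand_means) ** 2, axis=0)
    w = np.sum((chains - chain_means[:, None, :]) ** 2, axis=(0, 1)) / (k * (n - 1))
    if np.any(w == 0):
        raise ZeroDivisionError("within-chain variance is zero for some parameter")
    return np.sqrt((w * (n - 1) / n + b / n) / w)


@dataclass
class CalibrationResult:
    """Multi-chain calibration output: archives, G-R, and a summary table."""

    archives: list
    gr: np.ndarray
    param_names: tuple

    @property
    def posterior(self) -> np.ndarray:
        """Post-burn-in samples pooled across chains, shape (K*N, P)."""
        return np.concatenate([a.posterior for a in self.archives], axis=0)

    def summary(self, space=None) -> pd.DataFrame:
        """Posterior mean +/- SD and G-R per parameter, one row each."""
        post = self.posterior
        df = pd.DataFrame({
            "name": list(self.param_names),
            "mean": post.mean(axis=0),
            "sd": post.std(axis=0, ddof=1),
            "GR": self.gr,
        })
        if space is not None:
            df.insert(1, "lower", space.lower)
            df.insert(2, "upper", space.upper)
            df.insert(3, "default", space.defaults)
        return df


def calibrate(model, obs, n_chains=5, n_accept=50_000, burn_in=2_500,
              seed=0, step_divisor=5.0, **mh_kwargs) -> CalibrationResult:
    """Run K parallel chains against one observation set and compute G-R.

    Chain starts are drawn uniformly from the prior; per-chain seeds are
    spawned deterministically from ``seed``.
    """
    space = model.space
    loglik = lambda theta: log_likelihood(theta, obs, model)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_chains) % (2**31)
    archives = [
        mh_run(loglik, space, n_accept, burn_in, int(s), step_divisor, **mh_kwargs)
        for s in child_seeds
    ]
    chains = np.stack([a.posterior for a in archives], axis=0)
    gr = gelman_rubin(chains)
    bad = [n for n, g in zip(space.names, gr) if g > 1.1]
    if bad:
        logger.warning("G-R above 1.1 (non-convergence) for: %s", bad)
    return CalibrationResult(archives=archives, gr=gr, param_names=space.names)
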