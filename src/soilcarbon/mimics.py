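"""Microbial-explicit soil carbon model (MIMICS-type).

Five pools: three soil organic matter pools — physically protected (SOM_p),
chemically recalcitrant (SOM_c), available (SOM_a) — and two microbial
guilds (MIC_r, MIC_k; r- and K-strategists).  Microbial uptake of SOM
follows Michaelis-Menten kinetics,

    U = MIC * Vmax * SOM / (K_O * K_m + SOM)

with Vmax and K_m exponential in temperature (``exp(slope*T + intercept)``
times a guild/pool modifier) and the oxidation modifier K_O applied to
SOM_c uptake only.  Desorption from SOM_p to SOM_a proceeds at rate
``D = Da * exp(Db * clay)``.

Litter is partitioned by fixed fractions fm (to SOM_p) and fs (to SOM_c);
the remainder feeds the two guilds in proportion to per-cell normalization
uptakes computed once with default parameters.  Dead microbial biomass
(MIC * tau) is routed to the SOM pools by guild-specific fractions that sum
to one, so the only respiration term is (1 - MGE1) of SOM_a uptake.

With microbial biomass held at its observed value (the calibration-time
treatment) the SOM steady states are closed-form: SOM_p linear, SOM_c and
SOM_a the "+sqrt" roots of quadratics.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import InfeasibleParameterError
from .forcing import monthly_to_daily

logger = logging.getLogger(__name__)

__all__ = [
    "kinetics_at",
    "mm_uptake",
    "partition_litter",
    "positive_quadratic_root",
    "mimics_steady_state",
    "mimics_rhs",
    "MimicsModel",
]

N_POOLS = 5  # SOM_p, SOM_c, SOM_a, MIC_r, MIC_k
_EULER_LIMIT = 0.5

# Dead microbial biomass routing to (SOM_p, SOM_c, SOM_a) per guild; each
# row sums to 1 (no respiration on the necromass pathway).
NECROMASS_SPLIT = {
    "r": (0.3, 0.1, 0.6),
    "k": (0.2, 0.3, 0.5),
}


def kinetics_at(t_soil, clay, p):
    """Uptake kinetics at a given temperature and clay fraction.

    Returns a dict with Vmax and K_m per (guild, substrate) — keys like
    ``vmax_ra`` (r-guild on SOM_a) — the oxidation modifiers ``ko_r``/
    ``ko_k`` and the desorption rate ``desorption``.  All outputs are
    positive; inputs broadcast.
    """
    clay = np.asarray(clay, dtype=float)
    if np.any(clay < 0) or np.any(clay > 1):
        raise ValueError("clay fraction must lie in [0, 1]")
    t = np.asarray(t_soil, dtype=float)
    vbase = np.exp(p["Vs"] * t + p["Vi"])
    kbase = np.exp(p["Ks"] * t + p["Ki"])
    return {
        "vmax_ra": vbase * p["Vmra"],
        "vmax_ka": vbase * p["Vmka"],
        "vmax_rc": vbase * p["Vmrc"],
        "vmax_kc": vbase * p["Vmkc"],
        "km_ra": kbase * p["Kmra"],
        "km_ka": kbase * p["Kmka"],
        "km_rc": kbase * p["Kmrc"],
        "km_kc": kbase * p["Kmkc"],
        "ko_r": p["Kor"] * np.ones_like(t),
        "ko_k": p["Kok"] * np.ones_like(t),
        "desorption": p["Da"] * np.exp(p["Db"] * clay) * np.ones_like(t),
    }


def mm_uptake(mic, vmax, km, k_mod, som):
    """Michaelis-Menten uptake flux MIC*Vmax*SOM/(K_mod*K_m + SOM).

    Non-negative, saturating in SOM, bounded by MIC*Vmax.
    """
    mic, vmax, km, som = (np.asarray(a, dtype=float) for a in (mic, vmax, km, som))
    denom = np.asarray(k_mod, dtype=float) * km + som
    if np.any(denom <= 0):
        raise ValueError("uptake denominator must be positive")
    return mic * vmax * som / denom


def partition_litter(total_input, fm, fs, norm_uptakes):
    """Split total litter input into (R_l-p, R_l-c, R_l-r, R_l-k).

    ``norm_uptakes`` are the four normalization uptakes
    (U_m-r, U_m-k, U_s-r, U_s-k) — metabolic and structural litter uptake by
    each guild, computed once with default parameters.  The guild share of
    the residual input is (U_m-g + U_s-g) / sum(U).  Outputs are
    non-negative and sum exactly to the total input.
    """
    if fm + fs > 1.0 + 1e-12:
        raise ValueError("fm + fs must not exceed 1")
    umr, umk, usr, usk = (float(u) for u in norm_uptakes)
    if min(umr, umk, usr, usk) < 0:
        raise ValueError("normalization uptakes must be non-negative")
    total_u = umr + umk + usr + usk
    if total_u == 0:
        raise ZeroDivisionError("all normalization uptakes are zero")
    r_lp = fm * total_input
    r_lc = fs * total_input
    residual = total_input - r_lp - r_lc
    r_lr = (umr + usr) / total_u * residual
    r_lk = residual - r_lr
    return r_lp, r_lc, r_lr, r_lk


def positive_quadratic_root(e, f, g):
    """The "+sqrt" root of e*x^2 + f*x + g = 0, with a linear fallback.

    As e -> 0 the root tends to -g/f; coefficients may be arrays.  Returns
    NaN where the discriminant is negative.
    """
    e, f, g = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (e, f, g)))
    disc = f * f - 4.0 * e * g
    root = np.full(e.shape, np.nan)
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    # For f > 0 the "+sqrt" numerator cancels; the equivalent form
    # -2 g / (f + sqrt(disc)) is stable there and tends to -g/f as e -> 0.
    stable = ok & (f > 0)
    root[stable] = -2.0 * g[stable] / (f[stable] + sq[stable])
    classic = ok & (f <= 0) & (e != 0)
    root[classic] = (-f[classic] + sq[classic]) / (2.0 * e[classic])
    lin = ok & (f < 0) & (e == 0)
    root[lin] = -g[lin] / f[lin]
    return root if root.shape else float(root)


def _necromass_inputs(mic_r, mic_k, tau_r, tau_k):
    """(R_mic-p, R_mic-c, R_mic-a) from dead microbial biomass."""
    dead_r = mic_r * tau_r
    dead_k = mic_k * tau_k
    sr, sk = NECROMASS_SPLIT["r"], NECROMASS_SPLIT["k"]
    return tuple(dead_r * sr[i] + dead_k * sk[i] for i in range(3))


def mimics_steady_state(mic_r, mic_k, kin, r_lp, r_lc, p):
    """Closed-form SOM steady states with microbial biomass held fixed.

    Returns (SOM_p, SOM_c, SOM_a); inputs broadcast over cells.  Raises
    :class:`InfeasibleParameterError` on a negative discriminant or a
    non-positive root.

    SOM_p = (R_l-p + R_mic-p) / D.  SOM_c solves the quadratic with
    coefficients (e, f, g); SOM_a likewise with (l, m, n), where the SOM_a
    input collects necromass, the SOM_c throughput and desorption.
    """
    rmic_p, rmic_c, rmic_a = _necromass_inputs(mic_r, mic_k, p["tau_r"], p["tau_k"])
    d = kin["desorption"]
    if np.any(d <= 0):
        raise InfeasibleParameterError("non-positive desorption rate")
    som_p = (r_lp + rmic_p) / d

    # SOM_c quadratic: e*x^2 + f*x + g = 0
    r_c = r_lc + rmic_c
    cap_r = mic_r * kin["vmax_rc"]
    cap_k = mic_k * kin["vmax_kc"]
    kk_r = kin["ko_r"] * kin["km_rc"]
    kk_k = kin["ko_k"] * kin["km_kc"]
    coeff_e = cap_r + cap_k - r_c
    coeff_f = cap_r * kk_k + kk_r * cap_k - (kk_r + kk_k) * r_c
    coeff_g = -(kk_r * kk_k) * r_c
    som_c = positive_quadratic_root(coeff_e, coeff_f, coeff_g)

    # SOM_a quadratic: at steady state the SOM_c uptake equals r_c and
    # desorption equals r_lp + rmic_p, so the total SOM_a input is
    r_a = rmic_a + r_c + r_lp + rmic_p
    cap_ra = mic_r * kin["vmax_ra"]
    cap_ka = mic_k * kin["vmax_ka"]
    km_ra, km_ka = kin["km_ra"], kin["km_ka"]
    coeff_l = cap_ra + cap_ka - r_a
    coeff_m = cap_ra * km_ka + km_ra * cap_ka - (km_ra + km_ka) * r_a
    coeff_n = -(km_ra * km_ka) * r_a
    som_a = positive_quadratic_root(coeff_l, coeff_m, coeff_n)

    stacked = np.broadcast_arrays(som_p, som_c, som_a)
    if any(np.any(~np.isfinite(s)) or np.any(s < 0) for s in stacked):
        raise InfeasibleParameterError("no non-negative MIMICS steady state")
    return som_p, som_c, som_a


def mimics_rhs(state, kin, total_litter, p, norm_uptakes, mic_dynamic=True):
    """Pool tendencies for the five-pool state (g C m-2 yr-1).

    ``state`` is (SOM_p, SOM_c, SOM_a, MIC_r, MIC_k).  When ``mic_dynamic``
    is False the microbial tendencies are zeroed (calibration-time
    treatment with biomass pinned to observations).
    """
    som_p, som_c, som_a, mic_r, mic_k = (np.asarray(s, dtype=float) for s in state)
    if any(np.any(s < 0) for s in (som_p, som_c, som_a, mic_r, mic_k)):
        raise ValueError("pools must be non-negative")
    r_lp, r_lc, r_lr, r_lk = partition_litter(total_litter, p["fm"], p["fs"],
                                              norm_uptakes)
    rmic_p, rmic_c, rmic_a = _necromass_inputs(mic_r, mic_k, p["tau_r"], p["tau_k"])
    d = kin["desorption"]
    u_cr = mm_uptake(mic_r, kin["vmax_rc"], kin["km_rc"], kin["ko_r"], som_c)
    u_ck = mm_uptake(mic_k, kin["vmax_kc"], kin["km_kc"], kin["ko_k"], som_c)
    u_ar = mm_uptake(mic_r, kin["vmax_ra"], kin["km_ra"], 1.0, som_a)
    u_ak = mm_uptake(mic_k, kin["vmax_ka"], kin["km_ka"], 1.0, som_a)
    d_som_p = r_lp + rmic_p - som_p * d
    d_som_c = r_lc + rmic_c - u_cr - u_ck
    d_som_a = rmic_a + u_cr + u_ck + som_p * d - u_ar - u_ak
    if mic_dynamic:
        d_mic_r = r_lr + u_ar * p["MGE1"] - mic_r * p["tau_r"]
        d_mic_k = r_lk + u_ak * p["MGE1"] - mic_k * p["tau_k"]
    else:
        d_mic_r = np.zeros_like(mic_r)
        d_mic_k = np.zeros_like(mic_k)
    return d_som_p, d_som_c, d_som_a, d_mic_r, d_mic_k


class MimicsModel:
    """Vectorized MIMICS model bound to a grid, forcing, and biomass map.

    Calibration uses the closed-form SOM steady state with microbial biomass
    fixed at the observed 0-1 m map split by the global parameter fr;
    projection integrates all five pools (daily step) starting from the
    observed biomass.  Observations are compared against
    SOM_p + SOM_c + SOM_a over 0-1 m.
    """

    kind = "mimics"
    n_pools = N_POOLS

    def __init__(self, grid, spinup, microbial_biomass):
        from .params import mimics_space

        self.grid = grid
        self.space = mimics_space()
        self.biomass = np.asarray(microbial_biomass, dtype=float)
        if np.any(self.biomass <= 0):
            raise ValueError("microbial biomass must be positive")
        self.clay = np.asarray(spinup.clay, dtype=float)
        self._t_mean = spinup.temperature.mean(axis=1)  # (n,)
        self._litter_mean = spinup.litter.mean(axis=1)  # (n,) g C m-2 yr-1
        self._norm_uptakes = self._normalization_uptakes()

    def _normalization_uptakes(self):
        """Per-cell (U_m-r, U_m-k, U_s-r, U_s-k) with default parameters.

        Metabolic and structural litter stocks are proxied by half the mean
        annual litter input each; these constants only normalize the guild
        split of litter input and are held fixed thereafter.
        """
        p = self.space.to_dict(self.space.defaults)
        kin = kinetics_at(self._t_mean, self.clay, p)
        mic_r = p["fr"] * self.biomass
        mic_k = (1.0 - p["fr"]) * self.biomass
        lit = self._litter_mean / 2.0
        u_mr = mm_uptake(mic_r, kin["vmax_ra"], kin["km_ra"], 1.0, lit)
        u_mk = mm_uptake(mic_k, kin["vmax_ka"], kin["km_ka"], 1.0, lit)
        u_sr = mm_uptake(mic_r, kin["vmax_rc"], kin["km_rc"], kin["ko_r"], lit)
        u_sk = mm_uptake(mic_k, kin["vmax_kc"], kin["km_kc"], kin["ko_k"], lit)
        return np.stack([u_mr, u_mk, u_sr, u_sk], axis=0)  # (4, n)

    def _unpack(self, thetas):
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return {name: thetas[:, i] for i, name in enumerate(self.space.names)}

    def guild_shares(self):
        """Per-cell r-guild share of the litter input to microbes."""
        u = self._norm_uptakes
        return (u[0] + u[2]) / u.sum(axis=0)

    def _scalar_params(self, theta):
        theta = np.asarray(theta, dtype=float)
        if theta.ndim != 1:
            raise ValueError("expected a single parameter vector")
        return self.space.to_dict(theta)

    # -- steady state --------------------------------------------------------

    def try_steady_state(self, theta):
        """Per-cell steady state (n, 5) with MIC fixed, or None if infeasible."""
        p = self._scalar_params(theta)
        if p["fm"] + p["fs"] > 1.0 or not 0.0 <= p["fr"] <= 1.0:
            return None
        kin = kinetics_at(self._t_mean, self.clay, p)
        mic_r = p["fr"] * self.biomass
        mic_k = (1.0 - p["fr"]) * self.biomass
        r_lp = p["fm"] * self._litter_mean
        r_lc = p["fs"] * self._litter_mean
        try:
            som_p, som_c, som_a = mimics_steady_state(mic_r, mic_k, kin,
                                                      r_lp, r_lc, p)
        except InfeasibleParameterError:
            return None
        return np.stack([som_p, som_c, som_a, mic_r, mic_k], axis=1)

    def steady_state(self, theta):
        x = self.try_steady_state(theta)
        if x is None:
            raise InfeasibleParameterError("infeasible MIMICS steady state")
        return x

    # -- observation mapping -------------------------------------------------

    def log_predicted_stocks(self, theta):
        """Log of SOM_p + SOM_c + SOM_a per cell, or None if infeasible."""
        x = self.try_steady_state(theta)
        if x is None:
            return None
        totals = x[:, :3].sum(axis=1)
        if np.any(totals <= 0):
            return None
        return np.log(totals)

    # -- forward simulation --------------------------------------------------

    def simulate_ensemble(self, thetas, forcing, x0, max_substeps=8):
        """Advance an ensemble with a daily step; (M, n_years+1, n, 5) states.

        A monthly forcing series is resampled to daily by step-function
        repetition.  All five pools are dynamic.  The explicit Euler step
        sub-steps adaptively so the fastest first-order loss rate satisfies
        rate * h <= ``_EULER_LIMIT``; members whose kinetics would need more
        than ``max_substeps`` sub-steps per day (uptake turnover times far
        below a day, outside the integrator's regime) are set to NaN for the
        caller to flag, as are members that destabilize mid-run.
        """
        if forcing.resolution != "daily":
            forcing = monthly_to_daily(forcing)
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        p = self._unpack(thetas)
        m = thetas.shape[0]
        n = self.grid.n_cells
        dt = forcing.dt
        steps_per_year = round(1.0 / dt)
        n_years = forcing.n_steps // steps_per_year
        x = np.array(x0, dtype=float)
        if x.shape != (m, n, N_POOLS):
            raise ValueError(f"x0 must have shape {(m, n, N_POOLS)}")
        out = np.empty((m, n_years + 1, n, N_POOLS))
        out[:, 0] = x
        col = lambda name: p[name][:, None]  # (M, 1) for cell broadcasting
        share_r = self.guild_shares()[None, :]  # (1, n)
        desorption = col("Da") * np.exp(col("Db") * self.clay[None, :])  # (M, n)
        sr, sk = NECROMASS_SPLIT["r"], NECROMASS_SPLIT["k"]
        alive = np.ones(m, dtype=bool)
        n_killed = 0
        with np.errstate(over="ignore", invalid="ignore"):
            for t in range(forcing.n_steps):
                temp = forcing.temperature[:, t][None, :]  # (1, n)
                vbase = np.exp(col("Vs") * temp + col("Vi"))
                kbase = np.exp(col("Ks") * temp + col("Ki"))
                lit = forcing.litter[:, t][None, :]  # (1, n) g C m-2 yr-1
                r_lp = col("fm") * lit
                r_lc = col("fs") * lit
                residual = lit - r_lp - r_lc
                r_lr = share_r * residual
                r_lk = residual - r_lr
                remaining = dt
                n_sub = 0
                while remaining > 0.0:
                    som_p, som_c, som_a = x[..., 0], x[..., 1], x[..., 2]
                    mic_r, mic_k = x[..., 3], x[..., 4]
                    # per-unit-MIC uptake intensities s_* (1/yr) and the
                    # resulting first-order loss-rate coefficients per pool
                    s_cr = vbase * col("Vmrc") * som_c / (
                        col("Kor") * kbase * col("Kmrc") + som_c)
                    s_ck = vbase * col("Vmkc") * som_c / (
                        col("Kok") * kbase * col("Kmkc") + som_c)
                    s_ar = vbase * col("Vmra") * som_a / (
                        kbase * col("Kmra") + som_a)
                    s_ak = vbase * col("Vmka") * som_a / (
                        kbase * col("Kmka") + som_a)
                    # fastest loss/growth rate per member (1/yr): SOM_c and
                    # SOM_a depletion, desorption, microbial death/growth
                    denom_c = np.maximum(som_c, 1e-12)
                    denom_a = np.maximum(som_a, 1e-12)
                    rate = np.maximum(
                        (mic_r * s_cr + mic_k * s_ck) / denom_c,
                        (mic_r * s_ar + mic_k * s_ak) / denom_a)
                    rate = np.maximum(rate, desorption)
                    rate = np.maximum(rate, np.maximum(col("tau_r"), col("tau_k")))
                    rate = np.maximum(rate, col("MGE1") * np.maximum(s_ar, s_ak))
                    rate_m = np.max(np.where(alive[:, None], rate, 0.0), axis=1)
                    # NaN rates (state went non-finite) also fail this test
                    too_stiff = alive & ~(rate_m * dt / max_substeps <= _EULER_LIMIT)
                    if np.any(too_stiff):
                        n_killed += int(too_stiff.sum())
                        x[too_stiff] = np.nan
                        alive &= ~too_stiff
                        rate_m = np.where(alive, rate_m, 0.0)
                        if not np.any(alive):
                            remaining = 0.0
                            break
                    h = min(remaining,
                            _EULER_LIMIT / max(float(rate_m.max()), 1e-30))
                    u_cr, u_ck = mic_r * s_cr, mic_k * s_ck
                    u_ar, u_ak = mic_r * s_ar, mic_k * s_ak
                    dead_r = mic_r * col("tau_r")
                    dead_k = mic_k * col("tau_k")
                    desorb = som_p * desorption
                    x[..., 0] += h * (r_lp + dead_r * sr[0] + dead_k * sk[0] - desorb)
                    x[..., 1] += h * (r_lc + dead_r * sr[1] + dead_k * sk[1]
                                      - u_cr - u_ck)
                    x[..., 2] += h * (dead_r * sr[2] + dead_k * sk[2] + u_cr + u_ck
                                      + desorb - u_ar - u_ak)
                    x[..., 3] += h * (r_lr + u_ar * col("MGE1") - dead_r)
                    x[..., 4] += h * (r_lk + u_ak * col("MGE1") - dead_k)
                    np.clip(x, 0.0, None, out=x)
                    x[~alive] = np.nan
                    remaining -= h
                    n_sub += 1
                    if n_sub > 8 * max_substeps:  # infinite-loop failsafe
                        logger.warning("substep failsafe tripped at step %d", t)
                        break
                if (t + 1) % steps_per_year == 0:
                    out[:, (t + 1) // steps_per_year] = x
        if n_killed:
            logger.warning("%d MIMICS members too stiff for the daily "
                           "integrator; set to NaN", n_killed)
        return out
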