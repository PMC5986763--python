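# Methods

This package quantifies how the *structure* of a soil-carbon decomposition
model — not just its parameter values — shapes projections of global soil
carbon change. It implements three model structures of increasing
complexity, calibrates each of them against the same synthetic soil-carbon
observations with a Bayesian sampler, and propagates the calibrated
posterior through a warming scenario to compare the resulting projection
ensembles.

## The synthetic study world

Because the package is self-contained, it generates its own study domain
(`soilcarbon.synthetic`): a grid of 50 land cells spanning 5–75° N with
cell areas, sand/clay fractions, and a monthly climatology of soil
temperature (seasonal cycle, depth-damped for the layered fields),
moisture/oxygen/nitrogen scalars and litterfall. The coldest quarter of
the cells is flagged permafrost. A 20-year spin-up window has no trend;
the 95-year scenario window applies a linear temperature trend (default
+5 °C per century) and a litter trend (default +5 % per century).
Pseudo-observations are the log steady-state carbon stocks under known
"truth" parameters plus lognormal noise, so calibration quality can be
scored against the truth.

## Model structures

All three models share the environmental rate modifier: a Q10 temperature
scalar `Q10^((T − 25)/10)` multiplied by the moisture and oxygen scalars
(the conventional model also applies the nitrogen scalar).

**Conventional three-pool model** (`soilcarbon.conventional`). Fast, slow
and passive pools obey `X′ = R + F ξ K X` with baseline turnover
`K = diag(k1, k2, k3)`, environmental modifier ξ, and a transfer matrix F
whose slow→fast fraction depends on soil texture:
`f21 = 1 − (t1 − t2 (1 − sand)) − f31`. The steady state is the linear
solve `X_ss = −(F ξ K)⁻¹ R`. Ten global parameters.

**Vertically resolved model** (`soilcarbon.vertical`). The same three
pools in each of 10 soil layers (exponentially thickening to ≈3.7 m),
coupled by a finite-volume diffusion operator acting on concentration
(cryoturbation/bioturbation), with diffusivity D2 in permafrost cells and
D1 elsewhere, plus a depth attenuation `exp(−z/z_t)` of the decomposition
rate and of the litter-input profile. `X′ = R + F ξ K X + Tr X`; the
transport operator has zero column sums (it redistributes carbon without
creating or destroying it). Thirteen global parameters. Permafrost cells
contribute three independent observations (0–1, 1–2, 2–3 m).

**Microbial-explicit model** (`soilcarbon.mimics`, MIMICS-type). Five
pools: physically protected, chemically protected and available soil
organic matter (SOM_p, SOM_c, SOM_a) plus two microbial guilds (MIC_r,
MIC_k). Decomposition is reverse Michaelis–Menten:
`uptake = MIC · Vmax · SOM / (K_O · K_m + SOM)` with
`Vmax = exp(Vs·T + Vi) · modifier` and `Km = exp(Ks·T + Ki) · modifier`;
desorption from SOM_p is `Da · exp(Db · clay)`. Litter is split by
fractions fm (→SOM_p) and fs (→SOM_c) with the remainder routed to the
guilds. For calibration, microbial biomass is pinned to an observed map
split by the parameter fr, which makes the SOM steady states closed-form:
SOM_p is linear and SOM_c/SOM_a are the positive roots of quadratics
(solved with a cancellation-safe formula and verified against bisection).
Twenty-two global parameters with priors spanning [default/3, 3·default].

## Calibration

Observations are natural logs Z of carbon stocks per (cell, depth
interval) with assumed error σ = 0.5·Z; the Gaussian log-likelihood is
`−Σ (Z − pred)² / (2σ²)`. Priors are uniform over the parameter bounds.
The Metropolis–Hastings sampler perturbs every coordinate by a uniform
step of width (upper − lower)/5, reflecting at the bounds (a symmetric
proposal), and stores accepted states only, running until the requested
number of acceptances. Five parallel chains per model are checked with
the Gelman–Rubin potential scale reduction
`GR = sqrt((W(N−1)/N + B/N)/W)`; values below 1.1 are treated as
converged.

## Projection and attribution

Each posterior member receives its own steady-state initial condition
under spin-up mean forcing and is integrated forward through the scenario
(monthly explicit Euler with automatic sub-stepping for the two linear
models; a daily, rate-guarded adaptive step for the stiff microbial
model, with members requiring more than 8 sub-steps per day excluded as
numerically stiff). The outcome is the annual global soil-carbon total
(Σ stock·area, in Pg C); ensembles of ΔC = C(2100) − C(2005) are
summarized by their 95 % spread. Pearson correlations of ΔC and the final
stock against the parameters and the initial stock S_i attribute the
projection uncertainty; a deliberately outcome-independent noise
regressor provides a null check.

## Numerical verification

The test suite verifies, among other things: analytic steady states
against long BDF forward integrations (0.1 % per pool over ≥100 random
feasible parameter draws per model); exact per-step carbon balance
(change = input − respiration); conservation and flattening under
diffusion-only dynamics; the reduction of the vertical model to the
conventional model when transport and depth attenuation are switched off;
the quadratic steady-state roots against bisection and their linear
limit; sampler uniformity under a flat likelihood, the Metropolis accept
frequency, and Gelman–Rubin on iid chains; truth recovery on the
synthetic study; and bitwise reproducibility under fixed seeds.
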