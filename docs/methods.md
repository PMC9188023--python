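# Methods

## The individual model

`debtraits` implements the standard Dynamic Energy Budget (DEB) model for
an ectotherm without metabolic acceleration or surface heating. An
individual is described by reserve energy `E` (J), structural length
`L = V^(1/3)` (cm) and maturity `E_H` (J). Assimilation enters the
reserve at rate `f {p_Am} L^2`, where `f` in (0, 1] is the scaled
functional response (food availability; `f = 1` is abundant food).
Reserve is mobilized at

    p_C = E (v/L) (g + L/L_m) / (e + g),      e = E / (L^3 [E_m]),

with energy conductance `v`, investment ratio `g = [E_G]/(kappa [E_m])`,
maximum reserve capacity `[E_m] = {p_Am}/v` and maximum length
`L_m = kappa {p_Am} / [p_M]`. A fixed fraction `kappa` of `p_C` pays
somatic maintenance `[p_M] L^3` first and builds structure (at cost
`[E_G]` per cm^3) with the remainder; the `1 - kappa` branch pays
maturity maintenance `k_J E_H` and cumulates maturity before puberty or
is converted to eggs with efficiency `kappa_R` after. This mobilization
closure respects weak homeostasis: at constant `f`, the reserve density
`e` stays equal to `f` after birth, and length follows the von
Bertalanffy curve

    L(a) = L_i - (L_i - L_b) exp(-r_B (a - a_b)),
    L_i = f L_m,   r_B = k_M / (3 (1 + f/g)),   k_M = [p_M]/[E_G].

Both properties are verified against the integrated raw balance
equations in the test suite rather than assumed. The specific growth
rate at the age of maximum absolute growth (`dL^3/da` maximal, at
`L = (2/3) L_i`) equals `1.5 r_B`; the implementation locates the age
numerically so this identity is a genuine check of the trajectory.

## Embryo stage and egg cost

An embryo starts with reserve `E_0` (the egg's energy cost), negligible
structure (`L(0) = 1e-5 L_m`) and zero maturity, and does not feed.
Birth is the first age at which `E_H` reaches `E_Hb`. The maternal
closure fixes `E_0` as the root of `e(a_b) - f = 0`: offspring start
life with their mother's reserve density. The root is found by
bracketed bisection (bracket grown geometrically by factors of 2 from a
no-maintenance analytic guess, relative tolerance 1e-8 on `E_0`, each
residual evaluated with an adaptive integrator at relative tolerance
1e-10 and event-based birth detection). Candidates too small stall —
`(1 - kappa) p_C` falls to `k_J E_H` before `E_Hb` — and count as
negative residuals. Two failure modes are reported as `NonViableError`:
maturation stalls for every bracketed egg size, or the bisection
converges onto the stall/birth discontinuity, meaning no egg satisfies
the closure (the residual at the viability boundary is bounded away
from zero); the stall maturity level is attached to the error. The
adaptive route is cross-checked in the tests against an independent
fixed-step RK4 integration plus bisection oracle (0.1% agreement).

## Puberty, reproduction, respiration

After birth, maturity obeys the linear ODE
`dE_H/da = (1 - kappa) p_C(L(a)) - k_J E_H` along the closed-form growth
curve; puberty is the event `E_H = E_Hp`. If maturity maintenance
absorbs the whole branch before `E_Hp`, the species is flagged
`stalled` and its puberty-dependent traits are missing (not zero).

Reproduction at ultimate size converts the `1 - kappa` branch surplus
continuously into eggs:

    R_i = kappa_R ((1 - kappa) f [E_m] v L_i^2 - k_J E_Hp) / E_0,

clipped at zero with a `demand_bound` flag. Continuous conversion is a
convention — batch spawning with species-specific buffer rules gives the
same long-run rate.

Respiration uses a single oxycaloric coefficient (`mu_O2` = 4.48e5 J per
mol O2) rather than the full stoichiometric mass balance: dissipated
power is `p_A - kappa_R p_R - kappa_G p_G` (everything assimilated that
is not fixed in eggs or new structure, `kappa_G` being the fraction of
the growth flux fixed in structure). Only the scaling of respiration is
exercised by the comparative analyses, for which the oxycaloric closure
is sufficient. Whether assimilation overhead should count as respiration
is a convention; it is excluded here (`p_A` enters only as the input
side of the balance). Wet weight is `Ww = d_Vw L^3 (1 + e omega)` with
`omega = [E_m] w_E / (d_Vw mu_E)`: structure plus reserve mass, the
reproduction buffer excluded.

## Aging and life span

The Weibull-Gompertz damage model: aging acceleration `q` (1/d^2) and
hazard `h` (1/d) obey

    dq/da = (q (L/L_m)^3 s_G + h_a) e (v/L - r) - r q,
    dh/da = q - r h,   dS/da = -h S,

with `r = 3 (dL/da)/L`, integrated from birth with `q = h = 0`, `S = 1`
along the closed-form growth curve. Mean life span is
`a_m = a_b + integral of S` over time since birth; the integral is
truncated when `S < 1e-7` and the tail bound `S/h` is added. For a
fully-grown individual with `s_G = 0` the model collapses to a Weibull
survival `exp(-h_a f v t^3 / (6 L_i))` with mean
`Gamma(4/3) (6 L_i/(h_a f v))^(1/3)`; the integrator is held to 0.5% of
this closed form in the tests.

## Dimensionless life-history indices

Supply stress `s_s = p_J p_S^2 / p_A^3` at ultimate size simplifies to
`k_J E_Hp [p_M]^2 / (f {p_Am})^3`. Setting maturity maintenance to its
reproduction-zero ceiling `p_J = (1 - kappa) p_A` gives
`s_s = kappa^2 (1 - kappa)`, maximal at `kappa = 2/3` with value `4/27`
— the upper bound for any parameter set with nonnegative reproduction.
The precociality coefficient is `s_Hbp = E_Hb / E_Hp`; it tracks the
ratio of birth to puberty weight at abundant food (asserted as a rank
correlation, not an equality, across generated families).

## Temperature

All traits are computed and reported at the reference temperature
20 degC (293.15 K); parameters are assumed given at that temperature.
On request, rates (`{p_Am}`, `v`, `[p_M]`, `k_J`) are multiplied by the
Arrhenius factor `TC = exp(T_A/T_ref - T_A/T)` and the aging
acceleration `h_a` (1/d^2) by `TC^2` before traits are derived.

## Synthetic families

The generator emulates a cross-species collection under the body-size
covariation rules: a zoom factor `z`, log-uniform over `z_range`
(default 0.1-100, three decades), scales `{p_Am}` linearly and the
maturity thresholds as `E_Hb ~ z^beta_b`, `E_Hp ~ z^beta_p`
(defaults 1.7454 and 3). `beta_b = 3 x 0.5818` is chosen so the
family's designed birth-weight exponent equals the empirical reptile
value, giving the pipeline a known ground truth to recover; `beta_p = 3`
makes puberty weight exactly proportional to ultimate weight. Intensive
parameters are size-free up to independent lognormal scatter of 0.1 in
log10 per parameter. Scatter applies to `v`, `[p_M]`, `k_J`, `{p_Am}`,
`E_Hb`, `E_Hp`; it is withheld from `kappa` and `kappa_R` (bounded
fractions for which multiplicative scatter is ill-defined), from
`[E_G]` (bounded below at 6276 J/cm^3 by the composition constants via
`kappa_G < 1`, so 0.1-dex scatter would make a sixth of all draws
inadmissible) and from the aging parameters `h_a`, `s_G` (no
covariation rule is imposed on aging). Draws failing a cheap
admissibility screen (maturity ceiling headroom) are redrawn, up to 100
times per species.

`omega_mode` selects where the assimilation scaling lives. In
`"negligible"` (default) `v` scales with `z` too, so `[E_m]` and hence
the reserve share of weight are size-free and `Ww_i ~ z^3` exactly; in
`"covarying"` `v` stays fixed, `[E_m] ~ z`, and reserve dominates the
weight of large species — the regime in which weight-specific
respiration approaches the -1/4 slope against ultimate weight. In that
limit respiration power scales as `z^3` while weight scales as `z^4`,
giving the quarter-power law without any allometric assumption.

The reference (z = 1) parameter values are reptile-like: `{p_Am}` = 250
J/d/cm^2, `v` = 0.06 cm/d, `kappa` = 0.8, `[p_M]` = 20 J/d/cm^3,
`k_J` = 0.002 1/d, `[E_G]` = 7800 J/cm^3, `E_Hb` = 3.5 kJ,
`E_Hp` = 900 kJ, `h_a` = 1e-9 1/d^2, `s_G` = 1e-4. They give a 10-cm,
~1.2-kg turtle-like animal that hatches at ~2 g after ~80 d, matures at
~40% of ultimate weight (the empirical reptile fraction) after ~6
years, lives ~30 years and has supply stress 0.031, within the band
observed for turtles. `E_Hp` was calibrated once to the 0.4 puberty
weight fraction and not revisited.

What the generator does **not** emulate: estimation-error correlation
structure of real collections, phylogenetic correlation between
species, and any covariation of the aging parameters with size. The
last point means the life-span-vs-respiration slope of -1 seen across
real taxa is *not* expected from synthetic families (life span is
z-free in `negligible` mode and grows only as `z^(1/3)` in `covarying`
mode); the pipeline therefore reports that diagnostic without asserting
a value. Passing tests on synthetic families show the machinery
(shooting, integration, regression, embedding) is correct under the
covariation rules, not that real reptiles obey them.

A second caveat concerns the regression checks themselves: with 0.1-dex
scatter on `{p_Am}` and `[p_M]`, ultimate weight carries ~0.4 dex of
noise that barely propagates to birth or puberty weight (both are
maturity-threshold-dominated). Ordinary least squares of log birth or
puberty weight on log ultimate weight is then attenuated below the
designed exponent by roughly 1-2% (classic errors in variables). The
same structure is present in real collections, where the printed
exponents are likewise OLS on noisy abscissae.

## Trait table and comparative statistics

One row per species; the twelve comparison traits are `a_b`, `a_p`,
`a_m`, `Ww_i`, `R_i`, `E_0`, `E_m`, `v`, `p_M`, `p_Am`, `s_s`,
`s_Hbp`. Failures are flags (`non_viable`, `stalled`, `demand_bound`)
with missing traits, never dropped rows, so survivor curves can state
their denominators. Lifetime cumulated neonate mass is
`R_i (a_m - a_p) Ww_b` — reproduction runs from puberty to death; a
`window="lifespan"` option uses `a_m` alone for comparison with
conventions that ignore the juvenile period. The weight-specific
reproduction survivor diagnostic, where used, is `R_i Ww_b / Ww_i` (a
convention; the normalization is not standardized).

Survivor curves use strict inequality (the fraction of species whose
value *exceeds* the threshold; ties do not exceed). Scaling exponents
are ordinary least squares on log10-log10 axes with conventional
standard errors. Reference lines of fixed slope (-1, -1/4, +1) are
conventions for display, never fitted, and never reported as estimates.
Medians of even-sized groups are the mean of the central pair.

## Trait-space embedding

The distance between two species over K traits is the symmetric bounded
loss

    d_ij = sqrt( (1/K) sum_k (x_ik - x_jk)^2 / (x_ik^2 + x_jk^2) ),

with 0/0 terms counted as zero. It lies in [0, 1], and is invariant to
per-trait unit changes, which is the point: the twelve traits span
~10 orders of magnitude in incompatible units. The square root, the 1/K
normalization and equal trait weights are conventions fixed here so
that distances are bounded by 1; scale invariance is asserted end to
end. Classical (Torgerson) scaling double-centers the squared
distances, `B = -1/2 J D^2 J`, and eigendecomposes; coordinates are
eigenvectors scaled by the square roots of the positive eigenvalues.
Bounded-loss distances are not Euclidean, so negative eigenvalues
occur; they are reported, never embedded. Axis signs are fixed by
making the largest-magnitude coordinate per axis positive, so output is
reproducible. Traits are log10-transformed before correlating with the
axis coordinates (raw scale available via `log_transform=False`);
traits are correlated with eigen*vector* coordinates — correlating with
scalar eigenvalues is not meaningful. Species with any missing
comparison trait are dropped from the embedding with a reported count.
A constant trait has no defined correlation and is reported missing.

## Numerical conventions

- ODEs: `scipy.integrate.solve_ivp` (LSODA), relative tolerance 1e-10,
  scaled absolute tolerances, event-based detection of birth, puberty,
  stall and the survival cutoff.
- Shooting: bisection to 1e-8 relative on `E_0`; residual `|e_b - f|`
  greater than 1e-4 f after convergence signals non-viability.
- Survival integral truncated at `S = 1e-7`, tail bound `S/h` added.
- Degenerate thresholds (`E_Hp` at `E_Hb`) return birth values.
- Log base 10 throughout the comparative layer.

## Problem sizes

The default synthetic family is 300 species (a full trait table takes
about half a minute: ~30 adaptive embryo integrations per species for
the shooting, plus the puberty and aging integrations). The noiseless
scaling checks use 30 species; the quarter-power limit uses 40 species
in the reserve-dominated regime, where no embryo integration is needed.
These sizes give standard errors a few per mill wide, adequate for the
recovery checks.

## Known limitations

- Single-food, constant-environment trajectories only; no starvation
  rules, torpor, or dynamic food histories.
- No metabolic acceleration (type-M) or surface heating length; the std
  model as used for turtles, crocodiles and squamates.
- Oxycaloric respiration closure; no O2/CO2/N-waste stoichiometry.
- Continuous egg production; clutch structure and nesting phenology are
  outside the model.
- The generator's lognormal, independent scatter is a caricature of
  estimation scatter in real collections (see above).
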