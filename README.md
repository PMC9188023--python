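# debtraits

Life-history traits of reptiles from Dynamic Energy Budget (DEB)
parameters, and the comparative statistics used to contrast taxa such as
turtles, crocodiles and squamates: survivor curves, taxon medians,
log-log scaling exponents, and trait-space multidimensional scaling.

The package is for comparative ecophysiologists who have per-species
parameter sets of the standard DEB model (e.g. exported from a curated
collection) and want the derived traits and cross-species patterns,
plus a covariation-rule generator of synthetic species families for
testing the whole pipeline without external data.

## The model in brief

The standard DEB model tracks reserve `E` (J), structural length `L`
(cm) and maturity `E_H` (J). Reserve is mobilized at
`p_C = E (v/L)(g + L/L_m)/(e + g)` with `e = E/(L^3 [E_m])`; a fraction
`kappa` goes to somatic maintenance `[p_M] L^3` plus growth, the rest to
maturity maintenance `k_J E_H` plus maturation (or reproduction after
puberty). At constant food the growth curve is von Bertalanffy with
rate `r_B = k_M / (3(1 + f/g))` and asymptote `L_i = f L_m`. From one
parameter set the package derives: egg cost `E_0` (by shooting on the
embryo ODEs so reserve density at birth equals the mother's `f`), ages
and weights at birth and puberty, ultimate weight, growth and
reproduction rates, weight-specific respiration, Weibull-Gompertz mean
life span, the supply stress `s_s = k_J E_Hp [p_M]^2/(f {p_Am})^3`
(bounded by 4/27) and the precociality coefficient
`s_Hbp = E_Hb/E_Hp`. Details, conventions and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import debtraits as dt

p = dt.reference_fixture()[0]     # a synthetic pond-turtle parameter set
lh = dt.life_history(p)           # all traits at f=1, 20 degC
```

The fields of `lh`, formatted:

```text
pond_turtle_synthetic (Testudines)
  egg cost           E_0  =     58037 J
  age at birth       a_b  =      97.4 d   (hatchling 4.5 g)
  age at puberty     a_p  =      1940 d   (1171 g, 25% of ultimate)
  mean life span     a_m  =     12837 d   (35.1 y)
  ultimate weight    Ww_i =      4718 g
  reproduction rate  R_i  =     0.212 1/d (77 eggs/y)
  specific O2 use    jO2  = 3.43e-05 mol/d/g
  supply stress      s_s  =    0.0302
  precociality       s_Hbp=    0.0035
```

A 58 kJ egg incubates ~97 days into a 4.5 g hatchling; the animal
matures after ~5 years at a quarter of its 4.7 kg ultimate weight, lays
~77 eggs a year at full size and lives ~35 years on average. Its supply
stress (0.03) sits in the band observed for turtles, and the small
precociality coefficient (0.0035) says hatchlings are very immature
relative to adults — both typical of the taxon.

The same works table-wise and from the shell:

```sh
debtraits simulate --seed 1 --n 100 --output-dir out/   # synthetic family
debtraits traits   --input out/parameters.csv --output-dir out/
debtraits scaling  --input out/traits.csv     --output-dir out/
debtraits mds      --input out/traits.csv     --output-dir out/
```

`scaling.csv` then holds, e.g., the log-log slope of birth weight
against ultimate weight (~0.58 for the default family: hatchling size
increases much more slowly than adult size), the puberty-weight slope
(~1: maturation weight is a fixed fraction of adult weight), and the
slope of reserve capacity on assimilation rate (1 by construction,
since `[E_m] = {p_Am}/v`).

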