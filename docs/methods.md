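# Methods

## Renormalization of the mass-specific BMR

The male Harris–Benedict equation gives the whole-body BMR as a linear
function of weight W (kg), height H (cm) and age T (years); per unit mass,

```
msBMR(W,H,T) = (88.362 + 13.397·W + 4.799·H − 5.677·T) / W ,
```

which decreases in W toward the asymptote 13.397 kcal day⁻¹ kg⁻¹.

**First renormalization.** Each subject's recorded weight is replaced by
the weight his height implies at a reference BMI of 21.5 kg/m²
(`W1 = (H/100)²·21.5`). 21.5 is the value the cohort's BMI converges to as
inter-individual dispersion vanishes with age, and the middle of the
healthy range. This removes the weight-driven scatter of msBMR but leaves
a height trend: the HBE rewards height less than the implied weight costs,
so tall men sit below and short men above the common curve.

**Second renormalization.** The weight is readjusted so that msBMR equals
the universal decline `F(T) = F0·e^(−uT)` exactly. Linearity in W gives
the closed form

```
W2 = (88.362 + 4.799·H − 5.677·T) / (F(T) − 13.397) ,
```

the unique positive solution whenever `F(T) > 13.397` (true for all
T ≤ 120 under the default law). We use the closed form rather than a
numeric root-finder for exactness and speed; a `brentq` cross-check lives
in the tests. Defaults `F0 = 27.63`, `u = 0.00364 yr⁻¹` are the published
calibration; `DecayLaw` is a value object so refits never overwrite the
constants.

Tabulated worked-sample values follow the convention that the weight is
rounded to 0.1 kg *before* the BMI is computed (exposed as
`printed_second_renorm`); full precision is used everywhere internally.
One boundary case: the short worked sample's exact weight is 59.849 kg,
which rounds down while the tabulated value (59.9) apparently rounded
59.85 half-up from a coarser intermediate; tests therefore assert
agreement within one printed 0.1-kg unit for that single value.

**Decay-law fit.** `fit_decay_law` is unweighted ordinary least squares of
log(msBMR) on age — exact on noiseless exponential data, and adequate for
per-age means whose sampling noise is small and homoscedastic on the log
scale. Negative fitted slopes within 1e−12 of zero (constant input) are
clamped to u = 0.

## Synthetic cohort generator

`generate_cohort` emulates the structure of a male anthropometric survey
(ages 16–80, five population groups with different height distributions):

* ages: integer uniform on [16, 80] (the analysis bins by integer age);
* group: categorical with default mix 0.35/0.25/0.18/0.12/0.10;
* height: normal per group, means {178, 177, 170, 168, 165} cm, SD 7 cm.
  These means are placeholders — only the tall/short ordering matters,
  because it produces the height trend the second renormalization removes;
* BMI: normal with age-dependent moments, mean linear from 26.1 (age 16)
  to 21.5 (age 105) and SD linear from 5.0 (age 16) to 0 (age 105) — the
  convergence endpoints of the real cohort, without committing to any
  particular polynomial shape in between;
* weight: derived exactly as `(H/100)²·BMI`. Heights are floored at
  130 cm and BMI at 12 so weights stay physiological (≈0.2 % of draws).

One root seed feeds a `SeedSequence`; pipeline stages spawn independent
substreams, so every output is reproducible and stages are decoupled.

What the generator does *not* emulate: survey sampling weights, ethnic
differences in BMI (only heights differ), measurement error, secular
trends, or any correlation between height and BMI. Passing recovery tests
therefore show that the *pipeline* identifies its parameters under the
assumed dispersion structure, not that the model fits any real survey.

With ~300 subjects per integer age at n = 20 000, the per-age sample SD of
msBMR carries ≈4 % sampling noise while its true decline is ≈2 %/yr, so
raw consecutive-age SDs are not strictly ordered; the dispersion-shrinkage
check mirrors the analysis' own smoothing (a quadratic in age over 45–80,
required to be decreasing throughout) plus a rank-correlation bound.

## Binned statistics and convergence extrapolation

`bin_stats` uses sample SDs (n−1); bins with fewer than 10 subjects report
no SD. `quadratic_summary` fits `a·T² + b·T + c` by least squares to any
binned series or mean±SD band over a configurable window (default 45–80).
`convergence_age` solves upper(T) = lower(T) analytically from the
quadratic difference, returning the smallest real root in (80, 200];
identical bands converge at the window edge, parallel bands raise
`NonConvergentError`. A double root is reported as the root.

## Mortality model

`P(T) = expit(C·{F(T_c) − F(T)})` is interpreted as an *annual death
probability* and the survival transform as the yearly product
`S(T+1) = S(T)·(1 − P(T))` anchored at S(80) = 1 — this reproduces the
plateau arithmetic exactly and keeps S in [0, 1]. The centenarian plateau
clamps F (not P) at its value at the plateau age (default 108), which is
numerically equivalent for P and mirrors the mechanism: a floor on the
metabolic rate, maintained by weight loss, not a change in the hazard law.

Defaults (C, T_c): US (1.55, 101), Italy (1.4, 101), Japan (1.5, 102).
Under the US parameters P(108) = 0.678; the adopted plateau constant in
the source analyses is 0.67 (≈1.2 % apart — rounding, or the Italian
parameterization; both are exposed).

**Fitting.** Since `logit P(T) = C·F(T_c) − C·F(T)` is affine in F(T), the
joint least-squares problem over (C, T_c) on the logit scale reduces
*exactly* to one OLS regression of logit(rate) on F(T): slope = −C,
intercept/C = F(T_c), inverted through F. No grid search is needed — the
closed form is the global optimum of the stated objective. A fixed-T_c
mode (regression through the origin) covers the alternative reading in
which T_c is pinned at the observed P = 0.5 age. The default fit window
is 80–104, excluding plateau ages. Degenerate inputs (fewer than four
usable ages, constant rates, rates at 0/1, non-positive fitted C, implied
F(T_c) outside (0, F0)) raise `DegenerateSeriesError`.

## Organ model

The packaged reference table (`rmsbmr/data/reference_organs.csv`) holds
the 70-kg reference male: organ metabolic rates msBMR_k and original
weights W_0k, plus the renormalized weights W_k(r) (total 67.0 kg at age
32, height 175.6 cm, msBMR(r) = 24.59 = F(32)). Weight changes distribute
over organs with shares ∝ msBMR_k^−q, q = 1.15 — exact mass conservation,
most of the change absorbed by adipose tissue, residual mass and muscle.

Renormalized organ weights scale proportionally across subjects,
`W_k(i) = W_k(r)·W(i)/W(r)`, so organ composition is invariant after
renormalization; recorded weights are decomposed back to original organ
weights by distributing the surplus with the same rule.

`calibrate_reference` has two modes. *Fixture* mode returns the tabulated
calibration above — the anchor all decompositions use. *Search* mode runs
the stated iteration (trial age → second-renormalized total → distributed
reduction → organ-weighted mean rate = F(T)) with a 0.01 kcal day⁻¹ kg⁻¹
fixed-point tolerance, solved by bracketing + `brentq` on [16, 106]. On
the shipped table the organ-weighted mean of the adjusted weights is
≈22.2 kcal day⁻¹ kg⁻¹, so the search fixed point sits at a higher age than
the tabulated one; the tabulated organ rates (notably adipose 5.0 and
residual 4.5) are evidently not the exact values behind the printed
calibration, which is why the fixture, not the search result, anchors the
decomposition. Search mode is validated on self-consistent synthetic
profiles. Likewise the tabulated *original* decompositions W_0k(s3/s4) are
not reproducible from the pure msBMR^−q rule and serve as inputs only;
the renormalized columns are reproduced to ±0.01 kg.

Per-organ decay constants (yr⁻¹): muscle 0.00181, liver 0.00624, brain
0.00239, heart 0.00326, kidneys 0.00532, from turnover-time data; adipose
and residual carry the global mean 0.00364 for lack of data. Their
BMR-weighted mean over the reference organs is 0.00366, within 1 % of the
global u — the consistency that justifies using one u for the whole body.

## Allometric sweep

From the reference male's renormalized organs, body mass is swept 1→800 kg
in 0.5-kg steps (final partial steps land exactly on the bounds). Shares
use the *reference* rates throughout, exponent q = 1.05 generally and 1.4
for the brain, under a single joint normalization
`share_k ∝ msBMR_k^−q_k` so each step conserves mass in one pass. The
brain starts at 1/8 of its human weight (the human brain being the outlier
among mammals); the freed 7/8 is not reassigned, so the sweep starts at
65.78 kg. On the downward branch organs are floored at zero with the
shortfall redistributed among the remaining organs — adipose empties near
32 kg and residual near 22 kg, which is precisely what enriches small
bodies in high-rate organs and bends the log BMR–log mass relation onto
the empirical ¾ law (full-range OLS slope 0.787; BMR(1 kg) ≈ 63 kcal/day,
BMR(800 kg) ≈ 9205 kcal/day). The exponent is reported as a range check —
the underlying relation is piecewise-affine in mass, not an exact power
law, and no fitted exponent exists to match digit-for-digit.

## Mitochondrial fusion/fission dynamics

The two-state linear transport system (fission count N1, fusion count N2,
rates per year)

```
N2' = −P21·N2 + P12·N1
N1' = −(P12 + P13 − P11)·N1 + P21·N2
```

has characteristic polynomial λ² + Bλ + C with
B = P12 + P21 + P13 − P11 and C = P21·(P13 − P11); the discriminant equals
(P12 + P13 − P11 − P21)² + 4·P12·P21 ≥ 0 for admissible rates, so the
slow root `u = (B − √(B²−4C))/2` is always real (the complex-root guard is
defensive). `analytic_solution` is the slow eigenmode: N2 = N2(0)e^(−uT),
N1 = N2(0)·(P21 − u)/P12·e^(−uT) (the eigenmode occupancy ratio — the
fast mode decays on the exchange timescale and is irrelevant past a
transient), so the total is a single exponential; sign convention u > 0
for net decay (P13 > P11). The independent check integrates the raw system
with `solve_ivp` (DOP853, rtol 1e−12). In the fast-exchange regime
(P12 + P21 ≫ |P13 − P11|) u ≈ P21(P13−P11)/(P12+P21), and with the
turnover identity N1·P11·TOT = N1 + N2 this is `(P13 − P11)/(P11·TOT)`:
e.g. a 2 % mitophagy/biogenesis imbalance with a 5.49-year turnover gives
u = 0.00364 yr⁻¹ — a 0.36 % yearly loss, 1000 → 685 mitochondria over a
104-year adult span. Constructing parameters outside that regime emits
`FastExchangeWarning` (threshold: exchange < 10× imbalance) rather than an
error. A stochastic (Gillespie) counterpart is a natural extension; the
claims here concern the deterministic mean only.

The mouse rescaling compresses the human decline onto the mouse lifespan:
`F(T) = 58.0·exp{−30·u_liver·(T − 0.5)}` for mouse age T ≥ 0.5 y
(30 = 120 y / 4 y; u_liver = 0.00624, giving an effective 0.1872 yr⁻¹),
with the development phase 0 ≤ T ≤ 0.5 covered by the Gaussian rise
`58.0·exp{−0.8(T − 0.5)²}`, continuous at weaning.

## Pipeline and problem sizes

`run_full_pipeline` chains cohort generation → binned statistics → first
renormalization → decay-law refit → second renormalization → mortality
series generation and refit per population → survival curves (with and
without plateau) → organ decomposition of the four exemplar subjects →
allometric sweep, writing seed-stamped CSVs and a JSON manifest of every
fitted parameter. The pipeline is pure in its config; all randomness
derives from the root seed via spawned substreams.

Default problem sizes — 20 000–25 425 subjects, 10 000 at risk per age in
mortality series, 0.5-kg sweep steps, 100 random parameter sets for the
ODE cross-check — keep the full suite around a minute on one CPU while
leaving sampling error far below the recovery tolerances (10 % on u and C,
1 year on T_c).

## Known limitations

* Male-only: the female Harris–Benedict form and any female calibration
  are out of scope.
* The generator's BMI/height independence and group-invariant BMI curves
  are simplifications; recovery results quantify pipeline correctness, not
  real-survey fit.
* The organ table's printed original decompositions and the printed
  reference calibration are internally inconsistent with the stated
  redistribution rule (see above); only the renormalized columns are
  treated as reproducible.
* The mortality model is a period, all-cause description of ages ≥ 80; no
  cohort life-table or cause-of-death structure.
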