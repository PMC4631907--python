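# Methods

## The model

Net CO2 assimilation of a C3 leaf follows the Farquhar–von Caemmerer–Berry
(FvCB) model. At chloroplast CO2 mole fraction `Cc` the gross carboxylation
rate is the minimum of a Rubisco-limited and an RuBP-regeneration-limited
rate,

    Wc = Vcmax · Cc / (Cc + Kc·(1 + O/Ko))
    Wj = J · Cc / (4·Cc + 8·Γ*)

and net assimilation is

    A = (1 − Γ*/Cc) · min(Wc, Wj) − Rd .

Above the photorespiratory compensation point Γ* this is identical to the
familiar `min(Ac, Aj)` of the two net branch rates; taking the minimum on
the gross rates also selects the correct (least-negative) branch below Γ*,
where the photorespiratory factor changes sign. This matters in practice:
CO2-response curves start at a 50 µmol mol⁻¹ setpoint, slightly below Γ*
for these species, and with the net-rate minimum that single efflux point
becomes a degenerate lever on Jmax during fitting (a 0.5 µmol m⁻² s⁻¹
perturbation there moves the fitted Jmax by hundreds). The gross-rate form
removes the artifact because the Rubisco branch is the active one at low
CO2 for any realistic Jmax/Vcmax.

Kinetic constants default to the widely used tobacco-derived C3 values at
25 °C (Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹)
and are injected, never hard-wired. Γ* presets for the three montane study
species are 52.513 (Quercus spinosa), 54.145 (Salix atopantha) and 52.512
µmol mol⁻¹ (Rumex dentatus). All fitting is done in mole-fraction units
(the instrument's native scale) at 25 °C; partial pressures are a display
conversion through the site pressure. Triose-phosphate limitation is not
modelled. Respiration in the light is set equal to the dark respiration
measured on the same leaf (`FitOptions.rd`); co-fitting Rd is available
(`fit_rd=True`) but off by default.

## A/Ci fitting

`fit_aci` least-squares fits `(Vcmax, Jmax)` (optionally Rd) against the
measured intercellular CO2. The model is piecewise linear in the capacity
parameters, so the solver is given the exact branch-assignment Jacobian.
Initial values are deterministic — Vcmax from the closed-form
Rubisco-window estimate, Jmax from `4·(max A + Rd)` — expanded into a fixed
three-point multi-start grid; among converged candidates within 1 %
relative cost of the best, the smallest-capacity one is chosen, so the flat
directions described below can never return an initialisation-dependent
number. Repeated fits of the same curve are bitwise identical.

**Identifiability.** A capacity parameter is only informed by the data
where its branch limits. With the default constants, a curve measured up to
2000 µmol mol⁻¹ expresses RuBP limitation only when Jmax/Vcmax ≲ 3.1 (the
branch crossing `C* = (J·Km − 8Γ*V)/(4V − J)` must fall inside the measured
range). Beyond that the likelihood is exactly flat in Jmax. When a branch
never limits, `fit_aci` reports the smallest value consistent with the
curve — the boundary where that branch just touches the active one
(`Jmax_b = V·max_i (4Ci+8Γ*)/(Ci+Km)`, and symmetrically for Vcmax) — and
flags it through `jmax_identified` / `vcmax_identified`. Fitted values for
such curves are lower bounds, not estimates, and the parameter-recovery
study therefore samples Jmax/Vcmax in the identifiable 1.5–3.0 window
(Vcmax spans the full 30–102 µmol m⁻² s⁻¹ range of the emulated study).

**Vcmax for group comparison.** The pipeline's group statistics use the
slope-window estimate of Vcmax (Rubisco branch fitted to the points with
setpoints in 40–200 µmol mol⁻¹, closed form, `vcmax_slope_estimate`) — the
operational definition of carboxylation capacity in this workflow. It is
linear, bounded and stable even on curves whose branch structure is
ambiguous under noise, where the full fit can occasionally run away. The
full-fit Vcmax stays in the fits table, and a
`slope_estimate_divergent` flag marks leaves where the two disagree by more
than 10 % (e.g. RuBP contamination of the window at low Jmax).

Amax is reported as the fitted model's prediction at the saturating
setpoint (2000 µmol mol⁻¹ by default); it can never exceed the
RuBP-regeneration ceiling `Jmax/4 − Rd`.

## Variable-J mesophyll conductance

The operating quantum yield of PSII, `ΦPSII = (Fm′ − F)/Fm′`, converts to a
linear electron transport rate `J = ΦPSII·PPFD·α·β` with the standard field
calibration α = 0.85, β = 0.5 (configurable). Inverting the
RuBP-regeneration equation at the measured A locates the chloroplast CO2,

    Cc = Γ*·(J + 8(A+Rd)) / (J − 4(A+Rd)),   Gm = A / (Ci − Cc),

which is the exact algebraic inverse of the forward chain (roundtrip error
≤ 1e-10 over random draws — an acceptance gate). The estimator is undefined
for `J ≤ 4(A+Rd)` and such records are dropped with a reason, never
imputed. Additionally, the sensitivity of the inversion,
`|dCc/dJ| = 12·Γ*·(A+Rd)/(J − 4(A+Rd))²`, is computed for every record and
estimates above the conventional reliability limit of 50 are likewise
dropped: near the validity boundary a fraction of a percent of fluorescence
noise translates into order-of-magnitude Gm errors. Stomatal conductance
carries an explicit water/CO2 basis flag; the 1.6 diffusivity ratio is
applied exactly once. Total conductance combines the two pathways in
series, `Gtot = Gs·Gm/(Gs+Gm)`, and the diffusional drawdown is summarised
by the mole-fraction ratios Pi/Pa = Ci/Ca and Pc/Pa = Cc/Ca (equal to the
partial-pressure ratios at common total pressure).

## Elevation physics

Site pressure defaults to the international standard atmosphere
`P = 101.325·(1 − 0.0065·h/288.15)^5.25588` kPa and can be overridden by an
instrument-sensed value; the partial pressure of CO2 is
`p = x·10⁻⁶·P·10³` Pa and temperature follows a linear lapse of 5.5 °C per
km by default. The default campaign pins the two sites to the study
conditions — ambient pCO2 of 27.7 Pa at 2500 m and 24.6 Pa at 3500 m (an
11.2 % reduction) at a cuvette CO2 of 380 µmol mol⁻¹ — via the measured-
pressure override (72.89 and 64.74 kPa), because those endpoints are not
mutually consistent with the barometric formula (which gives 74.7 and
65.8 kPa).

## Leaf traits

SLA = area/dry mass (cm² g⁻¹); Narea = 10·Nmass/SLA (g m⁻², the factor 10
reconciling mg→g and cm²→m²); PNUE = A·14/Narea (µmol mol⁻¹ s⁻¹, 14 g
mol⁻¹ the atomic mass of nitrogen); δ¹³C = 1000·(Rsample/Rstandard − 1) ‰
against Pee Dee Belemnite (R = 0.0112372). PNUE is computed per leaf and
averaged afterwards; a ratio of group means differs from the mean of
per-leaf ratios by under 1 % at these CVs, which is why reproducing
published group-mean arithmetic agrees to ≈1 % rather than exactly. δ¹³C
values outside the plausible C3 range (−35 to −20 ‰) warn but do not fail.

## Statistics

Classical equal-variance one-way ANOVA over the six species × elevation
groups (df 5, 30 at n = 6), with the sum-of-squares decomposition computed
directly (cross-checked against an independent implementation in the test
suite) because MS_within feeds the post hoc step. Pairwise structure uses
Fisher's LSD, `t(0.975, df_w)·sqrt(MSw·(1/n_i + 1/n_j))`, rendered as a
compact letter display via the insert-and-absorb algorithm with groups
ordered by descending mean (deterministic); the display satisfies, and the
tests assert, shared letter ⇔ |mean difference| < LSD for every pair. LSD
is protected by default — letters collapse to a single group when the
omnibus test is not significant at α = 0.05 — with an unprotected flag.
Elevation effects are signed percent changes of the high-elevation group
mean, `100·(high − low)/low`, with a first-order delta-method SE assuming
independent groups (validated against Monte Carlo within 5 %); the SE
definition for such derived effects is this package's choice and is
labelled as such. Simple regressions report OLS slope, R², and
`F = (n−2)·R²/(1−R²)` on (1, n−2) df.

## Synthetic campaigns

The generator emulates a two-elevation (2500/3500 m) field comparison of
three species with 6 leaves per group. Each leaf draws Vcmax, Jmax/Vcmax,
Rn, Gs, Gm, SLA, Narea and δ¹³C from truncated-Gaussian distributions
around the group means, with between-leaf SD = SE·√6 from the published
group summaries, clipped to CV ≤ 0.5. Jmax is constructed as
(Jmax/Vcmax)·Vcmax rather than drawn independently, which honours the
tight published ratio distributions; other quantities are independent (a
known simplification — real leaves correlate Gs with Gm and capacity with
nitrogen).

A point measurement solves the supply/demand balance
`A = FvCB(Ca − A·(1/Gs + 1/Gm))` by bracketed root finding and emits
fluorescence `(F, Fm′)` scaled so the implied electron transport satisfies
the RuBP equation at the leaf's Cc exactly — with noise off, every
downstream estimator recovers its generating value, which is the package's
core self-consistency surface. Response curves run a 12-step setpoint
ladder (50…2000 µmol mol⁻¹) with stomatal limitation suppressed (Gs = 3
mol m⁻² s⁻¹, emulating low-CO2 pre-conditioning of the leaves) and the
mesophyll path transparent, giving pure A/Ci curves. Species-specific
saturating PPFD: 1200 (Q. spinosa), 1400 (S. atopantha), 2000 (R. dentatus)
µmol m⁻² s⁻¹.

Noise: additive Gaussian with SD 0.5 µmol m⁻² s⁻¹ on A, and multiplicative
0.2 % per raw fluorescence signal (the repeatability of signal-averaged
modulated fluorometry). The fluorescence figure was fixed by sensitivity
analysis before any end-to-end testing: ΦPSII error is amplified by
≈(1−φ)/φ into J and by the |dCc/dJ| factor into Cc, so percent-level
per-signal noise would make Gm from low-assimilation leaves meaningless.
Noisy A is propagated into Ci and Cc through Fick's law so each record
stays internally consistent. A leaf whose emitted record fails the
variable-J validity or sensitivity criteria is redrawn (and counted),
mirroring a campaign that remeasures until each group reaches its quota of
usable leaves. Output is byte-identical for a fixed config and seed.

What the generator does not emulate: instrument drift, leaks and gasket
diffusion, leaf-temperature error, covariance between traits, diurnal or
water-status variation, and any systematic (non-random) error in the
fluorescence calibration. Passing the recovery tests therefore shows the
estimators invert this forward model correctly at realistic noise — not
that field data meet the model's assumptions.

## Problem sizes and numerics

The test suite and the acceptance script use: 100 synthetic curves for the
recovery study (noiseless and noisy), 1000 random draws for the variable-J
roundtrip, 100 random 6-group configurations for the letter-display oracle,
and 100 seeded campaign replicates for the end-to-end design check — sizes
chosen to estimate each rate comfortably while keeping a full run in the
low minutes on one core. Optimiser tolerances are 1e-12 (xtol/ftol/gtol)
with bounds Vcmax ∈ [1e-3, 1500], Jmax ∈ [1e-3, 3000]; the fixed-point
solver brackets A between the model's efflux floor and the supply-line
limit and solves to 1e-12. Ties in the letter display are broken by group
ordering; degenerate inputs (flat curves, all-constant groups, zero
baselines) raise typed errors rather than returning numbers.

## Known limitations

- Jmax above ≈3.1·Vcmax is reported as a flagged lower bound, never an
  estimate; group comparisons of Jmax for such populations compare bounds.
- Single-point variable-J Gm has a heavy right tail on leaves operating
  near the compensation point even inside the conventional sensitivity
  limit; at the emulated noise level the direction of a 6-leaf group
  contrast in Gm is stable in roughly 19 of 20 campaigns, not always.
- No temperature normalisation of capacity parameters (everything at
  25 °C) and no Ci→Cc refitting of the A/Ci curves through Gm.
- Published F statistics of the emulated study cannot be reconstructed
  from group means ± SE alone and are treated as consistency references
  only.
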