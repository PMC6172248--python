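# Methods

## Model structure

`sulfor` integrates 20 state variables over 570 Myr of forward time
(all masses in 10¹⁸ mol, fluxes in 10¹⁸ mol/Myr, compositions in ‰):

* **masses** — ocean–atmosphere carbon `OA_C`; young/ancient crustal organic
  carbon and carbonate; young/ancient pyrite and gypsum; ocean sulphate
  `OA_S`; ocean–atmosphere O₂;
* **compositions** — δ¹³C of the four crustal carbon reservoirs, δ³⁴S of
  sulphate and the four crustal sulphur reservoirs.

Seawater δ¹³C is *prescribed* by the driving record — that is what the IMB
inversion means — so it is not a free state. Each crustal reservoir is split
into a rapidly re-weathered young pool and a slowly cycled ancient pool
("rapid recycling"), with young→ancient transfer proportional to the young
mass so the ancient inventories can drift rather than being pinned.

### Carbon fluxes

Organic burial comes from the isotope mass balance of the surface carbon
reservoir (see README). Weathering fluxes are multiplicative GEOCARB-family
laws: a present-day anchor flux × reservoir ratio × an erosion term
fA^0.5 · fD^0.65 × (for silicate and young carbonate) a climate multiplier,
plus the chemically-weathering land fraction fAW and plant enhancement on
silicates and the carbonate land fraction fL on young carbonates. Oxidative
weathering of young and ancient organic carbon carries O₂mr^β (β = 0.5,
matching the exponent the young-pyrite weathering law uses, for internal
consistency). Degassing of each crustal reservoir is a rate constant ×
reservoir mass × spreading rate fSR, with a platform/deep-ocean weighting
for carbonates (deep-ocean carbonate is recycled more efficiently;
platform fraction 0.5 at present, shallow efficiency 0.5 relative to deep).

### CO₂ closure

Carbonate burial is set by alkalinity supply, `F_bc = F_wc + F_ws`, so the
surface carbon balance reduces to the classical quasi-equilibrium

```
F_ws(m) = degassing + organic weathering − F_bg(m)
```

where `m` is the climate multiplier. Because `F_bg` from IMB is *linear* in
`m` (only young carbonate weathering among the carbon inputs carries the
climate term), `m` has a closed form at every evaluation — the right-hand
side of the ODE system contains no root-finding. RCO₂ is recovered
diagnostically by inverting the climate function

```
m(RCO₂) = exp(ACT·ΔT) · (1 + RUN·ΔT)^0.65 ,  ΔT = gcm·ln(RCO₂) + GEOG
```

with ACT = 0.09 K⁻¹, RUN = 0.045 K⁻¹ and gcm = 4 K per e-fold of CO₂. The
multiplier is 1 at present and strictly increasing in RCO₂. A consequence of
the quasi-equilibrium closure is that GEOG shifts the diagnosed RCO₂ rather
than the weathering fluxes themselves — CO₂ adjusts to whatever level the
mass balance demands. CO₂ is internal state here; the package's outputs of
record are pO₂ and the synthetic δ³⁴S.

If the IMB demands negative organic burial (possible under strongly negative
record excursions) the flux is clipped to zero, flagged per reported age and
counted in the solver diagnostics; if silicate weathering would have to be
negative to balance the books, the run is terminated as a structured
`co2_collapse` failure.

### Sulphur fluxes

The four forward laws are given in the README. Ancient pyrite and gypsum
weather as rate constant × reservoir × erosion, with the O₂mr^0.5 oxidative
feedback on pyrite only. Degassed sulphur is routed to ocean sulphate
(emitted oxidized), keeping the five-reservoir system closed. `Calc`, the
normalized seawater calcium reservoir entering gypsum burial, is supplied as
a forcing series defaulting to 1 — no governing equation is adopted for it.
The 1/O₂mr factor in pyrite burial is guarded by an O₂mr floor of 10⁻³;
reaching the floor terminates the run as an `o2_floor` failure (this is the
"oxygen crashes to zero" outcome, reported as data).

δ³⁴S budget: pyrite is buried at sulphate δ³⁴S − α_s (α_s = 35‰ constant,
used *only* for the synthetic δ³⁴S output, never to compute fluxes); gypsum
is buried unfractionated; weathering and degassing return each reservoir's
own composition. Total ³⁴S-weighted mass is conserved by construction.

### Legacy diagnostic

The legacy scheme — α_s = Δ_s0 · O₂mr^n with Δ_s0 = 35‰, n = 1.5, feeding an
IMB inversion for pyrite burial — is retained purely as a diagnostic
(`legacy_sulphur_diagnostic`, CLI verb `legacy-s`). Its constants are
configurable; the power-law form and defaults are standard for this model
family rather than derived here. The diagnostic holds the carbon/sulphur
background at its present-day reference because it illustrates the flux
relationship, not a transient run.

## Calibration

Present-day fluxes form a self-consistent steady state (COPSE-like values):
silicate weathering 6.65, carbonate weathering 8.0 + 5.35 (young + ancient),
organic burial 4.5, organic weathering 2.0 + 1.75, carbon degassing
0.5/0.25/1.0/5.65 per reservoir, carbonate burial 20 by alkalinity closure;
pyrite burial 0.53, gypsum burial 1.0, young pyrite/gypsum weathering
0.35/0.6, ancient 0.15/0.3, sulphur degassing 0.01/0.02/0.05/0.05 and
transfers 0.17/0.35 (all 10¹⁸ mol/Myr). Reservoir anchors: OA carbon 3.193,
organic 250 + 1000, carbonate 1000 + 4000, sulphate 38, O₂ 38, pyrite
70 + 210, gypsum 40 + 60 (10¹⁸ mol). Config validation enforces the closure
identities (every reservoir balances at the anchors), so changing one
constant without its counterparts fails loudly instead of silently breaking
the steady state. The young/ancient split of the sulphur totals is not
independently constrained; defaults are 25% young pyrite and 40% young
gypsum, exposed in the config.

Initial reservoir compositions default to δ¹³C = +1‰ (carbonate), −24‰
(organic), δ³⁴S = +20‰ (sulphate/gypsum), −15‰ (pyrite); with Δ₀ = 25‰ and
α_s = 35‰ these make the present state an exact fixed point of the isotope
budgets as well as the mass budgets.

Key tunables: `j` (default 4) couples O₂ to carbon fractionation — larger J
stabilizes the model harder; `delta0` = 25‰ present fractionation; `beta` =
0.5 oxidative-weathering exponent; solver `rtol` 10⁻⁶ / `atol` 10⁻⁹ and
`max_step` 5 Myr (so ~10-Myr isotope excursions cannot be stepped over).

## Numerics

scipy's Radau method (adaptive implicit Runge-Kutta, stiff-capable)
integrates the system; dense reporting is on a 1-Myr grid. Runge-Kutta
methods preserve linear invariants exactly, so total C and total S are
conserved to roundoff; the quadratic isotope invariant is conserved to
solver tolerance (verified < 10⁻⁵ relative in tests). The record and
forcings are interpolated piecewise-linearly; the record's time derivative
uses a ±0.5 Myr central difference of the interpolant, which keeps the
right-hand side continuous across grid kinks. State floors (O₂mr ≥ 10⁻³,
sulphate ≥ 10⁻³ of present) are implemented as terminal solver events and
convert unphysical excursions into structured failures with age and cause.
Solver quality is tested two ways: tolerance halving changes pO₂ by < 0.1%
everywhere on the excursion fixture, and a brute-force explicit Euler oracle
at 1-kyr steps agrees with the stiff solution to < 0.5% in every state
variable over a 10-Myr sub-interval spanning the excursion.

## Synthetic data

The generator emulates the *structure* of the real inputs: smooth forcing
curves equal to 1 at 0 Ma with bounded deviation; a δ¹³C record with a
baseline near the steady-state value, localized excursions of a few ‰ and
pointwise sd of ~1‰. The `steady` scenario computes its flat record value
from the configured fluxes by the closed-form steady state (never
hard-coded); `excursion` adds one +2‰ event at 500 Ma (width 10 Myr);
`stress` adds a deep (−8‰) sustained negative excursion near the start,
which drives the IMB to demand negative burial and collapses oxygen — the
designed structured-failure path, emulating what a −1 SD shift does to a
realistic record. What the fixtures do **not** emulate: the spectral
content, sampling irregularity and lithology-dependent scatter of real
compilations, or any covariance between forcings. Passing tests on fixtures
therefore demonstrate correctness of the machinery and the qualitative
feedback structure, not agreement with the geological record — that requires
user-supplied digitized inputs.

## Design choices made where the design was open

* Interpolation of forcings/records is piecewise-linear (higher order would
  invent structure in coarse tables); loaders are strict about present-day
  normalization by default, with an opt-in lenient mode that renormalizes.
* The moving-average smoother for records is defined over an age window
  (Myr), not sample counts; a second-pass spline smoother was considered and
  rejected as the default so that the documented moving average remains the
  canonical treatment.
* Pointwise sd (not a global sd) is used for record-shift envelopes.
* `Pyr₀`/`Gyp₀` in the young weathering laws are the present-day *young*
  reservoir masses.
* Negative IMB burial demands are clipped (negative burial is unphysical)
  and surfaced as a health flag rather than allowed or fatal.
* Sulphur degassing is emitted oxidized (no O₂ consumption on emission);
  partial reduced emission would add an O₂ sink term and is noted as a
  limitation.

## Known limitations

* The CO₂ side is a quasi-equilibrium diagnostic, not a prognostic CO₂
  reconstruction; comparing RCO₂ to proxies is out of scope.
* Seawater calcium is a forcing, not a dynamic reservoir, so gypsum burial
  cannot feed back on calcium.
* The model inherits the IMB framework's sensitivity to the driving δ¹³C
  record: sustained strongly negative excursions terminate the run (by
  design, as a reported failure) rather than being absorbed by additional
  stabilizing feedbacks.
* Rate constants are a self-consistent calibration of this package, not a
  fitted inversion of geological data; absolute flux magnitudes carry that
  uncertainty even though normalization anchors make the *relative* dynamics
  robust.
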