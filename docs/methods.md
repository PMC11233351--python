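# Methods

## Model

Live macrophages carry lipid `a ≥ 1` (units of endogenous membrane lipid;
time in mean lifespans `1/β`).  The dimensionless densities `m(a,t)` and
`p(a,t)` of live and apoptotic cells are probability distributions — the
population scales live in a closed aggregate subsystem for
`(M, P, A_M, A_P, N)`.  Five processes move lipid:

* **advection** at speed `v = λ/M + θN`: net LDL uptake / HDL offloading
  (`λ`, shared across the population, hence the `1/M`) plus consumption of
  necrotic lipid (`θN`);
* **efferocytosis** (rate coefficient `η`): a live cell of lipid `a − a′`
  eats a whole apoptotic cell of lipid `a′`, a convolution source with sink
  `−ηPm`;
* **proliferation** (rate `ρ`): the parent at `2a − 1` synthesises one lipid
  unit and divides into two daughters at `a`; pantograph source
  `4ρ m(2a−1)` (the factor 4 = two daughters × interval compression 2) and
  sink `−ρm`;
* **apoptosis, emigration, secondary necrosis** (`1, γ, ν` after scaling):
  kinetic exchanges between the compartments;
* **recruitment**: monocytes enter at `a = 1` at the Hill-type rate
  `R = (A_M − M)/(κ + A_M − M)`, encoded as the boundary flux
  `v·m(1,t) = R/M`.

Because `m` is kept normalised, the transport equation carries an extra
renormalisation sink `−(R/M + ρ)m`.  The aggregate subsystem is exact and
closed; for `ρ < 1 + γ` it has a unique positive equilibrium with `M*` the
positive root of

    (1+γ−ρ)(M*)² + [λ−1+γ(κ+γκ+λ)−ρ(λ+γκ)]M* − λ = 0,

evaluated in the cancellation-free branch of the quadratic formula
(`2λ/(b+√disc)` when the linear coefficient is positive).

## Default parameters

| symbol | default | meaning |
|--------|---------|---------|
| ρ      | 0.8     | divisions per mean lifespan (swept 0…1+γ in analyses) |
| γ      | 0.25    | emigration per lifespan (≈ 0.013 h⁻¹ / 0.05 h⁻¹) |
| ν      | 0.8     | secondary necrosis per lifespan |
| η, θ   | 1.5, 0.4 | efferocytic vs necrotic uptake; η > θ assumed |
| λ      | 0.1     | net LDL influx; sets M(0) ≈ 0.13 (resident cells) |
| κ      | 5       | internalised lipid at half-maximal recruitment |
| a_σ    | 2       | scale of the initial half-normal spread |

All are dimensionless; `redimensionalise` restores units given
`(a₀, β, α)`.  The initial condition is the half-normal of scale `a_σ` for
both densities with `M(0) = κλ√(2π)/(a_σ(a_σ√(2π) − 2λ))` pinned by the
boundary condition, `P(0)/M(0) = 0.5` (configurable), `N(0) = 0`.  Validity
requires `a_σ√(2π) > 2λ` (hard), `ρ < 1+γ` (hard); `η > θ` and `κ > a_σ`
are advisory modelling assumptions and produce warnings only.

## Numerical scheme

Method of lines on `a ∈ [1, a_max]`, `a_j = 1 + j/q` with integer `q`
(default `q = 20`, `a_max = 100`): the spacing divides 1 exactly, so the
pantograph argument `2a_j − 1 = a_{2j}` and all convolution offsets land on
nodes with zero interpolation error.  The lipid derivative uses the
three-point second-order upwind stencil (first-order at the first interior
node, where the stencil does not fit); the convolution uses the trapezoidal
rule as an exactly aligned discrete convolution (`numpy.convolve`, verified
against an O(J²) double loop to 1e-12); the pantograph source is omitted at
nodes with `2j > J`, where its argument leaves the domain.  The boundary
node is an algebraic constraint re-evaluated from the aggregate state at
every right-hand-side call; its stored derivative is zero.  Time
integration: adaptive explicit Runge–Kutta (rtol 1e-6, atol 1e-9 defaults);
the aggregate subsystem alone uses LSODA at rtol 1e-8 / atol 1e-10.

### Mass-error instability and the relaxation term

The exact dynamics leave the manifold `∫m da = ∫p da = 1` invariant, but the
manifold is **transversally unstable** whenever `ηP* > 1 + γ − ρ`.  Writing
`ε_m = ∫m − 1`, `ε_p = ∫p − 1`, linearising the integrated equations gives

    dε_m/dt = −(R/M) ε_m + ηP ε_p,      dε_p/dt = (M/P)(ε_m − ε_p),

a saddle with growth rate λ₊ ≈ +0.18 at the default parameter set.  The
discrete scheme seeds ε through its inflow-boundary quadrature defect — the
trapezoid rule applied to the upwind derivative mis-states the boundary
flux by `−(h/2) v m′(1)`, a first-order-in-h residual (measured directly;
it halves when the grid is refined twofold).  The seeded error is then
amplified by e^{λ₊ t}: integrated to t = 200 the literal scheme fails near
t ≈ 95–110 at every resolution q = 5…40 and with both explicit and implicit
integrators, while an exact closed moment hierarchy (below) shows the true
solution is perfectly stable.  The simulator therefore adds

    −σ (∫m da − 1) m(a, t),        σ = 5 by default,

to the live-density equation.  The term vanishes identically on the
invariant manifold, so the semi-discrete scheme remains consistent with the
continuous model and second-order convergent; it turns the saddle into a
sink for any `σ > λ₊`.  The normalisation error is still *monitored, not
enforced*: it equilibrates at (quadrature residual)/(σ − λ₊) ≈ 3×10⁻⁴ on the
default grid — an honest measure of discretisation quality — and the run
aborts if it ever exceeds a configurable ceiling (default 0.05).  Setting
`mass_relaxation = 0` recovers the literal scheme, which is how the
instability statements above can be reproduced.

### Independent oracles used in the tests

* **Closed moment hierarchy**: multiplying the transport equation by `a^n`
  and integrating closes `dμ_n/dt` on lower moments and the aggregates —
  an exact, grid-free reference for the time-dependent problem.  Its
  long-time limits agree with the steady-state recurrence to 1e-6.
* **Steady moment recurrence** (`φ₀ = 1`, `φ₁ = A_M*/M*` from the ODE
  equilibrium, `φ_n` for n ≥ 2 by the full-history recurrence): preferred
  over quadrature of the simulated distribution because it is free of
  tail-truncation error; quadrature is used only as a cross-check
  (`φ₂` agrees to ≈ 1 % at `a_max = 100`; the deficit is the genuine tail
  mass beyond the domain — the equilibrium tail is heavy, decaying at only
  ≈ 0.09–0.15 per lipid unit at the defaults).
* **Series solution** for `η = 0`: the inner alternating products
  `2^i/∏_{ℓ≠i}(1 − 2^{i−ℓ})` are accumulated as sign + log-magnitude
  (they span hundreds of orders and alternate); terms are truncated when the
  geometric bound `(k₃/2k₂)^j max_i|c_{j,i}|` falls below 1e-12 (cap
  j = 40).  The series is verified directly against the steady
  boundary-value equation and against time-marched solutions.

## Profile classification

At `a = 1` the convolution vanishes and the pantograph argument coincides
with the boundary, so the equilibrium slope is analytic:
`dm*/da(1) = (k₃ − k₂) m₁*`, positive exactly when `3ρ > ηP* + 1 + γ`.
Class a/b (boundary maximum) vs c/d (interior maximum) is decided by this
criterion, never by peak counting; a vs b and c vs d are separated by the
presence of secondary peaks (relative height ≥ 1 % of the maximum,
separation ≥ 2 cells — both configurable).  Class d's secondary peak sits
near twice the primary location (a cell that ate an equally laden apoptotic
cell).  The positive-slope boundary structure has width `1/k₂`, which can be
a few hundredths of a lipid unit in strongly proliferative regimes; grids
for classification runs are chosen with `h ≪ 1/k₂` (`q = 40` in the tests).

## Problem sizes and horizons

Production runs use `q = 20`, `a_max = 100`, `t = 200` (≈ 50 s on one CPU).
The test suite exercises the same code on compact domains
(`a_max = 15–60`, `q = 5–40`) with horizons t = 150–400 chosen per regime:
the no-efferocytosis cases relax slowly (t = 400), strongly proliferative
cases quickly (t = 250–300).  The Richardson ratio of terminal profiles at
q = 5/10/20 is ≈ 4 away from the boundary (second order); the first-order
boundary closure limits the local order near `a = 1`, and the kink at
`a = 2` (convolution onset) limits it there — both expected properties of
the stencil, not defects.

## What the defaults do and do not show

The default parameter set describes a mid-stage plaque with efficient
efferocytosis and moderate proliferation; sweeps vary `(ρ, γ, η, θ)` only.
The model assumes division rate, emigration and uptake are independent of a
cell's lipid load, no crowding (hence the unphysical `ρ ≥ 1 + γ` regime is
excluded rather than saturated), equal lipid split between daughters, and no
plaque regression mechanism.  Conclusions about real plaques inherit those
assumptions; the tests validate the mathematics, not the biology.

## Known limitations

* The equilibrium tail is heavy; moments of order ≥ 3 computed by
  quadrature on a truncated domain are substantially under-estimated — use
  the recurrence.
* The boundary-layer width `1/k₂` must be resolved for slope-sensitive
  outputs; the default grid is adequate for the default regime but
  `q` should be raised for `ρ` near `1 + γ` or large `η`.
* With `mass_relaxation = 0` the simulator reproduces the literal scheme
  and inherits its finite-time mass blow-up in regimes with
  `ηP* > 1 + γ − ρ`; this mode exists for demonstration, not production.
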