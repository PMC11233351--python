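# plaquesim

Simulation and steady-state analysis of a lipid-structured population model
of macrophages in early atherosclerotic plaques, with local proliferation.

## The scientific problem

Atherosclerotic plaques grow when lipid-laden macrophages in the artery wall
die faster than their corpses can be cleared, spilling lipid into an
extracellular necrotic core.  Many plaque macrophages are born *inside* the
plaque by cell division rather than recruited from the blood, yet division is
awkward for classical "macrophage vs foam cell" models: a dividing foam cell
splits its lipid between two daughters whose class is ambiguous.  Treating
the cellular lipid content `a` as a continuous structural variable removes
the ambiguity: division becomes a non-local *pantograph* term that maps cells
at `2a − 1` to cells at `a` (the parent synthesises one endogenous unit of
membrane lipid, then splits everything equally).

The model tracks the lipid densities of live macrophages `m(a, t)` and
apoptotic cells `p(a, t)` on `a ≥ 1` (lipid in units of the endogenous
membrane lipid `a₀`, time in units of the mean macrophage lifespan `1/β`):

```
∂m/∂t + (λ/M + θN) ∂m/∂a = ηP [ (m⋆p)(a) − m ]          efferocytosis
                           + ρ [ 4 m(2a−1) − m ]          proliferation
                           − ( R/M + ρ ) m                renormalisation
∂p/∂t = (M/P) (m − p)
```

with the convolution `(m⋆p)(a) = ∫₁^{a−1} m(a−a′) p(a′) da′` (a live cell
eats a whole apoptotic cell), a recruitment boundary condition
`(λ/M + θN) m(1,t) = R/M` driven by the Hill-type flux
`R = (A_M − M)/(κ + A_M − M)`, and a closed five-variable ODE subsystem for
the aggregates: live cells `M`, apoptotic cells `P`, their lipid totals
`A_M`, `A_P`, and the necrotic core lipid `N`.  The aggregate subsystem has a
closed-form equilibrium (`M*` solves a quadratic with exactly one positive
root) whenever `ρ < 1 + γ`, i.e. whenever division does not outpace apoptosis
plus emigration.

The package answers, quantitatively: does proliferation shrink or feed the
necrotic core, how does it reshape the population's lipid distribution
(mean, skewness, number and position of peaks), and how does a
proliferation-dominant plaque differ from a recruitment-dominant plaque of
identical size and composition?

## What is implemented

* `parameters` — dimensional ⇄ dimensionless conversion, regime validation,
  half-normal initial conditions with the recruitment-consistent `M(0)`.
* `ode` — aggregate right-hand side, adaptive integration, closed-form
  steady states, finite-difference sensitivities, the
  proliferation-vs-recruitment equivalence `(β + γ − ρ)/α = const` and the
  proliferation fraction `r = ρ/(1 + γ)`.
* `pde` — method-of-lines simulator: uniform grid with `q` nodes per lipid
  unit (so `2a − 1` and all convolution offsets land exactly on nodes),
  second-order upwinding, trapezoidal convolution, pantograph truncation
  rule, algebraic boundary pinning, and a consistent mass-relaxation term
  (see `docs/methods.md` — the normalisation manifold is transversally
  unstable and the literal scheme fails without it).
* `steady` — boundary-value constants `k₁, k₂, k₃, m₁*`, the alternating
  series solution for the no-efferocytosis case, the full-history moment
  recurrence, mean/skewness, and the four-profile classifier with the
  analytic boundary-slope criterion `3ρ ≷ ηP* + 1 + γ`.
* `cli` — `plaquesim simulate | steady | sweep | profile-map | tradeoff |
  validate-config`, all emitting CSV plus a JSON manifest; the pipeline is
  deterministic.

## Worked example

The reference regime (`ρ = 0.8`, `γ = 0.25`, `ν = 0.8`, `η = 1.5`,
`θ = 0.4`, `λ = 0.1`, `κ = 5`, `a_σ = 2`):

```
$ plaquesim steady --out out/
{
  "M_star": 1.0783066603457587,
  "P_star": 0.44604943394096075,
  "A_M_star": 5.791533301728795,
  "A_P_star": 2.395710094249084,
  "N_star": 4.443467118121853,
  "k1": 0.3577697782655536,
  "k2": 1.4539532796686168,
  "k3": 1.7111157095072207,
  "m1_star": 0.24062564664945288,
  "mean": 5.370951988622366,
  "skewness": 3.6453504425922922,
  "r": 0.64,
  ...
}
```

Reading: the plaque equilibrates at `M* ≈ 1.08` live macrophages
(in units of `α/β`) carrying on average `μ = A_M*/M* ≈ 5.37` endogenous-lipid
units each; the necrotic core holds `N* ≈ 4.44` lipid units; 64 % of
macrophages are sourced from division rather than recruitment.  The
equilibrium lipid distribution starts at `m*(1) ≈ 0.241` and, because
`k₃ > k₂` (equivalently `3ρ > ηP* + 1 + γ`), rises away from the boundary —
a proliferation-dominated, unimodal "class c" profile.  Time-dependent runs
(`plaquesim simulate --t-end 200 --q 20 --a-max 100 --out out/`) reach this
state after ≈ 120 dimensionless lifetimes; 200 lifetimes at `β = 0.05 h⁻¹`
correspond to about 167 days.

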