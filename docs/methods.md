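# Methods

## Model and assumptions

The package implements a deterministic, homogeneously mixing compartmental
model in which two behaviours — violence and racism — spread through a
community like interacting infections.  The state is the vector
(S, V, U, R, I_vr, R1, R2, R3) of compartment counts, in that fixed order
everywhere (state vectors, Jacobians, CSV columns).  The dynamics are

```
dS/dt   = Λ + αR1 + ρR2 + θR3 − (λ_v + λ_r + μ) S
dV/dt   = λ_v S − (δ + κ λ_r + μ) V
dU/dt   = δV − (ε + μ) U
dR/dt   = λ_r S + ω I_vr − (σ + β λ_v + μ) R
dI_vr/dt = β λ_v R + κ λ_r V − (ϕ + ω + μ) I_vr
dR1/dt  = εU − (α + μ) R1
dR2/dt  = σR − (ρ + μ) R2
dR3/dt  = ϕ I_vr − (θ + μ) R3
```

with forces of infection λ_v = β₁(V + θ₂ I_vr), λ_r = β₂(R + θ₁ I_vr).
The factored form (rather than β₁V + θ₂I_vr) is the only reading consistent
with the model's own next-generation matrix, whose entries are β₁θ₂Λ/μ and
β₂θ₁Λ/μ; the package adopts it throughout.

Assumptions worth keeping in mind: mixing is homogeneous (no age, network
or spatial structure); co-infection arises only sequentially (an
already-infected individual acquiring the second behaviour), never by a
single double transmission — this is why the co-infected class contributes
no eigenvalue of its own to the threshold; and all rates are constant in
time.  Time is measured in years, the natural unit for the rates involved.

Two structural identities follow from the equations and serve as oracles in
the tests:

* conservation: the componentwise sum of the right-hand side is exactly
  Λ − μN, so N(t) = Λ/μ + (N(0) − Λ/μ)e^{−μt} in closed form;
* forward invariance of the nonnegative orthant: a compartment at zero has
  a nonnegative derivative.

## Parameters

Sixteen nonnegative constants (ASCII names as used in configuration files):

| name | meaning | default (reference preset) |
|---|---|---|
| `Lambda` | recruitment rate (persons/yr) | 5 (reconciled) / 50 (printed) |
| `mu` | natural exit rate (1/yr) | 0.01 |
| `beta1`, `beta2` | transmission rates (1/(person·yr)) | 0.003, 0.007 |
| `delta` | negotiation rate of violence-infected (1/yr) | 0.40 |
| `epsilon` | recuperation rate of negotiated (1/yr) | 0.60 |
| `alpha` | return rate, violence-recuperated → susceptible (1/yr) | 0.51 |
| `sigma` | recuperation rate of racism-infected (1/yr) | 0.50 |
| `rho` | return rate, racism-recuperated → susceptible (1/yr) | 0.61 |
| `omega` | violence-only control on co-infected (1/yr) | 0.60 |
| `phi` | recuperation rate from co-infection (1/yr) | 0.50 |
| `theta` | return rate, co-infection-recuperated → susceptible (1/yr) | 0.72 |
| `beta_mod` | racism-infected acquiring violence (–) | 1.2 |
| `kappa` | violence-infected acquiring racism (–) | 1.3 |
| `theta1`, `theta2` | co-infected transmission modification (–) | 1.0 |

Two reference presets ship with the package.  `table2_printed` carries the
tabulated recruitment rate Λ = 50.  `table2_reconciled` sets Λ = 5, the
value consistent with the reported thresholds ℜ₀ᵛ = 3.7 at β₁ = 0.003 and
ℜ₀ʳ = 6.9 at β₂ = 0.007 (Λ = 50 yields values exactly tenfold larger, 36.6
and 68.6).  Both are preserved so either reading of the source material is
reproducible; threshold-level results quoted in the README use the
reconciled preset.  θ₁ and θ₂ have no tabulated value and default to 1
(co-infected transmit like singly infected) — a neutral choice, exposed in
every configuration.

Greek-letter aliases are deliberately not accepted in configuration files,
and unknown keys are a hard error naming the key: the tabulated source
contains a duplicate ω row, and silent aliasing would let that ambiguity
leak into configs.

## Reproduction numbers

Each submodel has one infectious class, so its next-generation matrix is
scalar and ℜ₀ is a ratio: transmission in a fully susceptible population of
size Λ/μ times the mean infectious period (1/(δ+μ) for violence, 1/(σ+μ)
for racism).  The full model's 3×3 NGM over (V, R, I_vr) is block
upper-triangular with a zero bottom row (sequential-acquisition assumption),
so its spectral radius is max{ℜ₀ᵛ, ℜ₀ʳ} for any θ₁, θ₂.  The implementation
computes the spectral radius with a general eigenvalue solver and the tests
require agreement with the closed form to 1e−9 relative over 1000 random
parameter draws — a dual-route check, not a restatement.

## Sensitivity indices

Normalized forward sensitivity (elasticity) SI(ζ) = (∂ℜ₀/∂ζ)(ζ/ℜ₀).  For
the closed-form thresholds these are analytic: +1 for the multiplicative
parameters (β₁ or β₂, and Λ), −δ/(δ+μ) and −1−μ/(δ+μ) for the violence
removal rates (σ in place of δ for racism), exactly 0 for every parameter
the threshold does not contain.  A central finite difference with relative
step 1e−6 provides the independent oracle; the two paths agree to 1e−6
relative in the tests.  The exact identity
SI(β₁)+SI(Λ)+SI(μ)+SI(δ) = 0 is asserted as algebra.

Note: published tabulations of the negative indices for this model
(−0.81, −0.31, −0.86, −0.34) are not consistent with the definition
evaluated at the tabulated parameter values (−0.976, −1.024, −0.980,
−1.020); the package follows the definition.  Only the +1 entries are used
as reference values.

max{ℜ₀ᵛ, ℜ₀ʳ} is not differentiable at a tie, so a sensitivity report for
the full-model threshold delegates to whichever submodel ℜ₀ is strictly
larger and raises an explicit error on an exact tie.

## Equilibria and stability

Behaviour-free equilibria are (Λ/μ, 0, …) in all three systems.  The
submodel endemic points are closed-form: solving the steady state gives the
endemic force of infection

```
λ_v* = μ(δ+μ)(α+μ)(ε+μ)(ℜ₀ᵛ−1) / [(α+μ)(ε+μ)(δ+μ) − αεδ]
λ_r* = μ(σ+μ)(ρ+μ)(ℜ₀ʳ−1) / [(ρ+μ)(σ+μ) − ρσ]
```

(positive iff ℜ₀ > 1; the denominators are positive for μ > 0), and the
compartments follow by back-substitution, e.g. S* = (δ+μ)/β₁.  Every
closed-form endemic state is checked against the residual oracle
‖RHS‖∞ < 1e−10·Λ.

The full model has no closed-form endemic point.  `endemic_full_numeric`
integrates for 500 years from a lightly seeded state and polishes the final
state with scipy's Powell-hybrid root finder, using the package's
finite-difference Jacobian; acceptance requires residual < 1e−8·Λ and no
component below −1e−9 (negative roots are rejected, not clipped).  A
library root finder was preferred over a hand-rolled damped Newton because
it meets the same contract (simulation-derived guess, same residual
threshold) with better-tested step control.

Jacobians are computed by central finite differences with relative step
1e−6 (step 1e−6·(1+|xᵢ|) per component).  The right-hand sides are at most
quadratic, so central differences are exact up to roundoff; the tests
require the violence-DFE spectrum {−μ, (δ+μ)(ℜ₀ᵛ−1), −(ε+μ), −(α+μ)} to
1e−8 relative.  A printed version of the full-model DFE Jacobian in the
source material contains a transcription slip (a (δ+μ) where the racism
submodel requires (σ+μ)); deriving the Jacobian numerically from the RHS
sidesteps it, and the test suite asserts the (σ+μ)(ℜ₀ʳ−1) eigenvalue.

Stability verdicts use eigenvalue real parts with tolerance 1e−9: all
below −1e−9 is `stable`, any above +1e−9 is `unstable`, anything else is
`marginal` — never silently rounded to a definite verdict.

## Simulation

Integration uses scipy's RK45 (adaptive explicit Runge–Kutta 4(5), the same
family as MATLAB's ode45) with rtol 1e−8, atol 1e−10 — the system is
non-stiff and cheap, so tight tolerances cost little.  States are reported
on an even grid of 201 times by default.  After every run the positivity
and population-bound invariants are verified: undershoot in [−1e−9, 0) is
clipped to zero and counted; anything below −1e−9 aborts with diagnostics,
on the view that it indicates solver misconfiguration rather than model
behaviour.  The closed form for N(t) doubles as an end-to-end integration
accuracy check (1e−6 relative on every run).

The simulations never tabulate an initial state in the source material; the
package default places the population at its demographic equilibrium Λ/μ
with one person in each of V, R and I_vr and the remainder susceptible.
This is a package choice, configurable per run.

Scenario presets: `fig4_eradication` (β₁=0.0001, β₂=0.0002; both
thresholds below 1, 200-year horizon — the coexistence dies out),
`fig5_persistence` (β₁=0.001, β₂=0.004; both above 1, 500-year horizon to
reach the plateau), and `fig6_omega`/`fig7_phi` (control-rate sweeps over
{0.6, 0.7, 0.8} on the persistence parameters, 10-year horizon).

### An empirical note on "persistence"

At the persistence parameters the two behaviours compete for a shared
susceptible pool.  The racism-endemic boundary state has
S* = (σ+μ)/β₂ = 127.5, at which violence's effective reproduction number
β₁S*/(δ+μ) ≈ 0.31 < 1: violence cannot invade the racism-endemic state, and
the trajectory converges to a boundary equilibrium with V = I_vr = 0.  The
co-infected class is therefore transient at every tabulated parameter set,
even when both basic reproduction numbers exceed 1.  "Persistence" is
reproduced as a plateau at the numeric root (which the trajectory matches
within 1% per component, with an absolute slack of 1e−6·Λ/μ on components
that are exactly zero at the root), and the control experiments on ω and ϕ
are run on a 10-year horizon where the transient co-infected class is still
well above solver noise (terminal I_vr ≈ 1e−2), so the monotone decrease
with increasing control is a resolved effect, not tolerance noise.  The
"peak" of I_vr is taken over reported times after the shared initial
instant, since all sweep members start from the identical state.

## What the tests do and do not show

The randomized property tests draw parameters from epidemiologically
plausible ranges (transmission 1e−5–0.02 per person-year, removal rates
0.05–1 per year, μ 0.005–0.5 per year) — they exercise the algebraic
structure (conservation, NGM-vs-closed-form, residual oracles, threshold
dichotomy), not the realism of any particular calibration.  The model
itself is a stylized description: no empirical contact data enters
anywhere, compartment counts are continuous, and conclusions about real
communities would require validation the model's sources do not provide.

## Known limitations

* No global-stability certificates: the Lyapunov-type results are checked
  numerically (50 random sub-threshold starts draining to the
  behaviour-free state), not proved.
* The full-model endemic state is available only numerically.
* No optimal control, stochasticity, or structured populations; sweeps are
  one-parameter only.
* Quick-look CSV/JSON output only; no plotting.
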