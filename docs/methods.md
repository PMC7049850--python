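# Methods

## Model and assumptions

The model couples a logistically growing tumor `T` to five immune/therapy
compartments. The tumor is killed three ways: mass-action NK lysis (`−cNT`),
saturating CD8⁺ lysis (`−DT` with `D = d(L/T)^l/(s + (L/T)^l)`, a function of
the effector-to-target ratio), and cytokine-mediated kill driven by CD4⁺ T
cells (`−c₁ T/(a₁+T)·I`). NK cells and naive CD8⁺ activation are sourced
from a circulating-lymphocyte pool `C` that follows its own linear balance
`dC/dt = α − βC` independent of everything else. Chemotherapy acts through a
saturating log-kill factor `1 − e^(−M)` on tumor and immune populations
alike, with first-order drug decay. Doses enter as four piecewise-constant
rate channels (chemo, IL-2, CD8⁺, CD4⁺).

Structural consequences used throughout:

* **Lysis at the boundary.** `D` is evaluated as `d·L^l/(s·T^l + L^l)`,
  algebraically identical for `T > 0` and well defined at `T = 0` (`D = d`
  for `L > 0`, `0` for `L = 0`), so `D·T → 0` as the tumor vanishes. The
  right-hand side is otherwise evaluated exactly as written, with no
  clipping inside the model: nonnegativity is a solver policy.
* **The CD4⁺/IL-2 loop has an ignition threshold.** For fixed large `T`, the
  `(Y, I)` subsystem is linear with determinant
  `μ_I(μ₁ + δ₂T) − β₁β₂·T²/((α₁+T)(α₂+T))`; it becomes self-amplifying for
  `T < (β₁β₂/μ_I − μ₁)/δ₂ ≈ 3.51e6` cells (both reference patients). Below
  that size any CD4⁺ seed ignites the cytokine loop and the constant-rate
  kill term `≈ c₁·I` eliminates the tumor; above it the loop decays and
  sustained kill is capped by what the dose rates can maintain. This single
  number organizes most qualitative treatment outcomes.

## Parameters

The 36 constants (units in the fixture YAMLs and the `ParameterSet`
docstring) are the two published human parameterizations, shipped verbatim
as `patient1`/`patient2`. The patients differ in CD8⁺ lysis shape
(`d, l, s`), CD8⁺ turnover (`m, q, k`), NK inactivation `p`, and lymphocyte
balance (`α, β`) — notably `eα/(fβ)` and `α/β` agree between them, so both
share the same tumor-free state. All fields are validated strictly positive.

## Integrator

A fixed-step Adams–Bashforth (explicit) / Adams–Moulton (implicit)
predictor–corrector in PECE form: predict with the order-`k` Bashforth
formula, evaluate, correct once with the Moulton formula, evaluate again for
the stored history. Design choices:

* **Coefficients** are generated, not transcribed: the weights solve the
  interpolatory-quadrature conditions (exactness on polynomials of maximal
  degree) in exact rational arithmetic (`fractions.Fraction`), for orders
  1–12; floats are derived once. The test suite checks every order against
  an independent symbolic Lagrange-integration oracle.
* **Pairing.** An "order-`k`" step pairs the order-`k` predictor with the
  order-`k` corrector (`k−1` history nodes plus the implicit node) — the
  classical same-order pairing, so the observed global convergence order
  equals `k` (verified empirically for orders 2/4/6). A corrector using all
  `k` history nodes (one order higher) is available via
  `SolverConfig.full_corrector`.
* **Startup.** Multistep history is built per segment by an order ramp on a
  step-doubling fine grid: the first step uses order 1 at step `Δt/2^J`,
  order and step grow as history accumulates (decimating the history to
  double the spacing), with `J` chosen so the order-1 startup error is at
  the level of the order-`k` local error. A plain ramp at the working step
  would leave an `O(Δt²)` startup residue that caps the observable order
  near 2; the fine-grid ramp removes it for a few hundred extra evaluations
  per segment.
* **Dose discontinuities.** Piecewise-constant doses invalidate the equally
  spaced history, so integration restarts (with the startup ramp) at every
  pulse on/off instant; within a segment the dose rates are bound as
  constants. Restarts at times where the dose does not actually change alter
  the trajectory only at the local-error level (tested at 1e-10 relative).
* **Nonnegativity and divergence.** Components that undershoot zero after a
  step are clipped to zero (populations/concentrations; the lysis term is
  undefined for negative values); clips are counted in the trajectory
  metadata. A guard aborts with time and state when any component exceeds
  `max_state_magnitude` (default 1e30) or turns non-finite.
* **Defaults.** Order 12, `Δt = 2⁻⁹` day. Scenario runs use 60-day horizons
  (no-treatment, continuous) and 100 days (pulsed, covering the 9-pulse
  course plus regrowth margin).

**Stiffness limitation (known and deliberate).** Near tumor carrying
capacity (`T ≳ 1e8`), NK/CD8⁺ turnover terms `pNT` and `qLT` reach rates of
order 1e3/day, i.e. `λ·Δt ≈ 2–5` — outside every explicit multistep
stability region. There the solver stays bounded through clip-rectified
oscillation of the (dynamically negligible) `N` and `L` pools and continues
to track the tumor qualitatively; eradication verdicts agree with an
adaptive stiff reference solver on every scenario (tested), but pointwise
endpoints of capacity-escape runs are not refinement-stable. Grid-refinement
self-consistency is therefore asserted on immune-clearance runs, which relax
to a smooth state. No implicit/BDF fallback is provided; that is out of
scope by design.

## Equilibria and stability

Setting the unforced equations to zero splits the analysis into three
branches:

* **Tumor-free** (closed form), with closed-form eigenvalues; the leading
  one, `a − ceα/(fβ)`, yields the recurrence condition and the critical
  values `a*`, `c*`.
* **Tumor present, cytokine-free** (`I = Y = 0`): `N(T)` follows from the
  NK/lymphocyte balances, the demanded lysis rate from the tumor balance,
  `L(T)` by inverting the lysis saturation, and roots are sign changes of
  the remaining CD8⁺ balance, scanned over `T ∈ (1, 1/b)` on a 2000-point
  log grid and refined by bisection to 1e-10 relative. Tumor sizes whose
  demanded lysis rate falls outside `[0, d)` are branch-invalid and skipped
  rather than erroring the search. Negative `L` roots of the quadratic-type
  balance are discarded.
* **Active cytokine loop**: admissible tumor sizes are positive roots of a
  cubic (companion-matrix solve plus one Newton polish); at each, the same
  lysis/CD8⁺ construction runs over a log grid in `I` (4000 points), and
  `Y` follows from the cytokine balance. Only fully nonnegative points with
  full-system residual < 1e-6 (relative to the largest competing term in
  each equation) are reported.

Stability verdicts come from the eigenvalues of a finite-difference Jacobian
(central differences, step `max(1e-6·|x|, 1e-3)`, one-sided at zero
components where the lysis term is one-sided). A closed-form Jacobian is
only exhibited at the tumor-free point and is used there as a test oracle.
Verdicts within `1e-8` of neutral (relative to the spectral radius) are
reported as `marginal` rather than forced — parameter sweeps pass through
zero eigenvalues.

## Bifurcation sweeps

A sweep substitutes each grid value of one constant, enumerates all
branches, classifies them, and links points across adjacent values by
nearest-neighbour matching in `log10(1 + state)` with a jump threshold.
Default grids: 400 log-spaced samples plus 100 linear samples near zero
(the tumor-free thresholds sit ~5 decades below the range top). Events —
verdict changes along a branch, and branch-count changes per tag — are
refined by bisection on the parameter to a relative bracket width of 1e-4;
tumor-free switches are cross-checked against the closed forms. Branch ends
at the swept range boundary are reported as `censored`, not as bifurcations.

Findings the sweeps expose (worth knowing before comparing to the published
curves): for the first patient the cytokine-free tumor branch is created at
a *fold* near `a ≈ 9.8e-4` as a pair of large-tumor equilibria (one of them
stable) rather than appearing singly near 0.01, and admissible
active-cytokine equilibria exist for `a ≳ 2`; for the second patient the
equilibrium count is constant (three) across the whole `c ∈ (0, 4e-6]`
range. All such points carry residuals below 1e-10 and are confirmed by an
independent quadratic-in-`L` construction in the tests.

## Scenarios and outcomes

Pulses are constant-rate infusions on half-open windows
`[start + i·period, start + i·period + duration)`, default duration one day
— the printed regimens give intensity/start/period/count but no duration,
and one-day infusions are the predecessor-model convention. The
six-IL-2-pulses-in-four-days regimen is realized as six half-day infusions
evenly spaced over days 8–11.5. Dose-intensity units are the model's
implicit concentration units; no conversion is attempted. Initial `I` and
`M` are zero unless a scenario states otherwise; the predecessor-comparison
run has no CD4⁺ compartment (`Y(0) = 0`).

A tumor counts as **eradicated** when its burden falls below one whole cell
and stays below it to the horizon; the first crossing time is the
eradication day. The threshold operationalizes "elimination" for an
unstable tumor-free state: anything that can regrow within the horizon is
not eliminated. Verdicts are invariant to halving `Δt` and to switching
order 12 ↔ 8 (tested), and the whole pipeline is deterministic — identical
configurations produce byte-identical outputs.

Three published pulsed-CD4⁺ eradication claims do not reproduce from the
printed equations and constants (pulsed CD8⁺+IL-2+CD4⁺ at `T₀ = 8e5`;
pulsed chemo+CD4⁺ at `T₀ = 3e6`; reduced chemo+CD4⁺ at `T₀ = 1e7`). The
mechanism is the ignition threshold above: with therapy starting on day 6,
the tumor has grown past ~3.5e6 cells, where the printed CD4⁺ intensities
sustain an IL-2 level an order of magnitude short of outpacing logistic
growth. The verdicts are robust across dose conventions (1-day infusion,
full-period infusion, instantaneous bolus) and integration routes (this
package's PECE, scipy LSODA, an independent R implementation during
development). The corresponding acceptance tests are left failing rather
than tuned; all other printed outcomes — including the chemotherapy
successes/failures and the triple-therapy ~9-day clearance — reproduce.

## What the fixtures do and do not show

The bundled parameter sets are literature-derived human values, not fits to
any dataset in this package; scenario verdicts are statements about the
model, not predictions validated against patient outcomes. Passing tests
demonstrate internal correctness (closed forms, oracles, convergence,
cross-solver agreement) and faithful reproduction of the published analysis
where it is reproducible — they do not validate the model's biology.
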