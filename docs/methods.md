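# Methods

## Model

All simulated systems reduce to one of two constitutive laws evaluated
along a prescribed displacement history.

**Kelvin–Voigt element.** A linear spring (stiffness k, N/m) in parallel
with a linear dashpot (damping η, N·s/m):

    F(x, ẋ) = k·x + η·ẋ + F_adh(x)

The indentation coordinate is one-sided (x ≥ 0); negative displacements are
rejected rather than extrapolated, because the contact interpretation (a
particle pressing a membrane, a specimen under stretch) has no meaning for
x < 0. The adhesion term defaults to zero; `constant` (a fixed pull f0 for
any positive indentation) and `exponential` (f0·e^{−x/λ}) forms are
available as plug-ins. No published functional form exists for the adhesion
contribution in this setting — both shapes are this package's own choices,
offered as generic short-range profiles, and all golden-value results use
no adhesion.

**Hill muscle.** The concentric force–velocity hyperbola
(F + a)(v + b) = (F_max + a)·b, solved for force:

    F(v) = (F_max + a)·b/(v + b) − a,    0 ≤ v ≤ v_max = b·F_max/a

Eccentric lengthening (v < 0) and super-maximal shortening (v > v_max) are
domain errors: the hyperbola is only a model of concentric contraction and
extrapolating it would silently produce unphysical forces. At v = v_max the
analytic force is zero but floating-point evaluation leaves a residue of
order 1e-14·F_max; the implementation clamps negative residues to zero so
that F(v_max) = 0 holds exactly. Work per contraction is W(v) = F(v)·D for
constant-velocity shortening over distance D — the model has no internal
elastic/viscous partition, so only the total is reported for Hill rows.

## Loading protocols

The only first-class protocol is the constant-velocity linear ramp
x(t) = D·(t/T) on a uniform time grid. Velocity at t = 0 is defined as the
right-limit D/T, so the KV force starts at η·D/T rather than zero; this
jump is the behaviour of the ideal ramp (the closed forms assume constant
ẋ over the whole ramp) and is documented rather than smoothed. Other
profiles named in the literature — holds, spikes, oscillations — can be
expressed by building a `Trace` from custom kinematics but are not built-in
behaviour; in particular hysteresis loops and unloading are out of scope,
and `partition_trace` rejects any trace whose displacement decreases.

## Energy partition

Analytic, for the linear ramp:

    W_el = ½·k·D²        W_visc = η·D²/T        W_adh = ∫₀ᴰ F_adh dx

Numerical, for any sampled monotone trace, by trapezoidal quadrature:

    W_el = ∫k·x dx   W_visc = ∫η·ẋ² dt   W_adh = ∫F_adh dx   W_total = ∫F dx

W_total is integrated independently rather than summed, so the conservation
identity W_total = W_el + W_visc + W_adh is a genuine cross-check; the
`EnergyBudget` constructor enforces it at 1e-9 relative (analytic budgets)
and 1e-6 (numerical ones). Trapezoid is the right rule here: every
integrand arising from a linear ramp is affine in its integration variable,
which the rule integrates exactly up to float rounding, so the
analytic/numerical agreement at the default grid is limited only by
accumulation error (~1e-12 relative). The generic O(n⁻²) order of the rule
is exercised in the tests on the curved exponential-adhesion integrand,
whose work has the closed form f0·λ·(1 − e^{−D/λ}).

The crossover duration T\* = 2η/k (from η·D²/T = ½·k·D²) is exposed as
`crossover_time`; it is amplitude-independent and separates
viscous-dominated (T < T\*) from elastic-dominated (T > T\*) ramps.

## Parameters and scenarios

Defaults are the published reference conditions, all SI internally:

| scenario | parameters | loading |
|---|---|---|
| tendon-like KV specimen | k = 1000 N/m, η = 50 N·s/m, D = 0.10 m | T = 1.0 s (slow), 0.01 s (fast) |
| KV ramp traces | same k, η; D = 0.02 m | T = 2.0 s (slow), 0.5 s (fast) |
| Hill muscle | F_max = 100 N, a = 10 N, b = 0.5 m/s, D = 0.05 m | v = 0.10 (slow), 0.50 m/s (fast) |
| NP reference (50 nm) | k = 0.01 N/m, η = 5.00e-7 N·s/m | T = 0.1 s (slow), 1e-4 s (fast) |
| NP worked example (100 nm) | k = 0.010 N/m, η = 1.0e-6 N·s/m, D = 100 nm | T = 0.1 s, 1e-4 s |

Two conventions in the nanoparticle grid need stating because they are
design decisions, not physics:

* **Depth = diameter.** The grid labels D the particle diameter and uses
  the same value as indentation depth in both energy formulas (full
  engulfment requires membrane deflection of one diameter). The published
  energies are consistent only under this reading, so it is adopted and
  surfaced in the `NPScenario.depth` property.
* **Linear-in-diameter scaling.** Membrane stiffness and damping are scaled
  in proportion to particle diameter from the 50 nm reference. The source
  material describes the scaling as "with contact area" yet its tabulated
  values quadruple for a 4× diameter (not 16×); the tabulated behaviour
  wins. Hertz/JKR contact laws can be substituted by passing explicit
  parameters but are not implemented.
* The 100 nm worked example keeps its standalone stiffness k = 0.010 N/m,
  which the linear rule would put at 0.02 N/m. The two parameter sets are
  deliberately preserved as distinct fixtures rather than reconciled —
  they answer different questions (a self-contained numeric example vs a
  scaling study).

The ramp durations for the worked-example force/work traces reuse the
worked example's own T = 0.1 s and 1e-4 s, since no separate values are
given for those figures.

## Numerical choices

* Uniform grid, default n = 10,001 samples; keeps trapezoidal work
  integrals at ≲1e-8 relative on linear ramps while costing milliseconds.
  Tests and the acceptance script use between 101 and 10,001 points
  depending on what the check needs.
* Degenerate n = 2 traces are valid (the affine integrands make even the
  two-point trapezoid exact for KV ramps) but documented as accuracy-losing
  for any curved integrand.
* Analytic identities are asserted at 1e-9 relative, numeric-vs-analytic at
  1e-6 on the default grid; the Hill hyperbola residual at 1e-12.
* Serialization: parameters as JSON with explicit unit strings ("k_units":
  "N/m"); convenience units (nm, ms, nN, …) are converted to SI on ingest.
  Traces as RFC-4180 CSV with 8-significant-digit scientific notation;
  identical inputs give byte-identical files.

## What the simulator does and does not show

All inputs are parameter sets, so "synthetic data" here means the scenario
grid itself: the package emulates idealised constant-velocity loading of
linear viscoelastic elements with noise-free parameters. Passing tests
demonstrate internal consistency (closed forms vs quadrature, conservation,
monotonicity) and exact agreement with the published reference energies —
they do not validate the KV model against real tissue. Real membranes and
tendons are nonlinear, heterogeneous, poroelastic and actively remodelled;
none of that is modelled. Specific known limitations: no inertial terms (no
simulated scenario carries a mass), no unloading or hysteresis loops, no
Hertzian/bending nonlinear stiffness k(x), no membrane rupture criterion,
no thermal fate of the dissipated energy, and the standard-linear-solid /
poroelastic extensions are interface hooks only.
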