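# Methods

## Model

Two coupled objects are implemented.

**Memristor emulator.**  A voltage-controlled, non-ideal memristor with
memductance `W(v0) = a − b·tanh(v0)` and inner-state dynamics
`τ·v0' = −(v0 + v)`.  The inner-state equation is linear, so under a
sinusoidal drive `v = Vm·sin(2πft)` the steady state has the closed form
of a first-order low-pass response (amplitude `Vm/√(1+(2πfτ)²)`, phase
lag `atan(2πfτ)`, sign inversion); this closed form serves as the test
oracle for the numerical loop simulation.  In circuit units the port
current is `i = (1/Ra − (g/Rb)·tanh(v0))·v` and the dimensionless
parameters are `a = R/Ra`, `b = gR/Rb`, `τ = RC`.  Both the circuit form
and a dimensionless form (τ = 1) are exposed.

**Memristive Hopfield network.**  Three Hopfield neurons (unit membrane
constants, zero bias, tanh activation) with fixed synaptic weights,
except the weight from neuron 1 into neuron 3, which is the memristive
synapse `k·W(x4)` driven by the inner state `x4' = −x4 + tanh(x1)`.
The flow is dissipative: with `V = ‖x‖²/2`, the cross terms of `V̇` are
dominated by the linear form `9.6|x1| + 3.9|x2| + (kM+6)|x3| + |x4|`
with `M = max{|a−b|, |a+b|}`, which is beaten by `−2V` outside a large
ball, so all orbits are trapped (verified numerically by a seeded
100-trajectory property test and by direct sampling of `V̇` on large
spheres).  The field is equivariant under `(x, b) → (−x, −b)`; negative
`b` is representable only through `HNNParams.mirrored()`, keeping the
public constructor aligned with the physical parameter range.

## Equilibria

Setting the `x2`- and `x4`-rates to zero reduces the equilibrium problem
to two residual curves in `(y, z) = (x1, x2)`, with
`x4 = tanh(y)` and `tanh(x3) = u = (z − 1.1·tanh y)/2.8` (requiring
`|u| < 1`).  `curve_residuals` exposes exactly this reduced form.

The solver, however, works in the smooth coordinates `(y, x3)`, with
`z = 1.1·tanh y + 2.8·tanh x3` substituted from the `x2`-nullcline.
This removes the `atanh` domain boundary entirely, which matters: as `b`
grows, the positive-branch equilibrium approaches the asymptote
`z → 1.1·tanh y − 2.8` (distance ~0.01 at b = 3), where the `(y, z)`
formulation is numerically and graphically degenerate.  Roots are
bracketed on a 200×200 lattice and polished by a hybrid-Powell
refinement to residual < 1e-10.  Seeds are taken from every lattice
cell crossed by the `h1 = 0` curve with small `h2`, not only from cells
where both residuals change sign — the two curves become near-tangent
at large `b` and a double-sign-change criterion intermittently misses
the crossing.  Duplicates are merged at 1e-6; equilibria are ordered
origin first, then by descending `x1`.

Stability labels come from the Jacobian spectrum (eigenvalues ordered by
descending real part, ties by descending imaginary part): all real
parts negative → stable node(-focus with a complex pair); mixed signs →
saddle point when the unstable eigenvalues are real, saddle-focus when
they include a complex pair; any real part within 1e-9 of zero →
"other".  At the origin the characteristic polynomial factors as
`(λ+1)(λ³ + 0.4λ² + (7ka−3.52)λ + 3.64ka−5.2)`; the binding
Routh–Hurwitz condition is the constant term, giving the critical
coupling `k = 5.2/(3.64a)` (1.4286 for a = 1).

`regime_scan` refines two boundaries in `b` by bisection to 1e-3: the
stability onset of the positive branch (0.4364 for k = 0.8, a = 1,
consistent with the reported bracket (0.43, 0.44)) and the value at
which that branch ceases to exist — which, see Discrepancies below, does
not occur.

## Lyapunov spectra

`wolf_spectrum` implements the tangent-space form of Wolf's algorithm:
the flow and four tangent vectors are advanced together by a fixed-step
RK4 (default step 0.1, horizon 10 000 time units, matching the published
protocol), the tangent matrix is re-orthonormalized every step by a QR
factorization with positive diagonal (equivalent to Gram–Schmidt), and
the logs of the stretch factors are averaged after a 1 000-unit
transient.  The variational equations use the analytic Jacobian rather
than an orbit-separation approximation.  Each spectrum also records the
time-averaged divergence `trace J = −4 − 1.4·sech²x1 + 4·sech²x3`; the
exponent sum matches it to 2e-3 on every computed spectrum (a standing
invariant of the test suite).

## Attractor classification

With `ε = 5e-3` the zero tolerance on exponents and `θ = 2.0` the
double-scroll threshold on `x1`:

1. `L1 < −ε` → stable point, verified by the orbit endpoint lying
   within 1e-4 of an equilibrium found independently by the equilibrium
   solver (which must be labelled stable).
2. `L1 > ε` → chaotic; double-scroll when the post-transient orbit
   exceeds `+θ` **and** falls below `−θ`, otherwise a one-sided spiral
   with handedness the sign of the time-mean of `x1`.
3. `|L1| ≤ ε` → limit cycle of period `n` = the number of distinct
   clusters of `x1` local maxima (parabolic-refined, clustered at
   absolute tolerance 1e-3, capped at 8).  Periodicity is confirmed by
   the bounded cluster count rather than by requiring `L2 < −ε`: a
   weakly stable cycle just past a tangent bifurcation (e.g. the
   right-period-3 at k = 1, b = 0.24) has `L2 ≈ −0.003`, inside the
   zero band, while a quasi-periodic or unconverged orbit produces an
   unbounded number of distinct maxima and falls to "unresolved".

θ = 2.0 was calibrated on the computed orbit geometry: a double scroll
wraps around both nonzero foci and extends past `|x1| = 2.5` on both
sides, while one-sided chaotic spirals overshoot the opposite side by at
most ~1.35 (the spiral at k = 0.95, b = 0.14 reaches −1.335).  A
threshold at 0.5 or 1.0 misclassifies those spirals as double scrolls.

**Basin-faithful transients.**  Multistable basins here are finely
interleaved, so *which* coexisting attractor an initial condition
selects depends on the integration protocol, not only on the exact
flow.  Classification therefore settles each initial condition with the
reference protocol — Dormand–Prince 4(5) at the standard loose
tolerances (rtol 1e-3, atol 1e-6) with steps capped at 0.1 — and then
measures geometry on a 500-unit window re-integrated tightly
(rtol 1e-9, atol 1e-12) from the settled state, with the Lyapunov
spectrum started from that same state.  With tight-tolerance transients
instead, the (0, 0.1, 0, 0) orbit at k = 0.95, b = 0.14 lands on the
period-2 cycle rather than the chaotic spiral, and a fixed-step tangent
run restarted from the raw initial condition can likewise settle on a
different coexisting attractor than the orbit being labelled.

Bifurcation scans restart every grid point from the fixed initial
conditions (no continuation) with a 900-unit transient and a 300-unit
measurement window, recording `x1` local maxima per branch.  All scans
are deterministic: there is no hidden randomness anywhere in the
package, and repeated runs are bit-identical.

## Problem sizes and defaults

Spectra default to the published protocol (dt = 0.1, t_end = 10 000,
transient 1 000).  Classification uses a 1 500-unit transient and a
500-unit window; the coexistence table computes its spectra over 1 500
units with a 200-unit transient, sufficient because the start state is
already on the attractor.  The test suite shortens Lyapunov horizons to
1 500–3 000 units (tolerance 0.03 instead of 0.015 for the spectrum
comparisons), which keeps the whole suite within minutes at the stated
tolerances.

## Discrepancies with the published reference values

Three reference numbers do not withstand recomputation; all three are
traceable to the graphic-analytic equilibrium method used to produce
them.  The package reports the recomputed values.

1. **Nonzero-equilibrium coordinates.**  The printed roots (e.g.
   y1 = 2.1661 at k = 0.8, b = 0.26) differ from the exact roots of the
   printed equations (y1 = 2.1647266, verified at 40-digit precision) by
   ~1.5e-3 — graphical read-off error.  The printed eigenvalues are
   exactly the eigenvalues evaluated at those imprecise coordinates, so
   they inherit the ~1e-3 error.  Stability labels and eigenvalue
   structure are unaffected.
2. **"P1 disappears at b = 3.06".**  The positive-branch equilibrium in
   fact persists, stable, for all b (approaching (4.478, −1.700, …) with
   x3 → −∞ slowly); its `(y, z)` representation approaches the `atanh`
   asymptote of the printed curves, where a graphical intersection is
   lost against the near-vertical branch.  `regime_scan` accordingly
   reports no existence boundary.
3. **The b = 0.26 "double-scroll chaotic attractor".**  Over the whole
   reported coexistence band [0.2595, 0.2640] the both-lobe attractor is
   a stable period-4 limit cycle (on-attractor L1 ≈ 5e-4, four maxima
   clusters, stable under horizon and tolerance refinement; a 24-start
   random census at b = 0.26 finds only it and the right chaotic
   spiral).  The chaotic appearance in the reference is attributed to
   integrating this weakly stable cycle at rtol 1e-3.

## Limitations

- The transistor-level tanh circuit, op-amp non-idealities and the
  breadboard/PSPICE reproductions are out of scope; the ideal tanh is
  used throughout.
- Attractor labels rest on finite-horizon spectra with the stated ε;
  orbits inside ~5e-3 of a bifurcation boundary can be labelled
  "unresolved".
- Basin assignment is protocol-faithful rather than protocol-free; it
  reproduces the reference assignments under the reference integrator,
  which is the strongest statement the interleaved basins admit.
- The generic n-neuron evaluator covers bias currents and non-unit
  membrane constants, but all dynamical analyses target the 4-D model.
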