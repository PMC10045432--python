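# Methods

## The model

`ffrtree` estimates fractional flow reserve (FFR) on a coronary artery
tree represented as a rooted network of cylindrical segments with one
inlet face and N outlet faces. Three ingredients:

**Murray's-law outlet split.** The power to drive laminar flow Q
through a vessel of radius r and length l is P_t = (8μl/πr⁴)Q²; the
power to maintain the contained blood is P_m = λπlr² with λ the
metabolic rate of blood. Setting d(P_t+P_m)/dr = 0 gives the optimum
Q = (π/4)r³√(λ/μ): flow proportional to radius cubed. Dividing one
branch's optimum by the sum over all branches cancels λ and μ, leaving
the cube-fraction split αᵢ = dᵢ³/Σdⱼ³ used to initialise the outlet
flows from the measured inlet flow Q_exp. Only the normalised split
enters the pipeline; `optimal_flow` keeps λ for the power analysis
itself.

**Reduced-order network solver.** Each segment is a lumped element with
pressure loss ΔP(Q) = R·Q + S·Q·|Q|, R = 8μl/(πr⁴) the Poiseuille
resistance and S a stenosis loss S = K_t·ρ/(2A₀²)·(A₀/A_s − 1)² with
A₀ = πr² the reference lumen, A_s the stenotic lumen and K_t = 1.52 the
classical sudden-expansion coefficient. ΔP is strictly increasing in Q
(the Q|Q| form keeps it odd, so signed flows are admissible), which
makes both boundary-value problems below uniquely solvable. Blood is
Newtonian with μ = 0.0035 Pa·s and ρ = 1056 kg/m³ by default; walls are
rigid (no compliance or inertance).

Two solve modes:

* *flows prescribed* (inlet pressure + per-outlet flows): direct —
  segment flows are subtree sums of outlet flows, pressures march down
  from the inlet;
* *pressures prescribed* (inlet flow + per-outlet pressures): a damped
  Newton solve for the N outlet flows and the inlet pressure, with
  analytic Jacobian assembled from shared-path conductances, seeded
  from the linearised (S = 0) dense solve, step-halving on residual
  increase, at most 50 iterations, and a scaled residual tolerance of
  1e−12 (every path and conservation equation is satisfied to well
  below 1e−10 relative).

**Alternating boundary iteration.** Round 1 prescribes the measured
inlet pressure P_exp with the Murray-split outlet flows and records the
solved outlet pressures. Round 2 prescribes the measured inlet flow
Q_exp with those pressures and records the solved outlet flows. Rounds
alternate until the mean (over outlets) relative percent change of both
outlet pressures and outlet flows between consecutive rounds falls
below the tolerance. FFR = min(P₁…P_N)/P_exp on the final state, with
the minimising outlet reported (lowest index on ties). Per-outlet
pressure ratios are also exposed, since whether the clinical minimum
should range over all outlets or only the interrogated branch is a
reporting choice; the headline number takes the literal all-outlet
minimum.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `tolerance_pct` | 0.1 | % | outer-loop boundary residual; same order as the 10⁻³ residual reduction conventionally required of steady inner solvers |
| `max_rounds` | 10 | – | round cap; runs that have not converged by then are returned unconverged with full history |
| `divergence_patience` | 3 | – | consecutive rounds of jointly increasing residuals before flagging divergence (the behaviour coarse discretisations of the 3D analogue exhibit) |
| `K_t` | 1.52 | – | sudden-expansion (Borda–Carnot) loss coefficient |
| μ, ρ | 0.0035, 1056 | Pa·s, kg/m³ | standard Newtonian blood properties |
| `cycles`, `steps_per_cycle` | 2, 100 | – | pulsatile discretisation; two cycles suffice because each step is an independent steady solve (see below) |

Residual definition: pressures are compared to the previous round's
pressures and flows to the previous round's flows. Every solved state
carries both quantities, so the consecutive-round comparison is well
defined even though the *prescribed* kind alternates.

## Pulsatile mode

The network has no storage elements, so pulsatility is treated
quasi-steadily: at each of `cycles × steps_per_cycle` time samples the
inlet prescriptions are scaled by periodic waveforms (flow rounds by the
flow waveform, pressure rounds by the pressure waveform, default
constant 1) and the full steady iteration is run at those values.
FFR(t) is evaluated against the instantaneous scaled inlet pressure;
the outcome value is the trapezoidal mean of FFR(t) over the final
cycle, closed periodically.

Warm starting: a preliminary steady run, and thereafter each step's
converged flows, seed the next step's Newton iterations. The seed is an
initial guess only — each step's round 1 re-initialises from the Murray
split of the instantaneous inlet flow — so freezing the waveform at any
t and running the steady pipeline reproduces FFR(t) exactly (a tested
invariant). This mirrors mapping a converged steady field onto a
transient run as an initial condition rather than as boundary data. A
step whose inner iteration diverges is flagged; a run with more than
10 % flagged steps is marked diverged.

The built-in waveform is the benchmark coronary sinus
u(t) = 0.184 − 0.02432·cos(2πt) − 0.09822·sin(2πt) m/s (period 1 s),
whose exact time-average is the 0.184 m/s steady inlet velocity — the
harmonics integrate to zero. Tabulated waveforms (two-column CSV) are
interpolated periodically and averaged by the trapezoidal rule.
Two-peaked physiological waveforms can be supplied as tables; none is
built in because no tabulation of one is published alongside the
fixtures.

## Fixtures and the synthetic generator

The packaged fixtures store, verbatim, the published outlet-area tables
(9 outlets for CT209; 6 each for CHN13 and CHN03), the inlet pairs
(P_exp, Q_exp), and the nozzle inlet (63.61 mmHg / 8480 Pa, 0.184 m/s).
Two recorded data quirks are preserved rather than repaired: the CHN13
inlet prints an mmHg/Pa pair that disagrees by ~6 % (the verbatim Pa
value is used, and `inlet_pressure_consistent("CHN13")` returns False),
and the CHN03 flow column was evidently computed with an extra unprinted
digit of Q_exp (the fixture follows the cube-fraction chain; the ~0.03 %
residual against print is tolerated explicitly in tests).

What the published data do **not** fix: the internal branching topology
and all segment lengths. Fixture trees use an illustrative two-level
grouping (first half of the outlets on a "left" branch, second half on
a "right" branch, echoing the left/right coronary split) with radii
from the cube law and lengths synthesized as 10× radius. Consequently
the absolute FFR values computed on fixture trees are illustrative
only; what is data-anchored — and asserted — is the Murray split, flow
conservation at every round, and the iteration's fixed-point behaviour.
Reproducing the published patient FFRs (0.76-range values) would
require the 3D geometry the tables were derived from, which is not
distributable; the test suite substitutes a property battery (linear
oracle, fixed point, stenosis monotonicity, transient-reduces-to-steady,
symmetry preservation) at desk scale.

`generate_tree` builds seeded random binary trees whose radii satisfy
r_parent³ = Σ r_daughter³ exactly at every bifurcation (daughter cube
shares ½ ± asymmetry/2), with optional random stenoses. It emulates the
cube-law structure of arterial trees, not real coronary morphometry: no
trifurcations, no tapering within segments, no side-branch anatomy, and
a uniform length-to-radius ratio. Tests passing on these trees therefore
validate the algorithmic properties, not anatomical realism.

## Numerical and design notes

* Units are SI internally (m, Pa, m³/s); interfaces accept the clinical
  units of the tables (cm², cm³/s, mmHg) with the conversion constant
  1 mmHg = 133.322 Pa. Verbatim table Pa values take precedence over
  conversion so that stored pairs round-trip exactly; FFR is a pressure
  ratio, so consistency matters more than the constant itself.
* Murray splits are computed from areas via d = 2√(A/π), the derivation
  chain of the tables; stored diameters serve only as a 0.5 %
  cross-check.
* A consistent round-1 state (Murray flows summing to Q_exp under
  P_exp) is already a fixed point of the alternation on this
  reduced-order model, so clean fixtures converge at round 2 with ≈ 0
  residuals. The iteration is genuinely exercised when prescriptions
  are inconsistent — a non-Murray initial split, or the step-to-step
  rescaling of the pulsatile driver — and the convergence/divergence
  machinery is tested through those paths.
* Degenerate inputs: zero prescribed outlet flows give a uniform
  pressure field; ties in the FFR argmin report the lowest outlet
  index; trees with a single segment (N = 1) are valid.
* Determinism: there is no randomness anywhere in the solve path;
  identical inputs give bit-identical histories. The only seeded
  randomness is in `generate_tree`.

## Known limitations

* No 3D flow features: no convective pressure recovery, no wall shear
  stress, no turbulence; the quadratic loss term is a surrogate for
  inertial/stenotic losses, calibrated by a textbook coefficient, not
  by patient data.
* Rigid walls and quasi-steady transients: wave propagation,
  reflection, and the high-frequency oscillations seen in full
  transient solvers are out of scope by design.
* Murray exponent fixed at 3; no generalised-exponent fitting.
* Fixture tree topology is illustrative (see above); absolute fixture
  FFRs should not be read clinically.
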