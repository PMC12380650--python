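# Methods

`armreach` simulates and optimizes point-to-point reaching movements of a
three-joint arm (shoulder, elbow, wrist) in the horizontal plane, under four
smoothness optimality principles, with an eight-muscle musculoskeletal layer
underneath the muscle-stress-based model. This note records the model,
its numerical choices, and the places where the design was genuinely open.

## Arm model

**Kinematics.** The shoulder is fixed at the origin. Angles are
`theta1` (shoulder, CCW from +x), `theta2` (elbow flexion, relative),
`theta3` (wrist flexion, relative); zero angles mean a fully extended arm
along +x. This convention is a package choice: it makes the five workspace
points (all at positive y) reachable with positive shoulder/elbow flexion
for a right arm reaching forward. Inverse kinematics takes the wrist angle
as given (it is the redundant degree of freedom selected by the optimizer),
folds forearm+hand into one effective link
`r = sqrt(L2² + L3² + 2 L2 L3 cos θ3)`, and solves the two-link problem in
closed form. The default elbow branch puts the elbow clockwise of the
shoulder→fingertip chord (positive flexion); the mirror branch is available.

**Dynamics.** Rigid-body dynamics `M(θ)θ̈ + H(θ,θ̇) + Dθ̇ = τ`, no gravity
term (horizontal plane). The implementation evaluates the equation of motion
in absolute link angles, where the kinetic energy is
`½ Σ k_ij cos(φ_i−φ_j) φ̇_i φ̇_j` and the Coriolis term collapses to
`Σ_j k_ij sin(φ_i−φ_j) φ̇_j²`; a second, independent route assembles `M` by
congruence and `H` from Christoffel symbols. The two routes agree to machine
precision in the tests, and an energy oracle (kinetic energy computed from
link geometry vs Simpson-accumulated joint power) closes the loop.

The fixture inertias `I1..I3` are treated as moments of inertia of each link
**about its proximal joint** (the fixture file documents this assumption):
the own-link rotational term uses `I_i` directly and no additional
parallel-axis term is added for the link's own mass; coupling terms use only
masses and COM offsets. Whether the published estimates already include the
parallel-axis contribution is not recorded alongside the estimates; this reading is the
self-consistent one and is what the energy oracle validates.

**Joint viscosity.** `D` has shoulder/elbow entries from perturbation
estimates during reaching, a symmetric shoulder–elbow interaction term, and
a wrist entry referenced to the mean of the other two:

    D11 = 0.63 αA + 0.095 |τ̄1|
    D12 = D21 = 0.175 αA + 0.0375 |τ̄2|
    D22 = 0.76 αA + 0.185 |τ̄2|
    D33 = 0.695 αA αB + 0.140 |τ̄3|     [N·m·s/rad]

`αA` scales all joints, `αB` only the wrist; the five named conditions are
B05A10, B10A10 (reference), B20A10, B10A05, B10A20. The `|τ̄_i|` terms are
mean absolute joint torques *of the movement being evaluated*, which
themselves depend on `D` — a circularity the model statement leaves open. It is
resolved here by fixed-point iteration from `τ̄ = 0` until the largest entry
change of `D` falls below 1e-6 N·m·s/rad (usually 4–12 iterations; 50 is an
error). Because only the viscous term depends on `D`, the rigid-body torque
is computed once and the iteration itself is nearly free; the package
therefore runs the full fixed point for every evaluation rather than a
single warm-started sweep inside the optimizer loop — one fewer piece of
hidden state, no measurable cost.

**Integration.** Forward dynamics uses fixed-step classical Runge–Kutta 4
with piecewise-linear torque interpolation. The dynamics are smooth and
non-stiff at desk scale; the inverse→forward roundtrip at `dt = tf/2000`
reproduces joint angles to RMS ≲ 1e-6 rad, two orders below the 1e-4
tolerance the test suite demands.

## Muscle layer

Eight muscle groups (shoulder flexor/extensor, elbow flexor/extensor,
biarticular pair, wrist flexor/extensor) with published PCSA and moment-arm
combinations S11–S42 packaged verbatim; moment arms are stored in cm and
converted to metres inside the 3×8 matrix `A`. Torque is `τ = A T`,
tensions nonnegative.

**Tension distribution.** Redundancy is resolved per time sample by
minimizing the sum of squared muscle stresses `Σ (T_i/PCSA_i)²` subject to
`A T = τ`, `T ≥ 0` — a strictly convex QP with a unique minimizer, solved by
a primal active-set method (feasible start from one monoarticular muscle per
joint; equality-constrained subproblems in closed form; KKT multiplier check
on released muscles). Along a trajectory the optimal support changes only at
isolated instants, so the series solver works in runs: under a tentative
support the minimizer is a single linear map applied to a window of samples,
re-deriving the support only at violations. The wrist pair decouples exactly
(separable objective, block-diagonal constraints) and is solved in closed
form. Tests verify the QP against exhaustive enumeration of all 2⁸ supports.

Stresses are kept in N/cm² (PCSA is tabulated in cm²); a helper converts to
kPa. Uniform unit rescaling multiplies the stress-change cost by a constant
and cannot change any argmin.

## Cost functionals

All five costs are `½ ∫ Σ (dq_i/dt)² dt` over the movement: hand jerk (HJ,
`q` = fingertip acceleration), angular jerk (AJ), torque change (TC),
muscle-stress change (MSC, with the QP inside), motor-command change (MCC).
If tension is modelled as `T_i = k α_i PCSA_i`, stress equals `k α_i` and
`C_MSC = k² C_MCC` exactly; the tests assert this identity at 1e-10.

Numerics: first derivatives by second-order central differences; third
derivatives by a dedicated stencil (5-point central interior, 6-point
one-sided edges) because a jerk integrand peaks exactly at the boundaries
where repeated `np.gradient` passes lose an order of accuracy; trapezoidal
integration, matching the differencing order. Stress derivatives are
numerical differences across QP solutions; a kink where the active set
changes is accepted — the dense grid keeps its contribution below the
grid-halving tolerance (0.1 %) verified in tests. Differentiating the
stresses analytically through the QP is possible in principle; numeric
differencing is the package's choice.

## Candidate movements and the outer search

A candidate is three 7-knot vectors (fingertip x, fingertip y, wrist angle)
at equally spaced times, interpolated by quintic splines with clamped
rest-to-rest ends (velocity and acceleration zero at both ends). The end
conditions are an assumption — measured movements are rest-to-rest and the
closed-form comparison optima assume it — with a `natural` switch provided
to probe sensitivity. Spline interpolation at fixed knots is linear in the
knot values, so the sampler uses precomputed design matrices. Endpoint
knots are pinned to the task (start/target fingertip, initial wrist); the
final wrist knot is free, so the final posture is selected by optimization.

The search grid is `dt = tf/200` (matching the 200 Hz measurement rate);
joint velocities/accelerations come from central differences on the dense
angle grid — the induced error is second order and sits below every
tolerance used.

**Genetic algorithm.** Real-coded GA over the 16 free genes: tournament
selection (size 3), BLX-0.5 blend crossover, per-gene Gaussian mutation with
per-channel scales (5 mm, 5 mm, 0.05 rad) and optional geometric annealing,
elitism (2), independent restarts (3 by default, best taken).  A second,
*smooth* mutation adds a random ramp-plus-bump profile across a whole
channel's knots (probability 0.25 per child, symmetric coefficients):
independent knot noise produces wiggly, expensive candidates that selection
removes before coordinated low-frequency moves — a net wrist rotation, a
lateral path bow — can emerge, so those modes are explored directly.  The
same profiles are mixed into the initial scatter.  Reachability
is enforced by an additive penalty (mean annulus excess × 1e6) with the
offending samples clamped radially, so the population can skirt the
workspace boundary without collapsing. The population is initialized by
Gaussian perturbation of the straight-path/constant-wrist seed (spread
1 cm / 1 cm / 0.1 rad), which matches the gross shape of measured reaches
without biasing curvature direction. The original operator definitions and
hyperparameters are not available to reproduce; these defaults are
stand-ins, all config-exposed.

Validation of the search: on a two-joint reduction (wrist locked) the GA
recovers the closed-form hand-jerk optimum (straight path, quintic timing,
cost `360 d²/tf⁵`) to well under 5 %, and the angular-jerk optimum (each
joint a quintic between its endpoint angles) to ≲ 1 % sup-norm.

**Problem sizes.** Tests and the qualitative-trend suite run scaled GA
budgets chosen as the package's own working sizes: populations 60–120 and
150–300 generations with annealed mutation for single-model checks.
Condition contrasts repeat each search three times from independent seeds
and keep the best-cost movement — the same repeated-optimization protocol
the restart machinery implements — and run the search on a `dt = tf/100`
grid, with final metrics always re-evaluated on the `tf/200` grid.
Defaults in `GAConfig` remain at population 200 / 500 generations /
3 restarts for production runs.

## Measurement pipeline

Marker recordings (shoulder, elbow, wrist, fingertip at 200 Hz) are filtered
with a zero-phase 4th-order Butterworth low-pass at 10 Hz (forward–backward,
so the passband gain is the squared one-pass magnitude and pulses keep their
timing). Onset/offset come from the planar path curvature in mm⁻¹ with
threshold 0.3: curvature is tiny at speed and blows up in the
noise-dominated rest phases, so the detector walks backward (forward) from
the movement midpoint to the first crossing. "Midpoint" is taken as the
peak-tangential-speed sample — "midpoint" has no standard definition for
this detector; the peak-speed choice is robust to asymmetric rest tails. Velocities for the
curvature are central differences on the filtered series, positions
converted to mm first.

Model-vs-measurement discrepancy is summarized by RMS errors after
resampling both movements onto 101 points of normalized time `t/tf`:
fingertip RMS is the RMS Euclidean distance; joint RMS pools the squared
errors of all three joints by default (per-joint reporting is available;
there is no canonical pooling convention).

Out of scope by design: outlier-trial removal policies and
multiple-comparison statistics.

## Synthetic data generator

The generator is a kinematic phantom of the measurement setup, not a
simulation of human control: fingertip follows the task chord (optionally
bowed laterally by a single bump parameter, emulating the gently curved
directions) with minimum-jerk progress; the wrist rotates smoothly by a
configurable Δθ3 along the same profile; stationary rest tails are appended
on both sides; markers are placed by the package's own forward kinematics
(single source of kinematic truth) and i.i.d. Gaussian noise of σ = 0.3 mm
(OPTOTRAK-like, configurable) is added per coordinate. Movement times
default to the published per-direction means (≈ 0.53–0.69 s); start/target
pairs are the five packaged workspace points.

What passing the pipeline tests shows: filtering, detection, angle
extraction and RMS comparison are self-consistent and recover known ground
truth at realistic noise. What it does not show: robustness to soft-tissue
artefacts, marker occlusion/mislabelling, non-Gaussian noise, or genuinely
human kinematics (asymmetric speed profiles, submovements).

A physical limit worth recording: with ~0.16 mm residual noise after
filtering, a minimum-jerk reach moves less than the noise floor for roughly
its first 20 ms, so *any* detector carries a lag of that order. The
curvature detector's mean onset lag at σ = 0.5 mm is ≈ 20 ms (inward-biased
on both ends), which is why pipeline accuracy is asserted on means over
seeds rather than per-realization maxima.

## Degenerate inputs and tie-breaks

Hold tasks (start = target) are legal and produce exactly static
trajectories with zero cost. The tension QP needs no tie-break (strict
convexity). Zero-speed samples in the curvature are treated as resting
(curvature → ∞). A torque series identically zero distributes to zero
tension, so rest-to-rest movements begin and end with silent muscles — a
known idealization of the stress-minimizing inner step: real muscles hold
slight tonic activation at rest, which this model cannot represent.

## Viscosity dependence of the comparison models

The trend suite optimizes the torque-change and muscle-stress-change models
on the same task under named viscosity conditions and compares the optima.
Two ladders behave differently. On the wrist-only ladder (`alpha_B` halved /
reference / doubled) the wrist damping coefficient alone prices wrist
motion, and the TC-optimal wrist rotation collapses monotonically as it
rises — the direct form of the excessive-rotation effect. On the all-joint
ladder (`alpha_A`) the TC response is mixed postural and path-shaped:
raising all coefficients also amplifies the shoulder/elbow torque change
that folding the hand inward can reduce, so a wrist-rotating optimum can
reappear at high `alpha_A` and the rotation range need not shrink
monotonically there, even though the fingertip-path deviation does.  The
MSC's own response to the all-joint ladder shows up as the amplitude of a
lateral path bow (its torques, hence stresses, scale with the viscosity),
which can move its path between extreme conditions by more than the TC path
moves.  The test suite asserts the directions above and records the
measured values in its failure messages where an ordering does not hold.

## Known limitations

- The muscle layer has no force–length/velocity or activation dynamics and
  predicts no EMG; it exists to define stress, not muscle physiology.
- The GA guarantees no global optimum; restart agreement is a diagnostic,
  not a proof.
- Group-level PCSAs/moment arms are packaged as published; the underlying
  per-muscle summation is not reproducible from the packaged data.
- Comparisons against *human* data require supplying real marker recordings
  in the documented CSV dialect; everything shipped here validates against
  synthetic references only.
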