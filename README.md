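# armreach

Trajectory and posture selection for planar three-joint arm reaching
movements, built around the **minimum muscle-stress-change** optimality
principle and its classical comparators.

## The problem

Point-to-point reaches in the horizontal plane show invariant features —
near-straight fingertip paths with bell-shaped speed profiles — suggesting
the brain selects movements by optimizing a smoothness criterion. With a
third joint (the wrist) the arm becomes kinematically redundant: the same
fingertip path admits infinitely many postures, so a model must select the
trajectory *and* the arm posture. This package implements and compares four
such models for a shoulder–elbow–wrist arm:

| model | cost functional `C = ½∫₀^tf Σᵢ (dqᵢ/dt)² dt` with `q` = |
|-------|---------------------------------------------------------|
| HJ    | fingertip acceleration (hand jerk; posture-blind, used for validation) |
| AJ    | joint angular acceleration (angular jerk) |
| TC    | joint torque (torque change) |
| MSC   | muscle stress `Sᵢ = Tᵢ/PCSAᵢ` over 8 muscles (muscle-stress change) |

The MSC is a two-step optimization: at every instant a strictly convex
quadratic program distributes the joint torque over eight muscle groups by
minimizing `Σ Sᵢ²` subject to `τ = A T`, `T ≥ 0`; the outer search then
minimizes the integrated squared stress rate over candidate movements. With
tension proportional to command times PCSA (`Tᵢ = k αᵢ PCSAᵢ`), the MSC cost
is exactly `k²` times a motor-command-change cost, which the package exposes
and tests as an identity.

Candidate movements are three 7-knot quintic-spline vectors (fingertip x/y
and wrist angle; rest-to-rest ends); a real-coded genetic algorithm with
tournament selection, BLX crossover, Gaussian mutation, elitism and
independent restarts searches the 16 free knots. Arm dynamics are standard
planar three-link rigid-body equations with a configurable joint-viscosity
matrix whose entries grow with the mean absolute joint torques of the
movement (resolved by fixed-point iteration). Published segment parameters,
muscle PCSAs/moment arms (selections S11–S42) and five viscosity conditions
are packaged as fixtures.

The measurement side mirrors an optical motion-capture pipeline: 200 Hz
four-marker recordings, zero-phase 4th-order Butterworth filtering at 10 Hz,
movement onset/offset from a 0.3 mm⁻¹ path-curvature threshold, and RMS
model-vs-data comparison on normalized time. A synthetic-movement generator
(kinematic phantom with ground truth) makes the whole pipeline testable
without human data.

See `docs/methods.md` for model details, numerical choices and limitations.

## Worked example

Optimize the muscle-stress-change movement for the T41 direction (from
(0.15, 0.56) m to (0.00, 0.30) m, 0.537 s) under the reference viscosity
condition and muscle selection S21, then score it against a synthetic
reference movement:

```python
import numpy as np
from armreach import (ViscosityCondition, ga_optimize, GAConfig,
                      build_selection, make_task, individual_to_arm_trajectory)
from armreach.arm_model import ArmParameters
from armreach.measurement import process_recording, rms_errors
from armreach.synthetic import SynthConfig, synth_measurement

arm = ArmParameters.from_profile("table2_mean")
task = make_task("T41")
sel = build_selection("S21")
cond = ViscosityCondition.named("B10A10")

cfg = GAConfig(population_size=60, generations=150, restarts=2,
               mutation_decay=0.985, seed=1)
result = ga_optimize(task, arm, sel, cond, "MSC", cfg)
built = individual_to_arm_trajectory(result.best, task, arm, cond=cond)

print(f"best C_MSC          : {result.best_cost.value:.1f} (N/cm^2)^2/s")
print(f"wrist rotation range: "
      f"{np.degrees(built.wrist_angle.max() - built.wrist_angle.min()):.1f} deg")

rec, truth = synth_measurement(SynthConfig(task=task, seed=1), arm)
measured = process_recording(rec, task)
f_rms, j_rms = rms_errors(built.traj.t, built.fingertip, built.traj.theta,
                          measured.traj.t, measured.fingertip,
                          measured.traj.theta)
print(f"fingertip RMS vs reference: {1000 * f_rms:.1f} mm")
print(f"joint RMS vs reference    : {np.degrees(j_rms):.2f} deg")
```

Output (exact values are seed-reproducible):

```
best C_MSC          : 728.2 (N/cm^2)^2/s
wrist rotation range: 7.7 deg
fingertip RMS vs reference: 4.1 mm
joint RMS vs reference    : 2.66 deg
```

The optimal T41 path is close to straight, the wrist barely rotates, and the
movement sits a few millimetres from the straight minimum-jerk reference —
the behaviour expected of the stress-change criterion in this direction.
The same run from a shell:

```bash
armreach optimize --model MSC --task T41 --viscosity B10A10 --selection S21 \
    --population 60 --generations 150 --restarts 2 --seed 1 --out msc_t41.csv
```

Other subcommands: `synth` (generate a synthetic recording + ground truth),
`evaluate` (cost of a trajectory CSV), `simulate` (forward dynamics under a
torque file), `compare` (condition-grid RMS report).

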