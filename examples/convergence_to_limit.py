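"""Watch both sides of the scaling limit converge as migration slows.

Backward: the block-counting genealogy, observed at time t/c, approaches the
ancient ancestral lines process (TV distance to the degenerate-semigroup row
shrinks).  Forward: the rescaled diffusion's mean active frequency approaches
the exact jump-process moment while paths concentrate on the boundaries.
"""

import seedbank as sb

print("backward (genealogy) side: TV distance to the limit law at t = 1")
report = sb.convergence_experiment_backward(
    sb.SampleConfig(2, 2), K=1.0, schedule=sb.ScalingSchedule((0.2, 0.05, 0.01)),
    t=1.0, reps=5000, seed=0, final_threshold=0.05)
for c, v in zip(report.c_values, report.metric_values):
    print(f"  c = {c:<5g}  TV = {v:.4f}")
print(f"  decreasing within noise: {report.monotone}; final below 0.05: {report.final_ok}")

print("\nforward (frequency) side: |E[X^c(1/c)] - E[X~(1)]| with dt = c * 1e-3")
report = sb.convergence_experiment_forward(
    sb.DiffusionState(0.3, 0.7), K=1.0, schedule=sb.ScalingSchedule((0.2, 0.07)),
    t=1.0, dt_base=1e-3, reps=2000, seed=0)
for c, gap, bf in zip(report.c_values, report.metric_values,
                      report.extras["boundary_fraction"]):
    print(f"  c = {c:<5g}  moment gap = {gap:.4f}   P(X near boundary) = {bf:.3f}")
print("  (the first moment agrees exactly at every c by duality, so the gap is "
      "pure Euler-Maruyama bias plus Monte-Carlo noise)")
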