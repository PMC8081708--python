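"""Simulate the super-evolutionary limit of the seed bank diffusion.

In the limit of very long dormancy the active frequency is binary: it
fixates instantly (at 1 with probability x0) and thereafter flips whenever a
resuscitating ancient allele of the opposite type fixates, at hazard Y (from
0) or 1 - Y (from 1), while the dormant frequency relaxes exponentially
toward the active state.  Jump times are drawn by exact hazard inversion, so
the simulation has no discretisation error.
"""

import numpy as np

import seedbank as sb

K, horizon = 1.0, 5.0
rng = np.random.default_rng(7)

path = sb.simulate_limit_pdmp((0.3, 0.7), K, horizon, rng)
print(f"X(0+) = {path.initial_x} (Bernoulli with success probability x0 = 0.3)")
print("jump skeleton (time, new x, y at jump):")
for t, x, y in zip(path.jump_times, path.jump_x, path.y_at_jumps):
    print(f"  t = {t:6.3f}  x -> {x}  y = {y:.4f}")
if path.absorbed:
    print("path absorbed: residual switching hazard exhausted")

est, se, exact = sb.pdmp_moments((0.3, 0.7), K, 2.0, 1, 0, reps=10_000, rng=rng)
print(f"\nE[X(2)]: Monte-Carlo {est:.4f} +/- {se:.4f}, exact telegraph value {exact:.4f}")
print("the exact value is x0*p11(t) + y0*p10(t) from the two-state closed form")
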