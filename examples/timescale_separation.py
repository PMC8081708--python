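"""Extract the degenerate limit of the seed bank genealogy numerically.

With migration rate c -> 0 and time sped up by 1/c, coalescence becomes
instantaneous.  This script discretises the chain at step c^2, splits the
one-step matrix into fast (coalescence) and slow (migration) parts, recovers
the projection P from high matrix powers, forms the limit generator
G = P B P, and confirms both equal their analytic forms.
"""

import numpy as np

import seedbank as sb

sample, K, c = sb.SampleConfig(3, 2), 1.0, 0.05
a, b = c**-2, c**-3

Q = sb.build_blockcounting_Q(sample, sb.ModelParams(c=c, K=K))
Pi = sb.discretise(Q, a)                      # one-step matrix at step 1/a
mask = sb.coalescence_fast_mask(Q.space)
dec = sb.decompose(Pi, mask, b)               # Pi = A + B/b

P, diag = sb.extract_projection(dec.A, a)
print("norm decay ||A^ceil(C a)| - P|| over C:", [f"{v:.2e}" for v in diag["norm_decay"]])

aalp = sb.build_aalp(sample, K)
print("recovered P equals the analytic projection:", np.array_equal(P, aalp.P))

B = sb.build_slow_limit_matrix(aalp.space, K, "seedbank")
G, _ = sb.limit_generator(P, B=B)
print("P B P equals the analytic limit generator:", np.array_equal(G, aalp.G))

# the degenerate semigroup is not standard: Pi(0+) = P, not the identity
sg = aalp.semigroup
print("||Pi(1e-12) - P|| =", sb.matrix_norm(sg(1e-12) - P))
print("Pi(0) is the identity:", np.array_equal(sg(0.0), np.eye(len(aalp.space))))
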