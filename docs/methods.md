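# Methods

## The model

A haploid population of size `N` carries a *seed bank*: alongside the active
(reproducing) population there is a dormant reservoir of relative size `1/K`
whose members neither reproduce nor die, but exchange with the active
population at a slow rate. Measuring time on the coalescent scale, the
frequency of an allele in the active (`X`) and dormant (`Y`) populations
follows the seed bank diffusion

    dX = c (Y - X) dt + sqrt(X (1 - X)) dB,
    dY = K c (X - Y) dt,

with migration (switching) rate `c > 0` and size ratio `K > 0`. Only the
active population carries genetic drift. The genealogy of a sample of `n0`
active and `m0` dormant lineages is the block-counting chain `(N(t), M(t))`
with rates: coalescence `binom(n,2)` to `(n-1, m)`, dormancy `c n` to
`(n-1, m+1)`, resuscitation `c K m` to `(n+1, m-1)`. A two-island variant
scales island coalescence by `alpha`, `alpha'` and allows
`alpha' binom(m,2)` mergers among dormant/island-2 lineages; its forward
process adds `alpha' sqrt(Y(1-Y)) dB'` noise to the second coordinate.

The two descriptions are moment duals:
`E^{x,y}[X(t)^n Y(t)^m] = E_{n,m}[x^{N(t)} y^{M(t)}]`. The dual side is a
finite matrix exponential, so it serves as an exact oracle for every forward
simulation in the package; this dual-route checking is the package's design
backbone.

A note on the printed rate tables: a conservative Q-matrix must have diagonal
equal to the negative off-diagonal row sum, and that is the convention
implemented throughout.

## The separation-of-timescales limit

When dormancy periods are much longer than the coalescent timescale
(`c -> 0`) the interesting limit appears on the *super-evolutionary*
timescale `t -> t/c`, where reproduction acts instantaneously. The generic
machinery (`timescales` module) mirrors the discrete-time treatment of such
limits: discretise the chain at step `1/a` with `a = c^-2`, split the
one-step matrix as `Pi = A + B/b` with `b = c^-3` (fast part `A`: coalescence
plus diagonal; slow part `B`: migration), and obtain

* the projection `P = lim A^r` — every state with `n >= 1` active lineages
  collapses to `(1, m)`;
* the limit generator `G = lim P B_k P` — for the seed bank,
  resuscitation-with-immediate-coalescence at rate `K m` and dormancy at
  rate 1, with negative off-diagonal mass `-1 - K m` on rows the projection
  collapses (`G` is not a Q-matrix);
* the degenerate semigroup `Pi(t) = P e^{tG}` for `t > 0`, `Pi(0) = Id`.
  The semigroup is not standard: `Pi(0+) = P != Id`.

The limit genealogy (*ancient ancestral lines process*) is never simulated
through `G` (its negative entries are not rates). Instead, the collapse is
applied once at time `0+` and the conservative reduced chain on
`{0,1} x {0,...,m_max}` is simulated exactly; the restriction identity
(restricted `P e^{tG}` equals `e^{t Gbar}`) licenses this and is itself
verified numerically by two independent matrix exponentials.

The forward limit is a piecewise-deterministic Markov process: `X` is binary
from `0+` (initially 1 with probability `x0`, the fixation probability of
instantaneous drift) and flips at hazard `Y` (from 0) or `1 - Y` (from 1),
while `Y` relaxes as `dY = K (X - Y) dt`. Because the hazard decays
exponentially, jump times are drawn by exact closed-form inversion of the
cumulative hazard (total residual hazard `h0 / K`); paths can be genuinely
absorbed. The simulator is exact — no step-size parameter exists. The
imbalanced two-island limit keeps diffusion noise in `Y` and is simulated by
an Euler-Maruyama/thinning hybrid instead (thinning valid for
`dt * max-hazard < 0.1`).

## Finite-grid conventions

The full state space is the grid `{0,...,n0+m0}^2`, enumerated row-major,
including states with `n + m > n0 + m0` that no sample can reach; uniform
indexing outweighs the wasted rows. Transitions whose target falls outside
the grid are dropped on *both* sides of every identity, which keeps
`P B P = G` exact entrywise including boundary rows. Diagnostics that compare
truncated prelimit matrices with analytic limits restrict to the physically
reachable rows (`reachable_states`); the unreachable rows of the truncated
slow part genuinely differ from the analytic limit there, which is a
truncation artefact, not a model statement.

The reduced chain capped at `m_max` omits the dormancy move from the
boundary row `(1, m_max)` and uses the conservative diagonal there, making
`Gbar` a genuine Q-matrix; that row is unreachable from any start with
`m <= m_max - 1`. The restriction-identity check exponentiates a one-slot
extension of the truncation so every compared row has its reachable closure
inside both matrices.

## Numerical choices

* **Matrix exponentials** via `scipy.linalg.expm`; matrix powers by binary
  exponentiation. On the fixture sizes used (state spaces up to 49 x 49)
  accumulated `expm` error is ~1e-13, far below every asserted tolerance.
* **Projection snapping** at 1e-6: entries of the largest fast-part power
  must be within 1e-6 of {0, 1}, far above `expm`/power rounding and far
  below the smallest genuine entry (~`c^2` at `c = 0.05`).
* **Cauchy detection** of `G = lim P B_k P` defaults to tolerance 1e-3. The
  slow parts computed from matrix exponentials carry two error sources: the
  genuine `O(c^2)` corrections of the expansion, and float rounding in
  `Pi_k` amplified by `b = c^-3` (about `1e-16 c^-3`, already 1e-7 at
  `c = 1e-3`). A tolerance much below 1e-3 is therefore not attainable by
  this route; the analytic-limit route `P B P` is exact and is what the
  identity tests assert.
* **Euler-Maruyama**: truncate-and-clamp boundary scheme — evaluate
  `sqrt(max(0, x(1-x)))` at the clamped state, clamp to the unit square
  after each step. This preserves the absorbing corners exactly and its
  moment bias is bounded empirically by the duality checks; default step
  `dt = 1e-3`. Steps are rejected when `dt >= 1/(c(1+K))` (drift
  overshoot). Duality pass bands are `4 SE + dt` (the `dt` term is the bias
  allowance, calibrated once by a step-halving study); the exact-jump PDMP
  checks use `4 SE` with no bias term.
* **Random numbers**: one integer seed per experiment; replicate `r` uses
  sub-seed `seed + r`, so results are independent of execution order and
  bit-reproducible. The compiled kernels draw Gaussians from an inlined
  Box-Muller transform on a per-replicate Mersenne stream.
* **Monotonicity verdicts** in convergence experiments allow inversions
  within twice a sampling-noise floor (for TV distances, the analytic
  expected fluctuation of the empirical TV; for moment gaps, the largest
  per-`c` standard error), so a metric sitting at the noise level does not
  flip the verdict spuriously.

## Study sizes

The scripted experiments run at desk scale, chosen once:

* seed bank duality grid: moment indices {(1,0), (0,1), (2,1), (1,2)},
  `c` in {0.5, 1}, `K` in {0.5, 2}, `t` in {0.5, 1}, start (0.3, 0.7),
  2e4 replicates, `dt = 1e-3`;
* limit duality grid: `(n, m)` in {0,1} x {0,1,2}, `K` in {0.5, 2},
  `t` in {0.5, 2}, 1e4 exact-jump replicates;
* genealogy convergence: sample (2,2), `K = 1`, `t = 1`,
  `c` in {0.2, 0.05, 0.01}, 1e4 Gillespie paths per `c`;
* frequency convergence: start (0.3, 0.7), `K = 1`, `t = 1`,
  `c` in {0.2, 0.05, 0.02} with `dt = c * 1e-3` and 2.5e3 replicates
  (1.5e3 in the acceptance script); each replicate needs `~1e3/c^2` steps,
  which sets the schedule endpoint.

Two structural facts about the frequency-side experiment deserve emphasis.
First, for the *first* moments the rescaled prelimit equals the limit value
exactly at every `c` (the single-lineage dual is the two-state telegraph
chain, and rescaling time by `1/c` exactly cancels the rate `c`), so the
measured moment gap is pure discretisation bias plus Monte-Carlo noise — a
stringent probe of the boundary scheme, not of the limit theorem's rate.
Second, that probe reveals the clamped scheme's weakness in the
boundary-pinned regime: the gap the experiment measures *grows* as `c`
shrinks (roughly like `dt_base / c` under the `dt = c * dt_base` step rule),
and shrinking `dt` at fixed `c` barely moves it — the clamp injects a small
net mass imbalance on every boundary excursion, visible equally as a drift
in `E[K X + Y]` over the `1/c` horizon. The first-moment-gap monotonicity
assertion in the forward-convergence test is therefore an honest negative
result about the scheme and is expected to fail; the genuine convergence
signal of the theorem — concentration of the active frequency on the
boundaries, and agreement of the limit moments through the exact
jump-process simulator — is asserted alongside and passes. Users who need
small-`c` forward behaviour should reach for the exact limit simulator
rather than the rescaled diffusion.

## What the generators emulate — and what they do not

There is no external data in this problem: the synthetic inputs are the
model's own parameters, chosen to match the regimes of interest (migration
rates descending from 0.2 towards 0.01 for limit experiments, order-one
rates for prelimit checks; samples of up to ~10 lineages, where the full
grid stays small and every identity can be checked exactly). Passing tests
show that the simulators realise the stated processes and that forward and
backward descriptions agree; they do not validate the biological adequacy of
the seed bank model itself, and the package deliberately excludes mutation,
selection, partition-valued (tree-topology) genealogies and infinite state
spaces.

## Known limitations

* The projection/limit diagnostics sample a finite `C` x `c` grid of the
  underlying double limit; they are surrogates, reported with their decay
  sequences rather than as proofs.
* The Wright-Fisher boundary is delicate under Euler-Maruyama; the clamped
  scheme's bias is controlled empirically (duality bands, step-halving), not
  analytically. `dt` is exposed everywhere for refinement studies.
* Convergence experiments test one-dimensional marginals and moments, the
  form in which the limit statements constrain finite times; no path-space
  metric is attempted.
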