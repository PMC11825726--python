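# Methods

## Ground-truth networks

Directed Erdos-Renyi digraphs: each ordered off-diagonal pair (i, j)
receives a connection independently with probability `p`, so the expected
edge count is `p N (N-1)` and reciprocal pairs occur at rate `p^2`.  The
matrix orientation is `weights[i, j]` = strength of the connection *from j
into i* (row i lists node i's inputs); every module uses this convention.
Nonzero weights are U(0,1] by default (`weight_scheme="uniform01"`), with a
binary option for the linear benchmark.  Distances are drawn U(0, 10] mm at
every connection — independently per ordered pair, also for reciprocal
pairs, which is the simplest reading of a "filled at nonzero positions"
distance matrix — and become transmission delays through a constant signal
speed (1 mm/ms by default, so delays are U(0, 10] ms).  One master seed
spawns independent sub-streams for topology, weights and distances, so
regeneration from a seed is bit-exact.

## Delayed Hopf (Stuart-Landau) network

Each node is a Stuart-Landau oscillator in real coordinates, with diffusive
delayed coupling and an additive Ornstein-Uhlenbeck (OU) drive per node and
per variable (defaults: a = 0.25, w = 0.5 rad/ms ~ 79.6 Hz, K_gl = 0.6,
tau_OU = 5 ms, sigma_OU = 0.1, dt = 0.1 ms, 200000 steps = 20 s).  For
a > 0 an uncoupled noiseless node settles on a limit cycle of radius
sqrt(a); the diffusive term `x_l(t - tau_il) - x_i(t)` vanishes between
synchronized nodes.

Numerical choices:

- Explicit Euler(-Maruyama) at fixed dt; delays rounded to integer
  multiples of dt; the history buffer is pre-filled with the initial
  condition for t < 0.  Initial states are uniform on a disc of radius
  0.05 around the origin.  The explicit-Euler limit-cycle radius carries an
  O(dt) bias (sqrt(a + dt w^2 / 2), about 2.5% at dt = 0.1 ms); tests that
  check the continuous-system radius use a finer step.
- Non-finite states abort the integration with an error naming the first
  offending step.
- **OU scaling.**  `ou_scheme="per_step"` (default) treats `sigma_OU` as
  the standard deviation of the raw per-step Gaussian increment, i.e. an
  effective diffusive scale of `sigma_OU / sqrt(dt)`; at the defaults the
  drive's stationary standard deviation, `sigma_OU * sqrt(tau_OU / (2 dt))`
  = 0.5, matches the limit-cycle radius.  This noisy-oscillator regime is
  the one the estimator stack is validated in: the drive is strong enough
  to decorrelate indirectly connected nodes (so pairwise estimators can
  separate direct from indirect influence) while direct connections remain
  detectable.  `ou_scheme="euler_maruyama"` selects the textbook SDE
  scaling `sigma_OU * sqrt(dt)`, which at these defaults is a weak-noise
  regime with long-range coherence and noticeably harder pairwise
  estimation.  Note that under `per_step` the physical noise intensity is
  tied to the step size, so dt-refinement studies should use
  `euler_maruyama`.
- Noise sub-streams are derived from the master seed and the node count
  only — never from the coupling matrix — so a regeneration run with a
  different matrix but the same seed receives identical OU paths and
  initial conditions.  This is what makes the same-seed regeneration
  protocol exact.

## Linear benchmark

`dX = C X dt + u`, `u ~ N(0, sigma^2 dt)` per step, integrated by
Euler-Maruyama (dt = 0.01 s, 1000 s by default, sigma = 1 — the noise
scale is not critical because the estimators are scale-invariant, and it is
exposed in the parameters).  `C = C0 - (m/N + 1) I` with binary
off-diagonal structure C0 and realized edge count m.  The negative diagonal
makes every realization diagonally dominant and stable; writing the
diagonal with the opposite sign would contradict the decaying single-node
dynamics the benchmark assumes, so the stable sign is used.  No
observational noise is added.  This is the regime in which linear DDC is
the least-squares estimator of C, which the tests verify (GT-vs-estimate
Pearson >= 0.95 at the default run length).

## Estimators

All estimators consume the x channel, return an N x N matrix in the
row-receives convention with a zero diagonal, and are tagged with their
method name and parameters.

- **Cross-correlation (`xcorr_fft`).**  Both series demeaned; the
  cross-spectrum `conj(F(x)) * F(y)` is inverted after zero-padding to at
  least 2T - 1 points (no circular wrap) and normalized so autocorrelation
  at lag 0 is 1 — the lag-0 value is then the plain Pearson coefficient.
  Sign convention: `R(tau) = sum_t x(t) y(t + tau)`, so `tau_max > 0` means
  the second series lags the first.  Swapping arguments mirrors the lag
  axis exactly, so one computation per unordered pair yields both
  directions.
- **LCC (`lcc_estimate`).**  Direction from the sign of `tau_max` within
  `|lag| <= max_lag` (default 200 samples, twice the largest possible
  delay, bounding spurious distant-lag maxima); `tau_max = 0` is read as
  bidirectional when the Pearson coefficient is at least 0.1 in magnitude
  (aligned with the global threshold), otherwise no connection.  The
  selected entry is filled with the *lag-aligned* correlation maximum
  (default).  The zero-lag Pearson fill is available but is not the
  default: for delayed oscillatory dynamics the zero-lag coefficient of a
  true connection is suppressed by the phase factor
  `cos(2 pi tau / period)` and can vanish or turn negative at delays near
  half a period, while the lag-aligned maximum is phase-invariant.
- **Thresholding** clamps raw signed values below 0.1 to zero (values at
  the boundary are kept; negative entries are always clamped — note this
  differs from absolute-value thresholding).  **Binarization** for
  ROC-style scans uses the complementary strict `>`, so the two rules agree
  at the boundary.
- **Cut variants** keep every 15th sample; spectral content above the new
  Nyquist frequency aliases.
- **DDC** (linear form): `Chat = Cov(dX/dt, X) Cov(X, X)^-1`.  The
  derivative is the forward difference `(X_{t+1} - X_t)/dt` paired with
  `X_t`: for SDE-generated data this is the consistent least-squares
  estimator (`E[(X_{t+1} - X_t) X_t^T]/dt -> C Sigma`), whereas the
  central difference — second-order accurate on smooth trajectories, and
  available via `scheme="central"` — converges on noise-driven data to the
  antisymmetrized drift `(C Sigma - Sigma C^T)/2` and systematically
  degrades recovery.  Near-singular covariances are ridge-regularized
  (1e-6 trace/N) with a warning.  The intrinsic-decay diagonal is zeroed
  in the returned estimate (and preserved in its parameter record).
- **LCC+DDC** keeps entries exceeding 0.1 in both estimates; surviving
  values are taken from the LCC matrix, the primary estimator.
- **Partial correlation** from a GraphicalLasso (L1-penalized) precision
  matrix, `-P_ij / sqrt(P_ii P_jj)`; falls back to the unpenalized
  pseudo-inverse precision on non-convergence.
- **Naive transfer entropy**: pairwise, 8 equal-width bins, one-step
  history, natural logarithms, no conditioning on third nodes.  Runtime is
  orders of magnitude above LCC at larger N, which is why the sweep tables
  restrict it to small networks.

## Evaluation and regeneration

Estimates are scored by the Pearson correlation of flattened off-diagonal
entries (the structurally-zero diagonal would inflate the score; a switch
re-includes it for cross-checks).  Negative estimated entries are scored
as-is.  Confusion counts and ROC-style threshold scans operate on
off-diagonal positions only.  `method_sweep` evaluates every requested
method on the same simulated realization per cell, with per-cell seeds
spawned from one master seed; sweep grids follow the constant-pN design
(N=10: p 0.1-1.0; N=100: 0.01-0.1; N=250: 0.004-0.04).

Regeneration re-runs the Hopf simulator with the estimated matrix in place
of the ground truth, under the identical seed.  Delays reuse the
ground-truth distances where the estimate overlaps a true connection;
estimated edges without a true counterpart fall back to the mean
ground-truth distance (the delay of a false-positive edge is otherwise
undefined).  Trace agreement is the per-node Pearson correlation of the x
traces after discarding the first 10% of samples as transient —
initial-condition mismatch is not the object of study — and a node whose
incoming row is exactly right regenerates bit-identically (correlation
exactly 1).

## What the synthetic generators do and do not emulate

The generators reproduce the study conditions end-to-end: sparse directed
random wiring, distance-dependent delays, per-node stochastic drive, and a
stationary oscillatory regime.  They do not emulate biophysical observation
models (calcium indicator dynamics, photobleaching, slow or irregular
sampling), partial observation of a larger circuit, inhibitory
connections, or non-stationarity.  Passing tests therefore demonstrate
correct recovery under complete observation of a stationary, purely
excitatory system with high sampling rate — not performance on raw
biological recordings, for which the activity-table loader and
binarization-threshold scan provide the entry point.

## Known limitations

- Pairwise estimators cannot fully remove confounder motifs (common
  drivers, two-hop chains); residual false positives at moderate densities
  are intrinsic, and fidelity collapses once the expected in-degree pN
  grows past ~5 and the network approaches a single connected component.
- Bidirectional pairs are only detected at (near-)zero lag difference;
  asymmetric reciprocal delays yield one direction.
- Direction inference degrades for delays below a few samples (the
  cross-correlation peak plateaus around zero lag).
- Under the same-seed regeneration protocol the shared noise drive keeps
  regenerated traces aligned with the original even for imperfect
  estimates, so trace-to-trace correlations are a lenient score: estimate
  quality separates LCC from DDC by a few hundredths here, versus tenths
  in direct matrix correlation.  Mean trace correlations for dense,
  error-carrying estimates remain above 0.9 in this implementation.
- The NTE implementation covers one-step history only.
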