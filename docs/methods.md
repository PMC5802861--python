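# Methods

## Model

All networks are continuous-time rate networks of `N` units with
activation vector `x`, rates `H(x) = tanh(x)`, and time constant
`tau = 10 ms`:

- **Task-performing network** (the product of training):
  `tau dx/dt = -x + J H(x) + u_in f_in(t)`, with linear readout
  `z(t) = w^T H(x(t))`.
- **Output-feedback (FORCE) network**: the same with an extra feedback
  term `u z(t)`; only `w` is learned, so the effective recurrence is the
  rank-one update `J^D + u w^T` of a fixed random matrix.
- **Driven target-generating network** (used only during training):
  `tau dx^D/dt = -x^D + J^D H(x^D) + u f_out(t) + u_in f_in(t) +
  u_hint f_hint(t)`.

`J^D` entries are i.i.d. `Normal(0, g^2/N)` with `g = 1.5`; `u_in`, `u`,
`u_hint` entries are i.i.d. `Uniform(-1, 1)`. Undriven, a `g > 1`
network is chaotic; driven by the target output the dynamics become
input-locked and reproducible (the echo-state property), which is what
makes the driven activity usable as a source of per-unit learning
targets. Note that convergence of distinct initial conditions under the
oscillation drive is slow — of order seconds, i.e. a few task periods —
and finite networks at `g = 1.5` can be multistable undriven (a stable
limit cycle coexisting with the chaotic sea). Neither property affects
training, which integrates one continuous driven trajectory.

## Learning

full-FORCE trains the entire matrix `J` (from `J = 0`) so the internal
drive `J H(x)` of the task network matches the internal-plus-external
drive `J^D H(x^D) + u f_out (+ u_hint f_hint)` of the driven network,
both integrated concurrently on the same input stream. Minimization is
by recursive least squares (RLS): a single inverse-correlation matrix
`P` (initialized to `I/alpha`, `alpha = 1`) serves all rows of `J` and
the readout `w` because every row regresses onto the same rate vector.
At each update, `P` is downdated first, then
`J <- J - (J r - target)(P r)^T` and `w <- w - (w^T r - f_out) P r`.
With this ordering and zero initialization, the RLS endpoint on a frozen
sample sequence equals batch ridge regression exactly; tests verify this
and the direct-inverse identity for `P`.

Update times are drawn with geometrically distributed gaps on the 1-ms
integration grid, mean 2 ms, so periodic tasks are not sampled at
redundant phases. `w` is trained concurrently with `J` by default; a
sequential mode (readout trained afterward on the closed-loop network)
exists for comparison. FORCE training uses the same `P` machinery for
`w` only, with output feedback active during training.

Hints enter the target-generating network only and only during
training. The trained task-performing network has no hint channel; the
API refuses to wire one at inference.

## Integration and noise

Forward Euler with `dt = 1 ms` (`tau/10`); tests check first-order
convergence against finer-step references. White-noise input with
diffusion coefficient `2D` (units 1/ms) enters the task-performing
network like any other input, inside the `tau dx/dt` bracket, so one
Euler step adds a state increment of standard deviation
`sqrt(2D dt)/tau` per unit. The driven network is integrated noise-free
(clean targets). Noise is applied during both training and testing at
the same level.

## Test protocol

Tasks are continuous trial streams; network state is carried across
trials and batches, and testing continues from the state at the end of
training (a fresh random state is available via `x0="random"`). This
matters: a trained oscillator probed from an arbitrary random state can
sit outside the learned attractor's basin and produce a desynchronized
oscillation even when its on-attractor error is ~1e-4.

Normalized test error is the mean squared output error divided by the
target variance (0 perfect, ~1 output-at-mean). Oscillation-task error
is scored over test periods after one unscored warmup period. Pulse
tasks are scored per trial with the 0.25 normalized-error threshold; the
interval task allows the comparison window to center anywhere within
±250 ms of the nominal response time (a strict-centering mode exists),
and comparison-task percent correct excludes undetermined trials.

## Tasks

- **Oscillation**: 2-s period, `f_out(t) = sin(omega(t) t)` with
  `omega` rising linearly from `2*pi` to `6*pi` rad/s over the first
  half and the signal reflected about the period midpoint. The formula
  is implemented literally (not as an instantaneous-frequency chirp,
  which would differ). A 50-ms, amplitude-1 input pulse at the start of
  each period pins the phase.
- **Interval matching**: 50-ms amplitude-1 pulse pair; interval =
  onset-to-onset spacing, uniform on 0.1–2.1 s (configurable); response
  bump (Beta(4,4) profile, 500 ms, peak 1.5) starting at second-pulse
  offset + interval; inter-trial intervals exponential with mean 2.4 s.
  Hint: a ramp of slope 1 unit/s from the first pulse onset, peaking at
  the second pulse and returning to zero symmetrically.
- **Delayed comparison**: pulse amplitudes uniform on 0.125–1.875,
  silent gap uniform on 0.1–1 s for training (20 ms–2 s for
  extrapolation tests); signed response bump right after the second
  pulse, positive when the first pulse was larger. Hint: the first
  amplitude held during the gap.
- Pulse-task targets ride on a +0.25 constant baseline (magnitude is a
  package choice; the constant drive suppresses residual chaotic
  activity during silent periods).

## Synthetic data and what tests show

All inputs are generated by these task modules; there is no external
data. The generators emulate the stimulus statistics above exactly, but
not features of real experiments (trial-by-trial nonstationarity,
correlated noise, measurement noise on outputs), so passing tests
demonstrate properties of the training algorithm on its intended task
family, not performance on recorded neural data.

## Desk-scale experiment sizes

Full-scale results in the literature use up to 100 training batches of
100 periods and 100–200 random initializations per condition. The
package's test suite and acceptance script use scaled-down protocols
chosen as the package's own defaults:

- Size sweep (both algorithms): sizes {100, 150, 200, 300, 400}, 5
  random draws of `J^D` per size (3 in the quick suite), batches of 100
  periods with 4 batches for sizes ≤ 200 and 2 for larger sizes (small
  networks are cheap and sit near their training-saturation plateau;
  large ones saturate in fewer batches and dominate runtime). Sizes are
  scanned ascending and the scan stops at the first success — larger
  sizes cannot change the reported onset. Success threshold: median
  normalized error < 0.05.
- Noise comparison: N = 300, `2D ∈ {1e-3, 1e-1}`/ms, 10 seeds at the
  decisive high-noise level, test over 10 periods.
- Hint comparison: N = 300, intervals shortened to ≤ 0.8 s and
  inter-trial intervals to mean 1.2 s, 2 batches of 40 trials, 5 seeds,
  30 test trials.

At these scales the qualitative results are stable (full-FORCE onset at
200 units vs 400 for FORCE; order-1e-4 errors at N = 300), but
individual cells are noisier than the full-scale medians.

## Numerical choices

- `P` downdates subtract a term-by-term symmetric outer product, so `P`
  stays symmetric to rounding without explicit symmetrization in the
  compiled path (the reference path symmetrizes explicitly).
- Compiled (numba) kernels implement training and long simulations;
  they are pinned against the pure-Python reference implementation to
  1e-8 on small problems. Noise inside kernels comes from the legacy
  global numpy stream seeded per batch from the run's generator.
- Degenerate inputs: a constant target has no normalized error and is
  rejected, except the all-zero target in the driven-readout check,
  which returns zero weights and zero error by convention. Equal
  comparison-task amplitudes are resampled. Non-finite states raise a
  numerical-failure error naming the batch or step.
- `batch_ridge_solve` requires `alpha > 0`; the near-zero limit is
  exercised in tests at `alpha = 1e-10`.

## Known limitations

- The interval/comparison headline percentages from full-scale
  (N = 1000, long-training) experiments are out of desk-scale reach; the
  suite checks the hint-vs-no-hint ordering on a shortened interval
  range instead.
- Trained oscillators at desk scale are sensitive to test-time noise:
  the dominant failure mode is phase desynchronization between the
  internally generated chirp and the target, which the once-per-period
  input pulse only weakly corrects. Training with matched noise
  mitigates but does not remove this.
- Driven and task-performing networks must be the same size; spiking
  units, alternative integrators, and sparse connectivity are out of
  scope.
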