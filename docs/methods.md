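# Methods

## Model

A two-alternative forced choice is simulated as a discrete-time
drift-diffusion process coupled to a constant-speed reach. The decision
variable starts at `z(0) = 0` and accumulates Gaussian increments until the
trial terminates; positive drift points toward target 1, so arrival at
target 1 is scored correct and arrival at target 2 an error. The agent
lives in a 2D arena (start `(0,0)`, targets `(∓1, 1.5)`, speed `v = 2`
units/s), and all coupling between the two systems passes through the
*action focus* — the point the movement currently steers toward. The five
architectures (no-action baseline; serial; changes of mind; action
preparation; preparation + commitment) differ only in the focus rule and
are described in the README.

### Accumulator discretization

`EvidenceParams` carries *per-step* increment parameters: each step draws
`Δz ~ N(drift_mu, noise_sigma²)`. This is the natural contract for exact
unit tests (zero-noise configurations cross bounds at exact multiples of
`Δt`) and for scripted-noise experiments.

The *study configuration* — the default for `ModelSpec`, `make_spec`, the
CLI and the acceptance script — is the standard diffusion discretization
`EvidenceParams.from_rates(mu_rate=1/3, sigma_rate=1, dt=0.05)`, i.e.
per-step increments `N(μΔt, σ²Δt) = N(1/60, 0.05)`. Treating μ and σ as a
drift rate (1/s) and a diffusion coefficient (1/√s) keeps the model's
behavior invariant under refinement of the time step and is what produces
the reference phenomenology reproduced by the acceptance checks (minimum
mean response times around 1.2 s for the change-of-mind and preparation
models, the reported deviation areas, the near-vertical launch of prepared
movements). Reading the same numbers as per-step parameters makes the
per-step drift/noise ratio 20× larger, decisions resolve within 2–3 steps,
and none of those signatures appear. Both conventions are available;
mixing them changes every downstream number, so each function documents
which it expects.

### Step semantics

Each iteration covers one interval `[(k−1)Δt, kΔt]`: the agent first moves
toward the focus computed at the end of the previous iteration, then the
evidence increment lands, then the focus is updated. Movement therefore
lags evidence by exactly one step. This makes the serial model's response
time *exactly* the first-crossing time plus the straight-line travel time
`√3.25/2 ≈ 0.9014 s` — the defining property of a decide-then-act
architecture — and the identity is exercised per-trial in the tests.

Arrival is detected when the focus coincides with a target and lies within
one step (`v·Δt`) of the agent; the terminal step is shortened to land
exactly and contributes `distance/v` to the response time, so response
times are not quantized to the step grid. A step toward a non-target focus
within reach snaps onto it (the agent then tracks the focus along the
target line). A hard cap of 10⁶ steps guards non-terminating
configurations and raises rather than truncating.

### Focus conventions

For the interpolated focus the weight `(b+z)/2b` multiplies target 1, so
that `z = +b` clamps the focus onto target 1, continuously with the
serial/switching rules under the `+b ↔ target 1` orientation used
throughout. The commitment term is `g·(d₂−d₁)/(d₁+d₂)` with `g = 4b` by
default: approaching target 1 (d₁ shrinking) adds positive effective
evidence, making an initiated approach self-reinforcing — an
anti-commitment sign would contradict the mechanism the term exists to
model. The commitment model's focus clamp reads the effective evidence
(raw `z` plus the positional term); the raw accumulator is never modified,
so the positional term vanishes the moment the agent is removed from the
arena.

Bound crossing is inclusive (`|z| ≥ b`), chosen so zero-noise cases
terminate exactly; no within-step interpolation of the crossing time is
applied, matching the discrete formulation.

## Trajectory metrics

Every focus lies on the target line `y = 1.5`, so height is non-decreasing
along any trajectory and all metrics reparameterize by `y`.

* **Deviation area** — `∫ |x(y) − x_target| dy`, trapezoidal on the raw
  samples. Constant-height segments (the stationary pre-decision phase,
  the terminal slide along the target line) have `dy = 0` and contribute
  nothing, which is the correct path integral. A straight dash to a target
  scores exactly 0.75.
* **Mean trajectory** — per-height average of `x` over a common 101-point
  grid ("parallel to the x-axis"), *not* the time-normalized average usual
  in mouse-tracking software; duplicate heights within a trajectory are
  collapsed to the last sample so `x(y)` is single-valued and the mean path
  ends on the target.
* **Angles from vertical** — least-squares slope of the mean trajectory
  over an end window, `arctan|dx/dy|`. Headline windows: the first 20% of
  the rise for the initial heading and the terminal grid segment (2%
  window) for the final approach, which captures a horizontal slide that a
  longer window dilutes. Any window reproduces `arctan(1/1.5) = 33.69°` on
  a straight path; the ad-hoc `angle_from_vertical` defaults to a generic
  10% window.
* **AUC curvature** — area between the raw path and its straight endpoint
  chord, again integrated over height.

Per-trajectory areas are averaged; angles are read off the mean path.

## Calibration and sweeps

Speed–accuracy frontiers use 31 geometrically spaced bounds on
`[0.01, 10]` (geometric because the range spans three decades), 10⁴ trials
per point by default, one independent substream per point. Calibration of
`b` to a target mean RT evaluates a 13-point coarse grid with common
random numbers, then bisects inside the first interval that crosses the
target (tolerance 0.02 s at n = 10⁴). The bracket scan is essential for
the commitment model, whose mean RT first *falls* with `b` (the `g = 4b`
gain strengthens commitment faster than the bound slows decisions) before
rising again; the smallest-`b` crossing is returned, which is the branch
continuous with the preparation model's frontier.

## Randomness and reproducibility

Trial `i` of a batch draws from `SeedSequence((master_seed, i))`, so
results are independent of execution order, batch splitting and growth.
`run_trial` is a scalar reference implementation; `run_batch` is a
vectorized synchronous-stepping engine over the same substreams, and the
test suite asserts bitwise agreement between the two (the arithmetic of
the movement update is deliberately written operation-for-operation
identically in both). CSV artifacts round-trip exactly and repeated runs
are byte-identical.

## What the simulator does and does not emulate

The generated trajectories emulate tabular 2AFC tracking records
(per-sample `t, x, y` plus evidence traces) under idealized kinematics:
constant speed, instantaneous heading changes, no motor noise, no
non-decision time, movement onset at a fixed rule per model. Real tracking
data have smooth velocity profiles, curved rather than kinked revisions,
onset latencies and endpoint scatter; passing tests therefore validate the
decision–action coupling logic and the metric definitions, not biological
realism of individual paths. A generic reader maps external
`(trial_id, t, x, y)` files onto the default arena by endpoint
normalization so the same metrics apply to empirical data.

## Known limitations

* The change-of-mind model's revisions are sharp kinks; smoothing (e.g.
  angular-velocity limits) is out of scope.
* At small bounds the models' error rates are governed by the one-step
  drift/noise ratio and sit well above typical human error rates; the
  framework is a mechanism comparison, not a fitted model of any dataset.
* The final-approach angle of the commitment model is sensitive to the
  calibrated bound and retains a partial terminal slide; its measured
  value (~63–68° across seeds) should be read with that sensitivity in
  mind.
* The noise-difficulty curvature contrast (σ×4) is small relative to
  Monte-Carlo noise at 150 trajectories; conclusions from it require many
  more trials than the headline protocol uses.
* Asymmetric target geometries, collapsing bounds, urgency signals and
  biomechanical cost models are not implemented.
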