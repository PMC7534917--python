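# Methods

## Task environment

The W-maze has arms 1, 3 (outer) and 2 (center). One *well visit* (trial)
is one arrival at a reward well; it is the time axis of every analysis.
Reward delivery: from an outer arm (or the session-start position) the
center arm pays; from the center arm the *less recently visited* outer arm
of the current session pays, and if the center was the session's first
visit either outer arm pays. Trials beginning at an outer arm or at the
session start are *inbound* (correct response: center); trials beginning
at the center are *outbound*. A session's first visit that is not to the
center counts as an inbound error — this is what produces the periodic
bumps in inbound-error curves at session boundaries.

Two rule details are not fixed by the delivery algorithm itself and are
explicit choices here:

* A session-start visit to the center arm is itself rewarded (it follows
  the "go to center" rule from the start position); the first-visit
  exception is read as governing the *next*, outbound, trial. The flag
  `reward_first_center=False` inverts this; classification never treats a
  center start as an error in either case.
* Outer-arm visit history resets at session boundaries; the first-visit
  exception only makes sense without carry-over.

The state space indexes all 13 (previous, current) pairs — the nine
arm×arm pairs plus (START, arm) and (START, START) — even though the
three diagonal (arm, arm) pairs are dynamically unreachable (revisiting
the current arm has probability exactly zero). `state_index` rejects
diagonal pairs unless explicitly asked, so table shapes match the model
definition while trajectories stay valid.

## Agent

Softmax-in-propensity actor with a TD(0) critic; see the README for the
equations. Numerical choices:

* Softmax is max-stabilized; propensities are clamped to |m| ≤ 500. The
  clamp never binds in fitted regimes; it only guards runaway parameter
  proposals during annealing.
* One learning rate α is shared by every update rule, and γ ∈ [0, 1)
  (the annealing bound is 0.9999).
* The last trial of a session is treated as terminal (successor value 0):
  sessions end on an external clock, so there is no learnable successor.
  Swapping this for bootstrapping into the would-be successor state
  changes the headline decay constants by under 2%.
* The neighbor-preference gradient uses the neighbor indicator of the
  *pre-choice* current arm: `Δbn1 = α·δ·Σ_a (χ(a=chosen) − p(a))·χ(a =
  a_t ± 1)`. At the center both outer arms are neighbors, so outbound
  trials contribute zero to `bn1` (the indicator covers the whole allowed
  set); `bn1` learns on inbound and session-start-adjacent structure.
* Exactly one uniform RNG draw is consumed per trial (the arm sample), so
  ensembles driven by the same seed vector stay aligned across parameter
  sets (common random numbers). Repeat `i` of an ensemble is seeded
  `base_seed + i` and is bit-identical to the corresponding single run.
* The inner loop is compiled with numba; the interpreted function is the
  readable reference, and the suite asserts bit-identical logs between
  the compiled kernel, the interpreted kernel, and a step-by-step
  composition of the public primitives (all scalar transcendentals go
  through libm to make this exact).

### Initialization

Initial conditions emulate the outer-arm preference animals bring into
the task: a single value is added to the propensity of going to arms 1
and 3 across all states (`b`), and, for variants with the independent arm
preference, to `bi(1)` and `bi(3)` as well; arm-2 entries, `bn1` and `V`
start at 0. The magnitude is calibrated so the *frozen-policy* (α = 0)
agent's expected center-arm share of the first ten visits is 0.1,
computed by exact forward propagation of the resulting Markov chain (with
learning off, the initial propensities are state-independent, so the walk
is a chain on the current arm). The frozen-policy definition makes the
calibration deterministic and independent of (α, γ); calibrated values
are ≈2.03 for `memory`/`memory+neighbor` and ≈1.02 for variants whose
arm preference doubles the effective bias — the enhanced models need a
lower per-component value for the same overt behavior. When fitting to a
target cohort's average behavior the magnitude is instead matched to the
target's initial reward rate (bisection on the frozen-policy ensemble's
mean reward over the first 25 visits); for individual-subject fits it is
a third free parameter.

## Behavioral metrics

* Reward curves: each trace's binary reward sequence is smoothed with a
  Gaussian kernel of SD 2.25 well visits (reflect padding; support
  truncated at 4 SD), then traces are averaged; spread is the SEM across
  traces. Smoothing is applied per trace *before* averaging.
* Error curves: per trace and trial type, the error indicator of that
  type's trials is smoothed with SD 2.25 in units of the type's own trial
  index, placed at those trials' well-visit positions, and linearly
  interpolated onto the well-visit axis (held constant outside the first
  and last trial of the type). Traces with fewer than 3 trials of a type
  are excluded with a warning.
* Exponential fits: nonlinear least squares of
  `y = offset + scale·exp(−t/τ)` over the first 300 visits for reward
  curves (the window that brackets the learning transient) and the full
  window for error curves. The 99% CI on τ is parametric (fit covariance,
  t critical value on residual degrees of freedom); a residual bootstrap
  is available behind `ci_method="bootstrap"`. Curves with no appreciable
  decay (|scale| ≈ 0, or τ far beyond the window) are flagged degenerate
  rather than reported. Two fits are called different (p < 0.01) only
  when each τ lies outside the other's 99% CI.

## Fitting

Distance-based point estimation (no posterior): a candidate (α, γ[, init])
is scored by a 200-repeat common-random-number ensemble against the
target — RMS on the reward curve, RMS(inbound) + RMS(outbound) with equal
weights on error curves, or negative mean total reward for reward
maximization — over the first 1012 well visits (the standard window all
synthetic subjects cover). Simulated session lengths are matched to
the target cohort's per-session counts. Minimization is restarted
simulated annealing (default ≥4 restarts): Gaussian proposals scaled to
the bound ranges, geometric cooling of both temperature and proposal
width (floored at 0.5% of the range so late proposals resolve the narrow
γ-near-1 valley), initial temperature set from the objective spread over
a few random probes divided by 10, and a short deterministic Nelder-Mead
polish of each restart's best point. Everything is seeded; the same spec
always returns the identical fit, and the best-of-restarts objective is
monotone in the number of restarts.

## Synthetic cohort

The generator produces the cohort structure the analyses assume: 10
subjects, 15 sessions, per-session lengths drawn uniformly from 64–72
visits (mimicking clock-limited sessions; any shortfall below 1012 total
visits is added to the final session so every subject covers the analysis
window). The rat-like default is the full-variant agent at α = 0.120,
γ = 0.997 with the calibrated initialization above. Generated cohorts
show the qualitative phenomenology the pipeline is built to measure:
strong initial outer-arm preference, reward probability rising over tens
of visits, inbound errors collapsing to near zero several times faster
than outbound errors decline toward their nonzero asymptote, and
session-start inbound-error bumps. Reference generators (perfect
alternator, uniform-random walker, scripted sequences) provide
hand-verifiable fixtures.

What the synthetic cohort does *not* emulate: inter-animal variability
beyond seed noise (no litter/cohort structure, no subject-specific
parameters), running speeds or inter-visit intervals, satiety or
within-day session-order effects, and any sensory/motor noise. Passing
tests therefore demonstrate internal consistency of the pipeline and the
model's qualitative error structure, not a quantitative match to any
particular animal dataset.

## Known limitations

* The exact notational form of the update rules is not pinned down by the
  model description alone; this package uses the canonical actor-critic REINFORCE forms
  (score function χ − p on every component, shared α). At the reference
  enhanced-model parameters (α = 0.120, γ = 0.997) this implementation
  learns with τ ≈ 59 visits rather than the reference value of ≈ 39.5 — across
  every initialization magnitude the minimum attainable is ≈ 45 — while
  reward-maximized memory-only learning (τ ≈ 54 vs 55.1), the
  inbound/outbound error-structure reversal, and the variant ordering all
  reproduce. The discrepancy is consistent with a ~1.6× difference in
  effective per-α update size relative to the original implementation
  and is reported as measured.
* At γ ≳ 0.9 the memory-only agent frequently converges to a stable
  1→2→3→1 cycling policy (reward 2/3, saturated softmax, self-consistent
  critic) — a genuine local optimum of actor-critic learning on this
  task. Reward maximization therefore selects low γ; the task pays on
  every correct visit, so it is learnable at γ ≈ 0.
* Sessions are defined by trial counts, not wall-clock time; continuous
  trajectories between wells are out of scope.
* Problem sizes used throughout (200-repeat ensembles, 15×68-trial runs,
  annealing budgets of 120–300 evaluations per restart in the test suite
  and 250 in the acceptance script, with the 2000-evaluation default for
  library users) were chosen as the smallest at which the reported
  quantities are stable across seeds.
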