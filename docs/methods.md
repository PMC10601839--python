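# Methods

## Plume model

The simulator is a particle (puff) model of odour dispersal in a
horizontally homogeneous wind, run at 100 iterations per second over a
12 m × 10 m arena with the source at the origin.  It reproduces the
short-timescale statistics that matter for tracking — intermittent whiffs,
rapidly fluctuating instantaneous concentration — together with a Gaussian
time-averaged cross-section, while remaining cheap enough to sit inside a
reinforcement-learning loop.

Per iteration (dt = 0.01 s):

- **Births.** The number of new puffs is Poisson with mean
  `birth_rate × birth_fold` (baseline 1.0/iteration).  New puffs start at
  the origin with radius r₀ = 0.01 m and concentration c₀ = 1 a.u.
- **Transport.** Every puff moves by `wind · dt`; non-centreline puffs get
  an additional crosswind displacement `v · dt` with v ~ 𝒩(0, 0.005 m/s)
  drawn independently per puff per iteration, applied perpendicular to the
  instantaneous wind.  Each puff therefore performs a biased random walk
  downwind.
- **Diffusion.** Radii grow at `r_δ × diffusion_fold` (baseline 0.01 m/s)
  and concentration is recomputed from mass conservation,
  c = c₀ (r₀/r)³, which holds to machine precision for every puff at every
  iteration.
- **Centreline.** One noiseless puff is emitted per iteration; its position
  is exactly the integral of the wind schedule, so the set of such puffs
  traces the plume spine.
- **Culling.** Puffs whose centre leaves the arena by more than their own
  radius are deleted.  This keeps memory bounded (~2,000 live puffs at the
  baseline) without affecting anything an in-arena agent can sense.

**Concentration sampling.**  The instantaneous concentration at a point is
the *sum* of c over all puffs covering the point (uniform-disc profile).
Superposition is the simplest rule consistent with intermittency of the
instantaneous signal; a max- or nearest-puff rule would discard overlap
structure near the source.

**Wind regimes.**  `constant` (0° throughout), `switch-once` (0° then +45°
at a configurable time placed a few seconds into the episode window),
`switch-many` (piecewise-constant; switch times form a renewal process with
exponential inter-event intervals of mean 3 s — the least-structured
reading of "random switches roughly every 3 s" — and increments are
Gaussian, sd 45°, truncated at ±60°), `sparse` (birth rate × 0.4) and
`sparser` (additionally diffusion × 0.5).  Angles are degrees anticlockwise
from +x; a 0° wind blows toward +x.

**Local centreline angle.**  The median orientation of centreline segments
whose x coordinate lies within ±2 cm of the query point, computed on
birth-ordered centreline puffs with one neighbouring puff included on each
side so that a single in-band puff still defines a segment.  An empty band
returns a nan sentinel and the caller skips that time step.

## Environment

The agent loop runs at 25 steps/s; each environment step advances the
plume four simulator iterations.  The observation is (w_X, w_Y, odour):
the ambient wind rotated by −Θ_HEAD into the agent's heading frame, and the
sampled concentration clipped to the sensing range — below 10⁻⁴ a.u. the
odour is imperceptible (reported as 0), above 1.0 it saturates.  Sensed
wind is ambient, not airspeed-relative: self-motion is not subtracted.

Actions are `turn ∈ [−1, 1]` (fraction of θ_max = 6.25π rad/s) and
`move ∈ [0, 1]` (fraction of Δ_max = 2.5 m/s; no backward flight).  The
heading updates first; the realized displacement is the commanded motion
along the *new* heading plus full wind advection, which is what makes
course direction differ from head direction.

Outcomes: **success** within the 0.2 m homing radius; **stray_fail** when
the distance to the nearest puff edge exceeds 2 m (an agent outside the
arena is also folded into stray_fail — the outcome set is deliberately
three-valued); **timeout** at 300 steps (12 s).

**Reward.** r = 100·1[success] + 1.0·(d_prev − d_now) − 0.05 −
2.0·max(0, stray − 1.5).  The coefficients are free choices exposed in
config; they respect the qualitative ordering the task needs (homing bonus
far above any per-step shaping, mild dense shaping toward the source, time
pressure, and a stray penalty that ramps up before the 2 m kill boundary).

**Initialization.**  Uniform over a downwind box x ∈ [1, 8] m with y inside
the nominal plume envelope (the radius a puff reaches at that x) plus a
0.5 m margin — "within or slightly outside" the plume.  The standardized
evaluation grid is the cartesian product of 15 locations × 2 initial plume
timestamps (25 s and 30 s of warm-up) × 8 evenly spaced head directions =
240 episodes per regime, with deterministic plume seeds per cell.

## Agents and training

Policies are actor–critic networks: a 64-unit vanilla RNN
(h_t = tanh(W_h h_{t−1} + W_x x_t + b)) or, as a fixed-memory control, a
feedforward network over the concatenated last K observations
(K ∈ {2, 4, 6, 8, 10, 12}), both feeding two-layer 64-wide tanh actor and
critic heads.  The recurrence matrix is initialized with normal entries of
sd 1/√64 (spectral radius ≈ 1); feedforward layers are orthogonal, with the
actor output layer scaled by 0.01.  The action distribution is a diagonal
Gaussian over pre-squash actions with a state-independent learned log-sd;
samples are squashed (tanh for turn, logistic for move) and the likelihood
is evaluated on the pre-squash sample.  Hidden state resets to zero at
episode start.

Training is PPO with the clipped surrogate (clip 0.2), GAE (γ = 0.99,
λ = 0.95), rollouts of 2048 steps, 10 epochs per rollout on the full
sequence with backpropagation-through-time truncated at the rollout
boundary, entropy coefficient 0.05, value coefficient 0.5, Adam at 3e-4
with linear decay, and global gradient-norm clipping at 0.5.  Default
budgets are 5M steps (recurrent) and 2M (feedforward).  Observations pass
through a running mean/variance normalizer updated during rollouts and
frozen at evaluation.  The whole stack — forward, BPTT, Adam — is plain
numpy; the architectures are small and fixed, so the gradients are written
out by hand and verified against finite differences in the test suite.

**Curriculum.**  Stage 1 uses near-source starts (x ∈ [0.4, 1.5] m, no
margin) in constant wind; stage 2 switches to full-range starts under
switch-many wind at a configurable fraction (default 0.5) of total steps.
Staged difficulty is the minimal curriculum that lets the sparse homing
reward be discovered before the harder regimes are introduced.

**Scaled study sizes.**  The training-dependent checks in the test suite
run one recurrent agent for ~49k environment steps under the stage-1
conditions and compare it against its untrained initialization on a shared
60-episode near-source grid with a paired binomial test.  This problem
size is the package's chosen desk-scale study: large enough for PPO to
reliably separate from the untrained baseline, small enough to keep the
full suite fast.  Full-budget runs (5M steps, 14 seeds, top-5 selection by
total successes) are reachable through the same `train`/`evaluate`/`select`
interfaces.

## Behavioural analysis

An odour *encounter* is the onset step of each contiguous perceptible run.
T_last counts steps since odour was last perceptible (not since the last
onset), running from episode start before first contact.  Modules:
tracking for T_last ≤ 12 steps (0.48 s, honouring the "under half a
second" gap that characterizes tracking), lost for T_last at or above a
per-agent threshold (defaults 30/25/35/38/25 steps for agents 1–5, mirrors
of thresholds chosen by visual inspection), recovering in between.

Course-direction statistics aggregate tracking-module steps from up to 60
random successful episodes per regime; switch-once data are trimmed to
post-switch steps.  Angles are wrapped to (−180°, 180°].  Kernel-density
estimation (Scott's rule) is presentation-layer only; all assertions are on
samples and quantiles.

## Neural analysis

The EWMA window convention is the span mapping α = 2/(w + 1), making w = 1
the identity smoother; the window scan regresses the 64-dimensional hidden
state onto the smoothed signal for each candidate window (grid 2–80 steps,
step 2) and reports in-sample R² — fit quality, not held-out prediction.
Head direction is regressed as (cos Θ, sin Θ) to avoid the wrap
discontinuity, reporting the mean R² of the two components.  PCA
dimensionality is the eigendecomposition of the centred covariance of
hidden states pooled across regimes.

The action classifier discretizes turn into 3 equal-width bins and move
into 2 (6 classes), uses an 80/20 split stratified on regime × outcome,
and a 20-trial three-fold cross-validated randomized search over
n_estimators ∈ [10, 50] for a random forest, refit on the full training
set.  Features are not standardized (tree ensembles are scale-invariant).
Permutation importance is the mean accuracy drop over 30 independent
within-column shuffles of the test set, with quartiles.

## Connectivity analysis

J^rec = diag(1 − tanh² z) W_h at an expansion point (h, x); at (0, 0) with
zero bias it equals W_h exactly.  Stable eigenvalues map to integration
timescales τ = |1/ln|λ||; eigenvalues within 10⁻⁶ of the unit circle are
flagged marginal and excluded (τ diverges there), unstable ones are counted
separately, and λ = 0 maps to τ = 0 by the limiting convention.  The
trajectory profile evaluates J^rec at (h_t, 0) — zero input, after
observation normalization — at every step of a pooled episode set
(intended: one successful and one unsuccessful episode from each of three
wind regimes), averages the rank-sorted timescales across steps, and
attaches a 99% normal-approximation confidence band.

## What the synthetic fixtures do and do not show

The scripted controllers (upwind surge, cast-and-surge, spiral, random)
generate trajectories with *known* structure through the real environment,
and the synthetic trace builder plants known functions of the behavioural
features (EWMAs, T_last, heading) into a 64-unit state at a chosen
signal-to-noise ratio.  Tests built on them demonstrate that the analysis
code recovers planted structure (windows to ±1 step, importance rankings,
module labels) — they do not show that *trained* networks represent those
variables; that claim is only reachable by running the full training and
analysis pipeline.

## Numerical notes and limitations

- Degenerate inputs: zero displacement gives an undefined (nan) course
  direction and such steps are skipped; empty centreline bands return a
  sentinel; constant regression targets report nan R²; a class missing from
  the classifier training split raises rather than silently degrading.
- Random streams (puff births, crosswind noise, wind switches, agent
  initialization, action sampling) are independently seeded sub-streams of
  one master seed, so each process is reproducible in isolation.
- The plume model does not capture filamentous fine structure or the
  dependence of whiff-duration statistics on source distance; plumes and
  kinematics are two-dimensional; there is no inertia, sensor noise, or
  biomechanics.
- Whether the original sensed wind included self-motion, the exact reward
  magnitudes, curriculum details, action-distribution family, EWMA decay
  convention and normalization scheme are all open design points; the
  choices above are this package's own and are recorded in config and run
  manifests.
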