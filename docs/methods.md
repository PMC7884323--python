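# Methods

`swingsim` is a desk-scale, fully closed-loop re-creation of a robot-assisted
motor-training experiment: a participant holds a robot end-effector that
haptically renders a planar pendulum, swings the pendulum ball to hit targets
arriving every second, and may be helped by one of three robotic assistance
strategies.  Everything runs offline and deterministically; human subjects
are replaced by tunable synthetic surrogates.  This note records the models,
the numerical choices, and what the simulator can and cannot say about the
original human experiment.

## Rendered pendulum and coupled hand model

The virtual pendulum is a point ball (mass `m = 0.6 kg`) on a massless rigid
rod (`l = 0.25 m`) under reduced gravity (`g = 9.81/3 m/s²`, chosen so the
swing tempo suits a desk workspace) and almost no rotational damping
(`c = 3e-6 N·m·s/rad`, low enough that the pendulum never settles by
itself).  The internal angle θ is measured counter-clockwise from straight
down and is never wrapped, so spectral analysis sees a continuous signal.
The small-oscillation natural frequency is `sqrt(g/l)/(2π) ≈ 0.576 Hz`
(colloquially "0.57 Hz").

The swing obeys

    θ̈ = −(1/l)((z̈ + g) sin θ + ÿ cos θ) − c/(m l²) θ̇ + F_b cos θ/(m l)

where (ÿ, z̈) is the pivot (end-effector) acceleration and `F_b` an optional
horizontal force applied directly at the ball (zero for the plain rendered
pendulum).  The rod force rendered to the hand is the tension

    F_rod = m((z̈ + g) cos θ − ÿ sin θ + θ̇² l) + F_b sin θ

acting on the pivot along the pivot→ball direction `(sin θ, −cos θ)`.

The original apparatus treated pivot motion as human-commanded; a closed
loop needs pivot dynamics, so the hand + end-effector is modelled as an
admittance — apparent mass `m_ee = 0.3 kg` and viscous damping
`b_ee = 2 N·s/m` per axis (both configurable; no published value exists for
the apparent inertia of the device-plus-hand).  The rod tension couples
pivot and swing, giving the classic cart-pendulum inertia coupling; the two
pivot accelerations come from a 2×2 linear solve each step.  With damping
removed the combined system conserves energy, which the tests verify.

Integration is fixed-step RK4 at `dt = 1 ms` with forces held constant over
a step (zero-order hold between controller updates).  Determinism is exact:
identical inputs give bit-identical trajectories.  Degenerate modes used for
verification: a clamped pivot (`m_ee = inf`) isolates the free swing, and
`m = 0` removes the pendulum to expose the bare pivot admittance.

## Task and scores

Targets arrive every 1 s at one of three lateral slots (0, ±12 cm) with
Gaussian jitter (σ = 1.25 cm, untruncated; slots drawn uniformly).  The hit
score is `max(0, 100 − miss_mm · 0.5)` with the lateral ball position
linearly interpolated at the exact impact time.  The transfer task asks the
participant to invert the pendulum; its score integrates `k · z_diff`
(k = 1 by default) over the time the ball is above the pivot and is retained
between inversions.

## Assistance strategies

All three strategies act only laterally (no vertical assistance — it would
mask the perceived ball weight while mostly supporting arm weight) and share
one trajectory-optimization core: minimize, over a horizon from "now" to the
current target's impact,

    Σ_k  w_d(τ_k) d_k² + w_s v_k² + w_F(τ_k) F_k²

where `d_k` is the lateral ball-to-target distance, `v_k` the ball linear
speed, `F_k` the assist force, and `τ_k` the remaining time to impact.  Both
weights are scheduled along the horizon: the force weight falls linearly
with τ (assistance is cheap just before impact, expensive when the wall is
far — maximizing the participant's freedom early in each approach), and the
distance weight rises quadratically as impact approaches (accuracy is only
meaningful at the moment of impact; pricing mid-approach distance too
heavily pushed the optimizer into degenerate "whip" solutions that spin the
pendulum).  Defaults: `w_dist = 60 m⁻²`, `w_speed = 0.5 s²/m²`,
`w_force_base = 4e-3 N⁻²`.  The speed term is what keeps planned swings
stable; with it weakened the optimizer discovers physically valid but
inhuman full-rotation trick shots.

The solver is a projected Levenberg–Marquardt iteration on a direct
single-shooting parameterization (decision variables: one force per 25 ms
grid step, grid stretched to land exactly on the impact time, at most 40
steps).  The Jacobian is finite-difference, computed inside a compiled
kernel; damping adapts by the usual accept/reject rule; forces are clipped
to the box limit after each update; the iteration budget is fixed (20
iterations for the first solve of a target, 5 for warm-started replans) so
the controller is deterministic and never raises mid-episode.  A 1e-9
regularizer keeps the normal equations well posed when the force weight
vanishes at impact.  The planner's internal model of the human is a passive
admittance (zero future hand force): robustness comes from replanning at
80 Hz, not from predicting the participant.

* **End-effector MPC (eeMPC)** applies the first-interval force at the
  pivot, clamped to 8 N — calibrated so that a fully passive participant is
  guided to within a centimetre of every target (observed: ~2 mm).
* **Ball MPC** applies its force directly at the ball, clamped to 1 N (the
  planned force is what is limited).  The ball force also loads the pivot
  through the rod (`F_b sin θ` along the rod), so the participant feels a
  projection of it.
* **Haptic guidance (HG)** runs the same optimization once per target (at
  the previous impact), fits a cubic B-spline through the optimal
  end-effector path, and tracks it with a PD controller
  (P = 100 N/m per kg, D = 20 N·s/m per kg, scaled by the 0.6 kg pendulum
  mass → 60 N/m and 12 N·s/m), clamped to 8 N.  The trajectory is frozen:
  later state changes never alter it.  If the optimization fails the
  fallback is a straight line to a point above the target, flagged.

A single-plan optimum deliberately leaves a millimetre-scale terminal miss
(the speed penalty prices the final correction); closed-loop replanning at
80 Hz grinds this down further.

## Synthetic participants

Surrogates exist to exercise the controllers across skill levels; they are
explicitly *not* models of human learning — skill is constant within a
session, so training-induced improvement is out of scope by design.  A
surrogate:

* plans an intended end-effector path per target with the same trajectory
  optimizer, but on an internal pendulum model whose rod length and gravity
  are each biased by a fixed, per-participant random fraction up to
  ±30 %·(1 − skill), and with a human-scale effort cap (25 N);
* tracks the intent with a hand PD controller (defaults 400 N/m, 40 N·s/m)
  on a reference delayed by `reaction_delay` (default 120 ms), plus Gaussian
  motor noise held at 20 Hz (band-limited, roughly matching physiological
  force fluctuations) whose amplitude scales with the tracking drive
  (signal-dependent noise);
* re-plans its intent from the actual state whenever the tracking error
  exceeds 12 cm — people correct after a gross error rather than chasing a
  stale intention; without this the delay occasionally produced windup
  spirals no human would sustain;
* modulates lateral effort under assistance by
  `1 − slack_gain·min(1, |F_cmd|/limit) + stiffen_gain·min(1, |F_hand|/limit)`:
  the first term is slacking (effort reduction when the robot is seen to do
  the work, wherever its force acts), the second is impedance up-regulation
  against forces actually felt at the hand (people stiffen when pushed
  around).  Ball-applied assistance is barely felt at the hand, so it
  slackens without stiffening — this asymmetry is what lets the simulator
  reproduce the observed rise of interaction forces under hand-applied
  assistance and their fall under ball-applied assistance;
* always stabilises the vertical axis with an un-slacked PD about a home
  height (the arm rests on a table).

Presets: `passive` (no voluntary lateral effort), `novice` (skill 0.5,
noise 0.8 N, slack 0.5, stiffen 0.6 — the default mid-skill study
surrogate), `skilled`, and `ideal` (perfect model, no noise or delay; used
as an upper bound, scoring > 95 unassisted).  During transfer tests the
surrogate switches to a standard energy-pumping swing-up law with a
workspace-centering PD, with pumping gain scaled by skill.

## Protocol

A session is: baseline (40 targets) → transfer baseline (60 s) → 32
training blocks of 20 targets with 8 catch blocks (assistance silently off)
pseudo-randomly placed, exactly half before the mid-session break → washout
(20) → short-term retention (40) → transfer → long-term retention (40) →
transfer.  Baseline and both retention tests reuse one layout built by
repeating the catch-block layout twice, so those four block types share
identical target orders; training layouts differ between blocks but are
identical across simulated participants.  Catch placement depends only on
its own seed; all schedule content derives from configuration seeds, never
from simulation outcomes.  The study's 1–3-day gap before long-term
retention has no simulated analogue (surrogates do not learn or forget);
the block is an immediate re-test and labelled as such.  The break is a
no-op marker.

## Metrics

Per block: mean and standard deviation (population, n-convention) of the
per-target scores; the percentage of the θ spectrum's power within
±0.05 Hz of the natural frequency; standard deviations of the end-effector
lateral position and of θ over the whole block; mean |assist force|; and
mean |interaction force|.  The band half-width equals the DFT bin width of
the shortest (20 s) block.  The spectral estimator is a Hann-window
periodogram of the mean-removed angle with inclusive band edges: with a
rectangular window, an oscillation falling between DFT bins leaks so much
power out of a ±1-bin band that the fraction loses its meaning; the Hann
window keeps the leakage of near-band components concentrated while leaving
the Parseval partition property intact (complementary bands still sum to
100 %).

The interaction force is estimated with a first-order disturbance observer
on the lateral admittance — the simulation-side analogue of a joint-level
reaction-torque observer, which would need robot-joint dynamics that are
out of scope: `F̂ = LPF(m_ee ÿ + b_ee ẏ − F_rod,y − F_assist,ee)` with ÿ
differenced from the logged velocity and a causal second-order Butterworth
low-pass at 20 Hz.  In simulation the true hand force is logged, and the
observer is validated against it (< 5 % RMS error after the filter
transient).

## What passing tests do and do not show

The surrogates reproduce the *qualitative* signature of the original
human-subject contrasts when assistance is toggled mid-training — score up
in every assisted group, mean assist-force ordering HG > eeMPC > ballMPC,
interaction forces up under hand-applied assistance and down under ball
assistance, score variability suppressed most by ball assistance — as
orderings and signs over 20 seeded episodes, never as magnitudes.  They say
nothing about human learning, retention differences between strategies,
motivation, or sense of agency; surrogate skill is fixed, real humans
adapt.  Within-session learning curves, questionnaires and inferential
statistics are deliberately absent; the metrics tables are written so
standard statistics packages can consume them.

## Problem sizes and determinism

Tests simulate 20-target (20 s) blocks; the qualitative-contrast battery
runs 3 strategies × ON/OFF × 20 seeds of such blocks.  A full default
session (~16 minutes of simulated time) runs in roughly one to two minutes
on one core, with the compiled kernels doing the 1 kHz integration and the
re-planning at 80 Hz.  All randomness (target layouts, catch placement,
motor noise, participant model bias) flows from named integer seeds through
`numpy` seed sequences; repeated runs are bit-identical.
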