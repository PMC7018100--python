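# Methods

## Model

The circuit has three stages, all integrated jointly at dt = 0.5 ms by
forward Euler–Maruyama.

**Sensorimotor stage.** Two populations selective for leftward and
rightward motion are summarised by NMDA gating variables S_L, S_R in
[0, 1], with self-excitation (J_N,ii = 0.248 nA), cross-inhibition
(J_N,ij = 0.0497 nA), tonic input (I_0 = 0.3255 nA) and the standard
sigmoid-linear transfer H(x) = G_S(ax − b)/(1 − e^{−d(ax−b)}) (a = 270
(V nC)⁻¹, b = 108 Hz, d = 0.154 s, gain G_S = 1.12). The removable
singularity of H at ax = b is evaluated analytically (limit G_S/d) and
both exponential branches are handled asymptotically, so H is globally
continuous, strictly increasing and overflow-free. The stimulus
contributes J_A,ext μ_0 (1 ± c) for 0 ≤ t < 800 ms. Unit bookkeeping is
concentrated in a single helper: rates are Hz, currents nA, time ms,
and the γH product in the gating kinetics is converted Hz → per-ms in
exactly one place.

**Uncertainty monitor.** One population, y_HU, drives both sensorimotor
inputs with current J_mc0·y_HU and integrates
[J_VHU(H_L + H_R) − g]₊ with τ_mc = 150 ms. The gate schedule: g = 1000
nA from trial start (monitoring suppressed), g = 0 from 600 ms after
stimulus onset (monitoring active), g = 3000 nA from the moment either
sensorimotor rate reaches S_th = 42.5 Hz (monitoring halted; the
published description of this schedule is truncated mid-sentence, and
this reading — suppressed, open at 600 ms, re-suppressed at decision —
is the one consistent with the surrounding text and with the phasic
uncertainty transients it produces).

**Motor stage.** Two threshold-linear hand populations with mutual
inhibition (J_N,LR = J_N,RL = 1 nA, τ_h = 50 ms) form a line-attractor
race. They are suppressed by g_hand = 1000 nA until the decision (any
suppression exceeding the maximal feasible drive is equivalent) and
released at the S_th crossing. The rate difference maps to cursor
position x = (|C_pos|/H_th)(y_HL − y_HR) with C_pos = 760 px and
H_th = 17.4 Hz, so the cursor reaches a choice target when the
difference reaches 17.4 Hz.

## Trial classification

* **Response time** is the first S_th crossing, reported relative to
  stimulus offset (800 ms); it is negative when the threshold is
  crossed during the stimulus.
* **Change-of-mind**: dominance episodes are maximal intervals with
  |y_HL − y_HR| > 2 Hz; the reversal count is the number of sign
  alternations between successive episodes. Trials with more than one
  reversal are flagged and excluded from CoM analyses, mirroring the
  experimental exclusion of multi-change trials.
* **Non-decision**: a trial with no completed response by t_max — the
  decision threshold was never crossed, or the motor race never
  resolved to a choice target. With the calibrated parameters the
  uncertainty feedback loop makes the 42.5 Hz crossing essentially
  certain, so in practice non-decisions are symmetric "indecision"
  trials whose hand race never separates by 17.4 Hz. This reading of
  "target threshold not reached" is the only one that yields a nonzero
  non-decision rate in this regime.
* **Choice** at the hand-target crossing (or, for decided trials that
  time out mid-race, the currently dominant side; an exact tie is
  broken by one logged RNG draw).

## Parameters left open by the published description

* **γ = 0.641**: the gating kinetic constant of the parent two-variable
  model, from which the sensorimotor equations are taken unchanged.
* **Noise**: the integration scheme implies a stochastic term but its
  form and amplitude are unprinted. Independent Ornstein–Uhlenbeck
  currents (τ_noise = 2 ms, the fast-synaptic value of the parent
  model) are added to each sensorimotor input; the stationary s.d.
  σ_noise is the model's single calibration knob. σ_noise = 0.017 nA is
  the packaged default: at that value the simulated non-decision rate
  is 3.3–3.5% against the published 3.4% (three master seeds, 12,000
  trials each) and the uncertainty–RT correlation is 0.96 against the
  published 0.95. The calibrated value is recorded in every run
  manifest.
* **t_max = 4000 ms**: long enough that non-decisions are rare but
  nonzero; configurable.
* **Cursor sign convention**: positive x toward the left target,
  following the y_HL − y_HR ordering of the mapping; presentational
  only.

## Stability analysis

The two-variable subsystem is analysed with J_mc0·y_HU replaced by a
constant feedback current, noise off and stimulus off. The stimulus-off
choice is deliberate: the feedback transient does its work late in the
trial, after stimulus offset, and only in this regime does the fold sit
at the published ≈ 0.03 nA (with the stimulus current included it moves
to ≈ 0.017 nA). Fixed points are found by seeding a Newton-hybrid root
finder from every cell of a 200×200 grid on which both drift components
change sign, deduplicating, validating a 1e−10 residual bound, and
classifying stability by central-difference Jacobian eigenvalues. The
critical feedback is located by bisection on the predicate "more than
one stable fixed point". At zero feedback the system also has a
low-activity spontaneous state below the decision branches; assertions
are restricted to the decision-state structure (two stable asymmetric
states merging away, one stable symmetric state remaining).

## Random numbers and reproducibility

A master seed expands to per-trial streams via counter-based seed
sequences keyed by (condition index, trial index), so each trial's
noise is independent of how many trials run beside it and batches of
any size reproduce bit-for-bit. Noise-off runs are deterministic and
seed-independent. The vectorized batch kernel and the single-trial
integrator share the same stepping rule; tests pin the kernel to a
literal scalar transcription of the equations at 1e−12.

## Synthetic cursor trajectories

The generator emulates the mouse-tracking setup (1920×1080 screen,
start button bottom-centre, targets in the top corners at ±760 px from
the centre line, 60 Hz sampling during the stimulus and 100 Hz after)
with minimum-jerk reaches between via-points: straight reaches, single
and double changes-of-mind (excursions ≥ 220 px past the centre line),
pre-offset movement starts, and sub-100-px tremor. The ground-truth
onset is defined analytically as the first sampled interval of the
reach whose speed reaches the stationarity threshold. What it does
*not* emulate: curved human reach variability, velocity-profile
asymmetries, pauses mid-reach, drift, or device quantisation — so
detector tests on these fixtures validate the rule implementations
(thresholds, band exclusion, segmentation, alternation counting), not
detector performance on real recordings.

Detector conventions where the published rules are silent: movement
segments are delimited by samples slower than 0.05 px/ms sustained for
≥ 50 ms (both configurable); the response area spans from the target
row to the start button, with the bottom 10% of that vertical extent
(screen coordinates, y downward) as the exclusion band; repeated
same-side excursions count once, alternating ones accumulate.

## Analysis conventions

Tertiles are the empirical 1/3 and 2/3 quantiles over decided trials —
pooled across coherences by default, optionally within-coherence (both
exposed; the within-coherence variant matches per-coherence panel
layouts). Uncertainty tertiles are computed on min–max-normalised peak
uncertainty. Summary curves report mean, sample s.d./√n and n. The
uncertainty–RT correlation discards zero-uncertainty trials (decisions
reached before the monitoring gate opened).

## Problem sizes

The packaged analyses use 6,000 trials per coherence condition (36,000
trials, ~30 s vectorized); the test suite exercises the same pipeline
at 600 trials per condition, and the bifurcation tests use 150–200
point seed grids. These sizes are the package's defaults and are all
configurable.

## Known limitations

* Decision times concentrate within a few tens of ms after the
  monitoring gate opens, because the calibrated feedback loop is
  strongly supercritical; response-time variance is correspondingly
  small. Relatedly, a small minority (~10%) of simulated CoM trials
  fall just below the top within-condition response-time tertile —
  the qualitative RT–CoM association is strong but not absolute under
  this noise model.
* The experimental mixed-effects regressions and binomial tests on the
  original behavioural dataset are out of scope; the analysis module
  emits tidy tables suitable for external statistical software.
* The uncertainty monitor is a single population; no
  excitatory–inhibitory column structure is modelled.
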