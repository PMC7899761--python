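# Methods

## The fatigue metric

Fatigue is defined as any reduction in the maximal capacity to generate
force. The package quantifies it with the Maximum Force Loss under static
contraction,

    MFL = (MVC_i - MVC_t) / (MVC_i - MVC_f),

where `MVC_i` is the initial maximal voluntary contraction, `MVC_t` the
maximal force measured at a later probe, and `MVC_f` the required (target)
force of the task. The ratio is 0 when the muscle is fresh and 1 when the
maximal force has fallen to the required level (the subject can no longer
exceed the task demand — exhaustion). A simpler normalised form
`(MVC_i - MVC_t)/MVC_i` is provided as `mfl_basic` but the static-contraction
form is the operative metric throughout, because only it has the [0, 1]
exhaustion-anchored range.

Two boundary conventions matter in practice:

* **Clipping.** Measurement noise (and probes taken past exhaustion) can push
  the raw ratio outside [0, 1]. `mfl_static` clips by default and logs clip
  counts, matching the metric's defined range. For *slope fitting*, however,
  clipped values would bias the rate estimate downward — at the fastest
  fatigue rate a session yields only two MVC probes, one of them past
  saturation — so the fitting helpers (`fit_session_gradient`,
  `anchor_mfl(clip=False)`) use the raw ratio. Fatigue continues to grow past
  the nominal exhaustion point; the unclipped ratio is the right regressand.
* **Assignment.** Per-window MFL is piecewise-linear interpolation between
  MVC-probe anchors (MFL grows linearly during sustained contraction, which
  the simulated and fitted trajectories confirm), constant 0 before the first
  anchor and held constant after the last.

The across-level model `MFL = a*exp(b*level)*t + c` captures the nonlinear
growth of the per-level linear rate with target force level. The fit is joint
nonlinear least squares over all levels; because the model is exactly
log-linear in the per-level slopes, the start point comes from regressing
`log(slope)` on level, with bounds `a > 0`, `c in [-0.1, 0.1]`. Convergence
failure raises with diagnostics; it is never silently defaulted.

## The synthetic session generator

No public recordings exist for this protocol, so the generator is a
first-class, tested component that emulates the experiment end to end on a
compressed clock (rest periods carry no signal and are removed; session time
*is* active-contraction time, so ground-truth MFL(t) = min(1, gradient·t)).

One session at target level `x` of `MVC_i` (default 500 N; levels 0.5/0.6/0.7
with per-level fatigue rates 0.0077, 0.0108, 0.0532 MFL/s): a 5 s initial MVC
probe, then loops of a 10 s steady hold at `x·MVC_i` followed by a 5 s MVC
probe, until a measured probe falls below `MVC_f = x·MVC_i`. The achievable
maximum force is `MVC_i - MFL·(MVC_i - MVC_f)`; MVC probes measure the
*unclipped* linear decline plus Gaussian noise (default sd 2 N), so a subject
past exhaustion genuinely fails the required force and the termination rule
is well-posed even without noise. Force is tracked at 100 Hz with Gaussian
tremor (default sd 3 N, floored at 0 N).

sEMG (1000 Hz, one channel per muscle: palmaris longus, flexor carpi
ulnaris, extensor digitorum) is synthesised per ~1 s stationary block as
Gaussian noise with a Gaussian-bump power spectrum:

* expected RMS = `gain · activation · (1 + alpha·MFL)` — enforced *exactly*
  by rescaling before baseline noise (RMS floor 0.01) is added;
* spectral mean = `center_freq · (1 - beta·MFL)`, bump width a quarter of the
  centre so the periodogram mean frequency hits the target to well under 1%.

Defaults `alpha = 0.8` (RMS nearly doubles at exhaustion) and `beta = 0.3`
(30% MNF decline) reflect the reported magnitude of amplitude and spectral
fatigue effects in forearm sEMG. During MVC probes the drive is maximal
(activation 1); during steady holds the drive rises with fatigue,
`activation = target force / remaining capacity`.

**Synergy weighting.** With purely capacity-relative drive, every session's
activation converges to 1 at exhaustion, making the force level *information-
theoretically unrecoverable* from (RMS, MFL) near exhaustion — an artefact of
an overly symmetric model, not of real muscle, where the balance of activity
across synergists shifts with absolute grasp force. Each channel therefore
carries a synergy exponent `level_exp` (defaults 0, 1, 2 across the three
muscles): during steady holds its drive share scales as
`(target_level/0.75)**level_exp`. The 0.75 reference keeps all factors <= 1
for protocol levels below 75%. These defaults were calibrated once so that
per-subject best R^2 lands in the realistic 0.6–0.95 band with the expected
method ordering; they are not revisited per experiment.

Cohorts draw one multiplicative jitter factor per subject (default 10%
relative sd, floored at 0.2) on channel gain/alpha/beta and on the per-level
fatigue rates, then simulate one session per level.

What the generator does **not** emulate: motor-unit action-potential
structure, recruitment/firing-rate dynamics, electrode shift, sweating,
crosstalk, movement artefacts, or day-to-day variability. Passing tests
therefore show that the pipeline recovers what this phenomenological model
encodes — not that the estimation accuracy transfers to any particular real
recording.

## Signal conditioning and features

Band-pass 20–450 Hz (order-4 Butterworth) plus a 50 Hz IIR notch (quality
factor 30), both zero-phase (forward–backward) since the pipeline is offline.
The emulated hardware band is 20–500 Hz, but 500 Hz is Nyquist at 1000 Hz
sampling, so the digital upper edge is 450 Hz (>99% of typical sEMG power).

Windows are 300 ms long with a 100 ms shift, half-open `[k·S, k·S + W)`,
trailing partial windows discarded: `floor((L - W)/S) + 1` windows. Per
window and channel: RMS, ARV, MNF (power-weighted mean of the single-taper
periodogram of the mean-detrended, untapered window — the window is too
short to subdivide, and a rectangular taper keeps RMS/ARV exact), and
MNF/ARV. The force target is the mean of the force samples in the same
interval (30 samples at 100 Hz). Degenerate windows (zero power or zero ARV)
yield NaN and are dropped with a logged count, never zero-filled.

## Estimation protocol

Design matrices: TMLM = RMS per channel (width 3); CMLM = RMS + MNF/ARV
(width 6); FMLM = RMS + assigned MFL (width 4). Inputs and target are
min-max scaled to [0, 1] on the *training folds only* (zero-range columns map
to 0; test values are not clipped), and predictions are inverse-mapped to
newtons before scoring, so R^2 is always on the physical scale.

The regressor is a single-hidden-layer feed-forward network with log-sigmoid
hidden units and linear output (bounded output adds nothing once the target
is scaled, and a linear head trains more stably). Training is full-batch
L-BFGS on the backpropagated gradient (scikit-learn `MLPRegressor`), at most
500 iterations, tolerance 1e-6; non-convergence is flagged, not raised.
L-BFGS was chosen over stochastic first-order updates for determinism and
speed on these small networks.

Cross-validation uses *blocked* folds: each session's windows are split into
`k` contiguous time blocks and fold `j` tests on block `j` of every session.
Adjacent 300 ms windows overlap by 200 ms, so random shuffling would leak
test information into training; contiguous blocks avoid that (and make the
task honestly harder). Training rows come from steady-hold windows only —
MVC-probe windows anchor the fatigue label, and training on them would leak
it into the force target. The node sweep covers 2–20 hidden units by
default, each retrained (default 10 times) per fold with fresh seeds;
"mean ± sd" pools all retrain×fold R^2 values per node, and the best node
maximises the pooled mean. All randomness descends from one root seed via
`SeedSequence` spawning.

Comparisons pair per-subject (or per-fold) best-node R^2 values: percent
increase `(R2_b - R2_a)/R2_a · 100` between means (undefined for a
non-positive baseline), and two-sided paired t-tests at alpha 0.05 (a
zero-difference pair vector short-circuits to t = 0, p = 1 rather than the
0/0 form).

## Problem sizes

Default cohort experiments use 3 subjects, three sessions each (the
50/60/70% levels with their per-level fatigue rates, giving roughly 90, 60
and 20 s of steady contraction per session and ~1500–1700 pooled windows per
subject), a reduced node sweep {4, 5, 10} and 3 retrains for the replicated
ordering experiment. These sizes are the package's default study conditions;
the full 2–20 sweep with 10 retrains is available through the config and CLI.

## Known limitations

* The generator's fatigue trajectory is exactly linear in active time; real
  trajectories are only approximately so, and the assignment rule inherits
  the linearity assumption between anchors.
* Near exhaustion the force level is encoded only through the synergy
  weighting; the difficulty of that region is controlled by `level_exp`
  rather than measured from data.
* Absolute R^2 values depend on generator noise settings and are not
  comparable to any specific real recording; only identities, recovery of
  injected parameters, and the qualitative method ordering are claims the
  tests support.
* The per-window spectral estimate on 300 ms windows has ~3.3 Hz resolution;
  MNF-based features inherit that granularity.
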