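# Methods

## The measurement problem

An anticipatory postural adjustment (APA) is the force the support leg
produces *before* a voluntary movement of the other leg, stabilizing the
body against the coming perturbation. The toolkit models two versions of
the same behavior:

- **Upright step initiation.** The subject stands on a force platform and
  steps with the right foot on a go cue. The APA appears as a biphasic
  medio-lateral force deflection (F_ml) beginning a few hundred
  milliseconds before foot-off; foot-off itself is read from an ankle
  marker's antero-posterior displacement.
- **Supine leg raise (in-scanner).** The subject lies in the scanner with
  one heel on each force sensor and raises the right leg to a restraining
  bar on the go cue. The APA appears as loading of the left (support)
  sensor before the right sensor loses its load at lift.

In both tasks an external support (walker / knee pad) removes the need for
the APA; the supported condition therefore acts as a within-subject control
with roughly half the APA amplitude.

## Paradigm model

Each trial is a cross (relax), a prepare circle and a go circle. Durations
are drawn from finite grids: prepare ∈ {1.0, 1.5, …, 3.0} s, inter-stimulus
interval ∈ {5.5, 6.0, …, 8.5} s. A "Poisson-distributed duration" on a
bounded grid is formalized here as a Poisson(λ) index truncated and
renormalized to the grid, i.e. `duration = min + step·j` with
`j ~ Poisson(λ) | j ≤ k`. λ defaults to 1.5, which concentrates mass on the
short durations while covering the whole grid; any λ > 0 preserves the
printed ranges, and the value is configurable. The go stimulus is
*scheduled* at its 5 s maximum; its realized duration is an
acquisition-time outcome (it ends at the relax command), so the schedule
and the execution are kept separate. Cue assignment (which circle means
"prepare") and condition order are counterbalanced by an even split over a
seeded shuffle, the odd subject going to the first group.

## Trial simulator

The simulator is the package's substitute for recordings that cannot be
redistributed; it generates the *shape* of the signals the analysis relies
on, with ground truth for every trial.

Supine channels (32 Hz): the left force is
`baseline + A·s(t; onset, rise)·(1 − release)` where `s` is a smoothstep
(C¹, exactly 0 before the onset and exactly 1 after `rise = 3·ramp_tau`),
the APA onset is the go cue plus a uniform 150–400 ms reaction-time jitter,
and the release returns the trace to baseline after the relax command. The
right force drops by `lift_drop_fraction` at lift onset
(= APA onset + `apa_lead`); the touch channel fires when the foot reaches
the bar. Step-task channels: F_ml is a toward-then-away pair of sine lobes
(full amplitude, then half-amplitude opposite) starting at the APA onset,
synthesized at 1000 Hz with white sensor noise and band-limited by a
zero-phase 4th-order Butterworth at 100 Hz to emulate the platform's analog
filter; the marker follows a smoothstep of amplitude `marker_excursion`
from the step onset, sampled at 200 Hz.

Default parameters (units, rationale):

| parameter | default | why |
|---|---|---|
| supine baselines | 40 N per heel | supine heels bear roughly leg weight |
| supine APA amplitude | 36 N | equals the load released by the lifted leg (0.9 × 40 N), keeping the generator's force budget consistent |
| lift drop fraction | 0.9 | the lifted heel keeps only strap/skin contact |
| supine sensor noise | 0.2 N RMS | strain-gauge class noise at 32 Hz |
| F_ml amplitude | 20 N | typical young-adult medio-lateral APA on a lab platform |
| platform force noise | 0.1 N RMS | research-grade platform noise floor |
| APA lead (both tasks) | 250 ms | standard APA-to-movement interval |
| marker excursion | 300 mm | ankle AP travel of a normal first step |
| marker noise | 0.2 mm | optical motion-capture jitter |
| suppression factor | 0.5 | supported APAs run at about half the unsupported amplitude |
| reaction latency | U(150, 400) ms | plausible cue-to-onset jitter; a free simulator parameter |

What the generator does **not** emulate: postural sway and drift, muscle
tremor (relevant for Parkinsonian cohorts), trial-to-trial amplitude
variability beyond noise, failed or hesitated steps, sensor nonlinearity
and drift, and any coupling between head motion and leg forces. Passing
parameter-recovery tests therefore shows the detection chain is correct and
unbiased *for signals of this shape at these noise levels*, not that the
thresholds are optimal for clinical recordings.

## Online trigger

The acquisition loop calibrates the moving-leg force over the relax phase
(mean m, SD s) and triggers at the first sample after the go cue with value
below `m − 20·s`; the relax command follows 500 ms later. Two numerical
guards: the calibration window must hold at least 5 samples, and s is
floored at 0.5% of |m| — with noiseless input s = 0 would make the
threshold unreachable, while real sensors always carry noise; the floor
makes the degenerate case explicit and testable. The online sample-by-sample
loop and an independent vectorized full-trace scan must agree exactly; this
equivalence is asserted over a thousand simulated trials.

## Onset detection and quantification

Onsets are threshold crossings relative to the baseline window, which
defaults to the instructed relax phase (cross onset → prepare onset), the
only quiescent epoch the paradigm defines. The detection (movement) window
starts at the **go cue**: no response can precede the imperative stimulus,
and scanning earlier epochs only adds false crossings. A crossing counts
when the signal stays beyond mean ± 2·SD for a debounce run: 2 samples
(62 ms) at 32 Hz, and at least 10 ms of samples for high-rate signals. The
debounce values follow from the noise model — a single Gaussian sample
exceeds 2 SD with probability ≈ 2.3%, so a 1-sample rule false-triggers in
a sizeable fraction of trials at any rate, and at 1000 Hz the 100 Hz-filtered
noise is correlated across neighboring samples, so a run shorter than the
filter's correlation time would not reject it. Because genuine onsets keep
rising once they cross, the debounce does not bias the detected onset time.

Step amplitude is the peak |F_ml − baseline mean| inside
[APA onset, step onset], normalized by foot length (N/cm) — peak deviation
is the standard APA amplitude convention. Scanner magnitude is the
trapezoidal integral of the raw (not baseline-subtracted) left force over
the APA interval divided by its integral over the movement window, × 100.
Integrals interpolate the window edges, so sub-interval ratios are exact
(a constant trace over 10% of the window gives exactly 10%), the value is
bounded in [0, 100] for nonnegative traces, and it is invariant under
positive rescaling of the force. Trials where either onset is missing, or
ordered inconsistently, are returned flagged invalid with a reason — never
silently dropped.

## Head-motion QC

Per-volume displacement is the Euclidean norm of the three translations
relative to a reference volume (first by default; middle available).
Rotations are reported but excluded from the criterion. A run passes when
the maximum displacement is below 1 mm. Frame-to-frame displacement is also
available, since summary statistics in the literature do not always state
which convention they use.

## Exact statistics

All tests target cohorts of ~8–14 subjects, where large-sample
approximations are unreliable:

- **Wilcoxon signed-rank**: zero differences dropped (Wilcoxon's original
  rule), midranks for tied magnitudes; the exact distribution of the
  positive rank sum over all 2^m sign assignments is built by polynomial
  convolution (midranks double to integers), alongside the tie-corrected
  normal approximation Z.
- **Mann-Whitney U**: pooled midranks; exact p by enumerating all
  C(n_a+n_b, n_a) group assignments up to 4·10⁵ combinations, with a
  seeded permutation fallback beyond. The reported U is min(U_A, U_B).
- **Spearman**: rank correlation with midranks; exact permutation p over
  all n! orderings for n ≤ 8, t approximation above.
- Two-sided p-values double the smaller tail, capped at 1.

The validation battery combines these on matched per-subject condition
means: unsupported − supported difference scores per task, exact Wilcoxon
condition contrasts, the task-task Spearman correlation, and optional
clinical (UPDRS motor) correlations.

## Problem sizes and numerical choices

The simulation-backed checks use 200 trials per task and condition for
parameter recovery, 200 matched pairs for the suppression direction, a
10-subject × 10-trial cohort for the paired contrast, 1000 trials for the
trigger equivalence, and 10⁴ draws/schedules for the distributional and
grid properties — sizes at which the binomial/Monte-Carlo error of each
check is far below its margin. Forces serialize with 6 significant digits
and times at 1 ms, so log round-trips are exact at the declared precision.
Run-log channels that share a rate are stored as one tick table; signals at
other rates (the 200 Hz marker next to 1000 Hz force) get their own block.

## Known limitations

- The threshold detector is systematically late by the time the signal
  needs to clear 2 SD of baseline noise; at the default signal slopes this
  bias is under two sample periods (median), but it grows for shallow
  onsets.
- The supine force-magnitude denominator is the cue-defined movement window
  (go cue → trace end); other choices (whole trial including relax, whole
  run) rescale the percentage and are not interchangeable across studies.
- The exact Mann-Whitney switches to sampled permutations for large groups;
  p-values then carry Monte-Carlo error (seeded, reproducible).
- The simulator's waveform shapes are minimal smooth archetypes; effect
  *directions* and detector calibration transfer to real data, absolute
  magnitudes (e.g. the force-magnitude percentage) depend on waveform and
  windowing details.
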