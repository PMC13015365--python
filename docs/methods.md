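# Methods

`placecode` analyzes tetrode recordings from mice running alternating
direction blocks on a rectangular track, and ships a synthetic-session
generator so that every stage of the analysis has a parameter-recovery
test. This note documents the models, the defaults and why, the numerical
choices, and what a green test does and does not establish.

## Track model and linearization

The track is the outer loop of a figure-8 maze (center arm blocked), walked
as a rectangle of perimeter 264 cm. Position is linearized by projecting
each camera sample onto the nearest point of the rectangle and measuring
arc length with the reward zone at 0 cm, the left-arm center at 66 cm and
the right-arm center at 198 cm. Those three anchors fix the perimeter
(264 cm) but not the aspect ratio; the default geometry is 84 x 48 cm,
which is configurable and does not affect any linearized quantity. Samples
farther than 10 cm from the path (default) are treated as lost tracking,
like camera dropouts, and are never interpolated.

Arc length increases in the clockwise (CW) travel direction by convention.
Spatial bins are half-open 4 cm intervals, bin i = [4i, 4(i+1)) cm, giving
66 bins. All smoothing and field logic wraps across the 0/264 cm seam: the
reward zone is a physical place on a closed loop, not an edge.

## Behavior

Running speed is the mean of sample-to-sample displacement rates inside a
centered 1 s window stepped every 0.1 s and interpolated back to the camera
timestamps; samples with missing position get missing speed. Analysis uses
only "running" samples, speed >= 2 cm/s (the source protocol writes both
">= 2" and "> 2"; the Methods form, >=, is used).

A trial is one reward-zone-to-reward-zone traversal. When trial boundaries
are not provided they are inferred from full-lap crossings of the unwrapped
arc (with hysteresis, so jitter at the reward zone cannot split a trial);
trials with more than 20 cm of retracing against the net travel direction
are flagged and excluded from maps. Epochs are blocks of 10 consecutive
same-direction trials, counted per direction. A session is valid only if 60
trials were completed within 30 minutes of the first trial's start
(wall-clock; the protocol does not say whether block-handling time counts,
so we include it).

The two running directions are analyzed independently everywhere: every
per-unit quantity is really per (unit, direction).

## Rate maps, fields, tuning

Raw per-trial maps divide running-period spike counts by running occupancy
per bin; spikes are assigned the linearized position of the nearest camera
sample in time (robust to missing samples; no interpolation). Bins never
occupied while running in a trial are missing. Maps are smoothed with the
five-point kernel [0.02, 0.10, 0.16, 0.10, 0.02]. The printed weights sum
to 0.40; by default they are renormalized to unit sum so smoothing
conserves rate (the kernel "approximates a Gaussian", i.e. a density), with
the literal 0.40-scaling available by config. Smoothing is masked: missing
bins stay missing and are excluded from both the numerator and the weight
sum of their neighbours. Per-trial maps are smoothed first and then
averaged (the alternative order is not distinguished by the source text;
this one matches "maps were then smoothed" directly following per-trial
construction).

A (unit, direction) is "high firing" iff the trial-averaged map's mean
exceeds 0.1 Hz and its max exceeds 1 Hz; a control variant (0.5/5 Hz) is a
config switch. Only high-firing unit-directions enter field, stability,
theta and precession analyses; every exclusion is logged with a reason.

Place fields are maximal wrap-contiguous runs of bins strictly above 10% of
the map max that contain at least one bin strictly above 50% of the max
(ties at the thresholds excluded — literal reading of "above"). Spatial
information (bits/spike) and sparsity use the standard occupancy-weighted
forms over defined bins. In/out-of-field rates are occupancy-weighted bin
means by default (a simple-mean variant is exposed); SNR is their ratio.
Peak-aligned population profiles exclude fields spanning more than half the
track (configurable), mirroring the removal of suspected interneurons with
track-wide tuning; the exclusion is a flag, never silent.

## Stability

Epoch stability is the Pearson correlation between trial-averaged maps of
successive epochs on pairwise-complete bins (a bin missing in either epoch
is dropped from both; fewer than 3 joint bins makes the comparison
missing). The null rotates every trial's map independently by a whole-bin
circular shift of at least 3 bins (= 12 cm, the smallest whole-bin shift
satisfying the 10 cm minimum), re-averages epochs, re-correlates, and
averages over 100 shuffles. Shifts are bin-granular rotations because they
preserve the occupancy structure of the map.

Peak shifts track the best E1 field, matched in later epochs by maximal bin
overlap (ties broken by nearer peak; the matching rule is ours — the source
does not describe one). Shifts are signed along the travel direction:
negative = toward the field entrance (the Mehta direction). |shift| <= 1
bin is "stable". Difference maps are later-minus-earlier epoch maps rolled
so the E1 peak is column 0, with the E2-E1 mean change exposed as the
population display ordering key.

## Theta and precession

Each unit's phases come from the LFP of its own tetrode, Butterworth
band-passed 4-12 Hz (order 4, forward-backward, so zero phase lag), with
instantaneous phase from the analytic (Hilbert) signal: 0 deg at the theta
peak, 180 deg at the trough. Spike phase is the phase of the nearest LFP
sample. Filter transients corrupt roughly the first and last second of a
trace; interior phase error on a pure tone is < 0.4 deg. Circular summaries
(mean vector length, preferred phase) are computed for all running in-trial
spikes and for in-field / out-of-field / best-field / burst / single
splits; the MVL-by-field-position profile uses 10 equal slices of the
normalized traversal with a 5-spike minimum per slice.

Phase precession is fit per trial on in-field spikes of the best
(highest-rate) field: phases are circularly shifted in 5 deg steps, the
shift minimizing the Pearson correlation of shifted phase vs normalized
field position is selected, and an ordinary least-squares line is fit at
that shift. Shifts with the same wrap pattern give mathematically identical
correlations, so the selected shift is an arbitrary member of a tie class;
slope and r are unaffected. Trials are included only with >= 5 in-field
spikes, >= 3 elapsed theta cycles between first and last in-field spike
(elapsed unwrapped filtered-theta phase >= 1080 deg — a temporal reading of
"spatial span"), and fit p < 0.05. The median slope over included trials
represents the neuron (the mean is also reported). Slopes are in degrees
per unit normalized traversal of the session-average field; per-trial field
sizes (for the size/slope analyses) are re-detected on each trial's map and
matched to the session field by overlap.

Cohort analyses: Spearman rank correlation of per-trial field size vs
median slope per genotype; OLS of transformed slope on log10 field size;
and a multiple regression transformed_slope ~ genotype + log10(size) + MVL
with coefficient table and adjusted R^2. The slope transform -log10(-slope)
exists only for negative slopes; non-negative-slope neurons are dropped
from transformed fits with a logged count (the source does not say how it
handled them). Shuffle controls permute phase or position within trials and
refit everything; the bootstrap resamples neurons with replacement within
genotype.

### A caution about the shift-search estimator

The shift-search + OLS procedure is only meaningful for genuinely
precessing cells. On non-precessing data the search places the phase
cluster across the 0/360 wrap, which manufactures steep artifactual
negative slopes, and because the reported p-value ignores the selection
over 72 correlated shifts, such trials pass the p < 0.05 gate far above
the nominal rate (~20-30% on shuffled phases). Consequently (a) a
zero-slope unit is not recoverable as "slope ~ 0" — its gate-surviving
trials are exactly the wrap artifacts — and (b) phase-shuffled nulls do not
center on zero slope; what shuffling actually destroys is the inclusion
rate and the tightness of the slope distribution, and those are what the
tests assert. Negative programmed slopes (-90 to -270 deg/field) are
recovered within +/-25 deg through the full pipeline.

## Classification

ISIs are successive spike-time differences, histogrammed at 10 ms; the
burst index is (# ISIs < 10 ms) / (# spikes). PSTHs align spikes to light
pulses in [-1000, +1000) ms windows at 1 ms bins, summed over pulses (the
opto-response threshold of 1 only makes sense on summed counts). The
opto-response is the max bin count in [0, 10) ms minus the max outside;
units are excluded at a mean session rate > 5 Hz (interneuron / overlap
rule) or when the response falls in the ambiguity band around 1 (width
configurable, default exact equality); otherwise response > 1 => KO
(ChR2-tagged), < 1 => WT.

## Synthetic sessions

The generator's defaults state the recorded world: 80 trials in blocks of
10 per direction, 30 Hz camera with 2% lost samples, 8 Hz theta on a 1/f^2
background at 1 kHz, light pulses at 0.5 Hz for 10 ms, opto latency 4 ms.
Running speed is 20 +/- 5 cm/s (AR(1)-smoothed, floored at 4 cm/s; the
protocol does not publish speeds — this is a typical trained-mouse pace),
with 1-3 s sub-threshold reward pauses to exercise the running filter.

Spike trains are an inhomogeneous Poisson process, sampled exactly by
thinning: rate = (Gaussian spatial envelope, truncated at its 10%
isocontour to the out-of-field floor) x (von Mises theta gain whose
preferred phase advances linearly across the normalized field — phase
precession as position-dependent phase, matching the analysis's
phase-vs-position fit). The ground-truth field edge is defined as that same
10% isocontour, so the generator and the analysis share one field
definition; with a zero floor this makes "all spikes in-field" exact.
Theta modulation applies only during trials (it accompanies locomotion);
home-cage/stim-period firing is unmodulated baseline, which also prevents
artifactual PSTH combs from the perfect-oscillator theta being phase-locked
to the exactly periodic stimulation. Bursts are doublets only (one
follower at 3-8 ms, probability per spike); KO units fire after each pulse
with the specified reliability and latency. All randomness flows from one
integer seed through a SeedSequence tree; event times are reproducible and
spikes closer than 1 us are merged.

What the generator does not emulate: overdispersed (non-Poisson) firing,
slow rate drift and remapping, theta frequency/amplitude fluctuations and
phase asymmetry, ripples/NREM, electrode drift, spike-sorting errors, or
multi-animal variability. Green recovery tests therefore establish that the
pipeline measures what the model encodes — not that real recordings satisfy
the model.

## Numerical choices

- Timestamps are float64 seconds on one session clock; session files store
  17 significant digits so write -> load round trips are bit-exact.
- The pipeline is a pure function of (session, config, seed); shuffle RNGs
  are spawned deterministically per unit-direction in iteration order, and
  result tables are byte-identical across repeat runs.
- Missing values are NaN end to end; result tables carry explicit
  exclusion-reason columns instead of dropping rows.
- Tie-breaks: best field = field containing the map max; shift-search ties
  resolve to the smallest shift index; field matching ties resolve to the
  nearer peak.
- Degenerate inputs: all-missing maps classify "low" with a reason; zero
  overall rate makes information/sparsity missing; zero out-of-field rate
  makes SNR missing; < 2 spikes gives burst index 0; a unit with no
  included precession trials is excluded from cohort fits with a reason.
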