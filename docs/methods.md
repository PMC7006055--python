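# Methods

This note records the models, conventions, and numerical choices behind
swallowkit, in the order data flows through the pipeline.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the study inputs a dysphagia phenotyping lab
would collect: fluoroscopic jaw-motion clips, endoscopic glottal-motion
clips, H&E lung sections, and home-cage event logs. Their defaults are the
study conditions — wild-type group means reported for adult mice
(`swallowkit.reference`): 8.71 licks/s at 30 fps for drinking, a swallow
every fourth lick with a ~3-frame (100 ms) pharyngeal transit,
breathing at 150 cycles/min over 10 s endoscopy clips, inflammation
fractions below 1% (wild-type) vs ~4% (deletion), and home-cage rates of
3.43 drinking / 19.0 eating / 16.1 grooming events per hour over 72 h.
Where a needed number is not reported, a derived or field-typical value is
used once and noted here:

* **Jaw amplitude** (0.79 mm peak-to-trough) is derived from the reported
  mean jaw-opening velocity: for a raised cosine the per-phase mean slope
  is 2·A·f, so A = v/(2f) ≈ 13.71/(2·8.71).
* **Closed-jaw baseline** (2.0 mm) is the marker separation with the jaw
  shut — a physical couple of millimetres in an adult mouse, which also
  keeps rendered marker disks disjoint.
* **Mouse-to-mouse spread** in the cohort simulators is the published SEM
  scaled back to a per-animal SD (SEM·√n at the study group sizes).
* **Event durations** in behavior logs are exponential with the class mean
  implied by the published per-bin values (e.g. 107.4 s / 82.32 events ≈
  1.3 s per drinking bout).

Waveforms are raised cosines, `x(t) = base + (A/2)(1 − cos 2πft)`, so every
cycle extremum is analytically known and the generators can emit exact
event-time truth. Real traces have jitter in cycle period and amplitude,
pauses, and drift; additive white Gaussian noise (default 5% of amplitude,
the level at which the recovery tests operate) is the only corruption
modeled. Passing tests therefore demonstrate correctness of the *metric
layer and its conventions* on signals of the right scale and rate — they do
not certify the peak detector against arrhythmic licking or the tracker
against real fluoroscopic contrast.

The home-cage generator draws per-class Poisson counts (mean
rate·total_hours) and exponential durations, then packs events
longest-first onto the timeline, redrawing any start time that collides
(up to 200 tries). Redrawing rather than discarding keeps per-class counts
exactly Poisson while guaranteeing a non-overlapping log; longest-first
placement is what makes multi-minute grooming bouts placeable after
thousands of short events. Requested loads with expected occupancy above
50% are rejected as infeasible.

The histology generator paints hard-edged circular pools on a tissue
ellipse and then grows/shrinks the pool mask pixel-by-pixel at its boundary
so the painted fraction matches the request exactly; real sections have
graded stain intensity and irregular pool shapes, so the 20% recovery
tolerance of the pipeline tests is about discretization and enhancement,
not stain variability.

Marker videos are dark frames with bright disks (1 px linear rim, so
sub-pixel position is encoded in rim intensities) plus a calibration bar of
known pixel length in frame 0. Frame geometry is freely chosen
(160 × 120 px default) since raw video characteristics are not reported.

All generator randomness flows from one integer seed through a
counter-based bit generator (Philox), making output bit-reproducible across
platforms.

## Tracking

The tracker is normalized cross-correlation template matching: a
(2h+1)² patch (default h = 5) captured around each marker in frame 0 is
searched within a radius (default 8 px) of the previous frame's position;
the correlation peak is refined by separable parabolic interpolation, and
the sub-pixel offset between the stated initial position and the integer
patch grid is carried forward. The template is never updated, so there is
no drift accumulation; the cost is sensitivity to appearance change, which
high-contrast radiographic markers do not exhibit. A best-match score below
the confidence floor (default 0.5) raises a tracking-lost error naming the
frame, rather than silently jumping. On rendered fixtures the tracker is
accurate to ~0.02 px; the search radius must exceed the true per-frame
displacement (a 0.79 mm, 8 Hz lick at 0.1 mm/px moves up to ~7 px/frame).

Calibration is exact arithmetic: mm/px = bar_mm / bar_px from the traced
10 mm bar. Coordinates are 0-based, origin top-left, y down.

For endoscopy, the left/right glottal points are first adjusted to be
equidistant from the dorsal commissure (the nearer point is moved outward
along its ray to the farther point's distance; idempotent). Lateral traces
are signed perpendicular distances from the *frame-0* glottal axis — the
bisector of ∠(L, C, R) anchored at the frame-0 commissure — negative left,
positive right. Fixing the axis from frame 0 matches the fixed-commissure
tracking convention and makes all laryngeal metrics invariant to rigid
transforms applied to the whole video.

## Jaw kinematics

Clips start on a swallow event; five context frames are appended to each
side for review but excluded from analysis, so a 2 s drinking clip is 70
frames with a 60-frame analysis window. Conventions the upstream tooling
leaves unstated are fixed as follows:

* a cycle is timestamped by its **closing minimum**; per-second counting
  uses half-open sub-windows [0,1), [1,2);
* the lick–swallow ratio counts closes in the half-open interval
  (s_i, s_{i+1}] between successive swallows (no double counting);
* velocities are per-phase mean slopes (|Δgape| / Δt over close→open or
  open→close), not instantaneous maxima;
* undefined metrics (no swallow pair, single cycle) are NaN with a
  warning, never zero.

Extrema detection wraps `scipy.signal.find_peaks` with a prominence
threshold (default 20% of the clip's range) and adds two refinements:
endpoint extrema, because a clip that starts on a swallow starts at a true
cycle minimum that interior-only detection would drop; and alternation
enforcement (of two same-sense extrema the more extreme survives).
An endpoint candidate must both clear one-sided prominence against its
neighboring interior extremum and reach the level of interior extrema of
its own sense within one prominence unit — the band that covers worst-case
sampling quantization, (1 − cos(πf/fps))/2 · A ≈ 0.19 A at 8.71 Hz and
30 fps — so a clip cut mid-phase cannot mint a false event. With these
rules, detection on noise-free study-condition traces lands every event on
the frame nearest the true extremum, and at 5% amplitude noise the
windowed lick-rate statistic matched truth in all 100 tested seeds.

Lick rate and ILI are deliberately *not* reciprocals: a uniform train that
starts on a close yields ⌈f⌉-style window counts (e.g. 9.0 at 8.71 Hz)
while the ILI stays 1/f. Reported group values for the two metrics in this
field show the same non-reciprocal relationship, which is why both are
computed and reported separately.

## Laryngeal kinematics

Cycle segmentation for amplitude-based metrics uses the glottal **width**
trace (the two-sided consensus: one cycle per width maximum, bounded by
adjacent width minima); per-side extrema counts feed only OCCR, which is
exactly the statistic allowed to differ between sides. MMRR uses min/max
amplitude ordering (symmetric, ≤ 1, consistent with reported values ≤ 1);
OCCR uses the fixed right/left order (reported values straddle 1). Both
orderings are arguments if a lab prefers otherwise.

Mcorr is the Pearson correlation of per-frame first differences of the two
signed lateral traces, after a 3-frame moving-average pre-smoothing
(`smooth_window=3`; 1 disables it). Smoothing is required for the stated
noise robustness: differencing amplifies white tracking jitter, and at 5%
amplitude noise the raw-difference correlation of perfectly anti-phase
motion already drops to ≈ −0.87, while the 3-frame average suppresses the
jitter band without touching the ~2.5 Hz breathing signal, keeping
|Mcorr| ≥ 0.95. Ideal anti-phase motion gives exactly −1 and paradoxical
motion exactly +1 with or without smoothing; a motionless larynx has
zero-variance differences and Mcorr is reported missing (the ~0-motion
case). The VF angle is reported as per-cycle max, min, and their midpoint
averaged across cycles; which of these corresponds to a single published
"average angle" is not determinable, so all three are exposed and
`vf_angle_mean` is used in cohort tables.

LAR duration is (end − start)/fps · 1000 from manually annotated frames;
presence/absence is consumed as an annotation, never inferred.

## Histology pipeline

The inflammation recipe is re-expressed as deterministic image math with
explicit slider semantics: background = pixels within a per-channel
tolerance (default 30) of the modal border color and 8-connected to the
border, set to white and excluded (interior pixels are never flagged);
in hue/lightness/saturation space, red-band pixels (hue ∈ [315°, 45°))
get saturation doubled and blue-band pixels (hue ∈ [195°, 255°)) are forced
to white; then every channel passes the polarizing map
v′ = clip(2(v − 128) + 128 + 150). Inflamed pixels are those with ITU-601
luminance below 130 after enhancement; the ratio's denominator is the
total pixel count of the *original* image (a tissue-only denominator is
available behind a flag and must be reported as such). The exact hue-band
edges and the original editor's brightness/contrast internals are
unrecoverable, so the definitions above are validated by synthetic-truth
recovery (within 20% relative across pool fractions 0.01–0.2, and exactly
monotone), not by bit-parity with any editor.

Mandible morphometry is Euclidean landmark distance × mm/px from a stage
micrometer, compared by a two-way genotype × side ANOVA with interaction
(type-II sums of squares via statsmodels OLS; every cell needs n ≥ 2).

## Behavior

Events are credited wholly to the 24 h bin containing their start time
(no splitting — the export format carries whole events). Per-mouse values
are means over the three bins; conversions are exact rationals
(events/hour = per-bin count / 24; minutes = seconds / 60). A log linter
(ordering, overlap, range) substitutes for the original manual video
spot-checks.

## Statistics

The group layer mirrors the study's workflow: classic equal-variance
independent t-tests (Welch behind a flag, since the original software's
default cannot be determined), mean ± SEM (SD/√n, ddof = 1), two-sided
p with α = 0.05, Shapiro–Wilk normality screening that reports but never
switches the test, and 1.5·IQR outlier flags with outliers retained. No
multiple-testing correction is applied by default, matching the original
analysis; Benjamini–Hochberg is available explicitly. Genotype labels live
in a separate table merged only at this stage, modeling the blinded
workflow. The implementation is checked against textbook-formula oracles
to 1e-10 and calibrated by a 10,000-replicate null simulation
(type-I error 0.05 ± 0.01).

## Problem sizes

Cohort simulations use the study group sizes (11 + 11 fluoroscopy and
endoscopy mice, 10 behavior mice, five 2 s drinking clips and one 20 s
eating clip per mouse, five 160 × 120 images per mouse, 72 h logs), chosen
so a full pipeline run plus the acceptance script completes in seconds.

## Known limitations

* Swallow, LAR, and rotary-chewing events are consumed as annotations;
  none are detected from video (out of scope by design).
* The peak detector's endpoint rules are tuned to clips that start on a
  cycle minimum; traces cut arbitrarily mid-phase lose at most the two
  boundary events.
* The synthetic cohorts reproduce group means and spreads, not
  within-mouse correlation structure across assessment domains.
* Parity with the interactive image-editor recipe is approximate by
  construction (see above).
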