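# Methods

This note documents the models, the tunable parameters, the numerical
choices, and the limits of what the synthetic benchmarks demonstrate.

## The measurement model

The heart tube of an intact fly is imaged through the cuticle as two
bright fluorescent wall bands on a dark background, the tube axis
horizontal by mounting convention. All geometry is in pixels internally;
diameters are reported in µm via the pixel size from the recording
metadata. Coordinates are 0-based, the space axis runs top to bottom, and
time is seconds from frame 0.

### Acquisition-zone selection

The analysis line must cross both walls. Candidate lines are single-pixel
image columns; each is scored by the sum over the line of per-pixel
temporal variance, and the argmax wins, with exact ties broken toward the
image centre. Wall motion is the dominant source of temporal variance in
these recordings, which makes the variance criterion a natural automated
stand-in for manual placement; it is this package's own documented choice.
The analysed span along the line is clipped to pixels whose time-mean
intensity exceeds the Otsu threshold of the time-mean image, dilated by a
3 px margin, with an 8 px minimum. A static stack (maximum per-pixel
temporal variance below 10⁻¹² of the squared intensity range) raises
`NoMotionError` rather than returning an arbitrary line. An optional
`auto_orient` mode estimates the tube axis as the principal axis of the
Otsu-bright region of the time-mean image and switches candidate lines to
rows when the tube is vertical; it is off by default so that default runs
are exactly reproducible.

### Midline and wall tracking

"Median position of the heart" is implemented as the median over frames of
the per-frame intensity centroid along the space axis. The median over
frames is robust to transient signal loss and yields a single static
reference line. Per frame, the spatial profile is smoothed with a Gaussian
of σ = 1 px (default), and the maximum-intensity position is taken on each
side of the midline, excluding the midline pixel itself so the two walls
cannot collapse onto one pixel at systole. Ties for the maximum resolve
toward the midline (the walls bound the lumen). Sub-pixel refinement fits
a parabola through the peak and its two neighbours (offset clamped to
±0.5 px) and is on by default: at 32 frames/s and a few px of wall motion,
integer peaks are coarse.

Frames fail quality control (`low_signal`) when the weaker wall peak does
not rise above the per-frame median intensity by 5% of the global p95−p5
intensity range, or when the wall separation falls below 2 px (wall
merge). Relative thresholds keep extraction invariant under intensity
scaling and robust to photobleaching, so no flat-field or bleach
correction is applied upstream. Low-signal frames have their wall
positions linearly interpolated from neighbouring good frames and are
flagged in the output so the interpolation is auditable; more than 50%
low-signal frames raises `NoWallSignalError`. Dropping instead of
interpolating was the alternative; interpolation preserves the uniform
time base the beat detector assumes.

### Beat detection

End-diastoles and end-systoles are the local maxima and minima of the
diameter trace. Taken literally this would include every noise wiggle, so
two configurable guards are applied (both revert to the literal reading at
0): a prominence floor of `prom_frac = 0.10` of the p95−p5 trace range,
and a refractory separation of 2 frames between successive same-type
events. Plateau extrema sit at the plateau centre. Alternation is enforced
by keeping the more extreme of two consecutive same-type events. Event
diameters are always read from the unsmoothed trace.

Detection runs on a smoothed copy of the trace. The smoothing width
adapts to the beat: a Schmitt trigger (traversals from below the 25th to
above the 75th percentile) counts beats robustly under both noise and
arrhythmia, and the Gaussian σ is one tenth of the implied period, clipped
to 5–40 ms. A fixed width cannot serve both a 120 ms beat (which
over-smoothing merges) and a 400 ms beat in noise (which under-smoothing
fragments). Because smoothing shifts the extrema of an asymmetric
waveform, each detected event is then re-localized to the extremum of a
lightly smoothed trace (σ = max(5 ms, one third of the detection width))
inside the window bounded by the midpoints to its neighbouring events;
the windows are disjoint, so event order is preserved. With smoothing
disabled the detector is exactly the brute-force extrema scan, which the
test suite verifies by full equivalence on traces up to 10,000 frames.

### Metrics

From the diastole-to-diastole intervals (ms): HP is the arithmetic mean,
HR = 1000/HP, and AI is the sample standard deviation (n−1 denominator —
beat counts are small, so the conventional unbiased-variance estimator is
used) divided by the median. EDD and ESD are means over all diastolic and
systolic event diameters of the recording; one value per fly. HP needs at
least 2 diastoles and AI at least 3; metrics that cannot be computed are
NaN with a machine-readable reason, never silently dropped. ESD is
included for symmetry with EDD. Metrics default to the full recording; a
shorter analysis window can be selected by slicing the stack or trace.

## Cohort statistics

Group comparisons use the two-sided Wilcoxon rank-sum test: exact null
enumeration when the combined sample is ≤ 12 without ties, otherwise the
normal approximation with midranks, tie correction, and continuity
correction. Stars follow the convention `*` p < 5·10⁻², `**` p < 5·10⁻³.
Raw p-values are reported; no multiple-testing correction is applied by
default (a Benjamini–Hochberg helper exists).

Age trends are ordinary least squares of a metric on age over individual
fly records with age ≥ 10 days (younger flies are still maturing and are
excluded from trend fits by default). Fitting per-fly values rather than
per-age means retains the residual degrees of freedom the slope test
needs; a `means` mode fits per-age group means for comparison. Two trends
are compared with the two-slope t-test (Zar): pooled residual variance
s² = (RSS₁+RSS₂)/(n₁+n₂−4), t = (b₁−b₂)/√(s²/Sxx₁ + s²/Sxx₂) on n₁+n₂−4
df. Exactly collinear inputs make s² = 0 up to rounding; the
implementation treats a standard error below 10⁻¹² of the slope scale as
degenerate, returning p = 1 for equal slopes and p = 0 with a degeneracy
flag otherwise. Empirically the test rejects equal planted slopes at
0.046 over 1000 simulated cohorts at α = 0.05 (the suite accepts
0.03–0.07).

## Gene-set enrichment

Identifiers are trimmed and case-normalized (FlyBase `FBgn` identifiers
are canonicalized to `FBgn` + digits; other tokens uppercased); symbol-to-
identifier mapping is out of scope, so lists should share one namespace.
The enrichment p-value is the upper-tail hypergeometric probability
P(X ≥ k), one-sided and including the observed k. The tail is summed in
log space from log-gamma binomial terms via logsumexp; an exact rational
path (`exact=True`) is practical for universes up to a few hundred genes
and agrees with the log-space path to 10⁻¹² relative error in the tests.
Published overlap counts rarely state the universe size, so the default is
N = 13,500 — the scale of the *Drosophila* protein-coding gene count — and
every report carries N plus the min/max p over a 10,000–17,000 sweep;
bound-style enrichment claims should be (and, for the bundled overlap
tests, are) robust across that whole range.

## The synthetic generator

The generator emulates each pipeline input with recorded ground truth.

* **Beat trains.** Diastole-to-diastole intervals are i.i.d. gamma by
  default (positive support; mean and CV map exactly to shape and scale),
  with lognormal and constant alternatives. Systoles sit at a configurable
  40% of each interval after the diastole; the true waveform shape in
  flies is not standardized, and the raised-cosine segments used here are
  smooth with extrema exactly at the event times. Recorded truth (HP, AI)
  is the realized statistic of the drawn intervals under the same
  definitions the estimator uses, so recovery tests have exact targets and
  CV = 0 implies a true AI of exactly 0.
* **Cardiograms and videos.** The diameter trace interpolates between EDD
  (70 µm default) at diastoles and ESD (45 µm) at systoles. Videos render
  two Gaussian wall bands (σ = 2 px) at midline ± d(t)/2 over a dark
  background, uniform along the tube axis, with optional exponential
  photobleaching, linear centre drift, and Gaussian (default) or Poisson
  intensity noise. Gaussian is the default because its effect on the
  downstream estimators is analytically transparent; `noise_sigma` is in
  intensity units, while `trace_noise_um` (µm) perturbs rendered
  cardiograms directly — separate knobs because the two live on different
  scales. Centre drift cancels in the diameter and therefore does not
  enter rendered cardiograms. The frame-rate precondition is checked at
  the configuration level (the *median* event spacing must exceed one
  frame period); individual short gaps in a stochastic train simply alias.
  Defaults follow the assay's recording setting (32 frames/s; a 1000-frame
  movie spans 31.25 s); 200 frames/s is used for quantization-free
  testing. No quantitative noise/SNR characterization of real recordings
  is available, so the noise defaults are engineering choices.
* **Cohorts.** Per-fly metrics lie on planted linear age trends plus
  Gaussian between-fly noise. Defaults emulate control flies (HP ≈ 154 ms
  at 10 days rising ≈ 2.4 ms/day, AI ≈ 0.1, EDD ≈ 70 µm falling
  ≈ 0.27 µm/day; 30 flies per age at 10/30/45/60 days), magnitudes chosen
  once to match aging cohorts of this assay.
* **Gene lists.** Two sets with an exactly planted overlap inside a fixed
  universe of FlyBase-style identifiers.

All generators are deterministic given a seed (bit-identical outputs).

## What the benchmarks do and do not show

On the 1,800-replicate grid (HP ∈ {120, 150, 400} ms, interval CV ∈
{0, 0.1, 0.3}, trace SNR ∈ {5, 10} where SNR = stroke amplitude / noise
SD, 32 and 200 frames/s, 50 replicates each, ~30 s of trace per
replicate), the pipeline recovers HP with a median relative error well
under 1% at 200 fps and AI with a mean absolute error near 0.03. At
32 fps — the real acquisition rate — HP is quantization-limited: the bias
stays below half a frame period (≈ 15.6 ms), and AI carries a
quantization floor of roughly 0.05–0.15 depending on the period, which is
why regular hearts measured at 32 fps should not be assigned AI values
below that floor. The recovery grid runs at the cardiogram level; the
video stages (zone location, M-mode, wall tracking) are validated
separately, including end-to-end runs on rendered stacks, because
rendering 1,800 full videos would add hours of compute without changing
what is tested.

The synthetic videos idealize real recordings in known ways: walls are
symmetric Gaussian bands of constant width and brightness, the background
is uniform, motion is purely transverse, and noise is white. Real movies
add cuticle scatter, gut autofluorescence, longitudinal motion and focus
drift. Passing the benchmarks therefore demonstrates correctness of the
algorithms under the stated model, not performance bounds on arbitrary
recordings; the quality flags and intermediate outputs exist so real-data
failures are visible rather than silent.
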