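# Methods

This note documents the models and procedures the package implements, the
defaults that matter, the numerical choices behind them, and what the
synthetic benchmarks do — and do not — establish about real recordings.

## Coordinate and data conventions

Frames are indexed `(t, y, x)`, pixel indices are 0-based, time is seconds
from recording start, intervals are half-open `[start, end)`, and physical
distances are `pixels × pixel_size` (µm).  The IHC row defines a curvilinear
axis; positions map to `(s, d)` with `s` the longitudinal arc length along
the row and `d` the signed radial distance, positive toward the modiolar
side (the GER).  All tables written by the CLI carry these units in their
column names.

## Synthetic epithelium and activity model

The generator emulates the apical coil of an immature cochlea at the level
of its observables, not its biophysics (no ATP diffusion or membrane-
potential model).

**Geometry.**  `n_ihc` (default 20) IHC somata of radius 4 µm spaced
8–10 µm (default 9) along a circular arc (default curvature 0.002 µm⁻¹);
glial-like supporting cells fill a GER band 8–44 µm modiolar of the row;
1–10 SGN terminal puncta per IHC, counts drawn from a normal (mean 4,
SD 2) rounded and clipped to [1, 10], placed within 6 µm of their parent
with side labels pillar / modiolar (45% each) / middle (10%).

**Schedule.**  Independent IHC transients are homogeneous Poisson per cell
(default 0.35 events/min).  GER waves arrive as a Poisson process (default
0.8 waves/min) with maximal longitudinal semi-extent drawn from a clipped
normal (17 ± 6.5 µm; full extent 34 µm on average), a fixed
longitudinal-to-radial aspect ratio (2.4), and expansion / contraction
speeds of the *equivalent radius* √(a·b) drawn around 22 and 15 µm/s.  The
footprint lifetime is derived as `r_max·(1/v_exp + 1/v_con)` rather than
drawn independently — extent, speeds and duration are geometrically coupled,
and the generator resolves the redundancy in favour of consistency.  A
fraction `p_reach` (default 0.31) of waves initiates a coordinated IHC
event: a contiguous cohort (clipped normal, 7 ± 4 cells, 3–20) centred on
the cell nearest the wave origin, activated sequentially at the lateral
spread speed `v_ihc` (default 61 µm/s), with internal cells skipped with
probability 0.15.  Coordinated transients are scaled ×1.9 in amplitude
relative to independent ones (0.25 dF/F₀), mirroring the observed contrast
between synchronised and solitary activity.  Terminals fire with their
parent IHC with probability 0.8 during multicell events and 0.3 during
single-cell transients, plus sporadic terminal-only transients that are
2× more frequent (and 1.3× larger) on the pillar side.

With a 20-cell field these defaults produce per-cell total rates below the
in vivo average: a finite window sees only the waves whose origin falls
inside it, whereas a real epithelium is recruited by waves from beyond the
field of view.  The wave rate and cohort statistics are kept at their
observed values rather than inflating one knob to force another's marginal.

**Rendering.**  Transients convolve the schedule with a
difference-of-exponentials indicator kernel (τ_rise = 50 ms; τ_decay solved
numerically so the kernel FDHM equals the configured 1.5 s) applied
multiplicatively to the cell's pixels.  Waves render as an
axis-aligned ellipse whose equivalent radius grows at `v_exp` and shrinks at
`v_con`, plateau 1 inside with a Gaussian rim (default softness 1.5 µm),
restricted to the modiolar side of the row, passed through a causal
exponential indicator (τ = 0.4 s for supporting cells); `indicator_kinetics
= False` renders footprints instantaneously for estimator validation (see
*Limitations*).  Breathing artifacts multiply whole frames by (1 − depth)
in bouts of 2–8 frames (depth 0.3–0.6, 2 bouts/min); optional sinusoidal
drift; Poisson shot noise last (gain 1 count/photon).  Identical
`(config, seed)` reproduce movie and sidecar bit for bit.

The default frame rate is 30 frames/s, the realistic rate of the
resonant-scanned two-photon systems this class of recording uses; it also
makes the 200 ms duration criterion (below) statistically meaningful —
at 10 frames/s only two samples span it.

## Frame quality control

The qc trace is the pixel average over the central 80% of the field.
Negative excursions are detected with `scipy.signal.find_peaks`: a
candidate must be prominent above 4 × robust SD *and* deviate that far
below the trace median (robust SD = 1.4826 × MAD of the first-differenced
trace, divided by √2 — insensitive to the transients being detected).
Intervals are expanded to the width at half prominence, merged with
template matches (normalized cross-correlation ≥ 0.8) and manual lists.
Positive-excursion detection exists but is **off by default**: with GER
waves in the field, large positive global excursions are genuine biology,
and the rare positive focus artifact is better handled by the template bank
or a manual interval.

Detection and substitution run on the **raw** stack, then the Gaussian
smoothing (spatial σ = 1 px; FWHM ≈ 2 px): a temporal Gaussian would smear
a dimmed frame into its in-focus neighbours before they could be compared.
Temporal smoothing is likewise off by default (σ_t configurable): it
correlates shot noise into bumps whose duration tail crosses the 200 ms
transient criterion, which costs up to ~1 false transient/min per silent
cell at the stated 2 × SD thresholds.

Removed frames are substituted by the last in-focus frame (a leading
interval takes the first in-focus frame after it), preserving timing; trace
samples there are replaced by linear interpolation and flagged.

Drift correction is rigid: per-frame translation against the frame-average
image by phase correlation with 1/20-px refinement, clamped at ±10 px, and
the output rescaled so the global mean matches the input.  Piecewise
non-rigid registration is out of scope; externally computed shift tables
can be applied instead.

## Transient detection

Detection operates on detrended dF/F₀ (centered rolling median, 30 s
window; edges shrink).  Candidate peaks need prominence above 2 × robust
SD; inclusion requires amplitude > 2 × SD(trace) and FDHM > 200 ms.  Three
numerical choices matter:

* **Local amplitude baseline.**  Amplitude is height above the minimum of
  the preceding 2 s (clipped at the detrended zero), so a noise wiggle
  riding the decay tail of a previous transient is measured against the
  tail, not against the distant baseline.
* **Schmitt-trigger width gate.**  The half-max walk terminates only when
  the trace falls 0.2 × peak height (capped at one robust SD) below
  half-max.  A marginal noise peak (half-level ≈ 1σ) terminates within a
  sample; a ≥4σ transient (half-level ≈ 2σ) survives isolated noise dips.
  Calibrated on white-noise traces: ≈0.03 false events/min at 30 frames/s
  with ≥98% sensitivity at 4σ.
* **Reported FDHM.**  The reported width uses crossing hysteresis (50 ms
  dwell) and a noise-robust peak height (50 ms-smoothed), which removes the
  ≈10–15% downward bias of the strict first-crossing estimate at realistic
  SNR.  The strict width still gates inclusion — the two roles deliberately
  use different estimators.

Peaks whose half-max span lies entirely in interpolated samples are
rejected.  Frequencies are total peaks / total observed duration per cell
(stitched recordings sum their durations; peaks never chain across a
boundary), and cells observed under 5 min are excluded from frequency and
correlation statistics.

Residual limitation: at default movie SNR ≈0.05–0.1 false transients/min
per cell survive, mostly late noise echoes on decay tails; the source
analysis handled these by manual curation, which this package deliberately
does not reproduce.

## Event grouping

Transients join the same event when chained by pairwise peak-time gaps
≤ 2 s (single linkage; sorted-sweep implementation, verified exactly
against an exhaustive union-find oracle on 1000 random instances).
Clusters then split positionally wherever more than 4 consecutive
non-participating cells separate participants — cell counts, not µm.
Classes: single (1 cell), pair (2), multiple (≥3).  A skipped cell lies
strictly inside a multiple event's positional range, has no transient in
the event window (or responds below 0.25 × the cohort median amplitude),
and is active elsewhere in the recording.  Complete linkage is available
behind a config switch.

## Correlations

Pearson r on detrended, simultaneously recorded samples; pairs with under
5 min of overlap stay undefined (excluded, never imputed as zero).
Averages and SDs use the Fisher z-transformation (tanh of mean/SD of
arctanh, |r| clamped at 1 − 10⁻¹²).  The r-vs-distance curve is
Fisher-averaged in 10 µm bins, with an optional exponential fit
r(d) = r₀·e^(−d/d₀).

## Wave segmentation and kinetics

The stack is spatially binned ×2, converted to per-pixel ΔF/F₀ (F₀ = 10th
temporal percentile), and labelled by Voronoi–Otsu: Gaussian(spot σ = 3
binned px) → local maxima as seeds (a connected plateau is one seed);
Gaussian(outline σ = 1) → threshold → mask; masked nearest-seed partition
via marker watershed on the distance-to-seed transform.  The automatic
threshold is max(Otsu, 6 × robust SD) of the smoothed volume — plain Otsu
on a noise-dominated volume happily splits the noise mode in half; the
floor replaces the manual threshold of the original workflow.  Objects
below 10 binned voxels or 100 µm² of footprint are dropped, and when a cell
label image is supplied, any object whose footprint lies ≥80% within one
dilated cell mask is excluded as a single-cell transient rather than an
intercellular wave.

Per wave: per-frame areas (voxels × binned-pixel area), maximal area and
its frame, footprint extents and centroid in `(s, d)` at maximal expansion
(extents include one binned pixel width), FDHM of the pixel-average ΔF/F₀
trace over the union footprint (skipped for boundary-truncated waves, which
still count toward frequency), and expansion / contraction speeds as the
slope of √(area/π) against time from onset→max and max→offset.  The
equivalent-radius estimator is the package's own choice — the measurement
protocol it replaces never states one — and a boundary-displacement
alternative sits behind `speed_estimator="boundary"`.  Manually drawn 2D
wave ROIs can be imported; they contribute to frequency and extension
statistics but not kinetics.

Kymographs sample the mean intensity over ±3 px transects perpendicular to
a polyline at 1 µm arc-length steps; build them from the ΔF/F₀ stack
(`dff_timelapse`), not raw intensity, or static cell brightness dominates
the ridge.  Propagation speed in a time × arc-length box: threshold at
half-max within the box, origin = earliest suprathreshold sample, speed =
|Δs|/Δt to the farthest suprathreshold sample (0 for a stationary blob;
undefined when simultaneous with the origin).

Waves whose centroid lies within 35 µm of the row are matched to the IHC
event overlapping [onset, offset + 2 s]; ambiguity resolves to the nearest
event in time and is flagged.

## Terminal analysis

Puncta: white tophat (disc radius 15 px ∈ [10, 20]) on the time-average
image, then 2D Voronoi–Otsu; specks under 4 px dropped.  Assignment: the
nearest IHC wins outright when it beats the second-nearest by more than
3 µm; otherwise the trace correlation with the two nearest decides (ties go
to the lower-index IHC and are flagged).  Side labels derive from the
signed radial coordinate: |d| ≤ 2 µm is "middle", positive is modiolar.
Middle terminals are excluded from side contrasts but included in totals.
Per-IHC traces average the member terminals; peaks across terminals of one
IHC merge within 1 s (single linkage).  A terminal counts active in an IHC
event if it has a transient within the event span ± 1 s.  The paired
pillar-vs-modiolar comparison uses per-IHC side means and the Wilcoxon
signed-rank test, only for IHCs with terminals on both sides, and reports
"insufficient n" below 6 pairs.

Cell-body segmentation by a trained model is out of scope; ground-truth
masks (synthetic) or user-supplied label images stand in.  At the default
1 µm/px rendering scale neighbouring puncta closer than ~4 µm merge into one
label, so segmented terminal counts per IHC undershoot the generative
distribution — a resolution limit, not a detection failure; real terminal
recordings are acquired at finer pixel pitch.

## What the benchmarks show — and what they do not

The test suite validates parameter recovery against the generator's hidden
truth: Poisson rates within 3 SE, kernel FDHM within 10%, artifact
detection at ≥95% sensitivity and ≤1% frame false positives, wave speeds
within 5% (footprint rendering) and kymograph speeds within 10%, wave
geometry within one binned pixel, terminal assignment ≥95% with side labels
exact outside the middle band, and recruitment couplings within binomial
confidence intervals.  Speed-estimator checks render footprints without
indicator kinetics: with a realistic indicator the apparent contraction of
*fluorescence* is decay-limited, so contraction speeds measured on real
movies under-estimate footprint contraction — visible in the default-movie
statistics as well.  The generator's simplifications cut the other way too:
real noise is not purely Poisson, real waves are not ellipses, cohort size
and wave extent are drawn independently although they co-vary in tissue,
and no manual curation cleans the residual false positives.  Passing these
benchmarks therefore establishes the correctness of the estimators under
the stated model, not the biology of any particular recording.

Simulated problem sizes (field of ~20 IHCs, 2–20 min recordings, 2–20
movies per check) were chosen as the smallest giving the statistical power
each tolerance needs.
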