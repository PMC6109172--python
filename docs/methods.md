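# Methods

This note documents the quantification procedures, the synthetic-data
model that provides ground truth for them, the numerical choices, and the
known limitations.

## Trace normalization and the 3-SD criterion

All fluorescence traces are ROI means expressed as ΔF/F0, with
F0 = mean of the frames in the first 10 s of the recording
(`round(10 / dt)` frames; 20 frames at the default 2 Hz). Time windows
are half-open `[start, end)` in seconds; frame `i` carries timestamp
`i·dt`; coordinates are 0-based `(row, col)`.

Events and responses are accepted when ΔF/F0 exceeds 3 standard
deviations of the baseline. The reference period for that SD is the F0
window of the same ROI (a per-ROI rather than global SD; both the factor
and the reference are configurable). With zero noise the SD is floored
at machine epsilon, so any positive deflection counts. Because the
maximum of N noise samples grows with N, the 3-SD criterion is only
meaningful over short windows: the responsive/silent classification
therefore evaluates the peak over the stimulation train plus a 2-s
margin (default), not over the whole post-stimulus period, and the
appearance detection for DCV events (below) uses a stricter threshold
than the per-ROI criterion.

## Punctum detection and ROIs

Detection smooths the image (Gaussian, σ = 1 px), takes local maxima
above `median + 3 × robust SD` (robust SD = 1.4826 × MAD), and refines
centroids with an intensity-weighted mean after subtracting a local
background (median of a square annulus around the peak). Punctum
intensity is by default the background-subtracted sum over a tight 7×7
window; the window is deliberately small so that at realistic punctum
spacing (≥ 8 px) neighbors leak negligibly into each other's integrated
intensity — with a wide window that leak inflates all intensities and
biases the modal quantum upward. A peak-pixel intensity mode is also
available.

ROIs are squares centered on the rounded centroid (round-half-up); for
even sizes the rounded centroid sits at the upper-left pixel of the
central 2×2 block (a 4×4 ROI at (10, 10) spans rows and columns 9–12).
ROIs that would cross the image border raise an error.

Mobility (used to exclude mobile puncta from synapse identification) is
assessed on block-averaged baseline images (5-s blocks) to suppress
frame noise; a punctum is mobile when any block centroid deviates more
than 2 px (default) from the first. Blocks without significant contrast
— e.g. a fully quenched punctum — are skipped; with fewer than two
trackable blocks the call is indeterminate (`None`, with a warning) and
such puncta are retained, since a quenched resting punctum is exactly
what the assay expects.

## SV (SypHy) analysis

Synapses are detected on the NH4+ maximum projection, measured in 4×4
ROIs, and kept when non-mobile with an NH4+ peak above the criterion. A
synapse is *silent* when its stimulation-window peak fails the
criterion. The fusion fraction is the ratio of stimulation peak to NH4+
peak ΔF/F0 — invariant under multiplicative gain of the raw movie, as
are all ΔF/F0-derived quantities. The half-decay time runs from the
stimulation peak to the first crossing of half the peak-above-baseline
level, linearly interpolated between bracketing frames; traces that
never reach half are flagged censored (NaN).

Peaks are raw maxima without smoothing. This makes the per-synapse
fusion fraction upward-biased at low SNR (the maximum of signal + noise
over a window exceeds the signal); at trace SNR ≳ 5 the mean recovery
stays within 10%.

## DCV (NPY-pHluorin) analysis

*Events.* Candidates are puncta that appear after the first train:
the post-stimulus segment (first train → NH4+ start) is smoothed with a
3-frame running mean, max-projected, and the baseline *mean* image
subtracted. Appearance detection on this difference image uses a
5-robust-SD threshold — stricter than 3 because the projection is a
maximum over hundreds of frames. Each candidate gets a 3×3 ROI and is
kept iff its peak ΔF/F0 in the post-stimulus segment passes the 3-SD
criterion; the onset is the first supra-threshold frame; events inside
the NH4+ window are never counted. Event duration is the run of
consecutive supra-threshold frames from onset times dt.

*Pool.* Puncta are counted on the NH4+ maximum projection. A punctum
may hold several vesicles (diffraction limit), so the corrected pool is
`Σ max(1, round(I / I_modal))`, rounding to the nearest integer with a
floor of one vesicle. The modal intensity is the mode of a Gaussian KDE
over punctum intensities with Silverman's rule-of-thumb bandwidth
`0.9 · min(SD, IQR/1.34) · n^(−1/5)`; the IQR term keeps the estimate
sharp for multimodal intensity distributions, where an SD-only factor
oversmooths and pulls the mode off the single-vesicle peak. Fusion
probability is 100 × events / corrected pool.

*Synaptic classification.* An event is synaptic when strictly more than
50% of its ROI pixels lie on true pixels of the synapse-marker mask.

*Train assignment* maps each event to the last train onset at or before
its onset; the histogram conserves events and the cumulative fraction is
normalized to the event total.

## Axonal influx (kymographs)

The kymograph samples the movie along a polyline at 1-px arc length,
averaging 3 px perpendicular to the path (configurable); row 0 is the
soma-side end. Per frame, peaks above `median + 3 × robust SD` of the
kymograph are refined to sub-pixel position by parabolic interpolation
and linked to the nearest active track within a maximum jump of 7 px per
frame (≈ 2.8 µm/s at the default calibration — above the fastest
expected cargo so that noise jitter on a 2-µm/s particle cannot break
its track), tolerating up to 2 missed frames. Tracks shorter than 3
frames are dropped. Velocity is the absolute least-squares slope;
direction is the slope sign. The influx counts tracks whose first
detected point lies within 3 px of the soma-side end, per minute; a
punctum is counted once per track segment.

## Golgi trafficking kinetics

The Golgi-region trace is the mean intensity inside the Golgi-marker
mask per frame, optionally minus the per-frame median of an
extracellular background mask. The peak frame is found on a 3-frame
median-filtered copy (guarding against single-frame noise peaks); values
at fractional times are linearly interpolated from the raw trace. The
entry slope is a least-squares fit of the peak-normalized (peak = 100)
trace from the biotin frame to the peak, in %/min — exactly 5.0/min for
a linear 0→100 rise over 20 min. Golgi exit at offset t is
`100 × (peak − value(peak_time + t)) / peak`; the reference point can be
the peak (default) or the biotin frame; traces ending before the offset
are censored. The delivery ratio for retrograde-transport readouts is
the mean inside the Golgi mask over the mean of cell-minus-Golgi.

## Static quantification

Neurite length sums inter-pixel steps over the morphological skeleton
(1 per 4-neighbor link, √2 per diagonal; a diagonal is skipped when an
orthogonal pixel already bridges the pair, so corners are not
double-counted). The measure is exact on axis-aligned and 45° paths;
skeletonization may shave about one diagonal step per corner. Puncta
within 2 px of the skeleton count toward the density. Sholl fractions
are percentages per half-open distance bin, normalized over the puncta
within range. Overlap is `100·|A∩B|/|A|` (directional). The masked
Spearman correlation mid-ranks ties and returns NaN with a warning for a
constant channel.

## Electrophysiology

Sweeps are uniformly sampled currents in pA (inward negative), read and
written as two-column delimited text. Charges are left-Riemann sums
(`Σ(I − baseline)·dt`), exact for rectangular test currents and within
0.5% of analytic values for exponential transients at 10 kHz. Baselines
are medians of a pre-stimulus (50 ms) or pre-application (500 ms)
segment. Samples within ±1 ms of a stimulus are blanked by linear
interpolation before integration. The default evoked integration window
is 500 ms after the stimulus (configurable). RRP is the total charge
during the sucrose window in nC; release probability is
100 × evoked pC / (RRP nC × 1000). Mini detection low-pass filters at
500 Hz (zero-phase Butterworth), thresholds at `median − 4 × robust SD`,
merges crossings closer than 3 ms, takes amplitudes from the raw trace
(baseline-referenced peak) and integrates each event until the filtered
trace recovers to baseline. The paired-pulse ratio divides the
baseline-referenced peak of the second response by the first. The RRP
here is the plain charge integral; no exponential-component
decomposition is attempted.

## Statistics

Comparisons pass through two gates at α = 0.05: Shapiro–Wilk per group
and Levene (median-centered) across groups. Both passing selects
parametric tests — Student's t (equal variances, justified by the Levene
gate) for two groups, one-way ANOVA with Tukey HSD for more — otherwise
Mann–Whitney U, or Kruskal–Wallis with pairwise Mann–Whitney and Holm
step-down adjustment. Holm multiplies sorted p-values by `m, m−1, …, 1`
with a running maximum and a cap at 1, preserving input order; it is
hand-implemented (a few lines) and cross-checked against an independent
implementation in the tests, as is Tukey. Every gate p-value is logged
in the decision record. Groups need n ≥ 3. Under the null, the
family-wise error of the full procedure stays at or below α within
Monte-Carlo error (verified over 2000 simulated three-group tables).

## Synthetic-data model

Movies are rendered as isotropic Gaussian spots (σ = 1.5 px, truncated
at 4σ) at integer positions with a hard minimum separation (8 px
default; at this spacing random placement caps near 25 puncta on a
64×64 frame, hence the default of 20), over a constant camera offset
(100 AU) that keeps F0 positive while pHluorin puncta are quenched at
rest. Intensities are integer multiples of a single-vesicle quantum
(100 AU); vesicles per punctum follow a configurable categorical
distribution (default mass 0.5/0.25/0.15/0.1 on 1–4 — a stand-in, as no
measured distribution is available). Noise is optional Poisson shot
noise on the clean signal plus additive Gaussian read noise; bleaching
is a global mono-exponential. One seeded generator drives everything:
identical configs give bit-identical movies and logs.

Protocol defaults mirror the assays: 2 Hz acquisition (dt = 0.5 s); for
DCV movies 16 trains of 50 APs at 50 Hz (1-s trains every 2 s from
t = 30 s — the inter-train interval is the package's choice) with NH4+
at 240–270 s over a 300-s recording; for SV movies a single 100-AP
40-Hz train at t = 30 s, a 30-s post-stimulus decay constant, and NH4+
at 120–150 s. DCV fusion events are a step of one quantum followed by a
single-exponential decay (default τ = 4 s); the event count is
`round(fusion_probability × pool)` assigned to distinct puncta (at most
one event per punctum, since the analysis counts appearing ROIs and two
fusions at one punctum are not separable), with onsets uniform over a
chosen train. During the NH4+ window every punctum shows
`vesicle count × quantum` exactly (before bleach and noise). SV puncta
ramp linearly during stimulation to `hfs_fraction` (default 0.25) of
their NH4+ amplitude, then decay exponentially; a chosen fraction is
silent. Flux movies translate puncta at set speeds through a dark
(photobleached) segment of a horizontal axon, entering on the soma side;
a punctum leaving the segment stops being rendered, as it would merge
with the bright unbleached axon. Static neurons place puncta along a
serpentine skeleton of known length, with soma/Golgi region masks of
exact mean intensity. Current sweeps provide analytic ground truth:
rectangular or bi-exponential sucrose currents with closed-form
integrals, Poisson-timed minis, and evoked transients with a 1.5-ms
synaptic delay (so artifact blanking never clips the response).

**SNR convention.** "SNR 5" in tests means the single-vesicle response
amplitude in the ROI-mean trace is five times that trace's baseline SD.
With the default quantum, offset and 4×4 ROI this corresponds to
Gaussian read noise of SD 10 AU plus Poisson shot noise.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: lateral punctum motion and focus
drift; spatially varying background and autofluorescence; detector gain
variation and saturation; overlapping or clustered puncta below the
separation floor; partial/kiss-and-run fusion; asynchronous release
between trains; multi-channel registration errors. Performance on real
recordings depends on these factors and on parameter choices
(thresholds, σ range, linking jump) that the synthetic conditions do not
stress.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use twenty 64×64×600-frame
movies for event detection, pools of roughly 110–1000 vesicles (60–540
puncta on frames up to 256×256) for the correction, three-track flux
movies, 30-s mini sweeps, and 2000 null tables for the family-wise error
— sizes chosen to exercise each estimator's regime at desk scale.

## Known limitations

* The peak-based fusion fraction and the train-assignment onset are
  biased by frame discretization (±1 frame) and by max-of-noise at low
  SNR.
* The modal-intensity correction assumes the single-vesicle mode is the
  most common punctum class; neurons where most puncta hold several
  vesicles would need an external quantum calibration.
* Track linking is greedy nearest-neighbor; crossing particles can swap
  or split tracks (splits do not double-count influx, which keys on the
  soma-side entry).
* `choose_test` applies one decision tree to all designs; litter is not
  modeled as a random effect.
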