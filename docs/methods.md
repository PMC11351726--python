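# Methods

## Measurement model

A scanning microscope repeatedly images a single line placed across a blood
vessel (line rate 650–850 Hz in typical mouse-ear recordings). Stacking the
lines gives a kymograph: axis 0 is the scan-line index (time), axis 1 the
position along the line (space). A fluorescent cell crossing the line leaves
a streak whose spatial extent is the cell diameter *d* (flowing leukocytes
are approximately round, so the traversing distance equals the diameter) and
whose temporal extent is the traverse time *t*; its velocity is *v = d/t*.
Counting *n* cells over a record of duration *T* in a vessel of lumen
diameter *D* samples the blood volume

    V = π (D/2)² · ave(v) · T

and the circulating concentration is *n/V*. ave(*v*) is the arithmetic mean
of per-event velocities **within one record** (the formula pairs each
record's count with that record's flow), not a pooled average.

Assumptions inherited from the volume formula: plug flow (a single mean
velocity represents the cross-section; no parabolic-profile or pulsatility
correction), cells crossing perpendicular to the line, and a circular lumen
whose width along the scan line equals its diameter. Hematocrit and
plasma-skimming corrections are out of scope.

### Units

Lengths in µm, times in seconds (per-event traverse time reported in ms),
velocities in µm/s. Volumes are computed in µm³ and reported in mL with the
fixed factor 1 mL = 10¹² µm³, avoiding float underflow ambiguity. The
physical length of a *k*-pixel extent is *k* × pixel size (count convention:
a one-pixel object has nonzero size); the simulator and the detector use the
same convention, so extents are comparable to ±1 px.

### Degenerate records

A record with no events reports concentration 0 with `low_confidence=True`
and undefined (NaN) volume, since ave(*v*) is not computable. If only
boundary-truncated events exist, their censored velocities are used as a
fallback and the summary is likewise flagged.

## Thresholding

The detection threshold is fitted on the first record of a session and
re-scaled to each later record's brightness (median ratio, clipped to
[0.5, 2] to stop runaway adaptation on pathological records).

Otsu's criterion is the fitted threshold when its split is plausible.
Kymographs are extremely foreground-sparse (streaks are well under a percent
of pixels), and under such class imbalance the between-class variance is
maximized by splitting the *background noise* distribution near its mean —
a known failure mode of Otsu's method, reproducible here on any noisy
simulated record. `fit_threshold` therefore checks the Otsu split: if it
marks more than `max_cell_fraction` (default 2%) of pixels as foreground,
the threshold falls back to a robust background floor, median + *k*·σ with
σ from sigma-clipped MAD and *k* = 3.5. The floor detects cells down to
SNR ≈ 4 while admitting ≈ 2×10⁻⁴ false pixels per pixel, which the minimum
component area (below) suppresses. On noise-free or well-balanced images
the Otsu split is kept. Background statistics are computed on a
deterministic pixel stride for large records; this changes estimates by
far less than one intensity quantum.

## Detection

Pixels strictly above threshold are 8-connected labeled (fast cells run
diagonally in a kymograph); components smaller than `min_area_px = 4`
pixels are discarded as shot noise. Per component: *d* = spatial bounding
box extent × pixel size, *t* = temporal extent ÷ scan rate, *v = d/t*,
per-channel mean/max intensity, and a `truncated` flag when the component
touches the first or last line. No declumping is attempted: overlapping
streaks count as one event, and the simulator quantifies the resulting bias
(negligible below ~1% pixel fill). Truncated events are **counted** in *n*
(their existence is evidence of a cell) but **excluded** from ave(*v*)
(their traverse time is censored); both policies are configurable.

The mapping of the two bounding-box axes is itself a choice: the default
takes *d* from the spatial axis (the extent along the scan line, in µm) and
*t* from the temporal axis, consistent with reading the traversing distance
of a round cell as its diameter. The fully transposed reading — for records
stored space-major, or to explore the alternative axis interpretation — is
obtained by loading with `read_kymograph(..., transpose=True)`; it is not
endorsed as a measurement convention.

## Vessel diameter

The dye channel's lumen/outside split is well balanced, so plain Otsu
applies. On each line the longest contiguous above-threshold run is the
lumen cross-section; *D* is the median run length across lines × pixel
size, with `px_bounds` anchored at the median run start so that
*D* = width(px_bounds) × pixel size holds exactly. The median over tens of
thousands of lines is insensitive to line subsampling (`line_stride`), which
the long-scenario runners use for speed. Streaks inside the lumen do not
affect the longest run, so the measurement is invariant to traffic.

## Two-color gating

The antibody channel contributes intensities at the positions of
reporter-detected events; it never drives primary detection. The reference
instrument gates on single-stained beads, which has no software equivalent,
so the default gate is background mean + 3 SD measured over in-lumen,
non-cell pixels (event boxes dilated by 3 px before masking), with a
fixed-threshold override. MFI is the background-subtracted mean event
intensity, floored at zero. Antibody-only cells (reporter-negative) are
recovered by a secondary detection pass on the antibody channel, restricted
to the lumen and matched against primary bounding boxes; they are flagged
`source_channel="antibody"` in the dot-plot table.

## Simulator

The generator inverts the concentration model: arrivals are Poisson with
rate λ = C·π(D/2)²·mean(v)·10⁻¹² per second (volumetric flux ×
concentration), with mean(v) the truncated-normal mean. Each cell draws
*d* and *v* from truncated normals (rejection at ≤ 0) and renders as a
filled ellipse with axes *d*/pixel-size (spatial) and (*d/v*)·scan-rate
(temporal) at a uniform lane inside the lumen, intensity flat at the
channel level. The ellipse is unioned with its equatorial row and column so
the rendered bounding box equals the lattice span of the analytic extents
exactly; lattice counting then bounds the rendered extent within ±1 px /
±1 line of the analytic value, which is what the detection-oracle tests
assert. Arrivals are drawn in a ±max-traverse-time margin around [0, T] so
boundary truncation occurs naturally. Gaussian read noise (clipped at 0) is
the default noise model — the simplest model that exercises thresholding;
SNR = (cell level − background)/noise SD. An `avoid_overlap` mode redraws
placements that would collide (used by oracle tests that require
non-overlapping streaks).

Default parameters are the study conditions of resting mouse-ear
recordings: D = 40 µm, T = 120 s, 750 Hz, 0.6 µm/px, C = 1.31×10⁵ /mL,
v ~ N(1063, 357²) µm/s, d ~ N(6.6, 1.4²) µm, SNR 5, antibody-positive
fraction 0.208 in two-color mode.

What the simulator does **not** emulate: optical PSF blur, photobleaching,
Poisson shot noise, autofluorescence structure, cell rolling/adhesion,
radial velocity profiles (beyond an optional sensitivity mode), or vessel
wall motion. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to every property of
real recordings.

## Statistics

Pearson *r* with the least-squares line and the slope F-test
(*F* = t²_slope with (1, n−2) df; p from the t distribution, identical for
*r* and *F*), and the unpaired two-sided t-test (Student/pooled by default,
Welch optional). Degenerate t-test inputs are defined rather than errors:
zero pooled variance with equal means → (t=0, p=1); perfect separation →
infinite t with p reported at the smallest positive normal float.
Per-timepoint t-tests on longitudinal curves are reported with raw
p-values, no multiplicity correction, and ignore within-subject correlation
— they reproduce the conventional procedure for annotating such curves
without endorsing it. Record-level concentration uncertainty is the exact
(Garwood/chi-square) Poisson interval on the count at fixed volume.

## Problem sizes in the test suite

Validation scenarios that pin physical conditions keep them (20 records at
T = 120 s for SNR-5 recovery; 50 replicates for dispersion; 100 replicates
at ~120 events for two-color coverage; 6 subjects × 9 timepoints × 20
replicates for the time course). Where record length is free, shorter
records and a coarser 0.8 µm / 64 px geometry are used: the time-course
records use T = 60 s, which at the baseline 2×10⁵ /mL still yields ~16
events per record and >90% per-timepoint t-test power at the 2× step, and
the detection-oracle records use T = 30 s (≥100 events across replicates).

## Known limitations

* Concentration is a per-record ratio estimator (n over a volume that uses
  the same record's ave(v)); at low counts it carries a small positive
  Jensen bias, well inside the Poisson noise at default conditions.
* The background-floor threshold assumes a unimodal background; records
  whose background is itself bimodal (e.g. lumen vs tissue in the reporter
  channel) would need the lumen-restricted variant used by the two-color
  secondary pass.
* Merged streaks are counted once; the undercount grows with concentration
  and record fill and is quantified only by simulation.
* The PrairieView-style XML dialect is a tolerant reconstruction
  (scanLinePeriod, micronsPerPixel, linesPerFrame, pixelsPerLine); unknown
  keys are ignored with a warning.
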