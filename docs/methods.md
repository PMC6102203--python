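# Methods

## The measurement problem

A microvessel-on-a-chip assay watches GFP-labelled cancer cells inside a
~100 µm endothelialised channel facing a collagen gel.  Confocal imaging
yields, per time point, a two-channel z-stack: GFP marks the cell bulk (the
nucleus is a dark core, since the cytoplasmic label is excluded there), and
brightfield shows cell edges — but sharp only at the slice where the cell
actually sits.  The pipeline's job is to convert these stacks into per-cell
trajectories and population statistics of transendothelial migration (TEM).

Coordinates are fixed throughout: x perpendicular to the barrier with x = 0
at the gel face (positive toward the collagen), y along the channel, z from
the channel bottom upward.  The field of view is partitioned into *channel*
(x < −40 µm), *barrier* (−40 ≤ x ≤ 0, closed on both edges so boundary
points are countable deterministically) and *gel* (x > 0).

## Focus stacking

For each pixel the vertical GFP profile is built by 3D Gaussian smoothing
(scale Σ, default 1.0) followed by lateral disc averaging (radius R, default
2 px).  The profile's z-argmax — ties resolved to the lowest slice for
determinism — selects the brightfield level; an integer correction ΔZ
(default 0) shifts it when the sharpest edge sits off the fluorescence peak.
Pixels whose peak rises less than a threshold above the background estimate
(median peak value, which makes the selection invariant to constant
intensity offsets) carry no level information and are filled from the modal
foreground level, where the static device structures are sharpest.  The
method is insensitive to all three parameters over a broad range; ΔZ is the
one worth adjusting when edge character matters.

GFP projection is the pixel-wise maximum over z: it preserves the dark
nucleus inside the bright bulk, which nucleus detection needs.  A sum
projection is available behind a flag.

## Registration

Stage drift is estimated per frame as the integer shift (±5 px bound)
maximizing the mean normalized cross-correlation of pillar-corner windows
against frame 0; low-correlation frames are rejected and interpolated from
neighbours.  Sub-pixel registration is deliberately omitted: the nucleus
localization error of segmentation (~2 µm, i.e. above one pixel at 0.8
µm/px) dominates any sub-pixel stage residual.  In the pipeline the
correction is applied to the measured nucleus coordinates (segmentation is
translation-equivariant, so this equals translating the images, without the
border-fill bookkeeping); the image-translation form (`apply_correction`)
exists for composite export.

## Segmentation, nucleus, z

Otsu thresholding of the GFP projection gives foreground; objects below
50 µm² are removed.  Inside each component, dark regions (< 0.6 × component
median, ≥ 20 µm²) seed one marker per nucleus — this is what splits touching
cells — and a marker-controlled watershed on the Sobel gradient of the
brightfield composite draws outlines.  The nucleus centroid is the largest
dark connected region's centroid, falling back (flagged) to the
intensity-weighted mask centroid for degenerate cells.  The cell
z-coordinate is the slice maximizing the summed GFP within the mask (lowest
slice on ties) times the 1.5 µm z-step; the masked *sum* rather than a
single brightest voxel is used for shot-noise robustness (a per-voxel-max
variant sits behind a flag).

## Tracking, behaviour, statistics

Nucleus centroids are linked greedily in ascending-distance order within a
gate of 30 µm per elapsed frame (typical frame displacement is ~10 µm:
0.5 µm/min × 20 min; 3× headroom still excludes inter-cell jumps at the
assay's 10–50 cells per ~413 µm field).  Tracks bridge up to 2 missing
frames; an override table (the stand-in for manual curation) is applied
last and wins.

Region membership is decided by the nucleus position.  A region *visit*
requires ≥ 2 consecutive frames; shorter runs inherit the preceding
accepted visit's label (leading runs inherit the following one).  This
smoothing prevents single-frame flicker at band edges from changing a
trajectory's class.  Behaviour types: Type I if the smoothed sequence ever
reaches the gel (gel entry is irreversible in this system), else Type II if
the final smoothed region is the barrier, else Type III.  The crossing
frame is the first frame that is gel both raw and smoothed, so backfilled
leading frames never backdate a crossing.

Count statistics use `N_av = (Σ_t n_t)/T`: `tot` counts lumen+barrier cells
per frame, `barrier` the barrier band only, and `ext` the cumulative number
of tracks whose crossing frame is ≤ t — the cumulative reading is chosen
because crossings are irreversible, making the ratios monotone and bounded
(a per-frame gel-count variant exists behind a flag).  Velocities are per
consecutive-frame in-plane displacements (x and y only; the 1.5 µm argmax
z-sampling is too coarse for a meaningful z-velocity), attributed to the
region at the interval's start.  Cross-sample pooling uses
`w_i = n_i/σ_i²` with `n_i` the number of *cells* of the sample,
`mean = Σw_i v̄_i/Σw_i`, `error = 1/√Σw_i`.

Hot spots: crossing (y, z) positions on the accessible barrier plane
(150 × 100 µm²) are smoothed with a fixed-bandwidth Gaussian KDE (default
10 µm); local maxima are candidates, and significance comes from n_null
(default 999) uniform redistributions of the same number of events, ranking
each candidate against the null distribution of *maximum* grid densities.
The max-statistic makes the family-wise false-positive rate under a uniform
pattern at most α (default 0.05) by construction.  This Monte-Carlo
formalization replaces visual hot-spot identification.

## Permeability

With `I_b` the pre-perfusion background, `I_1` the intensity immediately
after perfusion and `d` the vessel diameter (default 100 µm),
`P = (dI/dt)/(I_1 − I_b) · d/4` in cm/s, with the slope from OLS over the
analysis window and its SE propagated through the same scale factor.  The
default window is the first 15 min: beyond that the confined gel chamber
violates the perfect-sink assumption.  The estimator is invariant under
affine intensity rescaling with matching `I_b`.  The generator and the
estimator share this transport law, so correctness is established by round
trip; agreement with any particular instrument pipeline is not claimed.

## The synthetic-microscopy generator

The generator emulates the assay's study conditions: 120 µm lumen + 40 µm
barrier + 60 µm gel margin in view (x from −160 to +60 µm, matching the
occupancy-map extents), ~413 µm length, 0.8 µm pixels, 67 slices at 1.5 µm,
45 frames at 20 min, 10–50 cells.  Cells are ellipsoids (radius 8.5 ± 1.2
µm) with Gaussian-blurred GFP bodies, a dark nucleus cylinder (radius 3.5
µm, offset up to ~2.5 µm from the centre) and an axial Gaussian intensity
falloff; brightfield renders a dark edge ring blurred with
σ = σ₀ + k·|z − z_cell| (the simplest model reproducing
sharp-only-in-focus edges) plus static dark pillar rectangles whose corners
serve as fiducials.  Noise is Gaussian read noise plus a Gaussian
approximation of photon shot noise.  Stage drift is a bounded random walk
(≤ 5 px).

Motion is a persistent random walk at frame resolution with region-dependent
mean speed (defaults: the microvessel-system values 0.52/0.51/0.50 µm/min
for channel/barrier/gel; a reference-system preset 0.57/0.45/0.45 is
provided), gamma-distributed step lengths (CV 0.3) whose mean is exactly
speed × 20 min, a constant gravity drift in z with a reflecting floor, and
stochastic barrier crossing: a cell whose nucleus is within 12 µm of the
gel face crosses with probability `p_cross_per_frame` per frame,
irreversibly.  Wall handling retries directions deterministically
(golden-angle rotations) instead of shortening steps, so measured
per-interval speeds are unbiased by confinement; the barrier constraint is
applied to the *nucleus*, which is the tracked point.  Separate
fixed-consumption RNG streams drive crossing decisions and motion, so
calibrating the crossing probability perturbs nothing else — the realized
ground-truth ratio is then a clean step function of p and can be calibrated
by bisection on ground truth alone.

Two study-condition calibrations are prescribed for ratio benchmarks: the
seeding proximity to the barrier sets the barrier-occupancy fraction
`N_av-barrier/N_av-tot` (the published ratios imply ~0.21; uniform seeding
over the lumen gives ~0.25 — in a rounded lumen cells settle toward the
channel axis, away from the curved side wall, so the seeding edge is the
physically meaningful knob; the cell count cannot move this fraction since
numerator and denominator both scale with it), and `p_cross_per_frame` sets
the realized `N_av-ext/N_av-barrier`.  Both are solved on ground truth
only, never on pipeline output.

What the generator does *not* emulate: physically accurate point-spread
functions, cell shape change and protrusions, mitosis, cell entry/exit
along the channel, endothelial biology.  Passing tests therefore establish
that the pipeline recovers what this forward model encodes — geometry,
counts, kinematics, crossing events — not that it handles every artefact of
real recordings.

## Problem sizes and numerical choices

Benchmarks use the full study-condition frame size (516 × 275 px, 67
slices).  The segmentation benchmark uses 30 independent single-frame
fields of 3–10 cells so every detection can be matched to its ground-truth
mask unambiguously; the ratio benchmark runs the complete image→stats chain
on 6 samples of 45 frames; velocity pooling uses the generator's
ground-truth tracks through the same velocity/pooling code path, since it
validates the weighted-average formulas rather than segmentation (which the
other benchmarks cover).  Frames are rendered on demand and never held as a
full 4D array.  All argmax tie-breaks are lowest-index; all stochastic
components derive from a single seed; reruns are byte-identical.

## Known limitations

- Overlapping cells without separable dark nuclei merge, undercounting
  `N_av-tot` by a few percent at the default density.
- Crossings in the last frame of a series are suppressed by the 2-frame
  visit rule (negligible weight in time-averaged counts).
- Automated linking replaces the original manual tracking; its accuracy is
  established on the synthetic regime only, and the override table exists
  precisely for curating real data.
- The permeability module takes a pre-extracted intensity series; ROI
  extraction from 2D images is out of scope.
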