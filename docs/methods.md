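# Methods

## Pipeline model and assumptions

The pipeline assumes a fixed-geometry imaging deck: the three cameras view
the same tray from effectively the same axis, so a single resize-to-width
plus integer shift relates any two sensor frames. All cross-sensor
correspondence is handled by transforming *coordinates* of the FLUO-derived
mask; sensor images are never resampled, so every intensity that enters a
statistic is a genuine 8-bit sensor value. The segmentation model assumes
that chlorophyll fluorescence separates plant from substrate by brightness
alone — one global threshold, no local adaptation — which holds when the
substrate is non-fluorescent (mulched pots, peat pellets) and breaks down
under algal growth, which is why an optional minimum-region prefilter
exists (off by default; the physical fix on the platform is mulch).

### HSB convention

All HSB channels live on a 0–255 scale: brightness is exactly
`max(R, G, B)`, saturation and hue follow the standard HSV definitions
with hue scaled so 360° ↦ 256 units (hue wraps at red). Channels are kept
as *floats*; quantizing hue to 8 bits would cost up to ±3 RGB units on
inversion, while the float representation round-trips 8-bit RGB within ±1.
The segmentation threshold (`B > 25 + c`, strict) and the 65-bin hue
classification (`class = ⌊h·65/256⌋`, half-open bins `[i·256/65,
(i+1)·256/65)`) are both defined on this scale; the bin rule fixes the
edges explicitly because 256/65 is not an integer.

### Digital-plant selection

Region labeling defaults to 8-connectivity (contour-tracing labelers are
conventionally 8-connected); 4-connectivity is available. Filters are
strict inequalities: area `> min_area` (1000 px at full scale) and
centroid-to-center distance `< max_center_dist` (300 px). Among qualifying
regions the nearest wins, ties break by larger area then smaller label id.
Absence (soil-only pot, failed germination) is a value, not an error. In
the orchestrated pipeline a region may be claimed by only one pot — the
one whose center it is nearest — because when pots sit closer together
than the distance cap, a neighbour's rosette would otherwise stand in for
an empty pot. Merged rosettes spanning two pots are not modelled; the
generator keeps pots physically disjoint, as trays do.

### Registration

Transforms are resize-to-width `W_r` (2900 for VIS, 380 for NIR,
proportional height) plus shift `(dx, dy)` = (−290 + a, −122 + b) or
(−30 + a, −12 + b). The mask is carried into the resized frame as a dense
nearest-neighbour resize (the footprint a resized mask *image* would
have), then each resized coordinate `(u, v)` reads the target at
`(u − dx, v − dy)`; out-of-frame positions are counted, not read. The
dense-footprint reading matters in the upscaling direction (FLUO → VIS,
×~2.09): mapping mask coordinates one by one would sample only ~23% of
the plant's VIS pixels and could not satisfy a ≥0.95 IoU round trip.
Rounding is half-away-from-zero, applied once per coordinate. The sign
convention (subtracting the negative shifts when indexing the unshifted
target) is pinned by the synthetic round-trip test, not by convention
alone.

### Color-class clustering

Profiles are percentages, so the classifier is invariant to rosette size.
The Ward variant is the classic Lance–Williams update applied to the
supplied unsquared Euclidean distances. It is computed by feeding
`sqrt(D)` to a standard Euclidean-Ward linkage and squaring the merge
heights — algebraically identical, since the standard implementation
returns `sqrt(LW(y²))` for input `y`. The squared-distance (Euclidean
Ward) variant sits behind `squared_distances=True`. The tree is always cut
into exactly two groups (removing the final merge). Mapping groups to
labels is this package's own rule, needed for a reusable classifier: the
group centroid with more summed percentage over the green hue window
(hue 57–113, ≈80°–160°) is healthy; ties fall back to the brown window
(hue 7–56), and identical centroids are reported as degenerate rather
than guessed. Both windows are config constants chosen from hue geometry
and validated on synthetic cohorts only.

### NIR index

`Q3` is the linear-interpolation 75th percentile (position
`1 + 0.75(n−1)` on the sorted list) — the convention of mainstream
statistical environments; for plant-sized pixel counts the alternatives
differ by under one intensity unit, but a single definition is fixed for
reproducibility. The upper quartile is deliberately insensitive to the
minority of mask-edge pixels that fall on soil after registration. The
index is `100·Q3/Q3_base` with a per-experiment base day shared by all
samples. The base day is the earliest whose mean absolute relative cohort
change over the next two measurements is ≤ 2% (both the tolerance and the
two-measurement lookahead are configurable); if none qualifies the first
day is used with a warning. The stress call is strict: index > 120 ⇒
stressed, ≤ 120 ⇒ non-stressed.

### Statistics

The goodness-of-fit null for an agreement record (m matches of n) is an
equal split: χ² = (2m − n)²/n, df = 1, no continuity correction, upper-tail
p (equal to `erfc(√(χ²/2))`). This null exactly regenerates every printed
p-value of the published validation tables from their printed percentages
and cohort sizes (n = 50 and n = 47), which is the justification for
adopting it. Percentages round half away from zero (83 for 39/47). The
area test is Welch's two-tailed t-test; the survival test is the
classical CMH statistic over 2×2×K tables with continuity correction on
by default (the named environment's default), switchable. For a single
stratum the uncorrected CMH equals (N−1)/N times the Pearson statistic —
the tests assert this exact relation rather than treating the two as
interchangeable. No multiple-testing correction is applied; per-day tests
are reported raw, as in the validation design.

## Synthetic study conditions

The generator's defaults are the fixed study conditions, not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| healthy hue | 85 ± 5 (0–255) | mid-green leaf color |
| stressed hue trajectory | 85 → 30, linear over deficit days | browning of wilted tissue |
| FLUO brightness plant / soil | 120 / 10 | strong fluorescence contrast |
| NIR baseline / soil | 100 / 40 | mid-scale leaf reflectance |
| stressed NIR drift | +25% by final deficit day | the ≥20% rise seen in stressed cohorts |
| control NIR drift | ≤ +2% | quiet well-watered baseline |
| NIR noise sd | 1 intensity unit | sensor-level noise |
| VIS/FLUO channel noise sd | 2 | mild acquisition noise |
| DAS schedule | (20, 21, 22, 26, 28), deficit after 22 | two quiet measurements after the base day, mirroring the homogeneity condition |
| geometry | 1/4 sensor scale | keeps scenes fast; full scale via `scale=1` |

Scenes are rendered into each sensor by the *inverse* registration
transforms from a common FLUO-frame world, so the pipeline's forward
transforms are exercised non-circularly; ground-truth masks are analytic
rosette shapes rasterized per sensor. At 1/4 scale all platform constants
scale with the geometry, and the shift constants snap to whole pixels —
fractional shifts would introduce a systematic half-pixel offset between
ground truth and forward transfer that the full-scale platform does not
have. Rosette radii are derived from the achievable grid spacing by a
short fixed-point iteration so neighbouring plants can never touch.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: leaf architecture and self-occlusion, specular
soil highlights, algae beyond simple bright speckles, moisture gradients
across a tray, sensor vignetting or lens distortion, and rosettes merging
across pots. Synthetic recovery rates (100% at the design separations)
are a consistency check of the implementation at the stated conditions,
not a field accuracy claim.

## Problem sizes

Routine tests use 6–12 plant trays; the classifier-recovery checks use
48-plant cohorts over 5 timepoints and 20 seeds, and the registration
round trip uses 6-plant large-rosette trays over 20 seeds — sizes chosen
so the whole suite and the acceptance script each run in well under a
minute of compute apiece while keeping per-cohort counts (n = 48) at the
scale of one experimental tray batch.

## Known limitations

* The camera-to-tray geometry that produces theoretical pot centers is
  installation-specific; centers are user-supplied layout data.
* The two-group cut is forced even when no stress exists, so early-day
  cluster agreement is essentially arbitrary — expected behaviour, visible
  in the worked example.
* The CMH stratification (by protocol, by line, …) is the caller's choice;
  the function accepts arbitrary 2×2×K input and does not guess.
* `c`, `a`, `b` default to 0; on a real installation they must be
  calibrated before the registration constants hold.
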