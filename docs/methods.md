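# Methods

## Scope and model

`myoscreen` quantifies myoblast-to-myotube differentiation from two-channel
fluorescence plates: a myotube-marker channel (TnT/FITC-like) and a nuclear
channel (DAPI-like), acquired as 36 non-overlapping fields per well of a
96-well plate.  The pipeline is: threshold the marker channel to outline
myotubes, detect size-gated nuclei on the nuclear channel, overlay the
outlines on the nuclei to decide which nuclei are myotube nuclei, measure
per-myotube morphometry, collapse to per-well summaries, and run factorial
statistics across treatment wells.  A synthetic renderer with exact
per-object ground truth stands in for raw screen images, which are not
publicly available for this assay class.

## Synthetic plate generator

**Shape model.**  A myotube is a 2-D capsule (stadium): a rectangle of
width B capped by two semicircles, with end-to-end length L.  The capsule
is the one elongated shape family with closed forms for everything the
pipeline measures —

- area `A = L·B − B² + π(B/2)²`
- perimeter `P = 2(L − B) + πB`
- maximum Feret diameter `L`, minimum Feret diameter `B`

— so every rendered object carries an analytic oracle.  Branched or curved
myotubes are deliberately not modelled (see Limitations).

**Condition presets.**  Three presets encode the per-condition morphology
of the assay's reference conditions as truncated normal distributions
(truncation at 0.1·mean guarantees positivity; only mean and SD are
specified by the source distributions):

| parameter | vehicle | ethanol (100 mM) | rapamycin (100 nM) |
|---|---|---|---|
| length µm (SD) | 178 (11.3) | 147 (13) | 117 (6.86) |
| breadth µm (SD) | 46.2 (5.3) | 32.1 (2.33) | 30.0 (3.29) |
| nuclei/myotube (SD) | 6 (1) | 4 (1) | 3 (1) |
| myotube nuclear area µm² (SD) | 133 (3.77) | 140 (3.25) | 140 (3.42) |
| TnT− cell nuclear area µm² (SD) | 140 (7.37) | 164 (8.81) | 169 (9.78) |
| myotubes / field | 4 | 4 | 4 |
| TnT− cells / field | 137 | 103 | 84 |

Nucleus counts are rounded normal draws clipped to ≥ 1; nucleus areas are
truncated below at 4 px² so every nucleus survives rasterisation.  The
per-field object counts are fixed (not Poisson) to keep well-to-well
variance driven by morphology rather than by count noise.  They were chosen
once so the expected fusion index (assigned/total nuclei) lands at each
condition's reference value — vehicle 4·6/(24+137) = 14.9%, ethanol
16/119 = 13.4%, rapamycin 12/96 = 12.5% — independent of field size.
Marker intensities (325/438/344 units/px, 10% SD) put integrated
intensities at the default calibration in the reference range with the
correct vehicle > ethanol > rapamycin ordering, which is carried by area.

**Placement.**  Myotube capsules are rejection-placed with their surfaces
at least `min_separation` (default 6 µm) apart, because merged myotubes
would confound the count-recovery oracle (real outline-based analysis also
cannot split touching myotubes).  Nuclei are placed uniformly inside their
capsule, discs fully interior, non-overlapping; marker-negative cell
nuclei go anywhere outside every capsule.  Each level of the sampler
retries a bounded number of times and then restarts the layout; a field
that still cannot be packed raises `PlacementError` rather than silently
dropping objects.  Capsules may clip the field border (flagged in ground
truth) unless `interior_only` is set; nuclei are always fully in-field.

**Rendering.**  Pixel (r, c) is centred at ((r+0.5)·s, (c+0.5)·s) for
pixel size s.  Objects are rasterised by pixel-centre membership, channels
start at `background_level` (default 100), capsules add their marker
intensity, nuclei add `nuclear_intensity` (default 3000) on the nuclear
channel; Gaussian blur (σ = 1 px) then additive Gaussian noise
(SD = 20) emulate optics and camera, and the result is clipped to uint16.
Defaults: 1392×1040 px fields at 0.65 µm/px (a typical 10× CCD geometry;
the calibration is a configurable assay parameter recorded in the output
metadata, not a measured constant).  Plates are bit-reproducible: each
field draws from an independent child stream spawned from the plate seed.

## Segmentation

Marker regions are connected components (8-connected by default) of the
thresholded marker channel, hole-filled, gated at `marker_min_area`
(default 200 µm²).  The default threshold is per-field Otsu — robust to
plate-level intensity drift and to the fact that instrument thresholds for
such assays are never published — with a fixed threshold available for
bit-exact tests.  Nuclei are detected the same way and gated by
`nucleus_min_area` (default 40 µm², configurable; the real assay's cutoff
is an unpublished instrument setting) and optionally `nucleus_max_area`.
Connected nuclear components larger than 1.5× `nucleus_typical_area`
(default 140 µm²) are split by watershed on the distance transform with
peak markers: two minimally overlapping nuclei always cover slightly less
than twice a single one, so a 2× trigger would miss exactly the clumps the
split exists for, while singles vary only a few percent around typical and
never trigger at 1.5×.  Objects touching the field border are kept for
counting, fusion-index and intensity purposes but flagged and excluded
from per-object morphometry means, since clipped shapes bias length and
breadth downward and non-overlapping fields cannot be stitched.

## Morphometry

Per region: area = pixel count × s²; integrated intensity = sum of raw
marker values over the region (no background subtraction by default);
length and breadth = maximum and minimum Feret (caliper) diameters of the
convex hull of the region's pixel-corner cloud, computed by rotating
calipers (max = largest hull-vertex distance; min = smallest flush-edge
width).  Calipers are rotation-invariant and oracle-testable against a
brute-force 720-angle projection sweep, unlike skeleton-based length.
Perimeter is the length of that same convex-hull polygon: on rasterised
convex shapes it is exact for axis-aligned rectangles and within ~1% for
capsules at any orientation, whereas boundary tracing (pixel-edge or
marching-squares sub-pixel contours) overestimates smooth oblique
boundaries by up to ~8% from staircase artefacts.  For strongly concave
regions the hull perimeter is a rubber-band lower bound — a documented
limitation, acceptable for the near-convex shapes this assay measures.
A single-pixel region reports length = breadth = s and perimeter = 4s by
convention.  Doubling s doubles lengths and quadruples areas exactly.

Nuclei are assigned to myotubes by centroid containment: a nucleus belongs
to region k iff its centroid pixel lies in region k.  This matches the
overlay definition ("nuclei present within the outline"), gives every
nucleus a unique owner, and is unambiguous for nuclei straddling the
outline.  Marker-positive regions with fewer than `min_nuclei` (default 1)
assigned nuclei are not called myotubes; the threshold is exposed because
the assay literature states none.

## Aggregation

Per well: counts over all myotubes; morphometry means over non-border
myotubes; fusion index MFI = 100 × assigned / total detected nuclei;
undifferentiated-cell count = unassigned nuclei (marker-negative cells are
mononucleated, so in this pipeline the "all nuclei" and "nuclei of
scored cells" denominators coincide).  Wells with no myotubes report
missing morphometry means (never zeros) so downstream ANOVA is not biased
by failed wells; MFI is missing only when no nuclei were detected at all.
The replication unit for statistics is the well.

## Plate statistics

Two-sample t is pooled-variance Student by default (Welch by flag).
One-way ANOVA uses the closed-form between/within mean-square ratio with
Tukey HSD (studentized range) pairwise comparisons.  Two-way ANOVA fits
`y ~ A*B` with type-II sums of squares — the conventional choice absent an
interaction-first hypothesis, and identical to the classical closed form
on balanced designs (verified to 1e-8 relative).  Every cell of the design
must hold ≥ 2 wells; an empty cell makes the interaction inestimable and
raises.  Post-hoc cell comparisons are corrected by Bonferroni
(min(1, m·p)), Benjamini–Hochberg step-up, or Tukey HSD; α = 0.05
throughout.

## Benchmark studies and their sizes

`myoscreen.benchmarks` fixes the study sizes used by the acceptance
machinery; these are the package's own choices balancing statistical
resolution against a few minutes of single-core runtime:

- **Acquisition arithmetic** — a full 96-well × 36-field plate on 64×64 px
  stub fields (a miniature preset), counting 3,456 written images per
  channel.
- **Morphometry oracle suite** — 3 rectangles + 12 random capsules at
  1 µm/px, reporting worst-case area/perimeter error vs the closed forms
  and Feret error vs the 720-angle sweep.
- **Ordering benchmark** — 24 wells (8 per condition) × 4 fields at
  512×512 px, 1.0 µm/px, default blur/noise: per-condition well-mean
  morphometry and MFI, strict vehicle > ethanol > rapamycin ordering, and
  object-count recovery vs ground truth (within 5% over 96 fields).
- **Recovery benchmark** — 12 wells × 2 fields at 768×768 px, 0.5 µm/px,
  camera-noise-free: fraction of unclipped myotubes whose measured
  length, breadth and area all fall within 3% of analytic truth.  The
  finer calibration is used here because any pixel-corner caliper carries
  a ~1-pixel positive bias; at 1 µm/px that alone is ~3–4% of a 30 µm
  rapamycin breadth, i.e. the benchmark would measure rasterisation
  granularity rather than pipeline fidelity.
- **Statistics calibrations** — fusion-index 2×2 cells at the reference
  scale (control 14.9, ethanol 13.5, GSI 16.9 with complete rescue; SDs
  1.26 / 2.12 for no-ethanol / ethanol cells), n = 24 wells per cell.
  Type-I error of the interaction test over 1,000 additive-null
  simulations; power at p < 0.001 for the rescue interaction over 300
  simulations; closed-form F agreement over 10 random balanced designs.

On the rescue power: the programmed complete rescue is an interaction
contrast of 1.4 MFI points with standard error σ·√(4/n) ≈ 0.62 at these
SDs, i.e. t ≈ 2.3.  The simulation therefore detects the interaction at
α = 0.05 in roughly half of runs and at α = 0.001 in under 15% — a
correct reflection of the operating characteristics at this effect/noise
scale, reported as computed.

## What the synthetic data does and does not show

The generator reproduces acquisition geometry, per-condition morphology
distributions, fusion-index composition, border clipping, optical blur and
additive camera noise.  It does not reproduce: branched/curved myotube
shapes (capsules are convex, so generated areas at matched L×B run larger,
and perimeters smaller, than real tabulated values — ordering across
conditions is preserved but absolute area/perimeter magnitudes are
model-dependent); touching or overlapping myotubes; illumination gradients
(no flat-field correction stage exists, matching the modelled assay);
uneven cell spatial distributions; temporal differentiation dynamics (day
3→7 growth is representable only as distinct presets); photon-limited
(Poisson) noise.  Passing recovery tests therefore demonstrate pipeline
correctness on geometrically ideal, well-separated objects, not
performance on crowded or pathological real images.

## Known limitations

- Caliper length underestimates the arc length of curved myotubes; hull
  perimeter underestimates concave boundaries.
- Touching myotubes are not separated (one region), as in outline-based
  region analysis generally.
- Integrated intensity sums raw values including background (subtraction
  off by default), so its absolute scale is instrument-defined.
- The fusion-index denominator counts all detected nuclei; if a screen
  contains multinucleated marker-negative debris the index shifts.
- Statistics operate on well-level summaries; per-myotube-level inference
  (thousands of pseudo-replicates) is intentionally not offered.
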