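# Methods

## Scope and design

`vesselquant` reimplements, as a tested library, the quantification chain
used in microvessel-on-chip studies: an ImageJ-macro-style preprocessing
pipeline, 2-D skeleton morphometry, an apparent-permeability estimator for
dextran leakage, endpoint-scored leukocyte tracking, and the group
statistics used to compare culture conditions.  Because raw microscopy for
such studies is typically not deposited, correctness is established
against a synthetic phantom generator whose outputs carry exact ground
truth; the generator is first-class, tested code, not a test fixture.

## Preprocessing (imgproc)

The macro order is fixed: maximum-intensity z-projection → outlier
removal → Gaussian smoothing (σ = 2 px) → binarization, with every
parameter recorded in the mask's provenance.  Outlier removal replaces a
pixel with the median of its radius-2 disc neighbourhood only when it
deviates from that median by more than a threshold (default 50 on the
image's native intensity scale — the common despeckle convention; the bit
depth of the original exports is unknown, so the threshold is configurable
and logged rather than hard-coded).  Binarization defaults to Otsu, which
is parameter-free and reproducible; a `fixed:<value>` override exists.
All filtering uses reflective boundary handling so border pixels are not
systematically darkened, which would bias coverage.  Everything runs on
float copies; the mask is the only quantized product.

## Morphometry

Masks are thinned with topology-preserving 2-D skeletonization.  Skeleton
pixels are classified by 8-connected neighbour count (endpoint = 1,
slab = 2, junction ≥ 3); 8-adjacent junction pixels form one junction,
junction clusters bridged by slab runs shorter than 3 px are merged, and
terminal spurs shorter than 5 px are pruned iteratively — all three are
thinning artifacts rather than vessel topology.  Branch length is the
geodesic chain length (1 px orthogonal, √2 px diagonal steps) and is
measured between *node centres*: where a branch ends at a junction
cluster, the distance from its terminal pixel to the cluster centroid is
added, since the traced path stops at the cluster border.

Diameter at a centerline pixel is the wall-to-wall distance through that
pixel: distance to the nearest point of the sub-pixel vessel wall (the
0.5-level marching-squares contour) plus the distance to the nearest wall
point in the opposite direction.  The two-sided sum cancels, to first
order, the up-to-half-pixel offset between the thinned centerline and the
true tube axis that would otherwise bias a nearest-wall-only reading low.
Per-branch means exclude pixels within one local radius of each branch
end, where the junction pool widens and the cap tapers.

The connectivity ratio is junctions/endpoints.  A loop-only network
(endpoints = 0, junctions > 0) returns `inf` and is flagged as maximal
connectivity; an empty graph returns 0 with a flag.

## Permeability

The estimator implements
`P = A_T (I_Tf − I_T0) / (p_v · t · (I_V0 − I_T0))` with all lengths in
cm.  `p_v` is the summed length of the sub-pixel 0.5-level contours of
the vessel mask.  Marching squares was chosen over pixel-edge counting
(which over-reads smooth oblique boundaries by up to √2) and over Moore
chain-coding (which under-reads an axis-aligned square by 4 px); its only
systematic error is a constant ≈1.2 px corner-cut deficit on rectangular
shapes and ≈+1–2 % on capsule-shaped vessels.  `A_T` is the background
pixel count times pixel area.  Intensities are means over the mask
foreground/background of maximum projections, matching the mask's own
derivation.  A series yields per-interval estimates from frame 0; the
report is their mean.  Two assumption monitors flag (never reject)
results: tissue intensity falling below its initial value beyond the
empirical frame-to-frame noise, and total field intensity rising > 5 %
above what tissue gain alone explains (boundary influx).

## Tracking

Detection thresholds the PMN channel and reports intensity-weighted
centroids of components of at least `min_spot_px` pixels.  Linking is
greedy mutual-nearest-neighbour: candidate pairs sorted by distance (ties
by index), each detection used once, links capped at `max_disp_px`;
unmatched detections open new tracks and unmatched tracks terminate, so
the result is deterministic.  Mean speed is total step displacement over
elapsed time.  Fate is scored from the final frame only — mirroring
endpoint scoring of fixed samples — with a contact distance of 2 px
(configurable; no numeric contact criterion exists in the field, so this
operationalization is a declared choice).  Tracking runs in 2-D on
projections; at phantom scale the outputs (speed, fate percentages) are
projection-compatible, but 3-D trajectories that cross in projection
would not be resolved.

## Statistics

Tables are long-format (`experiment_id, device_id, condition,
metric_name, value`).  The device is the replication unit: field-of-view
values are averaged per device before testing.  Normalization to control
divides by the control mean *of the same experiment* (pooled mode exists
but is off).  Cytokine matrices are min–max scaled per cytokine to
[0, 1]; constant rows are emitted as mid-level 0.5 and flagged.  Group
comparisons: one-way ANOVA with Tukey HSD post-hoc when significant;
Welch's t-test for unpaired two-group designs (no equal-variance claim is
warranted) and a paired t-test where the design is paired.  Stars follow
the conventional 0.05/0.01/0.001/0.0001 thresholds.

## The phantom generator

The generator defines the study conditions under which the pipeline is
validated:

* **Networks** are unions of straight tubes; a pixel is foreground iff
  its centre lies within the branch radius of the branch polyline, so
  footprint, area fraction and capsule perimeter are analytically
  checkable.  `random_tree_network` grows side branches at right angles
  off a near-horizontal trunk (±2° jitter), with branch pieces of at
  least 55 px, lengths 70–120 px, and radii drawn from {3.5, 4.5} px in a
  256×256 px field at 1 µm/px.  Three choices here are deliberate
  numerical hygiene rather than realism: branch directions stay near the
  axis grid because the 1/√2 step metric reads up to ~8 % long near
  22.5°; junctions are right-angled because the medial-axis branch point
  of an acute junction is displaced along the parent by about one tube
  radius (a T-junction displaces it by only ~r/4); and radii sit on the
  half-pixel grid, where the rasterized tube width equals the nominal
  diameter exactly (integer radii rasterize to 2r+1 px).
* **Leakage** series use a single perfused vessel (radius 10 px) whose
  perimeter-to-tissue ratio (~90 cm⁻¹) keeps even P = 10⁻⁵ cm/s in the
  linear regime over four 5-min frames; tissue intensity follows the
  constant-flux forward model exactly, the vessel acts as a reservoir at
  I_V0 = 200 against I_T0 = 20 (a.u.), and the generator refuses series
  in which tissue would reach I_V0.  Noise studies use σ = 5 % of the
  contrast.
* **PMN cohorts** place 10 particles (4 intravascular, 3 transmigrating,
  3 extravasated by construction) in a wide vessel (28 px radius, 384 px
  field), with speeds drawn uniformly from 2–8 µm/min (physiological
  crawling speeds) over five 2-min frames.  Paths take exact
  `speed × interval` steps; final positions are placed with a half-pixel
  safety margin inside their fate band, and a per-frame 40 px minimum
  separation (more than two maximal steps) guarantees cohorts never cross
  or swap identities.
* Noise is additive Gaussian clipped at zero; identical spec + seed is
  bit-identical.  An optional thin 3-D mode replicates the 2-D footprint
  across z for projection testing.

What the phantoms do *not* emulate: optical blur (no PSF), photobleaching,
uneven illumination, 3-D tortuosity, touching/crossing particles, and
intensity heterogeneity inside vessels.  Passing the validation suite
therefore demonstrates the correctness of the measurement chain, not
robustness to every real-microscopy artifact.

## Validation studies and their tolerances

`vesselquant.validation` runs the recovery studies end-to-end (the
numbered `analysis/` drivers and `scripts/acceptance.py` wrap them):

* Morphometry, 10 seeded trees, noise-free masks: junction/endpoint
  counts and connectivity ratios exact; coverage exact; **mean branch
  length per field within 5 %** (observed ≤ ~2 %); per-branch diameters
  within 10 % (observed ≤ ~1.5 %).  Individual branch lengths carry an
  irreducible ±6 % worst case from thinning end effects on the shortest
  (55–70 px) pieces — the per-branch maximum is reported alongside, and
  the field-level statistic is the acceptance quantity because it is the
  statistic such studies report.
* Permeability: noise-free inversion of the forward model recovers
  P ∈ {10⁻⁷, 10⁻⁶, 10⁻⁵} cm/s to machine precision (< 1 %); with 5 %
  noise the median relative error over 20 seeds stays well under 10 %;
  the P = 0 null recovers a mean within 2 s.e. of zero over 20 seeds.
* Tracking, 5 cohorts × 10 particles: 100 % correct link assignments,
  speeds equal to the displacement-sum oracle to < 10⁻⁹, fates equal to
  generator truth.
* Preprocessing: every operator equals its dense brute-force counterpart
  on random images (median replacement and projection exact, Gaussian
  within 10⁻⁶ relative).
* Statistics: ANOVA type-I error within [0.03, 0.07] at α = 0.05 under a
  simulated global null (1000 replicates); the Tukey family-wise error
  check uses the studentized-range formulation directly (equivalent to
  Tukey HSD in the balanced case, and ~100× faster than calling the
  model-based implementation per replicate), with the model-based route
  cross-checked on a handful of replicates.

Problem sizes (10 phantoms, 20 noise seeds, 5 cohorts, 1000 statistical
replicates, 48×48 oracle images) were chosen so each study is decisive at
its stated tolerance while the whole suite completes in seconds.

## Known limitations

* Absolute diameters depend on the rasterization convention at the
  half-pixel level; comparisons across pixel sizes are safe, comparisons
  to measurements made with a different diameter convention are not.
* The permeability estimator inherits the constant-flux assumption; it
  under-reads once tissue intensity approaches saturation (the forward
  generator refuses that regime, the estimator flags its precursors).
* Endpoint-only fate scoring cannot distinguish a particle that crossed
  the wall and returned; a per-frame crossing mode exists but is off by
  default.
* 2-D tracking on projections merges particles that overlap in z.
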