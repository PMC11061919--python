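# Methods

`trabkit` measures the 3D microstructure of trabecular bone from CT volumes:
it separates bone from marrow inside a volume of interest (VOI), reduces the
bone phase to a medial skeleton, computes per-voxel thickness/separation/
spacing maps, and summarises each volume by nine structure parameters plus a
contrast-to-noise ratio. A phantom module generates synthetic trabecular
networks with known ground truth and emulates scanner degradation, and a
statistics module implements the paired method-comparison analyses
(correlation, Bland–Altman, paired t-tests) used to validate one device
against another. This note records the models, conventions and numerical
choices, and what the synthetic validation does and does not demonstrate.

## Segmentation

**Automated region growing (ARG).** Bone and background regions are seeded
from the intensity extremes of the VOI (defaults: top 2% of voxels seed
bone, bottom 20% seed background — bone is the bright minority phase).
Growth proceeds in alternating single-sweep turns, bone first: a frontier
voxel joins a region when its intensity lies within `t·σ_VOI` of the running
region mean, where `σ_VOI` is the global intensity SD of the VOI and `t` is
the homogeneity threshold; the mean is updated after each accepted batch. A
voxel claimed by bone in its sweep is unavailable to background (ties go to
bone by turn order). When a full bone+background cycle adds nothing, VOI
voxels claimed by neither region are assigned to the region whose final mean
is nearer (ties to bone), so the two phases partition the VOI.

The procedure is repeated over a threshold schedule — by default 20
geometric steps from `t = 0.05` (very restrictive, deliberately
under-segmenting) to `t = 2.0` (over-inclusive). Each candidate
segmentation is scored by the unweighted mean of the two region
homogeneities, where homogeneity is `1 − σ_region/σ_VOI` clipped to [0, 1]:
scale-free, 1 for a constant region, 0 for a region as heterogeneous as the
whole VOI. The scored regions are the *final* partition, not the grown
regions — scoring grown regions degenerates because a tiny seed region is
trivially homogeneous, which would always select the most restrictive
threshold. The segmentation with the highest combined score wins (first
maximum on ties); the full `(t, bone score, background score)` trace is
retained for inspection. The algorithm contains no randomness: identical
inputs and configuration give identical output.

**Otsu thresholding** is provided as the reference path for high-contrast,
low-partial-volume data (the micro-CT regime): the histogram bin edge (256
bins by default) maximising between-class variance over VOI intensities,
with exact ties — including the plateau across an empty histogram valley,
where every cut yields the same partition — broken toward the lower edge.
Voxels at or above the threshold are bone. On cleanly bimodal volumes the
ARG result coincides with Otsu voxel-for-voxel, which is asserted in the
tests.

## Skeletonization

The skeleton is computed by sequential topology-preserving thinning. A
voxel may be deleted only if it is a *simple point* — deletion changes
neither the 26-connectivity of the foreground nor the 6-connectivity of the
background, decided by the two topological numbers of its 3×3×3
neighbourhood. Before each directional subiteration, border voxels that are
curve isthmuses (two foreground components in the neighbourhood), surface
isthmuses (two background components: the voxel is a one-voxel-thin wall),
endpoints (≤1 foreground neighbour) or isolated are anchored permanently.
Deletion then peels one voxel layer per face direction (z−, z+, y−, y+,
x−, x+), requiring foreground on the opposite side of the deletion axis so
opposite directions erode symmetrically toward the middle. Rods thin to
their mid-curves and plates to their mid-surfaces — both archetypes of
trabeculae keep a meaningful midline, and the number of connected
components of the bone phase is preserved exactly. No branch pruning is
applied; small surface irregularities that survive thinning are counted as
termini, a known sensitivity of the terminus parameter. The kernel is
numba-compiled; the first call in a fresh environment pays a one-time
compilation cost.

## Local thickness and the derived parameters

The thickness model is the maximal inscribed sphere: the value at a voxel
is the diameter of the largest sphere fully contained in the structure that
covers the voxel. Implementation: Euclidean distance transform, reduction
to ridge centres (a centre is dropped when a neighbour's sphere provably
contains its own, a transitive test that preserves coverage), then
painting spheres in descending radius order. A sphere whose centre has
distance-transform value `r` covers voxels within distance `r` and carries
diameter `2r` voxels — a slab `w` voxels thick reads `w` (even `w`) or
`w+1` (odd `w`), accurate to one voxel either way; a truly isolated voxel
is the minimal one-voxel sphere and reads exactly one voxel. The grid
border counts as background, so map values never exceed the spheres the
grid can contain. Values are in mm (`voxels × spacing`).

The parameters, all computed inside the VOI:

| parameter | definition |
|---|---|
| BV/TV | bone voxels / VOI voxels |
| Tb.Th, s(Tb.Th) | mean and SD of the thickness map of the bone phase, over bone voxels |
| Tb.Sp, s(Tb.Sp) | mean and SD of the thickness map of the background phase (edge-to-edge separation), over background voxels |
| Tb.Sc, s(Tb.Sc) | mean and SD of the thickness map of the *complement of the skeleton*, sampled over background voxels — spheres may cross trabecular tissue but are stopped by midlines, so this measures midline-to-midline spacing |
| Tb.Nd | 26-connected clusters of skeleton voxels with ≥3 skeleton neighbours, per mm³ of VOI (clusters, not raw voxels, so thinning artefacts at one anatomical intersection count once) |
| Tb.Tm | skeleton voxels with exactly one skeleton neighbour, per mm³ |
| CNR | (mean intensity on the skeleton − mean background intensity) / SD of background intensity; the pipeline reports ∞ on noise-free synthetic volumes |

Dispersions `s(·)` are sample SDs (ddof = 1) over the same sampling domain
as the mean. By construction Tb.Sc ≥ Tb.Sp on every input (the skeleton
complement contains the background phase). On a plate stack of width
0.2 mm and pitch 1.0 mm at 0.05 mm voxels the pipeline recovers BV/TV
exactly and Tb.Th = 0.200, Tb.Sp = 0.787, Tb.Sc = 0.962 mm — within one,
one and two voxels of the 0.2 / 0.8 / 1.0 mm truth; the residual Tb.Sp/Tb.Sc
deficits come from sphere truncation at the grid faces.

## Phantoms and scanner emulation

Three phantom families with analytic ground truth: parallel plates
(`plate_stack`: BV/TV = w/p, Tb.Th = w, Tb.Sp = p − w, Tb.Sc = p), parallel
circular rods (`rod_lattice`: BV/TV = πw²/4p²), and three orthogonal rod
families (`mixed`), whose intersections give the network genuine nodes;
its BV/TV is taken from the rendered grid because of the overlap terms.
Analytic plate/rod BV/TV matches the rendered grid exactly when the extent
is a whole number of pitches; otherwise the truncated period makes the
rendered fraction deviate, so validation phantoms use aligned extents.
Default intensities are 100 (bone) and 20 (marrow); all parameters except
BV/TV depend only on the binary phase, and CNR is affine-invariant, so
these values are inconsequential.

Degradation emulates a scanner chain: isotropic Gaussian PSF (reflective
boundaries; default σ = 0.6 × target voxel size), resampling to the target
voxel size (block averaging for integer ratios, trilinear otherwise), then
additive Gaussian noise. Devices are characterised by CNR, not noise SD,
so the noise is calibrated by inverting the measured-CNR relation on the
noise-free degraded volume: `noise = sqrt((contrast/CNR_target)² − σ₀²)`,
with contrast and intrinsic background SD σ₀ measured using an Otsu
segmentation and its skeleton. The calibration anchors are the measured
device values 12.57 (micro-CT-like, 32.8 µm), 6.98 (61 µm) and 6.68
(82 µm). Because the noisy volume is re-segmented when CNR is measured
downstream, the realised CNR lands slightly (~10%) below the anchor at
coarse resolutions; the calibration is not iterated.

The multi-resolution experiment uses a `mixed` phantom with width 0.15 mm
and pitch 0.65 mm at a 16.4 µm base grid — trabecular dimensions for which
the coarsest emulated resolution (82 µm) leaves structures only ~2 voxels
wide. In that regime the blur-plus-threshold chain reproduces the known
partial-volume directions: measured BV/TV and Tb.Th increase with voxel
size while node density decreases. With well-resolved phantoms (width ≳3
voxels everywhere) the effect disappears, which is the expected physics,
not a defect.

The 23-specimen in-silico cohort samples rod width uniformly from
0.14–0.24 mm and pitch from 0.75–0.95 mm (2.5 mm cubes at a 25 µm base
grid), delivering each phantom at a micro-CT-like reference (32.8 µm,
CNR 12.57, analysed with Otsu) and an HR-pQCT-like test resolution (61 µm,
CNR 6.98, analysed with ARG). The width ceiling keeps the CNR calibration
feasible: wider rods push the blur-induced background variance above what
the 32.8 µm anchor permits. Everything is reproducible from one seed.

**What the phantoms do not model:** real trabecular networks are
heterogeneous, anisotropic and plate-rod mixed at the local level; marrow
has its own texture; scanners add beam hardening, ring artefacts and
non-Gaussian noise; registration error between paired scans is absent.
Passing the synthetic suite demonstrates that the measurement chain is
correct and direction-faithful under partial volume and noise, not that
accuracy on clinical data will match the phantom tolerances.

## Statistics

Paired per-specimen comparisons of two devices, per parameter:

* **Pearson correlation** with the t-based p-value for r = 0 and a 95%
  Fisher-z interval, `tanh(atanh(r) ± z_{0.975}/√(n−3))` — computable from
  the printed r and n alone, which is how published correlation tables are
  checked.
* **Bland–Altman**: bias = mean difference (test − reference), limits of
  agreement = bias ± 1.96 × sample SD of differences (the conventional
  normal quantile, not a t quantile), and an OLS regression of differences
  on pair means with 95% t-based CIs to expose proportional bias.
* **Paired two-sided t-test** with the CI of the mean difference; the
  paired form is used because both devices measure the same specimens.
  Degenerate inputs (all differences identical) return a zero-width CI,
  with p = 1 when the common difference is zero and p = NaN otherwise.

No multiple-testing correction or normality testing is applied. Report
rounding is 2 decimals.

## Problem sizes and numerical conventions

Validation volumes are 128³ voxels for segmentation recovery, 80³ for
morphometry recovery, a 3 mm cube for the resolution trend and 2.5 mm
cubes for the cohort — sizes at which every structure spans enough voxels
for the stated tolerances while the full suite runs in minutes on one
core. Internal index order is (z, y, x), spacings are millimetres
(micrometres at the CLI), volumes are float64, and every stochastic step
draws from an explicit seed recorded in the provenance file.

Known limitations: thinning anchors can leave locally thick junction
clusters (mitigated by counting node clusters); local thickness is
quantised to the distance-transform values, so sub-voxel width differences
are invisible; Tb.Sp/Tb.Sc are biased low by a fraction of a voxel near
grid faces where spheres are truncated; terminus counts are sensitive to
surface noise by design.
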