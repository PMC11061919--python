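"""Bone/marrow segmentation.

Two routes to a binary bone phase inside a VOI:

* :func:`otsu_threshold` — histogram thresholding by maximal between-class
  variance, adequate when contrast-to-noise is high and partial-volume voxels
  are few (the micro-CT regime).
* :func:`arg_segment` — automated region growing (ARG).  Bone and background
  regions are grown from high/low intensity seeds under a homogeneity
  threshold ``t``: a frontier voxel joins a region iff its intensity is within
  ``t * sigma_VOI`` of the running region mean.  Starting from a very small
  ``t`` (under-segmentation), the procedure is repeated over an increasing
  threshold schedule, and the iteration at which bone and background are
  jointly most homogeneous is selected.

The homogeneity of a region is measured as ``1 - sigma_region / sigma_VOI``
(clipped to [0, 1]) and the two regions are combined by an unweighted mean —
a scale-free score that is maximal for tight regions and symmetric in the
two phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume, MaskVolume

__all__ = [
    "ARGConfig",
    "Segmentation",
    "otsu_threshold",
    "homogeneity",
    "grow_regions",
    "arg_segment",
    "dice",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary grids (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def default_schedule(n: int = 20, lo: float = 0.05, hi: float = 2.0) -> tuple[float, ...]:
    """Geometric threshold schedule in units of the VOI intensity SD."""
    return tuple(np.geomspace(lo, hi, n))


@dataclass
class ARGConfig:
    """Configuration of the automated region growing segmentation.

    Attributes
    ----------
    threshold_schedule : strictly increasing homogeneity thresholds, unitless
        multiples of the global (VOI) intensity SD.  The default sweeps 20
        geometric steps from 0.05 (very restrictive, under-segmenting) to 2.0
        (over-inclusive).
    connectivity : 6 (faces) or 26 (faces+edges+corners) growth neighbourhood.
    seed_quantile_bone : top-intensity fraction of VOI voxels seeding bone.
    seed_quantile_background : bottom-intensity fraction seeding background.
    rng_seed : reserved for seed sub-sampling; the algorithm itself is
        deterministic.
    """

    threshold_schedule: tuple[float, ...] = field(default_factory=default_schedule)
    connectivity: int = 26
    seed_quantile_bone: float = 0.02
    seed_quantile_background: float = 0.20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        sched = tuple(float(t) for t in self.threshold_schedule)
        if len(sched) < 2 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("threshold_schedule must be strictly increasing, length >= 2")
        if any(t <= 0 for t in sched):
            raise ValueError("thresholds must be positive")
        self.threshold_schedule = sched
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        for q in (self.seed_quantile_bone, self.seed_quantile_background):
            if not 0 < q < 1:
                raise ValueError("seed quantiles must lie in (0, 1)")
        if self.seed_quantile_bone + self.seed_quantile_background >= 1:
            raise ValueError("seed quantiles overlap")


@dataclass
class Segmentation:
    """A binary bone labelling of a VOI.

    ``homogeneity_trace`` holds one ``(threshold, bone_score, background_score)``
    triple per schedule entry when produced by :func:`arg_segment`.
    """

    bone: np.ndarray
    voi: MaskVolume
    chosen_threshold: float | None = None
    homogeneity_trace: list[tuple[float, float, float]] = field(default_factory=list)
    #: bone region as actually grown, before unclaimed voxels were assigned
    #: to the nearest region mean (None unless produced by region growing)
    grown_bone: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bone = np.asarray(self.bone).astype(bool)
        if self.bone.shape != self.voi.shape:
            raise ValueError("bone grid and VOI shape mismatch")
        if np.any(self.bone & ~self.voi.data):
            raise ValueError("bone voxels outside the VOI")

    @property
    def background(self) -> np.ndarray:
        """VOI voxels not labelled bone (marrow/background phase)."""
        return self.voi.data & ~self.bone

    @property
    def spacing_mm(self) -> float:
        return self.voi.spacing_mm


def otsu_threshold(volume: ImageVolume, voi: MaskVolume, n_bins: int = 256) -> float:
    """Otsu threshold over the VOI intensities.

    Returns the histogram bin edge maximising the between-class variance,
    with ties broken toward the lower edge.  Voxels with intensity >= the
    returned threshold belong to the upper (bone) class.

    Raises
    ------
    ValueError
        If the VOI is constant (no two distinct intensities).
    """
    if volume.shape != voi.shape:
        raise ValueError("volume and VOI shape mismatch")
    vals = volume.data[voi.data]
    if vals.size == 0:
        raise ValueError("empty VOI")
    if np.ptp(vals) == 0:
        raise ValueError("constant intensity inside VOI; no threshold exists")
    counts, edges = np.histogram(vals, bins=n_bins)
    # cumulative class statistics at every internal edge: class 0 = bins below
    w0 = np.cumsum(counts)[:-1].astype(np.float64)
    w1 = vals.size - w0
    centers = (edges[:-1] + edges[1:]) / 2
    m = counts * centers
    m0 = np.cumsum(m)[:-1]
    m1 = m.sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = w0 * w1 * (m0 / w0 - m1 / w1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    best = int(np.argmax(var_between))  # argmax takes the first (lowest) maximum
    return float(edges[best + 1])


def homogeneity(volume: ImageVolume, region: np.ndarray, voi: MaskVolume) -> float:
    """Homogeneity score ``1 - sigma_region / sigma_VOI``, clipped to [0, 1].

    Standard deviations are population SDs of the intensities.  A constant
    region scores 1; a region as heterogeneous as the whole VOI scores 0.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    sigma_voi = float(volume.data[voi.data].std())
    if sigma_voi == 0:
        return 1.0
    sigma_region = float(volume.data[region].std())
    return float(np.clip(1.0 - sigma_region / sigma_voi, 0.0, 1.0))


_BONE, _BACKGROUND = 1, 2


def _neighbor_offsets(shape: tuple[int, int, int], connectivity: int) -> np.ndarray:
    """Flat-index offsets of the growth neighbourhood on a padded grid."""
    _, ny, nx = shape
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append(dz * ny * nx + dy * nx + dx)
    return np.asarray(offs, dtype=np.int64)


def grow_regions(
    volume: ImageVolume, voi: MaskVolume, t: float, config: ARGConfig | None = None
) -> Segmentation:
    """Grow bone and background regions at one homogeneity threshold ``t``.

    Bone is seeded by the top ``seed_quantile_bone`` intensities in the VOI,
    background by the bottom ``seed_quantile_background``.  Growth proceeds
    in alternating single-sweep turns, bone first: in a sweep, every frontier
    voxel with ``|intensity - region mean| <= t * sigma_VOI`` joins the
    region, and the running mean is updated from the accepted batch.  A voxel
    claimed by bone in its sweep is no longer available to background (bone
    wins ties by turn order).  Growth stops when a full bone+background cycle
    adds nothing; VOI voxels claimed by neither region are then assigned to
    the region whose final mean intensity is nearer (ties to bone).
    """
    if config is None:
        config = ARGConfig()
    if not t > 0:
        raise ValueError("threshold t must be positive")
    if volume.shape != voi.shape:
        raise ValueError("volume and VOI shape mismatch")

    # pad by one voxel so neighbour arithmetic never wraps across faces
    img = np.pad(volume.data, 1)
    inside = np.pad(voi.data, 1)
    shape = img.shape
    flat_img = img.ravel()
    label = np.zeros(flat_img.size, dtype=np.uint8)
    label[~inside.ravel()] = 255  # outside VOI: never grown into

    voi_vals = volume.data[voi.data]
    sigma = float(voi_vals.std())
    tol = t * sigma

    hi = np.quantile(voi_vals, 1.0 - config.seed_quantile_bone)
    lo = np.quantile(voi_vals, config.seed_quantile_background)
    flat_inside = inside.ravel()
    bone_seeds = np.flatnonzero(flat_inside & (flat_img >= hi))
    bg_seeds = np.flatnonzero(flat_inside & (flat_img <= lo) & (flat_img < hi))
    if bone_seeds.size == 0 or bg_seeds.size == 0:
        raise ValueError("empty seed set at the configured quantiles")

    offsets = _neighbor_offsets(shape, config.connectivity)

    sums = np.zeros(3)
    counts = np.zeros(3, dtype=np.int64)
    pending: dict[int, np.ndarray] = {_BONE: bone_seeds[:0], _BACKGROUND: bone_seeds[:0]}
    # per-region marker: voxel already sits in that region's frontier list
    # (avoids sort-based deduplication; each offset chunk is duplicate-free)
    queued = {_BONE: np.zeros(flat_img.size, np.uint8),
              _BACKGROUND: np.zeros(flat_img.size, np.uint8)}

    def claim(r: int, idx: np.ndarray) -> None:
        label[idx] = r
        sums[r] += flat_img[idx].sum()
        counts[r] += idx.size
        q = queued[r]
        chunks = [pending[r]]
        for off in offsets:
            nbk = idx + off
            keep = (label[nbk] == 0) & (q[nbk] == 0)
            nbk = nbk[keep]
            q[nbk] = 1
            chunks.append(nbk)
        pending[r] = np.concatenate(chunks)

    claim(_BONE, bone_seeds)
    claim(_BACKGROUND, bg_seeds)

    def sweep(r: int) -> bool:
        cand = pending[r]
        cand = cand[label[cand] == 0]  # drop voxels the other region claimed
        if cand.size == 0:
            pending[r] = cand
            return False
        mean = sums[r] / counts[r]
        ok = np.abs(flat_img[cand] - mean) <= tol
        accepted, rejected = cand[ok], cand[~ok]
        pending[r] = rejected
        if accepted.size == 0:
            return False
        claim(r, accepted)
        return True

    while True:
        grew = sweep(_BONE)
        grew |= sweep(_BACKGROUND)
        if not grew:
            break

    grown = (label.reshape(shape) == _BONE)[1:-1, 1:-1, 1:-1].copy()

    # unclaimed voxels go to the region whose mean is nearer, ties to bone
    unclaimed = np.flatnonzero(label == 0)
    if unclaimed.size:
        mb = sums[_BONE] / counts[_BONE]
        mg = sums[_BACKGROUND] / counts[_BACKGROUND]
        to_bone = np.abs(flat_img[unclaimed] - mb) <= np.abs(flat_img[unclaimed] - mg)
        label[unclaimed[to_bone]] = _BONE
        label[unclaimed[~to_bone]] = _BACKGROUND

    bone = (label.reshape(shape) == _BONE)[1:-1, 1:-1, 1:-1]
    return Segmentation(bone=bone, voi=voi, chosen_threshold=float(t),
                        grown_bone=grown)


def arg_segment(
    volume: ImageVolume, voi: MaskVolume, config: ARGConfig | None = None
) -> Segmentation:
    """Automated region growing over a threshold schedule.

    Runs :func:`grow_regions` for every threshold in the schedule, scores
    each candidate by the unweighted mean of bone and background
    :func:`homogeneity`, and returns the segmentation of the threshold with
    the highest combined score (first maximum on ties).  The full
    ``(threshold, bone_score, background_score)`` trace is retained.
    """
    if config is None:
        config = ARGConfig()
    trace: list[tuple[float, float, float]] = []
    best_score, best_seg = -np.inf, None
    for t in config.threshold_schedule:
        seg = grow_regions(volume, voi, t, config)
        hb = homogeneity(volume, seg.bone, voi) if seg.bone.any() else 0.0
        hg = homogeneity(volume, seg.background, voi) if seg.background.any() else 0.0
        trace.append((float(t), hb, hg))
        score = 0.5 * (hb + hg)
        if score > best_score:
            best_score, best_seg = score, seg
    assert best_seg is not None
    best_seg.homogeneity_trace = trace
    return best_seg
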