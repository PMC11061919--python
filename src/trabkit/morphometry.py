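"""3D trabecular bone structure parameters.

From a binary segmentation of the trabecular compartment this module
computes the nine structure parameters plus contrast-to-noise ratio that
summarise one volume:

=========  ==================================================================
BVTV       bone voxels / VOI voxels (bone volume fraction)
Tb.Th      mean trabecular width, mm — mean of the local-thickness map of
           the bone phase
Tb.Sp      mean edge-to-edge separation, mm — local thickness of the
           marrow/background phase
Tb.Sc      mean midline-to-midline spacing, mm — local thickness of the
           complement of the skeleton, sampled over background voxels
s(.)       intra-volume dispersion (sample SD) of each local map
Tb.Nd      skeleton intersections (node clusters) per mm^3
Tb.Tm      skeleton free ends (termini) per mm^3
CNR        (mean intensity on the skeleton - mean background intensity)
           / SD of background intensity
=========  ==================================================================

Local thickness follows the maximal-inscribed-sphere definition: the value
at a voxel is the diameter of the largest sphere that fits entirely inside
the structure and contains that voxel.  The skeleton is a one-voxel-thin,
topology-preserving medial representation obtained by sequential thinning
(see :func:`skeletonize`); rods thin to curves and plates to sheets, so the
skeleton is a valid midline/midsurface for both archetypes of trabeculae.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import ARGConfig, Segmentation, arg_segment, otsu_threshold
from .volume import ImageVolume, MaskVolume
from ._thinning import thin_sequential

__all__ = [
    "Skeleton",
    "LocalMap",
    "MorphometryResult",
    "bvtv",
    "skeletonize",
    "local_thickness",
    "tb_th",
    "tb_sp",
    "tb_sc",
    "tb_nd",
    "tb_tm",
    "cnr",
    "analyze",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: CSV column order of a morphometry row, matching the reporting convention.
RESULT_COLUMNS = (
    "BVTV", "Tb.Th", "s(Tb.Th)", "Tb.Sc", "s(Tb.Sc)",
    "Tb.Sp", "s(Tb.Sp)", "Tb.Nd", "Tb.Tm", "CNR",
)


@dataclass
class Skeleton:
    """One-voxel-thin medial representation of the bone phase."""

    voxels: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)

    def neighbor_counts(self) -> np.ndarray:
        """Number of 26-neighbouring skeleton voxels, per skeleton voxel."""
        counts = ndimage.convolve(
            self.voxels.astype(np.uint8), _STRUCT26.astype(np.uint8), mode="constant"
        ) - 1
        counts[~self.voxels] = 0
        return counts


@dataclass
class LocalMap:
    """Per-voxel metric map (mm) defined on a support set."""

    values: np.ndarray  # mm; NaN off support
    support: np.ndarray
    kind: str  # {"thickness", "spacing", "separation"}
    spacing_mm: float

    def sample(self, domain: np.ndarray | None = None) -> np.ndarray:
        """Map values on ``domain`` (default: the full support)."""
        domain = self.support if domain is None else (np.asarray(domain, bool) & self.support)
        return self.values[domain]

    def mean_sd(self, domain: np.ndarray | None = None) -> tuple[float, float]:
        v = self.sample(domain)
        if v.size == 0:
            raise ValueError("empty sampling domain")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd


@dataclass
class MorphometryResult:
    """The nine structure parameters plus CNR for one volume."""

    bvtv: float
    tb_th_mm: float
    s_tb_th_mm: float
    tb_sc_mm: float
    s_tb_sc_mm: float
    tb_sp_mm: float
    s_tb_sp_mm: float
    tb_nd_per_mm3: float
    tb_tm_per_mm3: float
    cnr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bvtv <= 1.0:
            raise ValueError("BVTV outside [0, 1]")
        for name in ("tb_th_mm", "tb_sc_mm", "tb_sp_mm", "s_tb_th_mm",
                     "s_tb_sc_mm", "s_tb_sp_mm", "tb_nd_per_mm3", "tb_tm_per_mm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_row(self) -> dict[str, float]:
        return dict(zip(RESULT_COLUMNS, (
            self.bvtv, self.tb_th_mm, self.s_tb_th_mm, self.tb_sc_mm,
            self.s_tb_sc_mm, self.tb_sp_mm, self.s_tb_sp_mm,
            self.tb_nd_per_mm3, self.tb_tm_per_mm3, self.cnr,
        )))


def bvtv(seg: Segmentation) -> float:
    """Bone volume fraction: bone voxels over VOI voxels."""
    n_voi = seg.voi.n_voxels
    if n_voi == 0:
        raise ValueError("empty VOI")
    return float(seg.bone.sum()) / n_voi


def skeletonize(seg: Segmentation) -> Skeleton:
    """Thin the bone phase to a one-voxel-thin medial representation.

    Sequential topology-preserving thinning: border voxels are deleted in
    six directional subiterations (z-, z+, y-, y+, x-, x+) if they are
    simple points (deletion preserves both foreground 26-topology and
    background 6-topology) and are not already locally one voxel thin along
    some grid axis.  Plates therefore retain their mid-surface and rods
    their mid-curve, and the number of 26-connected components of the bone
    phase is preserved exactly.
    """
    if not seg.bone.any():
        return Skeleton(np.zeros(seg.bone.shape, bool), seg.spacing_mm)
    padded = np.pad(seg.bone, 1).astype(np.uint8)
    thin_sequential(padded)
    return Skeleton(padded[1:-1, 1:-1, 1:-1].astype(bool), seg.spacing_mm)


def local_thickness(structure: np.ndarray, spacing_mm: float) -> LocalMap:
    """Maximal-inscribed-sphere local thickness map of a binary structure.

    For every structure voxel the value is the diameter, in mm, of the
    largest sphere fully contained in the structure that covers the voxel.
    Voxels outside the grid count as background, so the grid border
    truncates spheres.  A sphere centred at a voxel with Euclidean
    distance-transform value ``r`` covers the voxels within distance ``r``
    and carries diameter ``2*r`` voxels: a slab w voxels thick reads w for
    even w and w + 1 for odd w, accurate to one voxel either way.  An
    isolated voxel (no 26-neighbour in the structure) is the minimal
    one-voxel sphere and reads exactly one voxel.
    """
    orig = np.asarray(structure, dtype=bool)
    if not orig.any():
        raise ValueError("empty structure")
    structure = np.pad(orig, 1)  # the grid border counts as background
    dt = ndimage.distance_transform_edt(structure)

    # ridge extraction: drop centres whose sphere is contained in a
    # neighbour's sphere (dt[n] >= dt[c] + |n - c|); containment is
    # transitive, so coverage by the kept centres is preserved.
    keep = structure.copy()
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                d = float(np.sqrt(dz * dz + dy * dy + dx * dx))
                shifted = np.full_like(dt, -np.inf)
                src = tuple(slice(1, None) if o == 1 else slice(None, -1) if o == -1 else slice(None)
                            for o in (dz, dy, dx))
                dst = tuple(slice(None, -1) if o == 1 else slice(1, None) if o == -1 else slice(None)
                            for o in (dz, dy, dx))
                shifted[dst] = dt[src]
                keep &= ~(shifted >= dt + d - 1e-9)
    keep &= structure

    rmax = float(dt.max())
    pad = int(np.ceil(rmax))
    out = np.pad(np.zeros_like(dt), pad)
    centers = np.transpose(np.nonzero(keep)) + pad
    radii = dt[keep]
    flat = out.ravel()
    stride = np.array([out.shape[1] * out.shape[2], out.shape[2], 1])
    cflat = centers @ stride

    # paint spheres in descending radius order, one scatter-max per radius
    order = np.argsort(-radii)
    radii, cflat = radii[order], cflat[order]
    uniq, start = np.unique(-radii, return_index=True)
    start = np.append(start, radii.size)
    ball_cache: dict[float, np.ndarray] = {}
    for k, r in enumerate(-uniq):
        grp = cflat[start[k]:start[k + 1]]
        offs = ball_cache.get(r)
        if offs is None:
            q = int(np.floor(r + 1e-9))
            zz, yy, xx = np.mgrid[-q:q + 1, -q:q + 1, -q:q + 1]
            inside = zz * zz + yy * yy + xx * xx <= (r + 1e-9) ** 2
            offs = (np.stack([zz[inside], yy[inside], xx[inside]], axis=1) @ stride)
            ball_cache[r] = offs
        targets = (grp[:, None] + offs[None, :]).ravel()
        # radii are processed in descending order, so the first write at a
        # voxel is the largest diameter; later (smaller) spheres must not
        # overwrite it
        unpainted = flat[targets] == 0.0
        flat[targets[unpainted]] = 2.0 * r * spacing_mm
    p = pad + 1  # sphere padding plus the border-background voxel
    out = out[p:out.shape[0] - p, p:out.shape[1] - p, p:out.shape[2] - p]
    # isolated voxels are minimal one-voxel spheres
    n_neigh = ndimage.convolve(orig.astype(np.uint8), _STRUCT26.astype(np.uint8),
                               mode="constant") - 1
    out[orig & (n_neigh == 0)] = spacing_mm
    values = np.where(orig, out, np.nan)
    return LocalMap(values=values, support=orig, kind="thickness",
                    spacing_mm=spacing_mm)


def tb_th(seg: Segmentation) -> tuple[float, float]:
    """Trabecular thickness: mean and SD (mm) of bone local thickness."""
    if not seg.bone.any():
        raise ValueError("empty bone phase")
    m = local_thickness(seg.bone, seg.spacing_mm)
    m.kind = "thickness"
    return m.mean_sd()


def tb_sp(seg: Segmentation) -> tuple[float, float]:
    """Trabecular separation: mean and SD (mm) of background local thickness.

    Edge-to-edge distance between neighbouring trabeculae: the local
    thickness of the marrow phase (VOI minus bone).
    """
    bg = seg.background
    if not bg.any():
        raise ValueError("empty background phase")
    m = local_thickness(bg, seg.spacing_mm)
    m.kind = "separation"
    return m.mean_sd()


def tb_sc(seg: Segmentation, skel: Skeleton) -> tuple[float, float]:
    """Trabecular spacing: midline-to-midline distance, mean and SD in mm.

    Realised as the local thickness of the complement of the skeleton
    within the VOI, sampled over background voxels: spheres may cross
    trabecular tissue but are stopped by the midlines, so the map measures
    midline pitch rather than marrow gap width.
    """
    if not skel.voxels.any():
        raise ValueError("empty skeleton")
    structure = seg.voi.data & ~skel.voxels
    m = local_thickness(structure, seg.spacing_mm)
    m.kind = "spacing"
    return m.mean_sd(domain=seg.background)


def tb_nd(skel: Skeleton, voi: MaskVolume) -> float:
    """Trabecular nodes: skeleton intersection clusters per mm^3.

    A node voxel has >= 3 skeleton neighbours (26-connectivity); 26-connected
    clusters of node voxels count once, so thinning artefacts that split one
    anatomical intersection into adjacent high-degree voxels do not inflate
    the count.
    """
    if voi.n_voxels == 0:
        raise ValueError("empty VOI")
    counts = skel.neighbor_counts()
    _, n_clusters = ndimage.label(counts >= 3, structure=_STRUCT26)
    return n_clusters / voi.volume_mm3


def tb_tm(skel: Skeleton, voi: MaskVolume) -> float:
    """Trabecular termini: skeleton free ends per mm^3.

    A terminus is a skeleton voxel with exactly one skeleton neighbour
    (26-connectivity).  No branch pruning is applied, so surface
    irregularities that survive thinning are counted.
    """
    if voi.n_voxels == 0:
        raise ValueError("empty VOI")
    counts = skel.neighbor_counts()
    return int(np.sum(skel.voxels & (counts == 1))) / voi.volume_mm3


def cnr(volume: ImageVolume, skel: Skeleton, background: np.ndarray) -> float:
    """Contrast-to-noise ratio.

    Mean intensity over the skeletonised bone minus mean intensity over the
    background, divided by the standard deviation of the background
    intensities.
    """
    background = np.asarray(background, bool)
    if not skel.voxels.any() or not background.any():
        raise ValueError("skeleton and background must be non-empty")
    bg_vals = volume.data[background]
    sd = float(bg_vals.std())
    if sd == 0:
        raise ValueError("background has zero intensity SD")
    return float((volume.data[skel.voxels].mean() - bg_vals.mean()) / sd)


def analyze(
    volume: ImageVolume,
    voi: MaskVolume,
    method: str = "arg",
    config: ARGConfig | None = None,
    n_bins: int = 256,
) -> MorphometryResult:
    """Full per-volume pipeline: segment, skeletonize, measure.

    ``method`` selects the segmentation route: ``"arg"`` (automated region
    growing, the general path) or ``"otsu"`` (global threshold, adequate for
    high-CNR data).  Deterministic for fixed inputs and configuration.
    """
    if method == "arg":
        seg = arg_segment(volume, voi, config)
    elif method == "otsu":
        t = otsu_threshold(volume, voi, n_bins=n_bins)
        seg = Segmentation(bone=voi.data & (volume.data >= t), voi=voi,
                           chosen_threshold=t)
    else:
        raise ValueError(f"unknown method {method!r}")
    skel = skeletonize(seg)
    bg_vals = volume.data[seg.background]
    if bg_vals.size and bg_vals.std() == 0:
        # noise-free background (e.g. a synthetic binary volume): the
        # contrast-to-noise ratio is unbounded
        cnr_value = np.inf if volume.data[skel.voxels].mean() > bg_vals.mean() else 0.0
    else:
        cnr_value = cnr(volume, skel, seg.background)
    th_mean, th_sd = tb_th(seg)
    sp_mean, sp_sd = tb_sp(seg)
    sc_mean, sc_sd = tb_sc(seg, skel)
    return MorphometryResult(
        bvtv=bvtv(seg),
        tb_th_mm=th_mean, s_tb_th_mm=th_sd,
        tb_sc_mm=sc_mean, s_tb_sc_mm=sc_sd,
        tb_sp_mm=sp_mean, s_tb_sp_mm=sp_sd,
        tb_nd_per_mm3=tb_nd(skel, voi),
        tb_tm_per_mm3=tb_tm(skel, voi),
        cnr=cnr_value,
    )
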