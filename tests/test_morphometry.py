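import numpy as np
import pytest
from scipy import ndimage

from trabkit import (
    ImageVolume,
    MaskVolume,
    Segmentation,
    Skeleton,
    analyze,
    bvtv,
    cnr,
    local_thickness,
    skeletonize,
    tb_nd,
    tb_sc,
    tb_sp,
    tb_th,
    tb_tm,
)

S26 = np.ones((3, 3, 3), bool)


def seg_from(bone, spacing=0.05, voi=None):
    bone = np.asarray(bone, bool)
    if voi is None:
        voi = np.ones(bone.shape, bool)
    return Segmentation(bone=bone, voi=MaskVolume(voi, spacing))


class TestBvtv:
    def test_definition_and_bounds(self):
        bone = np.zeros((10, 10, 10), bool)
        bone.ravel()[:160] = True
        assert bvtv(seg_from(bone)) == pytest.approx(0.16)
        assert bvtv(seg_from(np.ones((4, 4, 4), bool))) == 1.0
        assert bvtv(seg_from(np.zeros((4, 4, 4), bool))) == 0.0


class TestSkeletonize:
    def test_straight_line_unchanged(self):
        bone = np.zeros((3, 12, 3), bool)
        bone[1, 2:10, 1] = True
        sk = skeletonize(seg_from(bone))
        np.testing.assert_array_equal(sk.voxels, bone)

    def test_solid_rod_thins_to_single_path(self):
        bone = np.zeros((7, 15, 7), bool)
        bone[2:5, 3:12, 2:5] = True  # 9x3x3 rod along y
        sk = skeletonize(seg_from(bone))
        assert sk.voxels.sum() >= 5
        assert np.all(sk.voxels <= bone)
        _, n = ndimage.label(sk.voxels, structure=S26)
        assert n == 1
        counts = sk.neighbor_counts()
        # a simple path: all voxels have <= 2 neighbours, exactly two ends
        assert counts[sk.voxels].max() <= 2
        assert (counts[sk.voxels] == 1).sum() == 2

    def test_component_count_preserved(self):
        rng = np.random.default_rng(5)
        bone = ndimage.binary_dilation(
            rng.random((24, 24, 24)) > 0.985, iterations=2)
        seg = seg_from(bone)
        sk = skeletonize(seg)
        _, n_bone = ndimage.label(bone, structure=S26)
        _, n_skel = ndimage.label(sk.voxels, structure=S26)
        assert n_skel == n_bone
        assert np.all(sk.voxels <= bone)

    def test_two_disjoint_rods_two_components(self):
        bone = np.zeros((10, 15, 10), bool)
        bone[2:4, 3:12, 2:4] = True
        bone[6:8, 3:12, 6:8] = True
        sk = skeletonize(seg_from(bone))
        _, n = ndimage.label(sk.voxels, structure=S26)
        assert n == 2

    def test_plate_thins_to_mid_sheet(self):
        bone = np.zeros((13, 20, 20), bool)
        bone[4:9] = True  # 5-voxel plate
        sk = skeletonize(seg_from(bone))
        zs = np.unique(np.nonzero(sk.voxels)[0])
        assert list(zs) == [6]  # central layer


def brute_force_thickness(structure, spacing):
    """Independent oracle: explicit sphere fitting on a tiny grid."""
    structure = np.asarray(structure, bool)
    coords = np.argwhere(structure)
    bg = np.argwhere(~np.pad(structure, 1)) - 1  # grid border is background
    out = np.zeros(structure.shape)
    radii = {}
    for c in coords:
        d2 = ((bg - c) ** 2).sum(axis=1)
        radii[tuple(c)] = np.sqrt(d2.min())
    for c in coords:
        r_c = radii[tuple(c)]
        covered = ((coords - c) ** 2).sum(axis=1) <= r_c ** 2 + 1e-9
        for x in coords[covered]:
            out[tuple(x)] = max(out[tuple(x)], 2 * r_c * spacing)
    for c in coords:  # isolated voxels: minimal one-voxel sphere
        others = ((coords - c) ** 2).sum(axis=1)
        if np.sum(others <= 3) == 1:
            out[tuple(c)] = spacing
    return out


class TestLocalThickness:
    def test_slab_of_seven_voxels(self):
        s = np.zeros((20, 24, 24), bool)
        s[6:13] = True
        m = local_thickness(s, 0.05)
        interior = m.values[9, 8:16, 8:16]
        assert np.all(np.abs(interior - 0.35) <= 0.05 + 1e-9)

    def test_isolated_voxel_reads_one_spacing(self):
        s = np.zeros((5, 5, 5), bool)
        s[2, 2, 2] = True
        assert local_thickness(s, 0.05).values[2, 2, 2] == pytest.approx(0.05)

    def test_rod_never_exceeds_diameter_plus_two_voxels(self):
        s = np.zeros((9, 14, 9), bool)
        s[3:6, 2:12, 3:6] = True  # 3-voxel-diameter rod
        m = local_thickness(s, 0.05)
        assert np.nanmax(m.values) <= 3 * 0.05 + 2 * 0.05 + 1e-9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        s = ndimage.binary_dilation(rng.random((9, 9, 9)) > 0.95, iterations=1)
        if not s.any():
            s[4, 4, 4] = True
        m = local_thickness(s, 0.1)
        expected = brute_force_thickness(s, 0.1)
        np.testing.assert_allclose(m.values[s], expected[s])

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_thickness(np.zeros((4, 4, 4), bool), 0.05)


class TestPlateRecovery:
    def test_thickness_separation_spacing(self, plate_phantom, plate_segmentation):
        _, _, truth = plate_phantom
        seg = plate_segmentation
        vox = seg.spacing_mm
        th, s_th = tb_th(seg)
        sp, s_sp = tb_sp(seg)
        sc, s_sc = tb_sc(seg, skeletonize(seg))
        assert abs(th - truth.tb_th_mm) <= vox
        assert abs(sp - truth.tb_sp_mm) <= vox
        assert abs(sc - truth.tb_sc_mm) <= 2 * vox
        assert sc >= sp
        assert s_th <= vox  # uniform plates: near-zero dispersion

    def test_two_slab_populations_mixture(self):
        # equal voxel counts in the 0.2 mm and 0.4 mm populations
        s = np.zeros((44, 20, 20), bool)
        s[2:6] = True     # 4 voxels = 0.2 mm
        s[12:16] = True   # 4 voxels = 0.2 mm
        s[26:34] = True   # 8 voxels = 0.4 mm
        m = local_thickness(s, 0.05)
        vals = m.values[s]
        assert np.mean(vals) == pytest.approx(0.3, abs=0.02)
        assert np.std(vals, ddof=1) == pytest.approx(0.1, abs=0.02)

    def test_separation_invariant_under_intensity_rescale(self, plate_phantom):
        volume, voi, _ = plate_phantom
        a = analyze(volume, voi, method="otsu")
        rescaled = ImageVolume(3.0 * volume.data + 17.0, volume.spacing_mm)
        b = analyze(rescaled, voi, method="otsu")
        assert b.tb_sp_mm == a.tb_sp_mm
        assert b.bvtv == a.bvtv

    def test_empty_bone_separation_reaches_voi_inscribed_sphere(self):
        seg = seg_from(np.zeros((20, 20, 20), bool))
        m = local_thickness(np.ones((20, 20, 20), bool), 0.05)
        # the largest inscribed sphere of the cubic VOI spans its edge length
        assert np.nanmax(m.values) == pytest.approx(20 * 0.05)
        sp, _ = tb_sp(seg)
        assert sp == pytest.approx(np.nanmean(m.values))


def neighbor_count_oracle(grid):
    """Exhaustive neighbour enumeration over all skeleton voxels."""
    grid = np.asarray(grid, bool)
    counts = {}
    for z, y, x in np.argwhere(grid):
        c = 0
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if (0 <= zz < grid.shape[0] and 0 <= yy < grid.shape[1]
                            and 0 <= xx < grid.shape[2] and grid[zz, yy, xx]):
                        c += 1
        counts[(z, y, x)] = c
    return counts


def plus_sign(n=11):
    g = np.zeros((n, n, n), bool)
    c = n // 2
    g[:, c, c] = True
    g[c, :, c] = True
    g[c, c, :] = True
    return g


class TestSkeletonCounts:
    def test_line_has_two_termini_no_nodes(self):
        g = np.zeros((10, 10, 10), bool)
        g[5, 1:9, 5] = True
        sk = Skeleton(g, 0.1)
        voi = MaskVolume(np.ones(g.shape, bool), 0.1)  # exactly 1 mm^3
        oracle = neighbor_count_oracle(g)
        assert sum(1 for c in oracle.values() if c == 1) == 2
        assert tb_tm(sk, voi) == pytest.approx(2.0)
        assert tb_nd(sk, voi) == pytest.approx(0.0)

    def test_closed_loop_no_termini(self):
        # octagonal digital loop: rectangle ring with the four corner
        # voxels cut so every member has exactly two 26-neighbours
        g = np.zeros((10, 10, 10), bool)
        g[5, 2:8, 2] = True
        g[5, 2:8, 7] = True
        g[5, 2, 2:8] = True
        g[5, 7, 2:8] = True
        for y, x in ((2, 2), (2, 7), (7, 2), (7, 7)):
            g[5, y, x] = False
        sk = Skeleton(g, 0.1)
        voi = MaskVolume(np.ones(g.shape, bool), 0.1)
        oracle = neighbor_count_oracle(g)
        assert all(c == 2 for c in oracle.values())
        assert tb_tm(sk, voi) == 0.0
        assert tb_nd(sk, voi) == 0.0

    def test_plus_sign_one_node_six_termini(self):
        g = plus_sign(10)
        sk = Skeleton(g, 0.1)
        voi = MaskVolume(np.ones(g.shape, bool), 0.1)  # exactly 1 mm^3
        oracle = neighbor_count_oracle(g)
        n_termini = sum(1 for c in oracle.values() if c == 1)
        assert n_termini == 6
        assert tb_tm(sk, voi) == pytest.approx(6.0)
        assert tb_nd(sk, voi) == pytest.approx(1.0)

    def test_double_cross_in_two_mm3(self):
        g = np.zeros((10, 10, 20), bool)
        for x0 in (2, 12):
            g[5, 1:9, x0 + 2] = True
            g[1:9, 5, x0 + 2] = True
        voi = MaskVolume(np.ones(g.shape, bool), 0.1)  # 2 mm^3
        sk = Skeleton(g, 0.1)
        assert tb_nd(sk, voi) == pytest.approx(2 / 2.0)

    def test_node_cluster_counted_once(self):
        g = plus_sign(10)
        # an off-axis voxel at the junction creates several adjacent
        # high-degree voxels; they must count as one node cluster
        g[4, 4, 5] = True
        sk = Skeleton(g, 0.1)
        voi = MaskVolume(np.ones(g.shape, bool), 0.1)
        assert tb_nd(sk, voi) == pytest.approx(1.0)


class TestCnr:
    def test_arithmetic(self):
        # foreground mean 100; background half 10, half 30 -> mean 20, SD 10
        data = np.full((4, 4, 4), 0.0)
        data[0, 0, :2] = 100.0
        data[2] = 10.0
        data[3] = 30.0
        bg = np.zeros(data.shape, bool)
        bg[2:] = True
        skel = Skeleton(np.zeros(data.shape, bool), 0.05)
        skel.voxels[0, 0, :2] = True
        assert cnr(ImageVolume(data, 0.05), skel, bg) == pytest.approx(8.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(50, 5, (6, 6, 6))
        skel = Skeleton(np.zeros(data.shape, bool), 0.05)
        skel.voxels[0] = True
        bg = np.zeros(data.shape, bool)
        bg[3:] = True
        a = cnr(ImageVolume(data, 0.05), skel, bg)
        b = cnr(ImageVolume(2 * data + 7, 0.05), skel, bg)
        assert a == pytest.approx(b)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (10, 10, 10))
        skel = Skeleton(np.zeros(data.shape, bool), 0.05)
        skel.voxels[:5] = True
        bg = ~skel.voxels
        assert abs(cnr(ImageVolume(data, 0.05), skel, bg)) < 0.1


class TestAnalyze:
    def test_complete_and_deterministic(self, plate_phantom):
        volume, voi, truth = plate_phantom
        a = analyze(volume, voi, method="otsu")
        b = analyze(volume, voi, method="otsu")
        assert a == b
        row = a.as_row()
        assert len(row) == 10
        assert a.bvtv == pytest.approx(truth.bvtv)

    def test_arg_and_otsu_agree_on_binary_phantom(self, plate_phantom):
        volume, voi, _ = plate_phantom
        a = analyze(volume, voi, method="arg")
        b = analyze(volume, voi, method="otsu")
        assert a == b
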