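"""Morphometry of binary MNV masks against analytic shapes."""

import numpy as np
import pytest

from mnvquant.morphometry import (
    MnvMaskPair,
    box_counting_dimension,
    compute_area,
    compute_flow_density,
    fractal_dimension,
    load_mask_pair,
    quantify,
    skeleton_to_graph,
    skeletonize,
    total_vessel_length,
)

PX = 0.012  # mm, 6 mm / 500 px


def pair_from(lesion, flow=None, px=PX):
    return MnvMaskPair(lesion, lesion if flow is None else flow, px)


def sierpinski(depth=9):
    """Sierpinski triangle raster via the bitwise-AND construction."""
    n = 2**depth
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (i & j) == 0


class TestMaskPair:
    def test_intersection_enforced(self):
        lesion = np.zeros((10, 10), bool)
        lesion[2:6, 2:6] = True
        flow = np.zeros((10, 10), bool)
        flow[4, 4] = True
        flow[9, 9] = True  # outside lesion -> dropped
        m = MnvMaskPair(lesion, flow)
        assert m.flow_mask.sum() == 1

    def test_errors(self):
        with pytest.raises(ValueError, match="size mismatch"):
            MnvMaskPair(np.ones((5, 5), bool), np.ones((6, 6), bool))
        with pytest.raises(ValueError, match="empty lesion"):
            MnvMaskPair(np.zeros((5, 5), bool), np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="pixel_size"):
            MnvMaskPair(np.ones((5, 5), bool), np.ones((5, 5), bool), 0.0)

    def test_load_from_png(self, tmp_path):
        import imageio.v3 as iio

        lesion = np.zeros((20, 20), np.uint8)
        lesion[5:15, 5:15] = 255
        flow = np.zeros((20, 20), np.uint8)
        flow[8:12, 5:15] = 255
        iio.imwrite(tmp_path / "lesion.png", lesion)
        iio.imwrite(tmp_path / "flow.png", flow)
        m = load_mask_pair(tmp_path / "lesion.png", tmp_path / "flow.png", PX)
        assert m.lesion_mask.sum() == 100
        assert m.flow_mask.sum() == 40
        with pytest.raises(OSError):
            load_mask_pair(tmp_path / "missing.png", tmp_path / "flow.png", PX)


class TestAreaAndDensity:
    def test_area_hand_values(self):
        one_px = np.zeros((10, 10), bool)
        one_px[5, 5] = True
        assert compute_area(pair_from(one_px)) == pytest.approx(1.44e-4)
        block = np.zeros((200, 200), bool)
        block[:100, :100] = True
        assert compute_area(pair_from(block)) == pytest.approx(1.44)
        full = np.ones((500, 500), bool)
        assert compute_area(pair_from(full)) == pytest.approx(250000 * PX**2)

    def test_flow_density(self):
        lesion = np.zeros((20, 20), bool)
        lesion[:10, :20] = True  # 200 px
        flow = np.zeros((20, 20), bool)
        flow.flat[np.flatnonzero(lesion.flat)[:82]] = True
        m = MnvMaskPair(lesion, flow)
        assert compute_flow_density(m) == pytest.approx(41.0)
        assert compute_flow_density(pair_from(lesion)) == 100.0
        assert compute_flow_density(MnvMaskPair(lesion, np.zeros_like(lesion))) == 0.0

    def test_area_scales_quadratically_with_pixel_size(self):
        block = np.zeros((50, 50), bool)
        block[10:30, 10:40] = True
        a1 = compute_area(pair_from(block, px=0.01))
        a3 = compute_area(pair_from(block, px=0.03))
        assert a3 == pytest.approx(9 * a1)


class TestSkeletonAndLength:
    def test_wide_bar_reduces_to_single_path(self):
        lesion = np.zeros((60, 60), bool)
        lesion[30:33, 5:55] = True  # 3-px-wide bar, length 50
        g = skeletonize(pair_from(lesion))
        import networkx as nx

        assert nx.number_connected_components(g) == 1
        degrees = [d for _, d in g.degree()]
        assert max(degrees) <= 2  # a simple path
        assert abs(g.number_of_nodes() - 50) <= 4  # ends erode slightly

    def test_single_pixel_and_disjoint_blobs(self):
        lesion = np.zeros((30, 30), bool)
        lesion[5, 5] = True
        g = skeletonize(pair_from(lesion))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0
        lesion[20:23, 20:23] = True
        import networkx as nx

        g2 = skeletonize(pair_from(lesion))
        assert nx.number_connected_components(g2) == 2

    def test_empty_flow_gives_empty_graph(self):
        lesion = np.ones((10, 10), bool)
        g = skeletonize(MnvMaskPair(lesion, np.zeros_like(lesion)))
        assert g.number_of_nodes() == 0
        assert total_vessel_length(g, PX) == 0.0

    @pytest.mark.parametrize(
        "diagonal,expected",
        [(False, 100 * PX), (True, 100 * np.sqrt(2) * PX)],
    )
    def test_path_lengths(self, diagonal, expected):
        img = np.zeros((120, 120), bool)
        if diagonal:
            idx = np.arange(101)
            img[idx, idx] = True
        else:
            img[60, 5:106] = True
        g = skeleton_to_graph(img)
        assert g.number_of_nodes() == 101
        assert total_vessel_length(g, PX) == pytest.approx(expected)

    def test_length_scales_linearly_with_pixel_size(self):
        img = np.zeros((50, 50), bool)
        img[25, 5:45] = True
        g = skeleton_to_graph(img)
        assert total_vessel_length(g, 0.024) == pytest.approx(
            2 * total_vessel_length(g, 0.012)
        )

    def test_removing_pixels_cannot_lengthen_skeleton(self):
        img = np.zeros((80, 80), bool)
        img[40, 5:75] = True
        img[5:75, 40] = True
        g_full = skeleton_to_graph(img)
        img2 = img.copy()
        img2[:40, :] = False
        g_sub = skeleton_to_graph(img2)
        assert total_vessel_length(g_sub, PX) <= total_vessel_length(g_full, PX)


class TestFractalDimension:
    def test_single_node_is_zero(self):
        img = np.zeros((64, 64), bool)
        img[10, 10] = True
        g = skeleton_to_graph(img)
        assert fractal_dimension(g, img.shape) == 0.0

    def test_line_is_one(self):
        img = np.zeros((512, 512), bool)
        img[256, :] = True
        assert box_counting_dimension(img) == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_triangle(self):
        fd = box_counting_dimension(sierpinski(9))
        assert fd == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_filled_square_is_two(self):
        assert box_counting_dimension(np.ones((512, 512), bool)) == pytest.approx(
            2.0, abs=0.05
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no structure"):
            box_counting_dimension(np.zeros((32, 32), bool))


class TestQuantify:
    def test_bundle_hand_values(self):
        lesion = np.zeros((120, 120), bool)
        lesion[10:110, 10:110] = True  # 100x100 block
        flow = np.zeros((120, 120), bool)
        flow[60, 5:115] = True  # overlong path; clipped to the lesion columns
        m = MnvMaskPair(lesion, flow, PX)
        ms = quantify(m)
        assert ms.area_mm2 == pytest.approx(1.44)
        # flow intersected with lesion: cols 10..109 -> 100 px -> 99 steps
        assert ms.suml_mm == pytest.approx(99 * PX)

    def test_full_frame_density(self):
        full = np.ones((64, 64), bool)
        assert quantify(pair_from(full)).flow_density_pct == 100.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        lesion = rng.random((90, 90)) < 0.3
        lesion[40:50, 20:70] = True  # guarantee non-empty structure
        m = quantify(pair_from(lesion))
        m_rot = quantify(pair_from(np.rot90(lesion)))
        assert m_rot.area_mm2 == m.area_mm2
        assert m_rot.flow_density_pct == m.flow_density_pct
        # thinning sub-iterations sweep directions in a fixed order, so the
        # skeleton of the rotated mask can differ by a few pixels
        assert m_rot.suml_mm == pytest.approx(m.suml_mm, rel=0.03)
        assert m_rot.fractal_dimension == pytest.approx(m.fractal_dimension, abs=0.02)

    def test_fd_substrate_choice(self):
        lesion = np.ones((256, 256), bool)  # plane-filling flow mask
        ms_bin = quantify(pair_from(lesion), fd_substrate="binarized")
        assert ms_bin.fractal_dimension == pytest.approx(2.0, abs=0.05)
        with pytest.raises(ValueError):
            quantify(pair_from(lesion), fd_substrate="nope")
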