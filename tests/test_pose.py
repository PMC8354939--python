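import math

import numpy as np
import pytest

from cathpose.contours import ShapeDescriptors, extract_contours
from cathpose.pose import (
    PoseConfig,
    estimate_anchor,
    estimate_pose,
    estimate_rotX,
    estimate_rotZ,
    estimate_scale,
    select_main_contour,
)
from cathpose.synth import ParamRanges, SceneParams, render_scene, sample_params


def desc(bbox, area=100, centroid=None):
    xmin, ymin, xmax, ymax = bbox
    if centroid is None:
        centroid = ((xmin + xmax) / 2, (ymin + ymax) / 2)
    return ShapeDescriptors(area=area, centroid=centroid, bbox=bbox)


class TestMainContourSelection:
    def test_single_contour(self):
        m = np.zeros((10, 10), np.uint8)
        m[2:5, 2:5] = 2
        cs = extract_contours(m, 2)
        assert select_main_contour(cs, m) is cs[0]

    def test_largest_region_wins(self):
        m = np.zeros((20, 20), np.uint8)
        m[1:3, 1:3] = 2          # area 4
        m[8:16, 8:13] = 2        # area 40
        cs = extract_contours(m, 2)
        main = select_main_contour(cs, m)
        assert main.start == (8, 8)

    def test_equal_area_tie_break_scan_order(self):
        m = np.zeros((20, 20), np.uint8)
        m[5:8, 12:15] = 2   # same area, starts later in scan order
        m[2:5, 3:6] = 2     # topmost first pixel
        cs = extract_contours(m, 2)
        assert select_main_contour(cs, m).start == (3, 2)

    def test_empty_gives_none_and_invalid_pose(self):
        m = np.zeros((10, 10), np.uint8)
        assert select_main_contour([], m) is None
        assert not estimate_pose(m).valid


class TestAnchorAndScale:
    def test_bbox_anchor_formula(self):
        assert estimate_anchor(desc((10, 5, 20, 30))) == (15.0, 5.0)
        assert estimate_anchor(desc((7, 2, 7, 2))) == (7.0, 2.0)

    def test_scale_formula(self):
        cfg = PoseConfig(catheter_diameter_mm=5.0)
        assert estimate_scale(desc((0, 0, 19, 40)), cfg) == pytest.approx(4.0)
        cfg2 = PoseConfig(catheter_diameter_mm=2.0)
        assert estimate_scale(desc((3, 0, 3, 9)), cfg2) == pytest.approx(0.5)

    def test_scale_doubles_with_rendered_width(self):
        base = dict(anchor=(48.0, 10.0), rotZ=0.0, rotX=0.0, length_px=70.0)
        narrow = render_scene(SceneParams(diameter_px=10.0, **base), 96, 96)
        wide = render_scene(SceneParams(diameter_px=20.0, **base), 96, 96)
        s1 = estimate_pose(narrow.mask).scale
        s2 = estimate_pose(wide.mask).scale
        assert s2 / s1 == pytest.approx(2.0, abs=0.1)

    def test_vertical_catheter_anchor_recovery(self):
        scene = render_scene(
            SceneParams(anchor=(48.0, 10.0), diameter_px=12.0, length_px=70.0), 96, 96
        )
        est = estimate_pose(scene.mask)
        assert math.hypot(est.p1 - 48, est.p2 - 10) <= 1.0


class TestRotZ:
    def test_centroid_straight_below_is_zero(self):
        assert estimate_rotZ((100, 50), (100, 120)) == 0.0

    def test_equal_offsets_45_degrees(self):
        assert estimate_rotZ((100, 50), (150, 100)) == pytest.approx(45.0)

    def test_trig_oracle_30_degrees(self):
        assert estimate_rotZ((0, 0), (30, 51.9615)) == pytest.approx(30.0, abs=1e-3)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_rotZ((5, 5), (5, 5))


class TestRotX:
    def test_rectangle_is_symmetric(self):
        m = np.zeros((40, 40), np.uint8)
        m[5:35, 10:20] = 2
        (c,) = extract_contours(m, 2)
        from cathpose.contours import shape_descriptors

        d = shape_descriptors(m, c)
        assert estimate_rotX(m, c, d, PoseConfig()) == 0.0

    def test_triangle_asymmetry_matches_closed_form(self):
        # apex-up triangle: continuous asymmetry (A_lo - A_up)/(A_lo + A_up) = 1/9
        h, half_base = 120, 40
        m = np.zeros((140, 100), np.uint8)
        for y in range(h):
            half = round(y / h * half_base)
            m[y + 5, 50 - half : 50 + half + 1] = 2
        (c,) = extract_contours(m, 2)
        from cathpose.contours import shape_descriptors

        d = shape_descriptors(m, c)
        cfg = PoseConfig(rotx_gain=1.0)
        assert estimate_rotX(m, c, d, cfg) == pytest.approx(1 / 9, abs=0.02)

    def test_monotone_in_true_rotx(self):
        """Estimated rotX increases strictly with true rotX across the sweep
        (rendered large enough that raster jitter is below the taper signal)."""
        estimates = []
        for rx in range(-40, 41, 10):
            scene = render_scene(
                SceneParams(
                    anchor=(750.0, 60.0), rotZ=0.0, rotX=float(rx),
                    diameter_px=110.0, length_px=700.0,
                ),
                1500, 830,
            )
            estimates.append(estimate_pose(scene.mask).rotX)
        assert all(b > a for a, b in zip(estimates, estimates[1:]))

    def test_sign_matches_for_large_rotx(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            rx = float(rng.choice([-1, 1]) * rng.uniform(15, 40))
            p = sample_params(ParamRanges(rotx=(rx, rx)), 608, 416, rng)
            scene = render_scene(p, 608, 416)
            est = estimate_pose(scene.mask)
            assert (est.rotX > 0) == (rx > 0)


class TestEstimatePose:
    CFG = PoseConfig()

    def test_parameter_recovery_example(self):
        scene = render_scene(
            SceneParams(anchor=(300.0, 40.0), rotZ=15.0, rotX=0.0,
                        diameter_px=45.0, length_px=280.0),
            608, 416,
        )
        est = estimate_pose(scene.mask, self.CFG)
        assert est.valid
        assert math.hypot(est.p1 - 300, est.p2 - 40) <= 2.0
        assert abs(est.rotZ - 15.0) <= 3.0

    def test_mirror_antisymmetry_exact(self):
        scene = render_scene(
            SceneParams(anchor=(300.0, 40.0), rotZ=17.0, rotX=12.0,
                        diameter_px=45.0, length_px=280.0),
            608, 416,
        )
        e = estimate_pose(scene.mask, self.CFG)
        m = estimate_pose(scene.mask[:, ::-1].copy(), self.CFG)
        w = scene.mask.shape[1]
        assert m.p1 == (w - 1) - e.p1
        assert m.p2 == e.p2
        assert m.rotZ == -e.rotZ
        assert m.rotX == e.rotX
        assert m.scale == e.scale

    def test_translation_equivariance_exact(self):
        scene = render_scene(
            SceneParams(anchor=(200.0, 30.0), rotZ=-12.0, rotX=-20.0,
                        diameter_px=40.0, length_px=250.0),
            608, 416,
        )
        e = estimate_pose(scene.mask, self.CFG)
        shifted = np.zeros_like(scene.mask)
        shifted[7:, 11:] = scene.mask[:-7, :-11]
        t = estimate_pose(shifted, self.CFG)
        assert (t.p1, t.p2) == (e.p1 + 11, e.p2 + 7)
        assert (t.rotZ, t.rotX, t.scale) == (e.rotZ, e.rotX, e.scale)

    def test_speckle_below_min_region_invalid(self):
        m = np.zeros((96, 96), np.uint8)
        m[3:8, 3:8] = 2  # 25 px < default min_region_px = 50
        assert not estimate_pose(m, self.CFG).valid

    def test_bbox_mode_matches_hull_mode_when_upright(self):
        scene = render_scene(
            SceneParams(anchor=(48.0, 10.0), diameter_px=14.0, length_px=70.0), 96, 96
        )
        hull = estimate_pose(scene.mask, PoseConfig(anchor_mode="hull"))
        bbox = estimate_pose(scene.mask, PoseConfig(anchor_mode="bbox"))
        assert abs(hull.p1 - bbox.p1) <= 1.0 and abs(hull.p2 - bbox.p2) <= 1.0
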