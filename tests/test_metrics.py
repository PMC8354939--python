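import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cathpose.metrics import (
    QuaternionRot,
    ThroughputReport,
    compute_iou,
    euclidean_distance,
    euler_xz_to_quaternion,
    geodesic_distance,
    mean_iou,
    measure_throughput,
)


def random_unit_quaternion(rng) -> QuaternionRot:
    return QuaternionRot.from_components(*rng.normal(size=4))


def matrix_of(q: QuaternionRot) -> np.ndarray:
    return Rotation.from_quat([q.x, q.y, q.z, q.w]).as_matrix()


class TestIoU:
    def test_identity_is_one(self, rng):
        m = rng.integers(0, 3, (20, 20)).astype(np.uint8)
        for c in (0, 1, 2):
            assert compute_iou(m, m, c).iou == 1.0
        assert mean_iou(m, m) == 1.0

    def test_partial_overlap_counts(self):
        pred = np.zeros((4, 4), np.uint8)
        gt = np.zeros((4, 4), np.uint8)
        pred[0, 0:4] = 2          # 4 px
        gt[0, 2:4] = 2            # overlap 2
        gt[1, 0:2] = 2            # +2 px elsewhere
        b = compute_iou(pred, gt, 2)
        assert (b.overlap_count, b.union_count) == (2, 6)
        assert b.iou == pytest.approx(2 / 6)

    def test_disjoint_is_zero(self):
        pred = np.zeros((4, 4), np.uint8)
        gt = np.zeros((4, 4), np.uint8)
        pred[0, 0] = 2
        gt[3, 3] = 2
        assert compute_iou(pred, gt, 2).iou == 0.0

    def test_symmetry_and_counting_oracle(self, rng):
        for _ in range(50):
            a = rng.integers(0, 3, (12, 12)).astype(np.uint8)
            b = rng.integers(0, 3, (12, 12)).astype(np.uint8)
            for c in (0, 1, 2):
                fwd = compute_iou(a, b, c)
                rev = compute_iou(b, a, c)
                assert fwd.iou == rev.iou
                inter = sum(
                    1 for y in range(12) for x in range(12) if a[y, x] == c == b[y, x]
                )
                union = sum(
                    1 for y in range(12) for x in range(12) if c in (a[y, x], b[y, x])
                )
                assert (fwd.overlap_count, fwd.union_count) == (inter, union)
                assert 0.0 <= fwd.iou <= 1.0

    def test_mean_iou_excludes_absent_classes(self):
        pred = np.zeros((6, 6), np.uint8)
        gt = np.zeros((6, 6), np.uint8)
        pred[0:2, 0:2] = 2
        gt[0:2, 0:2] = 2
        gt[4, 4] = 2
        # class 1 absent everywhere: mean over classes 0 and 2 only
        i0 = compute_iou(pred, gt, 0).iou
        i2 = compute_iou(pred, gt, 2).iou
        assert mean_iou(pred, gt) == pytest.approx((i0 + i2) / 2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_iou(np.zeros((3, 3), np.uint8), np.zeros((4, 4), np.uint8), 0)


class TestEuclidean:
    def test_three_four_five(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0
        assert euclidean_distance((7, 7), (7, 7)) == 0.0
        assert euclidean_distance((10, 20), (13, 24)) == 5.0


class TestQuaternions:
    def test_identity(self):
        q = euler_xz_to_quaternion(0, 0)
        assert (q.w, q.x, q.y, q.z) == (1.0, 0.0, 0.0, 0.0)

    def test_half_angle_x(self):
        q = euler_xz_to_quaternion(90, 0)
        assert q.w == pytest.approx(math.sqrt(2) / 2)
        assert q.x == pytest.approx(math.sqrt(2) / 2)
        assert q.y == q.z == 0.0

    def test_product_oracle_90_90(self):
        q = euler_xz_to_quaternion(90, 90)
        assert np.allclose(q.as_array(), [0.5, 0.5, 0.5, 0.5])

    def test_matrix_round_trip(self):
        # composed elemental rotations Rz @ Rx reproduced within 1e-12
        rng = np.random.default_rng(4)
        for _ in range(50):
            rx, rz = rng.uniform(-179, 179, 2)
            q = euler_xz_to_quaternion(rx, rz)
            rmat = (
                Rotation.from_euler("z", rz, degrees=True).as_matrix()
                @ Rotation.from_euler("x", rx, degrees=True).as_matrix()
            )
            assert np.abs(matrix_of(q) - rmat).max() < 1e-12

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            QuaternionRot(1.0, 1.0, 0.0, 0.0)

    def test_canonical_sign(self):
        q = QuaternionRot.from_components(-1, 0, 0, 0)
        assert q.w == 1.0


class TestGeodesicDistance:
    def test_zero_for_same_rotation(self, rng):
        q = random_unit_quaternion(rng)
        assert geodesic_distance(q, q) == 0.0

    def test_rotx60_vs_identity_is_pi_over_3(self):
        d = geodesic_distance(euler_xz_to_quaternion(60, 0), euler_xz_to_quaternion(0, 0))
        assert d == pytest.approx(math.pi / 3, abs=1e-12)

    def test_trace_oracle_symmetry_left_invariance(self, rng):
        for _ in range(300):
            q1, q2 = random_unit_quaternion(rng), random_unit_quaternion(rng)
            d = geodesic_distance(q1, q2)
            tr = float(np.trace(matrix_of(q2).T @ matrix_of(q1)))
            assert abs(d - math.acos(min(1.0, max(-1.0, (tr - 1) / 2)))) < 1e-9
            assert geodesic_distance(q2, q1) == pytest.approx(d, abs=1e-9)
            qc = random_unit_quaternion(rng)
            assert geodesic_distance(qc @ q1, qc @ q2) == pytest.approx(d, abs=1e-9)

    def test_sign_ambiguity_ignored(self, rng):
        q = random_unit_quaternion(rng)
        neg = QuaternionRot.from_components(-q.w, -q.x, -q.y, -q.z)
        assert geodesic_distance(q, neg) == 0.0

    def test_paper_literal_variant_is_constant_one(self, rng):
        """The L2 norm of the relative unit quaternion is identically 1 —
        the printed formula cannot discriminate rotations."""
        for _ in range(100):
            q1, q2 = random_unit_quaternion(rng), random_unit_quaternion(rng)
            assert geodesic_distance(q1, q2, "paper_literal") == pytest.approx(1.0, abs=1e-12)

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError):
            geodesic_distance(random_unit_quaternion(rng), random_unit_quaternion(rng), "bogus")


class TestThroughput:
    def test_report_arithmetic(self):
        r = ThroughputReport(n_iterations=10, elapsed_seconds=2.0, it_per_s=5.0)
        assert r.it_per_s == 10 / 2.0
        assert not r.is_realtime  # 5 < 10 threshold

    def test_measure_counts_and_rate(self):
        calls = []
        rep = measure_throughput(lambda: calls.append(1), n=7)
        assert len(calls) == 7
        assert rep.n_iterations == 7
        assert rep.it_per_s == pytest.approx(7 / rep.elapsed_seconds)

    def test_single_iteration(self):
        rep = measure_throughput(lambda: None, n=1)
        assert rep.it_per_s == pytest.approx(1 / rep.elapsed_seconds)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            measure_throughput(lambda: None, n=0)
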