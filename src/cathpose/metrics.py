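"""Evaluation metrics for segmentation and AR-overlay registration.

Four quantities: per-class and mean intersection-over-union, prediction
throughput in iterations per second, the Euclidean distance between anchor
points, and a rotation error between poses expressed as unit quaternions.

On the rotation error: the historically printed formula ``sqrt(Q·Q)`` with
``Q = q2⁻¹ ⊗ q1`` is the L2 norm of a unit quaternion and is therefore
identically 1 — it cannot discriminate rotations.  The default
``variant="angle"`` reports the geodesic arc length on the rotation group
instead, ``2·atan2(‖(Qx,Qy,Qz)‖, |Qw|)`` in radians, which is zero iff the
rotations agree and symmetric in its arguments.  The literal formula is kept
as ``variant="paper_literal"`` for inspection.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .mask_io import CLASS_IDS, validate_mask

__all__ = [
    "IoUBreakdown",
    "ThroughputReport",
    "QuaternionRot",
    "compute_iou",
    "mean_iou",
    "euclidean_distance",
    "euler_xz_to_quaternion",
    "geodesic_distance",
    "measure_throughput",
]

#: Prediction rate above which the live overlay was judged responsive.
REALTIME_IT_PER_S = 10.0


@dataclass(frozen=True)
class IoUBreakdown:
    """Pixel counts behind one class IoU.  ``absent`` flags an empty union
    (class missing from both masks), reported as IoU 1.0."""

    overlap_count: int
    union_count: int
    iou: float
    absent: bool = False


@dataclass(frozen=True)
class ThroughputReport:
    n_iterations: int
    elapsed_seconds: float
    it_per_s: float
    realtime_threshold: float = REALTIME_IT_PER_S

    @property
    def is_realtime(self) -> bool:
        return self.it_per_s > self.realtime_threshold


@dataclass(frozen=True)
class QuaternionRot:
    """Unit quaternion (w, x, y, z), canonicalized to w ≥ 0 (and, at w = 0,
    first nonzero vector component ≥ 0)."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        norm = math.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {norm} deviates from 1 beyond 1e-9")

    @staticmethod
    def from_components(w: float, x: float, y: float, z: float) -> "QuaternionRot":
        """Normalize and canonicalize the sign (q and −q are the same rotation)."""
        norm = math.sqrt(w * w + x * x + y * y + z * z)
        if norm == 0.0:
            raise ValueError("zero quaternion")
        if abs(norm - 1.0) > 1e-13:  # keep already-unit inputs bit-exact
            w, x, y, z = w / norm, x / norm, y / norm, z / norm
        for c in (w, x, y, z):
            if c != 0.0:
                if c < 0.0:
                    w, x, y, z = -w, -x, -y, -z
                break
        return QuaternionRot(w, x, y, z)

    def conjugate(self) -> "QuaternionRot":
        return QuaternionRot.from_components(self.w, -self.x, -self.y, -self.z)

    def __matmul__(self, other: "QuaternionRot") -> "QuaternionRot":
        """Hamilton product self ⊗ other (other applied first)."""
        w1, x1, y1, z1 = self.w, self.x, self.y, self.z
        w2, x2, y2, z2 = other.w, other.x, other.y, other.z
        return QuaternionRot.from_components(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])


def compute_iou(pred: np.ndarray, gt: np.ndarray, class_id: int) -> IoUBreakdown:
    """Intersection over union of one class between two label masks.

    ``iou = |pred=c ∧ gt=c| / |pred=c ∨ gt=c|``; an empty union (class
    absent from both) is flagged and scored 1.0.
    """
    p = validate_mask(pred)
    g = validate_mask(gt)
    if p.shape != g.shape:
        raise ValueError(f"mask dimension mismatch: {p.shape} vs {g.shape}")
    if class_id not in CLASS_IDS:
        raise ValueError(f"invalid class id {class_id}")
    pm = p == class_id
    gm = g == class_id
    overlap = int(np.count_nonzero(pm & gm))
    union = int(np.count_nonzero(pm | gm))
    if union == 0:
        return IoUBreakdown(0, 0, 1.0, absent=True)
    return IoUBreakdown(overlap, union, overlap / union)


def mean_iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Unweighted mean of per-class IoU over the classes {0, 1, 2} whose
    union is nonempty (classes absent from both masks are excluded)."""
    parts = [compute_iou(pred, gt, c) for c in CLASS_IDS]
    present = [b.iou for b in parts if not b.absent]
    if not present:  # unreachable for nonempty masks, kept for safety
        return 1.0
    return float(np.mean(present))


def euclidean_distance(p: tuple[float, float], p_hat: tuple[float, float]) -> float:
    """Euclidean distance between two anchor points, pixels."""
    return math.hypot(p[0] - p_hat[0], p[1] - p_hat[1])


def euler_xz_to_quaternion(rotX: float, rotZ: float) -> QuaternionRot:
    """Compose the overlay rotations (degrees, rotY ≡ 0) into a unit
    quaternion ``q = qZ ⊗ qX`` — the elemental X rotation applied first,
    then Z, in the fixed camera frame."""
    hx = math.radians(rotX) / 2.0
    hz = math.radians(rotZ) / 2.0
    qx = QuaternionRot.from_components(math.cos(hx), math.sin(hx), 0.0, 0.0)
    qz = QuaternionRot.from_components(math.cos(hz), 0.0, 0.0, math.sin(hz))
    return qz @ qx


def geodesic_distance(
    q1: QuaternionRot, q2: QuaternionRot, variant: str = "angle"
) -> float:
    """Rotation distance between two unit quaternions.

    ``variant="angle"`` (default): the relative rotation angle of
    ``Q = q2⁻¹ ⊗ q1``, i.e. ``2·atan2(‖(Qx,Qy,Qz)‖, |Qw|)`` ∈ [0, π]
    radians — the length of the geodesic arc between the two rotations.

    ``variant="paper_literal"``: ``sqrt(Q·Q)``, the L2 norm of Q, kept for
    inspection; it is identically 1 for unit quaternions.
    """
    same = (q1.w, q1.x, q1.y, q1.z) == (q2.w, q2.x, q2.y, q2.z)
    if same and variant == "angle":
        return 0.0
    rel = q2.conjugate() @ q1
    if variant == "angle":
        vec = math.sqrt(rel.x**2 + rel.y**2 + rel.z**2)
        return 2.0 * math.atan2(vec, abs(rel.w))
    if variant == "paper_literal":
        return math.sqrt(rel.w**2 + rel.x**2 + rel.y**2 + rel.z**2)
    raise ValueError(f"unknown variant {variant!r}")


def measure_throughput(
    step: Callable[[], object], n: int, realtime_threshold: float = REALTIME_IT_PER_S
) -> ThroughputReport:
    """Run ``step`` n times and report iterations per second (wall clock).

    One iteration is one segmentation prediction on a single frame; the
    report carries the configured real-time threshold.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t0 = time.perf_counter()
    for _ in range(n):
        step()
    elapsed = time.perf_counter() - t0
    elapsed = max(elapsed, 1e-12)
    return ThroughputReport(n, elapsed, n / elapsed, realtime_threshold)
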