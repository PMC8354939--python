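"""Catheter silhouette → 3D-overlay pose parameters.

Given the catheter class of a segmentation mask, this module recovers the
parameters used to attach a virtual 3D model to the 2D frame:

* anchor point ``(p1, p2)`` — where the model apex is pinned, the central
  point of the upper edge of the catheter's bounding geometry;
* ``scale`` — pixels per millimetre, the apparent catheter width divided by
  its known real-world diameter;
* ``rotZ`` — in-plane rotation, the angle of the vector from the anchor to
  the region centroid (0° when the centroid is straight below the anchor,
  positive when displaced rightward, degrees in (−180, 180]);
* ``rotX`` — rotation toward (+) or away (−) from the camera, inferred from
  the area asymmetry of the silhouette above vs below the centroid row: a
  cylinder tilted toward the camera projects a wider, larger near (lower)
  end.

Two anchor conventions are provided.  The default, ``anchor_mode="hull"``,
takes the upper edge of the convex hull of the main contour (the maximal
near-horizontal hull chain through the topmost vertex), which stays attached
to the catheter tip under in-plane rotation.  ``anchor_mode="bbox"`` is the
literal axis-aligned variant — the midpoint of the bounding box's top edge —
which coincides with the hull variant for an upright catheter but drifts
toward the silhouette's overall x-centre as |rotZ| grows, degrading both the
anchor and the anchor→centroid angle for tilted silhouettes.

The Y-axis rotation is fixed at 0 throughout (rarely involved for a
near-vertical catheter).  Internal angle and asymmetry computations use
exact integer sums over region pixels, so translation equivariance and
mirror antisymmetry hold bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contours import (
    Contour,
    ShapeDescriptors,
    convex_hull,
    extract_contours,
    shape_descriptors,
)
from .mask_io import validate_mask

__all__ = [
    "PoseConfig",
    "PoseEstimate",
    "select_main_contour",
    "estimate_anchor",
    "estimate_anchor_hull",
    "estimate_scale",
    "estimate_rotZ",
    "estimate_rotX",
    "estimate_pose",
]

CATHETER_CLASS = 2

_FG_STRUCT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PoseConfig:
    """Tunables of the silhouette-to-pose stage.

    catheter_diameter_mm
        Real-world catheter diameter used to convert apparent width to
        pixels-per-mm scale.  Default 6.0 mm (an 18 Fr urinary catheter).
    rotx_gain
        Degrees of X rotation per unit of area asymmetry
        ``s = (A_lower − A_upper) / (A_lower + A_upper)``.  The mapping from
        asymmetry to angle is linear by construction; only the sign and
        monotonicity of rotX should be treated as calibrated.
    min_region_px
        Minimum catheter region area (pixels) for a detection to be
        considered valid; smaller regions are speckle.
    anchor_mode
        ``"hull"`` (default) or ``"bbox"``; see module docstring.
    hull_edge_max_deg
        Maximal inclination from horizontal (degrees) for a hull edge to be
        counted as part of the upper edge chain in ``"hull"`` mode.
    """

    catheter_diameter_mm: float = 6.0
    rotx_gain: float = 60.0
    min_region_px: int = 50
    anchor_mode: str = "hull"
    hull_edge_max_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.catheter_diameter_mm <= 0:
            raise ValueError("catheter diameter must be positive")
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")
        if self.anchor_mode not in ("hull", "bbox"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")


@dataclass(frozen=True)
class PoseEstimate:
    """Overlay pose: anchor (p1, p2) in pixels, rotations in degrees,
    scale in px/mm.  ``valid=False`` marks a failed detection; numeric
    fields are NaN in that case.  rotY is implicitly 0."""

    valid: bool
    p1: float = field(default=math.nan)
    p2: float = field(default=math.nan)
    rotZ: float = field(default=math.nan)
    rotX: float = field(default=math.nan)
    scale: float = field(default=math.nan)

    @staticmethod
    def invalid() -> "PoseEstimate":
        return PoseEstimate(valid=False)

    def to_record(self, frame: str | int | None = None) -> dict:
        return {
            "frame": frame,
            "valid": bool(self.valid),
            "p1": self.p1 if self.valid else None,
            "p2": self.p2 if self.valid else None,
            "rotZ_deg": self.rotZ if self.valid else None,
            "rotX_deg": self.rotX if self.valid else None,
            "scale_px_per_mm": self.scale if self.valid else None,
        }


def _region_pixels(mask: np.ndarray, contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """(xs, ys) of the 8-connected component containing the contour start."""
    binary = mask == contour.class_id
    labels, _ = ndimage.label(binary, structure=_FG_STRUCT)
    sx, sy = contour.start
    ys, xs = np.nonzero(labels == labels[sy, sx])
    return xs.astype(np.int64), ys.astype(np.int64)


def select_main_contour(contours: list[Contour], mask: np.ndarray) -> Contour | None:
    """Pick the outer contour of the largest region; ties go to the contour
    whose start pixel comes first in scan order (topmost, then leftmost).
    Empty input returns None (no detection)."""
    arr = validate_mask(mask)
    outers = [c for c in contours if c.kind == "outer"]
    if not outers:
        return None

    def key(c: Contour):
        desc = shape_descriptors(arr, c)
        sx, sy = c.start
        return (-desc.area, sy, sx)

    return min(outers, key=key)


def estimate_anchor(desc: ShapeDescriptors) -> tuple[float, float]:
    """Anchor as the central point of the top edge of the axis-aligned
    bounding box: ``((xmin + xmax) / 2, ymin)``."""
    xmin, ymin, xmax, _ = desc.bbox
    return ((xmin + xmax) / 2.0, float(ymin))


def _upper_edge_chain(
    hull: list[tuple[float, float]], max_deg: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of the hull's upper edge: the maximal chain of
    near-horizontal hull edges containing the topmost vertex."""
    n = len(hull)
    if n == 1:
        return hull[0], hull[0]
    top = min(range(n), key=lambda i: (hull[i][1], hull[i][0]))
    max_slope = math.tan(math.radians(max_deg))

    def near_horizontal(a, b) -> bool:
        dx, dy = b[0] - a[0], b[1] - a[1]
        return dx != 0 and abs(dy) <= max_slope * abs(dx)

    left = right = top
    for _ in range(n - 1):
        j = (right + 1) % n
        if j == left or not near_horizontal(hull[right], hull[j]):
            break
        right = j
    for _ in range(n - 1):
        j = (left - 1) % n
        if j == right or not near_horizontal(hull[j], hull[left]):
            break
        left = j
    return hull[left], hull[right]


def estimate_anchor_hull(
    contour: Contour, cfg: PoseConfig
) -> tuple[tuple[float, float], float]:
    """Anchor as the midpoint of the convex hull's upper edge.

    Returns ``((p1, p2), upper_edge_width_px)`` where the width is the
    inclusive pixel extent of the upper edge (endpoint distance + 1), the
    apparent catheter diameter used for scale in ``"hull"`` mode.
    """
    hull = convex_hull(contour.points)
    a, b = _upper_edge_chain(hull, cfg.hull_edge_max_deg)
    p1 = (a[0] + b[0]) / 2.0
    p2 = (a[1] + b[1]) / 2.0
    width = math.hypot(b[0] - a[0], b[1] - a[1]) + 1.0
    return (p1, p2), width


def estimate_scale(desc: ShapeDescriptors, cfg: PoseConfig) -> float:
    """Scale in px/mm from the bounding-box width: ``(xmax − xmin + 1) / D``."""
    if cfg.catheter_diameter_mm <= 0:
        raise ValueError("catheter diameter must be positive")
    xmin, _, xmax, _ = desc.bbox
    return (xmax - xmin + 1) / cfg.catheter_diameter_mm


def estimate_rotZ(anchor: tuple[float, float], centroid: tuple[float, float]) -> float:
    """In-plane rotation from the anchor→centroid vector, degrees in
    (−180, 180]: 0° straight down, positive when the centroid lies to the
    right of the anchor (y grows downward)."""
    dx = centroid[0] - anchor[0]
    dy = centroid[1] - anchor[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("anchor and centroid coincide")
    return math.degrees(math.atan2(dx, dy))


def _asymmetry(xs: np.ndarray, ys: np.ndarray) -> float:
    """Area asymmetry s = (A_lower − A_upper)/(A_lower + A_upper) about the
    centroid row, pixels on the row split half to each side.

    Comparisons use the exact integer inequality ``n·y ≶ Σy`` so the value
    is invariant under integer translation and mirror flips.
    """
    n = ys.size
    sy = int(ys.sum())
    scaled = n * ys
    on_row = float(np.count_nonzero(scaled == sy))
    a_up = float(np.count_nonzero(scaled < sy)) + 0.5 * on_row
    a_lo = float(np.count_nonzero(scaled > sy)) + 0.5 * on_row
    return (a_lo - a_up) / (a_lo + a_up)


def estimate_rotX(
    mask: np.ndarray,
    contour: Contour,
    desc: ShapeDescriptors,
    cfg: PoseConfig,
) -> float:
    """Toward/away-from-camera rotation from area asymmetry about the
    centroid row.

    ``A_upper`` counts region pixels strictly above the centroid row,
    ``A_lower`` strictly below; pixels exactly on the centroid row count
    half to each.  ``rotX = rotx_gain · (A_lower − A_upper)/(A_lower +
    A_upper)``, positive (toward the camera) iff the lower part is larger.
    """
    arr = validate_mask(mask)
    if desc.area < 1:
        raise ValueError("empty region")
    xs, ys = _region_pixels(arr, contour)
    return cfg.rotx_gain * _asymmetry(xs, ys)


def estimate_pose(mask: np.ndarray, cfg: PoseConfig | None = None) -> PoseEstimate:
    """Full silhouette→pose pipeline on the catheter class of a label mask.

    Boundary extraction → main contour → anchor, scale, rotZ, rotX.
    Failure (no catheter region, region below ``min_region_px``, or centroid
    coincident with the anchor) is reported via ``valid=False`` rather than
    an exception.
    """
    cfg = cfg or PoseConfig()
    arr = validate_mask(mask)
    contours = extract_contours(arr, CATHETER_CLASS)
    main = select_main_contour(contours, arr)
    if main is None:
        return PoseEstimate.invalid()
    xs, ys = _region_pixels(arr, main)
    n = xs.size
    if n < cfg.min_region_px:
        return PoseEstimate.invalid()
    desc = ShapeDescriptors(
        area=int(n),
        centroid=(float(xs.mean()), float(ys.mean())),
        bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
    )
    if cfg.anchor_mode == "hull":
        anchor, width_px = estimate_anchor_hull(main, cfg)
        scale = width_px / cfg.catheter_diameter_mm
    else:
        anchor = estimate_anchor(desc)
        scale = estimate_scale(desc, cfg)
    # exact integer numerators of (centroid − anchor): hull/bbox anchors are
    # half-integers, so 2·anchor is integral and the atan2 arguments below
    # are exact — mirror flips negate dx2 bit-exactly.
    dx2 = 2 * int(xs.sum()) - n * round(2 * anchor[0])
    dy2 = 2 * int(ys.sum()) - n * round(2 * anchor[1])
    if dx2 == 0 and dy2 == 0:
        return PoseEstimate.invalid()
    rotz = math.degrees(math.atan2(dx2, dy2))
    rotx = cfg.rotx_gain * _asymmetry(xs, ys)
    return PoseEstimate(
        valid=True,
        p1=float(anchor[0]),
        p2=float(anchor[1]),
        rotZ=rotz,
        rotX=rotx,
        scale=float(scale),
    )
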