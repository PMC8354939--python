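"""Boundary extraction and basic shape geometry on label masks.

This is the classical "border following" stage: every 8-connected component
of a class region yields one closed outer boundary pixel chain, and every
enclosed background pocket yields a hole-border chain (the region pixels
surrounding the pocket).  Foreground connectivity is 8, background
connectivity is 4 — the standard convention that keeps boundary topology
consistent (an 8-connected curve separates a 4-connected background).

The convex hull is computed with Andrew's monotone chain on the boundary
points.  Hull vertices are returned counter-clockwise as seen on screen
(image coordinates, y pointing down), with collinear points dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask_io import CLASS_IDS, validate_mask

__all__ = [
    "Contour",
    "ShapeDescriptors",
    "extract_contours",
    "convex_hull",
    "shape_descriptors",
    "fill_contours",
]

# 8-neighbour steps in clockwise screen order starting East (x right, y down).
_DIRS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)
_DIR_INDEX = {(int(dx), int(dy)): k for k, (dx, dy) in enumerate(_DIRS)}

_FG_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connected foreground
_BG_STRUCT = ndimage.generate_binary_structure(2, 1)  # 4-connected background


@dataclass(frozen=True)
class Contour:
    """Closed boundary pixel chain.

    ``points`` is an ``(N, 2)`` integer array of (x, y) pixel coordinates;
    consecutive points (and last→first) are 8-connected with no consecutive
    duplicates.  ``kind`` is ``"outer"`` for component boundaries and
    ``"hole"`` for borders around enclosed background pockets.  ``component``
    ties hole borders to their outer boundary.
    """

    points: np.ndarray
    kind: str
    class_id: int
    component: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=np.int64))

    @property
    def start(self) -> tuple[int, int]:
        return int(self.points[0, 0]), int(self.points[0, 1])


@dataclass(frozen=True)
class ShapeDescriptors:
    """Filled-region descriptors: pixel count, mass centroid and bounding box.

    ``centroid`` is the sub-pixel (x, y) mean of the region pixel centres;
    ``bbox`` is (xmin, ymin, xmax, ymax), inclusive pixel extremes.
    """

    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


def _scan_clockwise(mask, px, py, bx, by):
    """First foreground neighbour of (px,py) scanning clockwise after the
    backtrack (bx,by); returns it with the last background pixel examined."""
    d0 = _DIR_INDEX[(bx - px, by - py)]
    for k in range(1, 9):
        d = (d0 + k) % 8
        cx, cy = px + int(_DIRS[d, 0]), py + int(_DIRS[d, 1])
        if mask[cy, cx]:
            pb = (d0 + k - 1) % 8
            return (cx, cy), (px + int(_DIRS[pb, 0]), py + int(_DIRS[pb, 1]))
    return None, None


def _trace(mask: np.ndarray, start: tuple[int, int], backtrack: tuple[int, int]) -> np.ndarray:
    """Moore-neighbour border following.

    ``mask`` is a padded boolean array indexed [y, x]; ``start`` is a
    foreground border pixel and ``backtrack`` a background neighbour of it.
    Termination: the start pixel is re-entered and the successor about to be
    visited equals the chain's second pixel (the trace transition repeats).
    Returns the closed chain as an (N, 2) array of (x, y) points.
    """
    second, b = _scan_clockwise(mask, *start, *backtrack)
    if second is None:  # isolated pixel
        return np.asarray([start], dtype=np.int64)
    points = [start, second]
    p = second
    # generous cap: every pixel can be entered from each of 8 directions
    limit = 8 * int(mask.sum()) + 8
    for _ in range(limit):
        nxt, nb = _scan_clockwise(mask, *p, *b)
        if p == start and nxt == second:
            break
        p, b = nxt, nb
        points.append(p)
    if len(points) > 1 and points[-1] == points[0]:
        points.pop()
    return np.asarray(points, dtype=np.int64)


def extract_contours(mask: np.ndarray, class_id: int) -> list[Contour]:
    """Extract outer and hole boundary chains for one class of a label mask.

    Returns one ``kind="outer"`` contour per 8-connected component of the
    class region, plus one ``kind="hole"`` contour per enclosed background
    pocket, ordered by component scan order (topmost-then-leftmost start
    pixel).  An empty region yields an empty list.
    """
    arr = validate_mask(mask)
    if class_id not in CLASS_IDS:
        raise ValueError(f"invalid class id {class_id}")
    binary = arr == class_id
    if not binary.any():
        return []
    labels, n_comp = ndimage.label(binary, structure=_FG_STRUCT)
    padded = np.pad(binary, 1)
    contours: list[Contour] = []
    slices = ndimage.find_objects(labels)
    for comp in range(1, n_comp + 1):
        sl = slices[comp - 1]
        comp_mask = labels == comp
        ys, xs = np.nonzero(comp_mask)
        top = ys.min()
        sx = int(xs[ys == top].min())
        sy = int(top)
        # padded coordinates are shifted by +1
        comp_padded = np.pad(comp_mask, 1)
        chain = _trace(comp_padded, (sx + 1, sy + 1), (sx, sy + 1))
        contours.append(Contour(chain - 1, "outer", class_id, comp))
        # hole pockets: 4-connected background components fully enclosed by
        # this component (they never reach the padded frame border)
        ysl, xsl = sl
        sub = comp_mask[ysl, xsl]
        sub_pad = np.pad(sub, 1)
        bg_labels, n_bg = ndimage.label(~sub_pad, structure=_BG_STRUCT)
        if n_bg <= 1:
            continue
        border_ids = np.unique(
            np.concatenate(
                [bg_labels[0], bg_labels[-1], bg_labels[:, 0], bg_labels[:, -1]]
            )
        )
        for bg_id in range(1, n_bg + 1):
            if bg_id in border_ids:
                continue
            hys, hxs = np.nonzero(bg_labels == bg_id)
            htop = hys.min()
            hx = int(hxs[hys == htop].min())
            hy = int(htop)
            # back to full-image padded coordinates
            gx = hx - 1 + xsl.start + 1
            gy = hy - 1 + ysl.start + 1
            # pixel above the topmost hole pixel belongs to the component
            chain = _trace(comp_padded, (gx, gy - 1), (gx, gy))
            contours.append(Contour(chain - 1, "hole", class_id, comp))
    return contours


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> list[tuple[float, float]]:
    """Convex hull of a 2-D point set (monotone chain).

    Vertices are returned counter-clockwise as seen on screen (y down), i.e.
    with negative shoelace signed area in the mathematical convention, and
    collinear interior points are excluded.  Degenerate inputs (one point,
    collinear sets) return the extreme points only.
    """
    pts = [(float(x), float(y)) for x, y in np.asarray(points, dtype=float).reshape(-1, 2)]
    if not pts:
        raise ValueError("convex hull of an empty point set")
    pts = sorted(set(pts))
    if len(pts) <= 2:
        return pts
    lower: list[tuple[float, float]] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) >= 0:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) >= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) == 2 and hull[0] == hull[1]:
        hull = hull[:1]
    return hull


def shape_descriptors(mask: np.ndarray, contour: Contour) -> ShapeDescriptors:
    """Descriptors of the filled region the contour belongs to.

    The region is the 8-connected component of ``contour.class_id`` pixels
    containing the contour's start point; area is its pixel count, the
    centroid the mean of its pixel coordinates and the bbox its inclusive
    axis-aligned extremes.
    """
    arr = validate_mask(mask)
    xs_c = contour.points[:, 0]
    ys_c = contour.points[:, 1]
    if np.any(arr[ys_c, xs_c] != contour.class_id):
        raise ValueError("contour pixel is not of the requested class in this mask")
    binary = arr == contour.class_id
    labels, _ = ndimage.label(binary, structure=_FG_STRUCT)
    sx, sy = contour.start
    comp = labels == labels[sy, sx]
    ys, xs = np.nonzero(comp)
    return ShapeDescriptors(
        area=int(comp.sum()),
        centroid=(float(xs.mean()), float(ys.mean())),
        bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
    )


def fill_contours(contours: list[Contour], shape: tuple[int, int]) -> np.ndarray:
    """Rebuild the class region from its boundary chains.

    Fills each outer chain and carves each hole's interior (keeping the hole
    border pixels, which belong to the region).  For chains produced by
    :func:`extract_contours` this reproduces the class region exactly.
    ``shape`` is (height, width); returns a boolean array.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    by_comp: dict[int, dict[str, list[Contour]]] = {}
    for c in contours:
        by_comp.setdefault(c.component, {"outer": [], "hole": []})[c.kind].append(c)
    for group in by_comp.values():
        region = np.zeros((h, w), dtype=bool)
        for c in group["outer"]:
            chain = np.zeros((h, w), dtype=bool)
            chain[c.points[:, 1], c.points[:, 0]] = True
            region |= ndimage.binary_fill_holes(chain)
        for c in group["hole"]:
            chain = np.zeros((h, w), dtype=bool)
            chain[c.points[:, 1], c.points[:, 0]] = True
            region &= ~(ndimage.binary_fill_holes(chain) & ~chain)
        out |= region
    return out
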