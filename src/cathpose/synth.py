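"""Synthetic endoscopy-like scenes with exact ground-truth masks and poses.

No deposited surgical footage exists for this problem, so every stage is
exercised on rendered stand-ins: a near-vertical tapered catheter silhouette
over a tissue-like background, optionally occluded by grey instrument
shapes, plus the two characteristic failure modes of intra-operative frames
(specular light blow-out and blood occlusion).

The silhouette construction inverts the pose-measurement geometry.  The
catheter is an isosceles trapezoid with its apex edge centred at the anchor
``(p1, p2)``, axis tilted ``rotZ`` degrees from vertical, projected length
``length_px·cos(rotX)`` and base width ``diameter_px·(1 + β·sin(rotX))``
(weak-perspective taper, β = ``taper_strength``), so that a catheter rotated
toward the camera (rotX > 0) shows a larger lower area.  The trapezoid is
symmetric about its axis, hence its centroid lies on the axis and the
anchor→centroid direction equals rotZ exactly; pose estimation on the clean
mask is therefore a genuine round-trip oracle.

Determinism: ``params.seed`` drives appearance only (background texture,
shading noise) — two scenes differing only in seed have bit-identical
masks.  Occluding-tool layout, which does change the mask, is controlled by
the separate ``layout_seed``.
"""

from __future__ import annotations

import csv
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pose import PoseEstimate

__all__ = [
    "SceneParams",
    "ParamRanges",
    "SyntheticScene",
    "render_scene",
    "corrupt_scene",
    "generate_dataset",
    "write_dataset",
    "random_blob_mask",
]

DEFAULT_DIAMETER_MM = 6.0


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth scene parameters.

    ``anchor`` is the catheter apex (p1, p2) in pixels; rotations are in
    degrees; ``taper_strength`` is the weak-perspective β; ``seed`` controls
    appearance, ``layout_seed`` the tool placement (derived deterministically
    from the geometry when left None).
    """

    anchor: tuple[float, float]
    rotZ: float = 0.0
    rotX: float = 0.0
    diameter_px: float = 12.0
    length_px: float = 70.0
    taper_strength: float = 0.35
    n_tools: int = 0
    corruption: str = "none"
    seed: int = 0
    layout_seed: int | None = None

    def __post_init__(self) -> None:
        if self.diameter_px < 3:
            raise ValueError("diameter_px must be >= 3")
        if self.length_px <= self.diameter_px:
            raise ValueError("length_px must exceed diameter_px")
        if not (abs(self.rotZ) < 90 and abs(self.rotX) < 80):
            raise ValueError("require |rotZ| < 90 and |rotX| < 80")
        if self.taper_strength < 0:
            raise ValueError("taper_strength must be >= 0")
        if self.corruption not in ("none", "highlight", "blood"):
            raise ValueError(f"unknown corruption {self.corruption!r}")

    def effective_layout_seed(self) -> int:
        if self.layout_seed is not None:
            return int(self.layout_seed)
        key = (
            f"{self.anchor[0]:.4f},{self.anchor[1]:.4f},{self.rotZ:.4f},"
            f"{self.rotX:.4f},{self.diameter_px:.4f},{self.length_px:.4f},{self.n_tools}"
        )
        return zlib.crc32(key.encode())


@dataclass
class SyntheticScene:
    """Rendered frame + exact mask + ground-truth pose.

    ``observed_mask`` is what a downstream consumer would see — identical to
    ``mask`` except after blood occlusion, which hides part of the catheter
    while ``mask`` keeps the clean ground truth.
    """

    image: np.ndarray
    mask: np.ndarray
    truth: PoseEstimate
    params: SceneParams
    observed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.observed_mask is None:
            self.observed_mask = self.mask


def _trapezoid_corners(params: SceneParams) -> np.ndarray:
    """Corners [T1, T2, B2, B1] of the silhouette, (x, y) rows."""
    ax, ay = params.anchor
    rz = math.radians(params.rotZ)
    rx = math.radians(params.rotX)
    u = np.array([math.sin(rz), math.cos(rz)])  # axis, downward
    v = np.array([math.cos(rz), -math.sin(rz)])  # across
    lp = params.length_px * math.cos(rx)
    w_top = params.diameter_px
    w_bot = params.diameter_px * (1.0 + params.taper_strength * math.sin(rx))
    a = np.array([ax, ay])
    b = a + lp * u
    return np.stack(
        [a - (w_top / 2) * v, a + (w_top / 2) * v, b + (w_bot / 2) * v, b - (w_bot / 2) * v]
    )


def _fill_convex(corners: np.ndarray, width: int, height: int) -> np.ndarray:
    """Boolean raster of a convex polygon: pixel centres inside all edges."""
    xs = np.arange(width, dtype=np.float64)
    ys = np.arange(height, dtype=np.float64)
    px, py = np.meshgrid(xs, ys)
    centre = corners.mean(axis=0)
    inside = np.ones((height, width), dtype=bool)
    n = len(corners)
    for i in range(n):
        c0, c1 = corners[i], corners[(i + 1) % n]
        ex, ey = c1[0] - c0[0], c1[1] - c0[1]
        val = (px - c0[0]) * ey - (py - c0[1]) * ex
        ref = (centre[0] - c0[0]) * ey - (centre[1] - c0[1]) * ex
        inside &= (val * np.sign(ref)) >= 0
    return inside


def _tissue_background(width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth reddish texture emulating tissue at cartoon level."""
    low = rng.random((max(height // 8, 2), max(width // 8, 2)))
    t = ndimage.zoom(low, (height / low.shape[0], width / low.shape[1]), order=1)
    t = t[:height, :width]
    if t.shape != (height, width):  # zoom can round down by one row/col
        t = np.pad(t, ((0, height - t.shape[0]), (0, width - t.shape[1])), mode="edge")
    img = np.empty((height, width, 3), dtype=np.float64)
    img[..., 0] = 110 + 90 * t
    img[..., 1] = 35 + 45 * t
    img[..., 2] = 45 + 35 * t
    img += rng.normal(0, 4, img.shape)
    return img


def _tool_polygons(
    params: SceneParams, width: int, height: int
) -> list[np.ndarray]:
    """Convex grey instrument quadrilaterals entering from a frame edge."""
    rng = np.random.default_rng(params.effective_layout_seed())
    polys = []
    for _ in range(params.n_tools):
        edge = rng.integers(0, 4)
        t = rng.uniform(0.2, 0.8)
        if edge == 0:
            entry, inward = np.array([t * width, 0.0]), np.array([0.0, 1.0])
        elif edge == 1:
            entry, inward = np.array([t * width, height - 1.0]), np.array([0.0, -1.0])
        elif edge == 2:
            entry, inward = np.array([0.0, t * height]), np.array([1.0, 0.0])
        else:
            entry, inward = np.array([width - 1.0, t * height]), np.array([-1.0, 0.0])
        ang = rng.uniform(-0.5, 0.5)
        c, s = math.cos(ang), math.sin(ang)
        d = np.array([c * inward[0] - s * inward[1], s * inward[0] + c * inward[1]])
        perp = np.array([-d[1], d[0]])
        length = rng.uniform(0.3, 0.6) * min(width, height)
        w0 = rng.uniform(0.06, 0.12) * min(width, height)
        w1 = w0 * rng.uniform(0.7, 1.0)
        polys.append(
            np.stack(
                [
                    entry - w0 * perp,
                    entry + w0 * perp,
                    entry + length * d + w1 * perp,
                    entry + length * d - w1 * perp,
                ]
            )
        )
    return polys


def render_scene(
    params: SceneParams,
    width: int = 96,
    height: int = 96,
    diameter_mm: float = DEFAULT_DIAMETER_MM,
) -> SyntheticScene:
    """Render one scene: tissue background, shaded catheter silhouette and
    optional occluding tools, with the exact class mask and true pose.

    Raises ``ValueError`` if the silhouette lies entirely outside the frame.
    Deterministic given ``params`` (bit-exact for image and mask).
    """
    corners = _trapezoid_corners(params)
    cath = _fill_convex(corners, width, height)
    if not cath.any():
        raise ValueError("catheter silhouette entirely outside the frame")

    rng = np.random.default_rng(params.seed)
    img = _tissue_background(width, height, rng)

    # cylinder-like lateral shading of the catheter: pale, brightest on axis
    ax, ay = params.anchor
    rz = math.radians(params.rotZ)
    v = np.array([math.cos(rz), -math.sin(rz)])
    xs = np.arange(width, dtype=np.float64)
    ys = np.arange(height, dtype=np.float64)
    px, py = np.meshgrid(xs, ys)
    dperp = (px - ax) * v[0] + (py - ay) * v[1]
    half_w = max(params.diameter_px, params.diameter_px * (1 + params.taper_strength)) / 2
    lat = np.clip(np.abs(dperp) / (half_w + 1e-9), 0.0, 1.0)
    shade = 0.72 + 0.28 * np.sqrt(1.0 - lat**2)
    img[cath, 0] = 236 * shade[cath]
    img[cath, 1] = 230 * shade[cath]
    img[cath, 2] = 206 * shade[cath]
    img[cath] += rng.normal(0, 2, (int(cath.sum()), 3))

    mask = np.zeros((height, width), dtype=np.uint8)
    mask[cath] = 2

    for poly in _tool_polygons(params, width, height):
        tool = _fill_convex(poly, width, height)
        mask[tool] = 1
        grad = 150 + 40 * ((px - poly[0, 0]) ** 2 + (py - poly[0, 1]) ** 2) ** 0.5 / (
            width + height
        )
        for ch, f in enumerate((1.0, 1.02, 1.06)):
            img[..., ch][tool] = np.clip(grad[tool] * f, 0, 255)
        img[tool] += rng.normal(0, 3, (int(tool.sum()), 3))

    image = np.clip(img, 0, 255).astype(np.uint8)
    truth = PoseEstimate(
        valid=True,
        p1=float(params.anchor[0]),
        p2=float(params.anchor[1]),
        rotZ=float(params.rotZ),
        rotX=float(params.rotX),
        scale=float(params.diameter_px) / diameter_mm,
    )
    scene = SyntheticScene(image=image, mask=mask, truth=truth, params=params)
    if params.corruption != "none":
        scene = corrupt_scene(scene, params.corruption, params.seed + 1)
    return scene


def corrupt_scene(
    scene: SyntheticScene,
    mode: str,
    seed: int,
    extent: float = 0.35,
    coverage: float = 0.3,
) -> SyntheticScene:
    """Apply one of the two characteristic failure modes.

    ``mode="highlight"``: saturate an elliptical patch (size ∝ ``extent``,
    placed near the catheter) to near-white — image only, masks unchanged;
    ``extent=0`` is a no-op.

    ``mode="blood"``: paint dark-red blobs over the lower ``coverage``
    fraction of catheter pixels and relabel them background in
    ``observed_mask``; ``mask`` keeps the clean ground truth.
    """
    h, w = scene.mask.shape
    rng = np.random.default_rng(seed)
    img = scene.image.astype(np.float64).copy()
    if mode == "highlight":
        if extent <= 0:
            return SyntheticScene(
                scene.image.copy(), scene.mask.copy(), scene.truth, scene.params,
                scene.observed_mask.copy(),
            )
        ys_c, xs_c = np.nonzero(scene.mask == 2)
        if xs_c.size:
            cx = float(xs_c.mean()) + rng.uniform(-0.1, 0.1) * w
            cy = float(ys_c.mean()) + rng.uniform(-0.1, 0.1) * h
        else:
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        a = extent * w / 2 * rng.uniform(0.7, 1.3)
        b = extent * h / 2 * rng.uniform(0.7, 1.3)
        px, py = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        r2 = ((px - cx) / max(a, 1e-9)) ** 2 + ((py - cy) / max(b, 1e-9)) ** 2
        blown = r2 <= 1.0
        # soft core: fully saturated centre, bright rim
        level = np.clip(255 - 40 * np.sqrt(np.clip(r2, 0, 1)), 0, 255)
        for ch in range(3):
            img[..., ch][blown] = np.maximum(img[..., ch][blown], level[blown])
        return SyntheticScene(
            np.clip(img, 0, 255).astype(np.uint8),
            scene.mask.copy(), scene.truth, scene.params, scene.observed_mask.copy(),
        )
    if mode == "blood":
        observed = scene.mask.copy()
        ys_c, xs_c = np.nonzero(scene.mask == 2)
        if ys_c.size:
            order = np.lexsort((xs_c, ys_c))  # by row, then column
            n_cover = int(round(coverage * ys_c.size))
            if n_cover > 0:
                sel = order[-n_cover:]  # lowest rows = near end of the catheter
                yy, xx = ys_c[sel], xs_c[sel]
                dark = rng.uniform(0.75, 1.0, yy.size)
                img[yy, xx, 0] = 70 * dark
                img[yy, xx, 1] = 12 * dark
                img[yy, xx, 2] = 16 * dark
                observed[yy, xx] = 0
        return SyntheticScene(
            np.clip(img, 0, 255).astype(np.uint8),
            scene.mask.copy(), scene.truth, scene.params, observed,
        )
    raise ValueError(f"unknown corruption mode {mode!r}")


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for :func:`generate_dataset`.

    Sizes default to fractions of the frame so the same ranges work at desk
    scale (96×96) and at the reference resolution (416×608): diameter
    0.10–0.15 and length 0.55–0.75 of the smaller frame side.  Anchors are
    placed so the whole silhouette stays inside the frame.
    """

    rotz: tuple[float, float] = (-30.0, 30.0)
    rotx: tuple[float, float] = (-40.0, 40.0)
    diameter_frac: tuple[float, float] = (0.10, 0.15)
    length_frac: tuple[float, float] = (0.55, 0.75)
    n_tools: tuple[int, int] = (0, 0)
    taper_strength: float = 0.35

    def __post_init__(self) -> None:
        for lo, hi in (self.rotz, self.rotx, self.diameter_frac, self.length_frac):
            if hi < lo:
                raise ValueError("empty range")


def sample_params(
    ranges: ParamRanges, width: int, height: int, rng: np.random.Generator
) -> SceneParams:
    """Draw one parameter set; the anchor window is tightened per-draw so the
    tilted trapezoid fits fully inside the frame."""
    side = min(width, height)
    rotz = rng.uniform(*ranges.rotz)
    rotx = rng.uniform(*ranges.rotx)
    diam = rng.uniform(*ranges.diameter_frac) * side
    length = rng.uniform(*ranges.length_frac) * side
    lp = length * math.cos(math.radians(rotx))
    w_half = diam * (1 + ranges.taper_strength) / 2 + 2
    dx = lp * math.sin(math.radians(rotz))
    x_lo = w_half + max(0.0, -dx)
    x_hi = width - 1 - w_half - max(0.0, dx)
    y_lo = abs(diam / 2 * math.sin(math.radians(rotz))) + 2
    y_hi = height - 1 - lp * math.cos(math.radians(rotz)) - w_half
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ValueError("frame too small for the requested silhouette ranges")
    anchor = (rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi))
    n_tools = int(rng.integers(ranges.n_tools[0], ranges.n_tools[1] + 1))
    return SceneParams(
        anchor=anchor,
        rotZ=rotz,
        rotX=rotx,
        diameter_px=diam,
        length_px=length,
        taper_strength=ranges.taper_strength,
        n_tools=n_tools,
        seed=int(rng.integers(0, 2**31 - 1)),
        layout_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n: int,
    ranges: ParamRanges | None = None,
    seed: int = 0,
    width: int = 96,
    height: int = 96,
    train_fraction: float = 0.8,
    diameter_mm: float = DEFAULT_DIAMETER_MM,
) -> tuple[list[SyntheticScene], list[dict]]:
    """Generate ``n`` seeded scenes plus a manifest of their ground truth.

    The manifest rows carry file-name stems, the split assignment
    (first ``train_fraction`` of scenes → train) and the true pose columns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or ParamRanges()
    rng = np.random.default_rng(seed)
    scenes: list[SyntheticScene] = []
    manifest: list[dict] = []
    n_train = int(round(train_fraction * n))
    for i in range(n):
        params = sample_params(ranges, width, height, rng)
        scene = render_scene(params, width, height, diameter_mm)
        scenes.append(scene)
        manifest.append(
            {
                "frame": f"scene_{i:05d}",
                "split": "train" if i < n_train else "test",
                "p1": scene.truth.p1,
                "p2": scene.truth.p2,
                "rotZ_deg": scene.truth.rotZ,
                "rotX_deg": scene.truth.rotX,
                "scale_px_per_mm": scene.truth.scale,
                "diameter_px": params.diameter_px,
                "length_px": params.length_px,
                "n_tools": params.n_tools,
                "seed": params.seed,
                "layout_seed": params.layout_seed,
            }
        )
    return scenes, manifest


def write_dataset(
    scenes: list[SyntheticScene], manifest: list[dict], out_dir: str | Path
) -> Path:
    """Write paired frame/mask PNGs plus the manifest CSV; returns the CSV path."""
    from .mask_io import write_frame, write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scene, row in zip(scenes, manifest):
        write_frame(out / f"{row['frame']}.png", scene.image)
        write_mask(out / f"{row['frame']}_mask.png", scene.mask)
        if scene.observed_mask is not scene.mask and not np.array_equal(
            scene.observed_mask, scene.mask
        ):
            write_mask(out / f"{row['frame']}_observed.png", scene.observed_mask)
    csv_path = out / "manifest.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()))
        writer.writeheader()
        writer.writerows(manifest)
    return csv_path


def random_blob_mask(
    width: int,
    height: int,
    seed: int,
    n_classes: int = 3,
    smooth: float = 4.0,
) -> np.ndarray:
    """Random smooth multi-class blob mask (thresholded filtered noise).

    A test fixture generator: produces organic regions with occasional holes
    for exercising boundary extraction and IoU counting; labelled synthetic.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=np.uint8)
    for class_id in range(1, n_classes):
        noise = ndimage.gaussian_filter(rng.standard_normal((height, width)), smooth)
        thr = np.quantile(noise, 0.8)
        mask[(noise > thr) & (mask == 0)] = class_id
    return mask
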