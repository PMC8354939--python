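import numpy as np
import pytest

from cathpose.synth import ParamRanges, generate_dataset
from cathpose.unet import SegModelConfig, TrainConfig, build_model, train_model


def brute_force_hull(points) -> set[tuple[float, float]]:
    """O(n^3) half-plane convex-hull vertex oracle.

    A directed pair (a, b) supports the hull iff every point lies on one
    side of (or on) the line a->b; of the points collinear with a supporting
    line only the two extremes are vertices.  Independent of the monotone
    chain implementation under test.
    """
    pts = sorted({(float(x), float(y)) for x, y in points})
    n = len(pts)
    if n <= 2:
        return set(pts)
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        ax, ay = pts[i]
        for j in range(n):
            if i == j:
                continue
            bx, by = pts[j]
            on_line = []
            one_side = True
            for px, py in pts:
                cr = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
                if cr > 0:
                    one_side = False
                    break
                if cr == 0:
                    on_line.append((px, py))
            if one_side:
                verts.add(min(on_line))
                verts.add(max(on_line))
    return verts


@pytest.fixture(scope="session")
def desk_scenes():
    """80 seeded desk-scale scenes with occluding tools: 64 train + 16 test."""
    scenes, manifest = generate_dataset(
        80, ParamRanges(n_tools=(0, 2)), seed=11, width=96, height=96, train_fraction=0.8
    )
    return scenes[:64], scenes[64:]


@pytest.fixture(scope="session")
def trained_model(desk_scenes):
    """Segmentation net trained once per session with the reference recipe
    (batch 4, Adam 0.001 / 0.9 / 0.999, categorical cross-entropy, 20 epochs)."""
    train, _ = desk_scenes
    model = build_model(SegModelConfig(input_hw=(96, 96)), seed=11)
    history = train_model(model, train, TrainConfig(seed=11))
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
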