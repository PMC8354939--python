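"""Minimal encoder-decoder semantic segmentation network in pure NumPy.

A U-Net-style net: an encoder of 3×3 conv + ReLU + 2×2 max-pool blocks, a
bottleneck conv, and a mirrored decoder of nearest-neighbour ×2 upsampling
with skip-connection concatenation, ending in a per-pixel 3-way softmax.
Convolutions run as im2col GEMMs in float32; training uses Adam with
categorical cross-entropy.  Everything is deterministic given the seeds, so
identical runs produce bit-identical histories on the same machine.

The network is intentionally small (default ~10⁵ parameters): trained
weights are not the reusable artefact here — the net exists to exercise the
full segmentation→pose→overlay chain at desk scale on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mask_io import N_CLASSES

__all__ = [
    "SegModelConfig",
    "TrainConfig",
    "TrainHistory",
    "SegModel",
    "build_model",
    "train_model",
    "predict_mask",
    "predict_proba",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture: ``input_hw`` must be divisible by ``2**depth``;
    encoder level *i* has ``base_channels · 2**i`` filters."""

    input_hw: tuple[int, int] = (96, 96)
    base_channels: int = 16
    depth: int = 3
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        h, w = self.input_hw
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(f"input dims {self.input_hw} not divisible by 2^{self.depth}")
        if self.n_classes != N_CLASSES:
            raise ValueError("this segmentation task has exactly 3 classes")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe; the defaults are the reference recipe
    (batch 4, Adam lr 0.001 with betas 0.9/0.999, categorical
    cross-entropy, 20 epochs)."""

    batch_size: int = 4
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss."""

    losses: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,loss\n")
            for i, v in enumerate(self.losses):
                fh.write(f"{i},{v}\n")


# ---------------------------------------------------------------------------
# conv primitives (NCHW, float32, 'same' padding for 3x3)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) → (N·H·W, C·9) patches of the zero-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N,C,H,W,3,3) → (N,H,W,C,3,3) → (NHW, C*9)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_in * 9, c_out)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = cols @ self.w + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray):
        cols, xshape = self._cache
        n, c, h, w = xshape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, -1)
        dw = cols.T @ d2
        db = d2.sum(axis=0)
        dx = _col2im(d2 @ self.w.T, xshape)
        return dx, [dw, db]


class _Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        flat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        out = flat @ self.w + self.b
        if train:
            self._cache = (flat, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray):
        flat, xshape = self._cache
        n, c, h, w = xshape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, dout.shape[1])
        dw = flat.T @ d2
        db = d2.sum(axis=0)
        dx = (d2 @ self.w.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        return dx, [dw, db]


def _relu_fwd(x):
    return np.maximum(x, 0.0)


def _pool2_fwd(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = r.argmax(axis=-1)
    return r.max(axis=-1), idx


def _pool2_bwd(dout, idx, in_shape):
    n, c, h, w = in_shape
    oh, ow = h // 2, w // 2
    scat = np.zeros((n, c, oh, ow, 4), dtype=dout.dtype)
    np.put_along_axis(scat, idx[..., None], dout[..., None], axis=-1)
    return scat.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def _up2_fwd(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_bwd(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SegModel:
    """Encoder-decoder segmentation net; see module docstring."""

    def __init__(self, cfg: SegModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        enc_ch = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self.enc = []
        c_prev = 3
        for c in enc_ch:
            self.enc.append(_Conv3x3(c_prev, c, rng))
            c_prev = c
        self.bottleneck = _Conv3x3(c_prev, c_prev, rng)
        self.dec = []
        for i in reversed(range(cfg.depth)):
            c_out = max(enc_ch[i] // 2, cfg.base_channels)
            self.dec.append(_Conv3x3(c_prev + enc_ch[i], c_out, rng))
            c_prev = c_out
        self.head = _Conv1x1(c_prev, cfg.n_classes, rng)
        self.layers = self.enc + [self.bottleneck] + self.dec + [self.head]

    @property
    def bottleneck_hw(self) -> tuple[int, int]:
        h, w = self.cfg.input_hw
        f = 2**self.cfg.depth
        return h // f, w // f

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N,3,H,W) float32 in [0,1] → logits (N,n_classes,H,W)."""
        self._caches = []
        skips = []
        for conv in self.enc:
            a = _relu_fwd(conv.forward(x, train))
            skips.append(a)
            pooled, idx = _pool2_fwd(a)
            if train:
                self._caches.append(("enc", a, idx, a.shape))
            x = pooled
        b = _relu_fwd(self.bottleneck.forward(x, train))
        if train:
            self._caches.append(("bott", b))
        x = b
        for i, conv in enumerate(self.dec):
            up = _up2_fwd(x)
            skip = skips[len(skips) - 1 - i]
            cat = np.concatenate([up, skip], axis=1)
            a = _relu_fwd(conv.forward(cat, train))
            if train:
                self._caches.append(("dec", a, up.shape[1]))
            x = a
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Gradient of the loss w.r.t. every parameter (same order as
        :meth:`parameters`); caches from the last ``forward(train=True)``."""
        grads: dict[int, list[np.ndarray]] = {}
        dx, g = self.head.backward(dlogits)
        grads[id(self.head)] = g
        cache_iter = list(self._caches)
        dskips = [None] * len(self.enc)
        for i in reversed(range(len(self.dec))):
            kind, a, up_ch = cache_iter.pop()
            assert kind == "dec"
            dx = dx * (a > 0)
            dcat, g = self.dec[i].backward(dx)
            grads[id(self.dec[i])] = g
            dup = dcat[:, :up_ch]
            dskip = dcat[:, up_ch:]
            si = len(self.enc) - 1 - i
            dskips[si] = dskip if dskips[si] is None else dskips[si] + dskip
            dx = _up2_bwd(dup)
        kind, b = cache_iter.pop()
        assert kind == "bott"
        dx = dx * (b > 0)
        dx, g = self.bottleneck.backward(dx)
        grads[id(self.bottleneck)] = g
        for i in reversed(range(len(self.enc))):
            kind, a, idx, ashape = cache_iter.pop()
            assert kind == "enc"
            dx = _pool2_bwd(dx, idx, ashape)
            if dskips[i] is not None:
                dx = dx + dskips[i]
            dx = dx * (a > 0)
            dx, g = self.enc[i].backward(dx)
            grads[id(self.enc[i])] = g
        return [g for layer in self.layers for g in grads[id(layer)]]

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_parameters(self, values: list[np.ndarray]) -> None:
        k = 0
        for layer in self.layers:
            layer.w = values[k].astype(np.float32)
            layer.b = values[k + 1].astype(np.float32)
            k += 2


def build_model(cfg: SegModelConfig, seed: int = 0) -> SegModel:
    """Construct a seeded (He-initialized) model for the given config."""
    return SegModel(cfg, seed)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _ce_loss_and_grad(logits: np.ndarray, targets: np.ndarray):
    """Categorical cross-entropy over pixels; targets (N,H,W) int."""
    p = _softmax(logits)
    n, k, h, w = logits.shape
    idx = (
        np.arange(n)[:, None, None],
        targets,
        np.arange(h)[None, :, None],
        np.arange(w)[None, None, :],
    )
    picked = np.clip(p[idx[0], targets, idx[2], idx[3]], 1e-12, None)
    loss = float(-np.log(picked).mean())
    grad = p.copy()
    onehot = np.zeros_like(p)
    onehot[idx[0], targets, idx[2], idx[3]] = 1.0
    grad = (grad - onehot) / (n * h * w)
    return loss, grad.astype(np.float32)


def _prep_images(images: list[np.ndarray]) -> np.ndarray:
    arr = np.stack([im.astype(np.float32) / 255.0 for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def train_model(model: SegModel, train_scenes, cfg: TrainConfig | None = None) -> TrainHistory:
    """Train on synthetic scenes (``scene.image`` / ``scene.mask`` pairs)
    with Adam and categorical cross-entropy; seeded shuffling each epoch.

    Requires at least one scene; returns the per-epoch loss history.
    """
    cfg = cfg or TrainConfig()
    if len(train_scenes) == 0:
        raise ValueError("empty training set")
    h, w = model.cfg.input_hw
    for s in train_scenes:
        if s.mask.shape != (h, w):
            raise ValueError(f"scene shape {s.mask.shape} does not match model input {(h, w)}")
    images = _prep_images([s.image for s in train_scenes])
    masks = np.stack([s.mask.astype(np.int64) for s in train_scenes])

    params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    n = len(train_scenes)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits = model.forward(images[sel], train=True)
            loss, dlogits = _ce_loss_and_grad(logits, masks[sel])
            grads = model.backward(dlogits)
            t += 1
            bc1 = 1.0 - cfg.beta1**t
            bc2 = 1.0 - cfg.beta2**t
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= cfg.beta1
                mi += (1 - cfg.beta1) * g
                vi *= cfg.beta2
                vi += (1 - cfg.beta2) * g * g
                p -= cfg.learning_rate * (mi / bc1) / (np.sqrt(vi / bc2) + 1e-8)
            epoch_losses.append(loss)
        history.losses.append(float(np.mean(epoch_losses)))
    return history


def predict_proba(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (n_classes, H, W) for one RGB frame."""
    h, w = model.cfg.input_hw
    if image.shape[:2] != (h, w):
        raise ValueError(f"image shape {image.shape[:2]} does not match model input {(h, w)}")
    x = _prep_images([image])
    return _softmax(model.forward(x, train=False))[0]


def predict_mask(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Predicted label mask: per-pixel argmax over the 3-class softmax
    (ties resolve to the lower class id)."""
    return predict_proba(model, image).argmax(axis=0).astype(np.uint8)


def save_model(model: SegModel, path) -> None:
    """Checkpoint: config JSON + weight arrays in one ``.npz``."""
    meta = json.dumps(
        {
            "input_hw": list(model.cfg.input_hw),
            "base_channels": model.cfg.base_channels,
            "depth": model.cfg.depth,
            "n_classes": model.cfg.n_classes,
            "seed": model.seed,
        }
    )
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> SegModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = SegModelConfig(
            input_hw=tuple(meta["input_hw"]),
            base_channels=meta["base_channels"],
            depth=meta["depth"],
            n_classes=meta["n_classes"],
        )
        model = SegModel(cfg, meta["seed"])
        values = [data[f"p{i}"] for i in range(len(model.parameters()))]
    model.set_parameters(values)
    return model
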