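"""Modified 2-D U-Net implemented directly on numpy.

The architecture is the classic encoder/decoder with skip connections,
modified in three ways that matter for slice-wise volume reassembly:

* "same" padding everywhere, so the per-pixel output aligns exactly with the
  input slice (the original valid-padded U-Net crops);
* a dropout layer after the two 3x3 conv+ReLU layers of every encoder level
  (regularization against the small-cohort setting);
* a reduced channel plan, default ``(32, 64, 128, 256, 512)`` along the
  contracting path.

The decoder upsamples by nearest-neighbour x2 followed by a 2x2 convolution,
concatenates the matching encoder feature map, and applies two 3x3 conv+ReLU
layers; the head is a 1x1 convolution to ``n_classes`` followed by a per-pixel
softmax.  The final 1x1 convolution is zero-initialized so an untrained model
outputs exactly uniform class probabilities; all other weights use seeded
He-normal initialization.

Convolutions are evaluated as sums of kernel-shifted BLAS matrix products in
float32; the module provides forward, backward (categorical cross-entropy)
and an Adam optimizer, which is all the training module needs.  Everything is
driven by explicit ``numpy.random.Generator`` instances, so runs are
reproducible bit-for-bit on a fixed seed in single-threaded BLAS mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["UNetConfig", "UNet", "Adam", "build_unet", "predict_batch", "softmax_cross_entropy"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**(len(encoder_channels)-1)`` so
    every max-pool halving is exact.
    """

    encoder_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    dropout_rate: float = 0.5
    input_size: int = 256
    n_classes: int = 2
    in_channels: int = 1
    up_mode: str = "nearest"  # nearest-neighbour x2 + 2x2 conv, or "transposed"
    seed: int = 0

    def validate(self) -> None:
        ch = self.encoder_channels
        if len(ch) < 2 or any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError("encoder_channels must be strictly increasing, length >= 2")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.up_mode not in ("nearest", "transposed"):
            raise ValueError("up_mode must be 'nearest' or 'transposed'")
        depth = len(ch) - 1
        if self.input_size % (2**depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{depth}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__ | {
            "encoder_channels": list(self.encoder_channels)}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "UNetConfig":
        d = json.loads(Path(path).read_text())
        d["encoder_channels"] = tuple(d["encoder_channels"])
        return cls(**d)


# ------------------------------------------------------------- primitives
# All feature maps are NHWC float32.


def _pad_for_kernel(k: int) -> tuple[int, int]:
    # "same" padding; even kernels pad one less on the leading side
    total = k - 1
    return total // 2, total - total // 2


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded cross-correlation as a sum of shifted BLAS products.

    For each kernel offset ``(i, j)`` the shifted input block is flattened
    and multiplied against the ``(cin, cout)`` weight slice — cheaper on one
    core than materializing a full im2col matrix.  Returns the output and
    the padded input (the backward cache).
    """
    kh, kw, cin, cout = w.shape
    if kh == 1 and kw == 1:
        y = x @ w.reshape(cin, cout) + b
        return y, x
    ph, pw = _pad_for_kernel(kh), _pad_for_kernel(kw)
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
    B, H, W = x.shape[:3]
    acc = np.zeros((B * H * W, cout), dtype=np.result_type(x.dtype, w.dtype))
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(xp[:, i : i + H, j : j + W, :]).reshape(-1, cin)
            acc += xs @ w[i, j]
    acc += b
    return acc.reshape(B, H, W, cout), xp


def _conv_backward(dy: np.ndarray, cache, x_shape, w: np.ndarray):
    """Gradients of a same-padded convolution given the padded-input cache."""
    kh, kw, cin, cout = w.shape
    B, H, W = x_shape[:3]
    dy2 = np.ascontiguousarray(dy).reshape(B * H * W, cout)
    if kh == 1 and kw == 1:
        x = cache
        dw = (x.reshape(-1, cin).T @ dy2).reshape(w.shape)
        db = dy2.sum(axis=0)
        dx = (dy2 @ w.reshape(cin, cout).T).reshape(B, H, W, cin)
        return dx, dw, db
    xp = cache
    ph, pw = _pad_for_kernel(kh), _pad_for_kernel(kw)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(xp[:, i : i + H, j : j + W, :]).reshape(-1, cin)
            dw[i, j] = xs.T @ dy2
            dxp[:, i : i + H, j : j + W, :] += (dy2 @ w[i, j].T).reshape(B, H, W, cin)
    db = dy2.sum(axis=0)
    return dxp[:, ph[0] : ph[0] + H, pw[0] : pw[0] + W, :], dw, db


def _maxpool_forward(x: np.ndarray):
    B, H, W, C = x.shape
    xw = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    xw = xw.reshape(B, H // 2, W // 2, C, 4)
    idx = xw.argmax(axis=-1)
    y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool_backward(dy: np.ndarray, idx: np.ndarray, x_shape):
    B, H, W, C = x_shape
    dxw = np.zeros((B, H // 2, W // 2, C, 4), dtype=dy.dtype)
    np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
    dx = dxw.reshape(B, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dx.reshape(B, H, W, C)


def _transposed_conv2x2_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Stride-2 2x2 transposed convolution (exact x2 upsampling).

    Every output position receives exactly one kernel term, so the forward
    pass is four strided assignments of BLAS products.
    """
    B, H, W, cin = x.shape
    cout = w.shape[-1]
    y = np.empty((B, 2 * H, 2 * W, cout), dtype=np.result_type(x.dtype, w.dtype))
    x2 = x.reshape(-1, cin)
    for di in range(2):
        for dj in range(2):
            y[:, di::2, dj::2, :] = (x2 @ w[di, dj]).reshape(B, H, W, cout)
    y += b
    return y, x


def _transposed_conv2x2_backward(dy: np.ndarray, x: np.ndarray, w: np.ndarray):
    B, H, W, cin = x.shape
    cout = w.shape[-1]
    x2 = x.reshape(-1, cin)
    dw = np.empty_like(w)
    dx = np.zeros((B * H * W, cin), dtype=dy.dtype)
    db = np.zeros(cout, dtype=dy.dtype)
    for di in range(2):
        for dj in range(2):
            dyb = np.ascontiguousarray(dy[:, di::2, dj::2, :]).reshape(-1, cout)
            dw[di, dj] = x2.T @ dyb
            dx += dyb @ w[di, dj].T
            db += dyb.sum(axis=0)
    return dx.reshape(B, H, W, cin), dw, db


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    B, H, W, C = dy.shape
    return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Per-pixel softmax + categorical cross-entropy (mean over all pixels).

    Returns ``(loss, probs, dlogits)``; the gradient is already scaled by
    1/(number of pixels).
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    npix = int(np.prod(logits.shape[:-1]))
    eps = 1e-12
    loss = -float(np.sum(onehot * np.log(probs + eps)) / npix)
    dlogits = (probs - onehot) / npix
    return loss, probs, dlogits


# ------------------------------------------------------------------ model


class UNet:
    """Trainable same-padded U-Net over numpy arrays (NHWC)."""

    def __init__(self, cfg: UNetConfig):
        cfg.validate()
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(cfg.seed))

    # -------------------------------------------------------------- setup

    def _add_conv(self, name: str, kh: int, kw: int, cin: int, cout: int,
                  rng: np.random.Generator, zero: bool = False) -> None:
        if zero:
            w = np.zeros((kh, kw, cin, cout), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / (kh * kw * cin))
            w = (rng.standard_normal((kh, kw, cin, cout)) * std).astype(np.float32)
        self.params[name + "_w"] = w
        self.params[name + "_b"] = np.zeros(cout, dtype=np.float32)

    def _init_params(self, rng: np.random.Generator) -> None:
        ch = self.cfg.encoder_channels
        cin = self.cfg.in_channels
        for i, c in enumerate(ch):
            self._add_conv(f"enc{i}_conv1", 3, 3, cin, c, rng)
            self._add_conv(f"enc{i}_conv2", 3, 3, c, c, rng)
            cin = c
        for i in range(len(ch) - 2, -1, -1):
            self._add_conv(f"dec{i}_up", 2, 2, cin, ch[i], rng)
            self._add_conv(f"dec{i}_conv1", 3, 3, 2 * ch[i], ch[i], rng)
            self._add_conv(f"dec{i}_conv2", 3, 3, ch[i], ch[i], rng)
            cin = ch[i]
        # zero head => exactly uniform class probabilities before training
        self._add_conv("head", 1, 1, ch[0], self.cfg.n_classes, rng, zero=True)

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------ forward

    def forward(
        self,
        images: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Run the network; returns ``(logits, cache)``.

        ``images`` is ``(B, H, W)`` or ``(B, H, W, in_channels)``.  In
        training mode inverted dropout is applied after each encoder block
        (requires ``rng``); in inference mode dropout is inactive.
        """
        if images.ndim == 3:
            images = images[..., None]
        x = np.ascontiguousarray(images, dtype=np.float32)
        if x.shape[1] != self.cfg.input_size or x.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}^2 slices, got {x.shape[1:3]}"
            )
        p = self.params
        ch = self.cfg.encoder_channels
        drop = self.cfg.dropout_rate if train else 0.0
        if drop > 0 and rng is None:
            raise ValueError("training-mode forward with dropout requires rng")
        cache: dict = {"x_shapes": {}, "convs": {}, "pools": {}, "drops": {}, "skips": {}}

        def conv_relu(name, x, relu=True):
            y, cc = _conv_forward(x, p[name + "_w"], p[name + "_b"])
            cache["convs"][name] = (cc, x.shape)
            if relu:
                y = np.maximum(y, 0.0)
                cache["convs"][name] = (cc, x.shape, y)  # keep post-relu for mask
            return y

        # encoder
        for i in range(len(ch)):
            x = conv_relu(f"enc{i}_conv1", x)
            x = conv_relu(f"enc{i}_conv2", x)
            if drop > 0:
                keep = (rng.random(x.shape) >= drop).astype(np.float32) / (1.0 - drop)
                x = x * keep
                cache["drops"][i] = keep
            if i < len(ch) - 1:
                cache["skips"][i] = x
                y, idx = _maxpool_forward(x)
                cache["pools"][i] = (idx, x.shape)
                x = y
        # decoder
        cache["tconvs"] = {}
        for i in range(len(ch) - 2, -1, -1):
            if self.cfg.up_mode == "nearest":
                x = _upsample2(x)
                x = conv_relu(f"dec{i}_up", x)
            else:
                y, xc = _transposed_conv2x2_forward(
                    x, p[f"dec{i}_up_w"], p[f"dec{i}_up_b"]
                )
                x = np.maximum(y, 0.0)
                cache["tconvs"][i] = (xc, x)
            x = np.concatenate([cache["skips"][i], x], axis=-1)
            x = conv_relu(f"dec{i}_conv1", x)
            x = conv_relu(f"dec{i}_conv2", x)
        logits, cc = _conv_forward(x, p["head_w"], p["head_b"])
        cache["convs"]["head"] = (cc, x.shape)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Backpropagate ``dlogits`` through the cached forward pass."""
        p = self.params
        ch = self.cfg.encoder_channels
        grads: dict[str, np.ndarray] = {}

        def conv_back(name, dy, relu=True):
            entry = cache["convs"][name]
            if relu:
                cc, x_shape, post = entry
                dy = dy * (post > 0)
            else:
                cc, x_shape = entry
            dx, dw, db = _conv_backward(dy, cc, x_shape, p[name + "_w"])
            grads[name + "_w"] = dw
            grads[name + "_b"] = db
            return dx

        dx = conv_back("head", dlogits, relu=False)
        dskip_from_decoder: dict[int, np.ndarray] = {}
        for i in range(0, len(ch) - 1):
            dx = conv_back(f"dec{i}_conv2", dx)
            dx = conv_back(f"dec{i}_conv1", dx)
            c = ch[i]
            dskip_from_decoder[i] = dx[..., :c]
            dx = dx[..., c:]
            if self.cfg.up_mode == "nearest":
                dx = conv_back(f"dec{i}_up", dx)
                dx = _upsample2_backward(dx)
            else:
                xc, post = cache["tconvs"][i]
                dx = dx * (post > 0)
                dx, dw, db = _transposed_conv2x2_backward(dx, xc, p[f"dec{i}_up_w"])
                grads[f"dec{i}_up_w"] = dw
                grads[f"dec{i}_up_b"] = db
        for i in range(len(ch) - 1, -1, -1):
            if i < len(ch) - 1:
                idx, x_shape = cache["pools"][i]
                dx = _maxpool_backward(dx, idx, x_shape)
                dx = dx + dskip_from_decoder[i]
            if i in cache["drops"]:
                dx = dx * cache["drops"][i]
            dx = conv_back(f"enc{i}_conv2", dx)
            dx = conv_back(f"enc{i}_conv1", dx)
        return grads

    # ---------------------------------------------------------- interface

    def loss_and_grads(
        self,
        images: np.ndarray,
        onehot: np.ndarray,
        rng: np.random.Generator | None = None,
    ):
        logits, cache = self.forward(images, train=True, rng=rng)
        loss, _, dlogits = softmax_cross_entropy(logits, onehot)
        grads = self.backward(dlogits.astype(np.float32), cache)
        return loss, grads

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode class probabilities, ``(B, H, W, n_classes)``."""
        outs = []
        for start in range(0, len(images), batch_size):
            logits, _ = self.forward(images[start : start + batch_size], train=False)
            z = logits - logits.max(axis=-1, keepdims=True)
            ez = np.exp(z)
            outs.append((ez / ez.sum(axis=-1, keepdims=True)).astype(np.float32))
        return np.concatenate(outs, axis=0)

    # -------------------------------------------------------- persistence

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(np.float32).copy()

    def save(self, weights_path: str | Path, config_path: str | Path | None = None) -> None:
        np.savez(str(weights_path), **self.params)
        if config_path is not None:
            self.cfg.to_json(config_path)

    @classmethod
    def load(cls, weights_path: str | Path, config_path: str | Path) -> "UNet":
        model = cls(UNetConfig.from_json(config_path))
        with np.load(str(weights_path)) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_unet(cfg: UNetConfig) -> UNet:
    """Construct a seeded, trainable U-Net from its configuration."""
    return UNet(cfg)


def predict_batch(model: UNet, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Per-pixel class probabilities for a batch of slices (dropout off)."""
    return model.predict(images, batch_size=batch_size)


# -------------------------------------------------------------- optimizer


class Adam:
    """Adam with the conventional defaults (b1=0.9, b2=0.999, eps=1e-7)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            self.params[k] -= lr_t * m / (np.sqrt(v) + self.eps)
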