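"""NumPy forward pass of the Xception feature extractor.

Only the convolutional trunk is instantiated (no classification head); the
final feature maps are globally average-pooled into a 2048-vector. Weights
are randomly initialized from a seeded generator: no pretrained download is
required, the adapter stays fully deterministic, and the embedding geometry
(2048 dimensions, 71-pixel minimum input) matches the published architecture.
When a Keras installation with pretrained weights is available it can be
dropped in behind the same :class:`~ionclust.embedding.Embedder` contract.

Batch normalization layers act as identity maps at initialization (unit gain,
zero shift, unit running variance) and are therefore folded away.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError, ValidationError


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1,
            padding: str = "valid") -> np.ndarray:
    """x: (H, W, Cin); w: (kh, kw, Cin, Cout) -> (H', W', Cout)."""
    kh, kw = w.shape[:2]
    if padding == "same":
        x = _pad_same(x, kh, kw, stride)
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    return np.tensordot(win, w, axes=((2, 3, 4), (2, 0, 1)))


def _depthwise2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x: (H, W, C); w: (kh, kw, C); stride 1, same padding."""
    kh, kw = w.shape[:2]
    x = _pad_same(x, kh, kw, 1)
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))
    return np.einsum("hwckl,klc->hwc", win, w, optimize=True)


def _pad_same(x: np.ndarray, kh: int, kw: int, stride: int,
              value: float = 0.0) -> np.ndarray:
    h, w = x.shape[:2]
    pad_h = max((-(-h // stride) - 1) * stride + kh - h, 0)
    pad_w = max((-(-w // stride) - 1) * stride + kw - w, 0)
    return np.pad(x, ((pad_h // 2, pad_h - pad_h // 2),
                      (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
                  constant_values=value)


def _maxpool_3x3_s2(x: np.ndarray) -> np.ndarray:
    x = _pad_same(x, 3, 3, 2, value=-np.inf)
    win = sliding_window_view(x, (3, 3), axis=(0, 1))[::2, ::2]
    return win.max(axis=(3, 4))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class XceptionEmbedder:
    """Xception trunk adapter honoring the Embedder contract.

    Grayscale patches in [0, 1] are replicated to 3 channels and affinely
    mapped to [-1, 1] (the backbone's documented input range) before the
    forward pass.
    """

    name = "xception"
    dim = 2048
    min_side = 71

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)
        self._weights = self._build_weights()

    # -- weight construction -------------------------------------------------

    def _he(self, shape, fan_in) -> np.ndarray:
        return (self._rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
                ).astype(np.float32)

    def _conv_w(self, kh, kw, cin, cout) -> np.ndarray:
        return self._he((kh, kw, cin, cout), kh * kw * cin)

    def _sep_w(self, cin, cout) -> tuple[np.ndarray, np.ndarray]:
        depth = self._he((3, 3, cin), 9)
        point = self._conv_w(1, 1, cin, cout)
        return depth, point

    def _build_weights(self) -> dict:
        w = {
            "entry1": self._conv_w(3, 3, 3, 32),
            "entry2": self._conv_w(3, 3, 32, 64),
        }
        cin = 64
        for i, cout in enumerate((128, 256, 728)):
            w[f"res{i}"] = self._conv_w(1, 1, cin, cout)
            w[f"block{i}_sep1"] = self._sep_w(cin, cout)
            w[f"block{i}_sep2"] = self._sep_w(cout, cout)
            cin = cout
        for i in range(8):
            for j in range(3):
                w[f"mid{i}_sep{j}"] = self._sep_w(728, 728)
        w["exit_res"] = self._conv_w(1, 1, 728, 1024)
        w["exit_sep1"] = self._sep_w(728, 728)
        w["exit_sep2"] = self._sep_w(728, 1024)
        w["exit_sep3"] = self._sep_w(1024, 1536)
        w["exit_sep4"] = self._sep_w(1536, 2048)
        return w

    # -- forward -------------------------------------------------------------

    def _sep(self, x, key):
        depth, point = self._weights[key]
        return _conv2d(_depthwise2d(x, depth), point)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=np.float32)
        if patch.ndim != 2:
            raise ValidationError("patch must be 2-D")
        if min(patch.shape) < self.min_side:
            raise ParameterError(f"patch side must be >= {self.min_side} pixels, "
                                 f"got {patch.shape}")
        if patch.min() < -1e-6 or patch.max() > 1 + 1e-6:
            raise ValidationError("patch values must lie in [0, 1]")

        x = (patch * 2.0 - 1.0)[:, :, None].repeat(3, axis=2)
        w = self._weights

        x = _relu(_conv2d(x, w["entry1"], stride=2))
        x = _relu(_conv2d(x, w["entry2"]))
        for i in range(3):
            res = _conv2d(x, w[f"res{i}"], stride=2, padding="same")
            if i > 0:
                x = _relu(x)
            x = _relu(self._sep(x, f"block{i}_sep1"))
            x = self._sep(x, f"block{i}_sep2")
            x = _maxpool_3x3_s2(x) + res
        for i in range(8):
            res = x
            for j in range(3):
                x = self._sep(_relu(x), f"mid{i}_sep{j}")
            x = x + res
        res = _conv2d(x, w["exit_res"], stride=2, padding="same")
        x = self._sep(_relu(x), "exit_sep1")
        x = self._sep(_relu(x), "exit_sep2")
        x = _maxpool_3x3_s2(x) + res
        x = _relu(self._sep(x, "exit_sep3"))
        x = _relu(self._sep(x, "exit_sep4"))
        return x.mean(axis=(0, 1)).astype(np.float64)
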