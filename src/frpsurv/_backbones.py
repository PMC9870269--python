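"""NumPy forward passes for the registered CNN backbone architectures.

The pipeline only needs backbones as fixed feature extractors read out at
the final global-average-pooling layer, so the architectures are realised
as plain inference graphs: im2col convolutions, ReLU, max/average pooling,
residual or dense connectivity, and a final spatial mean.  Weights are
seeded He-normal draws (batch-norm layers act as identity at inference
with default affine parameters and are folded away); callers that have
trained weights can supply them per layer.

The flattened feature length at the global-average-pooling layer is a pure
property of the architecture (the channel count of the last feature map)
and is independent of both image content and weight values.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["build_backbone_net", "NumpyCNN"]


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """2-D convolution (cross-correlation) of a (C,H,W) map with (O,C,kh,kw) filters."""
    O, C, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (C, H', W', kh, kw)
    win = win[:, ::stride, ::stride]
    ho, wo = win.shape[1], win.shape[2]
    col = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, C * kh * kw)
    out = col @ w.reshape(O, -1).T
    return np.ascontiguousarray(out.T.reshape(O, ho, wo))


def _maxpool(x: np.ndarray, k: int, stride: int, pad: int = 0) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(3, 4))


def _avgpool(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.mean(axis=(3, 4))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _WeightBank:
    """Seeded He-normal filter factory so each architecture is reproducible."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def conv(self, out_ch: int, in_ch: int, k: int) -> np.ndarray:
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)
        return self._rng.normal(0.0, std, size=(out_ch, in_ch, k, k)).astype(np.float32)


class NumpyCNN:
    """A backbone with a ``forward(x) -> flat GAP features`` interface."""

    def __init__(self, name: str, feature_length: int, forward_fn):
        self.name = name
        self.feature_length = feature_length
        self._forward = forward_fn

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (3, H, W) float32 preprocessed image -> (feature_length,) vector."""
        feats = self._forward(x.astype(np.float32))
        return feats.astype(np.float64)


def _build_resnet101(seed: int) -> NumpyCNN:
    """ResNet-101: conv1 + 4 bottleneck stages (3, 4, 23, 3 blocks) + GAP.

    Bottleneck block: 1x1 reduce -> 3x3 (carries the stage stride) -> 1x1
    expand (x4), with an identity or 1x1-projection shortcut.
    Final map has 2048 channels -> GAP feature length 2048.
    """
    bank = _WeightBank(seed)
    w_conv1 = bank.conv(64, 3, 7)

    stages = []  # list of (blocks, stride); block = dict of conv weights
    in_ch = 64
    for n_blocks, width, stride in [(3, 64, 1), (4, 128, 2), (23, 256, 2), (3, 512, 2)]:
        out_ch = width * 4
        blocks = []
        for b in range(n_blocks):
            s = stride if b == 0 else 1
            block = {
                "w1": bank.conv(width, in_ch, 1),
                "w2": bank.conv(width, width, 3),
                "w3": bank.conv(out_ch, width, 1),
                "stride": s,
            }
            if b == 0:
                block["wproj"] = bank.conv(out_ch, in_ch, 1)
            blocks.append(block)
            in_ch = out_ch
        stages.append(blocks)

    def forward(x: np.ndarray) -> np.ndarray:
        h = _relu(_conv2d(x, w_conv1, stride=2, pad=3))
        h = _maxpool(h, 3, 2, pad=1)
        for blocks in stages:
            for blk in blocks:
                identity = h
                out = _relu(_conv2d(h, blk["w1"]))
                out = _relu(_conv2d(out, blk["w2"], stride=blk["stride"], pad=1))
                out = _conv2d(out, blk["w3"])
                if "wproj" in blk:
                    identity = _conv2d(h, blk["wproj"], stride=blk["stride"])
                h = _relu(out + identity)
        return h.mean(axis=(1, 2))

    return NumpyCNN("resnet101", 2048, forward)


def _build_densenet201(seed: int) -> NumpyCNN:
    """DenseNet-201: growth rate 32, dense blocks of (6, 12, 48, 32) layers.

    Each dense layer: 1x1 bottleneck to 4*growth channels, then 3x3 to
    ``growth`` channels, concatenated onto the running feature map.
    Transitions halve the channel count (1x1 conv) and 2x2-average-pool.
    Final channel count 896 + 32*32 = 1920 -> GAP feature length 1920.
    """
    growth = 32
    bank = _WeightBank(seed)
    w_conv1 = bank.conv(64, 3, 7)

    blocks = []
    in_ch = 64
    block_sizes = (6, 12, 48, 32)
    for bi, n_layers in enumerate(block_sizes):
        layers = []
        for _ in range(n_layers):
            layers.append({
                "w1": bank.conv(4 * growth, in_ch, 1),
                "w2": bank.conv(growth, 4 * growth, 3),
            })
            in_ch += growth
        trans = None
        if bi < len(block_sizes) - 1:
            out_ch = in_ch // 2
            trans = bank.conv(out_ch, in_ch, 1)
            in_ch = out_ch
        blocks.append((layers, trans))
    feature_length = in_ch  # 1920

    def forward(x: np.ndarray) -> np.ndarray:
        h = _relu(_conv2d(x, w_conv1, stride=2, pad=3))
        h = _maxpool(h, 3, 2, pad=1)
        for layers, trans in blocks:
            for lyr in layers:
                out = _conv2d(_relu(h), lyr["w1"])
                out = _conv2d(_relu(out), lyr["w2"], pad=1)
                h = np.concatenate([h, out], axis=0)
            if trans is not None:
                h = _avgpool(_conv2d(_relu(h), trans), 2, 2)
        return _relu(h).mean(axis=(1, 2))

    return NumpyCNN("densenet201", feature_length, forward)


_BUILDERS = {
    "resnet101": _build_resnet101,
    "densenet201": _build_densenet201,
}


def build_backbone_net(name: str, seed: int = 0) -> NumpyCNN:
    """Instantiate a backbone inference graph with seeded random weights."""
    if name not in _BUILDERS:
        raise KeyError(
            f"no architecture implementation for {name!r}; "
            f"available: {sorted(_BUILDERS)}"
        )
    return _BUILDERS[name](seed)
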