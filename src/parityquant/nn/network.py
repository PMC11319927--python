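"""Residual backbone + parallel regression heads, with Grad-CAM support.

The backbone family covers the six standard residual recipes used for the
fidelity configuration (ResNet-50/101, ResNeXt-50/101, Wide-ResNet-50/101 —
depth/width/cardinality as in the literature, simplified stem, no batch norm)
plus a two-stage ``small-resnet`` intended for CPU-scale training.  A single
trunk produces one pooled feature vector; each of the ``n_heads`` scalar heads
owns its parameters, so gradients from head k never touch head j != k.
"""

from __future__ import annotations

import json

import numpy as np

from .layers import AvgPool2, BasicBlock, Bottleneck, Conv2d, GlobalAvgPool, Linear, ReLU, _Sequential

#: (block, stem_channels, stem_k, stem_stride, stem_pool, stage depths, planes, groups, base_width)
_BOTTLENECK_PLANES = (64, 128, 256, 512)

BACKBONES = {
    "small-resnet": None,  # handled separately
    "resnet50": dict(depths=(3, 4, 6, 3), groups=1, base_width=64),
    "resnet101": dict(depths=(3, 4, 23, 3), groups=1, base_width=64),
    "resnext50": dict(depths=(3, 4, 6, 3), groups=32, base_width=4),
    "resnext101": dict(depths=(3, 4, 23, 3), groups=32, base_width=8),
    "wide-resnet50": dict(depths=(3, 4, 6, 3), groups=1, base_width=128),
    "wide-resnet101": dict(depths=(3, 4, 23, 3), groups=1, base_width=128),
}


def normalize_backbone_name(name: str) -> str:
    key = name.strip().lower().replace("_", "-").replace(" ", "-")
    if key not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; options: {sorted(BACKBONES)}")
    return key


def _build_trunk(name: str, in_channels: int, rng, dtype) -> tuple[_Sequential, int]:
    key = normalize_backbone_name(name)
    if key == "small-resnet":
        # stride-2 stem keeps CPU training fast; two residual stages follow
        layers = [
            Conv2d(in_channels, 8, 3, 2, rng=rng, dtype=dtype),
            ReLU(),
            BasicBlock(8, 16, 2, rng=rng, dtype=dtype),
            BasicBlock(16, 32, 2, rng=rng, dtype=dtype),
        ]
        return _Sequential(layers), 32
    cfg = BACKBONES[key]
    layers = [Conv2d(in_channels, 64, 7, 2, rng=rng, dtype=dtype), ReLU(), AvgPool2()]
    cin = 64
    for planes, depth in zip(_BOTTLENECK_PLANES, cfg["depths"]):
        cout = planes * 4
        width = int(planes * cfg["base_width"] / 64.0) * cfg["groups"]
        for i in range(depth):
            stride = 2 if (i == 0 and planes != 64) else 1
            layers.append(Bottleneck(cin, cout, width, stride, cfg["groups"], rng=rng, dtype=dtype))
            cin = cout
    return _Sequential(layers), cin


class _Head:
    """One scalar regression head: Linear -> ReLU -> Linear (or a single Linear)."""

    def __init__(self, nfeat, hidden, rng, dtype):
        if hidden > 0:
            self.layers = _Sequential(
                [Linear(nfeat, hidden, rng=rng, dtype=dtype), ReLU(), Linear(hidden, 1, rng=rng, dtype=dtype)]
            )
        else:
            self.layers = _Sequential([Linear(nfeat, 1, rng=rng, dtype=dtype)])

    def params_grads(self):
        yield from self.layers.params_grads()

    def forward(self, f):
        return self.layers.forward(f)[:, 0]

    def backward(self, dy):
        return self.layers.backward(dy[:, None])


class MultiHeadNet:
    """Shared trunk + ``n_heads`` independent scalar regression heads."""

    def __init__(
        self,
        backbone: str = "small-resnet",
        n_heads: int = 9,
        head_hidden: int = 16,
        in_channels: int = 1,
        rng=None,
        dtype=np.float32,
    ):
        if n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.backbone = normalize_backbone_name(backbone)
        self.n_heads, self.head_hidden, self.in_channels = n_heads, head_hidden, in_channels
        self.dtype = np.dtype(dtype)
        self.trunk, self.n_features = _build_trunk(self.backbone, in_channels, rng, self.dtype)
        self.gap = GlobalAvgPool()
        self.heads = [_Head(self.n_features, head_hidden, rng, self.dtype) for _ in range(n_heads)]

    # -- parameters --------------------------------------------------------
    def trunk_params_grads(self):
        yield from self.trunk.params_grads()

    def params_grads(self):
        yield from self.trunk.params_grads()
        for h in self.heads:
            yield from h.params_grads()

    def head_params_grads(self, k):
        yield from self.heads[k].params_grads()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) or (N, C, H, W) -> predictions (N, n_heads)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        self._conv_out = self.trunk.forward(np.ascontiguousarray(x, dtype=self.dtype))
        self._features = self.gap.forward(self._conv_out)
        return np.stack([h.forward(self._features) for h in self.heads], axis=1)

    def backward(self, dpred: np.ndarray) -> None:
        """Backprop from d(loss)/d(predictions); accumulates grads on layers."""
        dpred = np.asarray(dpred, dtype=self.dtype)
        dfeat = np.zeros_like(self._features)
        for k, h in enumerate(self.heads):
            dfeat += h.backward(dpred[:, k])
        self.trunk.backward(self.gap.backward(dfeat))

    # -- Grad-CAM -----------------------------------------------------------
    def grad_cam(self, x: np.ndarray, head_index: int, output_size: int | None = None) -> np.ndarray:
        """Saliency map of one head on one image, min–max normalized to [0, 1].

        Channel weights are the spatially averaged gradient of the head's
        scalar output w.r.t. the final convolutional feature map; the map is
        the rectified weighted channel sum, upsampled to the input size.
        An all-zero map is returned as all zeros.
        """
        if not 0 <= head_index < self.n_heads:
            raise IndexError(f"head_index {head_index} out of range [0, {self.n_heads})")
        if x.ndim == 2:
            x = x[None]
        self.forward(x)
        acts = self._conv_out[0]  # (C, h, w)
        dfeat = self.heads[head_index].backward(np.ones(x.shape[0], dtype=self.dtype))
        # GAP means the per-channel gradient is spatially constant:
        weights = dfeat[0] / (acts.shape[1] * acts.shape[2])
        cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
        size = output_size or x.shape[-1]
        from skimage.transform import resize

        cam = resize(cam, (size, size), order=1, mode="edge", anti_aliasing=False)
        if cam.max() > 0:
            cam = (cam - cam.min()) / (cam.max() - cam.min())
        return cam

    # -- serialization ------------------------------------------------------
    def state_arrays(self):
        return [p for p, _ in self.params_grads()]

    def save(self, path, extra_meta: dict | None = None) -> None:
        meta = dict(
            backbone=self.backbone,
            n_heads=self.n_heads,
            head_hidden=self.head_hidden,
            in_channels=self.in_channels,
            dtype=self.dtype.name,
        )
        if extra_meta:
            meta["extra"] = extra_meta
        arrays = {f"p{i}": p for i, p in enumerate(self.state_arrays())}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["MultiHeadNet", dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            net = cls(
                meta["backbone"],
                meta["n_heads"],
                meta["head_hidden"],
                meta["in_channels"],
                dtype=np.dtype(meta.get("dtype", "float32")),
            )
            for i, p in enumerate(net.state_arrays()):
                p[...] = z[f"p{i}"]
        return net, meta.get("extra", {})
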