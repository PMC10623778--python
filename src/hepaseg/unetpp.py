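"""2D UNet++ with nested dense skip pathways.

The network is a triangular grid of convolutional nodes ``X(i, j)`` with
``i + j <= L - 1`` for ``L`` resolution levels.  Column ``j = 0`` is the
plain encoder (2x max-pool between levels); every decoder node ``X(i, j)``
receives the 2x-upsampled ``X(i+1, j-1)`` concatenated with all same-level
predecessors ``X(i, 0..j-1)`` — the nested, dense skip connections that
distinguish UNet++ from U-Net.  Each node is two 3x3 conv + batch-norm +
ReLU blocks; upsampling is bilinear followed by a 1x1 channel projection
(avoids the checkerboard artifacts of transposed convolution).

The segmentation head is a 1x1 convolution on ``X(0, L-1)``; with deep
supervision enabled, every top-row decoder node ``X(0, j >= 1)`` gets a
head and their softmax outputs are averaged at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .containers import MultisequenceVolume, ProbabilityMap


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``depth`` is the number of resolution levels L; channel width doubles
    per level from ``base_filters``.  ``in_channels`` is 2 for the
    dual-sequence stage-1 input and 3 for stage 2 (arterial, T2, liver
    mask).  Spatial inputs must be divisible by ``2**(depth-1)``.
    """

    depth: int = 4
    base_filters: int = 32
    in_channels: int = 2
    out_classes: int = 2
    deep_supervision: bool = False

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.in_channels < 1 or self.out_classes < 2:
            raise ValueError("need >= 1 input channel and >= 2 classes")

    @property
    def n_conv_nodes(self) -> int:
        return self.depth * (self.depth + 1) // 2


def _he_init(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class ConvBlock:
    """Two 3x3 conv + BN + ReLU stages."""

    def __init__(self, rng, c_in, c_out, name):
        self.layers = []
        for s, ci in enumerate((c_in, c_out)):
            w = nn.Parameter(
                _he_init(rng, (c_out, ci, 3, 3)), f"{name}.conv{s}.w", weight_decay=True
            )
            b = nn.Parameter(np.zeros(c_out), f"{name}.conv{s}.b")
            gamma = nn.Parameter(np.ones(c_out), f"{name}.bn{s}.gamma")
            beta = nn.Parameter(np.zeros(c_out), f"{name}.bn{s}.beta")
            running = {"mean": np.zeros(c_out), "var": np.ones(c_out)}
            self.layers.append((w, b, gamma, beta, running))

    def __call__(self, x, training):
        for w, b, gamma, beta, running in self.layers:
            x = nn.conv2d(x, w, b, pad=1)
            x = nn.batchnorm2d(x, gamma, beta, running, training)
            x = nn.relu(x)
        return x

    def parameters(self):
        for w, b, gamma, beta, _ in self.layers:
            yield from (w, b, gamma, beta)


class _Proj:
    """1x1 convolution used after bilinear upsampling."""

    def __init__(self, rng, c_in, c_out, name):
        self.w = nn.Parameter(
            _he_init(rng, (c_out, c_in, 1, 1)), f"{name}.w", weight_decay=True
        )
        self.b = nn.Parameter(np.zeros(c_out), f"{name}.b")

    def __call__(self, x):
        return nn.conv2d(nn.upsample_bilinear2x(x), self.w, self.b, pad=0)

    def parameters(self):
        yield from (self.w, self.b)


class UNetPlusPlus:
    """The nested encoder-decoder; see module docstring for topology."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.depth
        ch = [spec.base_filters * 2**i for i in range(L)]
        self.blocks: dict[tuple[int, int], ConvBlock] = {}
        self.projs: dict[tuple[int, int], _Proj] = {}
        for i in range(L):
            for j in range(L - i):
                if j == 0:
                    c_in = spec.in_channels if i == 0 else ch[i - 1]
                else:
                    c_in = (j + 1) * ch[i]
                    self.projs[(i, j)] = _Proj(
                        rng, ch[i + 1], ch[i], f"up({i},{j})"
                    )
                self.blocks[(i, j)] = ConvBlock(rng, c_in, ch[i], f"X({i},{j})")
        head_cols = range(1, L) if spec.deep_supervision else [L - 1]
        self.heads = {
            j: _Proj.__new__(_Proj) for j in head_cols
        }
        for j in head_cols:
            h = self.heads[j]
            h.w = nn.Parameter(
                _he_init(rng, (spec.out_classes, ch[0], 1, 1)),
                f"head{j}.w",
                weight_decay=True,
            )
            h.b = nn.Parameter(np.zeros(spec.out_classes), f"head{j}.b")

    # ------------------------------------------------------------ plumbing

    def parameters(self):
        for key in sorted(self.blocks):
            yield from self.blocks[key].parameters()
        for key in sorted(self.projs):
            yield from self.projs[key].parameters()
        for j in sorted(self.heads):
            yield from (self.heads[j].w, self.heads[j].b)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    @property
    def n_conv_nodes(self) -> int:
        return len(self.blocks)

    # ------------------------------------------------------------- forward

    def forward(self, x: np.ndarray, training: bool = False):
        """Map ``(N, in_channels, H, W)`` to per-head logits.

        Returns a list of logit Tensors, one per supervision head (a single
        element unless deep supervision is on).
        """
        n, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {c}"
            )
        div = 2 ** (self.spec.depth - 1)
        if h % div or w % div:
            raise ValueError(f"spatial dims must be divisible by {div}, got {h}x{w}")
        L = self.spec.depth
        X: dict[tuple[int, int], nn.Tensor] = {}
        t = nn.Tensor(x)
        for i in range(L):
            X[(i, 0)] = self.blocks[(i, 0)](
                t if i == 0 else nn.maxpool2x2(X[(i - 1, 0)]), training
            )
        for j in range(1, L):
            for i in range(L - j):
                up = self.projs[(i, j)](X[(i + 1, j - 1)])
                X[(i, j)] = self.blocks[(i, j)](
                    nn.concat([X[(i, k)] for k in range(j)] + [up]), training
                )
        heads = []
        for j in sorted(self.heads):
            hd = self.heads[j]
            heads.append(nn.conv2d(X[(0, j)], hd.w, hd.b, pad=0))
        return heads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode class probabilities, deep-supervision-averaged."""
        heads = self.forward(x, training=False)
        probs = [nn.softmax(h.data, axis=1) for h in heads]
        return np.mean(probs, axis=0)

    # ----------------------------------------------------------------- I/O

    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        for idx, p in enumerate(self.parameters()):
            arrays[f"p{idx}"] = p.data
        for key in sorted(self.blocks):
            for s, (_, _, _, _, running) in enumerate(self.blocks[key].layers):
                tag = f"bn_{key[0]}_{key[1]}_{s}"
                arrays[f"{tag}_mean"] = running["mean"]
                arrays[f"{tag}_var"] = running["var"]
        np.savez(path, spec=json.dumps(asdict(self.spec)), **arrays)

    @classmethod
    def load(cls, path) -> "UNetPlusPlus":
        with np.load(path, allow_pickle=False) as data:
            spec = NetworkSpec(**json.loads(str(data["spec"])))
            net = cls(spec)
            for idx, p in enumerate(net.parameters()):
                p.data = data[f"p{idx}"]
            for key in sorted(net.blocks):
                for s, (_, _, _, _, running) in enumerate(net.blocks[key].layers):
                    tag = f"bn_{key[0]}_{key[1]}_{s}"
                    running["mean"] = data[f"{tag}_mean"]
                    running["var"] = data[f"{tag}_var"]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> UNetPlusPlus:
    """Construct a randomly initialized UNet++ from ``spec``."""
    return UNetPlusPlus(spec, seed=seed)


def _pad_to_divisible(sl: np.ndarray, div: int):
    h, w = sl.shape[-2:]
    ph, pw = (-h) % div, (-w) % div
    if ph or pw:
        sl = np.pad(sl, [(0, 0)] * (sl.ndim - 2) + [(0, ph), (0, pw)], mode="edge")
    return sl, (h, w)


def predict_slices(
    network: UNetPlusPlus,
    vol,
    batch_size: int = 8,
    spacing_mm=None,
) -> ProbabilityMap:
    """Slice-wise 2D inference stacked into a 3D probability volume.

    Each axial (z) slice is pushed through the network independently and the
    2D class probabilities are superimposed along z onto the input grid.
    ``vol`` is a :class:`MultisequenceVolume` or a raw ``(C, Z, Y, X)``
    array (stage 2 passes three channels).
    """
    if isinstance(vol, MultisequenceVolume):
        arr = vol.channels
        spacing_mm = vol.spacing_mm
    else:
        arr = np.asarray(vol, dtype=np.float64)
        if spacing_mm is None:
            spacing_mm = (1.0, 1.0, 1.0)
    if arr.shape[0] != network.spec.in_channels:
        raise ValueError(
            f"volume has {arr.shape[0]} channels, network expects "
            f"{network.spec.in_channels}"
        )
    div = 2 ** (network.spec.depth - 1)
    slices = arr.transpose(1, 0, 2, 3)  # (Z, C, Y, X)
    padded, (h, w) = _pad_to_divisible(slices, div)
    out = np.empty((network.spec.out_classes,) + arr.shape[1:])
    for start in range(0, padded.shape[0], batch_size):
        chunk = padded[start : start + batch_size]
        probs = network.predict_proba(chunk)[:, :, :h, :w]
        out[:, start : start + chunk.shape[0]] = probs.transpose(1, 0, 2, 3)
    return ProbabilityMap(out, spacing_mm)
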