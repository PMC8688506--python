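"""Scalable U-net construction: layer plans and their analytic properties.

The architecture is scaled by three hyper-parameters: the width c0 (output
channels of the first conv layer; every later level doubles, c_{l+1} = 2 c_l),
the depth d (number of encoder conv-blocks; the decoder mirrors it), and the
training input size IS.  Each conv-block is two 3x3 "same" convolutions, each
followed by batch normalisation and Mish; encoder levels end in 2x2 max
pooling, decoder levels start with a 2x2 stride-2 transposed convolution that
halves the channel count, followed by concatenation with the encoder skip.
A final 1x1 convolution maps to the k class channels, normalised per pixel
by softmax.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import nn

#: hyper-parameter grid explored when scaling the model
GRID_WIDTHS = (32, 64, 96, 112)
GRID_DEPTHS = (3, 4, 5, 6)
GRID_INPUT_SIZES = ((384, 384), (512, 512), (640, 640))


@dataclass(frozen=True)
class ModelSpec:
    """The (width, depth, input size) scaling triple plus channel contracts."""

    width_c0: int
    depth_d: int
    input_size: tuple[int, int] = (384, 384)
    n_classes: int = 4
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.width_c0 < 1 or self.depth_d < 1:
            raise ValueError("width_c0 and depth_d must be positive")
        if self.n_classes < 2 or self.in_channels < 1:
            raise ValueError("invalid class/channel counts")
        w, h = self.input_size
        div = 2**self.depth_d
        if w % div or h % div:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^d = {div}"
            )

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.width_c0 * 2**l for l in range(self.depth_d))

    @property
    def bottleneck_channels(self) -> int:
        return self.width_c0 * 2**self.depth_d


@dataclass(frozen=True)
class LayerDescriptor:
    kind: str  # conv3x3 | batch-norm | mish | maxpool2 | upconv2 | concat-skip | conv1x1 | softmax
    in_channels: int
    out_channels: int
    stride: int = 1


@dataclass
class LayerPlan:
    spec: ModelSpec
    layers: list[LayerDescriptor] = field(default_factory=list)


def _conv_block(layers: list[LayerDescriptor], in_ch: int, out_ch: int) -> None:
    for cin in (in_ch, out_ch):
        layers.append(LayerDescriptor("conv3x3", cin, out_ch))
        layers.append(LayerDescriptor("batch-norm", out_ch, out_ch))
        layers.append(LayerDescriptor("mish", out_ch, out_ch))


def build_plan(spec: ModelSpec) -> LayerPlan:
    """Expand a ModelSpec into the ordered layer plan of the U-net."""
    layers: list[LayerDescriptor] = []
    enc = spec.encoder_channels
    in_ch = spec.in_channels
    for c in enc:
        _conv_block(layers, in_ch, c)
        layers.append(LayerDescriptor("maxpool2", c, c, stride=2))
        in_ch = c
    bott = spec.bottleneck_channels
    _conv_block(layers, in_ch, bott)
    up_in = bott
    for c in reversed(enc):
        layers.append(LayerDescriptor("upconv2", up_in, c, stride=2))
        layers.append(LayerDescriptor("concat-skip", c, 2 * c))
        _conv_block(layers, 2 * c, c)
        up_in = c
    layers.append(LayerDescriptor("conv1x1", up_in, spec.n_classes))
    layers.append(LayerDescriptor("softmax", spec.n_classes, spec.n_classes))
    return LayerPlan(spec, layers)


def count_parameters(plan: LayerPlan | list[LayerDescriptor]) -> int:
    """Exact count of trainable scalars (conv kernels + biases + BN affine)."""
    layers = plan.layers if isinstance(plan, LayerPlan) else plan
    total = 0
    for ld in layers:
        if ld.kind == "conv3x3":
            total += 9 * ld.in_channels * ld.out_channels + ld.out_channels
        elif ld.kind == "conv1x1":
            total += ld.in_channels * ld.out_channels + ld.out_channels
        elif ld.kind == "upconv2":
            total += 4 * ld.in_channels * ld.out_channels + ld.out_channels
        elif ld.kind == "batch-norm":
            total += 2 * ld.out_channels
        # mish / maxpool2 / concat-skip / softmax have no parameters
    return total


def receptive_field(plan: LayerPlan) -> int:
    """Theoretical receptive field (max support width, in input pixels) of a
    single output pixel, by exact jump/extent interval propagation.

    The input-index interval [lo, hi] feeding one output pixel is propagated
    backwards through the encoder-bottleneck-decoder path: a 3x3 "same" conv
    widens it by 1 on each side, a 2x2 pool maps it to [2 lo, 2 hi + 1], and
    a 2x2 stride-2 transposed conv maps it to [lo // 2, hi // 2] (each of its
    outputs depends on exactly one input).  Skip connections bypass pooling
    and never widen the interval beyond the deep path.  The width depends on
    the output pixel's phase relative to the pooling grid, so the maximum
    over all 2^d phases is returned.
    """
    best = 0
    for phase in range(2**plan.spec.depth_d):
        lo = hi = phase
        for ld in reversed(plan.layers):
            if ld.kind == "conv3x3":
                lo, hi = lo - 1, hi + 1
            elif ld.kind == "maxpool2":
                lo, hi = 2 * lo, 2 * hi + 1
            elif ld.kind == "upconv2":
                lo, hi = lo // 2, hi // 2
        best = max(best, hi - lo + 1)
    return best


def enumerate_grid(
    widths=GRID_WIDTHS, depths=GRID_DEPTHS, input_sizes=GRID_INPUT_SIZES,
    n_classes: int = 4, in_channels: int = 1,
) -> list[ModelSpec]:
    """Cartesian product of the scaling lists, deduplicated, lexicographic."""
    if not (widths and depths and input_sizes):
        raise ValueError("all hyper-parameter lists must be non-empty")
    ws = sorted(set(int(w) for w in widths))
    ds = sorted(set(int(d) for d in depths))
    iss = sorted(set((int(s[0]), int(s[1])) if not np.isscalar(s) else (int(s), int(s))
                     for s in input_sizes))
    return [
        ModelSpec(w, d, s, n_classes=n_classes, in_channels=in_channels)
        for w, d, s in itertools.product(ws, ds, iss)
    ]


def plan_summary(plan: LayerPlan) -> dict:
    """JSON-ready summary of a plan for inspection."""
    return {
        "width_c0": plan.spec.width_c0,
        "depth_d": plan.spec.depth_d,
        "input_size": list(plan.spec.input_size),
        "n_classes": plan.spec.n_classes,
        "in_channels": plan.spec.in_channels,
        "n_parameters": count_parameters(plan),
        "receptive_field_px": receptive_field(plan),
        "layers": [
            {"kind": l.kind, "in": l.in_channels, "out": l.out_channels, "stride": l.stride}
            for l in plan.layers
        ],
    }


# ---------------------------------------------------------------------------
# Instantiable network
# ---------------------------------------------------------------------------


class UNet:
    """A runnable U-net following the layer plan, on the NumPy engine.

    ``pool="avg"`` swaps max pooling for geometry-identical average pooling;
    this is used only for receptive-field measurements, where gradients must
    reach the whole pooling window.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0, pool: str = "max"):
        self.spec = spec
        rng = np.random.default_rng(seed)
        pool_cls = nn.MaxPool2 if pool == "max" else nn.AvgPool2
        self.enc_blocks: list[list[nn.Layer]] = []
        self.pools: list[nn.Layer] = []
        in_ch = spec.in_channels
        for c in spec.encoder_channels:
            self.enc_blocks.append(self._block(in_ch, c, rng))
            self.pools.append(pool_cls())
            in_ch = c
        self.bottleneck = self._block(in_ch, spec.bottleneck_channels, rng)
        self.ups: list[nn.ConvTranspose2x2] = []
        self.dec_blocks: list[list[nn.Layer]] = []
        up_in = spec.bottleneck_channels
        for c in reversed(spec.encoder_channels):
            self.ups.append(nn.ConvTranspose2x2(up_in, c, rng))
            self.dec_blocks.append(self._block(2 * c, c, rng))
            up_in = c
        self.head = nn.Conv2D(up_in, spec.n_classes, 1, rng)

    @staticmethod
    def _block(in_ch: int, out_ch: int, rng: np.random.Generator) -> list[nn.Layer]:
        layers: list[nn.Layer] = []
        for cin in (in_ch, out_ch):
            layers.append(nn.Conv2D(cin, out_ch, 3, rng))
            layers.append(nn.BatchNorm2D(out_ch))
            layers.append(nn.Mish())
        return layers

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        for up, blk in zip(self.ups, self.dec_blocks):
            out.append(up)
            out.extend(blk)
        out.append(self.head)
        return out

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def state(self) -> list[np.ndarray]:
        arrays = [p.copy() for p, _ in self.params()]
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm2D):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p, _ in self.params():
            p[...] = next(it)
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _run(layers: list[nn.Layer], x: np.ndarray, training: bool) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x, training)
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, in_channels, H, W) with H, W divisible by 2^d -> logits (N, k, H, W)."""
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = self._run(blk, x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self._run(self.bottleneck, x, training)
        self._concat_ch = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            self._concat_ch.append((skip.shape[1], x.shape[1]))
            x = np.concatenate([skip, x], axis=1)
            x = self._run(blk, x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads: list[np.ndarray] = []
        for up, blk, (c_skip, _) in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._concat_ch)
        ):
            for layer in reversed(blk):
                g = layer.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # skip_grads were collected shallow-first; encoder runs deep-first here
        for blk, pool, gs in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = g + gs
            for layer in reversed(blk):
                g = layer.backward(g)
        return g  # gradient w.r.t. the network input

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (N, k, H, W) in evaluation mode."""
        return nn.softmax(self.forward(x, training=False), axis=1)


def measure_gradient_support(spec: ModelSpec, input_hw: int, seed: int = 0) -> int:
    """Empirical receptive field: width of the non-zero input-gradient support.

    Instantiates the network with strictly positive conv weights, identity
    batch-norm statistics and average pooling so that no gradient path can
    cancel, backpropagates a one-hot gradient from single output pixels
    (covering all 2^d pooling phases), and measures the union support width.
    """
    net = UNet(spec, seed=seed, pool="avg")
    for blk in net.enc_blocks + [net.bottleneck] + net.dec_blocks:
        for i, layer in enumerate(blk):
            if isinstance(layer, nn.BatchNorm2D):
                # batch statistics couple all pixels; identity keeps locality
                blk[i] = nn.Identity()
    for layer in net._all_layers():
        if isinstance(layer, (nn.Conv2D, nn.ConvTranspose2x2)):
            layer.W[...] = np.abs(layer.W) + 1e-3
            layer.b[...] = 0.0
    x = np.full((1, spec.in_channels, input_hw, input_hw), 0.1, dtype=np.float32)
    centre = input_hw // 2
    phases = 2**spec.depth_d
    best = 0
    for off in range(phases):
        logits = net.forward(x, training=True)
        d = np.zeros_like(logits)
        d[0, 0, centre + off, centre + off] = 1.0
        gx = net.backward(d)
        support = np.abs(gx[0, 0]) > 1e-30
        rows = np.flatnonzero(support.any(axis=1))
        cols = np.flatnonzero(support.any(axis=0))
        best = max(best, int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))
    return best
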