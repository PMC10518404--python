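"""Encoder-decoder (U-Net style) segmentation network on the numpy layers.

Architecture, for ``depth`` levels and ``base_filters`` F (doubling per level,
capped at 512):

* encoder level l: [3x3 conv -> ReLU] x2 -> dropout(rate_l) -> 2x2 max-pool
* bottleneck:      [3x3 conv -> ReLU] x2
* decoder level l: 2x2 transposed conv -> concat skip from encoder level l
                   -> [3x3 conv -> ReLU] x2
* head:            1x1 conv to ``n_classes`` logits (softmax applied by the
                   loss / the ``predict_proba`` helper)

Skip connections are taken from the encoder conv-block output before dropout
and pooling, so decoder level l sees features at the same spatial resolution.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, Dropout, MaxPool2x2, ReLU, UpConv2x2, softmax

__all__ = ["UNet"]


class _ConvBlock:
    """Two 3x3 conv+ReLU pairs."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.layers = [Conv2D(c_in, c_out, rng), ReLU(),
                       Conv2D(c_out, c_out, rng), ReLU()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


class UNet:
    """Trainable segmentation network.

    Parameters
    ----------
    depth : number of pooling/upsampling levels (>= 1)
    base_filters : filters at the first level; doubled per level, capped at 512
    dropout_schedule : per-level dropout rates, length ``depth``
    n_classes : output classes (myocardium segmentation uses 2)
    input_size : square input side; must be divisible by ``2**depth``
    seed : weight-init / dropout seed
    """

    FILTER_CAP = 512

    def __init__(self, depth: int, base_filters: int,
                 dropout_schedule: list[float], n_classes: int = 2,
                 input_size: int = 64, in_channels: int = 1,
                 seed: int = 0) -> None:
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if len(dropout_schedule) != depth:
            raise ValueError(
                f"dropout_schedule needs {depth} entries, got {len(dropout_schedule)}"
            )
        if input_size % (2 ** depth) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^depth = {2 ** depth}"
            )
        self.depth = depth
        self.n_classes = n_classes
        self.input_size = input_size
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)

        def nf(level: int) -> int:  # level is 1-based
            return min(base_filters * 2 ** (level - 1), self.FILTER_CAP)

        self.enc_blocks, self.enc_drops, self.enc_pools = [], [], []
        c = in_channels
        for l in range(1, depth + 1):
            self.enc_blocks.append(_ConvBlock(c, nf(l), rng))
            self.enc_drops.append(Dropout(dropout_schedule[l - 1], rng))
            self.enc_pools.append(MaxPool2x2())
            c = nf(l)
        self.bottleneck = _ConvBlock(c, nf(depth + 1), rng)
        c = nf(depth + 1)

        self.dec_ups, self.dec_blocks = [], []
        for l in range(depth, 0, -1):
            self.dec_ups.append(UpConv2x2(c, nf(l), rng))
            self.dec_blocks.append(_ConvBlock(2 * nf(l), nf(l), rng))
            c = nf(l)
        self.head = Conv2D(c, n_classes, rng, kernel=1)

    # -- graph traversal -----------------------------------------------------

    def _all_layers(self):
        for blk in self.enc_blocks:
            yield from blk.layers
        yield from self.enc_drops
        yield from self.enc_pools
        yield from self.bottleneck.layers
        yield from self.dec_ups
        for blk in self.dec_blocks:
            yield from blk.layers
        yield self.head

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (B, H, W) or (B, H, W, C) in [0, 1] -> logits (B, H, W, n_classes)."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32, copy=False)
        skips = []
        for blk, drop, pool in zip(self.enc_blocks, self.enc_drops,
                                   self.enc_pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = drop.forward(x, train)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, blk, skip in zip(self.dec_ups, self.dec_blocks,
                                 reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = blk.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, blk, cs in zip(reversed(self.dec_ups),
                               reversed(self.dec_blocks),
                               reversed(self._skip_channels)):
            d = blk.backward(d)
            dskips.append(d[..., :cs])
            d = up.backward(d[..., cs:])
        d = self.bottleneck.backward(d)
        # dskips accumulated shallow-first; encoder unwinds deepest-first
        for blk, drop, pool, dskip in zip(reversed(self.enc_blocks),
                                          reversed(self.enc_drops),
                                          reversed(self.enc_pools),
                                          reversed(dskips)):
            d = pool.backward(d)
            d = drop.backward(d)
            d = blk.backward(d + dskip)

    # -- inference helpers ---------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def predict_mask(self, x: np.ndarray, foreground_class: int = 1) -> np.ndarray:
        """Per-pixel argmax; returns uint8 binary masks of the input shape."""
        logits = self.forward(x, train=False)
        return (logits.argmax(axis=-1) == foreground_class).astype(np.uint8)

    # -- parameter access ----------------------------------------------------

    def parameters(self):
        """Yield (layer, name, array) for every learnable parameter."""
        for l in self._all_layers():
            for name in l.params:
                yield l, name

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}_{name}": l.params[name].copy()
                for i, (l, name) in enumerate(self.parameters())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, (l, name) in enumerate(self.parameters()):
            l.params[name][...] = state[f"p{i}_{name}"]
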