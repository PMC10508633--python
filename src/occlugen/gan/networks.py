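"""U-Net generator and patch discriminator with hand-derived backward passes.

Generator: symmetric encoder/decoder, stride-2 4x4 (transposed) convolutions,
batch normalization and leaky/plain rectifiers, skip connections pairing
encoder stage i with decoder stage n-i, tanh output in [-1, 1].  Input is the
2-channel condition (mask image stacked with the opposing-tooth image).

Discriminator: stack of 4x4 convolutions (strides 2,2,2,1,1) mapping the
3-channel (condition, candidate) stack to an NxN matrix of per-patch
probabilities through a sigmoid; on 256x256 input N = 30.  The leaky-rectifier
outputs of stages 2-4 are exposed for the perceptual feature loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import DTYPE

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "build_generator", "build_discriminator",
           "UNetGenerator", "PatchDiscriminator"]

_MAX_CHANNELS = 512


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape of the U-Net: per-stage encoder channels (decoder mirrors them)."""

    resolution: int
    in_channels: int = 2
    out_channels: int = 1
    encoder_channels: tuple[int, ...] = ()
    dropout_stages: int = 3  # innermost decoder stages carrying noise dropout

    @classmethod
    def for_resolution(cls, resolution: int, base_channels: int = 64,
                       in_channels: int = 2, out_channels: int = 1) -> "GeneratorSpec":
        depth = int(np.log2(resolution))
        if 2**depth != resolution or depth < 3:
            raise ValueError("resolution must be a power of two, >= 8")
        chans = tuple(min(base_channels * 2**i, _MAX_CHANNELS) for i in range(depth))
        return cls(resolution, in_channels, out_channels, chans)

    def validate(self) -> None:
        depth = len(self.encoder_channels)
        if 2**depth != self.resolution:
            raise ValueError(
                "asymmetric spec: encoder depth must take the input down to 1x1 "
                f"(resolution {self.resolution}, depth {depth})"
            )


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Conv stages of the patch discriminator as (channels, stride) pairs."""

    resolution: int
    in_channels: int = 3
    stages: tuple[tuple[int, int], ...] = ((64, 2), (128, 2), (256, 2), (512, 1))
    exposed_layers: tuple[int, ...] = (2, 3, 4)  # 1-based conv-stage numbering

    @classmethod
    def for_resolution(cls, resolution: int, base_channels: int = 64,
                       in_channels: int = 3) -> "DiscriminatorSpec":
        stages = (
            (base_channels, 2),
            (base_channels * 2, 2),
            (base_channels * 4, 2),
            (min(base_channels * 8, _MAX_CHANNELS), 1),
        )
        return cls(resolution, in_channels, stages)

    def patch_size(self) -> int:
        s = self.resolution
        for _, stride in self.stages:
            s = (s + 2 - 4) // stride + 1
        return (s + 2 - 4) // 1 + 1  # final 1-channel conv, stride 1


def _winit(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.normal(0.0, 0.02, size=shape).astype(DTYPE)


class UNetGenerator:
    """Encoder-decoder with skips; batch size 1, CHW numpy arrays."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        chans = spec.encoder_channels
        self.depth = len(chans)
        p: dict[str, np.ndarray] = {}
        prev = spec.in_channels
        for i, c in enumerate(chans):
            p[f"enc{i}_W"] = _winit(rng, (c, prev, 4, 4))
            p[f"enc{i}_b"] = np.zeros(c, dtype=DTYPE)
            if self._enc_bn(i):
                p[f"enc{i}_gamma"] = rng.normal(1.0, 0.02, c).astype(DTYPE)
                p[f"enc{i}_beta"] = np.zeros(c, dtype=DTYPE)
            prev = c
        # decoder stage i consumes enc[depth-1-i] output (+ skip) and emits
        # enc[depth-2-i] channels; the last stage emits the image
        for i in range(self.depth):
            cin = chans[self.depth - 1 - i] * (1 if i == 0 else 2)
            cout = spec.out_channels if i == self.depth - 1 else chans[self.depth - 2 - i]
            p[f"dec{i}_W"] = _winit(rng, (cin, cout, 4, 4))
            p[f"dec{i}_b"] = np.zeros(cout, dtype=DTYPE)
            if i < self.depth - 1:
                p[f"dec{i}_gamma"] = rng.normal(1.0, 0.02, cout).astype(DTYPE)
                p[f"dec{i}_beta"] = np.zeros(cout, dtype=DTYPE)
        self.params = p

    def _enc_bn(self, i: int) -> bool:
        # no normalization on the first stage nor on the 1x1 bottleneck
        return 0 < i < self.depth - 1

    def forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """x: (in_channels, R, R) in [-1, 1] -> (out, cache); out in [-1, 1]."""
        spec = self.spec
        if x.shape != (spec.in_channels, spec.resolution, spec.resolution):
            raise ValueError(f"generator input shape {x.shape} does not match spec")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        p = self.params
        enc_caches = []
        skips = []
        h = x
        for i in range(self.depth):
            h, ccache = nn.conv2d_forward(h, p[f"enc{i}_W"], p[f"enc{i}_b"])
            bcache = None
            if self._enc_bn(i):
                h, bcache = nn.batchnorm_forward(h, p[f"enc{i}_gamma"], p[f"enc{i}_beta"])
            h, acache = nn.leaky_relu_forward(h)
            enc_caches.append((ccache, bcache, acache))
            skips.append(h)

        dec_caches = []
        for i in range(self.depth):
            h, ccache = nn.convT2d_forward(h, p[f"dec{i}_W"], p[f"dec{i}_b"])
            if i == self.depth - 1:
                h, tcache = nn.tanh_forward(h)
                dec_caches.append((ccache, None, None, tcache, False))
                break
            h, bcache = nn.batchnorm_forward(h, p[f"dec{i}_gamma"], p[f"dec{i}_beta"])
            h, dmask = nn.dropout_forward(
                h, spec_dropout_p(self.spec, i), dropout_rng if i < self.spec.dropout_stages else None
            )
            h, rcache = nn.relu_forward(h)
            skip = skips[self.depth - 2 - i]
            h = np.concatenate([h, skip], axis=0)
            dec_caches.append((ccache, bcache, dmask, rcache, True))
        return h, (enc_caches, dec_caches)

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Accumulate parameter gradients; returns them as a dict."""
        enc_caches, dec_caches = cache
        p = self.params
        g: dict[str, np.ndarray] = {}
        dskips: list[np.ndarray | None] = [None] * self.depth

        dh = dy.astype(DTYPE)
        for i in reversed(range(self.depth)):
            ccache, bcache, dmask, rcache_or_t, has_skip = dec_caches[i]
            if i == self.depth - 1:
                dh = nn.tanh_backward(dh, rcache_or_t)
            else:
                nch = dh.shape[0] // 2
                dskips[self.depth - 2 - i] = dh[nch:]
                dh = dh[:nch]
                dh = nn.relu_backward(dh, rcache_or_t)
                dh = nn.dropout_backward(dh, dmask)
                dh, dgam, dbet = nn.batchnorm_backward(dh, bcache)
                g[f"dec{i}_gamma"] = dgam
                g[f"dec{i}_beta"] = dbet
            dh, dw, db = nn.convT2d_backward(dh, p[f"dec{i}_W"], ccache)
            g[f"dec{i}_W"] = dw
            g[f"dec{i}_b"] = db

        for i in reversed(range(self.depth)):
            extra = dskips[i]
            if extra is not None:
                dh = dh + extra
            ccache, bcache, acache = enc_caches[i]
            dh = nn.leaky_relu_backward(dh, acache)
            if bcache is not None:
                dh, dgam, dbet = nn.batchnorm_backward(dh, bcache)
                g[f"enc{i}_gamma"] = dgam
                g[f"enc{i}_beta"] = dbet
            dh, dw, db = nn.conv2d_backward(dh, p[f"enc{i}_W"], ccache)
            g[f"enc{i}_W"] = dw
            g[f"enc{i}_b"] = db
        return g


def spec_dropout_p(spec: GeneratorSpec, stage: int) -> float:
    return 0.5 if stage < spec.dropout_stages else 0.0


class PatchDiscriminator:
    """Conv stack emitting per-patch probabilities; exposes hidden activations."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        p: dict[str, np.ndarray] = {}
        prev = spec.in_channels
        for i, (c, _) in enumerate(spec.stages):
            p[f"conv{i}_W"] = _winit(rng, (c, prev, 4, 4))
            p[f"conv{i}_b"] = np.zeros(c, dtype=DTYPE)
            if i > 0:
                p[f"conv{i}_gamma"] = rng.normal(1.0, 0.02, c).astype(DTYPE)
                p[f"conv{i}_beta"] = np.zeros(c, dtype=DTYPE)
            prev = c
        p["final_W"] = _winit(rng, (1, prev, 4, 4))
        p["final_b"] = np.zeros(1, dtype=DTYPE)
        self.params = p

    def forward(self, x: np.ndarray):
        """x: (in_channels, R, R) -> (patch probs (N, N), activations, cache).

        ``activations`` maps the 1-based conv-stage numbers listed in
        ``spec.exposed_layers`` to their post-activation blocks (C, H, W).
        """
        spec = self.spec
        if x.shape != (spec.in_channels, spec.resolution, spec.resolution):
            raise ValueError(f"discriminator input shape {x.shape} does not match spec")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        p = self.params
        caches = []
        acts: dict[int, np.ndarray] = {}
        h = x
        for i, (_, stride) in enumerate(spec.stages):
            h, ccache = nn.conv2d_forward(h, p[f"conv{i}_W"], p[f"conv{i}_b"], stride=stride)
            bcache = None
            if i > 0:
                h, bcache = nn.batchnorm_forward(h, p[f"conv{i}_gamma"], p[f"conv{i}_beta"])
            h, acache = nn.leaky_relu_forward(h)
            caches.append((ccache, bcache, acache, stride))
            if (i + 1) in spec.exposed_layers:
                acts[i + 1] = h
        h, fcache = nn.conv2d_forward(h, p["final_W"], p["final_b"], stride=1)
        probs, scache = nn.sigmoid_forward(h)
        caches.append((fcache, scache))
        return probs[0], acts, caches

    def backward(self, cache, dprobs: np.ndarray,
                 dacts: dict[int, np.ndarray] | None = None):
        """Backprop from patch probabilities (and optional hidden-activation
        gradients injected by the perceptual loss).  Returns (dx, grads)."""
        p = self.params
        g: dict[str, np.ndarray] = {}
        *stage_caches, (fcache, scache) = cache
        dh = nn.sigmoid_backward(dprobs[None, :, :].astype(DTYPE), scache)
        dh, dw, db = nn.conv2d_backward(dh, p["final_W"], fcache, stride=1)
        g["final_W"] = dw
        g["final_b"] = db
        for i in reversed(range(len(stage_caches))):
            ccache, bcache, acache, stride = stage_caches[i]
            if dacts and (i + 1) in dacts:
                dh = dh + dacts[i + 1].astype(DTYPE)
            dh = nn.leaky_relu_backward(dh, acache)
            if bcache is not None:
                dh, dgam, dbet = nn.batchnorm_backward(dh, bcache)
                g[f"conv{i}_gamma"] = dgam
                g[f"conv{i}_beta"] = dbet
            dh, dw, db = nn.conv2d_backward(dh, p[f"conv{i}_W"], ccache, stride=stride)
            g[f"conv{i}_W"] = dw
            g[f"conv{i}_b"] = db
        return dh, g


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    """Freshly initialized U-Net generator (weights N(0, 0.02), seeded)."""
    return UNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    """Freshly initialized patch discriminator (weights N(0, 0.02), seeded)."""
    return PatchDiscriminator(spec, np.random.default_rng(seed))
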