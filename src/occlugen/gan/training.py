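"""Alternating adversarial training loop (batch size 1) and inference.

Each iteration takes one (x, op, y) triplet, performs a discriminator update
on -(log D(real) + log(1 - D(fake))) plus the perceptual hinge, then a
generator update on the non-saturating adversarial term -log D(fake) plus the
L1 and perceptual terms of the active ablation group.  Both networks use the
adaptive-moment optimizer with the configured momenta.  Everything is seeded
and single-threaded deterministic: two runs with the same seed produce
identical loss histories and weights.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ..depth_projection import DepthImage
from .config import GanConfig
from .losses import EPS, discriminator_loss, generator_loss, l1_term, perceptual_deviation
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    UNetGenerator,
    build_discriminator,
    build_generator,
)
from .nn import DTYPE, Adam

__all__ = ["TrainHistory", "Checkpoint", "train", "generate", "load_triplet_arrays"]


@dataclass
class TrainHistory:
    """Per-iteration loss record of one training run."""

    iterations: list[int] = field(default_factory=list)
    loss_g: list[float] = field(default_factory=list)
    loss_d: list[float] = field(default_factory=list)
    adv_g: list[float] = field(default_factory=list)
    l1: list[float] = field(default_factory=list)
    perceptual: list[float] = field(default_factory=list)

    def append(self, it, lg, ld, adv, l1v, perc) -> None:
        self.iterations.append(int(it))
        self.loss_g.append(float(lg))
        self.loss_d.append(float(ld))
        self.adv_g.append(float(adv))
        self.l1.append(float(l1v))
        self.perceptual.append(float(perc))

    def __len__(self) -> int:
        return len(self.iterations)

    def save_csv(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("iteration,loss_g,loss_d,adv_g,l1,perceptual\n")
            for row in zip(self.iterations, self.loss_g, self.loss_d,
                           self.adv_g, self.l1, self.perceptual):
                fh.write(",".join(repr(v) for v in row) + "\n")


@dataclass
class Checkpoint:
    """Serializable weights + config of a trained generator/discriminator pair."""

    config: GanConfig
    resolution: int
    g_params: dict[str, np.ndarray]
    d_params: dict[str, np.ndarray]

    def save(self, path: str | os.PathLike) -> None:
        arrays = {f"G::{k}": v for k, v in self.g_params.items()}
        arrays.update({f"D::{k}": v for k, v in self.d_params.items()})
        arrays["__meta__"] = np.frombuffer(
            json.dumps({"config": self.config.to_dict(), "resolution": self.resolution}).encode(),
            dtype=np.uint8,
        )
        np.savez(os.fspath(path), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Checkpoint":
        with np.load(os.fspath(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            g = {k[3:]: data[k] for k in data.files if k.startswith("G::")}
            d = {k[3:]: data[k] for k in data.files if k.startswith("D::")}
        return cls(
            config=GanConfig.from_dict(meta["config"]),
            resolution=int(meta["resolution"]),
            g_params=g,
            d_params=d,
        )

    def generator(self) -> UNetGenerator:
        spec = GeneratorSpec.for_resolution(self.resolution, self.config.base_channels)
        gen = build_generator(spec, seed=0)
        if set(gen.params) != set(self.g_params):
            raise ValueError("checkpoint incompatible with the generator architecture")
        gen.params = {k: np.array(v, dtype=DTYPE) for k, v in self.g_params.items()}
        return gen


def _to_normalized(pixels: np.ndarray) -> np.ndarray:
    """uint8 [0, 255] -> float32 [-1, 1], shape (1, R, R)."""
    return (np.asarray(pixels, dtype=DTYPE) / 127.5 - 1.0)[None, :, :]


def _to_pixels(g_out: np.ndarray) -> np.ndarray:
    """float [-1, 1] -> uint8 [0, 255] with round-half-up."""
    v = np.floor((np.asarray(g_out[0], dtype=float) + 1.0) * 127.5 + 0.5)
    return np.clip(v, 0, 255).astype(np.uint8)


def load_triplet_arrays(entry: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read one manifest entry into normalized (x, op, y) arrays."""
    from PIL import Image

    out = []
    for tag in ("x_path", "op_path", "y_path"):
        img = np.asarray(Image.open(entry[tag]).convert("L"))
        out.append(_to_normalized(img))
    return tuple(out)


def _perc_grads(acts_r, acts_f, layer_weights, scale):
    """d(scale * sum_i lambda_i S_i)/d(acts): returns (d_real, d_fake)."""
    d_r: dict[int, np.ndarray] = {}
    d_f: dict[int, np.ndarray] = {}
    for i in acts_r:
        lw = layer_weights.get(i, 0.0)
        sgn = np.sign(acts_r[i] - acts_f[i]).astype(DTYPE)
        coeff = DTYPE(scale * lw / acts_r[i].size)
        d_r[i] = coeff * sgn
        d_f[i] = -coeff * sgn
    return d_r, d_f


def train(
    samples: list[dict] | list[tuple],
    config: GanConfig = GanConfig(),
    out_path: str | os.PathLike | None = None,
) -> tuple[Checkpoint, TrainHistory]:
    """Train the pit-and-fissure network on (x, op, y) triplets.

    ``samples`` is either a list of manifest entries (dicts with x/op/y PNG
    paths) or a list of pre-normalized (x, op, y) array triples.  Runs
    ``config.epochs`` passes over the samples in manifest order, one triplet
    per iteration.  Returns the checkpoint and the per-iteration history;
    aborts with a diagnostic if any loss becomes non-finite.
    """
    if not samples:
        raise ValueError("training requires at least one sample")
    data = [
        s if isinstance(s, tuple) else load_triplet_arrays(s) for s in samples
    ]
    res = data[0][0].shape[-1]

    g_seed = (config.seed * 2654435761 + 101) % (2**31)
    d_seed = (config.seed * 2654435761 + 202) % (2**31)
    gen = build_generator(GeneratorSpec.for_resolution(res, config.base_channels), g_seed)
    dis = build_discriminator(DiscriminatorSpec.for_resolution(res, config.base_channels), d_seed)
    opt_g = Adam(gen.params, config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(dis.params, config.learning_rate, config.beta1, config.beta2)
    noise_rng = (
        np.random.default_rng((config.seed * 2654435761 + 303) % (2**31))
        if config.noise == "dropout"
        else None
    )
    lw = config.layer_weights
    history = TrainHistory()

    it = 0
    for _epoch in range(config.epochs):
        for x, op, y in data:
            cond = np.concatenate([x, op], axis=0)
            real_in = np.concatenate([x, op, y], axis=0)

            # ---- discriminator update -------------------------------------
            # one generator forward serves both updates: G's weights do not
            # change until its own step, so the cache stays valid
            g_out, gcache = gen.forward(cond, noise_rng)
            fake_in = np.concatenate([x, op, g_out], axis=0)
            p_real, acts_r, cache_r = dis.forward(real_in)
            p_fake, acts_f, cache_f = dis.forward(fake_in)
            pr = float(np.clip(p_real.mean(), EPS, 1 - EPS))
            pf = float(np.clip(p_fake.mean(), EPS, 1 - EPS))
            if config.use_perceptual:
                _, perc_sum = perceptual_deviation(acts_r, acts_f, lw)
            else:
                perc_sum = 0.0
            loss_d = discriminator_loss(config, (np.log(pr), np.log(1 - pf)), perc_sum)

            npatch = p_real.size
            dpatch_r = np.full(p_real.shape, -1.0 / (pr * npatch), dtype=DTYPE)
            dpatch_f = np.full(p_fake.shape, 1.0 / ((1 - pf) * npatch), dtype=DTYPE)
            dacts_r = dacts_f = None
            if config.use_perceptual and perc_sum < config.margin:
                # d/dS of lambda_PD * (m - sum lambda_i S_i)
                dacts_r, dacts_f = _perc_grads(acts_r, acts_f, lw, -config.lambda_pd)
            _, g1 = dis.backward(cache_r, dpatch_r, dacts_r)
            _, g2 = dis.backward(cache_f, dpatch_f, dacts_f)
            opt_d.step({k: g1[k] + g2[k] for k in g1})

            # ---- generator update -----------------------------------------
            p_fake, acts_f, cache_f = dis.forward(fake_in)
            pf = float(np.clip(p_fake.mean(), EPS, 1 - EPS))
            adv_g = -float(np.log(pf))  # non-saturating form
            l1v = l1_term(g_out, y)
            if config.use_perceptual:
                _, acts_r, _ = dis.forward(real_in)
                _, perc_sum_g = perceptual_deviation(acts_r, acts_f, lw)
            else:
                perc_sum_g = 0.0
            loss_g = generator_loss(config, adv_g, l1v, perc_sum_g)

            dpatch_f = np.full(p_fake.shape, -1.0 / (pf * npatch), dtype=DTYPE)
            dacts_f = None
            if config.use_perceptual:
                _, dacts_f = _perc_grads(acts_r, acts_f, lw, config.lambda_pg)
            d_fake_in, _ = dis.backward(cache_f, dpatch_f, dacts_f)
            d_gout = d_fake_in[cond.shape[0]:]
            if config.use_l1:
                d_gout = d_gout + (config.lambda_l1 / y.size) * np.sign(g_out - y).astype(DTYPE)
            opt_g.step(gen.backward(gcache, d_gout))

            if not (np.isfinite(loss_g) and np.isfinite(loss_d)):
                raise RuntimeError(
                    f"non-finite loss at iteration {it}: L(G)={loss_g}, L(D)={loss_d}"
                )
            history.append(it, loss_g, loss_d, adv_g, l1v, perc_sum_g)
            it += 1

    ckpt = Checkpoint(
        config=config,
        resolution=res,
        g_params={k: v.copy() for k, v in gen.params.items()},
        d_params={k: v.copy() for k, v in dis.params.items()},
    )
    if out_path is not None:
        ckpt.save(out_path)
    return ckpt, history


def generate(
    checkpoint: Checkpoint | str | os.PathLike,
    x: DepthImage | np.ndarray,
    op: DepthImage | np.ndarray,
) -> DepthImage:
    """Single inference pass: (mask, opposing) -> generated fissure image.

    Deterministic when the checkpoint was configured with noise off.  The
    output inherits the projection metadata of ``x`` (when available) so it
    can be back-projected.
    """
    if not isinstance(checkpoint, Checkpoint):
        checkpoint = Checkpoint.load(checkpoint)
    x_pix = x.pixels if isinstance(x, DepthImage) else np.asarray(x)
    op_pix = op.pixels if isinstance(op, DepthImage) else np.asarray(op)
    if x_pix.shape != (checkpoint.resolution, checkpoint.resolution):
        raise ValueError(
            f"input resolution {x_pix.shape} does not match checkpoint "
            f"({checkpoint.resolution})"
        )
    gen = checkpoint.generator()
    noise_rng = None  # inference is noise-free
    cond = np.concatenate([_to_normalized(x_pix), _to_normalized(op_pix)], axis=0)
    g_out, _ = gen.forward(cond, noise_rng)
    pixels = _to_pixels(g_out)
    meta = x.meta if isinstance(x, DepthImage) else None
    if meta is None:
        from ..depth_projection import ProjectionMeta

        meta = ProjectionMeta(origin=(0.0, 0.0), spacing=1.0, plane_z=0.0,
                              h=6.5, n=1.4, gamma=1.0)
    return DepthImage(pixels=pixels, meta=meta)
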