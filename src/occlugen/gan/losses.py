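"""Objective terms of the adversarial pit-and-fissure extraction network.

The conditional objective is

    L_CGAN(G, D) = E[log D(x, op, y)] + E[log(1 - D(x, op, G(x, op, z)))]

with the patch matrix of the discriminator averaged into a single probability
before the log.  The generator additionally minimizes the L1 distance to the
target (weight lambda_1) and the perceptual feature deviation

    S_i(G, y) = (1/(C_i H_i W_i)) * sum |h_i(y) - h_i(G)|

summed over exposed discriminator layers with weights lambda_i (generator
weight lambda_PG).  The discriminator receives a hinge on the same quantity,
max{0, m - sum_i lambda_i S_i}, weighted by lambda_PD: it is rewarded for
keeping the feature deviation between real and generated images above the
margin m, sharpening its internal features.  All image-space losses are on
the [-1, 1] normalized pixel scale.
"""

from __future__ import annotations

import numpy as np

from .config import GanConfig

__all__ = [
    "patch_mean_prob",
    "adversarial_terms",
    "l1_term",
    "perceptual_deviation",
    "generator_loss",
    "discriminator_loss",
]

#: probabilities are kept this far away from {0, 1} inside logarithms
EPS = 1e-7


def patch_mean_prob(patch: np.ndarray, eps: float = EPS) -> float:
    """Average an NxN patch-probability matrix into one clamped probability."""
    p = float(np.mean(patch))
    return float(np.clip(p, eps, 1.0 - eps))


def adversarial_terms(discriminator, x, op, y, g_out) -> tuple[float, float]:
    """(log D(x,op,y), log(1 - D(x,op,G))) with patch outputs mean-reduced.

    Both discriminator evaluations are conditioned on (x, op); images are
    (1, R, R) arrays on the normalized scale.
    """
    for name, a, b in (("x/op", x, op), ("x/y", x, y), ("x/G", x, g_out)):
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch between {name}: {a.shape} vs {b.shape}")
    real, _, _ = discriminator.forward(np.concatenate([x, op, y], axis=0))
    fake, _, _ = discriminator.forward(np.concatenate([x, op, g_out], axis=0))
    return (
        float(np.log(patch_mean_prob(real))),
        float(np.log(1.0 - patch_mean_prob(fake))),
    )


def l1_term(g_out: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute deviation between generated and target images."""
    if g_out.shape != y.shape:
        raise ValueError(f"shape mismatch: {g_out.shape} vs {y.shape}")
    return float(np.mean(np.abs(np.asarray(g_out, float) - np.asarray(y, float))))


def perceptual_deviation(
    acts_y: dict[int, np.ndarray],
    acts_g: dict[int, np.ndarray],
    layer_weights: dict[int, float],
) -> tuple[dict[int, float], float]:
    """Per-layer size-normalized absolute feature deviations and their
    weighted sum sum_i lambda_i S_i."""
    if set(acts_y) != set(acts_g):
        raise ValueError("mismatched exposed layer sets")
    s: dict[int, float] = {}
    total = 0.0
    for i in sorted(acts_y):
        ay, ag = acts_y[i], acts_g[i]
        if ay.shape != ag.shape:
            raise ValueError(f"layer {i} activation shapes differ: {ay.shape} vs {ag.shape}")
        s[i] = float(np.abs(np.asarray(ay, float) - np.asarray(ag, float)).mean())
        total += layer_weights.get(i, 0.0) * s[i]
    return s, total


def generator_loss(config: GanConfig, adversarial: float, l1: float, perceptual: float) -> float:
    """L(G) = adversarial + lambda_1 * L1 + lambda_PG * sum_i lambda_i S_i.

    Group 1 keeps only the adversarial term; group 2 adds L1; group 3 adds
    the perceptual term.
    """
    loss = float(adversarial)
    if config.use_l1:
        loss += config.lambda_l1 * float(l1)
    if config.use_perceptual:
        loss += config.lambda_pg * float(perceptual)
    return loss


def discriminator_loss(
    config: GanConfig,
    adversarial_terms: tuple[float, float],
    perceptual_sum: float = 0.0,
) -> float:
    """L(D) = -(log D(real) + log(1 - D(fake))) + lambda_PD * max{0, m - sum}.

    The hinge is inactive once the real/fake feature deviation reaches the
    margin m, and absent entirely outside group 3.
    """
    t_real, t_fake = adversarial_terms
    loss = -(float(t_real) + float(t_fake))
    if config.use_perceptual:
        loss += config.lambda_pd * max(0.0, config.margin - float(perceptual_sum))
    return loss
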