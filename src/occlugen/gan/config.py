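"""Hyperparameter bundle of the pit-and-fissure extraction network."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class GanConfig:
    """Training hyperparameters and ablation switches.

    Defaults are the published operating point of the method: Adam with
    learning rate 2e-4 and momenta (0.5, 0.999), batch size 1, 200 epochs;
    L1 weight 100; perceptual-loss weights 50 (generator side) and 20
    (discriminator side) with hinge margin m = 0.35; per-layer perceptual
    weights 1, 2, 2 on discriminator stages 2-4.

    ``group`` selects the ablation: 1 = adversarial objective with the jaw
    spatial constraint only; 2 = group 1 + L1; 3 = group 2 + perceptual
    feature loss on both networks.

    ``noise`` is "none" (deterministic) or "dropout" (the stochastic z of
    the conditional objective, realized as generator dropout).
    """

    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 200
    lambda_l1: float = 100.0
    lambda_pg: float = 50.0
    lambda_pd: float = 20.0
    margin: float = 0.35
    layer_weights: dict[int, float] = field(default_factory=lambda: {2: 1.0, 3: 2.0, 4: 2.0})
    group: int = 3
    base_channels: int = 64
    dropout_p: float = 0.5
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise ValueError(f"unknown ablation group {self.group!r} (must be 1, 2 or 3)")
        if min(self.lambda_l1, self.lambda_pg, self.lambda_pd) < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0 < self.margin <= 1:
            raise ValueError("perceptual hinge margin must lie in (0, 1]")
        if self.batch_size != 1:
            raise ValueError("the training loop is defined for batch size 1")
        if self.noise not in ("none", "dropout"):
            raise ValueError("noise must be 'none' or 'dropout'")
        self.layer_weights = {int(k): float(v) for k, v in self.layer_weights.items()}

    @property
    def use_l1(self) -> bool:
        return self.group >= 2

    @property
    def use_perceptual(self) -> bool:
        return self.group == 3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layer_weights"] = {str(k): v for k, v in self.layer_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        d = dict(d)
        if "layer_weights" in d:
            d["layer_weights"] = {int(k): float(v) for k, v in d["layer_weights"].items()}
        return cls(**d)
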