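"""Shared optimisation settings for the autoencoder and both CNN stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class TrainingConfig:
    """SGD-with-momentum settings.

    Defaults follow the reference protocol (momentum 0.8, learning rate
    1e-5). Note that 1e-5 is far below what plain SGD needs to make visible
    progress in a few hundred epochs on small datasets; scaled-down
    experiments pass an explicitly larger rate (see docs/methods.md).
    ``target_loss`` optionally stops training once the epoch training loss
    reaches it.
    """

    learning_rate: float = 1e-5
    momentum: float = 0.8
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    weight_decay: float = 0.0
    target_loss: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")

    def asdict(self) -> dict:
        return asdict(self)
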