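"""Poisson-partitioned droplet assay simulator.

Each droplet receives Poisson(lambda) template copies and reads positive
when it received at least one, independently for the target and the
reference channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ddpcr import DropletAssay


@dataclass
class DropletSimConfig:
    n_droplets: int
    lambda_target: float
    lambda_reference: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.lambda_target < 0 or self.lambda_reference < 0:
            raise ValueError("lambda must be >= 0")


def gen_droplets(cfg: DropletSimConfig) -> tuple[DropletAssay, DropletAssay]:
    """Simulate one well: (target assay, reference assay).

    A droplet is positive iff its Poisson(lambda) copy draw is >= 1.
    Deterministic per config + seed.
    """
    rng = np.random.default_rng(cfg.seed)
    pos_t = int((rng.poisson(cfg.lambda_target, size=cfg.n_droplets) >= 1).sum())
    pos_r = int((rng.poisson(cfg.lambda_reference, size=cfg.n_droplets) >= 1).sum())
    return (
        DropletAssay("target", cfg.n_droplets, pos_t),
        DropletAssay("reference", cfg.n_droplets, pos_r),
    )
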