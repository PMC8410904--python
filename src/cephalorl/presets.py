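"""Canonical configurations at two problem sizes.

``paper_scale`` is the full-size configuration of the published system:
512x512 views, 128x128x4 states, the 32/32/64/64 + 512/256/128/4 agent
network, batch 96, replay 1e6.  Training it takes on the order of days per
landmark and is intended for GPU-class hardware.

``desk_scale`` is the package's self-contained configuration for training
and validating the whole method on synthetic phantoms on one CPU in
minutes: 128 px views of the 64 mm phantom (≈0.53 mm/px), 24 px
single-frame states, an 8/16-filter conv stack with one 64-unit hidden
layer, batch 32 and a few thousand steps per agent.  The algorithm is
identical; only the problem size changes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mdp_env import EnvConfig
from .networks import QNetworkSpec
from .dqn_agent import TrainConfig


@dataclass(frozen=True)
class ScaleConfig:
    netspec: QNetworkSpec
    train: TrainConfig
    env: EnvConfig
    view_size: int


def paper_scale(total_steps: int = 1_000_000) -> ScaleConfig:
    return ScaleConfig(
        netspec=QNetworkSpec(),
        train=TrainConfig(total_steps=total_steps),
        env=EnvConfig(),
        view_size=512,
    )


def desk_scale(total_steps: int = 5000) -> ScaleConfig:
    env = EnvConfig(patch_size=24, history=1, scales=(4, 2, 1), max_steps=60)
    return ScaleConfig(
        netspec=QNetworkSpec(
            input_size=24, in_channels=1, conv=((8, 5), (16, 3)), fc=(64,)
        ),
        train=TrainConfig(total_steps=total_steps, batch_size=32, target_sync=250),
        env=env,
        view_size=128,
    )
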