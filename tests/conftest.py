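"""Shared fixtures: tiny desk-scale configurations and synthetic data."""

import numpy as np
import pytest

from msssl.config import RunConfig
from msssl.synthetic import SyntheticConfig, generate_dataset


def tiny_run_config(**overrides) -> RunConfig:
    """Desk-scale configuration: 64x64 images, ViT depth 2 / dim 64,
    ResNet18 FPN at width 64, batch 8."""
    base = dict(
        data=dict(image_size=64, n_per_grade=60, lesion_rates=(0.0, 4.0, 10.0, 18.0, 30.0)),
        augment=dict(crop_size=64),
        encoder=dict(vit_variant="S", patch_size=16, embed_dim=64, depth=2, num_heads=4,
                     fpn_backbone="resnet18", fpn_channels=64, resnet_width=16,
                     input_size=64, proj_hidden=256, proj_dim=64),
        ssl=dict(batch_size=8, epochs=5),
        runtime=dict(seed=0),
    )
    for key, val in overrides.items():
        if key in base and isinstance(val, dict):
            base[key] = {**base[key], **val}
        else:
            base[key] = val
    return RunConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> RunConfig:
    return tiny_run_config()


@pytest.fixture(scope="session")
def small_dataset():
    """20 synthetic images (4 per grade) at 64 px plus their manifest."""
    syn = SyntheticConfig(image_size=64, lesion_rate_per_grade=(0.0, 4.0, 10.0, 18.0, 30.0),
                          seed=11)
    return generate_dataset(syn, 4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
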