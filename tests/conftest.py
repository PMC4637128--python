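import numpy as np
import pytest

from clift.classify import train_classifier
from clift.io import ChannelPair, RunConfig
from clift.pipeline import build_training_table
from clift.simulate import SimConfig, simulate_image


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def training_table(run_cfg):
    """Labelled cell-profile table from the simulator (balanced classes)."""
    return build_training_table(800, run_cfg, seed=7)


@pytest.fixture(scope="session")
def model(training_table, run_cfg):
    """Discriminant trained on 600 cells, leaving 200 for held-out checks."""
    return train_classifier(training_table.iloc[:600], run_cfg)


def simulate_pair(seed=0, **kwargs):
    """Simulate one image and wrap it as a ChannelPair."""
    cfg = SimConfig(rng_seed=seed, **kwargs)
    green, red, gt = simulate_image(cfg)
    pair = ChannelPair(
        green=green, red=red, bit_depth=16,
        biochip_id=f"B{seed:02d}", sample_id=f"S{seed:02d}",
    )
    return pair, gt


def kineto_only_intensity(amp, sd=None):
    """Organelle intensity map with only the kinetoplast varied."""
    return {
        "kinetoplast": (amp, sd if sd is not None else 0.15 * min(amp, 1.0)),
        "nucleus": (0.55, 0.1),
        "basal_body": (0.45, 0.08),
    }
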