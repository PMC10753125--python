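"""Shared fixtures.

The trained-model fixtures are session-scoped because CPU training is the
expensive part of the suite; every test that needs a converged model shares
the same benchmark runs (fixed seed) rather than retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from mamseg.phantom import PhantomConfig, generate_phantom

SEED = 7


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def mlo_phantom():
    """One deterministic MLO phantom with a pectoral wedge (128 x 128)."""
    cfg = PhantomConfig(image_size=128, pectoral_prob={"MLO": 1.0, "CC": 0.28})
    return generate_phantom(cfg, np.random.default_rng(SEED), view="MLO")


@pytest.fixture(scope="session")
def segmentation_run():
    """The end-to-end phantom segmentation benchmark (trains a model)."""
    from mamseg.benchmarks import segmentation_benchmark

    return segmentation_benchmark(seed=SEED)


@pytest.fixture(scope="session")
def raw_inclusion_run():
    """The raw-inclusion experiment benchmark (trains two models)."""
    from mamseg.benchmarks import raw_inclusion_benchmark

    return raw_inclusion_benchmark(seed=SEED)


@pytest.fixture(scope="session")
def style_holdout_run():
    """The leave-one-style-out benchmark (adversarial + null rounds)."""
    from mamseg.benchmarks import style_holdout_benchmark

    return style_holdout_benchmark(seed=SEED)
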