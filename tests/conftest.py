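import numpy as np
import pytest

from xvaekit.benchmark import BenchmarkConfig
from xvaekit.data import generate_paired_omics, rescale_dataset
from xvaekit.xvae import XvaeConfig


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny signal-rich paired dataset for fast model tests."""
    return rescale_dataset(generate_paired_omics(
        n=150, p=12, q=12, k=3, signal=4.0, seed=7))


@pytest.fixture()
def tiny_cfg():
    """Training config small enough for second-scale tests."""
    return XvaeConfig(view_hidden=16, fused_hidden=16, latent_dim=4,
                      epochs=5, batch_size=32, learning_rate=3e-3,
                      early_stop_patience=5, seed=3)


@pytest.fixture()
def tiny_bench_cfg(tmp_path):
    return BenchmarkConfig(
        scenario="categorical", models=("xvae",), repetitions=1,
        n=90, p=10, q=10, k=3, signal=4.0, base_seed=5,
        latent_dim=4, view_hidden=16, fused_hidden=16, epochs=3,
        n_draws=4, output_dir=None)
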