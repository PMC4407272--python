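import numpy as np
import pytest

from chromare.io import GenomicInterval, IntervalSet
from chromare.simulate import ElementClass, SimConfig, generate_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_sites():
    return IntervalSet(
        (
            GenomicInterval("chr1", 100, 300, name="a", summit=100),
            GenomicInterval("chr1", 1000, 1200, name="b", summit=100),
            GenomicInterval("chr2", 500, 700, name="c", summit=100),
        )
    )


def small_config(**overrides):
    """A fast, small simulation config for unit tests."""
    defaults = dict(
        seed=42,
        chrom_sizes={"chr1": 200_000, "chr2": 200_000},
        classes=(
            ElementClass("mare", 10, "tf_between_pair", tfs=("MITF", "SOX10"),
                         acetyl="both"),
            ElementClass("paired", 8, "paired", acetyl="both"),
            ElementClass("single", 6, "single"),
            ElementClass("tss", 8, "tss"),
        ),
        n_genes={"down": 0, "up": 0, "unchanged": 0},
        noise_rate=0.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture()
def noise_free_truth():
    return generate_truth(small_config())


@pytest.fixture()
def small_config_factory():
    return small_config
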