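import numpy as np
import pytest

import snpkaryo as sk


@pytest.fixture
def small_map() -> sk.ProbeMap:
    """One 5 Mb chromosome, 1 kb spacing, no jitter, half SNP probes."""
    return sk.build_probe_map([("1", 5_000_000)], spacing=1000,
                              snp_fraction=0.5, seed=0, jitter=0)


@pytest.fixture
def two_chrom_map() -> sk.ProbeMap:
    return sk.build_probe_map(
        [("1", 5_000_000), ("2", 5_000_000)],
        spacing=1000, snp_fraction=0.5, seed=1, jitter=0,
    )


@pytest.fixture
def zero_noise() -> sk.NoiseModel:
    return sk.NoiseModel(lrr_sd=0.0, baf_sd=0.0, het_fraction=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
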