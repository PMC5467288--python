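import pytest

from soxgrn.synthetic_data import SyntheticConfig, generate


def small_config(**overrides) -> SyntheticConfig:
    """A small but complete study layout for fast unit tests."""
    kwargs = dict(
        seed=7,
        n_chroms=2,
        n_genes=40,
        peaks_per_factor=12,
        planted_direct_fraction=0.25,  # 10 direct targets per factor
        trio_size=3,
        n_indirect=4,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config())


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate(small_config(seed=11, noise_sd_log2=0.0))
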