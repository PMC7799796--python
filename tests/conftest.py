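import pytest

from caregap.synthetic import RegionConfig, generate_region


@pytest.fixture(scope="session")
def tiny_config():
    """2 regions x 2 districts x 3 municipalities, fixed seed."""
    return RegionConfig(
        n_regions=2,
        districts_per_region=(2, 2),
        municipalities_per_district=(3, 3),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_region(tiny_config)


@pytest.fixture(scope="session")
def small_dataset():
    """A somewhat larger area for pipeline-level tests."""
    return generate_region(
        RegionConfig(
            n_regions=3,
            districts_per_region=(3, 5),
            municipalities_per_district=(4, 8),
            seed=11,
        )
    )
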