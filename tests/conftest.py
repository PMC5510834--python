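import pytest

from strainscreen.simulate import QualityModel, SimConfig, simulate_strains


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation: every true call passes every threshold and the
    other strain is always adequately covered, so recovery is exact."""
    cfg = SimConfig(
        seed=11,
        low_coverage_fraction=0.0,
        quality=QualityModel(hc_fail_fraction=0.0),
    )
    return simulate_strains(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Simulation under the default study conditions (evidence noise and
    under-covered sites in the other strain)."""
    return simulate_strains(SimConfig(seed=5))
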