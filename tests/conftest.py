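import pytest

from pegcal import GeneratorConfig, datasets


@pytest.fixture(scope="session")
def panel_samples():
    """All 14 reference PEG samples (SEC/MALLS Mw + DLS Rh)."""
    return datasets.reference_samples()


@pytest.fixture(scope="session")
def apeg_samples():
    """The ten-sample calibration series used to fit the scaling law."""
    return datasets.reference_samples("APEG")


@pytest.fixture(scope="session")
def profile16():
    return datasets.instrument_profile("16nm")


@pytest.fixture(scope="session")
def profile26():
    return datasets.instrument_profile("26nm")


@pytest.fixture(scope="session")
def ref_powerlaw():
    """The published h = 0.0718 * Mw^0.525 scaling law."""
    return datasets.reference_power_law()


@pytest.fixture
def gen_config():
    return GeneratorConfig(seed=1)
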