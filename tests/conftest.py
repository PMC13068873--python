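import pytest

from sciapt import (
    ModelRegistry,
    ScreeningParams,
    load_registry,
    packaged_ps_calibration,
)

# the 13 published PS aptamer candidates (PSApt 1-13)
PSAPT_SEQUENCES = {
    # universal
    "GGCGGCGAAG", "GGCGGCGGAG", "GGCGGCGCAG",
    # DNA
    "GGCGGCGTAG", "GGCGGCGTTG", "GGCGGCGATG", "GGCGGCGGTG", "GGCGGCGCTG",
    # RNA
    "GGCGGCGUAG", "GGCGGCGUUG", "GGCGGCGAUG", "GGCGGCGGUG", "GGCGGCGCUG",
}


@pytest.fixture(scope="session")
def registry() -> ModelRegistry:
    return load_registry()


@pytest.fixture(scope="session")
def ps(registry):
    return registry["PS"]


@pytest.fixture(scope="session")
def sp() -> ScreeningParams:
    return ScreeningParams()


@pytest.fixture(scope="session")
def ps_matrix():
    return packaged_ps_calibration()
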