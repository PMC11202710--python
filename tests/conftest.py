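import numpy as np
import pytest

from nutriferm.aa import AaMeasurement, AminoAcidProfile
from nutriferm.datasets import load_published_profiles


@pytest.fixture(scope="session")
def published_profiles():
    """Amino-acid profiles of the four products, transcribed from the
    published composition table."""
    return load_published_profiles()


@pytest.fixture
def simple_profile():
    """Small hand-made profile used where the full table is overkill."""
    return AminoAcidProfile(
        product_id="toy",
        contents={
            "Lys": AaMeasurement(0.87),
            "Met": AaMeasurement(0.64),
            "Cys": AaMeasurement(0.20),
            "Leu": AaMeasurement(1.00),
        },
        protein_pct=20.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240607)
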