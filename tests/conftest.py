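import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_oracles importable

from epimorph import synthetic_data as sd


@pytest.fixture
def cohort_spec():
    """Default study conditions, fixed seed."""
    return sd.SyntheticCohortSpec(seed=11)


@pytest.fixture
def cohort(cohort_spec):
    return sd.generate_cohort(cohort_spec)


@pytest.fixture
def flat_band_image():
    """300x300 px, 1 um/px, uniform 80 um epithelium over stroma."""
    spec = sd.SyntheticImageSpec(width_px=300, height_px=300,
                                 thickness_um=80.0, seed=0)
    return sd.generate_histology_image(spec)
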