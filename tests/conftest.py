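import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gain.synthetic import SyntheticConfig, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def clean_subject():
    """One noise-free synthetic participant with ground truth."""
    cfg = SyntheticConfig().zero_noise()
    rec, truth = generate_subject(cfg, "S01", 42)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_subject():
    rec, truth = generate_subject(SyntheticConfig(), "S01", 42)
    return rec, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants at default noise, for structural pipeline tests."""
    return generate_cohort(SyntheticConfig(), 3, 11)
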