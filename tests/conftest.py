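import numpy as np
import pytest

from dualprobe.kinetics import AcquisitionSchedule, RateConstants


@pytest.fixture
def schedule() -> AcquisitionSchedule:
    """Default stain-and-rinse schedule: 10 min stain, 10 rinses at 30 s."""
    return AcquisitionSchedule()


@pytest.fixture
def study_rates() -> RateConstants:
    """Moderate-EGFR conditions: BP = 1 with the fitted nonspecific rates."""
    return RateConstants(F=1.0, k3=0.1, k4=0.1, k5=0.16, k6=0.06)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
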