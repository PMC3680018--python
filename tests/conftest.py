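import numpy as np
import pytest

from podscan.simulate import AbnormalitySpec, SimConfig, simulate_trio

# compact genome for fast pipeline tests: 8 arms, 24k SNPs
SMALL_ARMS = {
    "1": (1500, 2000), "2": (1400, 1900), "3": (1300, 1800),
    "4": (1200, 1700), "5": (1100, 1600), "6": (1000, 1500),
    "7": (900, 1400), "8": (800, 1300),
}


def small_config(seed=0, abnormalities=(), **kw):
    return SimConfig(chrom_arms=dict(SMALL_ARMS), seed=seed,
                     abnormalities=list(abnormalities), **kw)


@pytest.fixture(scope="session")
def null_trio():
    """A trio with no planted abnormalities."""
    return simulate_trio(small_config(seed=11))


@pytest.fixture(scope="session")
def upd_trio():
    """A trio with a 30% mosaic maternal UPD covering most of arm 5q."""
    spec = AbnormalitySpec("5", 1200, 2500, "UPD", "mother", fraction=0.3)
    return simulate_trio(small_config(seed=7, abnormalities=[spec])), spec


@pytest.fixture(scope="session")
def deletion_trio():
    """A trio with a non-mosaic paternal deletion on arm 3q."""
    spec = AbnormalitySpec("3", 1500, 2600, "DEL", "father", fraction=1.0)
    return simulate_trio(small_config(seed=5, abnormalities=[spec])), spec
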