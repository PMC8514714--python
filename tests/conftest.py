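import numpy as np
import pytest

from ylineage.haplotypes import Haplotype
from ylineage.panels import yfiler17, yfiler_plus27


@pytest.fixture(scope="session")
def panel27():
    return yfiler_plus27()


@pytest.fixture(scope="session")
def panel17():
    return yfiler17()


def make_hap(sample_id, panel, calls=None, population="POP", stratum=None, base=12.0):
    """Haplotype with every panel series typed at ``base`` except overrides.

    ``calls`` overrides individual series; a value of None makes the
    series missing.
    """
    full = {s: base for s in panel.series}
    if calls:
        full.update(calls)
    return Haplotype(sample_id, population, full, stratum=stratum)


def random_hap(sample_id, panel, rng, population="POP"):
    calls = {s: float(rng.integers(10, 20)) for s in panel.series}
    return Haplotype(sample_id, population, calls)


#: Yfiler-Plus typed-series counts of the 25 excavated individuals by
#: stratigraphic unit (failed amplifications count as zero typed series).
ANCIENT_TYPED_COUNTS = [
    ("23-41", "SU23", 25),
    ("23-1", "SU23", 16),
    ("23-12", "SU23", 24),
    ("23-31", "SU23", 27),
    ("23-42", "SU23", 21),
    ("23-46", "SU23", 27),
    ("23-06", "SU23", 25),
    ("23-7", "SU23", 27),
    ("23-44", "SU23", 24),
    ("23-27", "SU23", 0),
    ("23-30", "SU23", 0),
    ("23-38", "SU23", 7),
    ("26-05", "SU26", 27),
    ("26-32", "SU26", 27),
    ("26-43", "SU26", 24),
    ("26-42", "SU26", 24),
    ("26-49", "SU26", 14),
    ("26-1", "SU26", 25),
    ("26-10", "SU26", 25),
    ("26-50", "SU26", 21),
    ("26-12", "SU26", 0),
    ("26-24", "SU26", 0),
    ("26-53", "SU26", 0),
    ("28-02", "SU28", 10),
    ("28-05", "SU28", 16),
]


@pytest.fixture(scope="session")
def ancient_typed_fixture(panel27):
    """Haplotypes reproducing the excavated cohort's typed-series counts."""
    haps = []
    rng = np.random.default_rng(42)
    for sid, su, n_typed in ANCIENT_TYPED_COUNTS:
        calls = {s: float(rng.integers(10, 20)) for s in panel27.series}
        for s in list(calls)[n_typed:]:
            calls[s] = None
        haps.append(Haplotype(sid, "RP_A", calls, stratum=su))
    return haps
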