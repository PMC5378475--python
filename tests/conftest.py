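import numpy as np
import pytest

from androdyn.survival import SurvivalRecord


@pytest.fixture
def make_records():
    """Factory: records from death days (and optional censoring days)."""

    def _make(deaths, censored=(), group="g"):
        recs = [SurvivalRecord(f"d{i}", group, float(d), True)
                for i, d in enumerate(deaths)]
        recs += [SurvivalRecord(f"c{i}", group, float(d), False)
                 for i, d in enumerate(censored)]
        return recs

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
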