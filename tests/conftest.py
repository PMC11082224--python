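import numpy as np
import pytest

from activetest import LabelLedger, SyntheticSpec, generate_pool, make_fixture


@pytest.fixture()
def fixture_pool():
    """The deterministic 8-record pool with hand-computed reference values."""
    return make_fixture()


@pytest.fixture(scope="session")
def packaged_pool():
    """The packaged binary benchmark pool: N=2000, miscalibration (0, 0.6)."""
    return generate_pool(SyntheticSpec(n_records=2000, miscalibration=(0.0, 0.6), seed=7))


def census_ledger(n: int) -> LabelLedger:
    """A ledger with every record selected at step 1 with probability one."""
    ledger = LabelLedger(n)
    ledger.record_step(np.ones(n, dtype=bool), np.ones(n))
    ledger.set_estimated_probs(np.ones(n, dtype=bool), np.ones(n))
    return ledger
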