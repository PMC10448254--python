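import pytest

from mitodbg.graph import build_mdbg
from mitodbg.simulate import SimSpec, make_leave_one_out_case


@pytest.fixture(scope="session")
def loo_case():
    """One leave-one-out case at the default study conditions."""
    return make_leave_one_out_case(SimSpec(seed=1))


@pytest.fixture(scope="session")
def loo_mdbg(loo_case):
    return build_mdbg(loo_case.db_genomes, 16)
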