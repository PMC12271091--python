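import pytest

from gsemkit.ldsc import build_S_V
from gsemkit.simulate import make_architecture, make_ld_scores, \
    simulate_sumstats_direct
from gsemkit.sumstats import harmonize


@pytest.fixture(scope="session")
def small_ld():
    return make_ld_scores(2000, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_ld):
    arch = make_architecture("small", M=2000, N=50_000, seed=5)
    return harmonize(simulate_sumstats_direct(arch, small_ld))


@pytest.fixture(scope="session")
def small_arch():
    return make_architecture("small", M=2000, N=50_000, seed=5)


@pytest.fixture(scope="session")
def small_sv(small_panel, small_ld):
    return build_S_V(small_panel, small_ld, n_blocks=100)
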