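import pytest

from kektess import build_rk, compute_all, theta_star_partition


@pytest.fixture(scope="session")
def rk_i_52():
    return build_rk("I", 5, 2)


@pytest.fixture(scope="session")
def rk_i_52_swg(rk_i_52):
    return rk_i_52.to_swg()


@pytest.fixture(scope="session")
def rk_i_52_partition(rk_i_52_swg):
    return theta_star_partition(rk_i_52_swg)


@pytest.fixture(scope="session")
def rk_i_52_direct(rk_i_52_swg):
    return compute_all(rk_i_52_swg)
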