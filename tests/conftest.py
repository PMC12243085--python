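import numpy as np
import pytest

from snowflake_water import GrowthConfig, Populations, StatePoint, load_preset
from snowflake_water.snowflake import ensemble_list

P_REF = 0.19  # reference reduced pressure used throughout


@pytest.fixture(scope="session")
def mb():
    return load_preset("MB-rose")


@pytest.fixture(scope="session")
def real():
    return load_preset("real-rose")


@pytest.fixture(scope="session")
def honeycomb_flake(mb):
    """Zero-noise, all-HB snowflake: a deterministic honeycomb fragment."""
    sp = StatePoint(T=0.15, p=P_REF)
    cfg = GrowthConfig(
        max_shells=9,
        n_replicas=1,
        seed=123,
        zero_noise=True,
        populations_override=Populations(f_HB=1.0, f_LJ=0.0, f_0=0.0, f_s=0.0),
    )
    return ensemble_list(sp, mb, cfg)[0]


@pytest.fixture(scope="session")
def ensemble_t015(mb):
    """Cold ordered ensemble (T*=0.15, p*=0.19), 10^4 replicas."""
    sp = StatePoint(T=0.15, p=P_REF)
    cfg = GrowthConfig(max_shells=9, n_replicas=10_000, seed=2015)
    return sp, ensemble_list(sp, mb, cfg)


@pytest.fixture(scope="session")
def ensemble_t020(mb):
    """Liquid-range ensemble (T*=0.2, p*=0.19), 10^4 replicas."""
    sp = StatePoint(T=0.2, p=P_REF)
    cfg = GrowthConfig(max_shells=9, n_replicas=10_000, seed=2020)
    return sp, ensemble_list(sp, mb, cfg)


@pytest.fixture(scope="session")
def small_ensembles_by_T(mb):
    """1,500-replica ensembles at T* in {0.15, 0.2, 0.25, 0.3} for trend tests."""
    out = {}
    for T in (0.15, 0.2, 0.25, 0.3):
        sp = StatePoint(T=T, p=P_REF)
        cfg = GrowthConfig(max_shells=9, n_replicas=1500, seed=900 + int(T * 100))
        out[T] = (sp, ensemble_list(sp, mb, cfg))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
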