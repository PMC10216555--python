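import numpy as np
import pytest

from gliodki import TissueParams, make_scheme


@pytest.fixture(scope="session")
def paper_scheme():
    """b = 0/1000/2500 s/mm², 60 directions per nonzero shell (121 volumes)."""
    return make_scheme(60, [0, 1000, 2500])


@pytest.fixture(scope="session")
def small_scheme():
    """Minimal well-posed scheme (31 volumes) for cheap fits."""
    return make_scheme(15, [0, 1000, 2500])


@pytest.fixture
def wm_params():
    """Reference white-matter-like tissue (awf 0.3, tort 2.5)."""
    return TissueParams(f=0.3, da_ax=0.8, de_ax=2.0, de_rad=0.8)


def random_tissue(rng: np.random.Generator) -> TissueParams:
    """Random physically plausible tissue draw for property tests."""
    de_ax = rng.uniform(1.5, 2.5)
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return TissueParams(
        f=rng.uniform(0.1, 0.7),
        da_ax=rng.uniform(0.4, 1.2),
        de_ax=de_ax,
        de_rad=rng.uniform(0.3, 0.9) * de_ax,
        orientation=tuple(v),
    )
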