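import numpy as np
import pytest

from mkdfe.dfe import GammaExpo, GammaZero
from mkdfe.synthetic import generate_sfs_dataset


@pytest.fixture(scope="session")
def gamma_zero_primate():
    """Deleterious-only DFE of the strongly leptokurtic kind fitted to primates."""
    return GammaZero(-740.0, 0.14)


@pytest.fixture(scope="session")
def gamma_expo_primate():
    return GammaExpo(-740.0, 0.14, 0.02, 1.0)


@pytest.fixture(scope="session")
def small_dataset(gamma_zero_primate):
    """One synthetic species dataset (n=20, L=1e6) with known truth."""
    return generate_sfs_dataset(
        gamma_zero_primate, theta=0.005, n=20, L_s=1e6, L_n=1e6,
        omega_a_true=0.05, seed=11,
    )
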