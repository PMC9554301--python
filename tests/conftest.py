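import numpy as np
import pytest

from circuitkinetics import MMParameters, InhibitionParameters, BiBiRates, TxtlParameters
from circuitkinetics.netlist import MotifSpec


@pytest.fixture(scope="session")
def betagal_params():
    """Beta-galactosidase / ONPG constants measured by plate-reader assay."""
    return MMParameters(K_m=0.167e-3, k_cat=2903.0, E0=0.3e-9, S0=1.2e-3)


@pytest.fixture(scope="session")
def betagal_spec(betagal_params):
    p = betagal_params
    return MotifSpec("mm_qssa", dict(K_m=p.K_m, k_cat=p.k_cat, E0=p.E0, S0=p.S0))


@pytest.fixture(scope="session")
def betagal_grid():
    """12-point substrate grid spanning 0.05-5 mM, log-spaced."""
    return np.geomspace(0.05e-3, 5e-3, 12)


@pytest.fixture(scope="session")
def inhibition_base():
    """Shared constants for the four inhibition mechanisms."""
    return dict(K_m=2e-3, k_cat=500.0, K_i=3e-3, E0=10e-9, S0=5e-3, I0=3e-3)


@pytest.fixture(scope="session")
def bibi_rates():
    """An arbitrary positive rate set for the reversible ordered Bi-Bi circuit."""
    return BiBiRates(
        k1=1e6, km1=100.0, k2=1e5, km2=50.0, k3=300.0, km3=100.0,
        k4=500.0, km4=1e5, k5=200.0, km5=1e6,
        E0=3.9e-9, NAD0=4e-3, S0=10e-3,
    )


@pytest.fixture(scope="session")
def txtl_params():
    """Plausible cell-free constants (synthetic stand-ins, order-of-magnitude
    realistic for an E. coli extract with T7 polymerase)."""
    return TxtlParameters(
        k_TX=0.05, d=2e-3, k_TL=0.05, k_mat=2e-3,
        Lm=1000.0, Lp=700.0, Cm=50.0, Cp=20.0,
        K_RNAP=100e-9, K_TetR=1e-9, K_ribo=500e-9,
        DNA0=6e-9, RNAP0=200e-9, Ribo0=1000e-9, TetR0=0.0,
    )
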