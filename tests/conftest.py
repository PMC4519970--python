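import numpy as np
import pytest

from lumifret import FretParameters, TitrationDesign

# Published photophysical constants of the Tb3+ -> TagRFP pair
TAU_D_MS = 0.33
TAU_DR_MS = 3.5
J_OVERLAP = 3.22591e15  # M^-1 cm^-1 nm^4
KAPPA2 = 2.0 / 3.0
REF_INDEX = 1.4

# Reported binding parameters of the 1-50 uM Tb3+ titration
KD_UM = 17.0
IMAX_AU = 95.0

TITRATION_GRID_UM = np.array([1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0])


@pytest.fixture
def sensor_params() -> FretParameters:
    """Photophysical constants of the terbium/red-fluorescent-protein pair."""
    return FretParameters(
        J=J_OVERLAP, tau_D=TAU_D_MS, tau_DR=TAU_DR_MS, kappa2=KAPPA2, n=REF_INDEX
    )


@pytest.fixture
def noiseless_design() -> TitrationDesign:
    return TitrationDesign(
        concentrations=TITRATION_GRID_UM,
        true_Kd=KD_UM,
        true_Imax=IMAX_AU,
        noise_sd=0.0,
        seed=0,
    )
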