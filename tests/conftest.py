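import numpy as np
import pandas as pd
import pytest

from quenchbind import DesignGrid, GroundTruth, QuenchingFit
from quenchbind.quenching import DEFAULT_TAU0

# Published-style four-temperature fit table: K_SV/kq in 1e5 / 1e13 units
# with their standard errors, used by the mechanism-classification tests.
TABLE_KSV = {273.0: 1.07e5, 298.0: 0.97e5, 318.0: 0.96e5, 338.0: 0.95e5}
TABLE_KSV_SE = {273.0: 0.01e5, 298.0: 0.02e5, 318.0: 0.03e5, 338.0: 0.07e5}
TABLE_KA = {273.0: 0.83e5, 298.0: 0.89e5, 318.0: 1.14e5, 338.0: 1.26e5}
TABLE_DH = 4003.0  # J/mol
TABLE_DS = 32.43  # J/mol/K
TABLE_DG = {273.0: -4850.0, 298.0: -5661.0, 318.0: -6310.0, 338.0: -6958.0}


@pytest.fixture
def table_fits():
    return [
        QuenchingFit(
            K_SV=ksv,
            intercept=1.0,
            kq=ksv / DEFAULT_TAU0,
            tau0=DEFAULT_TAU0,
            r_squared=0.95,
            stderr_K_SV=TABLE_KSV_SE[t],
            temperature=t,
        )
        for t, ksv in TABLE_KSV.items()
    ]


@pytest.fixture
def static_ratio_table():
    """Noiseless 1:1 static-model ratio table, Ka = 1e5 L/mol."""
    ka = 1e5
    q = np.array([0.0, 2e-6, 4e-6, 6e-6, 8e-6, 10e-6])
    return pd.DataFrame(
        {
            "quencher_conc_M": q,
            "F0_over_F": 1 + ka * q,
            "F0_minus_F_over_F": ka * q,
            "enhancement": False,
        }
    )


@pytest.fixture
def noiseless_truth():
    """Ground truth whose fixed band center makes ratios exact."""
    return GroundTruth(noise_rel=0.0, blueshift_max=0.0)


@pytest.fixture
def single_temp_grid():
    return DesignGrid(temperatures=(298.0,))


def closed_form_ols(x, y):
    """Independent Sigma-formula least squares (slope, intercept)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
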