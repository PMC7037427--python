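import numpy as np
import pytest

from dopatherm.kinetics import InitialRate, MichaelisMentenFit
from dopatherm.synthetic import (
    DEFAULT_KM_BY_T_MM,
    DEFAULT_VMAX_BY_T_MM_MIN,
    SimulationParams,
)

#: per-temperature (Km mM, Vmax mM/min) study-condition ground truth
TRUTH_BY_T = {
    t: (DEFAULT_KM_BY_T_MM[t], DEFAULT_VMAX_BY_T_MM_MIN[t])
    for t in (25.0, 31.0, 37.0, 43.0)
}

DOUBLING_SERIES_MM = (0.09375, 0.1875, 0.375, 0.75, 1.5, 3.0, 6.0)


def exact_rates(temperature_C: float, km_mM: float, vmax_mM_min: float,
                series=DOUBLING_SERIES_MM) -> list[InitialRate]:
    """Noise-free Michaelis-Menten velocities at the substrate series."""
    return [
        InitialRate(substrate_mM=s, temperature_C=temperature_C,
                    v_initial_mM_min=vmax_mM_min * s / (km_mM + s),
                    se_mM_min=0.0, n_points=10)
        for s in series
    ]


def table1_mean_fits() -> list[MichaelisMentenFit]:
    """Per-temperature mean fits at the study-condition (Km, Vmax) values."""
    return [
        MichaelisMentenFit(temperature_C=t, km_mM=km, vmax_mM_min=vm,
                           se_km=0.05, se_vmax=0.005, adj_r2=0.9, n_rates=3)
        for t, (km, vm) in sorted(TRUTH_BY_T.items())
    ]


@pytest.fixture
def noise_free_params() -> SimulationParams:
    return SimulationParams(noise_sigma_mOD=0.0, n_replicates=1, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
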