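import numpy as np
import pytest

import ionuptake as iu

SCHEDULE = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


@pytest.fixture(scope="session")
def recipes():
    return iu.load_recipes()


@pytest.fixture(scope="session")
def small_experiment():
    """Seeded 6-genotype x 3-replicate x 2-level experiment (36 plants)."""
    cfg = iu.SimulationConfig(seed=11, genotypes=6, replicates=3)
    return iu.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def panel_experiment():
    """Panel-sized experiment (26 genotypes x 2 reps x 2 levels = 104 plants)."""
    cfg = iu.SimulationConfig(seed=7, genotypes=26, replicates=2)
    return iu.simulate_experiment(cfg)


def mean_params(ion: str) -> iu.MMParams:
    """Population-mean kinetic parameters used by the simulator defaults."""
    p = iu.IonPopulationParams()
    return iu.MMParams(ion, p.mean_imax, p.mean_km)


def noiseless_series(ion, c0, i_max=0.019, k_m=100.0, length=400.0, volume=250.0,
                     schedule=SCHEDULE):
    params = iu.MMParams(ion, i_max, k_m)
    conc = iu.mm_depletion_conc(np.asarray(schedule), c0, params, length, volume)
    return iu.DepletionSeries(chamber="c1", ion=ion, times=np.asarray(schedule),
                              concentrations=conc, volume=volume)
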