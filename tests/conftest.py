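import numpy as np
import pytest

import morbigraph as mg


@pytest.fixture(scope="session")
def toy5():
    return mg.make_fixture("toy5")


@pytest.fixture(scope="session")
def path_fixture():
    return mg.make_fixture("path")


@pytest.fixture
def rng():
    return np.random.default_rng(20231215)


def ten_disease_config(n_persons=20_000, seed=0, *, cooccur=(), cost=(),
                       beta=0.35, zero_inflation=0.25, latent=False):
    """Ten diseases with realistic marginals; used by the planted-recovery
    and set-size-gradient checks."""
    names = list(mg.simulate.TABLE1_PREVALENCES)[:10]
    diseases = tuple(mg.DiseaseSpec(n, mg.simulate.TABLE1_PREVALENCES[n])
                     for n in names)
    factors = ()
    if latent:
        factors = (mg.LatentFactor(tuple(1.0 for _ in names), 0.9),)
    return mg.SimulationConfig(
        n_persons=n_persons,
        diseases=diseases,
        latent_factors=factors,
        planted_cooccur_sets=tuple(
            mg.PlantedCooccurrence(tuple(m), boost) for m, boost in cooccur
        ),
        outpatient=mg.HRUModel(
            zero_inflation=zero_inflation, baseline_mean=2.0,
            per_disease_log_increment=beta, dispersion=1.2,
            planted_cost_sets=tuple(
                mg.PlantedCost(tuple(m), g) for m, g in cost
            ),
        ),
        inpatient=mg.HRUModel(zero_inflation=0.5, baseline_mean=0.3,
                              per_disease_log_increment=0.4, dispersion=0.8),
        age_bands=((20, 45, 0.45), (45, 65, 0.35), (65, None, 0.20)),
        seed=seed,
    )
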