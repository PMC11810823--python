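import numpy as np
import pandas as pd
import pytest

from featherblup.config import SimConfig
from featherblup.lmm import ModelData
from featherblup.simulate import simulate_dataset


@pytest.fixture(scope="session")
def sim60():
    """Moderate synthetic recurrent test shared across read-only tests."""
    return simulate_dataset(SimConfig(n_sires=60, seed=11))


@pytest.fixture(scope="session")
def data60(sim60):
    return ModelData.from_sim(sim60)


def one_way_sire_data(n_sires=60, k=8, sigma2_S=0.3, sigma2_e=1.0, mu=2.0, seed=0):
    """Balanced one-way half-sib design: unrelated sires, k records each."""
    rng = np.random.default_rng(seed)
    sires = [f"S{i}" for i in range(n_sires)]
    ped = pd.DataFrame(
        {"animal": sires, "sire": None, "dam": None, "generation": 0, "sex": "M"}
    )
    u = rng.normal(0, np.sqrt(sigma2_S), n_sires)
    rows = []
    for i, sire in enumerate(sires):
        for j in range(k):
            rows.append(
                {
                    "cage_id": f"C{i}_{j}",
                    "sire_id": sire,
                    "mean_back45": mu + u[i] + rng.normal(0, np.sqrt(sigma2_e)),
                    "surv_frac45": 1.0,
                    "rt_number": "a",
                    "farm": "f",
                    "cross": "x",
                    "housing_date": "d",
                    "feather_gene": "g",
                    "representative_animal_id": f"R{i}_{j}",
                }
            )
    return ModelData(pedigree=ped, cages=pd.DataFrame(rows)), u


@pytest.fixture()
def balanced_oneway():
    return one_way_sire_data()
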