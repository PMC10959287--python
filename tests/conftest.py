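import numpy as np
import pandas as pd
import pytest

from lactomics.datamodel import FeatureTable, PhenotypeTable
from lactomics.simulate import SimulationParams, generate_study


def small_params(seed: int = 0, **overrides) -> SimulationParams:
    """A fast, reduced-size synthetic study for unit tests."""
    defaults = dict(
        n_features={
            "microbial_composition": 60,
            "microbial_function": 80,
            "rumen_metabolome": 50,
            "serum_metabolome": 40,
        },
        planted={"microbial_composition": {f"sp{j:04d}": 3.0 for j in range(10)}},
        n_phenotype_associated={"rumen_metabolome": 5, "serum_metabolome": 5},
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture
def small_study():
    return generate_study(small_params(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_table():
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2"],
    )
    return FeatureTable(df, "rumen_metabolome")


def make_phenotypes(
    n: int = 6,
    parity=None,
    lactation_days=None,
    groups=None,
    milk_yield=None,
) -> PhenotypeTable:
    rng = np.random.default_rng(0)
    idx = [f"b{i}" for i in range(n)]
    return PhenotypeTable(
        pd.DataFrame(
            {
                "milk_yield": milk_yield
                if milk_yield is not None
                else rng.normal(9, 1, n),
                "milk_fat_yield": rng.normal(0.6, 0.1, n),
                "group": groups
                if groups is not None
                else ["HH"] * (n // 2) + ["LL"] * (n - n // 2),
                "parity": parity if parity is not None else [1] * n,
                "lactation_days": lactation_days
                if lactation_days is not None
                else rng.uniform(50, 250, n),
            },
            index=idx,
        )
    )
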