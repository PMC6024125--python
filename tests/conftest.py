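import numpy as np
import pytest

from reintroipm.data_model_io import (
    CaptureHistory,
    Dataset,
    FecundityRecord,
    Individual,
    ModelConfig,
    ParameterSet,
    UnbandedCount,
)
from reintroipm.synthetic_data import ScenarioSpec, simulate_population, tawharanui_preset


@pytest.fixture
def toy_history() -> CaptureHistory:
    """Hand-written 3-individual, 4-occasion history."""
    individuals = [
        Individual(id="f1", sex="female", origin="translocated",
                   banding_method="not-applicable", first_occasion=0),
        Individual(id="m1", sex="male", origin="translocated",
                   banding_method="not-applicable", first_occasion=0),
        Individual(id="w1", sex="unknown", origin="wild-born",
                   banding_method="nestling", first_occasion=1),
    ]
    detections = np.array(
        [
            [1, 1, 0, 1],
            [1, 0, 1, 1],
            [0, 1, 1, 0],
        ]
    )
    return CaptureHistory(
        individuals=individuals,
        detections=detections,
        occasions=["2007r", "2007", "2008", "2009"],
        first_interval_fraction=0.5,
    )


@pytest.fixture
def toy_dataset(toy_history) -> Dataset:
    fecundity = [
        FecundityRecord(female_id="f1", year=1, fledglings=3, density=3.0),
        FecundityRecord(female_id="f1", year=3, fledglings=0, density=4.0),
    ]
    unbanded = [
        UnbandedCount(occasion=2, sex="male", count=1),
        UnbandedCount(occasion=3, sex="unknown", count=2),
    ]
    return Dataset(history=toy_history, fecundity=fecundity, unbanded=unbanded)


@pytest.fixture(scope="session")
def preset_dataset():
    """One realization of the case-study preset, shared across tests."""
    spec = tawharanui_preset(seed=20070301)
    return simulate_population(spec)


@pytest.fixture(scope="session")
def quick_config() -> ModelConfig:
    """Sampler settings for replicate studies: single chain, short run."""
    return ModelConfig.reduced(
        iterations=6000, burn_in=2000, chains=1, thin=2,
        check_convergence=False, seed=0,
    )


def small_scenario(seed: int, n_years: int = 3) -> ScenarioSpec:
    """Tiny scenario for fast property tests."""
    truth = ParameterSet(
        phi_a=0.8, phi_j_mean=0.3, p=0.85, alpha_f=np.log(2.0),
        sigma_female=0.2, sigma_year_j=0.3,
    )
    return ScenarioSpec(
        releases={0: (4, 3), 1: (0, 2)}, n_years=n_years, truth=truth, seed=seed
    )
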