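import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from mscmr.data import ADULT, FLEDGLING, Dataset, EncounterHistory, StudyCalendar
from mscmr.simulate import SimulationConfig, simulate_dataset


def random_history(rng: np.random.Generator, T: int, animal_id: str) -> EncounterHistory:
    """A random valid encounter history (for I/O and likelihood tests)."""
    mark = int(rng.integers(1, T + 1))
    fledgling = bool(rng.integers(2))
    det = [0] * T
    det[mark - 1] = 1
    for t in range(mark, T):
        det[t] = int(rng.random() < 0.4)
    mass = round(float(rng.uniform(2.5, 4.2)), 2) if fledgling else None
    return EncounterHistory(
        animal_id=animal_id,
        mark_occasion=mark,
        mark_class=FLEDGLING if fledgling else ADULT,
        detections=tuple(det),
        fledging_mass_kg=mass,
    )


def random_dataset(rng: np.random.Generator, T: int = 6, n: int = 30) -> Dataset:
    cal = StudyCalendar(first_season=2003, n_occasions=T)
    hs = [random_history(rng, T, f"a{i:06d}") for i in range(n)]
    return Dataset(calendar=cal, histories=hs)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset with active mass + annual covariate effects."""
    cfg = SimulationConfig(
        n_occasions=6,
        fledglings_per_cohort=80,
        adults_per_year=50,
        mass_slope=0.5,
        covariate_slopes={"pred_pressure": -0.4},
    )
    return simulate_dataset(cfg, seed=42)


@pytest.fixture(scope="session")
def adult_only_sim():
    cfg = SimulationConfig(
        n_occasions=4,
        fledglings_per_cohort=0,
        adults_per_year=170,
        n_age_classes=1,
        phi_means=(0.7,),
        p_by_effort={"high": 0.6, "mid": 0.6, "none": 0.6},
        gateway_days=(150.0,) * 4,
    )
    return simulate_dataset(cfg, seed=7)
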