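import numpy as np
import pytest

from fetalhand.data_model import Cohort, FetusInfo, MovementRecord, table2_fixture
from fetalhand.synthetic_cohort import SyntheticConfig, generate_cohort, recovery_config


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture()
def tiny_cohort():
    """Three fetuses, hand-built records (values chosen for easy arithmetic)."""
    fetuses = [FetusInfo("a", "right"), FetusInfo("b", "right"), FetusInfo("c", "left")]
    records = [
        MovementRecord("a", 18, "eye", "right", 400.0, 40.0),
        MovementRecord("a", 18, "eye", "right", 600.0, 42.0),
        MovementRecord("a", 18, "eye", "left", 800.0, 38.0),
        MovementRecord("b", 18, "eye", "right", 900.0, 41.0),
        MovementRecord("b", 18, "eye", "left", 700.0, 39.0),
        MovementRecord("c", 18, "eye", "right", 1000.0, 45.0),
        MovementRecord("c", 18, "eye", "left", 600.0, 44.0),
        MovementRecord("c", 14, "mouth", "left", 950.0, 50.0),
    ]
    return Cohort(fetuses=fetuses, records=records)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def dense_cohort():
    return generate_cohort(recovery_config(), seed=12)


def random_cohort(rng: np.random.Generator, n_fetuses: int = 5, n_records: int = 20) -> Cohort:
    """Small random (but valid) cohort for round-trip/property tests."""
    fetuses = [
        FetusInfo(f"f{i}", "right" if rng.random() < 0.7 else "left")
        for i in range(n_fetuses)
    ]
    records = []
    for _ in range(n_records):
        records.append(
            MovementRecord(
                fetus_id=f"f{rng.integers(n_fetuses)}",
                gw=int(rng.choice([14, 18, 22])),
                target=str(rng.choice(["eye", "mouth", "wall"])),
                hand=str(rng.choice(["right", "left"])),
                mt=float(rng.uniform(201.0, 3000.0)),
                tpv=float(rng.uniform(1.0, 99.0)),
            )
        )
    used = {r.fetus_id for r in records}
    return Cohort(fetuses=[f for f in fetuses if f.fetus_id in used], records=records)
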