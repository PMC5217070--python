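import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gengroups import Pedigree, PedigreeRecord, validate_and_order

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_pedigree(rng: np.random.Generator, n: int, p_unknown: float = 0.3,
                    p_immigrant: float = 0.2) -> Pedigree:
    """Random ordered pedigree: each individual's parents drawn from earlier
    positions or left unknown; some records immigrant-flagged."""
    records = []
    for i in range(n):
        dam = sire = None
        if i > 0 and rng.random() > p_unknown:
            dam = f"I{rng.integers(0, i)}"
        if i > 0 and rng.random() > p_unknown:
            sire = f"I{rng.integers(0, i)}"
        if dam is not None and dam == sire:
            sire = None
        records.append(
            PedigreeRecord(
                f"I{i}", dam, sire,
                cohort=int(i // 10) + 1,
                is_immigrant=bool(rng.random() < p_immigrant),
            )
        )
    return validate_and_order(Pedigree(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20160912)


@pytest.fixture
def trio():
    """sire, dam, offspring — the smallest informative pedigree."""
    return validate_and_order(
        Pedigree(
            [
                PedigreeRecord("s"),
                PedigreeRecord("d"),
                PedigreeRecord("i", "d", "s"),
            ]
        )
    )


@pytest.fixture
def fullsib_mating():
    """Founders A,B; full sibs C,D; inbred offspring E (F = 0.25), plus F1."""
    return validate_and_order(
        Pedigree(
            [
                PedigreeRecord("A"),
                PedigreeRecord("B"),
                PedigreeRecord("C", "A", "B"),
                PedigreeRecord("D", "A", "B"),
                PedigreeRecord("E", "C", "D"),
                PedigreeRecord("G", "C", "D"),
            ]
        )
    )
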