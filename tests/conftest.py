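import datetime as dt

import numpy as np
import pandas as pd
import pytest

from vocalkin import EffectConfig, Individual, Pedigree, generate_colony


@pytest.fixture(scope="session")
def small_effect_config() -> EffectConfig:
    """A reduced colony (fast) with strong individual signatures."""
    return EffectConfig(
        n_individuals_f=10,
        n_individuals_m=8,
        calls_per_individual=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_colony(small_effect_config):
    return generate_colony(small_effect_config)


@pytest.fixture(scope="session")
def default_colony():
    """The full-size study conditions: 22 F / 14 M, 482 calls."""
    return generate_colony(EffectConfig(seed=1))


@pytest.fixture()
def toy_pedigree() -> Pedigree:
    """Two founder couples, offspring, half/full sibs and an inbred child."""
    d = dt.date
    return Pedigree(
        [
            Individual("F1", "F", d(1990, 1, 1)),
            Individual("M1", "M", d(1990, 2, 1)),
            Individual("F2", "F", d(1990, 3, 1)),
            Individual("M2", "M", d(1990, 4, 1)),
            # full siblings from F1 x M1
            Individual("S1", "M", d(1992, 1, 1), sire_id="M1", dam_id="F1"),
            Individual("S2", "F", d(1992, 2, 1), sire_id="M1", dam_id="F1"),
            # half sibling (same dam, different sire)
            Individual("H1", "F", d(1993, 1, 1), sire_id="M2", dam_id="F1"),
            # offspring of full-sib mating -> inbred
            Individual("X1", "F", d(1994, 1, 1), sire_id="S1", dam_id="S2"),
        ]
    )


@pytest.fixture()
def housing_fixture() -> tuple[pd.DataFrame, dict]:
    """Three dyads with distinct co-housing durations; recordings afterwards.

    A-B share cage C1 for 100 days, C-D share C2 for 300 days, E-F share C3
    for 50 days; recordings are dated after every interval.
    """
    rows = []
    spans = {"C1": ("A", "B", 100), "C2": ("C", "D", 300), "C3": ("E", "F", 50)}
    start = dt.date(2005, 1, 1)
    for cage, (a, b, days) in spans.items():
        end = start + dt.timedelta(days=days - 1)
        for ind in (a, b):
            rows.append(
                {
                    "individual_id": ind,
                    "cage_id": cage,
                    "start_date": start.isoformat(),
                    "end_date": end.isoformat(),
                }
            )
    housing = pd.DataFrame(rows)
    rec = {i: dt.date(2007, 6, 1) for i in "ABCDEF"}
    return housing, rec
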