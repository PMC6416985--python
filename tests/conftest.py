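"""Shared fixtures: small synthetic datasets generated at test time."""

import logging

import numpy as np
import pandas as pd
import pytest

import recapture as rc
from recapture.config import SOURCES

logging.getLogger("recapture").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """One year of data under the default study conditions (with over-coverage)."""
    cfg = rc.SimulationConfig(true_population_size=2000, years=[2012], seed=42)
    return rc.simulate_population(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """One year with no police over-coverage and collision-free study IDs."""
    cfg = rc.SimulationConfig(
        true_population_size=1000,
        years=[2012],
        seed=7,
        member_fraction_pb=1.0,
        overcoverage_count=0,
        unique_study_ids=True,
    )
    return rc.simulate_population(cfg)


@pytest.fixture(scope="session")
def default_table(default_sim):
    hist = rc.histories_from_truth(default_sim.truth)
    return rc.build_contingency_table(hist, 2012)


@pytest.fixture()
def toy_histories():
    """Five hand-written person-year capture histories."""
    rows = [
        ("a", 1, 0, 0, 0, "M", 30, "15-44", "Harju"),
        ("b", 0, 1, 0, 0, "F", 50, "45+", "Ida-Viru"),
        ("c", 0, 1, 1, 0, "M", 22, "15-44", "other"),
        ("d", 1, 1, 1, 1, "M", 40, "15-44", "Harju"),
        ("e", 0, 0, 0, 1, "F", 33, "15-44", "Harju"),
    ]
    return pd.DataFrame(
        [
            {
                "study_id": sid,
                "year": 2012,
                "DR": dr,
                "PB": pb,
                "HIF-T": ht,
                "HIF-F": hf,
                "sex": sex,
                "age_midyear": age,
                "age_group": ag,
                "county": county,
            }
            for sid, dr, pb, ht, hf, sex, age, ag, county in rows
        ]
    )


def cells_grid():
    """A fresh unstratified 16-cell grid with zero counts."""
    rows = []
    for p in range(16):
        pat = {s: (p >> i) & 1 for i, s in enumerate(SOURCES)}
        rows.append(
            {
                **pat,
                "count": np.nan if sum(pat.values()) == 0 else 0.0,
                "flag": "missing" if sum(pat.values()) == 0 else "observed",
            }
        )
    return pd.DataFrame(rows)


def table_from_counts(counts: dict, year=2012):
    """Build a contingency table from {pattern tuple (DR,PB,HIF-T,HIF-F): count}."""
    from recapture.tabulation import StratifiedContingencyTable

    grid = cells_grid()
    for pat, c in counts.items():
        mask = np.ones(len(grid), dtype=bool)
        for s, v in zip(SOURCES, pat):
            mask &= grid[s] == v
        grid.loc[mask, "count"] = float(c)
    return StratifiedContingencyTable(year=year, strata=(), cells=grid)
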