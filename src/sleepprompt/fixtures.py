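"""Small packaged fixtures: baseline contingency tables, seed catalog, demo cohort.

The contingency tables are the published baseline lifestyle counts of
the trial this toolkit models (intervention arm first row), kept here so
the chi-square machinery can be exercised against known statistics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FIXTURE_NAMES", "contingency_table", "fixture_generator", "UnknownFixtureError"]


class UnknownFixtureError(KeyError):
    pass


#: (row labels = arms, column labels, counts) — SPA row first.
_TABLES = {
    # alcohol use among ISI-8 insomniacs: never / sometimes / everyday
    "table1-isi8-alcohol": (
        ("SPA", "control"),
        ("never", "sometimes", "everyday"),
        [[6, 23, 8], [15, 13, 6]],
    ),
    # current smoking among ISI-8 insomniacs: smoker / non-smoker
    "table1-isi8-smoking": (
        ("SPA", "control"),
        ("smoker", "non_smoker"),
        [[4, 33], [0, 34]],
    ),
    # alcohol as a sleep aid among ISI-8 insomniacs: user / non-user
    "table1-isi8-sleep-aid": (
        ("SPA", "control"),
        ("user", "non_user"),
        [[0, 37], [5, 29]],
    ),
    # alcohol as a sleep aid, total population: user / non-user
    "table1-total-sleep-aid": (
        ("SPA", "control"),
        ("user", "non_user"),
        [[1, 59], [6, 50]],
    ),
}

FIXTURE_NAMES = tuple(sorted(_TABLES)) + ("seed-catalog", "demo-cohort")


def contingency_table(name: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Row labels, column labels and counts for a packaged baseline table."""
    try:
        rows, cols, counts = _TABLES[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown table {name!r}; available: {sorted(_TABLES)}"
        ) from None
    return rows, cols, np.asarray(counts, dtype=int)


def fixture_generator(name: str, outdir) -> Path:
    """Write a named fixture to ``outdir`` and return the file/directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if name in _TABLES:
        rows, cols, counts = contingency_table(name)
        path = out / f"{name}.csv"
        pd.DataFrame(counts, index=list(rows), columns=list(cols)).to_csv(
            path, index_label="arm"
        )
        return path
    if name == "seed-catalog":
        from .catalog import seed_catalog
        from .prompts import save_catalog

        path = out / "seed_catalog.csv"
        save_catalog(seed_catalog(), path)
        return path
    if name == "demo-cohort":
        from .cohort import CohortConfig, simulate_trial

        data = simulate_trial(CohortConfig(n_per_arm=3, dropout_rate=0.0), seed=42)
        path = out / "demo_cohort"
        data.export(path)
        return path
    raise UnknownFixtureError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")
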