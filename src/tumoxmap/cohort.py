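"""Cohort bookkeeping: the per-patient characteristics table.

Ships the published per-patient table (age, sex, diagnosis, number of
biopsy samples per VOI) as package data and recomputes its aggregates —
sample counts per compartment and mean ages per diagnostic group —
rather than hard-coding them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort", "summarize_cohort"]


def load_cohort() -> pd.DataFrame:
    """Load the bundled per-patient characteristics table."""
    with resources.files("tumoxmap.data").joinpath("cohort.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_cohort(table: pd.DataFrame | None = None) -> dict:
    """Aggregate the cohort table.

    Returns biopsy-sample counts per VOI and in total, patient counts
    and mean ages per diagnostic group.
    """
    t = load_cohort() if table is None else table
    counts = {
        "necrosis": int(t["n_necrosis"].sum()),
        "enhancing": int(t["n_enhancing"].sum()),
        "nonenhancing": int(t["n_nonenhancing"].sum()),
    }
    counts["total"] = sum(counts.values())
    ages = t.groupby("group")["age"].mean().to_dict()
    n_patients = t.groupby("group")["patient"].count().to_dict()
    return {
        "sample_counts": counts,
        "mean_age": {k: float(v) for k, v in ages.items()},
        "n_patients": {k: int(v) for k, v in n_patients.items()},
    }
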