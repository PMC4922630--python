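"""Net transition counts: probabilities scaled to census population sizes.

``net persons transitioning = net transition probability x origin-category
prevalence x population count at that age``, mirroring how the estimated
probabilities are converted into numbers of people crossing a weight
boundary per year in a reference population (e.g. the 2010 civilian
noninstitutionalized population, supplied as a CSV of single-year-of-age
counts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prevalence import PrevalenceCurve

#: origin-category column in the prevalence surface per (boundary, direction)
ORIGIN = {
    ("normal_overweight", "up"): 0,
    ("normal_overweight", "down"): 1,
    ("overweight_obese", "up"): 1,
    ("overweight_obese", "down"): 2,
}

POP_COLUMNS = ["sex", "group", "age", "count"]


def validate_population(pop: pd.DataFrame) -> pd.DataFrame:
    missing = set(POP_COLUMNS) - set(pop.columns)
    if missing:
        raise ValueError(f"population counts missing columns: {sorted(missing)}")
    if (pop["count"] < 0).any():
        raise ValueError("population counts must be nonnegative")
    if pop.duplicated(["sex", "group", "age"]).any():
        raise ValueError("population counts must have one row per (sex, group, age)")
    return pop


def extrapolate_counts(
    table: pd.DataFrame,
    curve: PrevalenceCurve,
    pop: pd.DataFrame,
    sex: str | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Net numbers of persons transitioning per (age, boundary, direction).

    ``table`` is a net transition table for one stratum, ``curve`` the
    matching prevalence surface and ``pop`` single-year-of-age population
    counts (optionally filtered by ``sex``/``group``).  Adds
    ``net_count_raw`` (exact product) and ``net_count`` (rounded persons).
    """
    validate_population(pop)
    sub = pop
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    if group is not None:
        sub = sub[sub["group"] == group]
    counts = sub.set_index("age")["count"]

    ages_needed = sorted(table["age"].unique())
    gaps = [int(a) for a in ages_needed if a not in counts.index]
    if gaps:
        raise ValueError(f"population counts missing for ages: {gaps}")

    out = table.copy()
    age0 = int(curve.ages[0])
    prev = np.array(
        [curve.P[int(r.age) - age0, ORIGIN[(r.boundary, r.direction)]] for r in table.itertuples()]
    )
    popc = table["age"].map(counts).to_numpy(float)
    out["origin_prevalence"] = prev
    out["population"] = popc
    out["net_count_raw"] = out["net_prob"].to_numpy() * prev * popc
    out["net_count"] = np.rint(out["net_count_raw"]).astype(np.int64)
    return out
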