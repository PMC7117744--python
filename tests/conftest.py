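import numpy as np
import pandas as pd
import pytest

from habrep import BehaviorTable, ResamplingSettings, generate_paperlike

COLUMNS = ["animal_id", "strain", "experiment", "day", "measure", "value"]


def make_table(rows) -> BehaviorTable:
    """rows: iterable of (animal_id, strain, experiment, day, measure, value)."""
    return BehaviorTable(pd.DataFrame(list(rows), columns=COLUMNS))


def one_way_table(group_values, measure="m") -> BehaviorTable:
    """Balanced/unbalanced one-way layout: one group per animal, one row per day."""
    rows = []
    for g, values in enumerate(group_values):
        for d, v in enumerate(values, start=1):
            rows.append((f"g{g}", "s0", "e0", d, measure, float(v)))
    return make_table(rows)


def random_one_way(rng, n_groups, n_reps, sd_group, sd_resid, mean=0.0) -> BehaviorTable:
    effects = rng.normal(0.0, sd_group, size=n_groups)
    return one_way_table([
        mean + effects[g] + rng.normal(0.0, sd_resid, size=n_reps)
        for g in range(n_groups)
    ])


@pytest.fixture(scope="session")
def study_table():
    """One study-sized synthetic draw (68 animals, 7 days, two measures)."""
    table, truths = generate_paperlike(seed=1)
    return table, truths


@pytest.fixture()
def fast_settings():
    return ResamplingSettings(n_boot=50, n_permut=10, seed=7)
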