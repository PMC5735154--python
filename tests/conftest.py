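"""Shared fixtures: tiny constructed datasets and a reduced synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from intransit.choice_data import ChoiceDataset
from intransit.synthetic import CohortSpec, generate_cohort


def make_dataset(rows: list[tuple], n_items: int) -> ChoiceDataset:
    """Build a dataset from (subject, group, task, trial, a, b, choice, rt) rows."""
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "task", "trial_index",
            "item_a", "item_b", "choice", "rt",
        ],
    )
    return ChoiceDataset(trials=df, n_items=n_items)


def complete_subject_rows(
    subject: str,
    group: str,
    task: str,
    ranking: list[int],
    rng: np.random.Generator | None = None,
) -> list[tuple]:
    """One pair-complete session whose choices follow a strict ranking."""
    n = len(ranking)
    rank_of = {item: pos for pos, item in enumerate(ranking)}
    pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
    order = list(range(len(pairs)))
    if rng is not None:
        order = list(rng.permutation(len(pairs)))
    rows = []
    for trial, k in enumerate(order, start=1):
        a, b = pairs[k]
        choice = a if rank_of[a] < rank_of[b] else b
        rows.append((subject, group, task, trial, a, b, float(choice), 1.0))
    return rows


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A size-reduced cohort sharing every behavioral default."""
    return CohortSpec(n_con=4, n_etl=4, n_mtl=6, n_lesion=4)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, seed=1234)
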