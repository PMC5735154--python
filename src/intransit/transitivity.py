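"""Intransitivity statistics over exhaustive binary choices.

A subject who chooses between every unordered pair of ``n`` items defines a
tournament: a complete directed graph with one edge per pair, oriented toward
the chosen item.  A triple of items is *intransitive* when its three choices
form a directed 3-cycle (A beat B, B beat C, yet C beat A).  The proportion
of intransitive triples over all C(n, 3) triples is the choice-consistency
statistic this package is built around: under independent fair-coin choices
exactly 2 of the 8 equally likely orientation patterns of a triple are cyclic,
so the expected proportion is 0.25.

The realized proportion of a single tournament can exceed 0.25: the maximum
number of cyclic triples of an n-item tournament is (n^3 - n)/24 for odd n and
(n^3 - 4n)/24 for even n (330 of 1140, ~28.9%, for n = 20).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .choice_data import ChoiceDataset

__all__ = [
    "TripletRecord",
    "SubjectScore",
    "enumerate_pairs",
    "enumerate_triplets",
    "classify_triplet",
    "max_cyclic_triples",
    "count_cycles_from_wins",
    "score_subject",
    "score_dataset",
    "triplet_table",
    "item_involvement",
    "trial_involvement",
]


@dataclass(frozen=True)
class TripletRecord:
    """One unordered item triple and the orientation of its three choices.

    ``orientations`` holds the winners of (i, j), (j, k) and (i, k) for the
    canonically sorted triple i < j < k.  ``trial_indices`` are the positions
    (within the subject's session) of the three constituent trials, in the
    same pair order.
    """

    items: tuple[int, int, int]
    orientations: tuple[int, int, int]
    is_intransitive: bool
    trial_indices: tuple[int, int, int]
    last_trial_index: int
    trial_index_variance: float


@dataclass(frozen=True)
class SubjectScore:
    subject_id: str
    group: str
    task: str
    n_triplets: int
    n_intransitive: int
    pct_intransitive: float
    n_excluded: int = 0


def enumerate_pairs(n_items: int) -> list[tuple[int, int]]:
    """All unordered pairs of items 1..n_items, canonicalized as (min, max)."""
    if n_items < 2:
        raise ValueError(f"need at least 2 items, got {n_items}")
    return list(itertools.combinations(range(1, n_items + 1), 2))


def enumerate_triplets(n_items: int) -> list[tuple[int, int, int]]:
    """All unordered triples of items 1..n_items, sorted ascending."""
    if n_items < 3:
        raise ValueError(f"need at least 3 items, got {n_items}")
    return list(itertools.combinations(range(1, n_items + 1), 3))


def classify_triplet(
    items: tuple[int, int, int],
    winners: tuple[int, int, int],
) -> str:
    """Classify one triple's three pairwise choices as transitive or not.

    Parameters
    ----------
    items
        The triple (i, j, k); order defines which pair each winner refers to.
    winners
        Winners of (i, j), (j, k) and (i, k) respectively.

    Returns
    -------
    ``"intransitive"`` if the three choices form a directed 3-cycle (in
    either direction), else ``"transitive"``.  Equivalently, the triple is
    intransitive iff no item wins both of its comparisons.
    """
    i, j, k = items
    pairs = ((i, j), (j, k), (i, k))
    wins: dict[int, int] = {i: 0, j: 0, k: 0}
    for pair, w in zip(pairs, winners):
        if w not in pair:
            raise ValueError(f"winner {w} is not a member of pair {pair}")
        wins[w] += 1
    return "intransitive" if max(wins.values()) == 1 else "transitive"


def max_cyclic_triples(n_items: int) -> int:
    """Maximum attainable number of cyclic triples in an n-item tournament."""
    n = n_items
    return (n**3 - n) // 24 if n % 2 == 1 else (n**3 - 4 * n) // 24


@lru_cache(maxsize=8)
def _triple_index_arrays(n_items: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0-based (i, j, k) index arrays over all C(n, 3) sorted triples."""
    trip = np.array(list(itertools.combinations(range(n_items), 3)), dtype=np.intp)
    return trip[:, 0], trip[:, 1], trip[:, 2]


def _cycle_mask(beats: np.ndarray) -> np.ndarray:
    """Boolean per-triple cycle mask from a 0-based win matrix.

    ``beats[a, b]`` is True iff item a was chosen over item b.  For a sorted
    triple (i, j, k) with a = i beats j, b = j beats k, c = i beats k, the
    orientations are cyclic iff (a & b & ~c) | (~a & ~b & c).
    """
    n = beats.shape[0]
    i, j, k = _triple_index_arrays(n)
    a = beats[i, j]
    b = beats[j, k]
    c = beats[i, k]
    return (a & b & ~c) | (~a & ~b & c)


def count_cycles_from_wins(win_first: np.ndarray, n_items: int) -> int:
    """Count cyclic triples from per-pair outcomes, in O(n_pairs).

    ``win_first[p]`` is True iff the first (smaller) item of canonical pair
    ``p`` (in :func:`enumerate_pairs` order) was chosen.  Uses the tournament
    identity: #cyclic = C(n, 3) − Σ_i C(d_i, 2) with d_i the out-degrees.
    """
    pairs = np.array(enumerate_pairs(n_items), dtype=np.intp) - 1
    winners = np.where(win_first, pairs[:, 0], pairs[:, 1])
    deg = np.bincount(winners, minlength=n_items)
    n = n_items
    total = n * (n - 1) * (n - 2) // 6
    return int(total - (deg * (deg - 1) // 2).sum())


def _subject_matrices(
    sub: pd.DataFrame, n_items: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build win/observed/trial-index matrices from one subject×task table.

    Trials with a missing choice are treated as unobserved pairs.  Returns
    0-based square arrays ``(beats, observed, tidx)``.
    """
    beats = np.zeros((n_items, n_items), dtype=bool)
    observed = np.zeros((n_items, n_items), dtype=bool)
    tidx = np.zeros((n_items, n_items), dtype=np.int64)

    ia = sub["item_a"].to_numpy(dtype=np.int64) - 1
    ib = sub["item_b"].to_numpy(dtype=np.int64) - 1
    choice = sub["choice"].to_numpy(dtype=float)
    trial = sub["trial_index"].to_numpy(dtype=np.int64)

    ok = ~np.isnan(choice)
    ia, ib, trial = ia[ok], ib[ok], trial[ok]
    ch = choice[ok].astype(np.int64) - 1

    lo = np.minimum(ia, ib)
    hi = np.maximum(ia, ib)
    observed[lo, hi] = True
    tidx[lo, hi] = trial
    first_wins = ch == lo
    beats[lo[first_wins], hi[first_wins]] = True
    return beats, observed, tidx


def triplet_table(ds: ChoiceDataset) -> pd.DataFrame:
    """Vectorized triple-level features for every subject×task.

    One row per fully observed triple with columns ``subject_id, group, task,
    item_i, item_j, item_k, is_intransitive, t_ij, t_jk, t_ik,
    last_trial_index, trial_index_variance``.  Triples with any missing
    constituent choice are dropped (their count is recoverable by comparison
    with C(n_items, 3)).
    """
    n = ds.n_items
    i, j, k = _triple_index_arrays(n)
    frames = []
    for (subject_id, task), sub in ds.trials.groupby(["subject_id", "task"], sort=True):
        beats, observed, tidx = _subject_matrices(sub, n)
        full = observed[i, j] & observed[j, k] & observed[i, k]
        cyc = _cycle_mask(beats)[full]
        t3 = np.column_stack([tidx[i, j][full], tidx[j, k][full], tidx[i, k][full]])
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "group": sub["group"].iloc[0],
                    "task": task,
                    "item_i": i[full] + 1,
                    "item_j": j[full] + 1,
                    "item_k": k[full] + 1,
                    "is_intransitive": cyc,
                    "t_ij": t3[:, 0],
                    "t_jk": t3[:, 1],
                    "t_ik": t3[:, 2],
                    "last_trial_index": t3.max(axis=1),
                    "trial_index_variance": t3.var(axis=1, ddof=1),
                }
            )
        )
    if not frames:
        raise ValueError("dataset has no trials")
    return pd.concat(frames, ignore_index=True)


def score_subject(
    ds: ChoiceDataset, subject_id: str, task: str
) -> tuple[SubjectScore, list[TripletRecord]]:
    """Score one subject×task: intransitivity proportion plus triple records.

    The proportion is the number of intransitive triples divided by the number
    of fully observed triples, on a 0-100 scale.  Triples touched by a missing
    choice are excluded from numerator and denominator; their count is
    reported as ``n_excluded``.
    """
    mask = (ds.trials["subject_id"] == subject_id) & (ds.trials["task"] == task)
    sub = ds.trials[mask]
    if sub.empty:
        raise KeyError(f"no trials for subject {subject_id!r}, task {task!r}")
    n = ds.n_items
    beats, observed, tidx = _subject_matrices(sub, n)
    i, j, k = _triple_index_arrays(n)
    full = observed[i, j] & observed[j, k] & observed[i, k]
    cyc = _cycle_mask(beats)

    records: list[TripletRecord] = []
    for ii, jj, kk, ok, is_cyc in zip(i, j, k, full, cyc):
        if not ok:
            continue
        w_ij = ii if beats[ii, jj] else jj
        w_jk = jj if beats[jj, kk] else kk
        w_ik = ii if beats[ii, kk] else kk
        t3 = (int(tidx[ii, jj]), int(tidx[jj, kk]), int(tidx[ii, kk]))
        records.append(
            TripletRecord(
                items=(int(ii) + 1, int(jj) + 1, int(kk) + 1),
                orientations=(int(w_ij) + 1, int(w_jk) + 1, int(w_ik) + 1),
                is_intransitive=bool(is_cyc),
                trial_indices=t3,
                last_trial_index=max(t3),
                trial_index_variance=float(np.var(t3, ddof=1)),
            )
        )
    n_triplets = int(full.sum())
    n_intr = int((cyc & full).sum())
    score = SubjectScore(
        subject_id=subject_id,
        group=str(sub["group"].iloc[0]),
        task=task,
        n_triplets=n_triplets,
        n_intransitive=n_intr,
        pct_intransitive=100.0 * n_intr / n_triplets if n_triplets else float("nan"),
        n_excluded=len(full) - n_triplets,
    )
    return score, records


def score_dataset(ds: ChoiceDataset) -> pd.DataFrame:
    """Subject-level score table for every subject×task in the dataset."""
    n = ds.n_items
    i, j, k = _triple_index_arrays(n)
    rows = []
    for (subject_id, task), sub in ds.trials.groupby(["subject_id", "task"], sort=True):
        beats, observed, _ = _subject_matrices(sub, n)
        full = observed[i, j] & observed[j, k] & observed[i, k]
        cyc = _cycle_mask(beats)
        n_triplets = int(full.sum())
        n_intr = int((cyc & full).sum())
        rows.append(
            {
                "subject_id": subject_id,
                "group": sub["group"].iloc[0],
                "task": task,
                "n_triplets": n_triplets,
                "n_intransitive": n_intr,
                "pct_intransitive": 100.0 * n_intr / n_triplets
                if n_triplets
                else float("nan"),
                "n_excluded": int(len(full) - n_triplets),
            }
        )
    return pd.DataFrame(rows)


def dataset_involvement(
    ds: ChoiceDataset, triplets: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Annotate every trial in a dataset with intransitive-triple membership.

    Returns a copy of ``ds.trials`` with ``n_intransitive_triplets`` and
    ``involved`` columns, computed per subject×task.  Pass a precomputed
    :func:`triplet_table` to avoid rescoring.
    """
    trips = triplet_table(ds) if triplets is None else triplets
    cyc = trips[trips["is_intransitive"]]
    counts: dict[tuple[str, str, int], int] = {}
    for col in ("t_ij", "t_jk", "t_ik"):
        for key in zip(cyc["subject_id"], cyc["task"], cyc[col].astype(int)):
            counts[key] = counts.get(key, 0) + 1
    out = ds.trials.copy()
    keys = list(zip(out["subject_id"], out["task"], out["trial_index"].astype(int)))
    out["n_intransitive_triplets"] = np.fromiter(
        (counts.get(k, 0) for k in keys), dtype=np.int64, count=len(keys)
    )
    out["involved"] = out["n_intransitive_triplets"] > 0
    return out


def item_involvement(
    triplets: Sequence[TripletRecord] | pd.DataFrame, n_items: int
) -> np.ndarray:
    """Per-item count of intransitive triples containing that item.

    Counts sum to 3 × n_intransitive, since each cycle touches 3 items.
    """
    counts = np.zeros(n_items, dtype=np.int64)
    if isinstance(triplets, pd.DataFrame):
        cyc = triplets[triplets["is_intransitive"]]
        for col in ("item_i", "item_j", "item_k"):
            counts += np.bincount(
                cyc[col].to_numpy(dtype=np.intp) - 1, minlength=n_items
            )
        return counts
    for rec in triplets:
        if rec.is_intransitive:
            for item in rec.items:
                counts[item - 1] += 1
    return counts


def trial_involvement(
    triplets: Sequence[TripletRecord] | pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Annotate trials with their membership in intransitive triples.

    Returns a copy of ``trials`` with ``n_intransitive_triplets`` (count of
    cyclic triples the trial's pair participates in) and ``involved`` (binary
    flag).  A fully transitive subject gets all-zero annotations.
    """
    out = trials.copy()
    counter: dict[int, int] = {}
    if isinstance(triplets, pd.DataFrame):
        cyc = triplets[triplets["is_intransitive"]]
        for col in ("t_ij", "t_jk", "t_ik"):
            for t in cyc[col].to_numpy():
                counter[int(t)] = counter.get(int(t), 0) + 1
    else:
        for rec in triplets:
            if rec.is_intransitive:
                for t in rec.trial_indices:
                    counter[int(t)] = counter.get(int(t), 0) + 1
    out["n_intransitive_triplets"] = (
        out["trial_index"].map(counter).fillna(0).astype(np.int64)
    )
    out["involved"] = out["n_intransitive_triplets"] > 0
    return out
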