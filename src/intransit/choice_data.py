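"""Data model and I/O for two-alternative forced-choice experiments.

The central container is :class:`ChoiceDataset`: a long-format table of
binary choice trials (one row per presented pair) plus the item universe.
The complete-pairwise design presents every unordered pair of ``n_items``
exactly once per subject and task — n·(n−1)/2 trials (190 for 20 items) —
and :func:`validate_design` checks a dataset against that design, reporting
missing pairs, duplicated pairs and irregular trials as data, not exceptions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "TASKS",
    "Dialect",
    "Trial",
    "ChoiceDataset",
    "ValidationReport",
    "ChoiceTableFormatError",
    "read_choice_table",
    "write_choice_table",
    "validate_design",
]

GROUPS = ("CON", "ETL", "MTL")
TASKS = ("preference", "number")

REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "task",
    "trial_index",
    "item_a",
    "item_b",
    "choice",
    "rt",
)

_MISSING_MARKERS = {"", "NA", "N/A", "NaN", "nan", "None"}


class ChoiceTableFormatError(ValueError):
    """A choice table violates the expected file format."""


@dataclass(frozen=True)
class Dialect:
    """Delimiter / column-name / unit configuration for choice tables.

    ``columns`` maps canonical names (see ``REQUIRED_COLUMNS``) to the names
    used in the file.  ``rt_unit`` declares the response-time unit in the
    file; times are always seconds in memory.
    """

    delimiter: str = ","
    columns: dict[str, str] = field(default_factory=dict)
    rt_unit: str = "s"  # "s" or "ms"

    def __post_init__(self) -> None:
        if self.rt_unit not in ("s", "ms"):
            raise ValueError(f"rt_unit must be 's' or 'ms', got {self.rt_unit!r}")

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass(frozen=True)
class Trial:
    """One binary forced-choice trial."""

    subject_id: str
    group: str
    task: str
    trial_index: int
    item_a: int
    item_b: int
    choice: int | None  # None marks a missing response
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise ValueError(f"item_a == item_b == {self.item_a}")
        if self.choice is not None and self.choice not in (self.item_a, self.item_b):
            raise ValueError(
                f"choice {self.choice} not in pair ({self.item_a}, {self.item_b})"
            )
        if self.rt is not None and not np.isnan(self.rt) and self.rt < 0:
            raise ValueError(f"negative response time {self.rt}")


@dataclass
class ChoiceDataset:
    """Long table of binary forced-choice trials plus the item universe.

    ``trials`` columns: subject_id, group, task, trial_index, item_a, item_b,
    choice (float; NaN marks a missing response), rt (seconds, NaN allowed).
    Item codes are 1..n_items; ``item_labels`` optionally maps codes to
    display names.
    """

    trials: pd.DataFrame
    n_items: int
    item_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ChoiceTableFormatError(f"missing required columns: {missing}")
        self.trials = self.trials.astype(
            {
                "subject_id": str,
                "group": str,
                "task": str,
                "trial_index": np.int64,
                "item_a": np.int64,
                "item_b": np.int64,
                "choice": float,
                "rt": float,
            }
        )[list(REQUIRED_COLUMNS)]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.trials["subject_id"].unique())

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def equals(self, other: "ChoiceDataset") -> bool:
        """Field-level equality on sorted trials (the round-trip contract)."""
        if self.n_items != other.n_items:
            return False
        key = ["subject_id", "task", "trial_index"]
        a = self.trials.sort_values(key).reset_index(drop=True)
        b = other.trials.sort_values(key).reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class ValidationReport:
    """Design-completeness report; defects are data, not exceptions."""

    missing_pairs: list[tuple[str, str, tuple[int, int]]]
    duplicate_pairs: list[tuple[str, str, tuple[int, int]]]
    irregular_trials: list[str]

    @property
    def is_complete(self) -> bool:
        return not (self.missing_pairs or self.duplicate_pairs or self.irregular_trials)


def _parse_rows(raw: pd.DataFrame, dialect: Dialect, path: str) -> pd.DataFrame:
    """Coerce string columns to the canonical schema, reporting bad rows."""
    errors: list[str] = []
    n = len(raw)
    out = pd.DataFrame(index=raw.index)
    out["subject_id"] = raw["subject_id"].astype(str).str.strip()
    out["group"] = raw["group"].astype(str).str.strip()
    out["task"] = raw["task"].astype(str).str.strip()

    def _to_num(col: str, required: bool) -> np.ndarray:
        vals = np.full(n, np.nan)
        for pos, v in enumerate(raw[col].astype(str).str.strip()):
            if v in _MISSING_MARKERS:
                if required:
                    errors.append(f"line {raw.index[pos] + 2}: missing value in {col!r}")
                continue
            try:
                vals[pos] = float(v)
            except ValueError:
                errors.append(f"line {raw.index[pos] + 2}: unparseable {col}={v!r}")
        return vals

    out["trial_index"] = _to_num("trial_index", required=True)
    out["item_a"] = _to_num("item_a", required=True)
    out["item_b"] = _to_num("item_b", required=True)
    out["choice"] = _to_num("choice", required=False)  # NaN = missing response
    out["rt"] = _to_num("rt", required=False)
    if dialect.rt_unit == "ms":
        out["rt"] /= 1000.0

    bad = (out["item_a"] == out["item_b"]).to_numpy()
    for pos in np.flatnonzero(bad):
        errors.append(f"line {raw.index[pos] + 2}: item_a == item_b")
    if errors:
        raise ChoiceTableFormatError(
            f"{path}: {len(errors)} malformed row(s):\n  " + "\n  ".join(errors[:20])
        )
    for col in ("trial_index", "item_a", "item_b"):
        out[col] = out[col].astype(np.int64)
    return out


def read_choice_table(
    path: str | Path, dialect: Dialect | None = None
) -> ChoiceDataset:
    """Read a delimited choice table into a :class:`ChoiceDataset`.

    Item codes are normalized to 1..n_items (original codes preserved in
    ``item_labels`` when remapping occurs).  Malformed rows raise
    :class:`ChoiceTableFormatError` naming the offending lines — they are
    never silently dropped.  Lines starting with ``#`` are provenance
    comments and are ignored.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    raw = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, comment="#", keep_default_na=False
    )
    rename = {dialect.file_column(c): c for c in REQUIRED_COLUMNS}
    missing = [dialect.file_column(c) for c in REQUIRED_COLUMNS
               if dialect.file_column(c) not in raw.columns]
    if missing:
        raise ChoiceTableFormatError(
            f"{path}: missing required column(s): {missing}"
        )
    raw = raw.rename(columns=rename)
    trials = _parse_rows(raw, dialect, str(path))

    codes = np.unique(
        np.concatenate([trials["item_a"].to_numpy(), trials["item_b"].to_numpy()])
    )
    n_items = len(codes)
    item_labels = None
    if not np.array_equal(codes, np.arange(1, n_items + 1)):
        remap = {int(c): i + 1 for i, c in enumerate(codes)}
        item_labels = {v: str(k) for k, v in remap.items()}
        for col in ("item_a", "item_b"):
            trials[col] = trials[col].map(remap).astype(np.int64)
        trials["choice"] = trials["choice"].map(
            lambda v: np.nan if np.isnan(v) else float(remap[int(v)])
        )
    return ChoiceDataset(trials=trials, n_items=n_items, item_labels=item_labels)


def write_choice_table(
    ds: ChoiceDataset, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a dataset as delimited text, deterministically ordered.

    Rows are sorted by (subject_id, task, trial_index); columns follow the
    canonical order, so :func:`read_choice_table` inverts this exactly.
    Optional ``header_lines`` are written as ``#``-prefixed comments.
    """
    path = Path(path)
    out = ds.trials.sort_values(["subject_id", "task", "trial_index"]).reset_index(
        drop=True
    )
    # integers render without trailing .0; NaN renders empty
    for col in ("choice",):
        out[col] = out[col].map(lambda v: "" if np.isnan(v) else str(int(v)))
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)


def validate_design(ds: ChoiceDataset) -> ValidationReport:
    """Check every subject×task against the complete-pairwise design.

    Reports, per subject×task: unordered pairs never presented, pairs
    presented more than once, and irregular trials (missing responses,
    trial indices that are not a permutation of 1..n_trials).
    """
    if ds.trials.empty:
        raise ValueError("dataset has no trials")
    expected = set(itertools.combinations(range(1, ds.n_items + 1), 2))
    missing: list[tuple[str, str, tuple[int, int]]] = []
    duplicates: list[tuple[str, str, tuple[int, int]]] = []
    irregular: list[str] = []
    for (subject_id, task), sub in ds.trials.groupby(["subject_id", "task"], sort=True):
        lo = np.minimum(sub["item_a"], sub["item_b"])
        hi = np.maximum(sub["item_a"], sub["item_b"])
        seen = list(zip(lo.tolist(), hi.tolist()))
        seen_set = set(seen)
        for pair in sorted(expected - seen_set):
            missing.append((subject_id, task, pair))
        counts: dict[tuple[int, int], int] = {}
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
        for pair, c in sorted(counts.items()):
            if c > 1:
                duplicates.append((subject_id, task, pair))
        n_missing_choice = int(sub["choice"].isna().sum())
        if n_missing_choice:
            irregular.append(
                f"{subject_id}/{task}: {n_missing_choice} trial(s) with missing choice"
            )
        tix = np.sort(sub["trial_index"].to_numpy())
        if not np.array_equal(tix, np.arange(1, len(sub) + 1)):
            irregular.append(
                f"{subject_id}/{task}: trial_index not a permutation of 1..{len(sub)}"
            )
        valid_choice = sub["choice"].isna() | (
            (sub["choice"] == sub["item_a"]) | (sub["choice"] == sub["item_b"])
        )
        if not valid_choice.all():
            irregular.append(
                f"{subject_id}/{task}: {int((~valid_choice).sum())} choice(s) outside pair"
            )
    return ValidationReport(
        missing_pairs=missing, duplicate_pairs=duplicates, irregular_trials=irregular
    )
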