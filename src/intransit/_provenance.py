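"""Provenance headers for output files: version, seed, config hash."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(seed: int | None, cfg_hash: str | None = None,
                 extra: Mapping[str, Any] | None = None) -> list[str]:
    from . import __version__

    lines = [f"intransit {__version__}"]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if cfg_hash:
        lines.append(f"config: {cfg_hash}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}: {v}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    extra: Mapping[str, Any] | None = None,
) -> None:
    """Write a CSV with ``#``-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed, cfg_hash, extra):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips ``#`` comments)."""
    return pd.read_csv(path, comment="#")
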