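"""Validated readers for the pipeline's CSV inputs.

CSV dialect: comma-separated, UTF-8, mandatory header row, ``.`` decimal
mark.  Validation failures name the file and the 1-based line number(s)
involved (the header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ParseError", "read_collections", "read_observations"]

_VALID_ORDERS = {"Coleoptera", "Diptera", "Hymenoptera", "Lepidoptera"}


class ParseError(ValueError):
    """An input file failed validation; the message names file and line."""


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _lines(idx) -> list[int]:
    # DataFrame row i came from file line i+2 (header is line 1).
    return [int(i) + 2 for i in idx]


def read_collections(path: str | Path) -> pd.DataFrame:
    """Read and validate a collections table.

    Required columns: ``collection_id, x, y``; ``date`` and ``observer_id``
    are carried through when present.  Duplicate ids and non-finite
    coordinates are rejected with line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"collection_id": str})
    _require_columns(df, ["collection_id", "x", "y"], path)
    dupes = df["collection_id"].duplicated(keep=False)
    if dupes.any():
        which = df.loc[dupes, "collection_id"].iloc[0]
        lines = _lines(df.index[df["collection_id"] == which])
        raise ParseError(
            f"{path}: duplicate collection id {which!r} at lines {lines}"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            raise ParseError(
                f"{path}: non-finite value in column {col!r} at line(s) "
                f"{_lines(df.index[bad])[:5]}"
            )
        df[col] = vals.astype(float)
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observations table.

    Required columns: ``collection_id, taxon_id, taxon_order``; optional
    ``picture_count`` defaults to 1.  Unknown insect orders are rejected
    with line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"collection_id": str, "taxon_id": str})
    _require_columns(df, ["collection_id", "taxon_id", "taxon_order"], path)
    bad = ~df["taxon_order"].isin(_VALID_ORDERS)
    if bad.any():
        raise ParseError(
            f"{path}: unknown taxon order(s) "
            f"{sorted(set(df.loc[bad, 'taxon_order']))} at line(s) "
            f"{_lines(df.index[bad])[:5]}; expected one of {sorted(_VALID_ORDERS)}"
        )
    if "picture_count" not in df.columns:
        df["picture_count"] = 1
    return df
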