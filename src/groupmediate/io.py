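"""Reading and validating delimited datasets."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MediationDataset
from .errors import DataError

__all__ = ["load_dataset"]

log = logging.getLogger("groupmediate")


def load_dataset(
    path: str | Path, mapping: dict[str, str] | None = None
) -> MediationDataset:
    """Load a CSV/TSV file with a header row into a :class:`MediationDataset`.

    ``mapping`` maps the roles ``x``, ``m``, ``y``, ``group`` to column names
    (defaults to those very names). Rows with missing values in any mapped
    column are rejected listwise with a logged count; a non-numeric entry in
    a numeric column is an error naming the row. Exactly two group levels
    must remain after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    mapping = {**{"x": "x", "m": "m", "y": "y", "group": "group"}, **(mapping or {})}
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    missing_cols = [c for c in ("x", "m", "y", "group") if mapping[c] not in df.columns]
    if missing_cols:
        raise DataError(
            f"missing column(s) {[mapping[c] for c in missing_cols]} in {path.name}; "
            f"available: {list(df.columns)}"
        )
    sub = df[[mapping["x"], mapping["m"], mapping["y"], mapping["group"]]].copy()
    sub.columns = ["x", "m", "y", "group"]
    for col in ("x", "m", "y"):
        raw = sub[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any():
            i = int(bad.idxmax())
            raise DataError(
                f"non-numeric value {raw[i]!r} in column {mapping[col]!r} at row {i}"
            )
        sub[col] = coerced
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%d row(s) with missing values dropped from %s", n_dropped, path.name)
    sub = sub[keep]
    if len(sub) == 0:
        raise DataError(f"no complete rows in {path.name}")
    levels = sorted(set(str(g) for g in sub["group"]))
    if len(levels) != 2:
        raise DataError(
            f"group column {mapping['group']!r} must have exactly 2 levels, "
            f"found {len(levels)}: {levels}"
        )
    return MediationDataset(
        x=sub["x"].to_numpy(float),
        m=sub["m"].to_numpy(float),
        y=sub["y"].to_numpy(float),
        group=np.asarray([str(g) for g in sub["group"]], dtype=object),
        n_dropped=n_dropped,
    )
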