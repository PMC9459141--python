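"""Feature-table CSV round-tripping with schema validation.

Layout: header row of feature names, one row per patient, final columns
``label`` (0 benign / 1 malignant) and optionally ``reader_jr`` /
``reader_sr`` verdict columns. Floats are written at 17 significant
digits so write-then-read is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import parse_key

RESERVED_COLS = ("label", "reader_jr", "reader_sr", "case_id")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV (17 significant digits)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path, require_label: bool = True,
                       validate_catalog: bool = False) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Raises on duplicate feature names, non-numeric cells (named by row and
    column) and, when required, a missing ``label`` column. With
    ``validate_catalog=True`` every non-reserved column name must resolve
    to a catalogued descriptor.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    dupes = raw.columns[raw.columns.duplicated()].tolist()
    # pandas mangles duplicates to name.1; detect them from the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    seen, header_dupes = set(), []
    for h in header:
        if h in seen:
            header_dupes.append(h)
        seen.add(h)
    if header_dupes or dupes:
        raise ValueError(f"duplicate column header(s): {sorted(set(header_dupes + dupes))}")
    if require_label and "label" not in raw.columns:
        raise ValueError("feature table has no 'label' column")
    out = {}
    for col in raw.columns:
        try:
            out[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()
                            & raw[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {row}"
            ) from None
    table = pd.DataFrame(out)
    for col in ("label", "reader_jr", "reader_sr"):
        if col in table.columns:
            vals = table[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"column {col!r} must be binary 0/1")
            table[col] = table[col].astype(int)
    if validate_catalog:
        for col in table.columns:
            if col in RESERVED_COLS:
                continue
            parse_key(col)  # raises for unknown descriptors
    return table
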