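"""Dataset CSV input/output.

The on-disk format is a plain UTF-8 CSV with a header row: an outcome
column named ``y`` and feature columns (conventionally ``X1``..``Xp``),
every cell literally 0 or 1, no index column.  Feature coding is
strictly {0,1} at this boundary — no automatic recoding of factors.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .models import BinaryDataset

__all__ = ["read_dataset", "write_dataset"]


def read_dataset(path: str | Path) -> BinaryDataset:
    """Read and validate a dataset CSV; column order is preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, no header or subjects") from None
    if "y" not in df.columns:
        raise ValueError(f'{path}: missing required outcome column "y"')
    if len(df) == 0:
        raise ValueError(f"{path}: header only, no subjects")
    for col in df.columns:
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-binary value {vals.iloc[row]!r} in column {col!r}, "
                f"row {row} (all cells must be 0 or 1)"
            )
    return BinaryDataset.from_frame(df)


def write_dataset(data: BinaryDataset, path: str | Path) -> Path:
    """Write a dataset as CSV (header, 0/1 cells, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.to_frame().to_csv(path, index=False)
    return path
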