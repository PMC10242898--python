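"""Wide-table dialect, data dictionary and run manifests.

One row per extended family unit.  Structure descriptors come first, then
the eight adult indicator slots, the four child outcome slots, and the
child covariates.  Missing cells are written as ``NA``.  A child that does
not exist (beyond ``n_childrenJ``) has outcome and covariates ``NA``; a
child whose outcome was simply not returned keeps its covariates.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ADULT_SLOT_LABELS, CHILD_SLOT_LABELS

__all__ = [
    "STRUCTURE_COLUMNS",
    "COVARIATE_COLUMNS",
    "TABLE_COLUMNS",
    "write_table",
    "read_table",
    "write_data_dictionary",
    "write_manifest",
]

_CHILD_TAGS = ("c11", "c12", "c21", "c22")

STRUCTURE_COLUMNS = (
    "family_id", "sibling_link", "role1", "role2", "n_children1", "n_children2",
)
COVARIATE_COLUMNS = tuple(f"{c}_sex" for c in _CHILD_TAGS) + tuple(
    f"{c}_parity" for c in _CHILD_TAGS
)
TABLE_COLUMNS = (
    STRUCTURE_COLUMNS + ADULT_SLOT_LABELS + CHILD_SLOT_LABELS + COVARIATE_COLUMNS
)

_FLOAT_COLUMNS = ADULT_SLOT_LABELS + CHILD_SLOT_LABELS + COVARIATE_COLUMNS


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the wide-table contract; returns the frame in canonical column order."""
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing required columns: {missing}")
    bad = ~df["sibling_link"].isin(["MZ", "DZ", "FULLSIB", "HALFSIB"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"row {row}: unknown sibling_link {df['sibling_link'].iloc[row]!r}"
        )
    for col in ("role1", "role2"):
        bad = ~df[col].isin(["MOTHER", "FATHER"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"row {row}: invalid {col} {df[col].iloc[row]!r}")
    for col in ("n_children1", "n_children2"):
        vals = df[col].to_numpy()
        if not np.isin(vals, [0, 1, 2]).all():
            row = int(np.flatnonzero(~np.isin(vals, [0, 1, 2]))[0])
            raise ValueError(f"row {row}: {col} must be 0, 1 or 2, got {vals[row]!r}")
    return df.loc[:, list(TABLE_COLUMNS)]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a family table as UTF-8 CSV with ``NA`` for missing cells."""
    path = Path(path)
    validate_table(df).to_csv(path, index=False, na_rep="NA")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a family table written by :func:`write_table` (lossless round trip)."""
    df = pd.read_csv(
        path,
        na_values=["NA"],
        keep_default_na=False,
        dtype={
            "family_id": np.int64,
            "sibling_link": str,
            "role1": str,
            "role2": str,
            "n_children1": np.int64,
            "n_children2": np.int64,
            **{c: float for c in _FLOAT_COLUMNS},
        },
    )
    return validate_table(df)


_DICTIONARY = {
    "family_id": "integer unit identifier",
    "sibling_link": "relatedness class of the two linking adults: MZ | DZ | FULLSIB | HALFSIB",
    "role1": "parental role of linking sibling 1 in nuclear family 1: MOTHER | FATHER",
    "role2": "parental role of linking sibling 2 in nuclear family 2",
    "n_children1": "children in nuclear family 1 (0-2)",
    "n_children2": "children in nuclear family 2 (0-2)",
    "s1_n1 / s1_n2": "neuroticism indicators 1 and 2 of linking sibling 1",
    "sp1_n1 / sp1_n2": "indicators of linking sibling 1's spouse",
    "s2_n1 / s2_n2": "indicators of linking sibling 2",
    "sp2_n1 / sp2_n2": "indicators of linking sibling 2's spouse",
    "cJK_out": "outcome score of child K of nuclear family J (NA if absent or not returned)",
    "cJK_sex": "child sex: 1 = girl, 0 = boy (NA if child absent)",
    "cJK_parity": "child parity (birth order covariate, 0-3; NA if child absent)",
    "missing value code": "NA",
}


def write_data_dictionary(path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_DICTIONARY, indent=2) + "\n")
    return path


def write_manifest(path: str | Path, *, seed: int | None, stage: str, **fields) -> Path:
    """Record provenance (stage, seed, versions, free-form fields) as JSON."""
    from . import __version__

    manifest = {
        "stage": stage,
        "seed": seed,
        "cotfam_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        **fields,
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
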