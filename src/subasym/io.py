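"""Reading and writing the pipeline's table formats.

Site tables are comma-separated UTF-8 CSV with a mandatory header:
subject_id, sex (M/F), age_years, handedness (L/R, may be missing),
icv_mm3, then {structure}_L_mm3 / {structure}_R_mm3 pairs. Pedigrees are
whitespace-delimited PED-style columns family_id, individual_id, father_id,
mother_id, sex, with 0 marking an unknown (founder) parent; phenotypes
travel in a separate CSV keyed by individual_id.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import STRUCTURES

__all__ = [
    "read_site_table",
    "write_site_table",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_summary",
]

_REQUIRED = ["subject_id", "sex", "age_years", "handedness", "icv_mm3"]
_SEX_CODES = {"M", "F"}
_HAND_CODES = {"L", "R"}


def _volume_columns(columns) -> list[str]:
    out = []
    for s in STRUCTURES:
        for side in ("L", "R"):
            col = f"{s}_{side}_mm3"
            if col in columns:
                out.append(col)
    return out


def read_site_table(path, *, site_id=None, freesurfer_version=None) -> pd.DataFrame:
    """Read and validate one site's subject table.

    Missing required columns raise naming the column; malformed sex or
    handedness codes raise naming the row; unknown columns warn and are
    kept. Site metadata can be passed explicitly or is derived from the
    file name.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    known = set(_REQUIRED) | {f"{s}_{d}_mm3" for s in STRUCTURES for d in "LR"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown columns {unknown}")
    if not _volume_columns(df.columns):
        raise ValueError(f"{path.name}: no structure volume columns found")
    bad = ~df["sex"].isin(_SEX_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path.name}: invalid sex code {df['sex'].iloc[row]!r} "
            f"in row {row} (expected M or F)"
        )
    hand = df["handedness"]
    bad = hand.notna() & ~hand.isin(_HAND_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path.name}: invalid handedness code {hand.iloc[row]!r} "
            f"in row {row} (expected L, R or missing)"
        )
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path.name}: duplicate subject_id values")
    df.attrs["site_id"] = site_id or path.stem
    if freesurfer_version is not None:
        df.attrs["freesurfer_version"] = freesurfer_version
    return df


def write_site_table(table: pd.DataFrame, path) -> None:
    cols = _REQUIRED + _volume_columns(table.columns)
    table[cols].to_csv(path, index=False)


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def write_pedigree(ped: pd.DataFrame, path) -> None:
    out = ped[["family_id", "individual_id", "father_id", "mother_id", "sex"]].copy()
    for col in ("father_id", "mother_id"):
        out[col] = out[col].fillna("0")
    out.to_csv(path, sep=" ", index=False, header=False)


def read_pedigree(path) -> pd.DataFrame:
    """Read a whitespace-delimited PED-style file; rows may appear in any
    order (a topological sort happens downstream)."""
    ped = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex"],
        dtype=str,
    )
    ped.loc[ped["father_id"] == "0", "father_id"] = None
    ped.loc[ped["mother_id"] == "0", "mother_id"] = None
    return ped


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "individual_id" not in df.columns:
        raise ValueError("phenotype file must contain an individual_id column")
    return df
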