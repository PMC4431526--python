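"""Reading, validating and writing plate-structured screen tables.

Two tabular schemas are supported:

``raw_counts``
    One row per well x strain x technical replicate, carrying the raw parent
    and progeny counts.  Columns: ``Plate, Well, Strain, BioRep, TechRep,
    Description, GeneID, Parents, Progeny``.  This is the long layout the
    pipeline works on internally and the one the simulator emits.

``data_record``
    One row per clone x biological replicate, carrying strain-averaged
    reproductive fitness values, their ratio and the classification -- the
    layout of the published per-clone spreadsheets.  The two strain columns
    are named after the assayed strains: SV1069 (``myo-2::gfp`` marker,
    wild-type background) and SV1070 (marker plus the ``bmk-1(ok391)``
    deletion).

Values that could not be determined (ND) are written as the token ``"ND"``
and read back (case-insensitively) as missing values; an unparseable numeric
cell likewise becomes ND, never a silent zero.
"""

from __future__ import annotations

import io as _stdio
from os import PathLike
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from . import layout
from .errors import DuplicateWellError, SchemaError

RAW_COLUMNS = [
    "Plate", "Well", "Strain", "BioRep", "TechRep",
    "Description", "GeneID", "Parents", "Progeny",
]
RAW_KEY = ["Plate", "Well", "Strain", "BioRep", "TechRep"]
RAW_NUMERIC = ["Parents", "Progeny"]

WT_RF_COLUMN = "RF (AVG replicates) SV1069"
MUT_RF_COLUMN = "RF (AVG replicates) SV1070"
RECORD_COLUMNS = [
    "Plate", "Well", "Description", "GeneID",
    WT_RF_COLUMN, MUT_RF_COLUMN, "RFratio", "Lethality", "Classification",
    "BioRep",
]
RECORD_KEY = ["Plate", "Well", "BioRep"]
RECORD_NUMERIC = [WT_RF_COLUMN, MUT_RF_COLUMN, "RFratio", "Lethality"]

#: internal column names for the clone-level table
CLONE_COLUMNS = [
    "Plate", "Well", "BioRep", "Description", "GeneID",
    "rf_wt", "rf_mut", "rf_ratio", "lethality_wt", "classification",
]
_REC_TO_CLONE = {
    WT_RF_COLUMN: "rf_wt",
    MUT_RF_COLUMN: "rf_mut",
    "RFratio": "rf_ratio",
    "Lethality": "lethality_wt",
    "Classification": "classification",
}

ND_TOKEN = "ND"
_CLASS_OUT = {"no_effect": "no effect"}
_CLASS_IN = {"no effect": "no_effect"}

PathType = Union[str, PathLike, _stdio.IOBase]


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_text_table(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    # everything as text: ND tokens and numeric coercion are handled explicitly
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s): {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )


def _coerce_numeric(series: pd.Series) -> pd.Series:
    """Text -> float; empty cells, 'ND' (any case) and unparseable text -> NaN."""
    cleaned = series.str.strip()
    cleaned = cleaned.mask(cleaned.str.upper().isin({ND_TOKEN, ""}))
    return pd.to_numeric(cleaned, errors="coerce")


def _check_duplicates(df: pd.DataFrame, key: list[str]) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise DuplicateWellError(
            f"duplicate {tuple(key)} key: {tuple(first)} "
            f"({int(dup.sum())} duplicated row(s))"
        )


def read_screen_table(path: PathType, schema: str = "raw_counts") -> pd.DataFrame:
    """Read a screen table and return a typed DataFrame.

    Parameters
    ----------
    path
        CSV or TSV file; the delimiter is sniffed from the header line.
    schema
        ``"raw_counts"`` for per-well count tables or ``"data_record"`` for
        per-clone summary tables.

    Raises
    ------
    SchemaError
        If a mandatory column is absent or a description string is unknown.
    DuplicateWellError
        If the same well/replicate key occurs twice.
    """
    if schema == "raw_counts":
        return _read_raw_counts(path)
    if schema == "data_record":
        return _read_data_record(path)
    raise ValueError(f"unknown schema: {schema!r}")


def _read_raw_counts(path) -> pd.DataFrame:
    df = _read_text_table(path)
    _require_columns(df, RAW_COLUMNS)
    df = df[RAW_COLUMNS].copy()
    df["Well"] = df["Well"].map(layout.normalize_well)
    df["Strain"] = df["Strain"].str.strip()
    bad_strain = ~df["Strain"].isin(layout.STRAINS)
    if bad_strain.any():
        raise SchemaError(
            f"unknown strain value(s): {sorted(df.loc[bad_strain, 'Strain'].unique())}; "
            f"expected {list(layout.STRAINS)}"
        )
    df["Description"] = df["Description"].str.strip().map(layout.DESCRIPTION_TO_CONTENT)
    if df["Description"].isna().any():
        raise SchemaError(
            "unknown Description value; expected one of "
            f"{sorted(layout.DESCRIPTION_TO_CONTENT)}"
        )
    for col in ("BioRep", "TechRep"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    for col in RAW_NUMERIC:
        df[col] = _coerce_numeric(df[col])
    _check_duplicates(df, RAW_KEY)
    return df.reset_index(drop=True)


def _read_data_record(path) -> pd.DataFrame:
    df = _read_text_table(path)
    _require_columns(df, RECORD_COLUMNS)
    df = df[RECORD_COLUMNS].copy()
    df["Well"] = df["Well"].map(layout.normalize_well)
    df["Description"] = df["Description"].str.strip().map(layout.DESCRIPTION_TO_CONTENT)
    if df["Description"].isna().any():
        raise SchemaError(
            "unknown Description value; expected one of "
            f"{sorted(layout.DESCRIPTION_TO_CONTENT)}"
        )
    df["BioRep"] = pd.to_numeric(df["BioRep"], errors="raise").astype(np.int64)
    for col in RECORD_NUMERIC:
        df[col] = _coerce_numeric(df[col])
    df["Classification"] = (
        df["Classification"].str.strip().map(lambda s: _CLASS_IN.get(s, s))
    )
    _check_duplicates(df, RECORD_KEY)
    df = df.rename(columns=_REC_TO_CLONE)
    return df[CLONE_COLUMNS].reset_index(drop=True)


def write_data_record(results: pd.DataFrame, path: PathType) -> None:
    """Write a clone-level results table as a Data-Record-schema CSV.

    ND values are written as the token ``"ND"``;
    ``read_screen_table(path, "data_record")`` round-trips the table.
    """
    out = results.copy()
    if "classification" not in out.columns:
        raise SchemaError("results must carry a 'classification' column")
    out["Description"] = out["Description"].map(layout.CONTENT_TO_DESCRIPTION)
    out["classification"] = out["classification"].map(lambda s: _CLASS_OUT.get(s, s))
    out = out.rename(columns={v: k for k, v in _REC_TO_CLONE.items()})
    out = out.reindex(columns=RECORD_COLUMNS)
    out.to_csv(path, index=False, na_rep=ND_TOKEN)


def write_raw_counts(wells: pd.DataFrame, path: PathType) -> None:
    """Write a per-well count table in the ``raw_counts`` schema."""
    out = wells.copy()
    out["Description"] = out["Description"].map(layout.CONTENT_TO_DESCRIPTION)
    out = out.reindex(columns=RAW_COLUMNS)
    out.to_csv(path, index=False, na_rep=ND_TOKEN)


def validate_layout(wells: pd.DataFrame) -> list[str]:
    """Check a per-well table against the expected plate layout.

    Returns a list of human-readable violations; an empty list means the
    layout conforms.  Checks: controls confined to column 1, no samples in
    the column-1 control slots, and both strains present for every
    (plate, well) pair.
    """
    violations: list[str] = []
    cols = wells["Well"].map(layout.well_column)
    is_control = wells["Description"] != layout.SAMPLE

    stray = wells[is_control & (cols != 1)]
    for _, row in stray.drop_duplicates(subset=["Plate", "Well"]).iterrows():
        violations.append(
            f"control ({row['Description']}) outside column 1: "
            f"plate {row['Plate']} well {row['Well']}"
        )
    misplaced = wells[~is_control & (cols == 1)]
    for _, row in misplaced.drop_duplicates(subset=["Plate", "Well"]).iterrows():
        violations.append(
            f"sample in a control slot: plate {row['Plate']} well {row['Well']}"
        )

    strain_sets = wells.groupby(["Plate", "Well"])["Strain"].agg(lambda s: frozenset(s))
    for plate, group in strain_sets.groupby(level=0):
        unpaired = group[group != frozenset(layout.STRAINS)]
        if len(unpaired):
            missing = sorted(
                {s for fs in unpaired for s in set(layout.STRAINS) - fs}
            )
            violations.append(
                f"unpaired strain on plate {plate}: {len(unpaired)} well(s) "
                f"missing {', '.join(missing)}"
            )
    return violations
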