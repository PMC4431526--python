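"""Reproductive-fitness statistics.

Reproductive Fitness (RF) is the number of viable progeny per parent worm in
a well.  The pipeline applies a parent-count quality window (only wells with
2-12 parents are informative; progeny yield is linear in that range),
normalizes each physical assay plate by the median RF of its sample wells to
remove plate effects, averages the two technical replicates, and forms the
RF ratio between the mutant and wild-type strain for each clone.  A ratio
well below 1 means the knockdown is markedly more deleterious in the mutant
background (a candidate synthetic-lethal "enhancer"); well above 1, less
deleterious (a "suppressor").

ND ("not determined") values are represented as NaN and propagate: no
operation here turns an ND into a number.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import layout

logger = logging.getLogger(__name__)

#: inclusive parent-count window within which RF is considered reliable
PARENT_WINDOW = (2, 12)

#: grouping that identifies one physical assay plate: each library plate is
#: replicated per strain and per technical replicate (and per experiment)
PLATE_GROUP = ["Plate", "Strain", "BioRep", "TechRep"]

#: default minimum number of defined sample wells before a warning is logged
MIN_SAMPLES_DEFAULT = 10

ND = float("nan")


def is_nd(value: float) -> bool:
    """True if a fitness value or ratio is not determined."""
    return value is None or (isinstance(value, float) and math.isnan(value))


def compute_rf(
    parent_count: float,
    progeny_count: float,
    window: tuple[int, int] = PARENT_WINDOW,
) -> float:
    """Reproductive fitness of one well: progeny per parent.

    Returns ND (NaN) when the parent count falls outside the closed quality
    window (default 2-12) or when either count is itself ND.  Raises
    ``ValueError`` on negative counts.
    """
    if is_nd(parent_count) or is_nd(progeny_count):
        return ND
    if parent_count < 0 or progeny_count < 0:
        raise ValueError(
            f"counts must be non-negative, got parents={parent_count}, "
            f"progeny={progeny_count}"
        )
    lo, hi = window
    if not lo <= parent_count <= hi:
        return ND
    return progeny_count / parent_count


def normalize_plate(
    rfs: Mapping[str, float],
    sample_wells: Iterable[str],
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> tuple[dict[str, float], dict]:
    """Divide every RF on one physical plate by the median sample-well RF.

    Control wells are measurements too and are normalized by the same sample
    median; they never contribute to it.  Returns the normalized mapping and
    an info dict (``median``, ``n_samples``, ``normalizable``).  A plate
    whose sample median is zero or undefined is unnormalizable: every value
    becomes ND.
    """
    sample_wells = set(sample_wells)
    defined = [v for w, v in rfs.items() if w in sample_wells and not is_nd(v)]
    median = float(np.median(defined)) if defined else ND
    normalizable = bool(defined) and median > 0
    if defined and len(defined) < min_samples:
        logger.warning(
            "plate has only %d defined sample wells (minimum %d)",
            len(defined), min_samples,
        )
    if not normalizable:
        return {w: ND for w in rfs}, {
            "median": median, "n_samples": len(defined), "normalizable": False,
        }
    out = {w: (ND if is_nd(v) else v / median) for w, v in rfs.items()}
    return out, {"median": median, "n_samples": len(defined), "normalizable": True}


def summarize_technical(rf_r1: float, rf_r2: float) -> float:
    """Combine the two technical replicates of a well.

    Arithmetic mean when both are defined; the single defined value when the
    other replicate failed; ND when both are ND.
    """
    a, b = is_nd(rf_r1), is_nd(rf_r2)
    if a and b:
        return ND
    if a:
        return rf_r2
    if b:
        return rf_r1
    return (rf_r1 + rf_r2) / 2.0


def compute_rf_ratio(
    rf_mut: float,
    rf_wt: float,
    orientation: str = "mut_over_wt",
) -> float:
    """RF ratio between the strain-averaged, normalized fitness values.

    The default orientation puts the mutant strain in the numerator, so
    enhanced lethality in the mutant gives a ratio below 1.  ND if either
    input is ND or the denominator is zero.
    """
    if orientation == "mut_over_wt":
        num, den = rf_mut, rf_wt
    elif orientation == "wt_over_mut":
        num, den = rf_wt, rf_mut
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    if is_nd(num) or is_nd(den) or den == 0:
        return ND
    return num / den


def compute_lethality(rf_wt_normalized: float) -> float:
    """Lethality fraction in the wild-type strain from its normalized RF.

    Normalized RF 1 is typical viability on the plate, so lethality is
    ``1 - RF`` clamped to [0, 1].  ND propagates.
    """
    if is_nd(rf_wt_normalized):
        return ND
    return min(1.0, max(0.0, 1.0 - rf_wt_normalized))


# ---------------------------------------------------------------------------
# table-level drivers (vectorized counterparts used by the pipeline)

def add_rf(wells: pd.DataFrame, window: tuple[int, int] = PARENT_WINDOW) -> pd.DataFrame:
    """Append an ``RF`` column to a raw per-well table."""
    parents = wells["Parents"].to_numpy(dtype=float)
    progeny = wells["Progeny"].to_numpy(dtype=float)
    if np.nanmin(parents, initial=0) < 0 or np.nanmin(progeny, initial=0) < 0:
        raise ValueError("counts must be non-negative")
    lo, hi = window
    in_window = (parents >= lo) & (parents <= hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.where(in_window, progeny / parents, np.nan)
    out = wells.copy()
    out["RF"] = rf
    return out


def normalize_screen(
    wells: pd.DataFrame,
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plate sample-median normalization across a whole screen table.

    One physical plate is one (library plate, strain, biological replicate,
    technical replicate) combination.  Returns the table with an ``RF_norm``
    column plus a per-plate log (median, defined sample count, flag).
    """
    out = wells.copy()
    is_sample = out["Description"] == layout.SAMPLE
    sample_rf = out["RF"].where(is_sample)
    grouped = sample_rf.groupby([out[k] for k in PLATE_GROUP])
    medians = grouped.median()
    counts = grouped.count()

    key = pd.MultiIndex.from_frame(out[PLATE_GROUP])
    plate_median = medians.reindex(key).to_numpy()
    normalizable = np.isfinite(plate_median) & (plate_median > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["RF_norm"] = np.where(normalizable, out["RF"] / plate_median, np.nan)

    log = pd.DataFrame({
        "median": medians,
        "n_samples": counts,
        "normalizable": np.isfinite(medians) & (medians > 0),
    }).reset_index()
    low = log[log["normalizable"] & (log["n_samples"] < min_samples)]
    for _, row in low.iterrows():
        logger.warning(
            "plate %s (%s, bio %s, tech %s): only %d defined sample wells "
            "(minimum %d)",
            row["Plate"], row["Strain"], row["BioRep"], row["TechRep"],
            row["n_samples"], min_samples,
        )
    return out, log


def average_technical(wells: pd.DataFrame) -> pd.DataFrame:
    """Average normalized RF over technical replicates.

    Group key: (plate, well, strain, biological replicate).  The mean skips
    ND replicates, so one failed replicate leaves the other's value; all-ND
    groups stay ND.
    """
    keys = ["Plate", "Well", "Strain", "BioRep"]
    agg = (
        wells.groupby(keys, sort=False)
        .agg(
            Description=("Description", "first"),
            GeneID=("GeneID", "first"),
            RF_norm=("RF_norm", "mean"),  # skipna
        )
        .reset_index()
    )
    return agg


def build_clone_table(
    averaged: pd.DataFrame,
    orientation: str = "mut_over_wt",
) -> pd.DataFrame:
    """Pivot strain-averaged values into one row per clone per experiment.

    Adds the RF ratio and the wild-type lethality fraction; classification
    is added downstream.
    """
    keys = ["Plate", "Well", "BioRep"]
    wide = averaged.set_index(keys + ["Strain"])["RF_norm"].unstack("Strain")
    meta = averaged.groupby(keys, sort=False)[["Description", "GeneID"]].first()
    clone = meta.join(wide).reset_index()
    clone = clone.rename(
        columns={layout.WILD_TYPE: "rf_wt", layout.MUTANT: "rf_mut"}
    )
    for col in ("rf_wt", "rf_mut"):
        if col not in clone.columns:
            clone[col] = np.nan
    rf_wt = clone["rf_wt"].to_numpy(dtype=float)
    rf_mut = clone["rf_mut"].to_numpy(dtype=float)
    if orientation == "mut_over_wt":
        num, den = rf_mut, rf_wt
    elif orientation == "wt_over_mut":
        num, den = rf_wt, rf_mut
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den != 0, num / den, np.nan)
    clone["rf_ratio"] = ratio
    clone["lethality_wt"] = np.clip(1.0 - rf_wt, 0.0, 1.0)
    return clone[
        ["Plate", "Well", "BioRep", "Description", "GeneID",
         "rf_wt", "rf_mut", "rf_ratio", "lethality_wt"]
    ]
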