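"""Hit calling: threshold classification, cut-off calibration, replicate agreement.

Two classification regimes are used, with deliberately different boundary
semantics:

* the primary screen uses inclusive thresholds — enhancer when the RF ratio
  is <= 0.5, suppressor when >= 1.5 — plus an exclusion rule for clones
  whose knockdown kills more than 90% of the wild-type strain (the ratio is
  then unreliable);
* the secondary screen classifies at a percentage cut-off ``c`` with strict
  inequalities — enhancer when ratio < 1 - c/100, suppressor (symmetric
  convention) when ratio > 1 + c/100 — and the cut-off itself is calibrated
  from the control wells: the false-positive rate is estimated from negative
  controls, the false-negative rate from the positive control, and the
  cut-off on the grid with the most similar FP% and FN% is chosen.

Final hits must classify as enhancers in at least two of the three
biological replicates; clones hitting the same primary target are collapsed
to a single gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, GeneMappingError
from .fitness import is_nd

logger = logging.getLogger(__name__)

ENHANCER = "enhancer"
SUPPRESSOR = "suppressor"
NO_EFFECT = "no_effect"
EXCLUDED = "excluded"
ND_CLASS = "ND"

DEFAULT_GRID = (40, 45, 50, 55, 60, 65, 70)


def classify_primary(
    rf_ratio: float,
    lethality_wt: float,
    enhancer_max: float = 0.5,
    suppressor_min: float = 1.5,
    exclusion_lethality: float = 0.9,
) -> str:
    """Primary-screen classification with inclusive ratio thresholds.

    Exclusion (wild-type lethality strictly above ``exclusion_lethality``)
    is applied before any ratio rule; ND inputs yield ``"ND"``.
    """
    if not is_nd(lethality_wt) and lethality_wt > exclusion_lethality:
        return EXCLUDED
    if is_nd(rf_ratio):
        return ND_CLASS
    if rf_ratio <= enhancer_max:
        return ENHANCER
    if rf_ratio >= suppressor_min:
        return SUPPRESSOR
    return NO_EFFECT


def classify_at_cutoff(rf_ratio: float, cutoff_percent: float) -> str:
    """Secondary-screen classification at a percentage cut-off.

    Enhancer when ratio < 1 - c/100 (strict; at the 45% cut-off the rule is
    "ratio < 0.55"), suppressor when ratio > 1 + c/100 (strict, symmetric),
    otherwise no effect; ND propagates.
    """
    if not 0 < cutoff_percent < 100:
        raise ValueError(f"cutoff_percent must be in (0, 100), got {cutoff_percent}")
    if is_nd(rf_ratio):
        return ND_CLASS
    if rf_ratio < 1.0 - cutoff_percent / 100.0:
        return ENHANCER
    if rf_ratio > 1.0 + cutoff_percent / 100.0:
        return SUPPRESSOR
    return NO_EFFECT


@dataclass(frozen=True)
class CutoffCalibration:
    """FP/FN percentages per candidate cut-off and the chosen cut-off.

    ``fp_percent[c]``: percentage of negative-control ratios classified
    enhancer at cut-off ``c``; ``fn_percent[c]``: percentage of
    positive-control ratios *not* classified enhancer.  The chosen cut-off
    minimizes ``|FP% - FN%|`` over the grid (ties go to the smaller, more
    sensitive cut-off).
    """

    grid: tuple[float, ...]
    fp_percent: dict[float, float]
    fn_percent: dict[float, float]
    chosen_cutoff: float
    n_neg: int = 0
    n_pos: int = 0
    n_dropped: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": list(self.grid),
            "fp_percent": [self.fp_percent[c] for c in self.grid],
            "fn_percent": [self.fn_percent[c] for c in self.grid],
            "chosen": [c == self.chosen_cutoff for c in self.grid],
        })


def calibrate_cutoff(
    neg_ratios: Iterable[float],
    pos_ratios: Iterable[float],
    grid: Sequence[float] = DEFAULT_GRID,
) -> CutoffCalibration:
    """Estimate expected FP% and FN% from control ratios for each cut-off.

    At cut-off ``c`` the enhancer threshold is ``t = 1 - c/100``:
    FP% counts negative controls with ratio < t, FN% counts positive
    controls with ratio >= t.  ND ratios are dropped (and counted).
    """
    neg = np.asarray([r for r in neg_ratios], dtype=float)
    pos = np.asarray([r for r in pos_ratios], dtype=float)
    n_dropped = int(np.isnan(neg).sum() + np.isnan(pos).sum())
    if n_dropped:
        logger.info("calibration dropped %d ND control ratio(s)", n_dropped)
    neg = neg[~np.isnan(neg)]
    pos = pos[~np.isnan(pos)]
    if len(neg) == 0 or len(pos) == 0:
        raise CalibrationError(
            "cut-off calibration needs at least one defined negative and one "
            f"defined positive control ratio (have {len(neg)} neg, {len(pos)} pos)"
        )
    grid = tuple(float(c) for c in grid)
    fp = {c: 100.0 * float(np.mean(neg < 1.0 - c / 100.0)) for c in grid}
    fn = {c: 100.0 * float(np.mean(pos >= 1.0 - c / 100.0)) for c in grid}
    chosen = min(grid, key=lambda c: (abs(fp[c] - fn[c]), c))
    return CutoffCalibration(
        grid=grid, fp_percent=fp, fn_percent=fn, chosen_cutoff=chosen,
        n_neg=len(neg), n_pos=len(pos), n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class ReplicateAgreement:
    """Per-clone replicate agreement across the three experiments."""

    clone_id: tuple
    classifications: tuple[str, ...]
    final_status: str  # "final_hit" | "not_reproducible"
    venn_region: frozenset[str] = field(default_factory=frozenset)


def summarize_replicates(
    per_experiment: Mapping[object, Sequence[str]],
    min_agreement: int = 2,
    n_experiments: int = 3,
) -> tuple[list[ReplicateAgreement], dict[str, int]]:
    """Apply the >=2-of-3 replicate-agreement rule and tally Venn regions.

    ``per_experiment`` maps a clone id to its classification vector, one
    entry per biological replicate (ND entries allowed; they never count as
    enhancer evidence).  Returns the per-clone agreement records and the
    counts for the seven non-empty Venn regions over clones that are an
    enhancer in at least one experiment.
    """
    records: list[ReplicateAgreement] = []
    venn: dict[str, int] = {}
    for clone, classes in per_experiment.items():
        classes = tuple(classes)
        if len(classes) != n_experiments:
            raise ValueError(
                f"clone {clone!r} has {len(classes)} classifications, "
                f"expected {n_experiments}"
            )
        region = frozenset(
            f"E{i + 1}" for i, c in enumerate(classes) if c == ENHANCER
        )
        status = "final_hit" if len(region) >= min_agreement else "not_reproducible"
        records.append(ReplicateAgreement(clone, classes, status, region))
        if region:
            label = "&".join(sorted(region))
            venn[label] = venn.get(label, 0) + 1
    return records, venn


def collapse_to_genes(
    final_clones: Sequence[object],
    clone_to_gene: Mapping[object, str],
) -> list[str]:
    """Collapse clones sharing a primary target into a unique gene list.

    Order is stable (first occurrence in the given clone order, which the
    pipeline sorts by hit plate then well).  A clone without a mapping
    raises :class:`GeneMappingError`.
    """
    genes: list[str] = []
    seen: set[str] = set()
    for clone in final_clones:
        if clone not in clone_to_gene:
            raise GeneMappingError(f"clone {clone!r} has no gene mapping")
        gene = clone_to_gene[clone]
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes


def classify_table_primary(
    clone_table: pd.DataFrame,
    enhancer_max: float = 0.5,
    suppressor_min: float = 1.5,
    exclusion_lethality: float = 0.9,
) -> pd.DataFrame:
    """Vectorized primary classification of a clone-level table."""
    ratio = clone_table["rf_ratio"].to_numpy(dtype=float)
    leth = clone_table["lethality_wt"].to_numpy(dtype=float)
    out = np.full(len(clone_table), NO_EFFECT, dtype=object)
    with np.errstate(invalid="ignore"):
        out[ratio <= enhancer_max] = ENHANCER  # NaN compares False
        out[ratio >= suppressor_min] = SUPPRESSOR
        out[np.isnan(ratio)] = ND_CLASS
        out[leth > exclusion_lethality] = EXCLUDED  # exclusion overrides all
    result = clone_table.copy()
    result["classification"] = out
    return result


def classify_table_at_cutoff(
    clone_table: pd.DataFrame,
    cutoff_percent: float,
) -> pd.DataFrame:
    """Vectorized secondary classification of a clone-level table."""
    ratio = clone_table["rf_ratio"].to_numpy(dtype=float)
    lo = 1.0 - cutoff_percent / 100.0
    hi = 1.0 + cutoff_percent / 100.0
    out = np.full(len(clone_table), NO_EFFECT, dtype=object)
    with np.errstate(invalid="ignore"):
        out[ratio < lo] = ENHANCER
        out[ratio > hi] = SUPPRESSOR
    out[np.isnan(ratio)] = ND_CLASS
    result = clone_table.copy()
    result["classification"] = out
    return result
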