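"""End-to-end screen drivers: primary and secondary hit selection.

``run_primary`` chains the per-well statistics (RF -> plate normalization ->
technical-replicate averaging -> RF ratio) and applies the inclusive primary
thresholds; its selection list is the union of enhancers and suppressors,
with excluded and ND clones dropped.

``run_secondary`` runs the same chain on a three-experiment table,
calibrates the enhancer cut-off from the pooled control ratios, classifies
every clone in every experiment at the chosen cut-off, applies the
two-of-three replicate-agreement rule, and collapses the final clone list to
unique genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import fitness, hits, io, layout
from .errors import ConfigurationError
from .hits import CutoffCalibration, ReplicateAgreement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and options shared by the pipeline stages."""

    primary_enhancer_max: float = 0.5
    primary_suppressor_min: float = 1.5
    exclusion_lethality: float = 0.9
    cutoff_grid: tuple[float, ...] = hits.DEFAULT_GRID
    min_agreement: int = 2
    min_samples: int = fitness.MIN_SAMPLES_DEFAULT
    orientation: str = "mut_over_wt"

    def validate(self) -> None:
        if min(self.primary_enhancer_max, self.primary_suppressor_min,
               self.exclusion_lethality) <= 0:
            raise ConfigurationError("thresholds must be positive")
        grid = tuple(self.cutoff_grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("cutoff grid must be strictly increasing")
        if self.min_agreement < 1:
            raise ConfigurationError("min_agreement must be >= 1")


@dataclass
class PrimaryResult:
    clones: pd.DataFrame          # clone-level table with classification
    selection: list[tuple]        # (plate, well) kept for the secondary screen
    plate_log: pd.DataFrame
    counts: dict[str, int]


@dataclass
class SecondaryResult:
    clones: pd.DataFrame          # clone x experiment table with classification
    calibration: CutoffCalibration
    per_rep_calibrations: dict[int, CutoffCalibration]
    agreements: list[ReplicateAgreement]
    venn: dict[str, int]
    final_clones: list[tuple]     # (plate, well), sorted by plate then well
    final_genes: list[str]
    counts: dict[str, int] = field(default_factory=dict)


_EMPTY_CLONES = pd.DataFrame(columns=io.CLONE_COLUMNS)


def _clone_stage(wells: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared chain: raw wells -> clone-level table plus plate log."""
    scored = fitness.add_rf(wells)
    normalized, plate_log = fitness.normalize_screen(scored, config.min_samples)
    averaged = fitness.average_technical(normalized)
    clones = fitness.build_clone_table(averaged, orientation=config.orientation)
    return clones, plate_log


def run_primary(wells: pd.DataFrame, config: PipelineConfig | None = None) -> PrimaryResult:
    """Primary screen: classify every clone and select candidate hits."""
    config = config or PipelineConfig()
    config.validate()
    if wells.empty:
        logger.warning("primary screen received an empty well table")
        return PrimaryResult(_EMPTY_CLONES.copy(), [], pd.DataFrame(), {})
    violations = io.validate_layout(wells)
    for v in violations:
        logger.warning("layout: %s", v)

    clones, plate_log = _clone_stage(wells, config)
    clones = hits.classify_table_primary(
        clones,
        enhancer_max=config.primary_enhancer_max,
        suppressor_min=config.primary_suppressor_min,
        exclusion_lethality=config.exclusion_lethality,
    )
    samples = clones[clones["Description"] == layout.SAMPLE]
    selected = samples[samples["classification"].isin([hits.ENHANCER, hits.SUPPRESSOR])]
    selection = sorted(
        {(p, w) for p, w in zip(selected["Plate"], selected["Well"])},
        key=lambda pw: (str(pw[0]), layout.well_sort_key(pw[1])),
    )
    counts = samples["classification"].value_counts().to_dict()
    counts["n_wells_read"] = len(wells)
    counts["n_selected"] = len(selection)
    logger.info("primary screen: %s", counts)
    return PrimaryResult(clones, selection, plate_log, counts)


def run_secondary(
    wells: pd.DataFrame,
    config: PipelineConfig | None = None,
    n_experiments: int = 3,
) -> SecondaryResult:
    """Secondary screen: calibrate the cut-off, classify, and call final hits."""
    config = config or PipelineConfig()
    config.validate()
    bio_reps = sorted(wells["BioRep"].unique()) if not wells.empty else []
    if len(bio_reps) != n_experiments:
        raise ConfigurationError(
            f"secondary screen needs exactly {n_experiments} biological "
            f"replicates, found {len(bio_reps)}"
        )

    clones, _ = _clone_stage(wells, config)

    is_neg = clones["Description"] == layout.NEG_CONTROL
    is_pos = clones["Description"] == layout.POS_CONTROL
    calibration = hits.calibrate_cutoff(
        clones.loc[is_neg, "rf_ratio"],
        clones.loc[is_pos, "rf_ratio"],
        grid=config.cutoff_grid,
    )
    per_rep = {
        int(rep): hits.calibrate_cutoff(
            clones.loc[is_neg & (clones["BioRep"] == rep), "rf_ratio"],
            clones.loc[is_pos & (clones["BioRep"] == rep), "rf_ratio"],
            grid=config.cutoff_grid,
        )
        for rep in bio_reps
    }
    cutoff = calibration.chosen_cutoff
    clones = hits.classify_table_at_cutoff(clones, cutoff)

    samples = clones[clones["Description"] == layout.SAMPLE]
    vectors = (
        samples.pivot(index=["Plate", "Well"], columns="BioRep",
                      values="classification")
        .reindex(columns=bio_reps)
        .fillna(hits.ND_CLASS)
    )
    per_clone = {idx: tuple(row) for idx, row in vectors.iterrows()}
    agreements, venn = hits.summarize_replicates(
        per_clone, min_agreement=config.min_agreement,
        n_experiments=n_experiments,
    )
    final = [a.clone_id for a in agreements if a.final_status == "final_hit"]
    final = sorted(final, key=lambda pw: (str(pw[0]), layout.well_sort_key(pw[1])))
    clone_to_gene = (
        samples.groupby(["Plate", "Well"])["GeneID"].first().to_dict()
    )
    genes = hits.collapse_to_genes(final, clone_to_gene)

    counts = {
        "n_wells_read": len(wells),
        "n_clones": len(per_clone),
        "chosen_cutoff": cutoff,
        "n_final_clones": len(final),
        "n_final_genes": len(genes),
    }
    logger.info("secondary screen: %s", counts)
    return SecondaryResult(
        clones=clones,
        calibration=calibration,
        per_rep_calibrations=per_rep,
        agreements=agreements,
        venn=venn,
        final_clones=final,
        final_genes=genes,
        counts=counts,
    )
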