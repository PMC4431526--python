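"""Synthetic screen generator with known ground truth.

Emulates a liquid-culture 96-well reproductive-fitness screen: ~7 L1 larvae
dispensed per well, grown for four days, adults and progeny counted.  Counts
are generated hierarchically:

* ``parent_count`` ~ Poisson(``parent_mean``) truncated to ``parent_range``
  (dispensing is a volume draw, so the number of larvae per well is
  Poisson-like; wells occasionally receive too few or too many);
* expected progeny = parents x ``baseline_brood`` x gene viability x strain
  effect x a log-normal plate effect shared by all wells of one physical
  assay plate;
* ``progeny_count`` ~ negative binomial around that mean with gamma-shape
  ``dispersion`` (brood sizes are overdispersed relative to Poisson:
  worm-to-worm variation and developmental timing).

Gene effects are multiplicative on expected progeny, matching the ratio
statistic the pipeline estimates.  Planted enhancers reduce progeny only in
the mutant strain (multiplier drawn on (0, 0.5]); suppressors increase it;
a small fraction of broadly lethal genes kill both strains.  Controls
follow the column-1 roster; the positive-control wells draw their
mutant-specific multiplier from the same enhancer-effect distribution as
planted enhancers, so control-based error prediction and sample behaviour
share one effect model.

Technical replicates share gene effects and redraw counts and plate
effects; biological replicates additionally redraw nothing else — effects
are properties of the clone, not of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import layout
from .errors import ConfigurationError

__all__ = [
    "SyntheticScreenConfig", "generate_screen", "evaluate_recovery",
    "realized_error_rates",
]


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Study-design and noise parameters of a simulated screen.

    Defaults describe a desk-scale screen of 10 library plates (880 clones)
    with the replicate structure of a genome-wide secondary screen: two
    strains, three biological replicates, two technical replicates, controls
    in column 1.
    """

    n_plates: int = 10
    genes_per_plate: int = 88
    enhancer_fraction: float = 0.05
    #: enhancer mutant/wild-type multiplier bounds, uniform on (0, 0.5]
    enhancer_effect: tuple[float, float] = (0.1, 0.4)
    suppressor_fraction: float = 0.02
    suppressor_effect: tuple[float, float] = (1.6, 2.4)
    #: fraction of broadly lethal genes (>90% lethality in both strains)
    lethal_fraction: float = 0.02
    lethal_viability: tuple[float, float] = (0.0, 0.08)
    #: expected viable progeny per parent for an unperturbed well
    baseline_brood: float = 30.0
    #: negative-binomial shape (gamma heterogeneity); larger = less noise
    dispersion: float = 10.0
    #: log-scale SD of the per-physical-plate multiplicative effect
    plate_effect_sd: float = 0.15
    #: expected L1 larvae dispensed per well (~7 per 10 ul)
    parent_mean: float = 7.0
    #: truncation bounds for the dispensed parent count
    parent_range: tuple[int, int] = (1, 14)
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    seed: int | None = None

    def validate(self) -> None:
        frac = self.enhancer_fraction + self.suppressor_fraction + self.lethal_fraction
        if not (0 <= self.enhancer_fraction <= 1 and 0 <= self.suppressor_fraction <= 1
                and 0 <= self.lethal_fraction <= 1 and frac <= 1):
            raise ConfigurationError("effect fractions must lie in [0,1] and sum to <= 1")
        if not 0 < self.enhancer_effect[0] <= self.enhancer_effect[1] <= 0.5:
            raise ConfigurationError("enhancer_effect bounds must lie in (0, 0.5]")
        if self.suppressor_effect[0] <= 1:
            raise ConfigurationError("suppressor_effect must exceed 1")
        if min(self.baseline_brood, self.dispersion) <= 0 or self.plate_effect_sd < 0:
            raise ConfigurationError("brood, dispersion must be > 0 and plate SD >= 0")
        if not 1 <= self.genes_per_plate <= 88:
            raise ConfigurationError("genes_per_plate must be in 1..88")
        if self.n_plates < 1 or self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ConfigurationError("plate and replicate counts must be >= 1")
        lo, hi = self.parent_range
        if not 0 <= lo <= hi:
            raise ConfigurationError("parent_range must satisfy 0 <= lo <= hi")


def _truncated_poisson(
    rng: np.random.Generator, mean: float, bounds: tuple[int, int], size: int
) -> np.ndarray:
    lo, hi = bounds
    draws = rng.poisson(mean, size=size)
    bad = (draws < lo) | (draws > hi)
    while bad.any():
        draws[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = (draws < lo) | (draws > hi)
    return draws


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    """Negative-binomial counts with the given means and gamma shape."""
    counts = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = shape / (shape + mean[pos])
    counts[pos] = rng.negative_binomial(shape, p)
    return counts


def _assign_truth(rng: np.random.Generator, cfg: SyntheticScreenConfig) -> pd.DataFrame:
    n = cfg.n_plates * cfg.genes_per_plate
    labels = rng.choice(
        ["enhancer", "suppressor", "lethal", "neutral"],
        size=n,
        p=[cfg.enhancer_fraction, cfg.suppressor_fraction, cfg.lethal_fraction,
           1 - cfg.enhancer_fraction - cfg.suppressor_fraction - cfg.lethal_fraction],
    )
    ratio = np.ones(n)
    viability = np.ones(n)
    is_enh = labels == "enhancer"
    is_sup = labels == "suppressor"
    is_let = labels == "lethal"
    ratio[is_enh] = rng.uniform(*cfg.enhancer_effect, size=int(is_enh.sum()))
    ratio[is_sup] = rng.uniform(*cfg.suppressor_effect, size=int(is_sup.sum()))
    viability[is_let] = rng.uniform(*cfg.lethal_viability, size=int(is_let.sum()))
    labels = np.where(is_let, "neutral", labels)  # lethal genes carry no strain effect

    sample_coords = layout.sample_wells()[: cfg.genes_per_plate]
    plates = np.repeat(np.arange(1, cfg.n_plates + 1), cfg.genes_per_plate)
    wells = np.tile(sample_coords, cfg.n_plates)
    gene_ids = np.array(
        [f"sg-{p:02d}{w}" for p, w in zip(plates, wells)], dtype=object
    )
    return pd.DataFrame({
        "GeneID": gene_ids,
        "Plate": plates.astype(str),
        "Well": wells,
        "label": labels,
        "wt_viability": viability,
        "mut_over_wt_ratio": ratio,
    })


def generate_screen(
    config: SyntheticScreenConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic screen and its ground truth.

    Returns a ``raw_counts``-schema per-well table (plates x 2 strains x
    biological x technical replicates) and a truth table mapping each gene
    to its label, wild-type viability and mutant/wild-type effect ratio.
    The same seed always reproduces the same tables.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    truth = _assign_truth(rng, config)

    # per-well effect columns for one plate layout: controls then samples
    control_coords = list(layout.DEFAULT_CONTROL_ROSTER)
    pos_wells = [
        w for w, (c, _) in layout.DEFAULT_CONTROL_ROSTER.items()
        if c == layout.POS_CONTROL
    ]
    # positive-control effect: one draw per (plate, control well), a fixed
    # property of that control clone across all replicates
    pos_effects = {
        (str(p), w): rng.uniform(*config.enhancer_effect)
        for p in range(1, config.n_plates + 1)
        for w in pos_wells
    }

    frames = []
    truth_by_key = truth.set_index(["Plate", "Well"])
    for plate in range(1, config.n_plates + 1):
        plate_id = str(plate)
        rows = []
        for well, (content, gene) in layout.DEFAULT_CONTROL_ROSTER.items():
            viab = 0.0 if content == layout.LETHALITY_CONTROL else 1.0
            mult = (
                pos_effects[(plate_id, well)]
                if content == layout.POS_CONTROL else 1.0
            )
            rows.append((well, content, gene, viab, mult))
        plate_truth = truth_by_key.loc[plate_id]
        for well, rec in plate_truth.iterrows():
            rows.append(
                (well, layout.SAMPLE, rec["GeneID"],
                 rec["wt_viability"], rec["mut_over_wt_ratio"])
            )
        wells_df = pd.DataFrame(
            rows, columns=["Well", "Description", "GeneID", "viability", "mut_mult"]
        )
        n_wells = len(wells_df)

        for bio in range(1, config.n_bio_reps + 1):
            for strain in layout.STRAINS:
                strain_mult = (
                    wells_df["mut_mult"].to_numpy()
                    if strain == layout.MUTANT
                    else np.ones(n_wells)
                )
                for tech in range(1, config.n_tech_reps + 1):
                    plate_effect = rng.lognormal(0.0, config.plate_effect_sd)
                    parents = _truncated_poisson(
                        rng, config.parent_mean, config.parent_range, n_wells
                    )
                    mean = (
                        parents * config.baseline_brood
                        * wells_df["viability"].to_numpy()
                        * strain_mult * plate_effect
                    )
                    progeny = _nb_counts(rng, mean, config.dispersion)
                    frames.append(pd.DataFrame({
                        "Plate": plate_id,
                        "Well": wells_df["Well"],
                        "Strain": strain,
                        "BioRep": bio,
                        "TechRep": tech,
                        "Description": wells_df["Description"],
                        "GeneID": wells_df["GeneID"],
                        "Parents": parents.astype(float),
                        "Progeny": progeny.astype(float),
                    }))

    wells = pd.concat(frames, ignore_index=True)
    truth = truth[
        ["GeneID", "Plate", "Well", "label", "wt_viability", "mut_over_wt_ratio"]
    ].reset_index(drop=True)
    return wells, truth


def realized_error_rates(clones: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Realized per-experiment FP% and FN% of sample wells against truth.

    Mirrors the control-based calibration estimates: among sample clone x
    experiment rows with a defined classification, FP% is the share of
    neutral-gene rows called enhancer and FN% the share of planted-enhancer
    rows not called enhancer.  Used to test that control-based error
    prediction transfers to the samples.
    """
    labels = truth.set_index("GeneID")["label"]
    samples = clones[clones["Description"] == layout.SAMPLE].copy()
    samples = samples[samples["classification"] != "ND"]
    samples["label"] = samples["GeneID"].map(labels)
    neutral = samples[samples["label"] == "neutral"]
    planted = samples[samples["label"] == "enhancer"]
    fp = 100.0 * float((neutral["classification"] == "enhancer").mean()) if len(neutral) else float("nan")
    fn = 100.0 * float((planted["classification"] != "enhancer").mean()) if len(planted) else float("nan")
    return {
        "fp_percent": fp,
        "fn_percent": fn,
        "n_neutral": len(neutral),
        "n_enhancer": len(planted),
    }


def evaluate_recovery(
    called: list[str] | set[str],
    truth: pd.DataFrame,
    bins: tuple[float, ...] = (0.0, 0.2, 0.3, 0.4, 0.5),
) -> dict:
    """Confusion summary of a called gene list against the planted truth.

    ``sensitivity`` = recovered / planted enhancers; ``fdr`` = false calls /
    all calls (0 when nothing is called).  The breakdown bins planted
    enhancers by their true mutant/wild-type ratio.
    """
    called = set(called)
    known = set(truth["GeneID"])
    unknown = called - known
    if unknown:
        raise ConfigurationError(
            f"called gene(s) absent from truth: {sorted(unknown)[:5]}"
        )
    enhancers = truth[truth["label"] == "enhancer"]
    planted = set(enhancers["GeneID"])
    tp = len(called & planted)
    fp = len(called - planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = fp / len(called) if called else 0.0

    binned = enhancers.assign(
        bin=pd.cut(enhancers["mut_over_wt_ratio"], bins=list(bins)),
        recovered=enhancers["GeneID"].isin(called),
    )
    breakdown = (
        binned.groupby("bin", observed=False)["recovered"]
        .agg(n_planted="count", n_recovered="sum")
        .reset_index()
    )
    return {
        "tp": tp,
        "fp": fp,
        "fn": len(planted) - tp,
        "n_called": len(called),
        "n_planted": len(planted),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "breakdown": breakdown,
    }
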