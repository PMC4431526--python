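# Methods

## Measurement model

One well of a 96-well liquid-culture RNAi plate yields two counts: parents
(adults detected by their large GFP-marked pharynx) and progeny (larvae,
small pharynx). Reproductive fitness is `RF = progeny / parents`,
dimensionless, defined only when the parent count lies in the closed window
[2, 12]: below 2 the estimate is dominated by a single animal, above 12
crowding makes progeny yield non-linear in parent number. Wells outside the
window are ND (not determined). ND is represented as NaN everywhere and
propagates: no downstream operation converts an ND into a number.

Each *physical* assay plate — one library plate replicated for one strain,
one biological replicate and one technical replicate — has its own handling,
growth and imaging conditions, so RF values are comparable only after
per-plate normalization. Every measurement on a plate (controls included)
is divided by the median RF of that plate's *sample* wells; the sample
median, not a control-based reference, is used because 88 sample wells give
a far more stable location estimate than 8 control wells, and the bulk of a
genome-wide library is phenotypically silent. Controls are deliberately
excluded from the median itself: half of them (plk-1, dli-1 in the mutant)
are designed to be extreme. A plate whose sample median is zero or whose
sample wells are all ND is unnormalizable and all its values become ND;
plates with fewer than `min_samples` (default 10) defined sample wells are
flagged in the log but still normalized.

Normalization happens *before* technical-replicate averaging, because plate
effects attach to physical plates and the two technical replicates live on
different physical plates. The replicate average is the arithmetic mean of
the defined replicates (one failed replicate leaves the other's value; two
failed replicates give ND).

The per-clone statistic is `RF_ratio = RF_mut / RF_wt` from the
strain-averaged, normalized values, ND if either side is ND or the
denominator is zero. The mutant sits in the numerator so that enhanced
lethality in the mutant gives a ratio below 1 and the enhancer thresholds
read naturally as "ratio <= 0.5"; an `orientation` option flips the
convention (swapping strains maps every defined ratio r to 1/r).
Wild-type lethality is `clamp(1 - RF_wt_norm, 0, 1)`: normalized RF 1 is
typical plate viability, and the plate median is the only internal
reference available — no absolute brood-size standard exists across plates.

## Hit calling

Primary screen (one experiment, two technical replicates): exclusion first —
clones with wild-type lethality strictly above 0.9 are removed because the
ratio denominator is then a handful of survivors; applying exclusion before
any ratio rule is a deliberate ordering choice. Then inclusive thresholds:
enhancer at ratio <= 0.5, suppressor at ratio >= 1.5.

Secondary screen (three biological replicates): a cut-off percentage `c`
turns into the strict rule "enhancer iff ratio < 1 - c/100" (at 45%:
ratio < 0.55). The strict/inclusive asymmetry between the two stages is
intentional and tested. Suppressors get the symmetric strict rule
"ratio > 1 + c/100"; symmetry mirrors the primary 0.5/1.5 pair, since no
separate suppressor formula is established for the cut-off stage and
suppressors are not followed up further.

The cut-off is calibrated from controls pooled across the three
experiments. For each grid value (default 40, 45, ..., 70):

* FP% — share of negative-control ratios (empty vector, hil-5) below the
  enhancer threshold;
* FN% — share of positive-control ratios (dli-1) at or above it.

FP% is non-increasing and FN% non-decreasing in `c`; the chosen cut-off
minimizes |FP% - FN%|, with ties resolved toward the smaller (more
sensitive) cut-off. plk-1 is never used for calibration: it is an
RNAi-efficacy control, fully lethal in both strains, so it carries no
information about mutant-specific enhancement. Per-replicate calibration
tables are also computed for inspection, but the pooled table decides the
cut-off — three experiments' controls give three times the sample size for
the same decision.

Final hits must classify as enhancer in at least two of the three
experiments (`min_agreement = 2`); ND counts as absence of evidence, never
as an enhancer call. Clones that are enhancers in at least one experiment
are partitioned into the seven non-empty Venn regions over {E1, E2, E3};
the region counts must sum to that set's size. Finally, clones are
collapsed to unique genes by their primary target, keeping first-occurrence
order after sorting by plate and well (RNAi libraries contain distinct
clones targeting the same gene, so N final clones can yield N-1 genes).

## Synthetic screens

The generator emulates the screen's sampling hierarchy:

* parents ~ Poisson(`parent_mean` = 7, matching ~7 larvae per 10 µl of
  dispensed suspension) truncated to `parent_range` = (1, 14), so a
  realistic minority of wells falls outside the 2–12 QC window;
* expected progeny = parents x `baseline_brood` (30 viable progeny per
  parent under knockdown conditions) x gene viability x strain multiplier x
  a log-normal plate effect (`plate_effect_sd` = 0.15 on the log scale)
  drawn once per physical plate;
* progeny ~ negative binomial with that mean and gamma shape `dispersion`
  = 10 (CV ≈ 0.32 at typical means) — brood sizes are overdispersed
  relative to Poisson through worm-to-worm variation and developmental
  timing, and shape 10 represents that moderate overdispersion.

Effects are multiplicative on expected progeny, matching the ratio
statistic: planted enhancers (5% of clones) draw a mutant-only multiplier
uniform on [0.1, 0.4], suppressors (2%) uniform on [1.6, 2.4], and a small
fraction (2%) of broadly lethal genes draw a both-strain viability uniform
on [0, 0.08] to exercise the >90%-lethality exclusion. Controls follow the
column-1 roster; each dli-1 well position draws its mutant multiplier from
the *same* enhancer-effect distribution, fixed across replicates like any
clone property, so the control-based FP/FN forecast and the realized sample
error rates share one effect model — that sharing is what makes the
calibration-transfer check (agreement within ±5 percentage points)
meaningful. Technical replicates redraw counts and plate effects only;
biological replicates likewise redraw no clone properties, because effects
belong to the clone, not the experiment.

What the generator does not emulate: image segmentation errors, larvae
missed because developmental delay keeps their pharynx small (in real data
this depresses progeny counts and is a genuine hit mechanism), bacterial
growth failures, edge effects within a plate, and clone identity errors.
Passing recovery tests therefore demonstrates that the pipeline's
statistics behave as designed under the assumed noise model, not that real
screens achieve those sensitivity/FDR figures.

## Problem sizes and numerical choices

Recovery experiments use 10 plates x 88 clones (880 genes, 11,520 wells per
screen) over ten seeded screens — large enough that pooled sensitivity/FDR
estimates have standard errors of a few percent, small enough that the full
suite runs in seconds. Recovery runs set `lethal_fraction = 0`: a
secondary-stage clone population contains no broadly lethal clones by
construction, since the primary screen's exclusion rule removes them before
a secondary screen is assembled.

Threshold comparisons use plain floating-point inequalities on thresholds
of the form `1 - c/100`; boundary semantics (inclusive primary, strict
secondary) are asserted at the printed precision of the rules (0.5/1.5 and
0.55). Medians are numpy medians; the even-count median of normalized
values can differ from 1 by one ulp, so the median-equals-one invariant is
asserted at 1e-12. Well coordinates accept both "B8" and "B08" and are
normalized to the zero-padded form. Unparseable numeric cells in imported
tables become ND, never zero, so the parser can only lose, not invent,
measurements.

## Known limitations

* The published headline counts of the original genome-wide screen can only
  be recovered from the deposited raw spreadsheets, which are not shipped
  here; the package provides the re-analysis path (deposited-schema import
  plus threshold re-application) and verifies it on synthetic stand-ins.
* Primary-screen suppressor selection in the original workflow involved
  manual inspection beyond the ratio >= 1.5 rule; only the ratio rule is
  implemented.
* The exclusion rule keys on wild-type lethality relative to the plate
  median; on a plate where most sample wells are themselves sick, the
  internal reference shifts and exclusion becomes conservative.
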