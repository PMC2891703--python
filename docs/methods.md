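# Methods

## Scope and data model

The package implements the hit-calling computation of a three-phase RNAi
reporter screen. Measurements live in flat well tables (one CSV row per
well: plate id, row letter, 1-based column, reagent id, well role, firefly
signal, optional Renilla signal) wrapped by `ScreenDataset`, which adds the
stage (primary / secondary / tertiary), the stimulus condition, the plate →
replicate map, and invariant validation. Luminescence units are arbitrary
and never rescaled at parse time — every statistic downstream (Z-score,
firefly/Renilla ratio, percent of control) is scale-free, so normalisation
is always an explicit, inspectable step. Well addresses serialise as
zero-padded `A01`…`P24`, which sorts in plate order.

## Plate Z-scores (phase I)

For well *w* on plate *p*: `z_w = (x_w − mean_p) / sd_p`, with mean and SD
taken over all non-empty wells of the plate. Two conventions are
deliberately configurable because screening practice varies and the
original computation is under-documented:

* `ddof=1` (sample SD) by default — the common screening convention; at
  384 wells the difference from the population SD is ~0.1%.
* `include_controls=True` by default — the "whole plate" reading of the
  formula; excluding controls is available for robustness checks.

Degenerate plates (SD = 0, or fewer than 3 wells) are hard errors: a
Z-score is meaningless there and silent NaNs would propagate into calls. No
robust (median/MAD) variant is offered as a default; the plate statistic
here is mean/SD by construction, and a robust alternative would change the
meaning of the −2.5 cutoff.

Hit calling uses a fixed cutoff, default −2.5, strict inequality. The
default replicate rule is `any` (hit if either duplicate is below the
cutoff): the gene lists that feed the later phases were assembled under the
at-least-one-replicate criterion, while the replicate-mean view is the one
usually plotted; both are implemented and the choice is a flag. Because the
screen induces the reporter and looks for lost induction, only negative Z
matter; nothing is called on positive deviations.

An important behaviour of this normalisation, reproduced faithfully by the
simulator: the plate SD is inflated by whatever true effects sit on the
plate, so as the fraction of strongly affected wells grows past ~5–10%,
all Z-scores shrink toward the cutoff and sensitivity drops. This is a
property of the method, not a bug in the implementation.

## Exclusion filtering

Sequential set subtraction of named gene lists from the hit list, exact
string match after whitespace trimming, no synonym resolution (identifier
curation is out of scope; screens filter within one library's identifier
space). Per-list removal counts are taken on the running survivor set, so
counts always sum to input − survivors even when lists overlap; the
surviving *set* is order-invariant. Duplicated input ids are collapsed with
a warning rather than an error.

## Dual-reporter normalisation and classification (phases II/III)

Per well, `ratio = firefly / renilla`; a well with zero or missing Renilla
is a viability or measurement failure and is dropped (counted in
`n_failed_wells_`) or raised, never treated as an infinite ratio. Percent
of control is the ratio as a percentage of the mean GFP-control ratio **of
the same plate** — per-plate pooling is chosen (the pooling level is
otherwise unstated) because it makes the multiplicative plate factor cancel
exactly, which is the point of ratio + control normalisation. Percent
inhibition is 100 − percent of control; negative values (activation) are
retained in all tables but can never promote a hit.

Replicate wells are aggregated per amplicon as arithmetic mean and sample
SD (SD reported only for n ≥ 2). Classification is on the **maximum** of a
gene's amplicon means — the "at least one dsRNA" rule; single-amplicon
genes are classified on that amplicon alone. Thresholds are strict
(`> 50`, `> 75`) following the "more than 50%" / "over 75%" wording; an
`inclusive=True` option documents the alternative boundary reading. Strict
max-based thresholds make two properties hold by construction, and the
suite asserts both: labels are monotone non-decreasing in any amplicon's
inhibition, and every secondary hit (group A or B) is tertiary-positive on
identical inputs.

The tertiary candidate set is all group-A genes plus an explicitly
configured subset of group-B genes. That sub-selection was expert judgement
(functional relatedness to group A) in the screen this models, so it is
configuration, never inferred.

## qPCR and β-galactosidase

Comparative-Ct with tubulin as reference. Technical triplicates are
averaged on the Ct scale (standard Livak practice; the averaging scale is
otherwise unstated), ΔCt = mean Ct(target) − mean Ct(reference), and
relative expression is `2^−(ΔCt_sample − ΔCt_control)`. The base is exactly
2 — both target and reference reactions approach 100% efficiency on
standard curves — with `base=1+E` available for efficiency correction.

β-galactosidase activity comes from a CPRG colour-development time course
at 574 nm (typically t = 10, 30, 60, 120, 180 min): the heat-inactivated
background series is subtracted point-wise on the same time grid (grids
must match exactly; subtracting before fitting preserves the linearity
diagnostic), an OLS line of corrected OD vs time is fitted, and activity is
slope / µg protein. R² < 0.9 (configurable) sets a warning flag on the
result rather than failing: a noisy series is still a measurement. A flat
corrected series is reported as zero activity with R² treated as 1 (the
linearity check is about departure from a line, and a constant is one).

## The simulator: stated world and what it omits

Per sample well *w* on plate *p* for gene *g*:

    firefly(w) = P_p · F0 · I · (1 − e_g) · v_g · ε_w
    renilla(w) = P_p · R0 · v_g · ε′_w

* `P_p = exp(N(0, plate_effect_sd))`, one draw per physical plate
  (default SD 0.15 ≈ ±15% plate-scale variation).
* `F0 = 1000`, `R0 = 500` arbitrary-unit baselines; `I = 10` fold
  induction of the HRE reporter by the stimulus.
* `e_g` — reporter-specific knockdown: 0 for neutral genes and the GFP
  control, drawn from `hit_effect` (default uniform [0.5, 0.95]) for
  planted regulators, fixed at 0.9 for the positive-control dsRNA
  (matching the ~90% inhibition a HIF-alpha control shows).
* `v_g` — viability factor: 1 except for planted viability genes, where
  `1 − v_g` is drawn from `hit_effect` and multiplies **both** channels.
  This reproduces the confound that exclusion-list filtering and Renilla
  normalisation exist to handle: viability genes look like hits on the
  single-reporter phase but have unremarkable firefly/Renilla ratios.
* `ε, ε′` — independent mean-one log-normal noise with coefficient of
  variation `noise_cv` (default 0.2, which yields a replicate Z-score
  correlation around 0.6 on an otherwise-neutral screen — the agreement
  level a well-behaved duplicate screen shows). Multiplicative noise is
  chosen over additive Gaussian because luminescence is positive and its
  variability is fold-change-like.

Defaults describe a plausible well-behaved screen: 2 replicates, 5%
regulators, 5% viability genes, 4 control wells per role per plate spread
evenly through the plate (real control placement is unpublished, so it is
configurable). Replicates share the plate layout and gene effects and
redraw only plate factors and well noise. One root seed drives three
independent sub-streams (gene effects, plate factors, well noise), so the
planted biology for a seed is stable under changes to noise settings, and
the same seed gives a bit-identical dataset.

Not modelled: spatial edge/gradient artifacts, reagent carry-over,
off-target effects, dose-response. A green recovery test therefore
establishes that the pipeline's arithmetic and thresholds recover planted
effects under plate-scale and log-normal well variation — not that it is
robust to spatially structured artifacts, which would need a dedicated
correction this package deliberately omits.

## Numerical and design notes

* Plate Z-scores reproduce a brute-force two-pass mean/SD computation
  exactly and are affine-invariant to 1e−9.
* Fold-induction reciprocity (`f(a,b)·f(b,a)=1`) and ΔCt drift invariance
  hold to 1e−12.
* Boundary cases are strict everywhere (z exactly at the cutoff, inhibition
  exactly 50 or 75 → not a hit) and tested.
* The null hit rate of a no-effect screen under `rule="mean"` is *below*
  the Gaussian tail expectation at −2.5 (0.62% per replicate): the left
  tail of a mean-one log-normal is lighter than Gaussian. The suite asserts
  the bound, not equality.
* Pipeline runs are deterministic: identical config + seed give
  byte-identical per-stage TSVs and report JSON.
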