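# Methods

## Study design the package models

Two clones of one fungal strain — naturally infected with an endohyphal
bacterium (EHB+) and antibiotic-cured (EHB−) — are each inoculated onto five
replicate 96-well FF phenotype microarrays (95 carbon sources + one water
control). Plates are read at 490 nm and 750 nm every 12 h from day 0.5 to
day 7 (14 time points). All inference operates on this long-format table of
26,880 absorbance values per experiment.

## Channels and thresholds

The 750 nm read measures turbidity and is treated as growth. The 490 nm read
contains both turbidity and the signal of an irreversibly accumulating
formazan dye produced during respiration; since hyaline mycelium absorbs
evenly from 490 to 750 nm, the corrected respiration value is
A_c490 = A_490 − A_750. Corrected values may be negative under noise and are
kept as-is; clamping happens only where a downstream method requires
nonnegative input (Bray–Curtis), and the clamp count is logged.

Measurable growth is defined on the replicate-mean day-7 turbidity as
0.3 < Ā ≤ 3.0 — a strict lower bound separating lag-phase cultures from
those that reached log phase, and an inclusive upper bound at ~99.9% light
absorbance. Both bounds, the endpoint day and the significance level are
carried in one `GrowthThresholds` object (defaults 0.3 / 3.0 / day 7 /
α = 0.05) so sensitivity analyses change one value in one place. The
endpoint defaults to day 7 because the global strain effect is largest
there; it is configurable.

## Per-substrate inference and the census

Each substrate's day-7 means are compared by a two-sided Welch t-test on
summary statistics (scipy backend), reporting |t|, Welch–Satterthwaite df
and p. Benjamini–Hochberg adjustment (statsmodels backend) runs across
exactly the substrates where at least one strain is measurable; substrates
negligible for both strains are never tested and keep an absent adjusted p.
Absence is deliberately distinct from p = 1: the census must be able to tell
"tested, not significant" from "not tested".

Classification into the five outcomes uses only means, thresholds and the
adjusted p. The mirror of outcome 3 (cured strain measurable, infected
negligible) has no code of its own in the five-outcome scheme; it is
returned as code 4 with an explicit `mirror` flag rather than silently
folded in. A significant test with exactly equal means is an error, not a
tie-break — it cannot arise from real data at instrument precision.

The census is recomputed from the rules, never read off stored outcome
labels, so a printed summary table is a sufficient input. Two conventions
matter and are intentional:

* "EHB+ higher" includes outcome-3 substrates (the infected strain growing
  where the cured one does not is the extreme case of growing higher), so
  the directional counts partition the significant set.
* Percentages are whole percents of 95.

With these rules the packaged endpoint-table transcription yields
79 / 77 / 64 / 59 / 5 / 2 / 15 and 62% / 5% / 67%, with 16 substrates
negligible for both strains. One transcribed row (ethanolamine) carries a
printed outcome label ("1") inconsistent with its own printed means
(0.92 / 1.05, both measurable); the fixture preserves the printed label, and
the rule-based census classifies the row from its numbers, which is what
makes the headline counts internally consistent (16 + 15 + 64 = 95).

### Rounding-interval consistency

A summary table printed at two decimals hides the true means and SDs inside
±0.005 bands, so recomputing t and df from printed values need not hit the
printed statistics (for the strongest rows the point recomputation is off by
>10%). `welch_rounding_interval` computes the extreme t and df attainable
from any true values inside those bands (n = 5 per group): the t extremes
from the extreme numerator over the extreme pooled SE, the df extremes from
the SD-box corners, with the maximum 2n − 2 reachable exactly when the two
SD bands overlap and the minimum n − 1 reachable when a band touches zero.
Every row of the packaged table passes this check, i.e. the printed
statistics are jointly consistent with the printed summaries.

## Distance-based global statistics

At each time point the raw per-plate 750 nm profile over the 95 substrates
(water excluded by default; configurable) is the sample vector — no
standardisation is applied before Bray–Curtis, and this choice is exposed as
the matrix-construction options. Bray–Curtis, PERMANOVA, ANOSIM and MRPP
are implemented from their definitions in this package (they are its core);
scikit-bio's PERMANOVA and ANOSIM statistics and brute-force enumeration
oracles serve as independent cross-checks in the test suite only.

Conventions:

* Monte-Carlo p-values use (1 + #extreme) / (1 + n_perm), so p is never 0
  and the observed labeling counts as one permutation. Default
  n_perm = 1000.
* Exact enumeration (small N) enumerates all distinct assignments of the
  group-label multiset and reports #extreme / #labelings. Note that for two
  equal-sized groups the mirrored labeling always reproduces the observed
  statistic, so the smallest attainable exact p is 2/#labelings — e.g. 2/6 =
  1/3 for the 4-point worked instance, even though its observed partition is
  uniquely optimal.
* MRPP weights groups by n_g/N by default (the common community-ecology
  choice); (n_g−1)/(N−a) and pairs-based weights are available. E(δ) is the
  mean δ over the permuted (or enumerated) labelings.
* PERMANOVA reports F = +∞ when SS_within = 0 (perfect separation); the
  permutation comparison still behaves correctly.

Dendrograms use scipy's agglomerative linkage (UPGMA/average by default;
single and complete available). Trees are ultrametric — a cluster merged at
distance h sits at height h/2 — and children are ordered by smallest input
label index so output is deterministic under ties.

The global scan spawns one child seed per time point from the user seed, so
a 14-point scan is reproducible as a whole and per time point.

## Synthetic data generator

The generator emulates the study design, not any particular dataset. Each
substrate gets an archetype: planted outcome code plus logistic parameters
(baseline b = 0.1, rate r = 2 d⁻¹, midpoint t_mid = 3 d), with carrying
capacities encoding the outcome — equal K for "no difference", a gap of 0.3
absorbance units (the average day-7 difference observed on significantly
different substrates) for directional outcomes, K ≤ 0.15 for negligible
growth, K = 0 for the control. Base capacities are drawn uniformly from
[0.6, 1.8] so endpoints span the observed range while staying clear of both
growth bounds. The default outcome composition (17 negligible-both, 15
no-difference, 2 infected-only, 5 cured-higher, 56 infected-higher) echoes
the endpoint census mix of the study.

Observation noise is Gaussian with SD 0.03 (matching tight replicate SDs of
the endpoint table), truncated at zero because plate readers report
nonnegative OD. The redox channel is turbidity plus a gain (default 0.6)
times cumulative growth above baseline plus its own noise — the simplest
monotone coupling consistent with irreversible dye accumulation; its
noiseless corrected value is nondecreasing in time by construction.

What the generator does **not** emulate: spatial plate effects, edge
evaporation, batch effects between plates, non-logistic growth shapes
(diauxie, decline phase), heteroscedastic noise, or substrate-class
correlation structure. Passing recovery tests therefore demonstrates that
the pipeline's inference chain is correct under the declared noise model,
not that real plates meet that model.

## Problem sizes used in tests and the acceptance script

Planted-outcome recovery runs 10 seeded experiments at full design size
(5 replicates, 95 substrates); recovery is the fraction of the 950 planted
codes reproduced end-to-end (typically ≥ 99%, required ≥ 90%). Type-I
calibration of the global scan runs 20 seeded null experiments (equal
capacities in both strains) on a two-point time grid with 199 permutations,
counting day-7 PERMANOVA rejections at α = 0.05; the effect-trajectory check
runs one full 14-point scan. These sizes are the package's own defaults for
a thorough-but-quick validation; all of them scale up by changing one
argument.

## Known limitations

* The well-to-substrate map of the packaged layout is a convention
  (summary-table order, water last); physical well positions are not used by
  any computation.
* The packaged endpoint table stores printed precision only (two decimals);
  adjusted p-values printed as "<x" are carried as the bound x with the
  printed text preserved.
* No parametric growth-curve fitting is performed on observed data; curves
  are only generated.
* No ordination (PCoA/NMDS) or dispersion test (PERMDISP) is provided.
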