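# Methods

## Design and data model

The pipeline analyzes a factorial LFQ proteomics design: 2 strains × 2
conditions (control, induced) × 3 subcellular fractions (cytosolic,
membrane, extracellular) × n biological replicates (default 3).  The
canonical in-memory representation is a long-format pandas table with one
row per *detected* measurement (protein, strain, condition, fraction,
replicate, intensity, unique-peptide count).  Missing values are represented
by row absence, never by zeros: in LFQ data a zero means "not quantified",
and only the declared MaxQuant dialect maps zeros to absence on ingest;
anywhere else a non-positive intensity is a hard error.  Intensities are
stored linear and log2 is applied exactly once, tracked by a table-level
flag, so pre-logged supplementary-style exports cannot be double-logged.

## Qualification and presence calls

A protein qualifies in a (strain, fraction, condition) when it has ≥ 2
unique peptides (a protein-level property), is detected in ≥ 2 of the
replicates *of that condition*, and its localization class is compatible
with the fraction.  The default compatibility table maps Cytoplasmic →
cytosolic, CytoplasmicMembrane → membrane, Extracellular → extracellular,
and excludes Cellwall (no cell-wall enrichment is performed) and Unknown
everywhere; the table is a config-level object and can be overridden.  The
replicate rule is applied per condition rather than pooled across
conditions, because the ON/OFF definition needs a per-condition notion of
presence; this is one of the genuinely open readings and the alternative
(strict zero detections in the other condition) is available as
`strict_absence`.

ON means qualified under induction and not in the control; OFF is the
reverse; proteins qualified in both conditions ("both") proceed to the
fold-change test; everything else observed at least once is "neither".
These four calls partition the observed proteins of each (strain, fraction).

## Differential statistic and FDR

For "both" proteins the effect is the difference of mean log2 intensities
over detected replicates (induced − control).  Significance uses

    t_s0 = (mean_a − mean_b) / (se + s0),   s0 = 0.1 by default,

where se is the pooled-variance two-sample standard error (Welch by flag;
the pooled form is the default because the moderated statistic is
conventionally built on the pooled error).  s0 damps proteins whose tiny
variance would otherwise make trivial effects significant — the null
|t_s0| tail is governed by the Gaussian numerator once se + s0 is floored,
rather than by the heavy 4-df Student tail.

FDR is estimated SAM-style per (strain, fraction) block.  The permutation
unit is the replicate's condition label: an assignment selects which of the
n_a + n_b replicate columns count as "induced", shared by all proteins of
the block, and |t_s0| is recomputed for every protein under each
assignment.  For a threshold c,

    FDR(c) = mean over assignments of #{|t_perm| ≥ c} / #{|t_obs| ≥ c},

capped at 1; the significance threshold is the smallest observed |t| with
FDR ≤ the target (ties inclusive), and a protein's q-value is the minimum
FDR over candidate thresholds at or below its own |t|, which makes the
significant sets nest across FDR levels.

Numerical choices that matter:

* **Exhaustive enumeration.**  When the number of distinct label
  assignments C(n_a+n_b, n_a) is within the randomization budget (20 for a
  3-vs-3 design, budget 250), all assignments are enumerated instead of
  sampled; otherwise assignments are sampled uniformly with replacement
  with a seeded generator.
* **Null ensemble excludes the observed labelling.**  The observed
  assignment and its mirror image reproduce the observed statistics
  exactly and carry no information about the null.  Keeping them would
  give the FDR estimate a floor of 2/20 of the observed exceedance count
  in a 3-vs-3 design, which destroys all power whenever a substantial
  share of proteins is truly regulated.  They are therefore excluded (18
  informative assignments remain for 3-vs-3), in both exhaustive and
  sampled modes.
* **Missing replicates.**  Proteins need ≥ 2 finite values per group to be
  scored.  Under a permuted assignment a partially detected protein can
  drop below that; each permutation's exceedance count is rescaled by
  (number of observed-testable proteins) / (number valid in that
  permutation) so sparse permutations are not underweighted.
* **Nominal p-values** are empirical, pooled across the entire permutation
  null of the block, with add-one smoothing: p = (1 + #null ≥ |t|) /
  (1 + #null).  They are reported as −log10(p).
* **BH mode.**  `method="bh"` replaces the permutation machinery with
  two-sided Student-t p-values (pooled or Welch) corrected by
  Benjamini-Hochberg; the moderated t_s0 is still reported.  The two modes
  answer different readings of "FDR with randomizations" and both are
  exposed.

Fractions are tested separately and the results concatenated; nothing is
shared across blocks except the configuration.  Classification: ON/OFF from
the presence call; otherwise up (significant, positive difference), down
(significant, negative), or unchanged.

## Aggregation

Category paths (≤ 4 levels) are completed to exactly 4 levels by repeating
the deepest available label, so level-3/4 views retain proteins annotated
only at coarser levels.  Tallies count (protein, group) incidences — a
multi-category or multi-regulon protein increments every group it belongs
to — and a protein appearing in several fractions contributes once per
(strain, group) with its most extreme class (ON/OFF over up/down over
unchanged).  Strain-level "total altered" counts deduplicate proteins
across fractions (`per_fraction` disables).  Core-proteome analysis reports
all 15 exact-membership regions of the four qualified sets (2 strains × 2
conditions, union over fractions).  PCA QC runs on the complete-case
protein × sample matrix of one strain (samples are condition/replicate
columns) and reports the first two components, chi-square 95% confidence
ellipses per condition, and a separation verdict (between-centroid distance
> 2× mean within-condition spread).  The treemap export emits the weighted
hierarchy (node weight = descendant leaf count) with per-protein colors on
a symmetric orange/turquoise scale normalized by the largest |difference|,
and sentinel colors for ON (dark orange), OFF (dark turquoise), and
deleted/unidentified proteins (gray); the power-diagram layout itself is
deliberately out of scope.

## Secretome statistics

P_sec is computed on linear intensities: per replicate, 100 × (summed
intensity of qualified extracellular proteins with predicted Sec signal
peptides) / (summed intensity of all qualified extracellular proteins),
then averaged with an SD across replicates; a pooled-intensity variant
exists.  The denominator uses all qualified induced-condition proteins (not
only ON proteins) — the broader reading of "quantified".  Signal-peptide
calls are consumed from an input table; no prediction is performed.
Mislocalization lists signal-peptide proteins qualified in the cytosolic or
membrane fraction under induction but not extracellularly.

## Live-cell array

Background fluorescence is the per-time-point mean GFP of the designated
reporter-free control wells (background grows with biomass, so a scalar
subtraction would be wrong); OD600 enters the TAU denominator raw, with no
blank subtraction, since blanking information is usually absent from plate
exports.  TAU is undefined at the first time point (absent, not zero), and
negative values are preserved.  Per-strain summaries are time-resolved
mean ± SD over wells and the area under the mean profile.

## Synthetic-data generator

The generator emulates: log-normal protein abundances (log2 baseline mean
27, SD 2 — the typical span of MaxQuant LFQ intensities), replicate noise
of 0.5 log2 units, condition effects as ±2 log2 shifts for up/down
proteins, logistic intensity-dependent detection (midpoint log2 22, slope
1) so low-abundance proteins drop out first, ON/OFF proteins whose
detection probability is forced to zero in the excluded condition,
unique-peptide counts drawn once per protein (evidence is a protein
property), localization classes at 60/20/12/4/4% (cytoplasmic / membrane /
extracellular / cell wall / unknown) with measurements placed in the
compatible fraction, signal peptides on 80% of extracellular and 3% of
other proteins, and synthetic 4-level category paths plus regulon
assignments (signal-peptide proteins additionally join a "Secreted
proteins" category).  The plate generator grows wells logistically
(OD 0.05 → 1.5) and accumulates reporter GFP by activity × OD per step, so
with zero noise the TAU computation returns the injected activity exactly
from the second time point on; control wells carry only the shared
background (constant + OD-proportional).

What the generator does *not* emulate: peptide-level quantification and
protein inference, correlated replicate effects (batch structure),
between-fraction cross-contamination, saturation or dynamic-range
compression, and match-between-runs artifacts.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated generative assumptions, not performance on any particular
real data set.

## Verified guarantees and problem sizes

The acceptance suite checks, at these sizes: exact agreement of the
exhaustive 18-assignment FDR with an independent brute-force oracle (10
proteins, 3 vs 3); a false-positive fraction within binomial error of 0.05
under a global null (1000 proteins × 20 seeds); ON-recall ≥ 0.9 among
filter-eligible proteins (2000 proteins); the s0 = 0 reduction to the
classical pooled t and monotone damping in s0; the hand-computed 72.0%
three-protein Sec proportion with scale invariance and [0, 100] bounds; and
exact TAU recovery of a constant injected activity.  Parameter recovery on
spike-ins (2000 proteins, 10% regulated at 2 log2 units, replicate SD 0.5,
3 + 3 replicates) achieves mean sensitivity ≈ 0.72 at a realized
false-discovery proportion ≈ 0.05 over 10 seeds.  A stricter target of
sensitivity ≥ 0.9 at FDP ≤ 0.1 is not attainable under these conditions by
*any* thresholding of |t_s0|: an oracle threshold with access to the ground
truth that spends the entire FDP ≤ 0.1 budget reaches only ≈ 0.85 mean
sensitivity, because with 4 error degrees of freedom the null and
alternative |t_s0| distributions overlap too much.  The corresponding
acceptance test asserts the stricter target and is expected to fail; it
documents the power ceiling of the 3-replicate design rather than an
implementation defect (BH on Student-t p-values is far weaker still,
sensitivity ≈ 0.08 under the same conditions).

## Limitations

No missing-value imputation, no empirical-Bayes variance moderation beyond
the additive s0, no protein-group collapsing, no enrichment p-values for
the category tallies, no growth-model fitting or fluorescence-maturation
correction in the plate module, and no treemap layout computation.
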