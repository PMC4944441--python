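# Methods

This note documents the statistical machinery, the synthetic cohort
generator, and the numerical choices made where the design was open.

## Preprocessing

Count tables carry QIIME-1-style lineage strings
(`k__;p__;c__;o__;f__;g__`). The canonical order of operations is:

1. **Depth exclusion.** Samples with fewer than `min_reads` (default
   3000) total reads are dropped; the threshold is exclusive, so a
   3000-read sample is kept.
2. **Genus collapse.** Rows sharing the lineage truncated at the
   genus rank are summed. Genus identity is the *full* truncated
   lineage, not the bare genus name: an unnamed `g__` genus of
   Enterobacteriaceae and one of Lachnospiraceae remain distinct taxa.
3. **Relative abundance.** Each sample is divided by its total.
4. **Prevalence filter.** A genus is kept iff its maximum per-sample
   relative abundance is strictly greater than the threshold (default
   0.15 %). The filter is applied after depth exclusion and genus
   collapse, and is idempotent.

## Per-sample metrics

**Shannon diversity** H = −Σ pᵢ log pᵢ, log base 2 by default (bits);
natural log available and recorded in output.

**MD index** = log10 of (summed relative abundance of
increased-in-CD taxa + ε) over (decreased-in-CD taxa + ε).
Membership is matched per lineage field against rank-prefixed names
(`f__Enterobacteriaceae`), case-sensitively, after trimming
whitespace; the Veillonellaceae exclusion means a lineage under
Clostridiales;Veillonellaceae is *increased*, never decreased, so the
two sets are disjoint by construction. The pseudocount ε = 1e-5 (on
the relative-abundance scale, in both numerator and denominator)
keeps the index finite when either set is absent; the index is
scale-invariant in the raw counts. Because both sums are additive
over taxa, OTU-level and genus-collapsed input give identical values.

**Rarefaction robustness.** Each sample can be subsampled without
replacement (multivariate hypergeometric) to a fixed depth (default
3155), the metric recomputed, and the median over many replicates
reported (default 10,000). Draws are vectorized; each sample's
stream is derived from `(seed, stage, sample id)` so results do not
depend on sample order. Samples shallower than the target depth get
missing medians rather than an error at the cohort level.

## Weighted GEE

Linear model, identity link, independence working correlation. With
clusters (subjects) i: β solves Σᵢ Xᵢ′Wᵢ(yᵢ − Xᵢβ) = 0, i.e. weighted
least squares; the cluster-robust covariance is B⁻¹MB⁻¹ with
B = Σᵢ Xᵢ′WᵢXᵢ and M = Σᵢ Xᵢ′Wᵢeᵢeᵢ′WᵢXᵢ. Observation weights default
to 1/(cluster size), so every subject contributes total weight 1
regardless of visit count; the sandwich is invariant to rescaling all
weights. Wald tests are two-sided χ²₁ on (β/se)². No small-sample
degrees-of-freedom correction is applied; consequently, empirical
type-I error at nominal 0.05 sits near 0.06–0.07 with 30 clusters
(verified by simulation), and 95 % CIs under-cover mildly when a
group contributes ≲15 clusters — worth remembering when reading the
UC contrasts of small cohorts. Rows with missing response or
covariates are dropped listwise and logged; indicator columns for
empty groups are dropped with a warning rather than failing the fit.

The model suite covers: marker ~ diagnosis (average group
differences); marker ~ diagnosis + time (baseline contrasts, time
since enrollment as covariate); + diagnosis×time (trend differences);
and marker-on-marker models (calprotectin ~ MD index, calprotectin ~
activity index, etc.). The genus screen fits abundance ~ contrast
(+ time) per genus on the untransformed frequency scale by default —
no transformation is prescribed — with arcsin-√ and log+pseudocount
variants exposed as options; the responder screen is emitted both
with and without the time covariate.

## Weighted UniFrac and PERMANOVA

Raw weighted UniFrac: Σ over branches of branch length × |difference
in the fraction of each sample's reads descending through that
branch|. The raw (non-normalized) form is the default; the
normalized variant divides by the abundance-weighted mean
root-to-leaf depth of the pair. Implementation flattens the tree to
a branch×taxon incidence matrix, so distance matrices are a few
matrix products; it matches scikit-bio's weighted UniFrac to
machine precision and reduces to the L1 distance on a unit star tree.

PERMANOVA Gower-centers −½D² and attributes sequential (Type-I) sums
of squares to each term via the projection span it adds; pseudo-F
uses the full-model residual mean square. Responder status is
entered before IBD subtype, matching the pooling question the
partition answers. Permutation p-values jointly permute factor rows,
use the add-one convention (1 + #{F* ≥ F})/(1 + n), and compare F
with a 1e-8 relative tolerance so permutations that recreate the
observed partition count as ties rather than falling on either side
of floating-point round-off. Agreement with R vegan `adonis2`
(by="terms") is exact on fixtures.

## Random forest

Cost-sensitive CART: per-class weights (inverse class sizes,
normalized to sum to 2) enter both the Gini split criterion and leaf
voting; with equal classes the criterion reduces algebraically to
plain Gini. Trees grow to purity or exhaustion; `mtry` features
(default ⌊√p⌋) are drawn uniformly per node; split thresholds are
midpoints of adjacent sorted values; candidate ties break to the
lowest feature index, so fits are deterministic given the seed. Two
sampling modes: a full bootstrap of all n samples (imbalance handled
by the class weights) and a balanced subsample of n-per-class draws
with replacement per tree. Evaluation is out-of-bag: each sample is
scored by the fraction of trees where it was out-of-bag that vote
responder; predicted responder iff that fraction ≥ 0.5, with the tie
going to the (rarer) responder class. Gini importance per feature is
the node-weighted impurity decrease summed over its splits, averaged
over trees. The tree grower is a numba kernel (~10 µs/tree on
17×134 data) because permutation calibration refits the entire
forest per label shuffle; permutation runs default to 501 trees per
refit (the full 25,001-tree mode is a flag), and p-values use the
add-one convention. ⌊√134⌋ = 11; rounding up to 12 is available via
the `mtry` option since either convention appears in practice.

## Synthetic cohort generator

The generator emulates a treatment-naïve pediatric IBD cohort:
10 controls (6 familial, 4 unrelated), 15 CD (6 responders, 9
non-responders), 4 UC (non-responders), visit counts uniform on
1–12 (median ≈ 6) over 240 days of follow-up, lognormal sequencing
depths with median ≈ 66,000 reads floored at 3,155.

**Composition model.** Logistic-normal/softmax over a fixed
165-genus panel (35 named genera spanning the MD-index membership
sets plus Akkermansia-, Adlercreutzia-, Coprococcus-, Dialister-like
signature taxa, and 130 geometric-tail filler genera in common gut
families). Per sample: log-abundance = panel baseline + disease
offset + responder offset + per-subject random effect (σ = 0.4) +
per-visit noise (σ = 0.25); counts are multinomial at the drawn
depth. Disease offsets act *uniformly* (in log space) on the
increased-in-CD taxa: ln10×0.86 for CD, ln10×1.75 for UC. Because
the within-set weight profile is unchanged, the group contrast of
the MD index is exactly the configured offset, and the lognormal
noise bias cancels between groups — this is what makes the
generator→estimator recovery loop exact. Offsets fade linearly to
60 % of their baseline value over follow-up (dysbiosis improves but
persists); a linear ramp rather than an exponential was chosen so
the t = 0 contrast stays exactly identifiable by the group main
effect of a group + time + group×time GEE.

The panel baseline is calibrated once to the target control
conditions: control MD index ≈ −1.85 and Shannon ≈ 6.0 bits. Case
Shannon deficits are qualitative only (≈0.1–0.5 bits): pushing them
to the multi-bit deficits of real cohorts would require compositional
concentration that breaks the exact MD offsets, and no test depends
on Shannon magnitudes.

**Responder signature.** Non-responders carry log-fold offsets on the
signature genera (Coprococcus, Roseburia, Lachnospira, Blautia,
Dorea, Faecalibacterium, Adlercreutzia down ≈ 0.5–0.9; Akkermansia,
Veillonella, Dialister, Fusobacterium, Enterobacteriaceae up ≈
0.5–1.0). Part of this signature lies inside the increased-in-CD
set, so it adds ≈ +0.15 to the pooled CD group's MD contrast — a
deliberate property of the biology being emulated. Recovery
harnesses that target the *group* offsets therefore set
`responder_effect_scale = 0` to isolate them; classification tests
use the full signature.

**Calprotectin.** cal = 42 + 260 × (sample's realized MD index −
control reference MD) + subject effect (σ = 25) + residual (σ = 35),
truncated at 0. Tying calprotectin to the realized MD index gives
the marker~marker GEE a well-defined true slope of 260 µg/g per MD
unit; truncation affects < 1 % of the slope (verified by the coverage
harness). Direct group offsets beyond the MD link (`cal_extra_cd/uc`,
default 0) allow constructing cohorts with a prescribed total
baseline contrast (e.g. 313 µg/g for CD). The Gaussian noise is a
modeling convenience — real fecal calprotectin is strongly
right-skewed — and a lognormal option exists. PCDAI/PUCAI-like
activity scores are a noisy monotone transform of the calprotectin
rank among case samples.

**Tree.** A star phylogeny with unit branches over the panel, so
weighted UniFrac is analytically the L1 distance while still
exercising the tree code path. Note the synthetic UC/CD
compositional separation is larger than in the real cohort the
generator imitates, so the PERMANOVA subtype fraction comes out
higher than the published 4 %-style values.

**What passing tests show.** The generator reproduces the cohort's
reported *statistical structure* (group sizes, visit counts, depths,
MD levels and offsets, the calprotectin–dysbiosis link, a learnable
pretreatment responder signature). It does not model real-data
features such as OTU-level richness, skewed marker distributions,
antibiotics/diet covariates, or compositional correlations beyond
the subject random effect — so green tests certify the estimators,
not clinical effect sizes.

## Determinism and seeds

A single master seed; every stochastic stage derives its stream from
`(seed, stage name)` (CRC-tagged `SeedSequence`), so adding or
reordering stages never changes another stage's draws, and pipeline
reruns are byte-identical. The forest kernel seeds numba's internal
RNG per fit with a 31-bit child seed.

## Problem sizes used in the shipped checks

Calibration tests use: 2,000 null datasets of 30 subjects for Wald
type-I error; 100 default cohorts of 40 subjects for calprotectin
slope coverage; 100 cohorts at 3× scale for MD-offset recovery;
500 datasets × 199 permutations for PERMANOVA null uniformity; and
100 replicates of 501-tree forests × 200 permutations for the
permutation-p uniformity of the classifier. `scripts/acceptance.py`
runs rarefaction medians at 1,000 replicates per sample and the
forest permutation null at 1,000 shuffles of 501-tree refits.

## Known limitations

- No non-independence working correlations, GLM families, or
  multiple imputation; missing markers are dropped listwise.
- Sandwich CIs under-cover below ~15 clusters (no df correction, by
  design); interpret small-group contrasts accordingly.
- Unweighted UniFrac, ordination, and blocked permutations are out
  of scope.
- The forest offers no probability calibration or cross-validated
  model selection; evaluation is OOB only, which is the right tool
  at n ≈ 17 but optimistic if hyperparameters were tuned (they are
  fixed here).
- When a subject has several samples flagged pretreatment the
  earliest is used; the flag itself is never inferred from times.
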