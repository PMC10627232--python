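# Methods

`seqrubric` scores and ranks candidate MRI sequences for a segmentation
task from co-registered volumes and multi-observer contours.  This note
documents the models and procedures implemented, the defaults and why,
what the synthetic phantom does and does not emulate, and the numerical
choices that would otherwise be invisible.

## The unit of analysis

Every metric is computed per *sequence-structure pair*: one anatomical
structure as it appears on one candidate sequence.  Paired organs
(parotids, pterygoids) are treated as single structures — left and right
values pool into one sample before statistics, matching the single
per-organ columns of the final score table.  Pooled values are treated
as independent observations in the statistics layer; the sample-size
bookkeeping below makes the effective n of each metric explicit, and the
repeated-measures structure (same subjects, same observers across
sequences) is deliberately not modeled.

## Quantitative metrics

**SNR** of a pair is the mean signal under the structure segmentation
divided by the sample SD (ddof = 1) of a dedicated noise ROI — an
air-filled cavity, taken over 10 axial slices.  Observer ROIs are merged
with multiplicity (the mean over all (observer, voxel) samples), so
duplicated contours change nothing and larger contours weigh more.  One
value per subject enters statistics.  **Fat SNR**, the same quantity on
the fat reference mask, measures residual fat signal and is scored
lower-is-better; it is structure-agnostic and its score is broadcast to
every structure.  **CNR** is the signed SNR difference against the fat
or muscle reference; the muscle reference is the pterygoid pair, so CNR
vs muscle is omitted for the pterygoid itself (identically zero).

**Conspicuity** is slice-wise contrast over surround complexity.  From
each observer mask a family of spacing-aware 3D Euclidean morphs is
built (contract/expand by 1 and 2 mm; nesting is guaranteed by
construction from shared distance transforms).  Per axial slice occupied
by the structure:

    conspicuity = |mean(core) − mean(ring)| / SD(ring)

with core = the 1 mm contraction (a guard band against partial-volume
boundary voxels) and ring = the 1–2 mm expansion shell.  The literature
offers several contrast/complexity variants; this concrete reading is
isolated in one function (`slice_conspicuity`) so it can be swapped.
Slices where the core vanishes or the ring has fewer than two voxels are
skipped and logged.  A complexity floor of 1e-6 × the volume's intensity
range caps the ratio on noiseless synthetic input instead of dividing by
zero.  Values pool across slices, observers and subjects per pair, then
pass the inner-percentile filter.

**Pairwise agreement.**  With no ground truth, segmentation quality is
inter-observer precision: for every unordered observer pair, the Dice
coefficient 2|A∩B|/(|A|+|B|) and the 95th-percentile Hausdorff distance.
Surface voxels are mask voxels with a face neighbor outside; distances
are voxel-center to voxel-center in mm; the 95th percentile of the
concatenated bidirectional distance vector uses linear interpolation
between order statistics (fixed for bit-stability).  Dice is
higher-is-better, HD95 lower-is-better.

**Qualitative feedback.**  Observers rank the S sequences per structure
(grade 1 = most preferred); grades become higher-is-better scores
S + 1 − rank, pooled over observers × subjects.  The comment metric per
(sequence, structure, subject) is (n_positive − n_negative)/n_possible
∈ [−1, 1], where n_possible counts observers who left any comment;
neutral comments sit only in the denominator (a neutral baseline
opinion).  One value per subject.  Classifying free text into
positive/neutral/negative is out of scope; the package consumes
pre-tallied categories.

## Pooling and the outlier filter

Slice-wise and pairwise stacks are trimmed to the symmetric inner 90%
percentile band before testing (`inner_fraction` configurable).  A value
survives when its mean percentile rank lies in [5, 95] inclusive; for
the integers 1..100 the survivors are exactly 6..95.  Tied values keep
or drop together, so retention can deviate from 0.9 n by up to the
largest tie group.  The filter marks the sample as filtered and is a
no-op thereafter (idempotent at the sample level).  Per-subject metrics
(SNR, CNR, comment metric) and grades are not filtered.

## The statistics gate

Per (structure, metric), sequences are compared as independent groups:

1. **Normality screen** — Kolmogorov–Smirnov against a normal with
   sample-estimated mean and SD, i.e. the Lilliefors correction (the
   population parameters are never known in practice).  Parametric only
   if every group passes at α = 0.05; groups smaller than 4 or constant
   force the nonparametric branch with a warning.
2. **Parametric branch** — means ± SD, one-way ANOVA omnibus, Tukey HSD
   pairwise p-values.  The studentized-range tail probability uses the
   standard `psturng` approximation (p clipped to [0.001, 0.9]), which
   agrees with exact quadrature far beyond what a 0.05 threshold needs
   and is orders of magnitude faster; a unit test cross-checks it
   against the exact implementation.
3. **Nonparametric branch** — medians and IQRs, Kruskal–Wallis omnibus,
   Dunn pairwise z-tests on mean ranks with the standard tie correction.
   The multiplicity family for Dunn is Bonferroni over all C(S, 2) pairs
   by default (`holm` and `none` available).
4. **Omnibus gating** — pairwise findings are honored only when the
   omnibus test is significant at α, mirroring the "follow-up" structure
   of both procedures; configurable off.  All-identical data degenerates
   to p = 1 everywhere.

Monte-Carlo calibration (in the test suite): under a 4-group Gaussian
null with n = 25, the probability that any corrected pairwise comparison
fires is ≈ 0.04 (the family these corrections control at α = 0.05); power
at a 10-pooled-SD two-group separation is ≈ 1.

## The scoring rubric

Scores live on [1, S], S = number of sequences, best = S.

1. **Gated metric scores.**  Sequences are ordered best→worst by central
   tendency (mean or median per the branch) under the metric's
   direction.  A tier boundary between ordered positions i and i+1 is
   placed only when *every* sequence at or above i is pairwise
   significant against *every* sequence at or below i+1 — the strong
   reading of "better only if significant against all lower-scored
   pairs", and the only order-consistent one that yields a constant row
   when nothing separates.  Tier members share the mean of the ranks the
   tier spans, so {best significant vs all, rest inseparable} gives
   {4, 2, 2, 2}.  Missing p-values count as non-significant and are
   logged.
2. **Tie rescaling** maps any descending-tier raw vector to average
   ranks ({4, 2, 2, 1} → {4, 2.5, 2.5, 1}); every stage therefore
   conserves the rank mass S(S+1)/2 across sequences.
3. **Category normalization.**  Metric scores are summed per category
   (SNR/CNR, conspicuity, pairwise distance, segmentor) and re-ranked
   across sequences within each structure, so categories with many
   metrics weigh the same as categories with one.
4. **Totals.**  Category scores sum to the total score per pair;
   totals re-rank within structure to the normalized total.
5. **Combined scores.**  Totals sum across structures to the combined
   total.  For the final rank two readings exist: ranking the per-
   sequence *sums of normalized totals* versus ranking the combined
   totals directly.  The two can disagree (structures with large raw
   total spreads dominate the second).  The first is the default —
   applied to the bundled worked example it reproduces the published
   combined row exactly, which the second does not — and both are always
   reported side by side (`combined_normalized`,
   `combined_normalized_by_total`).

Multiplicative weights (default 1) apply at the three summing joints:
per metric, per category, per structure.  Whether the qualitative
metrics should bypass the significance gate is under-determined; the
same gate applies uniformly (in practice grade/comment samples rarely
separate, yielding the constant 2.5 row).

## The synthetic phantom

The generator emulates the study conditions end to end: by default four
candidate sequences (one nonsuppressed, three SPAIR-like), five
subjects, five observers.  Geometry is an axis-aligned ellipsoid layout
placed as fractions of the field of view (central GTV, paired lymph
nodes, parotids, pterygoids), a tubular air cavity and an edge fat slab
on a uniform background; the default grid is 64×64×40 at 1 mm.  Voxel
intensity is the containing region's mean plus zero-mean Gaussian noise
(per-sequence SD); the fat mean is scaled by the sequence's
fat-suppression factor (1.0 nonsuppressed, 0.04–0.06 SPAIR-like).
Tissue means (background 35, structures 45–70, fat 90, noise SD 6–9 in
arbitrary signal units) were chosen once as realistic T2w magnitudes
giving structure SNRs around 5–12 and a strongly suppressed fat signal,
comparable to the regime the pipeline targets.

Observer contours derive from the ground truth by a signed boundary
morph with radius ~ N(0, 1 mm) plus a voxel-rounded translation
~ N(0, 0.5 mm) per axis; a jitter that empties a mask is retried with
the radius halved (logged).  Qualitative feedback draws one comment
category per record from per-sequence (positive, neutral, negative)
probabilities and derives grades from a latent preference plus taste
noise.  A single seed drives everything; identical configs and seeds
reproduce the study bit for bit.

Deliberately **not** emulated: MRI physics (k-space, coil profiles,
B0/B1 inhomogeneity, burnout, Rician magnitude statistics, artifacts),
anatomical variation between subjects, spatially varying noise, and
systematic inter-observer bias.  Passing phantom tests therefore
demonstrates that the metrics, statistics and rubric do what they claim
on data with known truth — not that any particular clinical sequence is
superior.  The Gaussian (not Rician) noise choice keeps the SNR oracle
exact, and nothing downstream assumes a noise family.

## Problem sizes used in the checks

Monte-Carlo and end-to-end checks run on reduced-size phantoms chosen as
adequate for their statistical question: parameter-recovery studies use
a 40×40×28 grid at 1.25–1.5 mm with 5 subjects and 3 observers; the
100-seed ranking-recovery study (a sequence constructed with a 10×
contrast advantage must win the combined normalized score in ≥95% of
seeds) uses 36×36×24 at 1.5 mm, 5 subjects, 3 observers.  Tolerances are
3 standard errors for mean/SD recovery, 10% for the fat-suppression
factor, and strict ordering for jitter-level medians.

## Known limitations

* The conspicuity formulation is one admissible contrast/complexity
  reading; alternatives (gradient-based complexity, psychophysical
  weighting) are out of scope.
* No registration or resampling: all inputs must share one lattice.
* Independence is assumed across pooled values; crossed observer/subject
  random effects are not modeled.
* HD95 uses voxel-center surface points; sub-voxel surface meshes would
  differ by up to about half a voxel diagonal.
* `psturng` clips extreme Tukey p-values to [0.001, 0.9]; only the
  position relative to α matters downstream.
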