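# Methods

## Preprocessing model

A qPCR array measurement is a cycle threshold Ct (cycles); a single target
molecule corresponds to Ct ≈ 35, so Ct strictly greater than 35 is treated
as "not expressed" (the boundary value 35.0 itself counts as detected).
After censoring, miRNAs detected in at least `min_samples` samples
(default 10) are retained; the filter is applied before normalization so
that the analysis set is fixed once.

Global-mean centering subtracts each sample's mean Ct from all of that
sample's values, removing multiplicative loading/efficiency artifacts that
appear as additive Ct shifts. The sample mean is computed over **detected
entries only**: censored values sit at or above the detection limit and
would bias the mean upward. Undetected entries that survive the filter are
imputed at the detection limit (Ct = 35) before centering and flagged;
this is a conservative limit-of-detection floor that keeps two-group tests
defined for miRNAs detected in as few as 10 of 34 samples. A
`undetected="drop"` switch leaves them missing instead.

The normalized relative quantity is `NRQ = 2^(Ctmax − Ct)` with Ctmax the
per-miRNA maximum *centered* Ct across all samples in the analysis set.
Two invariants follow by construction and are asserted in tests: every
NRQ ≥ 1 with per-miRNA minimum exactly 1, and the final NRQ matrix is
invariant to arbitrary per-sample global Ct shifts — the property the
normalization exists to provide. The invariance is exact only while no
value crosses the censoring limit; once a shift pushes values past Ct 35,
censoring and imputation legitimately change the result.

## Differential expression

Per miRNA, a two-sided Wilcoxon rank-sum test compares NRQ between the two
sample classes. Two p-value routes:

- **exact** — enumerate all C(N, n₁) assignments of the pooled values to
  the group sizes, with ties handled by mid-ranks fixed on the pooled
  sample; the two-sided p is P(|W − E[W]| ≥ |w_obs − E[W]|), where W is the
  group-1 rank sum. This reproduces, e.g., p = 0.1 for [1,2,3] vs [4,5,6].
- **approx** — normal approximation with tie-corrected variance
  `n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]` and a 0.5 continuity correction.

`auto` uses exact for N ≤ 12 and approx otherwise; with the default 22-vs-12
design the approximation is used, and tests verify it agrees with exact
enumeration to < 0.01 at n ≥ 15 per group. If all pooled values are equal
the test is degenerate and returns p = 1 with a warning.

Bonferroni adjustment multiplies by the number of retained miRNAs (capped
at 1); "significant" throughout means adjusted p < α = 0.05. Fold change is
the ratio of group arithmetic means of NRQ (the ratio-of-medians alternative
was considered and not adopted: with NRQ floored at 1 and heavy censoring,
medians collapse to the floor more readily than means). A call is Up when
adjusted p < α and log2FC ≥ 1 (2-fold), Down for the mirror case, else NS.
Any two-class contrast (tumor vs control, genotype subgroups, amplified vs
non-amplified) uses the same operation with a different grouping.

The comparative-Ct utility for single-gene qPCR computes
ΔCt = Ct(target) − Ct(reference gene), ΔΔCt against the arithmetic-mean ΔCt
of a calibrator group, and relative expression 2^(−ΔΔCt); the calibrator's
geometric mean is 1 by construction.

## Homology and concordance

Mature miRNAs (~22 nt) are paired across species only on perfect identity
of the normalized mature sequence (uppercase, T→U) in both length and
nucleotides. A sequence shared by several mature names yields one pair per
cross-species name combination; `count_conserved` exposes per-name
(default) and per-sequence counting, since a conserved-miRNA total depends
on that convention. The seed region is defined as nucleotides 2–8
(1-based), the common convention for the target-recognition element.
Name-based pairing exists as a clearly labelled fallback for sequence-less
platforms and is never used by default.

Concordance: for each conserved miRNA DE in mouse and reported by at least
one human study, the row is Concordant iff every reporting human study
agrees with the mouse direction. If the human studies disagree among
themselves the row is flagged `conflict_within_human` and counted
Discordant regardless of the mouse call, so that a true within-human
conflict can never inflate the concordant count.

The overlap of two DE lists in a universe of N conserved miRNAs is tested
with the upper-tail hypergeometric probability, evaluated in log space
(gammaln + logsumexp) and agreeing with exact rational arithmetic to
1e−12 relative error for N ≤ 60. The universe is a **required explicit
argument**: the same overlap (29 shared miRNAs, universe 296) is extremely
enriched when both lists are the conserved DE subsets (63 vs 63,
p ≈ 4e−7) and not enriched at all against a 159-member list — silent
defaulting would hide a decision that flips the conclusion. The pipeline
exposes `conserved_measured` (conserved miRNAs measured on both platforms;
the recommended choice) and `conserved_all`.

## Clustering and PCA

Sample distance is d = 1 − Spearman ρ between expression profiles;
agglomeration is complete linkage (scipy), deterministic given input
order. Cutting the top merge yields two branches; branch 1 is the one
containing the first sample in input order, making runs bit-reproducible.
Branch composition against a binary class is tested with the Pearson χ²
statistic on the 2×2 table (1 df). No continuity correction by default —
expected counts in such tables can be small, so a Yates flag is provided
and documented rather than silently applied.

Because Spearman distances depend only on within-sample ranks, the tree is
invariant to any strictly monotone transform of expression; the choice of
transform therefore only matters for PCA. The default is log2(NRQ)
(variance-stabilizing; NRQ ≥ 1 keeps it defined), with raw NRQ and
centered Ct as alternatives. PCA is the SVD of the per-variable centered
samples×miRNAs matrix with no unit-variance scaling; loadings are
orthonormal, explained-variance fractions are non-increasing and sum to 1,
and each loading column's largest-magnitude element is made positive so
signs are reproducible. miRNAs are ranked by absolute loading (ties broken
by name) to identify the variables driving a component, and the overlap of
two components' top-n lists is reported on request.

## Synthetic data: what it emulates and what it does not

The generator draws per-miRNA baselines uniformly from 20–34 cycles,
per-sample global shifts Normal(0, 1 cycle), i.i.d. Gaussian Ct noise
(default σ = 0.5 cycles), plants group effects as Ct displacements (an
over-expressed miRNA is *lower* in Ct by `effect_log2fc` cycles, so the
Ct → NRQ → fold-change chain is exactly invertible in the noiseless
limit), and censors Ct > 35 as Undetermined. Defaults mirror the profiled
design: 591 miRNAs, 22 tumors vs 12 adrenal controls, 81 up + 78 down
planted at |log2FC| = 2. Two-species mode adds a human cohort (36 vs 110),
synthetic 22-nt mature sequences identical exactly for the planted
conserved set (all others globally unique, so the homology map recovers
the planted truth), and 29 conserved DE miRNAs of which 7 are
direction-flipped in human — a 22/7 concordant/discordant split.

What it does **not** emulate: correlated noise between miRNAs (real
polycistronic clusters co-vary), amplification-efficiency differences,
batch structure beyond a single global shift, heavy-tailed outliers, or
biological heterogeneity within classes. Passing recovery tests therefore
demonstrates that the statistical chain is implemented correctly and has
the expected operating characteristics under its own assumptions — not
that real tumor data would be recovered at the same rates.

One deliberate subtlety: with asymmetric planted DE (81 up vs 78 down),
global-mean centering leaks a small (~0.014 cycle) systematic shift into
every null miRNA. At near-zero noise the rank test can detect this
perfectly consistent shift, but the > 2-fold gate correctly leaves such
miRNAs NS. This is a real property of global-mean normalization under
asymmetric deregulation, not an artifact of the generator, and is why the
fold-change gate belongs in the DE definition.

## Numerical and design choices

- Exact Wilcoxon enumeration is refused above 5·10⁵ assignments; `auto`
  switches to the approximation at N > 12.
- Hypergeometric tails, Bonferroni caps and χ² tail probabilities are
  clipped to [0, 1]; k = 0 returns p = 1 exactly.
- Ties everywhere use mid-ranks; sorting tie-breaks are lexicographic;
  linkage tie handling follows scipy's deterministic order, so identical
  inputs give identical outputs byte-for-byte (asserted for the full
  pipeline).
- Ct write-out uses shortest round-tripping float repr, so write → read is
  bit-exact.
- Degenerate inputs (empty groups, zero detected entries in a sample,
  constant profiles, zero 2×2 marginals, sequences shorter than the seed)
  raise errors naming the offender rather than propagating NaNs.

## Problem sizes used in the test suite

Tests run the full 591 × 34 design for recovery and invariant checks, 50
replicates of the null design for false-positive control, ~500 randomized
cases for the exact-test oracle (total n ≤ 10), and every hypergeometric
parameterization with N ≤ 20; the complete suite finishes in about a
minute on one CPU.

## Known limitations

- The approximate Wilcoxon p is conservative for very small groups; `auto`
  avoids this by enumerating exactly there.
- Imputation at the detection limit compresses fold changes of miRNAs
  censored in one class toward the gate; strongly under-expressed miRNAs
  with baselines near 34 cycles can land at the 2-fold boundary.
- The concordance classifier treats "Absent" as missing, not as evidence
  of no change; a miRNA reported by neither human study simply drops out.
- Only enrichment (upper-tail) overlap testing is provided; depletion is
  out of scope.
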