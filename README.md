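# crossmir

Cross-species miRNA expression analysis for qPCR arrays: from raw cycle
thresholds to differential-expression calls, mouse–human concordance and
sample-structure analysis.

## The problem

TaqMan low-density arrays report a cycle threshold Ct per miRNA per sample
(lower Ct = higher abundance; one cycle ≈ two-fold). Profiling a murine
tumor model and asking whether its miRNA deregulation mirrors the human
disease requires a chain of steps that are easy to get subtly wrong:
censoring at the single-molecule limit, removing per-sample global shifts,
converting Ct to relative quantities, nonparametric two-group testing with
family-wise error control, calling orthologs between species, and testing
whether two differential-expression (DE) lists share more members than
chance allows. `crossmir` implements that chain as a tested, reusable
library for anyone comparing qPCR-array miRNA profiles across conditions or
species.

## The model

- **Detection.** Ct > 35 is below the single-molecule limit and treated as
  not expressed; miRNAs detected in fewer than `min_samples` (default 10)
  samples are dropped.
- **Normalization.** Global-mean centering removes each sample's mean
  detected Ct; the normalized relative quantity is
  `NRQ = 2^(Ctmax − Ct)`, with Ctmax the per-miRNA maximum centered Ct, so
  NRQ ≥ 1 and each miRNA's minimum is exactly 1.
- **Differential expression.** Two-sided Wilcoxon rank-sum per miRNA
  (exact enumeration for small cohorts, tie-corrected normal approximation
  otherwise), Bonferroni adjustment over the retained miRNAs, and a
  > 2-fold gate on the ratio of group-mean NRQs.
- **Homology.** Mouse and human mature miRNAs are paired iff their mature
  sequences are identical in both length and nucleotides (miRBase mature
  FASTA in, TSV map out).
- **Concordance.** A conserved miRNA DE in mouse is *concordant* when every
  human study reporting it agrees in direction, *discordant* otherwise;
  DE-list overlap is tested with the upper-tail hypergeometric
  `P(X ≥ k)` in an explicitly chosen universe of conserved miRNAs.
- **Structure.** Complete-linkage clustering on `1 − Spearman ρ` between
  sample profiles with a two-branch cut and Pearson χ² branch-enrichment;
  PCA by SVD of the centered `log2(NRQ)` matrix with loading-based miRNA
  ranking.
- **Synthetic data.** A ground-truthed generator reproduces the study
  shape (591 miRNAs, 22 tumors vs 12 controls, planted |log2FC| = 2
  effects, Gaussian Ct noise, per-sample shifts, censoring at 35) so every
  stage is testable without downloads.

## Worked example

```bash
python examples/01_simulate_and_differential_expression.py
```

prints

```
simulated 591 miRNAs x 34 samples; 0.9% of entries censored at Ct > 35
retained 591 miRNAs detected in >= 10 samples
differentially expressed: 159 (81 up, 78 down) at Bonferroni p < 0.05 and > 2-fold
recovery vs planted truth: sensitivity 1.000, FDR 0.000, direction accuracy 1.000
```

i.e. all 159 planted effects (81 over-, 78 under-expressed at four-fold)
are recovered with no false calls and no direction errors. The other
examples cover exact-identity homology mapping (`02`), the mouse–human
concordance table and the universe-sensitivity of the overlap test (`03`),
and clustering/PCA structure (`04`). A thin CLI wraps the same library:

```bash
crossmir table1-check            # concordance summary of the packaged table
crossmir simulate --seed 1 --out scratch/sim
crossmir run config.yaml         # full pipeline from a YAML config
```

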