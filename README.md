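# ctcmd

EpCAM/PSMA surface-marker dynamics on circulating tumor cells (CTCs) under
PSMA-targeted radioligand and alpha therapy — a reproducible, tested
re-implementation of the full analysis chain, for analysts working with
index-sorted CTC cytometry and plate-based single-cell RNA-seq from mCRPC
liquid biopsies.

## What it computes

**Flow cytometry.** Index-sorted events (one row per sorted CTC, with C4-2
control wells per sort session) are normalized by the session-matched
control median MFI per channel; samples with unknown treatment outcome are
excluded; negative MFIs (baseline-subtraction artifacts) are imputed as the
mean of two values drawn from the channel's ten lowest positive values;
outliers beyond median ± 3·MAD on the log10 scale are removed. Positivity
thresholds per channel are the minimum over samples of the per-sample
median MFI, partitioning CTCs into EpCAM⁺PSMA⁻, EpCAM⁺PSMA⁺ and
EpCAM⁻PSMA⁺ subpopulations. Readouts: subpopulation composition (χ²
goodness of fit), pooled and per-cycle group comparisons and
cycle-vs-baseline dynamics (two-sided Mann–Whitney U on log10 MFI, cycles
with fewer than 5 cells in either group dropped), and per-sample CTC-count
statistics.

**Single cell.** Cells with < 4,000 counts, < 1,000 or > 7,800 detected
genes, or > 75 % mitochondrial reads are removed (strict inequalities).
After depth log-normalization, per-gene two-cluster Wilcoxon tests with
Bonferroni correction define DEGs at p_adj < 0.05 and |log2FC| ≥ 1, ranked
by log2FC × (−log10 p_adj). Hub genes are significant DEGs whose
normalized expression has Spearman ρ ≥ 0.2 with p < 0.05 against a
gene-set score in at least two scoring methods.

**Library pooling.** Molarity from fragment-analyzer summaries
(nM = ng/µL × 10⁶ / (bp × 650)), sub-nanomolar discard, median split with
dilution-to-median, and an equimolar (fixed-fmol) pooling plan.

**Statistics** (Mann–Whitney U with exact small-sample enumeration,
χ² tests, Spearman with exact permutation branch, Bonferroni, robust
median/MAD/MADM summaries) are implemented in `ctcmd.stats_core` and
validated against brute-force oracles.

Because the study's patient data are not publicly deposited, the package
includes a seeded synthetic cohort generator (`ctcmd.synthio`) whose
defaults are calibrated to the published per-cycle medians — e.g.
Nonresponder EpCAM 0.8258 vs Responder 0.3299 at baseline, Responder PSMA
declining 0.1920 → 0.0453 → 0.0186, per-sample CTC count medians 8 vs 2 —
so every downstream stage is testable end to end.

## Worked example

```sh
ctcmd run-all --seed 1 --out out/
```

or equivalently in Python:

```python
from ctcmd import RunConfig, run_pipeline, write_report
bundle = run_pipeline(RunConfig(seed=1))
write_report(bundle, "out/")
```

With seed 1 the simulated cohort yields 1,265 sorted CTC events, of which
109 come from unknown-response patients and are excluded and 1,126 are
retained after imputation (12 negative PSMA values) and outlier filtering.
The pooled group comparison reports a Nonresponder EpCAM median of 0.434
(log10 −0.362) versus 0.214 (−0.670) in Responders, and a Nonresponder
PSMA median of 0.051 versus 0.066 (Mann–Whitney p = 8 × 10⁻⁴) — higher
EpCAM and lower PSMA in Nonresponders, the planted resistance signature.
Per-sample CTC counts recover medians 7 vs 2 (p ≈ 2 × 10⁻¹⁸), and the
Responder PSMA dynamics table shows the planted decline:

```
 cycle  n  median_mfi  p_vs_baseline
     0 40      0.1825            —
     1 38      0.1315        <1e-4
     2 56      0.0362        <1e-4
     3 29      0.0140        <1e-4
```

(cycle 4, simulated with 3 Responder and 0 Nonresponder cells, is removed
by the 5-cell cutoff). The single-cell stage keeps 92 of 120 cells, calls
96 significant DEGs (51 up, 45 down in cluster 0; 100 planted), finds
cluster composition associated with treatment cycle and type but not with
response, and recovers the three planted hub genes while rejecting the
single-method and non-DEG decoys. `out/report.md` and `out/summary.json`
contain every number above.

## Layout

```
src/ctcmd/
  synthio.py         seeded synthetic cohort / counts / score generators
  stats_core.py      nonparametric statistics with exact small-sample branches
  flow_pipeline.py   control QC, normalization, imputation, classification, dynamics
  scrna_pipeline.py  cell QC, lognormalization, Wilcoxon DGE, hub filter
  libprep_calc.py    molarity and equimolar pooling arithmetic
  pipeline.py        RunConfig, stage orchestration, report writing
  cli.py             ctcmd simulate | flow-* | scrna-* | hub-filter | libprep-pool | run-all
  validation.py      property-suite evaluations shared by tests and acceptance
  datasets.py        published cohort summary counts for bookkeeping checks
docs/methods.md      model assumptions, parameter rationale, limitations
```
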