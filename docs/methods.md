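# Methods

`ctcmd` re-implements, as a tested pipeline, a circulating-tumor-cell (CTC)
biomarker analysis for metastatic castration-resistant prostate cancer
(mCRPC) under PSMA-targeted radioligand/alpha therapy: index-sorted
flow-cytometry profiling of EpCAM and PSMA on CTCs, their longitudinal
dynamics over treatment cycles, and the downstream single-cell
transcriptomic computations. Because the underlying patient data are not
publicly deposited, the package ships a seeded synthetic cohort generator
that defines the study conditions every stage is validated against.

## Flow-cytometry model

**Data model.** One row per index-sorted cell (event) with per-channel
median fluorescence intensities (MFI) for EpCAM and PSMA, annotated with
patient, sample (patient x treatment cycle), sort session and treatment
response (Responder / Nonresponder / Unknown). Each sort session carries a
C4-2 control well; sessions pair one Responder with one Nonresponder sample
to balance batch effects.

**Generator.** Within a sample, channel MFIs are lognormal around a planted
per-(group, cycle, channel) median, multiplied by a per-session lognormal
batch factor shared with that session's control well, and then reduced by a
half-normal "baseline-subtraction" term that produces occasional negative
MFIs on dim channels. The lognormal within-sample form is an assumption
(flow MFIs are strictly positive pre-subtraction and right-skewed); the
half-normal artifact is a minimal model of instrument background
subtraction. Sorted-cell counts per sample follow a negative binomial whose
*zero-truncated median* is calibrated to the planted group median (samples
drawing zero cells emulate sorts without viable CTCs).

Key defaults, and why:

| parameter | default | rationale |
| --- | --- | --- |
| planted marker medians | published per-cycle medians | e.g. Nonresponder EpCAM 0.8258 / 0.8849 / 0.2872 / 0.2706 over cycles 0–3; Responder PSMA 0.1920 / 0.1181 / 0.0453 / 0.0186. Cells not published are fixed design choices: Responder EpCAM 0.25 at cycles 2–3 (the between-group difference disappears late), Nonresponder PSMA 0.055 / 0.030 at cycles 2–3 (declining, clearly lower by cycle 3), cycle 4 reuses cycle 3, Unknown group 0.5 / 0.1. |
| CTC count medians | 2 (Responder), 8 (Nonresponder) | the published per-sample medians; dispersion 1.5 reproduces ranges of roughly 1–44. |
| `log_mfi_sd` | 0.15 (log10) | set by an upfront power analysis: the weakest planted effect (cycle-1 between-group PSMA, Δlog10 ≈ 0.126) must be detectable per replicate with probability ≈ 0.99 at the default cohort size. |
| `n_patients_per_group` | 28 | gives ≈ 35 Responder and ≈ 225 Nonresponder cells per cycle, the sizes assumed by the same power analysis; pooled per-group totals comfortably exceed 150. |
| `session_batch_sd` | 0.10 (log10) | a visible sort-to-sort effect that session-matched normalization must cancel. |
| `detection_floor` | 0.01 (fraction of the control median) | yields a small but nonzero rate of negative PSMA MFIs so the imputation path runs on default data. |
| `unknown_response_fraction` | 0.10 | exercises the unknown-outcome exclusion rule. |
| cycle-4 caps | 3 Responder / 0 Nonresponder cells | reproduces the sparse final cycle so the dynamics cycle cutoff (minimum 5 cells per group) removes it. |

A master seed is split into independent substreams (cohort skeleton, flow
events, counts, scores) via `numpy.random.SeedSequence`, so stages can be
regenerated independently and a fixed seed yields byte-identical outputs.

**Analysis chain.**

1. *Control QC* — per-session control medians after dropping duplicated
   rows; cross-session grand median, MAD and MADM (MAD of the per-session
   medians). The MAD scale constant defaults to 1.0 (descriptive use) and
   can be set to 1.4826 for normal consistency.
2. *Normalization* — each event's channel MFI divided by the
   session-matched control median for that channel; a missing control
   session is a hard error naming the session. Negative raw values keep
   their sign.
3. *Exclusion* — events from patients with unknown treatment outcome are
   dropped and logged.
4. *Imputation* — per channel, the drawing set is the 10 lowest strictly
   positive normalized values across the merged table; each value ≤ 0
   (zeros are treated as imputable artifacts alongside negatives) is
   replaced independently by the mean of 2 values drawn *without*
   replacement from that set, keeping imputed values near the detection
   baseline while avoiding duplicated values. Imputation precedes outlier
   filtering.
5. *Outlier filter* — per channel, events with |log10 MFI − median| > k ×
   MAD (k = 3, scale 1.4826) are removed; an event flagged on either
   channel is dropped. The specific rule is unstated in the source
   workflow, so a conservative, scale-free median ± k·MAD filter was
   chosen and is configurable. If the MAD is zero (all values equal),
   nothing is removed.
6. *Thresholds and classification* — per channel, the positivity threshold
   is the minimum over samples of the per-sample median normalized MFI
   (matching a single dotted threshold line per channel on the sort
   scatterplot; taking the minimum over samples rather than patients or
   events is a documented interpretation). A channel is positive iff
   MFI ≥ threshold — the boundary counts as positive, an arbitrary but
   fixed convention — giving a complete partition into EpCAM⁺PSMA⁻,
   EpCAM⁺PSMA⁺, EpCAM⁻PSMA⁺ and double negatives (logged, excluded from
   the three-way distribution).
7. *Statistics* — subpopulation composition is tested per subpopulation by
   a χ² goodness of fit against either an equal Responder/Nonresponder
   split or the overall group proportions (default: overall proportions,
   which accounts for unequal group sizes). Pooled and per-cycle group
   comparisons use two-sided Mann-Whitney tests on log10 MFIs; per-cycle
   dynamics compare each cycle against baseline within groups and between
   groups per cycle, dropping cycles where either group has fewer than 5
   cells. Per-sample retained-cell counts are compared between groups with
   Mann-Whitney.

## Nonparametric statistics

All test statistics are implemented in `ctcmd.stats_core`; SciPy provides
only reference distribution functions (normal, χ², t) and midranks.

* **Mann-Whitney U** — exact two-sided p by enumerating the U null
  distribution (a count recursion) when n₁ + n₂ ≤ 16 and the pooled sample
  is tie-free; otherwise a normal approximation with tie correction and a
  0.5 continuity correction. Two-sided exact p is
  `min(1, 2·min(P(U≤u), P(U≥u)))`. The exact branch is verified against
  brute-force labeling enumeration for all layouts with n₁ + n₂ ≤ 10, and
  the asymptotic branch against an independent reference implementation.
  Calibration of the asymptotic branch was checked analytically from the
  exact U distribution at n = 20 per group: rejection rate 0.0491 at
  α = 0.05.
* **χ² tests** — Pearson goodness of fit (df = k−1) and independence
  (df = (r−1)(c−1)), no continuity correction.
* **Spearman** — Pearson correlation of midranks; p from the t
  approximation with n−2 df; an exact permutation branch (n ≤ 8) exists
  for validation against full enumeration.
* **Bonferroni** — `min(1, p·m)` with m = number of tests.

## Single-cell pipeline

* **Cell QC** — a cell is removed iff total counts < 4,000, detected
  genes < 1,000 or > 7,800, or mitochondrial fraction > 0.75, all strict
  inequalities (boundary cells kept). The MT fraction is computed on raw
  counts. The lenient MT cutoff mirrors plate-based full-length chemistry
  and radiation-stressed cells.
* **Normalization** — `ln(1 + 10⁴ · count / cell_total)`, a deterministic
  depth normalization standing upstream of the rank-based statistics.
  Variance stabilization, embedding and graph clustering are out of scope;
  cluster labels are inputs (synthetic truth here).
* **Composition tests** — χ² independence of cluster labels against
  response, cycle and treatment type; degenerate tables are skipped with a
  notice.
* **Differential expression** — per gene, a two-sided Mann-Whitney test
  between clusters on normalized values; Bonferroni with m = genes tested
  (whether the original workflow counted all detected or all tested genes
  is unstated; m = tested is used). log2FC is the log2 ratio of cluster
  means of back-transformed (`expm1`) normalized expression with
  pseudocount 1e−9 — the ratio-of-means convention of the common
  marker-finding tools. Significance requires adjusted p < 0.05 and
  |log2FC| ≥ 1. Ranking uses `log2FC × (−log10 max(p_adj, 1e−300))`; the
  floor keeps scores finite when p underflows (where two printed variants
  of this formula disagreed, the methods-style formula with −log10 wins).
* **Hub filter** — Spearman correlation of each candidate gene's
  normalized expression with per-cell gene-set scores, per scoring method,
  restricted to gene sets the gene belongs to (hub candidates are member
  genes of their pathways). A gene is a hub iff ρ ≥ 0.2 with p < 0.05 in
  at least two distinct methods for some gene set *and* the gene is a
  significant DEG. The "rank-correlation score" is taken to be Spearman's
  ρ itself. The per-cell scoring methods are out of scope; score matrices
  are inputs, and the synthetic generator builds them through a Gaussian
  copula on expression ranks (latent Pearson r = 2·sin(πρ/6), so the
  population Spearman equals the target ρ; ρ = 1 degenerates to an exact
  monotone transform).

**Count generator.** Two planted clusters of 60 cells; 100 of 2,000 genes
carry symmetric planted log2 fold changes (|log2FC| uniform in [1.5, 3]),
restricted to the more abundant half of the non-mitochondrial panel so
they are detectable at the simulated depth. Library sizes are log-uniform
over [2×10³, 2×10⁵] — deliberately straddling the 4,000-count cutoff — and
8% of cells are pushed above the 75% MT cutoff, so the QC filter removes
cells on both sides by construction. Counts are negative binomial
(dispersion 2). The 7,800 upper gene bound cannot be exercised by a
2,000-gene panel; it is covered by constructed boundary fixtures instead.

## Library pooling

Molarity from fragment-analyzer summaries uses the standard 650 g/mol per
double-stranded base pair: `nM = conc[ng/µL] × 10⁶ / (bp × 650)` (1 ng/µL
at 1,000 bp ≈ 1.54 nM). Samples below 1 nM are discarded; the cohort
median is computed over kept samples; samples strictly above the median
are diluted to it (exact ties at the median stay undiluted — documented
tie rule); each kept sample contributes a fixed amount of material,
defaulting to the median molarity × 1 µL (e.g. ≈ 6.95 fmol when the median
is 6.95 nM), so transfer volume = target fmol / working molarity. The plan
is scale invariant: scaling all molarities by c divides all volumes by c.

## Validation design and problem sizes

The acceptance-style checks (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use these sizes, chosen to make each property
measurable with stable margins while keeping a full run under a minute or
two on one CPU:

* effect-direction recovery: 50 end-to-end replicates of the default
  cohort (≈ 6,000 events each);
* Mann-Whitney null calibration: 2,000 replicates of n = 20 vs 20;
* exact-branch oracles: all Mann-Whitney layouts with n₁ + n₂ ≤ 10 and
  full permutation enumeration for Spearman at n = 4–6;
* DEG recovery: one planted fixture plus 20 null fixtures of 2,000 genes ×
  120 cells;
* hub recovery: planted ρ = 0.5 on a 200-cells-per-cluster fixture
  (≈ 330 post-QC cells), so the null sampling error of ρ (≈ 0.05) keeps
  chance correlation well below the 0.2 filter threshold — decoys can only
  pass through the filter logic, not through noise.

## What the synthetic cohort does and does not show

The generator reproduces the *structure* of the study data — session-paired
sorting with control wells, multiplicative batch effects,
baseline-subtraction negatives, group- and cycle-dependent marker levels,
dispersed per-sample CTC yields, QC-straddling single-cell libraries — and
the planted parameters are calibrated to the published medians. It does
not emulate spillover/compensation, doublets, gating of raw cytometer
events, patient-level random effects (cells are independent given group
and cycle), epithelial–mesenchymal heterogeneity of marker expression, or
transcript-level noise structure beyond a negative binomial. Passing
tests therefore demonstrate that the *implementation* of each rule and
statistic is faithful and that the planted effects are recoverable under
idealized noise — not that the clinical effect sizes would replicate in
new patients; the real study's patient-level p-values are not reproducible
without the original FCS and sequencing data.

## Known limitations

* The Mann-Whitney exact branch is limited to tie-free pooled samples;
  ties always route to the corrected normal approximation, which is
  anti-conservative for very small samples with heavy ties.
* The per-sample threshold minimum makes the classification sensitive to
  the single dimmest sample; with very few events per sample the
  threshold estimate is noisy.
* `simulate_geneset_scores` plants one hub gene per gene set; correlated
  multi-gene pathway structure is not modeled.
* The orchestration layer derives cluster labels from synthetic truth; a
  plain clustering utility for real data is deliberately not bundled.
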