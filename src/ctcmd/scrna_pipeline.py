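"""Single-cell RNA-seq downstream analysis of sorted CTCs.

Covers the in-text defined computations: per-cell QC filtering
(counts / detected genes / mitochondrial fraction), a simple depth
log-normalization, cluster-composition association tests, per-gene Wilcoxon
(Mann-Whitney) differential expression with Bonferroni correction and
2-fold-change filtering, DEG ranking, and the hub-gene Spearman-correlation
filter over per-method gene-set score matrices.

Upstream steps (alignment, variance stabilization, embedding, graph
clustering, per-cell enrichment scoring) are out of scope here: cluster
labels and score matrices are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .stats_core import (
    TestResult,
    bonferroni_adjust,
    chi_squared_independence,
    mann_whitney_u,
    spearman_corr,
)

__all__ = [
    "CellQCThresholds",
    "qc_filter_cells",
    "lognormalize",
    "composition_association",
    "dge_wilcoxon",
    "filter_and_rank_degs",
    "hub_correlations",
    "filter_hub_genes",
]

P_FLOOR = 1e-300  # floor on adjusted p in the ranking score


@dataclass(frozen=True)
class CellQCThresholds:
    """Cell-level QC cutoffs.

    A cell is removed iff ``total_counts < min_counts`` OR
    ``genes_detected < min_genes`` OR ``genes_detected > max_genes`` OR
    ``mt_fraction > max_mt_fraction`` — all strict inequalities, so boundary
    cells are retained.  The lenient default mitochondrial cutoff of 0.75
    reflects plate-based full-length protocols and radiation-stressed cells.
    """

    min_counts: int = 4000
    min_genes: int = 1000
    max_genes: int = 7800
    max_mt_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if not (0.0 < self.max_mt_fraction <= 1.0):
            raise ValueError("max_mt_fraction must lie in (0, 1]")


def _as_matrix(data: "ad.AnnData | np.ndarray") -> np.ndarray:
    if isinstance(data, ad.AnnData):
        X = data.X
    else:
        X = data
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-D cells x genes matrix")
    return X


def qc_filter_cells(
    adata: "ad.AnnData",
    thresholds: CellQCThresholds = CellQCThresholds(),
    mt_genes: Sequence[str] | None = None,
) -> tuple["ad.AnnData", pd.DataFrame]:
    """Apply the cell QC filter.

    ``mt_genes`` defaults to ``adata.uns['mt_genes']`` when present, else to
    gene ids starting with ``MT-``.  Returns the filtered AnnData (copy) and
    a per-cell QC record with the three summaries, the keep flag and the
    removal reasons (``low_counts``, ``low_genes``, ``high_genes``,
    ``high_mt``, semicolon-joined).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = _as_matrix(adata)
    if mt_genes is None:
        mt_genes = adata.uns.get("mt_genes") if "mt_genes" in adata.uns else None
    if mt_genes is None:
        mt_mask = np.asarray(adata.var_names.str.startswith("MT-"), dtype=bool)
    else:
        unknown = set(mt_genes) - set(adata.var_names)
        if unknown:
            raise ValueError(f"mitochondrial genes not in matrix: {sorted(unknown)[:5]}")
        mt_mask = np.asarray(adata.var_names.isin(mt_genes), dtype=bool)

    totals = X.sum(axis=1).astype(float)
    genes_detected = (X > 0).sum(axis=1).astype(int)
    mt_counts = X[:, mt_mask].sum(axis=1).astype(float)
    mt_fraction = np.divide(mt_counts, totals, out=np.zeros_like(mt_counts), where=totals > 0)

    reasons = []
    for t, g, f in zip(totals, genes_detected, mt_fraction):
        r = []
        if t < thresholds.min_counts:
            r.append("low_counts")
        if g < thresholds.min_genes:
            r.append("low_genes")
        if g > thresholds.max_genes:
            r.append("high_genes")
        if f > thresholds.max_mt_fraction:
            r.append("high_mt")
        reasons.append(";".join(r))
    keep = np.array([r == "" for r in reasons])

    qc = pd.DataFrame(
        {
            "total_counts": totals,
            "genes_detected": genes_detected,
            "mt_fraction": mt_fraction,
            "keep": keep,
            "removal_reason": reasons,
        },
        index=adata.obs_names,
    )
    return adata[keep].copy(), qc


def lognormalize(data: "ad.AnnData | np.ndarray", scale: float = 1e4) -> np.ndarray:
    """Depth normalization: ``ln(1 + scale * count / cell_total)`` per cell.

    A deterministic plumbing transform standing upstream of the rank-based
    statistics; it is invariant to per-cell depth scaling.  Cells with zero
    total counts are rejected (they should have been removed by QC).
    """
    X = _as_matrix(data).astype(float)
    totals = X.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("cell with zero total counts; run QC first")
    return np.log1p(scale * X / totals)


def composition_association(
    cluster_labels: Sequence, covariate: Sequence
) -> tuple[pd.DataFrame, TestResult]:
    """Chi-squared test of independence between cluster labels and a
    per-cell covariate (response, cycle, treatment type, ...).

    Returns the contingency table and the test result.  Degenerate tables
    (fewer than two levels on either margin) raise ``ValueError``; callers
    that iterate covariates should catch it and record a notice."""
    labels = pd.Series(list(cluster_labels), name="cluster")
    cov = pd.Series(list(covariate), name="covariate")
    if len(labels) != len(cov):
        raise ValueError("cluster labels and covariate must have equal length")
    table = pd.crosstab(labels, cov)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (needs >=2 levels per margin)")
    return table, chi_squared_independence(table.to_numpy())


def dge_wilcoxon(
    norm: np.ndarray,
    cluster_labels: Sequence[int],
    genes: Sequence[str],
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene two-cluster Wilcoxon differential expression.

    For each gene a two-sided Mann-Whitney test on the normalized values of
    cluster 0 vs cluster 1, Bonferroni-adjusted with m = number of genes
    tested.  ``log2fc`` is the log2 ratio of cluster means of the
    back-transformed normalized expression (``expm1``) with pseudocount
    ``eps``; positive values mean higher in cluster 0.  ``significant`` is
    ``p_adj < alpha`` and ``|log2fc| >= min_abs_log2fc``.
    """
    norm = np.asarray(norm, dtype=float)
    labels = np.asarray(cluster_labels)
    if norm.shape[0] != labels.size:
        raise ValueError("label length must match cell count")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("cluster labels must contain both 0 and 1")
    in0 = labels == 0
    in1 = labels == 1
    if in0.sum() < 3 or in1.sum() < 3:
        raise ValueError("each cluster needs at least 3 cells")
    if len(genes) != norm.shape[1]:
        raise ValueError("gene list length must match matrix width")

    back = np.expm1(norm)
    m0 = back[in0].mean(axis=0)
    m1 = back[in1].mean(axis=0)
    log2fc = np.log2((m0 + eps) / (m1 + eps))

    p_raw = np.empty(norm.shape[1])
    for j in range(norm.shape[1]):
        p_raw[j] = mann_whitney_u(norm[in0, j], norm[in1, j]).p_value
    p_adj = bonferroni_adjust(p_raw, m=norm.shape[1])
    significant = (p_adj < alpha) & (np.abs(log2fc) >= min_abs_log2fc)

    return pd.DataFrame(
        {
            "gene": list(genes),
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
        }
    )


def filter_and_rank_degs(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    top_k: int = 15,
    p_floor: float = P_FLOOR,
) -> dict:
    """Significance filter plus ranking of DGE records.

    ``rank_score = log2fc * (-log10(max(p_adj, p_floor)))``; the floor keeps
    scores finite when the adjusted p underflows.  Returns the annotated
    records, the significant subset sorted by |rank_score| (descending), the
    top-k slice for display, and up/down counts among significant genes.
    """
    rec = records.copy()
    rec["significant"] = (rec["p_adj"] < alpha) & (rec["log2fc"].abs() >= min_abs_log2fc)
    rec["rank_score"] = rec["log2fc"] * (-np.log10(np.maximum(rec["p_adj"], p_floor)))
    sig = rec.loc[rec["significant"]].copy()
    sig = sig.reindex(sig["rank_score"].abs().sort_values(ascending=False, kind="stable").index)
    return {
        "records": rec,
        "significant": sig,
        "top": sig.head(top_k),
        "n_up": int((sig["log2fc"] > 0).sum()),
        "n_down": int((sig["log2fc"] < 0).sum()),
    }


def hub_correlations(
    norm_expr: pd.DataFrame,
    score_matrices: Mapping[str, pd.DataFrame],
    candidate_genes: Iterable[str],
    geneset_members: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of candidate genes with gene-set scores.

    ``norm_expr`` is cells x genes; each score matrix is cells x gene sets
    over the *same* cell set (order may differ).  When ``geneset_members``
    is given, a gene is only correlated against the gene sets it belongs to
    (hub candidates are member genes of their pathways); otherwise every
    (gene, gene set) pair is evaluated.  Returns one row per
    (gene, gene set, method) with rho and the Spearman p-value.
    """
    if len(score_matrices) < 2:
        raise ValueError("at least two scoring methods are required")
    candidates = list(candidate_genes)
    unknown = set(candidates) - set(norm_expr.columns)
    if unknown:
        raise ValueError(f"candidate genes not in expression matrix: {sorted(unknown)[:5]}")
    members = (
        None
        if geneset_members is None
        else {gs: set(genes) for gs, genes in geneset_members.items()}
    )

    rows = []
    for method, scores in score_matrices.items():
        if set(scores.index) != set(norm_expr.index):
            raise ValueError(f"cell set of method {method!r} does not match expression matrix")
        scores = scores.loc[norm_expr.index]
        for gene in candidates:
            expr = norm_expr[gene].to_numpy()
            for gs in scores.columns:
                if members is not None and gene not in members.get(gs, ()):
                    continue
                rho, p = spearman_corr(expr, scores[gs].to_numpy())
                rows.append(
                    {"gene": gene, "geneset": gs, "method": method, "rho": rho, "p_spearman": p}
                )
    return pd.DataFrame(rows, columns=["gene", "geneset", "method", "rho", "p_spearman"])


def filter_hub_genes(
    hub_records: pd.DataFrame,
    significant_deg_genes: Iterable[str],
    min_rho: float = 0.2,
    alpha: float = 0.05,
    min_methods: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Three-criterion hub-gene filter.

    A gene is a hub iff, for some gene set, ``rho >= min_rho`` and
    ``p < alpha`` hold in at least ``min_methods`` distinct scoring methods,
    and the gene is a significant DEG.  Returns the sorted hub gene list and
    the annotated records (``passes_method`` per row, ``is_hub`` per gene).
    The decision is invariant to record and method ordering.
    """
    deg_set = set(significant_deg_genes)
    rec = hub_records.copy()
    rec["passes_method"] = (rec["rho"] >= min_rho) & (rec["p_spearman"] < alpha)
    per_set = (
        rec.loc[rec["passes_method"]]
        .groupby(["gene", "geneset"])["method"]
        .nunique()
        .rename("n_methods")
        .reset_index()
    )
    qualifying = set(per_set.loc[per_set["n_methods"] >= min_methods, "gene"])
    hubs = sorted(qualifying & deg_set)
    rec["is_hub"] = rec["gene"].isin(hubs)
    return hubs, rec
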