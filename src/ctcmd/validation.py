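"""Property-suite evaluations of the pipeline on its synthetic study design.

These routines re-run the package end to end under the default (calibrated)
generator conditions and measure recovery of the planted structure:
effect-direction recovery of the EpCAM/PSMA group differences and cycle
dynamics, null calibration of the Mann-Whitney test, exact-branch agreement
with enumeration oracles, the imputation contract, the cell-QC boundary
behaviour, planted-DEG recovery and the hub-gene filter.  They are shared
between the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from . import flow_pipeline as fp
from . import scrna_pipeline as sp
from . import synthio
from .pipeline import run_flow_stages, stage_seeds
from .stats_core import mann_whitney_u, spearman_corr

__all__ = [
    "effect_direction_replicate",
    "effect_direction_recovery",
    "mwu_null_rejection_rate",
    "mwu_exact_max_error",
    "spearman_exact_max_error",
    "imputation_contract",
    "qc_boundary_grid",
    "deg_recovery",
    "null_deg_counts",
    "hub_filter_recovery",
]

ALPHA = 0.05


# ---------------------------------------------------------------- effect direction


def effect_direction_replicate(seed: int) -> dict[str, bool]:
    """One seeded end-to-end flow replicate under the default scenario.

    Checks the planted study effects: Nonresponder EpCAM above Responder and
    Nonresponder PSMA below Responder at baseline and cycle 1 (two-sided
    p < 0.05 with the correct median ordering), plus significant Responder
    PSMA declines at cycles 2 and 3 versus baseline.
    """
    config = synthio.CohortConfig(seed=seed)
    skeleton = synthio.simulate_cohort(config)
    events = synthio.simulate_flow_events(skeleton)
    flow = run_flow_stages(events, imputation_seed=stage_seeds(seed)[1])

    out: dict[str, bool] = {}
    for ch, direction in (("epcam", "nonresponder_higher"), ("psma", "responder_higher")):
        dyn = flow["dynamics"][ch].set_index(["group", "cycle"])
        for cycle in (0, 1):
            try:
                med_r = dyn.loc[(synthio.RESPONDER, cycle), "median_mfi"]
                med_n = dyn.loc[(synthio.NONRESPONDER, cycle), "median_mfi"]
                p = dyn.loc[(synthio.RESPONDER, cycle), "p_between_groups"]
            except KeyError:
                out[f"{ch}_between_cycle{cycle}"] = False
                continue
            ordered = med_n > med_r if direction == "nonresponder_higher" else med_r > med_n
            out[f"{ch}_between_cycle{cycle}"] = bool(ordered and p < ALPHA)

    dyn = flow["dynamics"]["psma"].set_index(["group", "cycle"])
    base = dyn.loc[(synthio.RESPONDER, 0), "median_mfi"]
    for cycle in (2, 3):
        try:
            med = dyn.loc[(synthio.RESPONDER, cycle), "median_mfi"]
            p = dyn.loc[(synthio.RESPONDER, cycle), "p_vs_baseline"]
        except KeyError:
            out[f"responder_psma_decline_cycle{cycle}"] = False
            continue
        out[f"responder_psma_decline_cycle{cycle}"] = bool(med < base and p < ALPHA)
    return out


def effect_direction_recovery(n_replicates: int = 50, base_seed: int = 0) -> dict:
    """Fraction of seeded replicates recovering *all* planted effects."""
    per_check: dict[str, int] = {}
    n_all = 0
    for i in range(n_replicates):
        checks = effect_direction_replicate(base_seed + i)
        for k, v in checks.items():
            per_check[k] = per_check.get(k, 0) + int(v)
        n_all += int(all(checks.values()))
    return {
        "fraction_all_recovered": n_all / n_replicates,
        "per_check_fraction": {k: v / n_replicates for k, v in per_check.items()},
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------- MWU calibration


def mwu_null_rejection_rate(
    n_replicates: int = 2000, n_per_group: int = 20, seed: int = 0
) -> float:
    """Two-sided rejection rate at alpha=0.05 for two null normal samples."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        x = rng.standard_normal(n_per_group)
        y = rng.standard_normal(n_per_group)
        hits += mann_whitney_u(x, y).p_value < ALPHA
    return hits / n_replicates


# ---------------------------------------------------------------- exact oracles


def _enumerated_mwu_pvalues(n1: int, n2: int) -> dict[int, float]:
    """Brute-force two-sided p for every achievable U, by enumerating which
    of the pooled ranks belong to x (independent of the DP recursion used by
    the implementation)."""
    n = n1 + n2
    us = []
    for combo in itertools.combinations(range(1, n + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) // 2)
    us = np.array(us)
    total = us.size
    return {
        int(u): min(1.0, 2.0 * min((us <= u).sum(), (us >= u).sum()) / total)
        for u in np.unique(us)
    }


def mwu_exact_max_error(max_total: int = 10) -> float:
    """Largest |p_exact - p_enumerated| over all tie-free layouts with
    n1 + n2 <= max_total and every achievable U value."""
    worst = 0.0
    for n1 in range(1, max_total):
        for n2 in range(1, max_total - n1 + 1):
            oracle = _enumerated_mwu_pvalues(n1, n2)
            for u, p_ref in oracle.items():
                # build a tie-free sample realizing this U: x beats y in
                # exactly u pairs
                x, y = _sample_with_u(n1, n2, u)
                res = mann_whitney_u(x, y)
                assert res.method == "exact"
                assert int(round(res.statistic)) == u
                worst = max(worst, abs(res.p_value - p_ref))
    return worst


def _sample_with_u(n1: int, n2: int, u: int) -> tuple[list[float], list[float]]:
    """Construct tie-free samples with a prescribed U statistic.

    Start with all x below all y (U = 0) and promote x elements past y
    values, largest x element first: promoting one x element past ``s``
    y values raises U by ``s``.  Each element can rise past at most n2 y's,
    and giving larger promotions to larger elements keeps the ranks
    distinct.
    """
    ranks_x = []
    remaining = u
    for i in reversed(range(n1)):  # i+1 is the element's unpromoted rank
        step = min(remaining, n2)
        ranks_x.append(i + 1 + step)
        remaining -= step
    assert remaining == 0, "u exceeds n1*n2"
    xs = sorted(ranks_x)
    ys = [r for r in range(1, n1 + n2 + 1) if r not in set(xs)]
    return [float(v) for v in xs], [float(v) for v in ys]


def spearman_exact_max_error(
    n_values: Sequence[int] = (4, 5, 6), n_draws: int = 5, seed: int = 0
) -> float:
    """Largest |p_exact - p_enumerated| for random tie-free vectors, where
    the oracle enumerates all n! orderings of the raw y values directly."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in n_values:
        for _ in range(n_draws):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = spearman_corr(x, y, method="exact")
            # independent oracle: permute raw y values, recompute rho each time
            obs = abs(rho)
            hits = 0
            total = 0
            for perm in itertools.permutations(y):
                r, _ = spearman_corr(x, perm)
                hits += abs(r) >= obs - 1e-12
                total += 1
            worst = max(worst, abs(p - hits / total))
    return worst


# ---------------------------------------------------------------- imputation contract


def imputation_contract(seed: int = 0, n_negative: int = 25) -> dict:
    """Check the imputation rule on a constructed table: every imputed value
    must be the mean of two distinct members of the 10-lowest-positive
    drawing set (i.e. lie among the C(10,2) pairwise means) and strictly
    positive values must pass through unchanged."""
    rng = np.random.default_rng(seed)
    n_pos = 60
    pos = np.sort(rng.uniform(0.01, 2.0, n_pos))
    neg = -rng.uniform(0.0, 0.5, n_negative)
    vals = rng.permutation(np.concatenate([pos, neg]))
    events = pd.DataFrame(
        {
            "event_id": [f"e{i}" for i in range(vals.size)],
            "patient_id": "P1",
            "sample_id": "P1_c0",
            "session_id": "S0_01",
            "cycle": 0,
            "response": synthio.RESPONDER,
            "epcam_mfi": vals,
            "psma_mfi": 1.0,
            "is_control": False,
        }
    )
    cfg = fp.ImputationConfig(seed=seed)
    out, log = fp.impute_negative_mfi(events, "epcam", cfg)

    draw_set = pos[:10]
    pair_means = {
        round((a + b) / 2.0, 12) for a, b in itertools.combinations(draw_set, 2)
    }
    imputed = out["epcam_mfi"].to_numpy()
    violations = 0
    for orig, new in zip(vals, imputed):
        if orig > 0:
            violations += int(new != orig)
        else:
            violations += int(round(float(new), 12) not in pair_means)
    return {
        "n_imputed": int(len(log)),
        "n_checked": int(vals.size),
        "violations": int(violations),
    }


# ---------------------------------------------------------------- scRNA QC boundary


def qc_boundary_grid() -> dict:
    """The eight boundary cells around the QC cutoffs.

    For each threshold the cell exactly at the boundary must be kept (strict
    inequalities) and the cell one step past it removed.  Returns the number
    of cells classified incorrectly (0 when the rule is implemented
    faithfully)."""
    import anndata as ad

    cases = [
        # (total_counts, genes_detected, mt_fraction, expect_keep)
        (4000, 2000, 0.10, True),
        (3999, 2000, 0.10, False),
        (50_000, 1000, 0.10, True),
        (50_000, 999, 0.10, False),
        (50_000, 7800, 0.10, True),
        (50_000, 7801, 0.10, False),
        (50_000, 2000, 0.75, True),
        (50_000, 2000, 0.7501, False),
    ]
    n_genes = 7802
    genes = [f"G{i}" for i in range(n_genes - 1)] + ["MT-1"]
    X = np.zeros((len(cases), n_genes), dtype=np.int64)
    for i, (total, g, f, _) in enumerate(cases):
        mt = int(round(total * f))
        rest = total - mt
        n_nonmt = g - 1  # the MT gene is always detected
        base = rest // n_nonmt
        X[i, :n_nonmt] = base
        X[i, : rest - base * n_nonmt] += 1
        X[i, -1] = mt
        # patch up: ensure detected-gene count is exact
        assert (X[i] > 0).sum() == g, (i, (X[i] > 0).sum(), g)
        assert X[i].sum() == total
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"cell{i}" for i in range(len(cases))]),
        var=pd.DataFrame(index=genes),
    )
    kept, qc = sp.qc_filter_cells(adata, mt_genes=["MT-1"])
    errors = sum(
        int(bool(qc["keep"].iloc[i]) != expect)
        for i, (_, _, _, expect) in enumerate(cases)
    )
    return {"n_cells": len(cases), "errors": int(errors), "qc": qc}


# ---------------------------------------------------------------- DEG recovery


def deg_recovery(seed: int = 0) -> dict:
    """Sensitivity and false-discovery proportion on the planted DEG fixture
    (2,000 genes, 60 cells per cluster, 100 planted |log2FC| >= 1.5 genes)
    after Bonferroni and 2-fold filtering."""
    cfg = synthio.CountSimConfig(seed=seed)
    adata = synthio.simulate_counts(cfg)
    kept, _ = sp.qc_filter_cells(adata)
    norm = sp.lognormalize(kept)
    dge = sp.dge_wilcoxon(norm, kept.obs["true_cluster"].to_numpy(), list(kept.var_names))
    ranked = sp.filter_and_rank_degs(dge)

    truth = kept.var["true_log2fc"].abs() >= 1.0
    called = set(ranked["significant"]["gene"])
    true_set = set(kept.var_names[truth])
    tp = len(called & true_set)
    fp_ = len(called - true_set)
    return {
        "n_true": len(true_set),
        "n_called": len(called),
        "sensitivity": tp / len(true_set) if true_set else float("nan"),
        "fdp": fp_ / len(called) if called else 0.0,
    }


def null_deg_counts(n_seeds: int = 20, base_seed: int = 100) -> list[int]:
    """Significant-gene counts over fully null fixtures (no planted DEGs).

    With family-wise control at 0.05 the count should be 0 or 1 in nearly
    every seed."""
    out = []
    for i in range(n_seeds):
        cfg = synthio.CountSimConfig(n_deg=0, seed=base_seed + i)
        adata = synthio.simulate_counts(cfg)
        kept, _ = sp.qc_filter_cells(adata)
        norm = sp.lognormalize(kept)
        dge = sp.dge_wilcoxon(norm, kept.obs["true_cluster"].to_numpy(), list(kept.var_names))
        ranked = sp.filter_and_rank_degs(dge)
        out.append(int(ranked["significant"].shape[0]))
    return out


# ---------------------------------------------------------------- hub filter


def hub_filter_recovery(seed: int = 0, rho: float = 0.5) -> dict:
    """Planted hub genes (correlated in >=2 methods, significant DEGs) must
    pass the three-criterion filter; single-method and non-DEG decoys must
    fail.

    Hub candidates are planted on genes the DGE stage itself calls
    significant (mirroring the real workflow, where hub analysis follows
    differential expression), plus one decoy correlated in a single method
    and one decoy gene that is not a DEG.  The fixture uses 200 cells per
    cluster so the null sampling error of Spearman's rho (~0.05 post-QC)
    stays well below the 0.2 filter threshold: a decoy can then only pass
    through the filter logic, not through chance correlation.
    """
    cfg = synthio.CountSimConfig(cells_per_cluster=200, seed=seed)
    adata = synthio.simulate_counts(cfg)
    kept, _ = sp.qc_filter_cells(adata)
    norm = sp.lognormalize(kept)
    norm_df = pd.DataFrame(norm, index=kept.obs_names, columns=kept.var_names)

    dge = sp.dge_wilcoxon(norm, kept.obs["true_cluster"].to_numpy(), list(kept.var_names))
    ranked = sp.filter_and_rank_degs(dge)
    sig = set(ranked["significant"]["gene"])

    top_sig = list(ranked["significant"]["gene"].head(4))
    null_pool = kept.var_names[
        (kept.var["true_log2fc"].to_numpy() == 0) & ~kept.var["is_mt"].to_numpy()
    ]
    non_deg = str(null_pool[0])
    methods = ("AUCell", "UCell", "ssGSEA")
    planted = tuple(
        [synthio.PlantedHub(g, f"SET_{g}", rho, methods) for g in top_sig[:3]]
        + [
            synthio.PlantedHub(top_sig[3], f"SET_{top_sig[3]}", rho, methods[:1]),
            synthio.PlantedHub(non_deg, f"SET_{non_deg}", rho, methods),
        ]
    )
    hub_cfg = synthio.HubSimConfig(methods=methods, planted=planted, seed=seed)
    scores = synthio.simulate_geneset_scores(kept, hub_cfg, norm_expr=norm_df)

    candidates = sorted({p.gene for p in hub_cfg.planted})
    records = sp.hub_correlations(
        norm_df, scores, candidates, geneset_members=hub_cfg.geneset_members()
    )
    hubs, _ = sp.filter_hub_genes(records, sig)

    true_hubs = top_sig[:3]
    decoys = [top_sig[3], non_deg]
    return {
        "true_hubs": true_hubs,
        "decoys": decoys,
        "recovered": hubs,
        "all_true_recovered": set(true_hubs) <= set(hubs),
        "all_decoys_rejected": not (set(decoys) & set(hubs)),
    }
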