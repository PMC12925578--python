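"""End-to-end orchestration: config, stage chaining, summary and report.

A :class:`RunConfig` (deserializable from YAML) drives one reproducible run:
simulate -> flow QC -> normalize -> exclude unknown -> impute -> filter ->
classify -> dynamics -> scRNA QC -> DGE -> hub filter -> pooling (stages as
enabled).  Per-stage seeds are derived from the master seed through
``numpy.random.SeedSequence(master).generate_state(...)``, so one integer
reproduces the whole bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import flow_pipeline as fp
from . import scrna_pipeline as sp
from . import synthio
from .libprep_calc import plan_pooling
from .stats_core import TestResult

__all__ = ["RunConfig", "stage_seeds", "run_flow_stages", "run_scrna_stages", "run_pipeline", "write_report"]


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage integer seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``flow``, ``scrna`` and ``hub`` toggles enable stage groups; parameter
    sub-dicts override the simulation and analysis defaults.  ``libprep_csv``
    points at a fragment-analyzer summary CSV (the pooling stage is skipped
    when it is absent).
    """

    seed: int = 0
    run_flow: bool = True
    run_scrna: bool = True
    libprep_csv: str | None = None
    cohort: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)  # min_cells_per_cycle, outlier_k, expected
    scrna: dict = field(default_factory=dict)  # qc threshold overrides
    libprep: dict = field(default_factory=dict)  # target_fmol

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _test_dict(t: TestResult) -> dict:
    return {"statistic": t.statistic, "p_value": t.p_value, "method": t.method}


def run_flow_stages(
    events: pd.DataFrame,
    imputation_seed: int = 0,
    min_cells_per_cycle: int = 5,
    outlier_k: float = 3.0,
    expected: str = "overall_proportions",
) -> dict:
    """Run the flow analysis chain on a raw event table.

    Returns a bundle dict with every intermediate table, the derived
    thresholds, the classification/distribution/dynamics readouts and a
    JSON-able ``summary``.
    """
    summaries, robust = fp.summarize_controls(events)
    normalized = fp.normalize_events(events, summaries)
    ctc, exclusion_log = fp.exclude_unknown_response(normalized)
    n_unknown_excluded = int((~events["is_control"]).sum()) - len(ctc)
    imput_logs = {}
    for i, ch in enumerate(fp.CHANNELS):
        cfg = fp.ImputationConfig(seed=imputation_seed + i)
        ctc, imput_logs[ch] = fp.impute_negative_mfi(ctc, ch, cfg)
    rule = fp.OutlierRule(k=outlier_k)
    retained, outlier_log = fp.filter_outliers(ctc, rule)
    thresholds = fp.derive_thresholds(retained)
    classified = fp.classify_events(retained, thresholds)
    distribution = fp.subpop_distribution(classified, expected=expected)
    comparisons = {ch: fp.compare_groups_mfi(retained, ch) for ch in fp.CHANNELS}
    dynamics = {
        ch: fp.cycle_dynamics(retained, ch, min_cells_per_cycle) for ch in fp.CHANNELS
    }
    per_sample, count_summary, count_test = fp.ctc_count_stats(retained)

    summary = {
        "n_events_in": int(len(events)),
        "n_controls": int(events["is_control"].sum()),
        "n_ctc_in": int((~events["is_control"]).sum()),
        "n_excluded_unknown": n_unknown_excluded,
        "n_imputed": {ch: int(len(imput_logs[ch])) for ch in fp.CHANNELS},
        "n_outliers_removed": int(events.loc[~events["is_control"], "event_id"].isin(
            outlier_log["event_id"]).sum()) if len(outlier_log) else 0,
        "n_retained": int(len(retained)),
        "n_retained_by_group": {
            g: int((retained["response"] == g).sum())
            for g in (synthio.RESPONDER, synthio.NONRESPONDER)
        },
        "thresholds": {"epcam": thresholds.epcam, "psma": thresholds.psma},
        "control_grand_median": {ch: robust[ch].grand_median for ch in fp.CHANNELS},
        "control_mad": {ch: robust[ch].mad for ch in fp.CHANNELS},
        "control_madm": {ch: robust[ch].madm for ch in fp.CHANNELS},
        "subpop_counts": {
            r["subpop"]: {"responder": r["n_responder"], "nonresponder": r["n_nonresponder"]}
            for r in distribution.to_dict("records")
        },
        "group_comparison": {
            ch: {
                "responder_median": comparisons[ch].responder_median,
                "nonresponder_median": comparisons[ch].nonresponder_median,
                "responder_log10_median": comparisons[ch].responder_log10_median,
                "nonresponder_log10_median": comparisons[ch].nonresponder_log10_median,
                "p_value": comparisons[ch].test.p_value,
            }
            for ch in fp.CHANNELS
        },
        "ctc_counts": {
            "per_group": count_summary.set_index("group").to_dict("index"),
            "test": _test_dict(count_test),
        },
        "dynamics": {
            ch: dynamics[ch].to_dict("records") for ch in fp.CHANNELS
        },
    }
    return {
        "control_summaries": summaries,
        "control_robust": robust,
        "normalized": normalized,
        "exclusion_log": exclusion_log,
        "imputation_logs": imput_logs,
        "outlier_log": outlier_log,
        "retained": retained,
        "thresholds": thresholds,
        "classified": classified,
        "distribution": distribution,
        "comparisons": comparisons,
        "dynamics": dynamics,
        "counts_per_sample": per_sample,
        "counts_summary": count_summary,
        "counts_test": count_test,
        "summary": summary,
    }


def run_scrna_stages(
    adata,
    hub_config: synthio.HubSimConfig | None = None,
    qc_thresholds: sp.CellQCThresholds = sp.CellQCThresholds(),
) -> dict:
    """Run the single-cell chain: QC -> lognormalize -> composition tests ->
    Wilcoxon DGE on the cluster labels -> ranking -> hub filter.

    Cluster labels are taken from ``obs['true_cluster']`` (synthetic truth;
    with real data, pass an AnnData whose obs carries the cluster calls).
    """
    kept, qc = sp.qc_filter_cells(adata, qc_thresholds)
    norm = sp.lognormalize(kept)
    labels = kept.obs["true_cluster"].to_numpy()

    composition = {}
    for cov in ("response", "cycle", "treatment_type"):
        if cov not in kept.obs:
            continue
        try:
            table, test = sp.composition_association(labels, kept.obs[cov])
            composition[cov] = {"table": table, "test": test}
        except ValueError as err:
            composition[cov] = {"table": None, "notice": str(err)}

    dge = sp.dge_wilcoxon(norm, labels, list(kept.var_names))
    ranked = sp.filter_and_rank_degs(dge)

    hub = None
    if hub_config is not None:
        norm_df = pd.DataFrame(norm, index=kept.obs_names, columns=kept.var_names)
        scores = synthio.simulate_geneset_scores(kept, hub_config, norm_expr=norm_df)
        candidates = sorted({p.gene for p in hub_config.planted})
        hub_rec = sp.hub_correlations(
            norm_df, scores, candidates, geneset_members=hub_config.geneset_members()
        )
        hub_genes, hub_rec = sp.filter_hub_genes(hub_rec, set(ranked["significant"]["gene"]))
        hub = {"records": hub_rec, "hub_genes": hub_genes, "scores": scores}

    summary = {
        "n_cells_in": int(adata.n_obs),
        "n_cells_kept": int(kept.n_obs),
        "removal_reasons": qc.loc[~qc["keep"], "removal_reason"].value_counts().to_dict(),
        "composition_p": {
            cov: (d["test"].p_value if "test" in d else None) for cov, d in composition.items()
        },
        "n_significant_degs": int(ranked["significant"].shape[0]),
        "n_up": ranked["n_up"],
        "n_down": ranked["n_down"],
        "top_degs": list(ranked["top"]["gene"]),
        "hub_genes": hub["hub_genes"] if hub else None,
    }
    return {
        "adata": kept,
        "qc": qc,
        "norm": norm,
        "composition": composition,
        "dge": dge,
        "ranked": ranked,
        "hub": hub,
        "summary": summary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages of one seeded run and collect a bundle.

    The bundle's ``summary`` is a JSON-able dict holding every count and
    p-value together with the stage that produced it.
    """
    seeds = stage_seeds(config.seed)
    bundle: dict[str, Any] = {"config": dataclasses.asdict(config)}
    summary: dict[str, Any] = {"seed": config.seed}

    if config.run_flow:
        cohort_cfg = synthio.CohortConfig(seed=seeds[0], **config.cohort)
        skeleton = synthio.simulate_cohort(cohort_cfg)
        events = synthio.simulate_flow_events(skeleton)
        flow = run_flow_stages(
            events,
            imputation_seed=seeds[1],
            min_cells_per_cycle=int(config.flow.get("min_cells_per_cycle", 5)),
            outlier_k=float(config.flow.get("outlier_k", 3.0)),
            expected=str(config.flow.get("expected", "overall_proportions")),
        )
        bundle["events"] = events
        bundle["flow"] = flow
        summary["flow"] = flow["summary"]

    if config.run_scrna:
        counts_cfg = synthio.CountSimConfig(seed=seeds[2], **config.counts)
        adata = synthio.simulate_counts(counts_cfg)
        qc_kwargs = {
            k: config.scrna[k]
            for k in ("min_counts", "min_genes", "max_genes", "max_mt_fraction")
            if k in config.scrna
        }
        scrna = run_scrna_stages(
            adata,
            hub_config=synthio.default_hub_config(adata, seed=seeds[3]),
            qc_thresholds=sp.CellQCThresholds(**qc_kwargs),
        )
        bundle["scrna"] = scrna
        summary["scrna"] = scrna["summary"]

    if config.libprep_csv:
        samples = pd.read_csv(config.libprep_csv)
        plan, meta = plan_pooling(samples, target_fmol=config.libprep.get("target_fmol"))
        bundle["libprep"] = {"plan": plan, "meta": meta}
        summary["libprep"] = meta

    bundle["summary"] = summary
    return bundle


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays so json.dumps emits numbers."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, np.str_):
        return str(obj)
    return obj


def _fmt_df(df: pd.DataFrame) -> str:
    with pd.option_context("display.width", 120, "display.max_columns", 40):
        return df.round(6).to_string(index=False)


def write_report(bundle: dict, outdir: str | Path) -> Path:
    """Write the bundle's tables (CSV), summary (JSON) and a deterministic
    human-readable report.  Returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(bundle["summary"]), indent=2, sort_keys=True, default=str) + "\n"
    )

    lines = ["# ctcmd run report", ""]
    flow = bundle.get("flow")
    if flow is not None:
        flow["retained"].to_csv(outdir / "flow_retained_events.csv", index=False)
        flow["classified"].to_csv(outdir / "flow_classified_events.csv", index=False)
        flow["distribution"].to_csv(outdir / "flow_subpop_distribution.csv", index=False)
        pd.concat(flow["dynamics"].values()).to_csv(outdir / "flow_dynamics.csv", index=False)
        flow["counts_per_sample"].to_csv(outdir / "flow_counts_per_sample.csv", index=False)
        s = flow["summary"]
        lines += [
            "## Flow cytometry",
            f"events in: {s['n_events_in']} (controls {s['n_controls']})",
            f"unknown-response events excluded: {s['n_excluded_unknown']}",
            f"imputed negatives: {s['n_imputed']}",
            f"retained events: {s['n_retained']} {s['n_retained_by_group']}",
            f"thresholds: epcam={s['thresholds']['epcam']:.6g} psma={s['thresholds']['psma']:.6g}",
            "",
            "### Subpopulation distribution",
            _fmt_df(flow["distribution"]),
            "",
            "### CTC counts per sample",
            _fmt_df(flow["counts_summary"]),
            f"Mann-Whitney p = {flow['counts_test'].p_value:.4g}",
            "",
        ]
        for ch, dyn in flow["dynamics"].items():
            lines += [f"### Dynamics: {ch}"]
            lines += [_fmt_df(dyn) if len(dyn) else "not computed", ""]
    else:
        lines += ["## Flow cytometry", "not computed", ""]

    scrna = bundle.get("scrna")
    if scrna is not None:
        scrna["dge"].to_csv(outdir / "scrna_dge.csv", index=False)
        scrna["qc"].rename_axis("cell_id").to_csv(outdir / "scrna_qc.csv")
        if scrna["hub"]:
            scrna["hub"]["records"].to_csv(outdir / "scrna_hub_records.csv", index=False)
        s = scrna["summary"]
        lines += [
            "## scRNA-seq",
            f"cells kept: {s['n_cells_kept']} / {s['n_cells_in']}",
            f"removal reasons: {s['removal_reasons']}",
            f"composition test p-values: {s['composition_p']}",
            f"significant DEGs: {s['n_significant_degs']} (up {s['n_up']}, down {s['n_down']})",
            f"top DEGs: {', '.join(s['top_degs'])}",
            f"hub genes: {s['hub_genes']}",
            "",
        ]
    else:
        lines += ["## scRNA-seq", "not computed", ""]

    lib = bundle.get("libprep")
    if lib is not None:
        lib["plan"].to_csv(outdir / "libprep_pooling_plan.csv", index=False)
        lines += [
            "## Library pooling",
            f"median molarity: {lib['meta']['median_molarity_nM']:.4g} nM; "
            f"target {lib['meta']['target_fmol']:.4g} fmol/sample; "
            f"kept {lib['meta']['n_kept']}, discarded {lib['meta']['n_discarded']}",
            "",
        ]

    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report
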