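"""Sequencing-library pooling arithmetic.

Converts fragment-analyzer sample summaries (concentration in ng/uL,
average fragment size in bp over the 200-1,500 bp analysis window) to molar
concentrations, splits the cohort at the median molarity, dilutes
above-median samples to the median, discards sub-nanomolar samples, and
plans an equimolar pool (a fixed number of femtomoles per kept sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DSDNA_G_PER_MOL_PER_BP", "molarity_from_profile", "plan_pooling"]

# Standard average mass of one double-stranded DNA base pair.
DSDNA_G_PER_MOL_PER_BP = 650.0


def molarity_from_profile(conc_ng_per_ul: float, avg_fragment_bp: float) -> float:
    """Molarity (nM) of a library from its fragment-analysis summary.

    ``nM = conc[ng/uL] * 1e6 / (avg_fragment_bp * 650)`` — i.e. mass
    concentration divided by the average fragment's molar mass.
    """
    if avg_fragment_bp <= 0:
        raise ValueError("average fragment size must be positive")
    if conc_ng_per_ul < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ng_per_ul * 1e6 / (avg_fragment_bp * DSDNA_G_PER_MOL_PER_BP)


def plan_pooling(
    samples: pd.DataFrame,
    target_fmol: float | None = None,
    min_molarity_nm: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Equimolar pooling plan from fragment-analyzer summaries.

    ``samples`` needs columns ``sample_id, conc_ng_per_ul, avg_fragment_bp``.
    Samples below ``min_molarity_nm`` are discarded; the cohort median
    molarity is computed over kept samples; samples strictly above the
    median are assigned a dilution factor bringing them to the median
    (samples at or below the median, including exact ties, are left
    undiluted); every kept sample contributes ``target_fmol`` femtomoles
    (default: the median molarity x 1 uL), so
    ``volume_ul = target_fmol / working_molarity``.

    Returns the per-sample plan and a metadata dict with the median and the
    target.
    """
    needed = {"sample_id", "conc_ng_per_ul", "avg_fragment_bp"}
    missing = needed - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    plan = samples.copy()
    plan["molarity_nM"] = [
        molarity_from_profile(c, b)
        for c, b in zip(plan["conc_ng_per_ul"], plan["avg_fragment_bp"])
    ]
    plan["keep"] = plan["molarity_nM"] >= min_molarity_nm
    plan["discard_reason"] = np.where(plan["keep"], "", f"below {min_molarity_nm:g} nM")
    kept = plan.loc[plan["keep"], "molarity_nM"]
    if kept.empty:
        raise ValueError("all samples fall below the molarity floor")
    median = float(kept.median())
    if target_fmol is None:
        target_fmol = median  # median nM x 1 uL transfer

    above = plan["keep"] & (plan["molarity_nM"] > median)
    plan["group"] = np.where(above, "above_median", "below_median")
    plan.loc[~plan["keep"], "group"] = ""
    plan["dilution_factor"] = np.where(above, plan["molarity_nM"] / median, 1.0)
    plan["working_molarity_nM"] = np.where(above, median, plan["molarity_nM"])
    plan["volume_ul"] = np.where(plan["keep"], target_fmol / plan["working_molarity_nM"], 0.0)
    plan["fmol"] = plan["volume_ul"] * plan["working_molarity_nM"]
    plan.loc[~plan["keep"], ["dilution_factor", "working_molarity_nM"]] = np.nan
    meta = {
        "median_molarity_nM": median,
        "target_fmol": float(target_fmol),
        "n_kept": int(plan["keep"].sum()),
        "n_discarded": int((~plan["keep"]).sum()),
    }
    return plan, meta
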