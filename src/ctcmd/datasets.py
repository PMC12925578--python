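"""Reference summary counts of the mCRPC PSMA-radioligand CTC cohort.

Fixed, published bookkeeping numbers of the clinical cohort this pipeline's
reporting conventions follow (patients per response group, sorted and
retained CTC counts, sequencing-QC survivors, DEG tallies).  They are plain
inputs for consistency checks — nothing here is computed by the package.
"""

from __future__ import annotations

__all__ = ["MCRPC_COHORT", "check_cohort_bookkeeping"]

MCRPC_COHORT: dict = {
    # patient pre-classification
    "patients_total": 66,
    "patients_responder": 28,
    "patients_nonresponder": 16,
    "patients_unknown": 22,
    # samples per group (the reported grand total, 143, disagrees with the
    # component sum by two; the components are used for identity checks)
    "samples_responder": 74,
    "samples_nonresponder": 43,
    "samples_unknown": 28,
    "samples_total_reported": 143,
    # sorted CTCs
    "ctcs_sorted_total": 436,
    "ctcs_sorted_responder": 192,
    "ctcs_sorted_nonresponder": 244,
    # CTCs retained after flow normalization/filtering
    "ctcs_retained_total": 422,
    "ctcs_retained_responder": 181,
    "ctcs_retained_nonresponder": 241,
    # samples entering the per-sample CTC-count comparison
    "count_samples_total": 54,
    "count_samples_responder": 33,
    "count_samples_nonresponder": 21,
    # libraries passing cDNA QC, by group and cycle
    "libraries_sequenced_total": 138,
    "libraries_sequenced_pct_of_sorted": 31.6,
    "libraries_by_group_cycle": {
        "Responder": {0: 36, 1: 31, 2: 11},
        "Nonresponder": {0: 15, 1: 38, 2: 7},
    },
    # cells surviving scRNA-seq QC
    "cells_after_scrna_qc_total": 99,
    "cells_after_scrna_qc_responder": 58,
    "cells_after_scrna_qc_nonresponder": 41,
    # differential expression tallies
    "degs_bonferroni_significant": 8544,
    "degs_after_fc_filter": 7630,
    "degs_up_cluster0": 7176,
    "degs_down_cluster0": 454,
    "hub_genes": 30,
}


def check_cohort_bookkeeping(cohort: dict = MCRPC_COHORT) -> dict[str, bool]:
    """Recompute the cohort's bookkeeping identities from its components.

    Each entry is True when the recomputed sum (or percentage, to printed
    precision) agrees with the reported aggregate.
    """
    c = cohort
    lib = c["libraries_by_group_cycle"]
    lib_total = sum(sum(d.values()) for d in lib.values())
    pct = 100.0 * c["libraries_sequenced_total"] / c["ctcs_sorted_total"]
    return {
        "patient_groups_sum_to_total": (
            c["patients_responder"] + c["patients_nonresponder"] + c["patients_unknown"]
            == c["patients_total"]
        ),
        "sorted_ctcs_sum_to_total": (
            c["ctcs_sorted_responder"] + c["ctcs_sorted_nonresponder"]
            == c["ctcs_sorted_total"]
        ),
        "retained_ctcs_sum_to_total": (
            c["ctcs_retained_responder"] + c["ctcs_retained_nonresponder"]
            == c["ctcs_retained_total"]
        ),
        "count_comparison_samples_sum": (
            c["count_samples_responder"] + c["count_samples_nonresponder"]
            == c["count_samples_total"]
        ),
        "library_cells_sum_over_groups_and_cycles": lib_total
        == c["libraries_sequenced_total"],
        "library_fraction_matches_printed_pct": (
            abs(pct - c["libraries_sequenced_pct_of_sorted"]) < 0.1
        ),
        "scrna_qc_cells_sum_to_total": (
            c["cells_after_scrna_qc_responder"] + c["cells_after_scrna_qc_nonresponder"]
            == c["cells_after_scrna_qc_total"]
        ),
        "deg_directions_sum_to_filtered_total": (
            c["degs_up_cluster0"] + c["degs_down_cluster0"] == c["degs_after_fc_filter"]
        ),
        "fc_filter_is_subset_of_significant": (
            c["degs_after_fc_filter"] <= c["degs_bonferroni_significant"]
        ),
    }
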