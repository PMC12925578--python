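"""Plain-text readers and writers for the pipeline's tables.

Flow events travel as CSV (one row per event, controls flagged by the
``is_control`` column); count matrices as MatrixMarket (genes x cells) with
gene and cell TSV sidecars; gene-set score matrices as one CSV per method.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

FLOW_COLUMNS = [
    "event_id",
    "patient_id",
    "sample_id",
    "session_id",
    "cycle",
    "response",
    "epcam_mfi",
    "psma_mfi",
    "is_control",
]


def write_flow_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.loc[:, FLOW_COLUMNS].to_csv(path, index=False)


def read_flow_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cycle": int})
    missing = set(FLOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flow CSV missing columns: {sorted(missing)}")
    df["is_control"] = df["is_control"].astype(bool)
    df["response"] = df["response"].astype("object").where(df["response"].notna(), pd.NA)
    return df


def write_counts_mtx(adata: "ad.AnnData", outdir: str | Path) -> None:
    """Write counts as genes x cells MatrixMarket plus TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(adata.X).T)  # genes x cells
    spio.mmwrite(str(outdir / "counts.mtx"), mat, field="integer")
    adata.var.reset_index().to_csv(outdir / "genes.tsv", sep="\t", index=False)
    adata.obs.reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)
    mt = adata.uns.get("mt_genes", [])
    (outdir / "mt_genes.txt").write_text("\n".join(mt) + ("\n" if mt else ""))


def read_counts_mtx(indir: str | Path) -> "ad.AnnData":
    indir = Path(indir)
    mat = spio.mmread(str(indir / "counts.mtx")).toarray().T  # cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    adata = ad.AnnData(X=mat.astype(np.int64), obs=cells, var=genes)
    mt_path = indir / "mt_genes.txt"
    if mt_path.exists():
        adata.uns["mt_genes"] = [g for g in mt_path.read_text().splitlines() if g]
    return adata


def write_score_csvs(scores: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for method, df in scores.items():
        df.rename_axis("cell_id").to_csv(outdir / f"scores_{method}.csv")


def read_score_csvs(indir: str | Path) -> dict[str, pd.DataFrame]:
    indir = Path(indir)
    out = {}
    for path in sorted(indir.glob("scores_*.csv")):
        method = path.stem.removeprefix("scores_")
        out[method] = pd.read_csv(path).set_index("cell_id")
    if not out:
        raise ValueError(f"no scores_*.csv files under {indir}")
    return out
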