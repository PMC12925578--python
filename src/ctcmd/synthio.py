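"""Seeded synthetic cohort generators.

This module defines the study conditions the rest of the package is exercised
against, emulating the data structures of an index-sorted CTC cohort from
mCRPC patients under PSMA-targeted radioligand therapy:

* a flow-cytometry event table (one row per sorted cell) with per-session
  C4-2 control wells, multiplicative sort-session batch effects, lognormal
  within-sample MFI noise and a baseline-subtraction artifact producing
  negative MFIs;
* a Smart-seq2-like genes x cells count matrix with two planted clusters,
  planted differentially expressed genes and per-cell QC covariates that
  straddle the downstream filter thresholds;
* per-method (cells x gene sets) enrichment-score matrices with planted
  Spearman correlations to chosen hub genes.

All generators are pure functions of their config; a fixed seed yields
byte-identical outputs.  The master seed is split into independent per-stage
substreams (cohort skeleton, flow events, counts, scores) so stages can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

try:  # anndata is a hard dependency, guarded only to keep import errors readable
    import anndata as ad
except ImportError as exc:  # pragma: no cover
    raise ImportError("ctcmd.synthio requires the 'anndata' package") from exc

__all__ = [
    "ConfigError",
    "RESPONDER",
    "NONRESPONDER",
    "UNKNOWN",
    "CHANNELS",
    "DEFAULT_MARKER_MEDIANS",
    "CohortConfig",
    "CohortSkeleton",
    "CountSimConfig",
    "PlantedHub",
    "HubSimConfig",
    "simulate_cohort",
    "simulate_flow_events",
    "simulate_counts",
    "simulate_geneset_scores",
    "default_hub_config",
]


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


RESPONDER = "Responder"
NONRESPONDER = "Nonresponder"
UNKNOWN = "Unknown"
CHANNELS = ("epcam", "psma")

# Planted per-cycle median normalized MFIs (group, cycle, channel).  Printed
# study values are used wherever available; the remaining cells are fixed
# design choices (see docs/methods.md): Responder EpCAM converges toward the
# Nonresponder level at later cycles, Nonresponder PSMA declines with a clear
# cycle-3 drop, cycle 4 reuses cycle 3, the Unknown group sits between the
# two response groups.
DEFAULT_MARKER_MEDIANS: dict[tuple[str, int, str], float] = {
    (RESPONDER, 0, "epcam"): 0.3299,
    (RESPONDER, 1, "epcam"): 0.0992,
    (RESPONDER, 2, "epcam"): 0.25,
    (RESPONDER, 3, "epcam"): 0.25,
    (RESPONDER, 4, "epcam"): 0.25,
    (NONRESPONDER, 0, "epcam"): 0.8258,
    (NONRESPONDER, 1, "epcam"): 0.8849,
    (NONRESPONDER, 2, "epcam"): 0.2872,
    (NONRESPONDER, 3, "epcam"): 0.2706,
    (NONRESPONDER, 4, "epcam"): 0.2706,
    (RESPONDER, 0, "psma"): 0.1920,
    (RESPONDER, 1, "psma"): 0.1181,
    (RESPONDER, 2, "psma"): 0.0453,
    (RESPONDER, 3, "psma"): 0.0186,
    (RESPONDER, 4, "psma"): 0.0186,
    (NONRESPONDER, 0, "psma"): 0.0683,
    (NONRESPONDER, 1, "psma"): 0.0883,
    (NONRESPONDER, 2, "psma"): 0.0550,
    (NONRESPONDER, 3, "psma"): 0.0300,
    (NONRESPONDER, 4, "psma"): 0.0300,
}
for _c in range(5):
    DEFAULT_MARKER_MEDIANS[(UNKNOWN, _c, "epcam")] = 0.5
    DEFAULT_MARKER_MEDIANS[(UNKNOWN, _c, "psma")] = 0.1

_STAGE_INDEX = {"cohort": 0, "flow": 1, "counts": 2, "scores": 3}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic flow-cytometry cohort.

    Defaults reproduce the study conditions: paired Responder/Nonresponder
    sort sessions over treatment cycles 0-4, per-sample sorted-CTC counts
    with group medians 2 (Responder) and 8 (Nonresponder), per-cycle marker
    medians seeded from the printed study values, a small Unknown-response
    fraction to exercise the exclusion rule, and near-empty cycle-4 groups
    (Responder 3 cells, Nonresponder 0) so the dynamics cycle cutoff is
    exercised.

    ``log_mfi_sd`` and ``session_batch_sd`` are standard deviations on the
    log10 scale; ``detection_floor`` is the scale (as a fraction of the
    control median) of the half-normal baseline-subtraction noise that
    produces negative MFIs.
    """

    n_patients_per_group: int = 28
    cycles: tuple[int, ...] = (0, 1, 2, 3, 4)
    ctc_count_dispersion: float = 1.5
    group_ctc_count_medians: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: 2.0, NONRESPONDER: 8.0, UNKNOWN: 4.0}
    )
    marker_medians: Mapping[tuple[str, int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_MEDIANS)
    )
    log_mfi_sd: float = 0.15
    session_batch_sd: float = 0.10
    detection_floor: float = 0.01
    unknown_response_fraction: float = 0.10
    control_base_mfi: Mapping[str, float] = field(
        default_factory=lambda: {"epcam": 1000.0, "psma": 500.0}
    )
    control_log_sd: float = 0.05
    n_control_events: int = 30
    cycle_total_cell_caps: Mapping[int, Mapping[str, int]] = field(
        default_factory=lambda: {4: {RESPONDER: 3, NONRESPONDER: 0, UNKNOWN: 0}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients_per_group <= 0:
            raise ConfigError("n_patients_per_group must be positive")
        if self.ctc_count_dispersion <= 0:
            raise ConfigError("ctc_count_dispersion must be positive")
        cycles = tuple(self.cycles)
        if not cycles or cycles[0] != 0 or list(cycles) != sorted(set(cycles)):
            raise ConfigError("cycles must be sorted, unique and start at 0")
        if not (0.0 <= self.unknown_response_fraction < 1.0):
            raise ConfigError("unknown_response_fraction must lie in [0, 1)")
        for g, m in self.group_ctc_count_medians.items():
            if m <= 0:
                raise ConfigError(f"CTC count median for {g} must be positive")
        for key, m in self.marker_medians.items():
            if m <= 0:
                raise ConfigError(f"marker median {key} must be positive")
        for ch in CHANNELS:
            if self.control_base_mfi[ch] <= 0:
                raise ConfigError("control base MFIs must be positive")
        if self.log_mfi_sd < 0 or self.session_batch_sd < 0 or self.detection_floor < 0:
            raise ConfigError("noise scales must be non-negative")
        groups = [RESPONDER, NONRESPONDER]
        if self.unknown_response_fraction > 0:
            groups.append(UNKNOWN)
        for g in groups:
            for c in cycles:
                for ch in CHANNELS:
                    if (g, c, ch) not in self.marker_medians:
                        raise ConfigError(f"marker_medians missing entry {(g, c, ch)}")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent substream for one generation stage."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGE_INDEX))
        return np.random.default_rng(children[_STAGE_INDEX[stage]])


@dataclass(frozen=True)
class CohortSkeleton:
    """Sampled cohort layout: patients, sessions, samples with planned cells."""

    patients: pd.DataFrame  # patient_id, response
    samples: pd.DataFrame  # sample_id, patient_id, session_id, response, cycle, n_cells
    config: CohortConfig


def _zero_truncated_nb_median(mu: float, r: float) -> float:
    p = r / (r + mu)
    f0 = float(_sps.nbinom.cdf(0, r, p))
    q = f0 + 0.5 * (1.0 - f0)
    return float(_sps.nbinom.ppf(q, r, p))


@lru_cache(maxsize=None)
def _nb_mean_for_median(target_median: float, dispersion: float) -> float:
    """Mean of a zero-truncated NB whose median equals ``target_median``.

    The truncated median is a step function of the mean; the returned mean is
    the geometric midpoint of the plateau where the median equals the target,
    found by bisection (the median is monotone in the mean).
    """

    def boundary(level: float) -> float:
        lo, hi = 1e-3, 1e5
        for _ in range(80):
            mid = (lo * hi) ** 0.5
            if _zero_truncated_nb_median(mid, dispersion) >= level:
                hi = mid
            else:
                lo = mid
        return hi

    lo = boundary(target_median)
    hi = boundary(target_median + 1.0)
    return (lo * hi) ** 0.5


def simulate_cohort(config: CohortConfig) -> CohortSkeleton:
    """Sample the cohort layout: paired sort sessions and per-sample CTC counts.

    Each sort session holds one Responder and one Nonresponder sample plus a
    control well; Unknown-response patients get their own sessions.  Planned
    per-sample CTC counts are drawn from a negative binomial whose
    zero-truncated median matches the group's configured median (samples
    that draw zero cells model sorts that yielded no viable CTCs).  Cycle
    caps then truncate group totals (by default cycle 4 keeps at most 3
    Responder cells and no Nonresponder cells).
    """
    rng = config.stage_rng("cohort")
    npp = config.n_patients_per_group
    n_unknown = int(round(config.unknown_response_fraction * 2 * npp))

    responders = [f"R{i + 1:02d}" for i in range(npp)]
    nonresponders = [f"N{i + 1:02d}" for i in range(npp)]
    unknowns = [f"U{i + 1:02d}" for i in range(n_unknown)]
    patients = pd.DataFrame(
        {
            "patient_id": responders + nonresponders + unknowns,
            "response": [RESPONDER] * npp + [NONRESPONDER] * npp + [UNKNOWN] * n_unknown,
        }
    )

    # random pairing of Responder and Nonresponder patients per session
    r_order = list(rng.permutation(responders))
    n_order = list(rng.permutation(nonresponders))

    rows: list[dict] = []
    r = config.ctc_count_dispersion
    for cycle in config.cycles:
        for i, (rp, np_) in enumerate(zip(r_order, n_order)):
            session = f"S{cycle}_{i + 1:02d}"
            for pid, resp in ((rp, RESPONDER), (np_, NONRESPONDER)):
                rows.append(
                    {
                        "sample_id": f"{pid}_c{cycle}",
                        "patient_id": pid,
                        "session_id": session,
                        "response": resp,
                        "cycle": cycle,
                    }
                )
        for j, up in enumerate(unknowns):
            rows.append(
                {
                    "sample_id": f"{up}_c{cycle}",
                    "patient_id": up,
                    "session_id": f"S{cycle}_U{j + 1:02d}",
                    "response": UNKNOWN,
                    "cycle": cycle,
                }
            )
    samples = pd.DataFrame(rows)

    counts = np.zeros(len(samples), dtype=int)
    for group, median in config.group_ctc_count_medians.items():
        mask = (samples["response"] == group).to_numpy()
        if not mask.any():
            continue
        mu = _nb_mean_for_median(float(median), r)
        counts[mask] = rng.negative_binomial(r, r / (r + mu), size=int(mask.sum()))
    samples["n_cells"] = counts

    for cycle, caps in config.cycle_total_cell_caps.items():
        for group, cap in caps.items():
            mask = (samples["cycle"] == cycle) & (samples["response"] == group)
            idx = samples.index[mask]
            running = 0
            for i in idx:
                c = int(samples.at[i, "n_cells"])
                allowed = max(0, cap - running)
                samples.at[i, "n_cells"] = min(c, allowed)
                running += min(c, allowed)

    return CohortSkeleton(patients=patients, samples=samples, config=config)


def simulate_flow_events(skeleton: CohortSkeleton, config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the index-sorted flow event table (controls + CTCs).

    Per channel, a CTC event's raw MFI is::

        planted_median * control_base * session_batch_factor * lognormal_noise
          - |N(0, detection_floor * control_base)|

    so the half-normal subtraction term models the instrument's baseline
    subtraction and yields occasional negative MFIs on dim channels.
    Control-well events are drawn around ``control_base * session_batch_factor``
    without the subtraction artifact, which makes session-matched
    normalization cancel the batch factor exactly in expectation.
    """
    if config is None:
        config = skeleton.config
    rng = config.stage_rng("flow")
    samples = skeleton.samples

    sessions = sorted(samples["session_id"].unique())
    batch = {
        s: {ch: 10.0 ** rng.normal(0.0, config.session_batch_sd) for ch in CHANNELS}
        for s in sessions
    }

    recs: list[dict] = []
    for session in sessions:
        factors = batch[session]
        cycle = int(samples.loc[samples["session_id"] == session, "cycle"].iloc[0])
        vals = {
            ch: config.control_base_mfi[ch]
            * factors[ch]
            * 10.0 ** rng.normal(0.0, config.control_log_sd, config.n_control_events)
            for ch in CHANNELS
        }
        for k in range(config.n_control_events):
            recs.append(
                {
                    "event_id": f"{session}_ctrl_{k + 1:03d}",
                    "patient_id": "C4-2",
                    "sample_id": f"{session}_ctrl",
                    "session_id": session,
                    "cycle": cycle,
                    "response": pd.NA,
                    "epcam_mfi": vals["epcam"][k],
                    "psma_mfi": vals["psma"][k],
                    "is_control": True,
                }
            )

    for row in samples.itertuples(index=False):
        n = int(row.n_cells)
        if n == 0:
            continue
        factors = batch[row.session_id]
        vals = {}
        for ch in CHANNELS:
            med = config.marker_medians[(row.response, int(row.cycle), ch)]
            base = config.control_base_mfi[ch]
            raw = med * base * factors[ch] * 10.0 ** rng.normal(0.0, config.log_mfi_sd, n)
            if config.detection_floor > 0:
                raw = raw - np.abs(rng.normal(0.0, config.detection_floor * base, n))
            vals[ch] = raw
        for k in range(n):
            recs.append(
                {
                    "event_id": f"{row.sample_id}_e{k + 1:03d}",
                    "patient_id": row.patient_id,
                    "sample_id": row.sample_id,
                    "session_id": row.session_id,
                    "cycle": int(row.cycle),
                    "response": row.response,
                    "epcam_mfi": vals["epcam"][k],
                    "psma_mfi": vals["psma"][k],
                    "is_control": False,
                }
            )

    events = pd.DataFrame(recs)
    events["is_control"] = events["is_control"].astype(bool)
    return events


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the synthetic Smart-seq2-like count matrix.

    Two planted clusters of ``cells_per_cluster`` cells; ``n_deg`` genes carry
    a planted log2 fold change (positive = higher in cluster 0), applied
    symmetrically so the cluster mean ratio is exactly ``2**log2fc``.
    Library sizes are log-uniform across ``library_size_range`` (spanning the
    4,000-count QC cutoff) and a ``mt_stress_fraction`` of cells is pushed
    above the 75% mitochondrial cutoff so the QC filter is exercised on both
    sides.  Planted DEGs are restricted to the more abundant half of the
    non-mitochondrial genes.
    """

    n_genes: int = 2000
    cells_per_cluster: int = 60
    n_deg: int = 100
    deg_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_mt_genes: int = 50
    nb_dispersion: float = 2.0
    library_size_range: tuple[float, float] = (2_000.0, 200_000.0)
    mt_stress_fraction: float = 0.08
    mt_beta: tuple[float, float] = (2.0, 6.0)
    gene_abundance_log_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_cluster < 2:
            raise ConfigError("cells_per_cluster must be at least 2")
        if self.n_mt_genes >= self.n_genes:
            raise ConfigError("n_mt_genes must be smaller than n_genes")
        if self.n_deg > (self.n_genes - self.n_mt_genes) // 2:
            raise ConfigError("too many planted DEGs for the gene panel")
        lo, hi = self.deg_log2fc_range
        if not (0 <= lo <= hi):
            raise ConfigError("deg_log2fc_range must be non-negative and ordered")
        if not (0.0 <= self.mt_stress_fraction < 1.0):
            raise ConfigError("mt_stress_fraction must lie in [0, 1)")


def simulate_counts(config: CountSimConfig) -> "ad.AnnData":
    """Simulate a cells x genes AnnData of negative-binomial counts.

    ``obs`` carries response / cycle / treatment_type / true_cluster labels
    (treatment type tracks the cluster, response does not), ``var`` carries
    ``true_log2fc`` and ``is_mt``, and ``uns["mt_genes"]`` lists the
    mitochondrial gene ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_mt = config.n_mt_genes
    n_bg = config.n_genes - n_mt
    genes = [f"G{i + 1:04d}" for i in range(n_bg)] + [f"MT-S{i + 1:03d}" for i in range(n_mt)]
    is_mt = np.array([g.startswith("MT-") for g in genes])

    abundance = rng.lognormal(0.0, config.gene_abundance_log_sd, config.n_genes)
    # planted DEGs among the more abundant half of non-MT genes so they are
    # actually detectable at Smart-seq2-like depth
    bg_idx = np.flatnonzero(~is_mt)
    eligible = bg_idx[abundance[bg_idx] >= np.median(abundance[bg_idx])]
    deg_idx = rng.choice(eligible, size=config.n_deg, replace=False)
    lfc = np.zeros(config.n_genes)
    if config.n_deg:
        lo, hi = config.deg_log2fc_range
        mags = rng.uniform(lo, hi, config.n_deg)
        signs = rng.choice([-1.0, 1.0], config.n_deg)
        lfc[deg_idx] = mags * signs

    n_cells = 2 * config.cells_per_cluster
    clusters = np.repeat([0, 1], config.cells_per_cluster)
    lib = np.exp(
        rng.uniform(
            np.log(config.library_size_range[0]),
            np.log(config.library_size_range[1]),
            n_cells,
        )
    )
    a, b = config.mt_beta
    mt_frac = rng.beta(a, b, n_cells)
    stressed = rng.random(n_cells) < config.mt_stress_fraction
    mt_frac[stressed] = rng.uniform(0.76, 0.92, int(stressed.sum()))

    # per-cluster relative gene weights with the symmetric fold change
    w = np.tile(abundance, (2, 1))
    w[0, deg_idx] *= 2.0 ** (lfc[deg_idx] / 2.0)
    w[1, deg_idx] *= 2.0 ** (-lfc[deg_idx] / 2.0)

    mean = np.empty((n_cells, config.n_genes))
    for c in (0, 1):
        rows = clusters == c
        bg = w[c] * (~is_mt)
        mt = w[c] * is_mt
        bg = bg / bg.sum()
        mt = mt / mt.sum()
        f = mt_frac[rows][:, None]
        mean[rows] = lib[rows][:, None] * ((1.0 - f) * bg[None, :] + f * mt[None, :])

    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))

    cell_ids = [f"cell{c}_{i + 1:03d}" for c in (0, 1) for i in range(config.cells_per_cluster)]
    response = rng.choice([RESPONDER, NONRESPONDER], n_cells)
    cycle = np.where(
        clusters == 0,
        rng.choice([1, 2], n_cells),
        np.where(rng.random(n_cells) < 0.7, 0, 1),
    )
    treatment = np.where(cycle == 0, "NT", np.where(clusters == 0, "AL", "L"))

    obs = pd.DataFrame(
        {
            "response": response,
            "cycle": cycle,
            "treatment_type": treatment,
            "true_cluster": clusters,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"true_log2fc": lfc, "is_mt": is_mt},
        index=pd.Index(genes, name="gene_id"),
    )
    adata = ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)
    adata.uns["mt_genes"] = [g for g in genes if g.startswith("MT-")]
    return adata


@dataclass(frozen=True)
class PlantedHub:
    """A gene planted to correlate with one gene set's score.

    ``rho`` is the target population Spearman correlation between the gene's
    normalized expression and the gene-set score, applied in each listed
    method; in methods not listed the score is independent of the gene.
    """

    gene: str
    geneset: str
    rho: float
    methods: tuple[str, ...]


@dataclass(frozen=True)
class HubSimConfig:
    """Parameters of the synthetic per-method gene-set score matrices."""

    methods: tuple[str, ...] = ("AUCell", "UCell", "ssGSEA")
    planted: tuple[PlantedHub, ...] = ()
    n_null_genesets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.methods) < 2:
            raise ConfigError("at least two scoring methods are required")
        genesets = [p.geneset for p in self.planted]
        if len(set(genesets)) != len(genesets):
            raise ConfigError("each planted hub must target its own gene set")
        for p in self.planted:
            if not (-1.0 <= p.rho <= 1.0):
                raise ConfigError("target rho must lie in [-1, 1]")
            if not set(p.methods) <= set(self.methods):
                raise ConfigError(f"unknown method in planted hub {p.gene}")

    def geneset_members(self) -> dict[str, frozenset[str]]:
        """Gene-set membership of the planted hub candidates (each planted
        gene belongs to its own gene set)."""
        return {p.geneset: frozenset({p.gene}) for p in self.planted}


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (midranks, van der Waerden style)."""
    ranks = _sps.rankdata(values)
    return _sps.norm.ppf(ranks / (values.size + 1.0))


def simulate_geneset_scores(
    adata: "ad.AnnData",
    config: HubSimConfig,
    norm_expr: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Build per-method cells x gene-sets score matrices with planted hubs.

    Scores are built through a Gaussian copula on the gene's expression
    ranks: for a target Spearman rho the latent Pearson correlation is
    ``2 sin(pi * rho / 6)``, so the *population* Spearman correlation equals
    the target; ``rho = 1`` degenerates to an exact monotone transform of
    the expression ranks.  Non-planted (gene set, method) scores are
    independent standard normals.
    """
    from .scrna_pipeline import lognormalize  # late import to avoid a cycle

    if norm_expr is None:
        norm_expr = pd.DataFrame(
            lognormalize(adata), index=adata.obs_names, columns=adata.var_names
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = norm_expr.shape[0]

    genesets = [p.geneset for p in config.planted] + [
        f"NULL{i + 1:02d}" for i in range(config.n_null_genesets)
    ]
    planted_by_set = {p.geneset: p for p in config.planted}

    out: dict[str, pd.DataFrame] = {}
    for method in config.methods:
        cols = {}
        for gs in genesets:
            noise = rng.standard_normal(n)
            hub = planted_by_set.get(gs)
            if hub is not None and method in hub.methods:
                if hub.gene not in norm_expr.columns:
                    raise ConfigError(f"planted hub gene {hub.gene} not in expression matrix")
                z = _normal_scores(norm_expr[hub.gene].to_numpy())
                if abs(hub.rho) == 1.0:  # exact monotone transform, no noise
                    r = float(np.sign(hub.rho))
                else:
                    r = 2.0 * np.sin(np.pi * hub.rho / 6.0)
                cols[gs] = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
            else:
                cols[gs] = noise
        out[method] = pd.DataFrame(cols, index=norm_expr.index)
    return out


def default_hub_config(
    adata: "ad.AnnData",
    seed: int = 0,
    rho: float = 0.5,
    n_hubs: int = 3,
) -> HubSimConfig:
    """Default planted-hub layout derived from a simulated count fixture.

    Plants ``n_hubs`` true hubs (planted DEGs, correlated in all methods),
    one single-method decoy (a planted DEG correlated in only one method)
    and one non-DEG decoy (a null gene correlated in all methods).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    lfc = adata.var["true_log2fc"].to_numpy()
    deg_genes = list(adata.var_names[np.abs(lfc) >= 1.0])
    null_genes = list(adata.var_names[(lfc == 0) & ~adata.var["is_mt"].to_numpy()])
    if len(deg_genes) < n_hubs + 1 or not null_genes:
        raise ConfigError("fixture does not carry enough planted DEGs for hub planting")
    chosen = list(rng.choice(deg_genes, size=n_hubs + 1, replace=False))
    decoy_null = str(rng.choice(null_genes))
    methods = ("AUCell", "UCell", "ssGSEA")
    planted = tuple(
        [PlantedHub(g, f"SET_{g}", rho, methods) for g in chosen[:n_hubs]]
        + [
            PlantedHub(chosen[n_hubs], f"SET_{chosen[n_hubs]}", rho, methods[:1]),
            PlantedHub(decoy_null, f"SET_{decoy_null}", rho, methods),
        ]
    )
    return HubSimConfig(methods=methods, planted=planted, seed=seed)
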