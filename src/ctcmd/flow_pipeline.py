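"""Flow-cytometry MFI analysis of index-sorted CTCs.

Stages, in the order they are run on an event table:

1. ``summarize_controls`` — per-session C4-2 control medians plus
   cross-session grand median / MAD / MADM quality-control statistics.
2. ``normalize_events`` — divide each event's channel MFIs by the
   session-matched control median (cancels sort-to-sort variation).
3. ``exclude_unknown_response`` — drop samples from patients whose
   treatment outcome could not be classified.
4. ``impute_negative_mfi`` — replace non-positive normalized MFIs
   (baseline-subtraction artifacts) by the mean of two values drawn from
   the channel's ten lowest positive values.
5. ``filter_outliers`` — per-channel median +/- k*MAD filter on log10 MFIs.
6. ``derive_thresholds`` / ``classify_events`` — per-channel positivity
   thresholds (minimum over samples of the per-sample median MFI) and the
   EpCAM/PSMA subpopulation partition.
7. ``subpop_distribution``, ``compare_groups_mfi``, ``cycle_dynamics``,
   ``ctc_count_stats`` — the statistical readouts.

Event tables are pandas DataFrames with columns ``event_id, patient_id,
sample_id, session_id, cycle, response, epcam_mfi, psma_mfi, is_control``
(the dialect written by :mod:`ctcmd.synthio`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats_core import RobustSummary, TestResult, mann_whitney_u, chi_squared_gof, robust_summaries
from .synthio import CHANNELS, NONRESPONDER, RESPONDER

__all__ = [
    "ControlSummary",
    "ImputationConfig",
    "OutlierRule",
    "Thresholds",
    "GroupComparison",
    "summarize_controls",
    "compare_control_medians",
    "normalize_events",
    "exclude_unknown_response",
    "impute_negative_mfi",
    "filter_outliers",
    "derive_thresholds",
    "classify_events",
    "subpop_distribution",
    "compare_groups_mfi",
    "cycle_dynamics",
    "ctc_count_stats",
    "SUBPOP_LABELS",
]

_MFI = {ch: f"{ch}_mfi" for ch in CHANNELS}
SUBPOP_LABELS = ("EpCAM+PSMA-", "EpCAM+PSMA+", "EpCAM-PSMA+", "EpCAM-PSMA-")


@dataclass(frozen=True)
class ControlSummary:
    """Per-session control-well summary (median MFI per channel)."""

    session_id: str
    channel_medians: Mapping[str, float]
    n_events: int

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if ch not in self.channel_medians:
                raise ValueError(f"control summary missing channel {ch}")
            if self.channel_medians[ch] <= 0:
                raise ValueError(f"control median for {ch} must be positive")


@dataclass(frozen=True)
class ImputationConfig:
    """Negative-MFI imputation rule: mean of ``n_draws`` values drawn
    (without replacement by default) from the ``draw_set_size`` lowest
    strictly positive normalized values of the channel."""

    draw_set_size: int = 10
    n_draws: int = 2
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if not (self.draw_set_size >= self.n_draws >= 1):
            raise ValueError("need draw_set_size >= n_draws >= 1")


@dataclass(frozen=True)
class OutlierRule:
    """Two-sided median +/- k*MAD outlier rule, applied per channel after
    imputation.  ``transform='log10'`` (the default) works on log MFIs,
    which makes the rule scale free."""

    k: float = 3.0
    transform: Literal["log10", "identity"] = "log10"
    scale_constant: float = 1.4826

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Per-channel positivity thresholds with provenance (which sample's
    median set each minimum)."""

    epcam: float
    psma: float
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epcam <= 0 or self.psma <= 0:
            raise ValueError("thresholds must be positive")

    def for_channel(self, channel: str) -> float:
        return {"epcam": self.epcam, "psma": self.psma}[channel]


def _require_columns(events: pd.DataFrame) -> None:
    needed = {"event_id", "sample_id", "session_id", "cycle", "response", "is_control"} | set(
        _MFI.values()
    )
    missing = needed - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")


def summarize_controls(
    events: pd.DataFrame,
) -> tuple[list[ControlSummary], dict[str, RobustSummary]]:
    """Summarize C4-2 control wells per session.

    Duplicated control rows are removed before summarizing.  Returns the
    per-session summaries plus, per channel, the cross-session robust QC
    statistics (grand median, MAD of pooled control values, MAD of the
    per-session medians).
    """
    _require_columns(events)
    ctrl = events.loc[events["is_control"]].copy()
    if ctrl.empty:
        raise ValueError("no control events in table")
    ctrl = ctrl.drop_duplicates(subset=["session_id", *_MFI.values()])

    summaries: list[ControlSummary] = []
    for session, grp in ctrl.groupby("session_id", sort=True):
        medians = {ch: float(grp[_MFI[ch]].median()) for ch in CHANNELS}
        summaries.append(ControlSummary(str(session), medians, len(grp)))

    robust = {
        ch: robust_summaries(
            {str(s): g[_MFI[ch]].to_numpy() for s, g in ctrl.groupby("session_id", sort=True)}
        )
        for ch in CHANNELS
    }
    return summaries, robust


def compare_control_medians(
    summaries_a: Sequence[ControlSummary],
    summaries_b: Sequence[ControlSummary],
    channel: str = "epcam",
) -> TestResult:
    """Mann-Whitney comparison of per-session control medians of two batches."""
    a = [s.channel_medians[channel] for s in summaries_a]
    b = [s.channel_medians[channel] for s in summaries_b]
    return mann_whitney_u(a, b)


def normalize_events(
    events: pd.DataFrame, summaries: Sequence[ControlSummary]
) -> pd.DataFrame:
    """Divide each non-control event's channel MFIs by its session's control
    median MFI for the same channel.  Control rows pass through untouched;
    negative raw values keep their sign."""
    _require_columns(events)
    by_session = {s.session_id: s for s in summaries}
    ctc = events.loc[~events["is_control"]]
    missing = sorted(set(ctc["session_id"]) - set(by_session))
    if missing:
        raise ValueError(f"no control summary for session(s): {missing}")
    out = events.copy()
    for ch in CHANNELS:
        col = _MFI[ch]
        divisor = np.ones(len(out))
        mask = (~out["is_control"]).to_numpy()
        divisor[mask] = [
            by_session[s].channel_medians[ch] for s in out.loc[mask, "session_id"]
        ]
        out[col] = out[col] / divisor
    return out


def exclude_unknown_response(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only Responder/Nonresponder CTC events.

    Control rows and events from patients with unknown treatment outcome are
    dropped; the log counts excluded events per patient (controls under the
    pseudo-patient of their well)."""
    _require_columns(events)
    keep = (~events["is_control"]) & events["response"].isin([RESPONDER, NONRESPONDER])
    excluded = events.loc[~keep]
    log = (
        excluded.groupby("patient_id", dropna=False)
        .size()
        .rename("n_excluded")
        .reset_index()
    )
    return events.loc[keep].copy(), log


def impute_negative_mfi(
    events: pd.DataFrame,
    channel: str,
    config: ImputationConfig = ImputationConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute non-positive normalized MFIs on one channel.

    The drawing set is the ``draw_set_size`` lowest strictly positive values
    of the channel across the whole table; each non-positive value is
    replaced, independently, by the mean of ``n_draws`` values sampled from
    that set (without replacement within one imputation by default).
    Strictly positive values are never altered.
    """
    _require_columns(events)
    col = _MFI[channel]
    vals = events[col].to_numpy(dtype=float)
    positive = np.sort(vals[vals > 0])
    if positive.size < config.draw_set_size:
        raise ValueError(
            f"need at least {config.draw_set_size} positive values on {channel}, "
            f"found {positive.size}"
        )
    draw_set = positive[: config.draw_set_size]
    rng = np.random.default_rng(config.seed)

    out = events.copy()
    log_rows = []
    for pos in np.flatnonzero(vals <= 0):
        draws = rng.choice(draw_set, size=config.n_draws, replace=config.with_replacement)
        imputed = float(draws.mean())
        out.iloc[pos, out.columns.get_loc(col)] = imputed
        log_rows.append(
            {
                "event_id": events.iloc[pos]["event_id"],
                "channel": channel,
                "original": vals[pos],
                "drawn": ";".join(f"{d:.10g}" for d in draws),
                "imputed": imputed,
            }
        )
    log = pd.DataFrame(log_rows, columns=["event_id", "channel", "original", "drawn", "imputed"])
    return out, log


def filter_outliers(
    events: pd.DataFrame, rule: OutlierRule = OutlierRule()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove events with exceptionally high or low MFI on either channel.

    Per channel, events with ``|t - median(t)| > k * MAD(t)`` are flagged,
    where t is the (log10-)transformed channel MFI and MAD uses the rule's
    scale constant.  If the MAD is zero (all values equal) nothing is
    removed on that channel.
    """
    _require_columns(events)
    flagged: dict[str, list[str]] = {}
    reasons = []
    for ch in CHANNELS:
        vals = events[_MFI[ch]].to_numpy(dtype=float)
        if rule.transform == "log10":
            if (vals <= 0).any():
                raise ValueError(
                    f"non-positive {ch} MFI under log10 outlier rule; impute first"
                )
            t = np.log10(vals)
        else:
            t = vals
        med = float(np.median(t))
        mad = rule.scale_constant * float(np.median(np.abs(t - med)))
        if mad == 0.0:
            continue
        dev = t - med
        for i in np.flatnonzero(np.abs(dev) > rule.k * mad):
            eid = events.iloc[i]["event_id"]
            flagged.setdefault(eid, []).append(ch)
            reasons.append(
                {
                    "event_id": eid,
                    "channel": ch,
                    "value": vals[i],
                    "reason": "high" if dev[i] > 0 else "low",
                }
            )
    removed_ids = set(flagged)
    kept = events.loc[~events["event_id"].isin(removed_ids)].copy()
    log = pd.DataFrame(reasons, columns=["event_id", "channel", "value", "reason"])
    return kept, log


def derive_thresholds(events: pd.DataFrame) -> Thresholds:
    """Per-channel positivity threshold = minimum over samples of the
    per-sample median normalized MFI (mirrors a single dotted threshold
    line per channel on the sort scatterplot)."""
    _require_columns(events)
    ctc = events.loc[~events["is_control"]]
    if ctc.empty:
        raise ValueError("no CTC events to derive thresholds from")
    thr = {}
    prov = {}
    for ch in CHANNELS:
        med = ctc.groupby("sample_id")[_MFI[ch]].median()
        thr[ch] = float(med.min())
        prov[ch] = str(med.idxmin())
    prov["n_samples"] = str(ctc["sample_id"].nunique())
    return Thresholds(epcam=thr["epcam"], psma=thr["psma"], provenance=prov)


def classify_events(events: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Assign each event to an EpCAM/PSMA subpopulation.

    A channel is positive iff its MFI is >= the channel threshold (boundary
    counts as positive), so the four labels are a complete disjoint
    partition."""
    _require_columns(events)
    out = events.copy()
    ep = out[_MFI["epcam"]] >= thresholds.epcam
    ps = out[_MFI["psma"]] >= thresholds.psma
    out["subpop"] = np.select(
        [ep & ~ps, ep & ps, ~ep & ps],
        ["EpCAM+PSMA-", "EpCAM+PSMA+", "EpCAM-PSMA+"],
        default="EpCAM-PSMA-",
    )
    return out


def subpop_distribution(
    classified: pd.DataFrame,
    expected: Literal["equal", "overall_proportions"] = "overall_proportions",
) -> pd.DataFrame:
    """Responder/Nonresponder composition of the three marker-positive
    subpopulations, with a chi-squared goodness-of-fit test per
    subpopulation against the chosen expectation.

    Double-negative events are excluded from the three-way distribution
    (they appear in no row).  Empty subpopulations get a NaN test with a
    notice instead of a p-value.
    """
    df = classified.loc[classified["subpop"] != "EpCAM-PSMA-"]
    n_resp_all = int((df["response"] == RESPONDER).sum())
    n_non_all = int((df["response"] == NONRESPONDER).sum())
    total = n_resp_all + n_non_all
    if total == 0:
        raise ValueError("no labeled events in the three marker-positive subpopulations")
    if expected == "equal":
        props = (0.5, 0.5)
    else:
        props = (n_resp_all / total, n_non_all / total)

    rows = []
    for pop in ("EpCAM+PSMA-", "EpCAM+PSMA+", "EpCAM-PSMA+"):
        sub = df.loc[df["subpop"] == pop]
        n_r = int((sub["response"] == RESPONDER).sum())
        n_n = int((sub["response"] == NONRESPONDER).sum())
        n = n_r + n_n
        row = {
            "subpop": pop,
            "n_responder": n_r,
            "n_nonresponder": n_n,
            "pct_responder": 100.0 * n_r / n if n else float("nan"),
            "pct_nonresponder": 100.0 * n_n / n if n else float("nan"),
        }
        if n == 0 or 0.0 in props:
            row.update(chi2=float("nan"), p_value=float("nan"), notice="empty; test skipped")
        else:
            res = chi_squared_gof([n_r, n_n], props)
            row.update(chi2=res.statistic, p_value=res.p_value, notice="")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-cycle comparison of one channel between response groups."""

    channel: str
    responder_median: float
    nonresponder_median: float
    responder_log10_median: float
    nonresponder_log10_median: float
    test: TestResult


def compare_groups_mfi(events: pd.DataFrame, channel: str) -> GroupComparison:
    """Group medians (raw and log10) plus a two-sided Mann-Whitney test on
    the log-transformed pooled-cycle MFIs."""
    col = _MFI[channel]
    r = events.loc[events["response"] == RESPONDER, col].to_numpy(dtype=float)
    n = events.loc[events["response"] == NONRESPONDER, col].to_numpy(dtype=float)
    if r.size == 0 or n.size == 0:
        raise ValueError("both response groups must be non-empty")
    if (r <= 0).any() or (n <= 0).any():
        raise ValueError("MFIs must be positive (run imputation first)")
    res = mann_whitney_u(np.log10(r), np.log10(n))
    return GroupComparison(
        channel=channel,
        responder_median=float(np.median(r)),
        nonresponder_median=float(np.median(n)),
        responder_log10_median=float(math.log10(np.median(r))),
        nonresponder_log10_median=float(math.log10(np.median(n))),
        test=res,
    )


def cycle_dynamics(
    events: pd.DataFrame,
    channel: str,
    min_cells_per_cycle: int = 5,
) -> pd.DataFrame:
    """Per-cycle marker dynamics within and between response groups.

    Cycles in which *either* group has fewer than ``min_cells_per_cycle``
    cells are dropped entirely (with the default of 5 this reproduces a
    cycle-4 cutoff when cycle 4 holds 3 Responder and 0 Nonresponder
    cells).  Tests are two-sided Mann-Whitney on log10 MFIs: each cycle
    vs the group's baseline (cycle 0), plus a between-group test per cycle.
    """
    col = _MFI[channel]
    df = events.loc[events["response"].isin([RESPONDER, NONRESPONDER])].copy()
    if (df[col] <= 0).any():
        raise ValueError("MFIs must be positive (run imputation first)")
    df["logv"] = np.log10(df[col])

    cycles = sorted(df["cycle"].unique())
    kept_cycles = []
    for c in cycles:
        n_by_group = [
            int(((df["cycle"] == c) & (df["response"] == g)).sum())
            for g in (RESPONDER, NONRESPONDER)
        ]
        if all(n >= min_cells_per_cycle for n in n_by_group):
            kept_cycles.append(c)
    if 0 not in kept_cycles:
        raise ValueError("baseline (cycle 0) missing or below the cell minimum")

    base = {
        g: df.loc[(df["cycle"] == 0) & (df["response"] == g), "logv"].to_numpy()
        for g in (RESPONDER, NONRESPONDER)
    }
    rows = []
    for c in kept_cycles:
        vals = {
            g: df.loc[(df["cycle"] == c) & (df["response"] == g), "logv"].to_numpy()
            for g in (RESPONDER, NONRESPONDER)
        }
        p_between = mann_whitney_u(vals[RESPONDER], vals[NONRESPONDER]).p_value
        for g in (RESPONDER, NONRESPONDER):
            v = vals[g]
            median = float(10.0 ** np.median(v))
            rows.append(
                {
                    "group": g,
                    "cycle": c,
                    "channel": channel,
                    "n": v.size,
                    "median_mfi": median,
                    "log10_median": float(np.median(v)),
                    "p_vs_baseline": (
                        float("nan") if c == 0 else mann_whitney_u(v, base[g]).p_value
                    ),
                    "p_between_groups": p_between,
                }
            )
    return pd.DataFrame(rows)


def ctc_count_stats(
    events: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, TestResult]:
    """Retained-event counts per sample, group median/range, Mann-Whitney.

    Returns (per-sample counts, per-group summary with median / min / max /
    n_samples, between-group test on per-sample counts)."""
    df = events.loc[events["response"].isin([RESPONDER, NONRESPONDER])]
    per_sample = (
        df.groupby(["sample_id", "response"], sort=True, observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    groups = {}
    rows = []
    for g in (RESPONDER, NONRESPONDER):
        counts = per_sample.loc[per_sample["response"] == g, "n_cells"].to_numpy()
        if counts.size == 0:
            raise ValueError(f"no samples in group {g}")
        groups[g] = counts
        rows.append(
            {
                "group": g,
                "n_samples": counts.size,
                "median": float(np.median(counts)),
                "min": int(counts.min()),
                "max": int(counts.max()),
            }
        )
    test = mann_whitney_u(groups[RESPONDER], groups[NONRESPONDER])
    return per_sample, pd.DataFrame(rows), test
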