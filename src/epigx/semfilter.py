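"""Stochastic epimutation (SEM) detection, burden summaries and enrichment.

A SEM is a methylation value beyond Tukey-style fences at 3 x IQR for its
probe: high methylation outliers (HMO) above Q3 + 3 x IQR, low methylation
outliers (LMO) below Q1 - 3 x IQR.  Quartiles use linear interpolation
between order statistics; fences are computed from all values of the probe
(including candidates) and comparison with a fence is strict, so a value
equal to a fence is not an outlier.

Case-control enrichment is tested at the subject level (subjects with >= 1
SEM vs without) with a two-tailed Fisher exact test; the odds ratio is the
conditional maximum-likelihood estimate with an exact conditional CI from
the noncentral hypergeometric distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import DIABETIC, MethylationMatrix, SampleTable

__all__ = ["SEMCall", "EnrichmentResult", "detect_sems", "sem_burden",
           "sem_enrichment", "filter_sem_probes"]

HMO = "HMO"
LMO = "LMO"


@dataclass(frozen=True)
class SEMCall:
    probe_id: str
    sample_id: str
    sem_class: str  # HMO or LMO
    value: float
    lower_fence: float
    upper_fence: float


def detect_sems(meth: MethylationMatrix, multiplier: float = 3.0) -> list[SEMCall]:
    """Call fence-exceeding outliers per probe.

    Probes with fewer than 8 non-missing values are skipped with a warning.
    Returns calls ordered by probe, then sample.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    values = meth.values.to_numpy(dtype=float)
    sample_ids = list(meth.values.index)
    calls: list[SEMCall] = []
    n_ok = np.sum(~np.isnan(values), axis=0)
    skipped = [
        pid for pid, k in zip(meth.probe_ids, n_ok) if k < 8
    ]
    if skipped:
        warnings.warn(
            f"{len(skipped)} probes with < 8 non-missing values skipped",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        q1 = np.nanquantile(values, 0.25, axis=0)
        q3 = np.nanquantile(values, 0.75, axis=0)
    iqr = q3 - q1
    upper = q3 + multiplier * iqr
    lower = q1 - multiplier * iqr
    for j, pid in enumerate(meth.probe_ids):
        if n_ok[j] < 8:
            continue
        col = values[:, j]
        hi = np.flatnonzero(col > upper[j])
        lo = np.flatnonzero(col < lower[j])
        for i in hi:
            calls.append(SEMCall(pid, sample_ids[i], HMO, float(col[i]),
                                 float(lower[j]), float(upper[j])))
        for i in lo:
            calls.append(SEMCall(pid, sample_ids[i], LMO, float(col[i]),
                                 float(lower[j]), float(upper[j])))
    return calls


def calls_to_frame(calls: list[SEMCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": c.probe_id,
                "sample_id": c.sample_id,
                "class": c.sem_class,
                "value": c.value,
                "lower_fence": c.lower_fence,
                "upper_fence": c.upper_fence,
            }
            for c in calls
        ],
        columns=["probe_id", "sample_id", "class", "value",
                 "lower_fence", "upper_fence"],
    )


def sem_burden(calls: list[SEMCall]) -> dict:
    """Per-probe and per-subject SEM counts plus a per-subject summary."""
    df = calls_to_frame(calls)
    if df.empty:
        by_probe = pd.DataFrame(columns=[HMO, LMO, "total"])
        by_subject = pd.DataFrame(columns=[HMO, LMO, "total"])
    else:
        by_probe = (
            df.pivot_table(index="probe_id", columns="class", values="sample_id",
                           aggfunc="count", fill_value=0)
            .reindex(columns=[HMO, LMO], fill_value=0)
        )
        by_probe["total"] = by_probe.sum(axis=1)
        by_subject = (
            df.pivot_table(index="sample_id", columns="class", values="probe_id",
                           aggfunc="count", fill_value=0)
            .reindex(columns=[HMO, LMO], fill_value=0)
        )
        by_subject["total"] = by_subject.sum(axis=1)
    totals = by_subject["total"] if not by_subject.empty else pd.Series(dtype=float)
    summary = {
        "n_calls": int(len(df)),
        "n_probes_with_sem": int(len(by_probe)),
        "n_subjects_with_sem": int(len(by_subject)),
        "median_per_subject": float(totals.median()) if len(totals) else 0.0,
        "iqr_per_subject": float(totals.quantile(0.75) - totals.quantile(0.25))
        if len(totals) else 0.0,
    }
    return {"by_probe": by_probe, "by_subject": by_subject, "summary": summary}


@dataclass
class EnrichmentResult:
    table: np.ndarray          # rows: [group, other]; cols: [has SEM, none]
    odds_ratio: float          # conditional MLE; nan if degenerate
    ci_low: float
    ci_high: float
    p_value: float
    note: str = ""


def _cond_mle_or(table: np.ndarray) -> float:
    a = int(table[0, 0])
    r1, c1 = int(table[0].sum()), int(table[:, 0].sum())
    total = int(table.sum())
    lo, hi = max(0, r1 + c1 - total), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf

    def mean_minus_a(logor):
        return stats.nchypergeom_fisher.mean(total, c1, r1, np.exp(logor)) - a

    return float(np.exp(optimize.brentq(mean_minus_a, -50, 50)))


def _exact_ci(table: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    a = int(table[0, 0])
    r1, c1 = int(table[0].sum()), int(table[:, 0].sum())
    total = int(table.sum())
    lo, hi = max(0, r1 + c1 - total), min(r1, c1)

    def sf_at(logor):  # P(X >= a)
        return stats.nchypergeom_fisher.sf(a - 1, total, c1, r1, np.exp(logor))

    def cdf_at(logor):  # P(X <= a)
        return stats.nchypergeom_fisher.cdf(a, total, c1, r1, np.exp(logor))

    if a == lo:
        lower = 0.0
    else:
        lower = float(np.exp(optimize.brentq(
            lambda t: sf_at(t) - alpha / 2, -50, 50)))
    if a == hi:
        upper = np.inf
    else:
        upper = float(np.exp(optimize.brentq(
            lambda t: cdf_at(t) - alpha / 2, -50, 50)))
    return lower, upper


def sem_enrichment(
    calls: list[SEMCall],
    samples: SampleTable,
    group_class: str = DIABETIC,
) -> EnrichmentResult:
    """Fisher exact test of SEM carriage in ``group_class`` vs the rest.

    Orientation: rows are (group, non-group), columns (>=1 SEM, no SEM);
    the odds ratio is for SEM carriage in the group relative to the rest.
    """
    df = samples.included
    in_group = df["glycemic_class"] == group_class
    if in_group.sum() == 0 or (~in_group).sum() == 0:
        raise ValueError("both comparison groups must be non-empty")
    carriers = {c.sample_id for c in calls}
    has_sem = df["sample_id"].isin(carriers)
    a = int((in_group & has_sem).sum())
    b = int((in_group & ~has_sem).sum())
    c = int((~in_group & has_sem).sum())
    d = int((~in_group & ~has_sem).sum())
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return EnrichmentResult(table, np.nan, np.nan, np.nan, float(p),
                                note="degenerate table: odds ratio undefined")
    or_hat = _cond_mle_or(table)
    lo, hi = _exact_ci(table)
    return EnrichmentResult(table, or_hat, lo, hi, float(p))


def filter_sem_probes(
    meth: MethylationMatrix,
    calls: list[SEMCall],
    probe_set=None,
    target_probe: str | None = None,
) -> MethylationMatrix:
    """Drop probes carrying SEMs (or an explicit probe set).

    The designated target probe is never dropped unless it itself carries a
    call.  Dropping every probe yields an empty matrix with a warning.
    """
    if probe_set is None:
        probe_set = {c.probe_id for c in calls}
    else:
        probe_set = set(probe_set)
    called = {c.probe_id for c in calls}
    if target_probe is not None and target_probe not in called:
        probe_set.discard(target_probe)
    keep = [p for p in meth.probe_ids if p not in probe_set]
    if not keep:
        warnings.warn("all probes removed by SEM filter", stacklevel=2)
    return meth.subset_probes(keep)
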