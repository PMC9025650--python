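"""Step-wise additive multivariate models and stratified genotype comparisons.

Candidates (SNP main effects, exposure, or SNP x exposure interactions) are
ranked by the variance they explain on their own (univariate adjusted R²)
and fed one at a time into a growing OLS model.  A candidate is retained
only if its coefficient stays significant in the joint fit and the nested
extra-sum-of-squares F-test shows a significant gain in captured variance;
after each accepted addition, previously retained candidates that lost
significance are dropped in a single sweep.  Interaction terms carry their
parent main effects with them (hierarchy is never violated).

Stratified comparisons test mean methylation differences between genotype
groups (whole cohort and within each glycemic class) with Welch's t,
Holm-adjusted within each stratum's family of pairwise tests; the effect
size is a pooled-SD standardized mean difference with a seeded bootstrap
percentile CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SampleTable
from .scans import adjust_pvalues, ols_fit

__all__ = ["ModelFit", "StepwiseConfig", "StepwiseResult", "fit_linear",
           "stepwise_build", "compare_nested", "fit_ge_pair",
           "stratified_genotype_comparison"]

_COND_MAX = 1e10


@dataclass
class ModelFit:
    response: str
    terms: list[str]                 # regressors, excluding the intercept
    params: pd.Series                # indexed by const + terms
    pvalues: pd.Series
    n_used: int
    r2: float
    adj_r2: float
    rss: float
    df_resid: int
    sample_index: pd.Index           # rows used after complete-case deletion


def _expand_terms(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Materialize design columns; 'a:b' becomes the product of a and b."""
    cols = {}
    for t in terms:
        if t in data.columns:
            cols[t] = data[t].astype(float)
        elif ":" in t:
            a, b = t.split(":", 1)
            cols[t] = data[a].astype(float) * data[b].astype(float)
        else:
            raise KeyError(f"unknown term {t!r}")
    return pd.DataFrame(cols, index=data.index)


def fit_linear(data: pd.DataFrame, response: str, terms) -> ModelFit:
    """Complete-case OLS of ``response`` on ``terms`` (plus intercept)."""
    terms = list(terms)
    design = _expand_terms(data, terms)
    frame = pd.concat([data[response].astype(float), design], axis=1).dropna()
    y = frame[response].to_numpy()
    X = np.column_stack([np.ones(len(frame))] + [frame[t].to_numpy() for t in terms])
    fit = ols_fit(X, y)
    names = ["const"] + terms
    return ModelFit(
        response=response,
        terms=terms,
        params=pd.Series(fit.coef, index=names),
        pvalues=pd.Series(fit.p, index=names),
        n_used=fit.n_used,
        r2=fit.r2,
        adj_r2=fit.adj_r2,
        rss=fit.rss,
        df_resid=fit.df_resid,
        sample_index=frame.index,
    )


def compare_nested(fit_small: ModelFit, fit_large: ModelFit) -> tuple[float, float]:
    """Extra-sum-of-squares F-test for nested OLS fits on the same samples."""
    if not set(fit_small.terms) <= set(fit_large.terms):
        raise ValueError("models are not nested")
    if not fit_small.sample_index.equals(fit_large.sample_index):
        raise ValueError("nested comparison requires identical samples")
    df_diff = fit_small.df_resid - fit_large.df_resid
    if df_diff == 0:
        return 0.0, 1.0
    F = ((fit_small.rss - fit_large.rss) / df_diff) / \
        (fit_large.rss / fit_large.df_resid)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_diff, fit_large.df_resid))
    return float(F), p


@dataclass
class StepwiseConfig:
    """Entry/retention rules for the step-wise build."""

    entry_min_adj_r2: float = 0.0     # univariate screen (e.g. 0.03 for meQTLs)
    retention_alpha: float = 0.05
    comparison_alpha: float = 0.05

    def __post_init__(self) -> None:
        for a in (self.retention_alpha, self.comparison_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must be in (0, 1)")


@dataclass
class StepwiseResult:
    fit: ModelFit
    accepted: list[str]
    log: list[str] = field(default_factory=list)


def _parents(term: str) -> list[str]:
    return term.split(":", 1) if ":" in term else []


def _required_columns(term: str, base, accepted) -> list[str]:
    """Columns to add with ``term``: missing parents first (hierarchy)."""
    present = set(base) | set(accepted)
    return [p for p in _parents(term) if p not in present] + [term]


def stepwise_build(
    data: pd.DataFrame,
    response: str,
    candidates,
    base_terms=(),
    config: StepwiseConfig | None = None,
) -> StepwiseResult:
    """Additive step-wise construction with nested-model F-test gating.

    ``candidates`` is a list of term names ('snp_00012' or 'snp_00012:hba1c');
    interaction candidates pull their parents into the model when accepted.
    Candidates failing the univariate adjusted-R² entry screen never enter.
    """
    config = config or StepwiseConfig()
    base_terms = list(base_terms)
    log: list[str] = []

    # rank by univariate adjusted R² (descending; ties by name for determinism)
    ranked = []
    for cand in candidates:
        try:
            uni = fit_linear(data, response, _parents(cand) + [cand]
                             if ":" in cand else [cand])
        except KeyError as e:
            raise
        if uni.adj_r2 >= config.entry_min_adj_r2:
            ranked.append((cand, uni.adj_r2))
        else:
            log.append(f"screened out {cand} (adj R2 {uni.adj_r2:.4f})")
    ranked.sort(key=lambda t: (-t[1], t[0]))

    accepted: list[str] = []
    current = fit_linear(data, response, base_terms)
    for cand, uni_r2 in ranked:
        new_cols = _required_columns(cand, base_terms, accepted)
        trial_terms = base_terms + accepted + new_cols
        design = _expand_terms(data, trial_terms)
        frame = pd.concat([data[response], design], axis=1).dropna()
        X = np.column_stack([np.ones(len(frame))]
                            + [frame[t].to_numpy() for t in trial_terms])
        if np.linalg.cond(X) > _COND_MAX:
            log.append(f"skipped {cand}: collinear (condition number)")
            continue
        trial = fit_linear(data, response, trial_terms)
        small = fit_linear(
            data.loc[trial.sample_index], response, base_terms + accepted)
        _, p_f = compare_nested(small, trial)
        p_coef = trial.pvalues[cand]
        if p_coef < config.retention_alpha and p_f < config.comparison_alpha:
            accepted += new_cols
            current = trial
            log.append(f"accepted {cand} (coef p {p_coef:.3g}, F p {p_f:.3g})")
            # single sweep: drop retained candidates that lost significance
            drop = [
                t for t in accepted
                if current.pvalues[t] >= config.retention_alpha
                and not _is_parent_of_retained(t, accepted)
            ]
            if drop:
                accepted = [t for t in accepted if t not in drop]
                current = fit_linear(data, response, base_terms + accepted)
                log.append(f"dropped after sweep: {drop}")
        else:
            log.append(f"rejected {cand} (coef p {p_coef:.3g}, F p {p_f:.3g})")

    final = fit_linear(data, response, base_terms + accepted)
    return StepwiseResult(fit=final, accepted=accepted, log=log)


def _is_parent_of_retained(term: str, accepted) -> bool:
    return any(term in _parents(t) for t in accepted if t != term)


def fit_ge_pair(target_beta: pd.Series, snp_i: pd.Series, snp_j: pd.Series,
                samples: SampleTable) -> ModelFit:
    """Two-SNP additive model: beta ~ SNP_i + SNP_j + HbA1c + age."""
    if snp_i.name == snp_j.name:
        raise ValueError("snp_i and snp_j must be distinct SNPs")
    df = samples.included.set_index("sample_id")
    data = pd.DataFrame({
        "meth": target_beta,
        str(snp_i.name): snp_i,
        str(snp_j.name): snp_j,
        "hba1c": df["hba1c"],
        "age": df["age"],
    }).loc[df.index]
    return fit_linear(data, "meth",
                      [str(snp_i.name), str(snp_j.name), "hba1c", "age"])


def _smd(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def stratified_genotype_comparison(
    target_beta: pd.Series,
    snp: pd.Series,
    samples: SampleTable,
    min_group: int = 3,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise genotype-group methylation comparisons, overall and by class.

    For the whole cohort and within each glycemic class: Welch's t between
    every pair of genotype groups with >= ``min_group`` subjects,
    Holm-adjusted within the stratum; delta-beta reported in percentage
    points; pooled-SD standardized mean difference with a bootstrap
    percentile 95% CI (seeded).
    """
    df = samples.included.set_index("sample_id")
    frame = pd.DataFrame({"meth": target_beta, "geno": snp}).loc[df.index]
    frame["stratum"] = df["glycemic_class"]
    frame = frame.dropna()
    rng = np.random.default_rng(seed)

    rows = []
    strata = [("all", frame)] + [
        (name, sub) for name, sub in frame.groupby("stratum", sort=True)
    ]
    for stratum, sub in strata:
        groups = {
            g: grp["meth"].to_numpy(float)
            for g, grp in sub.groupby("geno")
            if len(grp) >= min_group
        }
        keys = sorted(groups)
        if len(keys) < 2:
            warnings.warn(f"stratum {stratum!r}: fewer than 2 genotype groups",
                          stacklevel=2)
            continue
        stratum_rows = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                x, y = groups[keys[i]], groups[keys[j]]
                t, p = stats.ttest_ind(x, y, equal_var=False)
                smd = _smd(x, y)
                boots = np.empty(n_boot)
                for b in range(n_boot):
                    xb = rng.choice(x, size=len(x), replace=True)
                    yb = rng.choice(y, size=len(y), replace=True)
                    boots[b] = _smd(xb, yb)
                lo, hi = np.percentile(boots, [2.5, 97.5])
                stratum_rows.append({
                    "stratum": stratum,
                    "group_a": int(keys[i]),
                    "group_b": int(keys[j]),
                    "n_a": len(x),
                    "n_b": len(y),
                    "delta_beta_pct": float((x.mean() - y.mean()) * 100),
                    "t": float(t),
                    "p": float(p),
                    "smd": smd,
                    "smd_ci_low": float(lo),
                    "smd_ci_high": float(hi),
                })
        ps = [r["p"] for r in stratum_rows]
        for r, ph in zip(stratum_rows, adjust_pvalues(ps, "holm")):
            r["p_holm"] = float(ph)
        rows.extend(stratum_rows)
    return pd.DataFrame(rows)
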