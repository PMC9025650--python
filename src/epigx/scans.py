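"""Genome-wide least-squares scans around a single target CpG.

Five scan families share one OLS kernel:

* ``ewas_scan``       — HbA1c ~ beta_i + age + sex + BMI, per probe (BH-FDR).
* ``polymorphic_scan``— the EWAS model restricted to polymorphic-flagged
                        probes, with its own BH-FDR family.
* ``meqtl_scan``      — target beta ~ dosage_i + age, per SNP, partitioned
                        into cis (same chromosome, <= 1 Mb), long-range cis
                        (same chromosome, > 1 Mb) and trans.
* ``gxe_scan``        — target beta ~ dosage_i x HbA1c + dosage_i + HbA1c
                        + age; the interaction p ranks SNPs.
* ``gxmeth_scan``     — HbA1c ~ beta_T x dosage_i + dosage_i + beta_T + age
                        + sex + BMI; interaction p with Bonferroni control,
                        additive (SNP) p reported alongside.

p-values come from classical t statistics of OLS coefficients
(homoskedastic errors); adjusted R² = 1 - (1-R²)(n-1)/(n-p-1).  Every fit
uses complete-case deletion, with n_used recorded.  Results are sorted by
focal p, ties broken by feature id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import GenotypeMatrix, MethylationMatrix, SampleTable

__all__ = ["ProximityRule", "ols_fit", "ewas_scan", "polymorphic_scan",
           "meqtl_scan", "gxe_scan", "gxmeth_scan", "adjust_pvalues",
           "manhattan_plot"]

CIS = "cis"
LONG_CIS = "long_cis"
TRANS = "trans"


@dataclass(frozen=True)
class ProximityRule:
    """Window defining cis vs long-range cis vs trans around the target CpG."""

    target_chromosome: int
    target_position: int
    cis_window: int = 1_000_000

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be > 0")

    def classify(self, chrom, pos) -> str:
        if int(chrom) != int(self.target_chromosome):
            return TRANS
        return CIS if abs(int(pos) - self.target_position) <= self.cis_window \
            else LONG_CIS


@dataclass
class OLSFit:
    """Classical least-squares fit summary (intercept first)."""

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    rss: float
    df_resid: int
    n_used: int


def ols_fit(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """OLS with t-based p-values; X must include the intercept column."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - rank
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
    if df_resid > 0 and rank == k:
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    else:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), max(df_resid, 1))
    return OLSFit(beta, se, t, p, r2, adj_r2, rss, df_resid, n)


def _scan_core(y_all, covars, varying, term_names, focal_term, feature_ids):
    """Shared per-feature loop.

    ``varying`` maps feature_id -> dict of extra columns (may contain NaN);
    ``covars`` is an (n, c) array of shared covariates (may contain NaN);
    ``y_all`` the shared or per-feature response.
    """
    rows = []
    for fid in feature_ids:
        extra = varying[fid]
        cols = [extra[name] for name in term_names if name in extra]
        y = y_all[fid] if isinstance(y_all, dict) else y_all
        M = np.column_stack([y, covars] + cols)
        mask = ~np.isnan(M).any(axis=1)
        n_used = int(mask.sum())
        names = ["const"] + [n for n in term_names]
        flag = ""
        k = 2 + covars.shape[1] + len(cols) - 1  # const + covars + extras
        if n_used <= k + 1:
            rows.append(_null_row(fid, names, n_used, "insufficient data"))
            continue
        ym = M[mask, 0]
        Xm = np.column_stack([np.ones(n_used), M[mask, 1:]])
        # constant focal column (monomorphic SNP / constant probe)
        focal_idx = names.index(focal_term)
        if np.ptp(Xm[:, focal_idx]) == 0:
            rows.append(_null_row(fid, names, n_used, "constant focal term"))
            continue
        fit = ols_fit(Xm, ym)
        row = {"feature_id": fid, "n_used": n_used, "flag": flag,
               "adj_r2": fit.adj_r2, "r2": fit.r2}
        for name, b, pv in zip(names, fit.coef, fit.p):
            row[f"coef_{name}"] = b
            row[f"p_{name}"] = pv
        row["focal_p"] = row[f"p_{focal_term}"]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["focal_p", "feature_id"], kind="mergesort") \
             .reset_index(drop=True)


def _null_row(fid, names, n_used, flag):
    row = {"feature_id": fid, "n_used": n_used, "flag": flag,
           "adj_r2": np.nan, "r2": np.nan, "focal_p": 1.0}
    for name in names:
        row[f"coef_{name}"] = np.nan
        row[f"p_{name}"] = np.nan
    return row


def _covariate_block(samples: SampleTable, cols):
    df = samples.included
    return df[list(cols)].to_numpy(dtype=float), df


def ewas_scan(meth: MethylationMatrix, samples: SampleTable,
              probe_ids=None) -> pd.DataFrame:
    """Per-probe OLS of HbA1c on beta + age + sex + BMI with BH-FDR q-values."""
    covars, df = _covariate_block(samples, ("age", "sex", "bmi"))
    y = df["hba1c"].to_numpy(dtype=float)
    probes = list(probe_ids) if probe_ids is not None else list(meth.probe_ids)
    vals = meth.values.loc[df["sample_id"]]
    # design order: meth first, then shared covariates
    varying = {p: {"meth": vals[p].to_numpy(dtype=float)} for p in probes}
    res = _scan_core(
        y_all=y,
        covars=np.empty((len(df), 0)),
        varying={p: {"meth": varying[p]["meth"],
                     "age": covars[:, 0], "sex": covars[:, 1],
                     "bmi": covars[:, 2]} for p in probes},
        term_names=["meth", "age", "sex", "bmi"],
        focal_term="meth",
        feature_ids=probes,
    )
    res.insert(1, "model_tag", "ewas")
    res.insert(2, "proximity", "n/a")
    res["q_value"] = adjust_pvalues(res["focal_p"].to_numpy(), "bh")
    return res


def polymorphic_scan(meth: MethylationMatrix, samples: SampleTable) -> pd.DataFrame:
    """EWAS model over polymorphic-flagged probes; BH-FDR within this family."""
    flagged = meth.manifest.loc[meth.manifest["polymorphic"].astype(bool),
                                "probe_id"].tolist()
    if not flagged:
        import warnings
        warnings.warn("no polymorphic-flagged probes", stacklevel=2)
        return pd.DataFrame()
    res = ewas_scan(meth, samples, probe_ids=flagged)
    res["model_tag"] = "polymorphic"
    res["q_value"] = adjust_pvalues(res["focal_p"].to_numpy(), "bh")
    return res


def _snp_scan_frame(genotypes: GenotypeMatrix, df: pd.DataFrame):
    dos = genotypes.dosages.loc[df["sample_id"]]
    return {s: dos[s].to_numpy(dtype=float) for s in genotypes.snp_ids}


def meqtl_scan(target_beta: pd.Series, genotypes: GenotypeMatrix,
               samples: SampleTable, rule: ProximityRule) -> pd.DataFrame:
    """Per-SNP OLS of the target probe's beta on dosage + age."""
    df = samples.included
    y = target_beta.loc[df["sample_id"]].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    dosages = _snp_scan_frame(genotypes, df)
    varying = {s: {"snp": dosages[s], "age": age} for s in genotypes.snp_ids}
    res = _scan_core(y, np.empty((len(df), 0)), varying,
                     ["snp", "age"], "snp", list(genotypes.snp_ids))
    res.insert(1, "model_tag", "meqtl")
    man = genotypes.manifest.set_index("snp_id")
    res.insert(2, "proximity", [
        rule.classify(man.loc[s, "chrom"], man.loc[s, "pos"])
        for s in res["feature_id"]
    ])
    res["retained"] = res["focal_p"] < 0.05
    return res


def gxe_scan(target_beta: pd.Series, genotypes: GenotypeMatrix,
             samples: SampleTable, rule: ProximityRule | None = None
             ) -> pd.DataFrame:
    """Per-SNP interaction scan: beta ~ SNP x HbA1c + SNP + HbA1c + age."""
    df = samples.included
    y = target_beta.loc[df["sample_id"]].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    hba1c = df["hba1c"].to_numpy(dtype=float)
    dosages = _snp_scan_frame(genotypes, df)
    varying = {
        s: {"snp:hba1c": dosages[s] * hba1c, "snp": dosages[s],
            "hba1c": hba1c, "age": age}
        for s in genotypes.snp_ids
    }
    res = _scan_core(y, np.empty((len(df), 0)), varying,
                     ["snp:hba1c", "snp", "hba1c", "age"],
                     "snp:hba1c", list(genotypes.snp_ids))
    res.insert(1, "model_tag", "gxe")
    if rule is not None:
        man = genotypes.manifest.set_index("snp_id")
        res.insert(2, "proximity", [
            rule.classify(man.loc[s, "chrom"], man.loc[s, "pos"])
            for s in res["feature_id"]
        ])
    else:
        res.insert(2, "proximity", "n/a")
    return res


def gxmeth_scan(target_beta: pd.Series, genotypes: GenotypeMatrix,
                samples: SampleTable) -> pd.DataFrame:
    """Per-SNP CpG x SNP interaction scan on the exposure.

    HbA1c ~ beta_T x SNP + SNP + beta_T + age + sex + BMI; the interaction p
    is Bonferroni-corrected at family size = SNPs tested, and the additive
    SNP main-effect p is reported alongside.
    """
    df = samples.included
    y = df["hba1c"].to_numpy(dtype=float)
    meth = target_beta.loc[df["sample_id"]].to_numpy(dtype=float)
    cov = df[["age", "sex", "bmi"]].to_numpy(dtype=float)
    dosages = _snp_scan_frame(genotypes, df)
    varying = {
        s: {"meth:snp": meth * dosages[s], "snp": dosages[s], "meth": meth,
            "age": cov[:, 0], "sex": cov[:, 1], "bmi": cov[:, 2]}
        for s in genotypes.snp_ids
    }
    res = _scan_core(y, np.empty((len(df), 0)), varying,
                     ["meth:snp", "snp", "meth", "age", "sex", "bmi"],
                     "meth:snp", list(genotypes.snp_ids))
    res.insert(1, "model_tag", "gxmeth")
    res.insert(2, "proximity", "n/a")
    res["bonferroni_p"] = adjust_pvalues(res["focal_p"].to_numpy(), "bonferroni")
    res["additive_p"] = res["p_snp"]
    res["additive_bonferroni_p"] = adjust_pvalues(
        res["p_snp"].fillna(1.0).to_numpy(), "bonferroni")
    return res


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment: BH step-up, Bonferroni or Holm step-down."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    lookup = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}
    if method not in lookup:
        raise ValueError(f"unknown method {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method=lookup[method])[1]


def manhattan_plot(results: pd.DataFrame, manifest: pd.DataFrame, path,
                   id_col: str = "feature_id", alpha_line: float | None = None):
    """Basic Manhattan plot: -log10(focal p) by genomic position."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    man = manifest.set_index(manifest.columns[0])
    df = results.copy()
    df["chrom"] = [int(man.loc[f, "chrom"]) for f in df[id_col]]
    df["pos"] = [int(man.loc[f, "pos"]) for f in df[id_col]]
    df = df.sort_values(["chrom", "pos"])
    offsets, cum = {}, 0
    for c, sub in df.groupby("chrom"):
        offsets[c] = cum
        cum += sub["pos"].max() + 1
    x = df["pos"] + df["chrom"].map(offsets)
    y = -np.log10(np.clip(df["focal_p"], 1e-300, None))
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(x, y, s=4, c=df["chrom"] % 2, cmap="tab10")
    if alpha_line is not None:
        ax.axhline(-np.log10(alpha_line), color="k", lw=0.8)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
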