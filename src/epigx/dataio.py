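"""Cohort data containers, genotype QC and phenotype binning.

The three core containers wrap pandas objects:

* :class:`SampleTable` — per-subject phenotypes (age, sex, BMI, HbA1c %),
  self-report flags, the derived glycemic class and exclusion bookkeeping.
* :class:`MethylationMatrix` — samples x probes beta values in [0, 1] plus a
  probe manifest (chromosome, 1-based position, CpG-island status, gene,
  polymorphic-target flag).
* :class:`GenotypeMatrix` — samples x SNPs additive dosages {0, 1, 2, NA}
  plus a SNP manifest (chromosome, 1-based position, alleles, MAF).

Glycemic classes follow the clinical HbA1c cut points: controls at
HbA1c <= 5.7 %, prediabetic strictly between 5.7 and 6.5, diabetic at
>= 6.5.  The two boundary values are assigned to the closed ends (5.7 ->
control, 6.5 -> diabetic), honouring the "<=" / ">=" convention; subjects
exactly on a boundary are a documented convention, not a clinical claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleTable",
    "MethylationMatrix",
    "GenotypeMatrix",
    "CONTROL",
    "PREDIABETIC",
    "DIABETIC",
    "bin_glycemic_class",
    "apply_exclusions",
    "filter_maf",
    "ld_prune",
    "cohort_bookkeeping",
    "read_sample_table",
    "write_sample_table",
    "read_methylation",
    "write_methylation",
    "read_genotypes",
    "write_genotypes",
]

CONTROL = "control"
PREDIABETIC = "prediabetic"
DIABETIC = "diabetic"

#: HbA1c (%) cut points separating control / prediabetic / diabetic.
HBA1C_CONTROL_MAX = 5.7
HBA1C_DIABETIC_MIN = 6.5

ISLAND_STATUSES = ("Island", "N Shore", "S Shore", "N Shelf", "S Shelf", "Open Sea")


class SchemaError(ValueError):
    """Raised when an on-disk table does not match the expected schema."""


@dataclass
class SampleTable:
    """Per-subject phenotype table.

    ``data`` columns: sample_id, age, sex (0 = male, 1 = female), bmi,
    hba1c (%), self_report_dx_diabetes, self_report_rx_diabetes,
    glycemic_class, excluded, exclusion_reason.
    """

    data: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "age",
        "sex",
        "bmi",
        "hba1c",
        "self_report_dx_diabetes",
        "self_report_rx_diabetes",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise SchemaError(f"sample table missing columns: {missing}")
        if (self.data["hba1c"] <= 0).any() or not np.isfinite(self.data["hba1c"]).all():
            raise ValueError("hba1c values must be finite and > 0")
        if "glycemic_class" not in self.data.columns:
            self.data = self.data.copy()
            self.data["glycemic_class"] = bin_glycemic_class(self.data["hba1c"])
        if "excluded" not in self.data.columns:
            self.data = self.data.assign(excluded=False, exclusion_reason="")

    @property
    def included(self) -> pd.DataFrame:
        return self.data.loc[~self.data["excluded"]]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MethylationMatrix:
    """Beta-value matrix (rows = samples, columns = probes) with manifest."""

    values: pd.DataFrame
    manifest: pd.DataFrame  # probe_id, chrom, pos, island_status, gene, polymorphic

    def __post_init__(self) -> None:
        if list(self.manifest["probe_id"]) != list(self.values.columns):
            raise SchemaError(
                "probe manifest does not cover the matrix columns "
                f"({len(self.manifest)} manifest rows vs {self.values.shape[1]} columns)"
            )
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError(f"{bad} beta values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        probe_ids = list(probe_ids)
        manifest = self.manifest.set_index("probe_id").loc[probe_ids].reset_index()
        return MethylationMatrix(self.values[probe_ids], manifest)


@dataclass
class GenotypeMatrix:
    """Additive-coded dosage matrix (rows = samples, columns = SNPs)."""

    dosages: pd.DataFrame
    manifest: pd.DataFrame  # snp_id, chrom, pos, a1, a2[, maf]

    def __post_init__(self) -> None:
        if list(self.manifest["snp_id"]) != list(self.dosages.columns):
            raise SchemaError(
                "SNP manifest does not cover the matrix columns "
                f"({len(self.manifest)} manifest rows vs {self.dosages.shape[1]} columns)"
            )
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def empirical_maf(self) -> pd.Series:
        """Minor-allele frequency from non-missing dosages, folded to <= 0.5."""
        p = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        manifest = self.manifest.set_index("snp_id").loc[snp_ids].reset_index()
        return GenotypeMatrix(self.dosages[snp_ids], manifest)


def bin_glycemic_class(hba1c):
    """Map HbA1c (%) to glycemic class.

    (0, 5.7] -> control; (5.7, 6.5) -> prediabetic; [6.5, inf) -> diabetic.
    Accepts a scalar or an array/Series; the three intervals partition (0, inf).
    """
    arr = np.asarray(hba1c, dtype=float)
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError("hba1c must be finite and > 0")
    out = np.where(
        arr <= HBA1C_CONTROL_MAX,
        CONTROL,
        np.where(arr < HBA1C_DIABETIC_MIN, PREDIABETIC, DIABETIC),
    )
    if np.isscalar(hba1c):
        return out.item()
    if isinstance(hba1c, pd.Series):
        return pd.Series(out, index=hba1c.index)
    return out


def apply_exclusions(samples: SampleTable) -> SampleTable:
    """Flag subjects whose self-report contradicts their glycemic class.

    Excluded: (a) control-class subjects self-reporting a diabetes diagnosis,
    (b) non-diabetic-class subjects self-reporting anti-diabetic medication.
    Phenotype values are never altered, only the flags.
    """
    df = samples.data.copy()
    cls = df["glycemic_class"]
    rule_a = (cls == CONTROL) & df["self_report_dx_diabetes"].astype(bool)
    rule_b = (cls != DIABETIC) & df["self_report_rx_diabetes"].astype(bool)
    df["excluded"] = rule_a | rule_b
    reason = np.where(
        rule_a & rule_b,
        "control with self-report dx; non-diabetic with self-report rx",
        np.where(
            rule_a,
            "control with self-report dx",
            np.where(rule_b, "non-diabetic with self-report rx", ""),
        ),
    )
    df["exclusion_reason"] = reason
    return SampleTable(df)


def filter_maf(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs whose empirical MAF is <= ``threshold``.

    MAF is computed from non-missing dosages (folded to the minor allele).
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    maf = genotypes.empirical_maf()
    keep = maf.index[maf > threshold]
    if len(keep) == 0:
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return genotypes.subset_snps(keep)


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 50,
    shift: int = 5,
    r2_threshold: float = 0.5,
) -> GenotypeMatrix:
    """Windowed LD pruning on squared Pearson correlation of dosages.

    Per chromosome, SNPs are taken in position order.  Within each window of
    ``window`` SNPs, while any retained pair correlates above
    ``r2_threshold`` the later SNP (in position order) is removed; the window
    then advances by ``shift``.  Removal is permanent across windows, so the
    result is a subset of the input columns and pruning is idempotent.
    """
    if not (window >= shift >= 1):
        raise ValueError("require window >= shift >= 1")
    man = genotypes.manifest
    removed: set[str] = set()
    for chrom, sub in man.groupby("chrom", sort=False):
        order = sub.sort_values(["pos", "snp_id"], kind="mergesort")["snp_id"].tolist()
        X = genotypes.dosages[order].to_numpy(dtype=float)
        start = 0
        while start < len(order):
            idx = [
                i for i in range(start, min(start + window, len(order)))
                if order[i] not in removed
            ]
            changed = True
            while changed:
                changed = False
                for a_pos in range(len(idx)):
                    if changed:
                        break
                    for b_pos in range(a_pos + 1, len(idx)):
                        i, j = idx[a_pos], idx[b_pos]
                        r2 = _pairwise_r2(X[:, i], X[:, j])
                        if r2 > r2_threshold:
                            removed.add(order[j])  # drop the later SNP
                            idx.remove(j)
                            changed = True
                            break
            if start + window >= len(order):
                break
            start += shift
    keep = [s for s in genotypes.snp_ids if s not in removed]
    return genotypes.subset_snps(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return 0.0
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def cohort_bookkeeping(
    group_sizes: dict[str, int],
    self_report_dx: dict[str, int],
    self_report_rx: dict[str, int],
) -> dict[str, float]:
    """Cohort summary arithmetic over printed per-class counts.

    Given per-class subject totals, per-class counts of subjects
    self-reporting a diabetes diagnosis, and per-class counts self-reporting
    anti-diabetic medication, returns the total cohort size, the number of
    diagnosis reporters, and the percentages of diagnosis reporters who
    (a) fall in the diabetic HbA1c class and (b) report medication.
    """
    n_total = sum(group_sizes.values())
    n_dx = sum(self_report_dx.values())
    n_rx = sum(self_report_rx.values())
    if n_dx == 0:
        raise ValueError("no diagnosis reporters")
    return {
        "n_total": float(n_total),
        "n_self_report_dx": float(n_dx),
        "pct_dx_reporters_diabetic_class": round(
            100.0 * self_report_dx.get(DIABETIC, 0) / n_dx
        ),
        "pct_dx_reporters_on_rx": round(100.0 * n_rx / n_dx),
    }


# ---------------------------------------------------------------------------
# Readers / writers.  All formats are plain TSV; round-trips are lossless.
# ---------------------------------------------------------------------------

def write_sample_table(samples: SampleTable, path) -> None:
    samples.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if "exclusion_reason" in df.columns:
        df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    return SampleTable(df)


def write_methylation(meth: MethylationMatrix, values_path, manifest_path) -> None:
    meth.values.to_csv(values_path, sep="\t", index_label="sample_id", na_rep="NA")
    meth.manifest.to_csv(manifest_path, sep="\t", index=False, na_rep="NA")


def read_methylation(values_path, manifest_path) -> MethylationMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id", na_values=["NA"])
    manifest = pd.read_csv(manifest_path, sep="\t", na_values=["NA"], keep_default_na=False)
    if len(manifest) != values.shape[1]:
        raise SchemaError(
            f"manifest has {len(manifest)} rows but matrix has "
            f"{values.shape[1]} probe columns ({values_path})"
        )
    return MethylationMatrix(values, manifest)


def write_genotypes(geno: GenotypeMatrix, raw_path, bim_path) -> None:
    """PLINK .raw-style additive TSV plus a BIM-like manifest TSV."""
    out = geno.dosages.copy()
    out.insert(0, "IID", geno.dosages.index)
    out.to_csv(raw_path, sep="\t", index=False, na_rep="NA")
    geno.manifest.to_csv(bim_path, sep="\t", index=False, na_rep="NA")


def read_genotypes(raw_path, bim_path) -> GenotypeMatrix:
    raw = pd.read_csv(raw_path, sep="\t", na_values=["NA"])
    if "IID" not in raw.columns:
        raise SchemaError(f"genotype file lacks IID column ({raw_path})")
    dosages = raw.set_index("IID")
    dosages.index.name = "sample_id"
    manifest = pd.read_csv(bim_path, sep="\t", na_values=["NA"], keep_default_na=False)
    if len(manifest) != dosages.shape[1]:
        raise SchemaError(
            f"manifest has {len(manifest)} rows but matrix has "
            f"{dosages.shape[1]} SNP columns ({raw_path})"
        )
    return GenotypeMatrix(dosages, manifest)
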