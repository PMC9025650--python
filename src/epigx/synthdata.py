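"""Synthetic cohort generator with planted, known-truth effects.

Emulates the statistical structure the downstream analysis assumes: a
quantitative glycemic exposure (HbA1c, %) drawn from a right-skewed
three-stratum mixture; Hardy-Weinberg genotypes over a configurable MAF
spectrum; beta-distributed (logit-normal) methylation with a dose-dependent
exposure effect at one target probe; planted cis/trans meQTL and
SNP x exposure interaction effects of stated latent variance fractions;
planted stochastic-epimutation (SEM) outliers beyond the 3 x IQR fences;
and CpG x SNP interaction effects on the exposure itself.

Every random draw flows from ``SimConfig.seed`` through seed-sequence
spawning, so an identical config yields byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .dataio import (
    CONTROL,
    DIABETIC,
    PREDIABETIC,
    GenotypeMatrix,
    MethylationMatrix,
    SampleTable,
    bin_glycemic_class,
)

__all__ = ["SimConfig", "GroundTruth", "simulate_genotypes",
           "simulate_phenotypes_and_methylation", "simulate_cohort"]

#: HbA1c strata: (lower bound, upper bound, mean, sd) on the % scale.
#: Means/sds are plausible defaults for control / prediabetic / diabetic
#: strata of a mature, majority-female cohort.
_HBA1C_STRATA = (
    (3.5, 5.7, 5.34, 0.26),
    (5.7 + 1e-9, 6.5 - 1e-9, 5.96, 0.21),
    (6.5, 16.0, 8.02, 1.84),
)


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass
class SimConfig:
    """Study-condition bundle for one synthetic cohort.

    Variance fractions are on the latent (logit) scale of the target probe
    and must sum to < 1 across exposure, age, meQTL main effects and GxE
    interactions.  ``planted_gxmeth`` effects are on the HbA1c % scale per
    SD x SD of the standardized CpG x SNP product.
    """

    n_subjects: int = 506
    n_probes: int = 500
    n_snps: int = 2000
    n_chromosomes: int = 22
    target_probe_id: str = "cg_target"
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_variance_fraction: float = 0.15
    age_variance_fraction: float = 0.01
    planted_meqtl: list = field(default_factory=list)   # (snp_id, var fraction)
    planted_gxe: list = field(default_factory=list)     # (snp_id, var fraction)
    planted_gxmeth: list = field(default_factory=list)  # (snp_id, effect, HbA1c %)
    planted_sem: list = field(default_factory=list)     # (probe_id, n, "high"/"low")
    class_proportions: tuple[float, float, float] = (142 / 506, 274 / 506, 90 / 506)
    missing_rate: float = 0.0
    target_mean_beta: float = 0.66
    latent_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        if self.n_subjects < 30:
            raise ConfigurationError("n_subjects must be >= 30")
        fracs = (
            [self.exposure_variance_fraction, self.age_variance_fraction]
            + [f for _, f in self.planted_meqtl]
            + [f for _, f in self.planted_gxe]
        )
        if any(not 0 <= f < 1 for f in fracs) or sum(fracs) >= 1:
            raise ConfigurationError(
                "variance fractions must lie in [0, 1) and sum to < 1"
            )
        if abs(sum(self.class_proportions) - 1) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted-effect records for downstream recovery checks."""

    effects: pd.DataFrame        # effect_type, target_id, effect_size
    sem_placements: pd.DataFrame  # probe_id, sample_id, class

    def to_tsv(self, effects_path, sem_path) -> None:
        self.effects.to_csv(effects_path, sep="\t", index=False)
        self.sem_placements.to_csv(sem_path, sep="\t", index=False)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw additive dosages at Hardy-Weinberg proportions.

    Each SNP's MAF is sampled uniformly from ``config.maf_range``;
    dosages are Binomial(2, maf).  Chromosome assignments are uniform over
    ``n_chromosomes`` and positions uniform on [1, 2.5e8].
    """
    rng = _rng(config, 0)
    n, m = config.n_subjects, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan
    snp_ids = [f"snp_{i:05d}" for i in range(m)]
    sample_ids = [f"S{i:04d}" for i in range(config.n_subjects)]
    alleles = rng.choice(list("ACGT"), size=(m, 2))
    manifest = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": rng.integers(1, config.n_chromosomes + 1, size=m),
            "pos": rng.integers(1, 250_000_000, size=m),
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
            "maf": mafs,
        }
    )
    df = pd.DataFrame(dosages, index=pd.Index(sample_ids, name="sample_id"),
                      columns=snp_ids)
    return GenotypeMatrix(df, manifest)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ConfigurationError("planted term is constant in this sample")
    return (x - x.mean()) / sd


#: Per-stratum (control / prediabetic / diabetic) age means and BMI medians,
#: mirroring the older, more obese profile of the diabetic stratum.
_AGE_MEANS = (45.3, 46.7, 52.1)
_BMI_MEDIANS = (31.0, 32.9, 36.9)


def _draw_hba1c(rng: np.random.Generator, n: int, proportions):
    strata = rng.choice(3, size=n, p=list(proportions))
    out = np.empty(n)
    for k, (lo, hi, mu, sd) in enumerate(_HBA1C_STRATA):
        idx = np.flatnonzero(strata == k)
        if idx.size == 0:
            continue
        a, b = (lo - mu) / sd, (hi - mu) / sd
        out[idx] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=idx.size,
                                 random_state=rng)
    return out, strata


def simulate_phenotypes_and_methylation(
    config: SimConfig, genotypes: GenotypeMatrix
) -> tuple[SampleTable, MethylationMatrix, GroundTruth]:
    """Generate phenotypes, the methylation matrix and the ground truth.

    The target probe's latent (logit-scale) value is a linear combination of
    the standardized exposure, age, planted SNP main effects and SNP x
    exposure interactions, each scaled so it explains its configured variance
    fraction of the latent variance; the remainder is Gaussian noise.  The
    latent value maps through the logistic function, so betas stay in (0, 1).
    Non-target probes are null logit-normal noise; probes carrying planted
    SEMs get their outlier subjects placed strictly outside the 3 x IQR
    fences of the probe's remaining values.
    """
    rng = _rng(config, 1)
    n = config.n_subjects
    sample_ids = list(genotypes.dosages.index)
    if len(sample_ids) != n:
        raise ConfigurationError("genotypes were not generated from this config")

    for snp_id, _ in list(config.planted_meqtl) + list(config.planted_gxe) + [
        (s, e) for s, e in config.planted_gxmeth
    ]:
        if snp_id not in genotypes.dosages.columns:
            raise ConfigurationError(f"planted SNP {snp_id!r} not in manifest")

    hba1c, strata = _draw_hba1c(rng, n, config.class_proportions)
    age_mu = np.array(_AGE_MEANS)[strata]
    bmi_med = np.array(_BMI_MEDIANS)[strata]
    age = np.clip(rng.normal(age_mu, 8.0), 22, 80)
    sex = (rng.random(n) < 0.75).astype(int)  # 1 = female
    bmi = np.exp(rng.normal(np.log(bmi_med), 0.24))

    # --- target probe on the latent logit scale -------------------------
    terms: list[tuple[str, str, float, np.ndarray]] = []
    terms.append(("exposure", "hba1c", config.exposure_variance_fraction,
                  -_standardize(hba1c)))  # demethylation with rising HbA1c
    terms.append(("age", "age", config.age_variance_fraction, -_standardize(age)))
    dos = genotypes.dosages
    for snp_id, frac in config.planted_meqtl:
        g = np.nan_to_num(dos[snp_id].to_numpy(float),
                          nan=float(dos[snp_id].mean()))
        terms.append(("meqtl", snp_id, frac, _standardize(g)))
    zh = _standardize(hba1c)
    for snp_id, frac in config.planted_gxe:
        g = np.nan_to_num(dos[snp_id].to_numpy(float),
                          nan=float(dos[snp_id].mean()))
        terms.append(("gxe", snp_id, frac, _standardize(_standardize(g) * zh)))

    # Sequentially orthogonalize the planted terms and residualize the noise
    # against them, so each term explains exactly its configured variance
    # fraction of the latent (logit-scale) variance in the emitted sample.
    basis: list[np.ndarray] = []
    ortho_terms = []
    for _, _, f, x in terms:
        for b in basis:
            x = x - (x @ b) / (b @ b) * b
        x = _standardize(x)
        basis.append(x)
        ortho_terms.append((f, x))
    eps = rng.standard_normal(n)
    for b in basis:
        eps = eps - (eps @ b) / (b @ b) * b
    eps = _standardize(eps)
    frac_sum = sum(f for _, _, f, _ in terms)
    z = logit(config.target_mean_beta) + config.latent_sd * (
        sum(np.sqrt(f) * x for f, x in ortho_terms)
        + np.sqrt(1 - frac_sum) * eps
    )
    target_beta = expit(z)

    # --- null probes ----------------------------------------------------
    probe_ids = [f"cg_{i:05d}" for i in range(config.n_probes - 1)]
    sem_map = {p: (k, d) for p, k, d in config.planted_sem}
    for pid in sem_map:
        if pid != config.target_probe_id and pid not in probe_ids:
            raise ConfigurationError(f"planted SEM probe {pid!r} not in manifest")
        k = sem_map[pid][0]
        if not 1 <= k <= n // 10:
            raise ConfigurationError("SEM outlier count must be in [1, n/10]")

    m = len(probe_ids)
    baseline = rng.uniform(0.2, 0.8, size=m)
    sd_logit = np.full(m, 0.30)
    # SEM-carrying probes: mid-range baseline and tight noise, leaving
    # headroom inside [0, 1] for fence-exceeding outliers.
    for j, pid in enumerate(probe_ids):
        if pid in sem_map:
            baseline[j] = rng.uniform(0.40, 0.55)
            sd_logit[j] = 0.10
    betas = expit(logit(baseline) + sd_logit * rng.standard_normal((n, m)))

    sem_records = []
    for j, pid in enumerate(probe_ids):
        if pid not in sem_map:
            continue
        k, direction = sem_map[pid]
        out_idx = rng.choice(n, size=k, replace=False)
        keep = np.setdiff1d(np.arange(n), out_idx)
        q1, q3 = np.quantile(betas[keep, j], [0.25, 0.75])
        iqr = q3 - q1
        if direction == "high":
            fence = q3 + 3 * iqr
            if fence >= 1:
                raise ConfigurationError(f"no headroom for high SEM at {pid}")
            value = fence + 0.5 * (1 - fence)
        elif direction == "low":
            fence = q1 - 3 * iqr
            if fence <= 0:
                raise ConfigurationError(f"no headroom for low SEM at {pid}")
            value = 0.5 * fence
        else:
            raise ConfigurationError(f"SEM direction must be high/low, got {direction!r}")
        betas[out_idx, j] = value
        cls = "HMO" if direction == "high" else "LMO"
        sem_records += [
            {"probe_id": pid, "sample_id": sample_ids[i], "class": cls}
            for i in sorted(out_idx)
        ]

    # --- planted CpG x SNP effects on the exposure ----------------------
    zt = _standardize(target_beta)
    for snp_id, effect in config.planted_gxmeth:
        g = np.nan_to_num(dos[snp_id].to_numpy(float),
                          nan=float(dos[snp_id].mean()))
        prod = _standardize(_standardize(g) * zt)
        hba1c = hba1c + effect * prod
    hba1c = np.clip(hba1c, 3.6, None)

    glycemic = bin_glycemic_class(hba1c)
    dx_p = {CONTROL: 0.03, PREDIABETIC: 0.08, DIABETIC: 0.57}
    rx_p = {CONTROL: 0.0, PREDIABETIC: 0.0, DIABETIC: 0.03}
    dx = rng.random(n) < np.vectorize(dx_p.get)(glycemic)
    rx = rng.random(n) < np.vectorize(rx_p.get)(glycemic)

    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "hba1c": hba1c,
        "self_report_dx_diabetes": dx,
        "self_report_rx_diabetes": rx,
        "glycemic_class": glycemic,
    }))

    all_ids = probe_ids + [config.target_probe_id]
    values = pd.DataFrame(
        np.column_stack([betas, target_beta]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=all_ids,
    )
    mp = len(all_ids)
    islands = rng.choice(
        ["Island", "N Shore", "S Shore", "N Shelf", "S Shelf", "Open Sea"],
        size=mp, p=[0.25, 0.1, 0.1, 0.05, 0.05, 0.45],
    )
    manifest = pd.DataFrame({
        "probe_id": all_ids,
        "chrom": rng.integers(1, config.n_chromosomes + 1, size=mp),
        "pos": rng.integers(1, 250_000_000, size=mp),
        "island_status": islands,
        "gene": ["" for _ in all_ids],
        "polymorphic": rng.random(mp) < 0.1,
    })
    # Anchor the target probe: chromosome 1, fixed coordinate, open sea.
    tloc = manifest.index[manifest["probe_id"] == config.target_probe_id][0]
    manifest.loc[tloc, ["chrom", "pos", "island_status", "polymorphic"]] = (
        1, 145_441_552, "Open Sea", False,
    )
    meth = MethylationMatrix(values, manifest)

    eff = [
        {"effect_type": "exposure", "target_id": config.target_probe_id,
         "effect_size": config.exposure_variance_fraction},
        {"effect_type": "age", "target_id": config.target_probe_id,
         "effect_size": config.age_variance_fraction},
    ]
    eff += [{"effect_type": "meqtl", "target_id": s, "effect_size": f}
            for s, f in config.planted_meqtl]
    eff += [{"effect_type": "gxe", "target_id": s, "effect_size": f}
            for s, f in config.planted_gxe]
    eff += [{"effect_type": "gxmeth", "target_id": s, "effect_size": e}
            for s, e in config.planted_gxmeth]
    truth = GroundTruth(
        effects=pd.DataFrame(eff),
        sem_placements=pd.DataFrame(
            sem_records, columns=["probe_id", "sample_id", "class"]
        ),
    )
    return samples, meth, truth


def simulate_cohort(config: SimConfig):
    """Convenience wrapper: genotypes, then phenotypes + methylation."""
    geno = simulate_genotypes(config)
    samples, meth, truth = simulate_phenotypes_and_methylation(config, geno)
    return samples, meth, geno, truth
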