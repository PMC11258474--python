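"""Seeded synthetic cohorts and summary-level datasets.

Everything downstream of this module (frailty index, instrument selection,
genetic risk scores, two-stage MR, SMR/HEIDI) is exercised on data generated
here, so the generators reproduce the statistical structure the analysis
assumes: LD-blocked biallelic genotypes, blood pressure with additive SNP
effects plus covariates and an unmeasured confounder, an antihypertensive
medication indicator that shifts *observed* BP down by 15/10 mmHg, binary
health-deficit items driven by a liability model in which BP has a known
causal effect, and eQTL+GWAS summary statistics under causal / pleiotropy /
linkage / null scenarios.

All generators are pure functions of (config, seed): the same configuration
and seed always reproduce the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdBlock",
    "SimulationConfig",
    "SummaryScenarioConfig",
    "GenotypeMatrix",
    "CohortPhenotypes",
    "SummaryScenario",
    "default_config",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_summary_scenario",
    "gwas_from_cohort",
]

N_DEFICIT_ITEMS = 49

SMOKING_LEVELS = ["never", "previous", "current"]
ALCOHOL_LEVELS = [
    "never",
    "occasionally",
    "1-3_per_month",
    "1-2_per_week",
    "3-4_per_week",
    "daily",
]


@dataclass(frozen=True)
class LdBlock:
    """A block of SNPs with AR-1 latent-Gaussian linkage disequilibrium.

    ``rho`` is the correlation of the latent Gaussian between adjacent SNPs;
    dosage-scale correlation is attenuated by the 3-level thresholding, so a
    latent rho of 0.9 yields a dosage r^2 of roughly 0.6-0.7 at common MAF.
    """

    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.3
    chrom: str = "1"
    start: int = 1_000_000
    spacing: int = 5_000

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("LD block needs at least one SNP")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.rho < 1.0):
            # rho = 1 makes the latent block correlation singular
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.start < 1 or self.spacing < 1:
            raise ValueError("positions are 1-based; start and spacing must be >= 1")


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    BP model (per individual, mmHg):
        true_sbp = sbp_base + sum_i snp_effects_sbp[i] * g_i
                   + covariate terms + confounder_bp * U + N(0, sbp_noise_sd)
    and analogously for DBP. ``U ~ N(0,1)`` is an unmeasured confounder shared
    with the frailty outcome. Individuals whose true SBP exceeds
    ``med_threshold`` are assigned antihypertensive medication with
    probability ``med_prob``; medication lowers *observed* SBP/DBP by exactly
    15/10 mmHg, so the standard +15/+10 correction inverts it.

    Deficit model (``outcome_mode="deficits"``): item j is present iff
        deficit_intercepts[j] + theta_sbp * (true_sbp - sbp_ref)
            + confounder_liability * U + e_ij > 0,   e_ij ~ N(0, 1).
    Intercepts are on the liability scale with SBP centred at ``sbp_ref``, so
    a_j = sqrt(1 + c^2) * Phi^-1(prev_j) gives item prevalence ``prev_j`` at
    the reference SBP.

    ``outcome_mode="multinomial"`` instead draws the frailty category directly
    from a multinomial logit in true SBP (log-RRR per mmHg given by
    ``cat_coef_pre``/``cat_coef_frail``, confounder loadings
    ``cat_conf_pre``/``cat_conf_frail``); this mode has an exactly known
    causal relative risk ratio and is used for estimator validation.
    """

    n_individuals: int = 20_000
    ld_blocks: list[LdBlock] = field(default_factory=list)
    snp_effects_sbp: np.ndarray | None = None  # mmHg per effect allele
    snp_effects_dbp: np.ndarray | None = None

    sbp_base: float = 125.0
    dbp_base: float = 72.0
    sbp_noise_sd: float = 16.0
    dbp_noise_sd: float = 9.0
    reading_noise_sd: float = 4.0  # within-visit variation between the two cuff readings
    frac_single_reading: float = 0.03

    theta_sbp: float = 0.02  # liability SD per mmHg of true SBP
    sbp_ref: float = 140.0
    confounder_bp: float = 5.0  # mmHg per SD of U
    confounder_liability: float = 0.3  # liability SD per SD of U

    med_threshold: float = 160.0
    med_prob: float = 0.7

    deficit_intercepts: np.ndarray | None = None  # length n_deficit_items
    n_deficit_items: int = N_DEFICIT_ITEMS
    deficit_missing_rate: float = 0.0

    # effects of measured covariates on BP (exercise the adjustment code path)
    age_effect_sbp: float = 0.45  # mmHg per year
    age_effect_dbp: float = 0.20
    bmi_effect_sbp: float = 0.5  # mmHg per kg/m^2
    bmi_effect_dbp: float = 0.3
    sex_effect_sbp: float = 4.0  # male minus female
    sex_effect_dbp: float = 2.0

    outcome_mode: str = "deficits"  # or "multinomial"
    cat_coef_pre: float = 0.0  # log-RRR per mmHg true SBP, pre-frail vs non-frail
    cat_coef_frail: float = 0.0
    cat_conf_pre: float = 0.0  # log-odds per SD of U
    cat_conf_frail: float = 0.0
    cat_intercept_pre: float = -0.75
    cat_intercept_frail: float = -3.4

    seed: int = 0

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.ld_blocks)

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.ld_blocks:
            raise ValueError("at least one LD block is required")
        for block in self.ld_blocks:
            block.validate()
        if not (0.0 <= self.med_prob <= 1.0):
            raise ValueError(f"med_prob must lie in [0, 1], got {self.med_prob}")
        for name in ("snp_effects_sbp", "snp_effects_dbp"):
            eff = getattr(self, name)
            if eff is not None and len(eff) != self.n_snps:
                raise ValueError(
                    f"{name} has length {len(eff)} but the LD blocks define {self.n_snps} SNPs"
                )
        if self.deficit_intercepts is not None and len(self.deficit_intercepts) != self.n_deficit_items:
            raise ValueError(
                f"expected {self.n_deficit_items} deficit intercepts, "
                f"got {len(self.deficit_intercepts)}"
            )
        if self.outcome_mode not in ("deficits", "multinomial"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``snps`` columns: snp, chrom, pos, effect_allele, other_allele, maf.
    Dosages count copies of the effect allele (0/1/2 after generation;
    readers may hold fractional imputed dosages in [0, 2]).
    """

    dosages: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} columns "
                f"but metadata describes {len(self.snps)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def observed_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = self.snps.set_index("snp").index.get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs absent from genotype matrix: {missing}")
        return GenotypeMatrix(self.dosages[:, idx], self.snps.iloc[idx].reset_index(drop=True))


@dataclass
class CohortPhenotypes:
    """Phenotypes, covariates and deficit items for a synthetic cohort.

    ``phenotypes`` columns: sbp_reading1, sbp_reading2, dbp_reading1,
    dbp_reading2 (reading 2 is NaN for single-measurement individuals),
    n_bp_readings, on_bp_med, true_sbp, true_dbp, age, sex, center, smoking,
    alcohol, bmi, deprivation, array, pc1..pc10 (plus frailty_category in
    multinomial outcome mode). ``deficits`` is persons x items in {0, 1}
    with NaN for missing answers.
    """

    phenotypes: pd.DataFrame
    deficits: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return len(self.phenotypes)


@dataclass
class SummaryScenarioConfig:
    """Configuration for one simulated gene window of summary statistics.

    The gene sits in a window of ``n_snps`` cis SNPs with AR-1 LD (latent
    correlation ``rho`` between adjacent SNPs, applied directly as the
    summary-level LD correlation). ``b_eqtl`` is the causal variant's effect
    on expression (SD of expression per allele); marginal effects at the
    other SNPs arise through LD. Standard errors reflect the eQTL and GWAS
    sample sizes (GTEx-scale tissue panels give top cis-eQTL |z| around
    10-20; the outcome GWAS is biobank-scale).

    Scenarios
    ---------
    causal      one variant drives expression, and the outcome through it:
                b_zy,true = b_xy_true * b_zx,true at every SNP.
    pleiotropy  the same single variant also affects the outcome directly;
                the marginal structure is proportional exactly as in the
                causal scenario (a single shared causal variant is the
                HEIDI null in both cases).
    linkage     two distinct causal variants in LD: one drives expression
                only, one drives the outcome only (b_outcome_direct).
    null        expression signal present, no outcome signal (b_zy,true = 0).
    """

    scenario: str = "causal"
    n_snps: int = 25
    rho: float = 0.9
    causal_index: int = 12
    second_causal_offset: int = 5  # linkage: r = rho**offset to the eQTL variant
    b_eqtl: float = 1.0
    b_xy_true: float = -0.02  # FI units per SD expression (causal/pleiotropy)
    b_outcome_direct: float = -0.02  # linkage: direct outcome effect of variant 2
    se_zx: float = 0.07
    se_zy: float = 5e-3  # FI-unit GWAS se; with |b_zy| ~ 0.02 the top outcome z is ~4
    gene: str = "GENE1"
    tissue: str = "artery_aorta"
    chrom: str = "7"
    gene_start: int = 150_600_000
    gene_end: int = 150_650_000
    snp_spacing: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in ("causal", "pleiotropy", "linkage", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_snps < 2:
            raise ValueError("a summary scenario needs at least 2 SNPs")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if not (0 <= self.causal_index < self.n_snps):
            raise ValueError("causal_index outside the SNP window")
        if self.se_zx <= 0 or self.se_zy <= 0:
            raise ValueError("standard errors must be positive")


@dataclass
class SummaryScenario:
    """Per-SNP eQTL and GWAS summary statistics plus the window's LD matrix.

    ``records`` columns: gene, tissue, snp, chrom, pos, a1, a2, b_zx, se_zx,
    p_zx, b_zy, se_zy, p_zy. ``ld`` holds signed correlations r (not r^2),
    symmetric with unit diagonal, eigenvalue-clipped to be PSD.
    """

    scenario: str
    records: pd.DataFrame
    ld: np.ndarray
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        m = len(self.records)
        if self.ld.shape != (m, m):
            raise ValueError("LD matrix dimension does not match the record count")
        if not np.allclose(self.ld, self.ld.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.ld), 1.0, atol=1e-9):
            raise ValueError("LD matrix must have unit diagonal")


# ---------------------------------------------------------------------------
# genotype generation


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """Latent N(0,1) draws with AR-1 correlation rho along the SNP axis."""
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an LD-blocked dosage matrix from the thresholded-Gaussian model.

    Within each block a latent multivariate normal with AR-1 correlation is
    thresholded per SNP at Hardy-Weinberg quantiles of its MAF, giving
    genotypes 0/1/2 with marginal frequencies (1-m)^2, 2m(1-m), m^2.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E0]))
    n = config.n_individuals

    dosage_cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for bi, block in enumerate(config.ld_blocks):
        mafs = rng.uniform(*block.maf_range, size=block.n_snps)
        z = _ar1_latent(rng, n, block.n_snps, block.rho)
        # HW thresholds: P(g=0) = (1-m)^2, P(g<=1) = (1-m)^2 + 2m(1-m)
        p0 = (1.0 - mafs) ** 2
        p01 = p0 + 2.0 * mafs * (1.0 - mafs)
        t0 = stats.norm.ppf(p0)
        t1 = stats.norm.ppf(p01)
        g = (z >= t0).astype(np.int8) + (z >= t1).astype(np.int8)
        dosage_cols.append(g.astype(float))
        for j in range(block.n_snps):
            meta_rows.append(
                {
                    "snp": f"rs{bi + 1:02d}{j + 1:03d}",
                    "chrom": block.chrom,
                    "pos": block.start + j * block.spacing,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "maf": mafs[j],
                }
            )

    dosages = np.concatenate(dosage_cols, axis=1)
    snps = pd.DataFrame(meta_rows)
    return GenotypeMatrix(dosages=dosages, snps=snps)


# ---------------------------------------------------------------------------
# cohort generation


def _default_deficit_intercepts(config: SimulationConfig) -> np.ndarray:
    """Item thresholds giving baseline prevalences from 1% to 22% at sbp_ref,
    which puts the bulk of the cohort below the 0.12 FI cutoff with a small
    frail tail, as in population FI distributions."""
    prev = np.linspace(0.01, 0.22, config.n_deficit_items)
    scale = np.sqrt(1.0 + config.confounder_liability**2)
    return scale * stats.norm.ppf(prev)


def simulate_cohort(genotypes: GenotypeMatrix, config: SimulationConfig) -> CohortPhenotypes:
    """Generate phenotypes, covariates, medication status and deficit items."""
    config.validate()
    if genotypes.n_snps != config.n_snps:
        raise ValueError(
            f"genotype matrix has {genotypes.n_snps} SNPs but the config defines {config.n_snps}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    n = genotypes.n_individuals
    g = genotypes.dosages

    eff_sbp = np.zeros(config.n_snps) if config.snp_effects_sbp is None else np.asarray(
        config.snp_effects_sbp, dtype=float
    )
    eff_dbp = np.zeros(config.n_snps) if config.snp_effects_dbp is None else np.asarray(
        config.snp_effects_dbp, dtype=float
    )

    age = rng.uniform(40.0, 69.0, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = male
    center = rng.integers(0, 22, size=n)
    smoking = rng.choice(len(SMOKING_LEVELS), size=n, p=[0.55, 0.34, 0.11])
    alcohol = rng.choice(len(ALCOHOL_LEVELS), size=n, p=[0.08, 0.11, 0.11, 0.26, 0.23, 0.21])
    bmi = np.clip(rng.normal(27.0, 4.5, size=n), 15.0, 55.0)
    deprivation = rng.integers(1, 6, size=n)
    array = rng.integers(0, 2, size=n)
    pcs = rng.normal(0.0, 1.0, size=(n, 10))

    confounder = rng.standard_normal(n)

    cov_sbp = (
        config.age_effect_sbp * (age - 55.0)
        + config.sex_effect_sbp * sex
        + config.bmi_effect_sbp * (bmi - 27.0)
        + 0.1 * pcs[:, 0]
    )
    cov_dbp = (
        config.age_effect_dbp * (age - 55.0)
        + config.sex_effect_dbp * sex
        + config.bmi_effect_dbp * (bmi - 27.0)
        + 0.05 * pcs[:, 0]
    )

    true_sbp = (
        config.sbp_base
        + g @ eff_sbp
        + cov_sbp
        + config.confounder_bp * confounder
        + rng.normal(0.0, config.sbp_noise_sd, size=n)
    )
    true_dbp = (
        config.dbp_base
        + g @ eff_dbp
        + cov_dbp
        + 0.6 * config.confounder_bp * confounder
        + rng.normal(0.0, config.dbp_noise_sd, size=n)
    )
    # physiological ordering: pulse pressure stays positive
    true_dbp = np.minimum(true_dbp, true_sbp - 10.0)

    on_med = (true_sbp > config.med_threshold) & (rng.random(n) < config.med_prob)
    obs_sbp = true_sbp - 15.0 * on_med
    obs_dbp = true_dbp - 10.0 * on_med

    single = rng.random(n) < config.frac_single_reading
    r_noise = rng.normal(0.0, config.reading_noise_sd, size=(n, 4))
    sbp1 = obs_sbp + r_noise[:, 0]
    sbp2 = np.where(single, np.nan, obs_sbp + r_noise[:, 1])
    dbp1 = obs_dbp + r_noise[:, 2]
    dbp2 = np.where(single, np.nan, obs_dbp + r_noise[:, 3])

    phen = pd.DataFrame(
        {
            "person_id": [f"id{i:06d}" for i in range(n)],
            "sbp_reading1": sbp1,
            "sbp_reading2": sbp2,
            "dbp_reading1": dbp1,
            "dbp_reading2": dbp2,
            "n_bp_readings": np.where(single, 1, 2),
            "on_bp_med": on_med.astype(int),
            "true_sbp": true_sbp,
            "true_dbp": true_dbp,
            "age": age,
            "sex": sex,
            "center": center,
            "smoking": smoking,
            "alcohol": alcohol,
            "bmi": bmi,
            "deprivation": deprivation,
            "array": array,
        }
    )
    for k in range(10):
        phen[f"pc{k + 1}"] = pcs[:, k]

    sbp_c = true_sbp - config.sbp_ref
    if config.outcome_mode == "multinomial":
        eta_pre = (
            config.cat_intercept_pre + config.cat_coef_pre * sbp_c + config.cat_conf_pre * confounder
        )
        eta_frail = (
            config.cat_intercept_frail
            + config.cat_coef_frail * sbp_c
            + config.cat_conf_frail * confounder
        )
        denom = 1.0 + np.exp(eta_pre) + np.exp(eta_frail)
        p_pre = np.exp(eta_pre) / denom
        p_frail = np.exp(eta_frail) / denom
        u = rng.random(n)
        cat = np.where(u < p_frail, 2, np.where(u < p_frail + p_pre, 1, 0))
        phen["frailty_category"] = pd.Categorical.from_codes(
            cat, categories=["non_frail", "pre_frail", "frail"]
        )
        deficits = pd.DataFrame(index=phen["person_id"])
    else:
        intercepts = (
            _default_deficit_intercepts(config)
            if config.deficit_intercepts is None
            else np.asarray(config.deficit_intercepts, dtype=float)
        )
        liab = (
            intercepts[None, :]
            + config.theta_sbp * sbp_c[:, None]
            + config.confounder_liability * confounder[:, None]
            + rng.standard_normal((n, config.n_deficit_items))
        )
        items = (liab > 0).astype(float)
        if config.deficit_missing_rate > 0:
            miss = rng.random(items.shape) < config.deficit_missing_rate
            items[miss] = np.nan
        deficits = pd.DataFrame(
            items,
            index=phen["person_id"],
            columns=[f"item{j + 1:02d}" for j in range(config.n_deficit_items)],
        )

    return CohortPhenotypes(phenotypes=phen, deficits=deficits)


# ---------------------------------------------------------------------------
# discovery GWAS from a simulated cohort


def gwas_from_cohort(
    genotypes: GenotypeMatrix, trait: np.ndarray, n_label: int | None = None
) -> pd.DataFrame:
    """Per-SNP marginal regressions of a trait on dosage, in .ma-style columns.

    Returns a DataFrame with columns SNP, A1, A2, freq, b, se, p, N plus
    chrom/pos carried over from the genotype metadata. This plays the role of
    the external discovery GWAS whose coefficients weight the risk score.
    """
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    g = genotypes.dosages
    gc = g - g.mean(axis=0)
    yc = trait - trait.mean()
    ss_g = (gc**2).sum(axis=0)
    beta = gc.T @ yc / ss_g
    resid_var = ((yc**2).sum() - beta**2 * ss_g) / (n - 2)
    se = np.sqrt(resid_var / ss_g)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    freq = g.mean(axis=0) / 2.0
    out = genotypes.snps[["snp", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out.columns = ["SNP", "chrom", "pos", "A1", "A2"]
    out["freq"] = freq
    out["b"] = beta
    out["se"] = se
    out["p"] = p
    out["N"] = n if n_label is None else n_label
    return out


# ---------------------------------------------------------------------------
# summary-level scenarios for SMR / HEIDI


def _psd_clip(r: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at zero and restore the unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def simulate_summary_scenario(config: SummaryScenarioConfig) -> SummaryScenario:
    """Draw eQTL and GWAS summary statistics for one cis window.

    Marginal true effects are the causal effects propagated through LD
    (b_marg,i = r_{i,c} * b_causal); estimates add multivariate-normal
    sampling noise with covariance se^2 * R within each study, the eQTL and
    GWAS samples being independent of each other.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5347]))
    m = config.n_snps
    idx = np.arange(m)
    r = config.rho ** np.abs(idx[:, None] - idx[None, :])
    r = _psd_clip(r)

    c1 = config.causal_index
    b_zx_true = r[:, c1] * config.b_eqtl

    if config.scenario in ("causal", "pleiotropy"):
        b_zy_true = config.b_xy_true * b_zx_true
    elif config.scenario == "null":
        b_zy_true = np.zeros(m)
    else:  # linkage
        c2 = c1 + config.second_causal_offset
        if not (0 <= c2 < m):
            raise ValueError("second causal variant falls outside the SNP window")
        b_zy_true = r[:, c2] * config.b_outcome_direct

    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    b_zx = b_zx_true + config.se_zx * (chol @ rng.standard_normal(m))
    b_zy = b_zy_true + config.se_zy * (chol @ rng.standard_normal(m))

    se_zx = np.full(m, config.se_zx)
    se_zy = np.full(m, config.se_zy)
    p_zx = 2.0 * stats.norm.sf(np.abs(b_zx / se_zx))
    p_zy = 2.0 * stats.norm.sf(np.abs(b_zy / se_zy))

    mid = (config.gene_start + config.gene_end) // 2
    pos = mid + (idx - m // 2) * config.snp_spacing
    records = pd.DataFrame(
        {
            "gene": config.gene,
            "tissue": config.tissue,
            "snp": [f"rs{config.gene}_{j + 1:03d}" for j in range(m)],
            "chrom": config.chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "b_zx": b_zx,
            "se_zx": se_zx,
            "p_zx": p_zx,
            "b_zy": b_zy,
            "se_zy": se_zy,
            "p_zy": p_zy,
        }
    )
    return SummaryScenario(
        scenario=config.scenario,
        records=records,
        ld=r,
        gene_start=config.gene_start,
        gene_end=config.gene_end,
    )


# ---------------------------------------------------------------------------
# default study configuration


def default_config(seed: int = 0, n_individuals: int = 20_000) -> SimulationConfig:
    """The default synthetic study: six drug-target gene blocks plus a
    polygenic background block, with BP effect sizes typical of genome-wide
    significant BP loci (0.3-1.2 mmHg per allele)."""
    blocks = [
        # one block per drug-target gene region (chrom, window start)
        LdBlock(n_snps=4, maf_range=(0.15, 0.45), rho=0.55, chrom="17", start=63_470_000),  # ACE
        LdBlock(n_snps=5, maf_range=(0.15, 0.45), rho=0.55, chrom="10", start=114_040_000),  # ADRB1
        LdBlock(n_snps=5, maf_range=(0.15, 0.45), rho=0.55, chrom="7", start=150_640_000),  # KCNH2
        LdBlock(n_snps=6, maf_range=(0.15, 0.45), rho=0.55, chrom="12", start=2_160_000),  # CACNA1C
        LdBlock(n_snps=5, maf_range=(0.15, 0.45), rho=0.55, chrom="10", start=18_420_000),  # CACNB2
        LdBlock(n_snps=5, maf_range=(0.15, 0.45), rho=0.55, chrom="16", start=56_860_000),  # SLC12A3
        # polygenic background away from any drug-target gene
        LdBlock(n_snps=10, maf_range=(0.10, 0.45), rho=0.0, chrom="2", start=30_000_000, spacing=2_000_000),
    ]
    n_snps = sum(b.n_snps for b in blocks)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEFF]))
    eff_sbp = rng.uniform(0.4, 1.2, size=n_snps) * rng.choice([-1.0, 1.0], size=n_snps)
    eff_dbp = 0.55 * eff_sbp + rng.normal(0.0, 0.08, size=n_snps)
    return SimulationConfig(
        n_individuals=n_individuals,
        ld_blocks=blocks,
        snp_effects_sbp=eff_sbp,
        snp_effects_dbp=eff_dbp,
        seed=seed,
    )
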