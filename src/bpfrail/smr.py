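"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

For a gene expression probe with top cis-eQTL effect b_zx and outcome GWAS
effect b_zy at the same variant, the SMR estimate of the expression-on-
outcome effect is the ratio b_xy = b_zy / b_zx, tested with

    T_SMR = z_zx^2 * z_zy^2 / (z_zx^2 + z_zy^2),   z = b / se,

referred to chi-square(1). HEIDI asks whether b_xy is constant across the
other cis SNPs in LD with the top eQTL: under a single shared causal
variant all per-SNP ratios estimate the same quantity, so the differences
d_i = b_xy(i) - b_xy(top) are jointly zero-mean; heterogeneity (small
HEIDI p) points to linkage of distinct causal variants. The covariance of
the d_i follows from a first-order delta method with the eQTL and GWAS
samples independent, and the null distribution of T_HEIDI = sum z_d,i^2 —
a sum of correlated squared standard normals — is evaluated by seeded
Monte Carlo over its eigenvalue mixture, with a Satterthwaite
moment-matched chi-square as an analytic cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SmrResult",
    "HeidiResult",
    "pick_top_cis_eqtl",
    "smr_test",
    "select_heidi_snps",
    "heidi_test",
    "smr_multiple_testing",
    "run_smr",
]

log = logging.getLogger(__name__)

HEIDI_ALPHA = 0.01  # HEIDI p below this flags a linkage (heterogeneous) signal
HEIDI_MIN_SNPS = 3
HEIDI_MAX_SNPS = 20
HEIDI_P_EQTL_MAX = 1.6e-3  # drop weak instruments from the HEIDI set
HEIDI_R2_TOP_MAX = 0.9  # drop near-perfect proxies of the top eQTL


@dataclass
class SmrResult:
    gene: str
    tissue: str
    top_snp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int

    @property
    def passed_heidi(self) -> bool | None:
        """True when there is no evidence the signal is driven by linkage."""
        if self.p_heidi is None:
            return None
        return self.p_heidi >= HEIDI_ALPHA


@dataclass
class HeidiResult:
    p: float  # Monte-Carlo p-value
    p_satterthwaite: float
    statistic: float
    n_snps: int  # SNPs contributing difference terms


def pick_top_cis_eqtl(
    eqtl_records: pd.DataFrame,
    gene_start: int,
    gene_end: int,
    cis_window: int = 1_000_000,
    p_max: float = 5e-8,
) -> pd.Series | None:
    """The lowest-p cis-eQTL of a gene, or None if the probe fails inclusion.

    cis = within ``cis_window`` bp of either gene end. Ties on p are broken
    by larger |z_zx|, then smaller position. Genes with no cis-eQTL at
    p < ``p_max`` are skipped.
    """
    cis = eqtl_records[
        eqtl_records["pos"].between(gene_start - cis_window, gene_end + cis_window)
    ]
    if cis.empty:
        log.info("no cis SNPs for gene window [%d, %d]", gene_start, gene_end)
        return None
    passing = cis[cis["p_zx"] < p_max]
    if passing.empty:
        log.info("gene skipped: no cis-eQTL at p < %g", p_max)
        return None
    ranked = passing.assign(_absz=(passing["b_zx"] / passing["se_zx"]).abs()).sort_values(
        ["p_zx", "_absz", "pos"], ascending=[True, False, True], kind="mergesort"
    )
    return ranked.iloc[0].drop("_absz")


def smr_test(b_zx: float, se_zx: float, b_zy: float, se_zy: float):
    """Ratio estimate and chi-square(1) SMR test.

    Returns (b_xy, se_xy, p_smr). se_xy is defined through the test
    statistic, se_xy = |b_xy| / sqrt(T_SMR); for b_zy = 0 the statistic is
    0, p = 1 and the se is undefined (NaN).
    """
    if se_zx <= 0 or se_zy <= 0:
        raise ValueError("standard errors must be positive")
    if b_zx == 0:
        raise ZeroDivisionError("b_zx = 0: the ratio estimate is undefined")
    z_zx = b_zx / se_zx
    z_zy = b_zy / se_zy
    b_xy = b_zy / b_zx
    denom = z_zx**2 + z_zy**2
    t_smr = (z_zx**2 * z_zy**2) / denom if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    se_xy = abs(b_xy) / math.sqrt(t_smr) if t_smr > 0 else float("nan")
    return float(b_xy), float(se_xy), p_smr


def select_heidi_snps(
    eqtl_records: pd.DataFrame,
    ld: pd.DataFrame,
    top_snp: str,
    p_eqtl_max: float = HEIDI_P_EQTL_MAX,
    r2_top_max: float = HEIDI_R2_TOP_MAX,
    m_max: int = HEIDI_MAX_SNPS,
    r2_min: float | None = None,
) -> list[str]:
    """SNPs contributing difference terms to HEIDI.

    Keeps cis SNPs (the top eQTL itself excluded) with eQTL p <=
    ``p_eqtl_max`` (weak instruments removed) and r^2 to the top SNP <=
    ``r2_top_max`` (near-perfect proxies carry no heterogeneity
    information). ``r2_min``, off by default, optionally drops SNPs nearly
    independent of the top eQTL. If more than ``m_max`` survive, the
    ``m_max`` smallest-p SNPs are kept.
    """
    cand = eqtl_records[eqtl_records["snp"] != top_snp]
    r_top = ld.loc[cand["snp"], top_snp].to_numpy(dtype=float)
    r2 = r_top**2
    mask = (cand["p_zx"].to_numpy() <= p_eqtl_max) & (r2 <= r2_top_max)
    if r2_min is not None:
        mask &= r2 >= r2_min
    kept = cand[mask]
    if len(kept) > m_max:
        kept = kept.nsmallest(m_max, "p_zx")
    return list(kept["snp"])


def _mixture_tail_mc(
    eigenvalues: np.ndarray,
    statistic: float,
    n_draws: int,
    rng: np.random.Generator,
    chi2_draws: np.ndarray | None = None,
) -> float:
    """P(sum_k lambda_k * chi2_1 >= statistic) by Monte Carlo.

    ``chi2_draws`` (n_draws x >= len(eigenvalues)) of iid chi-square(1)
    variables may be passed in to share draws across many genes.
    """
    m = len(eigenvalues)
    if chi2_draws is None:
        chi2_draws = rng.standard_normal((n_draws, m)) ** 2
    t_null = chi2_draws[:, :m] @ eigenvalues
    # add-one correction keeps the p-value in (0, 1]
    return float((1 + np.count_nonzero(t_null >= statistic)) / (len(t_null) + 1))


def heidi_test(
    records: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    top_snp: str,
    n_draws: int = 100_000,
    seed: int = 0,
    chi2_draws: np.ndarray | None = None,
) -> HeidiResult | None:
    """Heterogeneity test across the top eQTL and its selected cis SNPs.

    ``records`` must contain the top SNP and the HEIDI SNPs with columns
    snp, b_zx, se_zx, b_zy, se_zy; ``ld`` the signed correlation matrix of
    those SNPs (DataFrame indexed by snp id, or ndarray in record order).
    Returns None (HEIDI not computed) with fewer than HEIDI_MIN_SNPS
    difference terms or a singular difference covariance.
    """
    ids = list(records["snp"])
    m_total = len(ids)
    if m_total - 1 < HEIDI_MIN_SNPS:
        log.info("HEIDI not computed: only %d difference SNPs", m_total - 1)
        return None
    if isinstance(ld, pd.DataFrame):
        r = ld.loc[ids, ids].to_numpy(dtype=float)
    else:
        r = np.asarray(ld, dtype=float)
        if r.shape != (m_total, m_total):
            raise ValueError("LD matrix shape does not match the record count")

    b_zx = records["b_zx"].to_numpy(dtype=float)
    se_zx = records["se_zx"].to_numpy(dtype=float)
    b_zy = records["b_zy"].to_numpy(dtype=float)
    se_zy = records["se_zy"].to_numpy(dtype=float)
    if (b_zx == 0).any():
        raise ZeroDivisionError("b_zx = 0 for a HEIDI SNP: ratio undefined")
    t = ids.index(top_snp)

    b_xy = b_zy / b_zx
    # delta-method covariance of the per-SNP ratio estimates; the eQTL and
    # GWAS samples are independent so cross-study covariances vanish
    inv_zx = 1.0 / b_zx
    term_gwas = r * np.outer(se_zy * inv_zx, se_zy * inv_zx)
    term_eqtl = r * np.outer(b_zy * se_zx * inv_zx**2, b_zy * se_zx * inv_zx**2)
    v = term_gwas + term_eqtl

    others = [i for i in range(m_total) if i != t]
    d = b_xy[others] - b_xy[t]
    cov_d = (
        v[np.ix_(others, others)]
        - v[np.ix_(others, [t])]
        - v[np.ix_([t], others)]
        + v[t, t]
    )
    sd = np.sqrt(np.clip(np.diag(cov_d), 0.0, None))
    if (sd <= 0).any():
        log.warning("HEIDI not computed: zero-variance difference term")
        return None
    z_d = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    corr_d = (corr_d + corr_d.T) / 2.0

    statistic = float(np.sum(z_d**2))
    eig = np.clip(np.linalg.eigvalsh(corr_d), 0.0, None)
    if eig.sum() <= 0:
        log.warning("HEIDI not computed: singular difference covariance")
        return None

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E1D1]))
    p_mc = _mixture_tail_mc(eig, statistic, n_draws, rng, chi2_draws)
    # Satterthwaite: scale * chi2(df) matching the first two moments
    scale = float((eig**2).sum() / eig.sum())
    df = float(eig.sum() ** 2 / (eig**2).sum())
    p_satt = float(stats.chi2.sf(statistic / scale, df))
    return HeidiResult(p=p_mc, p_satterthwaite=p_satt, statistic=statistic, n_snps=len(others))


def smr_multiple_testing(p_smr, n_genes: int = 15):
    """Bonferroni flags for ``n_genes`` probes and one outcome.

    The reporting threshold is 0.05 / n_genes rounded to one significant
    digit (15 genes -> 0.003): p < threshold significant, threshold <= p
    < 0.05 suggestive, otherwise null. Returns (flags, threshold).
    """
    raw = 0.05 / n_genes
    exponent = math.floor(math.log10(raw))
    threshold = round(raw, -exponent)
    arr = np.atleast_1d(np.asarray(p_smr, dtype=float))
    flags = np.where(arr < threshold, "significant", np.where(arr < 0.05, "suggestive", "null"))
    if np.isscalar(p_smr) or getattr(p_smr, "ndim", 1) == 0:
        return str(flags[0]), threshold
    return list(flags), threshold


def run_smr(
    eqtl_gwas_records: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    gene_start: int,
    gene_end: int,
    gene: str = "",
    tissue: str = "",
    cis_window: int = 1_000_000,
    p_eqtl_top: float = 5e-8,
    heidi_seed: int = 0,
    heidi_draws: int = 100_000,
    heidi_r2_min: float | None = None,
) -> SmrResult | None:
    """SMR + HEIDI for one gene window of merged eQTL/GWAS records.

    ``eqtl_gwas_records`` columns: snp, pos, b_zx, se_zx, p_zx, b_zy,
    se_zy (one row per SNP; both studies aligned to the same effect
    allele). Returns None when the probe has no qualifying top cis-eQTL.
    """
    if isinstance(ld, np.ndarray):
        ids = list(eqtl_gwas_records["snp"])
        ld = pd.DataFrame(ld, index=ids, columns=ids)
    top = pick_top_cis_eqtl(eqtl_gwas_records, gene_start, gene_end, cis_window, p_eqtl_top)
    if top is None:
        return None
    b_xy, se_xy, p_smr = smr_test(top["b_zx"], top["se_zx"], top["b_zy"], top["se_zy"])
    heidi_ids = select_heidi_snps(
        eqtl_gwas_records, ld, top["snp"], r2_min=heidi_r2_min
    )
    subset = eqtl_gwas_records[eqtl_gwas_records["snp"].isin([top["snp"], *heidi_ids])]
    heidi = heidi_test(subset, ld, top["snp"], n_draws=heidi_draws, seed=heidi_seed)
    return SmrResult(
        gene=gene or str(top.get("gene", "")),
        tissue=tissue or str(top.get("tissue", "")),
        top_snp=str(top["snp"]),
        b_xy=b_xy,
        se_xy=se_xy,
        p_smr=p_smr,
        p_heidi=None if heidi is None else heidi.p,
        n_heidi_snps=0 if heidi is None else heidi.n_snps,
    )
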