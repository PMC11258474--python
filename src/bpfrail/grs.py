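"""Genetic risk scores and first-stage instrument diagnostics.

The weighted score follows
    GRS = (beta_1*SNP_1 + ... + beta_n*SNP_n) * n / sum_i(beta_i),
i.e. a beta-weighted allele count rescaled so it stays on the allele-count
scale; the unweighted score is the plain oriented allele count. Instrument
strength is summarised by the r^2 and F statistic of the simple regression
of (medication-corrected) BP on the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import InstrumentSet
from .synthdata import GenotypeMatrix

__all__ = [
    "ScoreVector",
    "FirstStageStats",
    "build_weighted_grs",
    "build_unweighted_grs",
    "first_stage_stats",
]

log = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    values: np.ndarray
    instruments: InstrumentSet
    weighting: str  # "weighted" | "unweighted"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("risk score contains non-finite values")


@dataclass
class FirstStageStats:
    r_squared: float
    f_stat: float
    n: int
    k: int = 1


def _oriented_dosages(genotypes: GenotypeMatrix, instruments: InstrumentSet) -> np.ndarray:
    """Dosages of each instrument's (BP-raising) effect allele.

    Where the instrument's effect allele is the genotype file's other allele
    the dosage is complemented as 2 - g. Missing dosages are imputed with
    the per-SNP mean.
    """
    sub = genotypes.subset(instruments.snp_ids)
    g = sub.dosages.astype(float).copy()
    nan = np.isnan(g)
    if nan.any():
        log.warning("mean-imputing %d missing dosages", int(nan.sum()))
        col_mean = np.nanmean(g, axis=0)
        g[nan] = np.take(col_mean, np.nonzero(nan)[1])
    geno_ea = sub.snps["effect_allele"].to_numpy()
    geno_oa = sub.snps["other_allele"].to_numpy()
    inst_ea = instruments.table["effect_allele"].to_numpy()
    inst_oa = instruments.table["other_allele"].to_numpy()
    same = (geno_ea == inst_ea) & (geno_oa == inst_oa)
    flipped = (geno_ea == inst_oa) & (geno_oa == inst_ea)
    if not (same | flipped).all():
        bad = sub.snps["snp"][~(same | flipped)].tolist()
        raise ValueError(f"allele mismatch between instruments and genotypes: {bad}")
    g[:, flipped] = 2.0 - g[:, flipped]
    return g


def build_weighted_grs(genotypes: GenotypeMatrix, instruments: InstrumentSet) -> ScoreVector:
    """GRS = (sum_i beta_i g_i) * n_snps / sum_i beta_i with oriented dosages."""
    if instruments.is_empty:
        raise ValueError(
            f"no instruments for {instruments.drug_class}/{instruments.exposure}: "
            "cannot build a risk score"
        )
    beta = instruments.weights
    beta_sum = beta.sum()
    if beta_sum == 0:
        raise ValueError("sum of instrument weights is zero; the score scale is undefined")
    g = _oriented_dosages(genotypes, instruments)
    values = (g @ beta) * len(beta) / beta_sum
    return ScoreVector(values=values, instruments=instruments, weighting="weighted")


def build_unweighted_grs(genotypes: GenotypeMatrix, instruments: InstrumentSet) -> ScoreVector:
    """Unweighted GRS: count of BP-raising alleles across instruments."""
    if instruments.is_empty:
        raise ValueError(
            f"no instruments for {instruments.drug_class}/{instruments.exposure}: "
            "cannot build a risk score"
        )
    g = _oriented_dosages(genotypes, instruments)
    return ScoreVector(values=g.sum(axis=1), instruments=instruments, weighting="unweighted")


def first_stage_stats(bp, grs: ScoreVector | np.ndarray) -> FirstStageStats:
    """r^2 and F from the simple linear regression of BP on the score.

    F = (r^2 / k) / ((1 - r^2) / (n - k - 1)) with k = 1: the score enters
    as a single instrument.
    """
    y = np.asarray(bp, dtype=float)
    x = grs.values if isinstance(grs, ScoreVector) else np.asarray(grs, dtype=float)
    n = len(y)
    if n <= 2:
        raise ValueError("need more than 2 observations")
    if x.std() == 0:
        raise ValueError("risk score has zero variance")
    r = np.corrcoef(x, y)[0, 1]
    r2 = min(float(r * r), 1.0)
    k = 1
    f = np.inf if r2 >= 1.0 else (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return FirstStageStats(r_squared=r2, f_stat=float(f), n=n, k=k)


def first_stage_pvalue(s: FirstStageStats) -> float:
    return float(stats.f.sf(s.f_stat, s.k, s.n - s.k - 1))
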