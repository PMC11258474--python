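"""Drug-target instrument selection from GWAS summary statistics.

Variants within +/-100 kb of a drug-target gene that are genome-wide
significant (p < 5e-8), common (MAF > 1%) and mutually independent at a
configurable LD threshold (r^2 < 0.4 within drug-gene regions; r^2 < 0.001
for the genome-wide score) proxy the BP-lowering action of that drug class.
Weights are oriented so every instrument's effect allele raises BP, which
keeps the risk-score formula sign-coherent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import GenotypeMatrix

__all__ = [
    "GeneRegion",
    "InstrumentSet",
    "DRUG_CLASSES",
    "select_candidates",
    "ld_clump",
    "orient_weights",
    "select_instruments",
    "ld_from_panel",
]

log = logging.getLogger(__name__)

DRUG_CLASSES = ["ACEi", "ARB", "BB", "CCB", "thiazide", "genome_wide"]

GWAS_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p"]


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene with its flanking instrument-search window (bp, 1-based)."""

    gene_symbol: str
    drug_class: str
    chrom: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start > end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start - self.flank, self.end + self.flank)


@dataclass
class InstrumentSet:
    """Selected and oriented instruments for one exposure and drug class.

    ``table`` columns: snp, effect_allele, other_allele, beta (> 0 after
    orientation, mmHg per effect allele), se, p, freq. An empty table is a
    legal state: a drug class with no proxy (e.g. ARB) flows through the
    pipeline without crashing.
    """

    exposure: str  # "SBP" or "DBP"
    drug_class: str
    table: pd.DataFrame
    p_max: float = 5e-8
    maf_min: float = 0.01
    r2_max: float = 0.4
    genes: list[str] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp"])

    @property
    def weights(self) -> np.ndarray:
        return self.table["beta"].to_numpy(dtype=float)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0


def select_candidates(
    gwas: pd.DataFrame,
    region: GeneRegion | None,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Filter a GWAS table to candidate instruments for one gene region.

    Keeps SNPs with position inside [start - flank, end + flank] on the
    region's chromosome (a ``None`` region, used for the genome-wide set,
    skips the positional filter), association p strictly below ``p_max``
    and MAF strictly above ``maf_min``. Inequalities are strict on both
    thresholds: p = 5e-8 and MAF = 1% are dropped.
    """
    df = gwas
    if region is not None:
        lo, hi = region.window
        df = df[(df["chrom"].astype(str) == str(region.chrom)) & df["pos"].between(lo, hi)]
    maf = np.minimum(df["freq"], 1.0 - df["freq"])
    out = df[(df["p"] < p_max) & (maf > maf_min)].copy()
    if out.empty:
        where = region.gene_symbol if region is not None else "genome-wide"
        log.warning("no candidate instruments for %s", where)
    return out.reset_index(drop=True)


def ld_from_panel(panel: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise dosage correlation r from a reference genotype panel."""
    g = panel.dosages
    sd = g.std(axis=0)
    if (sd == 0).any():
        monomorphic = panel.snps["snp"][sd == 0].tolist()
        raise ValueError(f"monomorphic SNPs in LD panel: {monomorphic}")
    r = np.corrcoef(g, rowvar=False)
    ids = panel.snps["snp"].tolist()
    return pd.DataFrame(r, index=ids, columns=ids)


def ld_clump(candidates: pd.DataFrame, ld: pd.DataFrame, r2_max: float = 0.4) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping.

    Candidates are sorted by GWAS p ascending (ties broken by position, then
    SNP id); each SNP is accepted iff its squared correlation with every
    already-accepted SNP is strictly below ``r2_max``. Output rows keep
    acceptance order. SNPs absent from the LD reference are dropped with a
    warning. The result is deterministic and invariant to input row order.
    """
    if candidates.empty:
        return candidates.copy()
    present = candidates["SNP"].isin(ld.index)
    if not present.all():
        log.warning("SNPs absent from LD reference dropped: %s", list(candidates["SNP"][~present]))
        candidates = candidates[present]
    ordered = candidates.sort_values(
        ["p", "pos", "SNP"], ascending=True, kind="mergesort"
    ).reset_index(drop=True)
    kept: list[int] = []
    kept_ids: list[str] = []
    for i, row in ordered.iterrows():
        snp = row["SNP"]
        if all(ld.loc[snp, k] ** 2 < r2_max for k in kept_ids):
            kept.append(i)
            kept_ids.append(snp)
    return ordered.iloc[kept].reset_index(drop=True)


def orient_weights(
    selected: pd.DataFrame,
    exposure: str,
    drug_class: str,
    genes: list[str] | None = None,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    r2_max: float = 0.4,
) -> InstrumentSet:
    """Re-express each instrument so its effect allele raises BP.

    Negative-beta SNPs have their allele labels swapped and the sign
    flipped (dosages are complemented as 2 - g downstream); zero-beta SNPs
    carry no information and are dropped with a warning.
    """
    df = selected.copy()
    zero = df["b"] == 0.0
    if zero.any():
        log.warning("zero-effect SNPs dropped during orientation: %s", list(df["SNP"][zero]))
        df = df[~zero]
    flip = df["b"] < 0
    a1 = df["A1"].where(~flip, df["A2"])
    a2 = df["A2"].where(~flip, df["A1"])
    freq = df["freq"].where(~flip, 1.0 - df["freq"])
    table = pd.DataFrame(
        {
            "snp": df["SNP"],
            "effect_allele": a1,
            "other_allele": a2,
            "beta": df["b"].abs(),
            "se": df["se"],
            "p": df["p"],
            "freq": freq,
        }
    ).reset_index(drop=True)
    return InstrumentSet(
        exposure=exposure,
        drug_class=drug_class,
        table=table,
        p_max=p_max,
        maf_min=maf_min,
        r2_max=r2_max,
        genes=list(genes or []),
    )


def select_instruments(
    gwas: pd.DataFrame,
    regions: list[GeneRegion],
    ld: pd.DataFrame,
    exposure: str,
    drug_class: str,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    r2_max: float = 0.4,
) -> InstrumentSet:
    """Full selection for one drug class: per-gene windows, pooled candidate
    list, LD clump across the pooled list, orientation.

    ``regions`` may be empty (a class with no proxy); for the genome-wide
    set pass a single ``None``-free list and ``drug_class="genome_wide"``
    via :func:`select_candidates` with ``region=None`` semantics — here,
    an empty ``regions`` list together with ``drug_class="genome_wide"``
    selects over the whole GWAS.
    """
    if drug_class == "genome_wide":
        pooled = select_candidates(gwas, None, p_max=p_max, maf_min=maf_min)
    else:
        parts = [select_candidates(gwas, r, p_max=p_max, maf_min=maf_min) for r in regions]
        pooled = (
            pd.concat(parts, ignore_index=True).drop_duplicates(subset="SNP")
            if parts
            else gwas.iloc[0:0].copy()
        )
    clumped = ld_clump(pooled, ld, r2_max=r2_max)
    return orient_weights(
        clumped,
        exposure=exposure,
        drug_class=drug_class,
        genes=[r.gene_symbol for r in regions],
        p_max=p_max,
        maf_min=maf_min,
        r2_max=r2_max,
    )
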