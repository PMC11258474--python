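"""End-to-end orchestration: synthesize -> instruments -> GRS -> MR -> SMR.

`run_pipeline` executes the whole drug-target MR study on synthetic data:
a discovery cohort provides the BP GWAS summary statistics, a reference
panel provides LD, and an analysis cohort provides individual-level
genotypes, BP, covariates and deficit items. Per drug class and exposure
the pipeline selects instruments, builds the risk score, runs the
two-stage MR, and finally runs SMR/HEIDI over simulated cis-eQTL windows.
All randomness descends from a single root seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .frailty import apply_missingness_filter, compute_fi, default_cardiometabolic_items
from .grs import build_unweighted_grs, build_weighted_grs
from .instruments import DRUG_CLASSES, GeneRegion, ld_from_panel, select_instruments
from .mr2sps import DEFAULT_COVARIATES, adjust_bp, run_two_stage_mr
from .smr import run_smr, smr_multiple_testing
from .synthdata import (
    GenotypeMatrix,
    SummaryScenarioConfig,
    default_config,
    gwas_from_cohort,
    simulate_cohort,
    simulate_genotypes,
    simulate_summary_scenario,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "default_gene_map",
    "run_pipeline",
    "descriptives",
    "round_half_up",
]

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.45 -> 2.5 at 1 digit), as used for the
    percentage tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def default_gene_map() -> list[GeneRegion]:
    """Illustrative drug-class -> target-gene map for the synthetic study.

    ACEi: ACE; BB: ADRB1, KCNH2; CCB: CACNA1C, CACNB2; thiazide: SLC12A3.
    ARB carries no proxy gene. Coordinates are aligned with the default
    synthetic genotype blocks; a real analysis supplies its own map.
    """
    return [
        GeneRegion("ACE", "ACEi", "17", 63_477_000, 63_498_000),
        GeneRegion("ADRB1", "BB", "10", 114_043_000, 114_047_000),
        GeneRegion("KCNH2", "BB", "7", 150_641_000, 150_675_000),
        GeneRegion("CACNA1C", "CCB", "12", 2_160_000, 2_800_000),
        GeneRegion("CACNB2", "CCB", "10", 18_420_000, 18_540_000),
        GeneRegion("SLC12A3", "thiazide", "16", 56_865_000, 56_915_000),
    ]


DEFAULT_SMR_SCENARIOS: dict[str, str] = {
    # one causal gene (the headline drug-target signal), one linkage decoy,
    # the rest null
    "KCNH2": "causal",
    "CACNB2": "linkage",
    "ACE": "null",
    "ADRB1": "null",
    "CACNA1C": "null",
    "SLC12A3": "null",
}


@dataclass
class RunConfig:
    """Thresholds, sample sizes and switches for a full pipeline run."""

    seed: int = 0
    n_individuals: int = 20_000
    n_discovery: int = 150_000
    n_reference: int = 10_000

    p_max: float = 5e-8
    maf_min: float = 0.01
    r2_max: float = 0.4  # within drug-gene regions
    r2_genome_wide: float = 0.001
    flank: int = 100_000

    cis_window: int = 1_000_000
    heidi_draws: int = 100_000
    smr_n_genes: int = 15  # probes entering the Bonferroni correction

    weighting: str = "weighted"  # or "unweighted"
    max_missing_items: int | None = None  # e.g. 10 for the missingness rule
    age_min: float | None = None  # e.g. 60.0 for the older-age subgroup
    modified_fi: bool = False  # exclude cardiometabolic items

    smr_scenarios: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SMR_SCENARIOS))

    def validate(self) -> None:
        for name, lo, hi in [
            ("p_max", 0.0, 1.0),
            ("maf_min", 0.0, 0.5),
            ("r2_max", 0.0, 1.0),
            ("r2_genome_wide", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.flank < 0 or self.cis_window < 0:
            raise ValueError("flank and cis_window must be >= 0")
        if self.weighting not in ("weighted", "unweighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class RunReport:
    mr_table: pd.DataFrame
    smr_table: pd.DataFrame
    descriptives: dict[str, pd.DataFrame]
    diagnostics: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mr_table.to_csv(out / "mr_estimates.tsv", sep="\t", index=False, float_format="%.6g")
        self.smr_table.to_csv(out / "smr_results.tsv", sep="\t", index=False, float_format="%.6g")
        for name, table in self.descriptives.items():
            table.to_csv(out / f"descriptives_{name}.tsv", sep="\t", float_format="%.6g")
        io.write_json(self.diagnostics, out / "diagnostics.json")


def descriptives(phenotypes: pd.DataFrame, category: pd.Series) -> dict[str, pd.DataFrame]:
    """Counts and percentages by frailty category, Table-1 style.

    Returns an ``overall`` table (n and % per category, percentages to one
    decimal, half-up) and per-stratum tables for sex, smoking, alcohol,
    deprivation and BMI categories (column percentages within each frailty
    category).
    """
    cat = pd.Series(category).reset_index(drop=True)
    phen = phenotypes.reset_index(drop=True)
    counts = cat.value_counts().reindex(["non_frail", "pre_frail", "frail"]).fillna(0).astype(int)
    total = int(counts.sum())
    overall = pd.DataFrame(
        {
            "n": counts,
            "pct": [round_half_up(100.0 * c / total, 1) if total else 0.0 for c in counts],
        }
    )
    tables = {"overall": overall}

    strata = {
        "sex": phen["sex"],
        "smoking": phen["smoking"],
        "alcohol": phen["alcohol"],
        "deprivation": phen["deprivation"],
    }
    if "bmi" in phen.columns:
        strata["bmi_category"] = pd.cut(
            phen["bmi"],
            bins=[-np.inf, 18, 25, 30, np.inf],
            labels=["<18", "18-25", "25-30", ">=30"],
        )
    for name, col in strata.items():
        if name not in phen.columns and name != "bmi_category":
            continue
        tab = pd.crosstab(col, cat)
        pct = tab.div(tab.sum(axis=0), axis=1) * 100.0
        pct = pct.apply(lambda s: s.map(lambda v: round_half_up(v, 1)))
        merged = pd.concat({"n": tab, "pct": pct}, axis=1)
        tables[name] = merged
    return tables


def _class_regions(regions: list[GeneRegion], drug_class: str, flank: int) -> list[GeneRegion]:
    return [replace(r, flank=flank) for r in regions if r.drug_class == drug_class]


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full synthetic drug-target MR study.

    Stages: (1) discovery GWAS, (2) LD reference panel, (3) analysis
    cohort, (4) frailty index, (5) instruments + GRS + two-stage MR per
    drug class and exposure, (6) SMR/HEIDI over simulated cis windows,
    (7) descriptives and report. Deterministic given ``config.seed``.
    """
    config.validate()
    seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9199]))
    child = lambda: int(seed_rng.integers(2**31))  # noqa: E731

    base = default_config(seed=config.seed, n_individuals=config.n_individuals)

    log.info("stage 1/7: discovery GWAS (n=%d)", config.n_discovery)
    disc_cfg = replace(base, n_individuals=config.n_discovery, seed=child())
    disc_geno = simulate_genotypes(disc_cfg)
    disc_cohort = simulate_cohort(disc_geno, disc_cfg)
    dphen = disc_cohort.phenotypes
    gwas = {}
    for exposure, cols in [("SBP", ["sbp_reading1", "sbp_reading2"]), ("DBP", ["dbp_reading1", "dbp_reading2"])]:
        adj = adjust_bp(dphen[cols], dphen["on_bp_med"], exposure=exposure)
        gwas[exposure] = gwas_from_cohort(disc_geno, adj.values.to_numpy())

    log.info("stage 2/7: LD reference panel (n=%d)", config.n_reference)
    panel_cfg = replace(base, n_individuals=config.n_reference, seed=child())
    panel = simulate_genotypes(panel_cfg)
    ld = ld_from_panel(panel)

    log.info("stage 3/7: analysis cohort (n=%d)", config.n_individuals)
    cohort_cfg = replace(base, seed=child())
    geno = simulate_genotypes(cohort_cfg)
    cohort = simulate_cohort(geno, cohort_cfg)
    phen = cohort.phenotypes

    log.info("stage 4/7: frailty index")
    exclude = default_cardiometabolic_items(cohort.deficits.columns) if config.modified_fi else None
    fi = compute_fi(cohort.deficits, exclude_items=exclude)
    keep = pd.Series(True, index=phen.index)
    n_excluded = {}
    if config.max_missing_items is not None:
        mask = apply_missingness_filter(cohort.deficits, config.max_missing_items)
        keep &= mask.reset_index(drop=True).to_numpy()
        n_excluded["missing_items"] = int((~mask).sum())
    if config.age_min is not None:
        age_ok = phen["age"] >= config.age_min
        keep &= age_ok
        n_excluded["age"] = int((~age_ok).sum())
    undefined = fi.table["fi"].isna().reset_index(drop=True)
    keep &= ~undefined.to_numpy()
    n_excluded["undefined_fi"] = int(undefined.sum())

    phen = phen[keep.to_numpy()].reset_index(drop=True)
    category = fi.table["category"].reset_index(drop=True)[keep.to_numpy()].reset_index(drop=True)
    geno_kept = GenotypeMatrix(geno.dosages[keep.to_numpy()], geno.snps)

    covariates = phen[list(DEFAULT_COVARIATES)]
    adj_bp = {
        "SBP": adjust_bp(phen[["sbp_reading1", "sbp_reading2"]], phen["on_bp_med"], "SBP"),
        "DBP": adjust_bp(phen[["dbp_reading1", "dbp_reading2"]], phen["on_bp_med"], "DBP"),
    }

    log.info("stage 5/7: instruments, risk scores, two-stage MR")
    regions = default_gene_map()
    mr_rows: list[dict] = []
    diag: dict = {"exclusions": n_excluded, "first_stage": {}}
    for exposure in ("SBP", "DBP"):
        unit = 10.0 if exposure == "SBP" else 5.0
        for drug_class in DRUG_CLASSES:
            r2 = config.r2_genome_wide if drug_class == "genome_wide" else config.r2_max
            inst = select_instruments(
                gwas[exposure],
                _class_regions(regions, drug_class, config.flank),
                ld,
                exposure=exposure,
                drug_class=drug_class,
                p_max=config.p_max,
                maf_min=config.maf_min,
                r2_max=r2,
            )
            if inst.is_empty:
                for contrast in ("pre_frail_vs_non", "frail_vs_non"):
                    mr_rows.append(
                        {
                            "exposure": exposure,
                            "drug_class": drug_class,
                            "contrast": contrast,
                            "n_snps": 0,
                            "rrr": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "unit_mmhg_decrease": unit,
                            "flag": "",
                            "note": "no proxy available",
                        }
                    )
                continue
            builder = build_weighted_grs if config.weighting == "weighted" else build_unweighted_grs
            score = builder(geno_kept, inst)
            estimates, fs, ss = run_two_stage_mr(
                adj_bp[exposure].values,
                score.values,
                category,
                covariates,
                exposure=exposure,
                drug_class=drug_class,
                unit=unit,
            )
            diag["first_stage"][f"{exposure}:{drug_class}"] = {
                "r_squared": fs.r_squared,
                "f_stat": fs.f_stat,
                "n": fs.n,
                "n_snps": inst.n_snps,
            }
            for est in estimates:
                mr_rows.append(
                    {
                        "exposure": est.exposure,
                        "drug_class": est.drug_class,
                        "contrast": est.contrast,
                        "n_snps": inst.n_snps,
                        "rrr": est.rrr,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "p": est.p,
                        "unit_mmhg_decrease": est.unit,
                        "flag": est.flag,
                        "note": "" if est.converged else "non-convergence",
                    }
                )
    mr_table = pd.DataFrame(mr_rows)

    log.info("stage 6/7: SMR + HEIDI")
    gene_lookup = {r.gene_symbol: r for r in regions}
    smr_rows: list[dict] = []
    for gene, scenario in config.smr_scenarios.items():
        region = gene_lookup.get(gene)
        sc_cfg = SummaryScenarioConfig(
            scenario=scenario,
            gene=gene,
            chrom=region.chrom if region else "1",
            gene_start=region.start if region else 1_000_000,
            gene_end=region.end if region else 1_050_000,
            seed=child(),
        )
        sc = simulate_summary_scenario(sc_cfg)
        res = run_smr(
            sc.records,
            sc.ld,
            sc.gene_start,
            sc.gene_end,
            gene=gene,
            tissue=sc_cfg.tissue,
            cis_window=config.cis_window,
            heidi_seed=child(),
            heidi_draws=config.heidi_draws,
        )
        if res is None:
            smr_rows.append({"gene": gene, "scenario": scenario, "note": "no qualifying cis-eQTL"})
            continue
        smr_rows.append(
            {
                "gene": gene,
                "tissue": res.tissue,
                "scenario": scenario,
                "top_snp": res.top_snp,
                "b_smr": res.b_xy,
                "se_smr": res.se_xy,
                "p_smr": res.p_smr,
                "p_heidi": res.p_heidi,
                "n_heidi_snps": res.n_heidi_snps,
                "note": "",
            }
        )
    smr_table = pd.DataFrame(smr_rows)
    if "p_smr" in smr_table.columns:
        flags, threshold = smr_multiple_testing(
            smr_table["p_smr"].fillna(1.0).to_numpy(), n_genes=config.smr_n_genes
        )
        smr_table["flag"] = flags
        diag["smr_threshold"] = threshold

    log.info("stage 7/7: descriptives and report")
    desc = descriptives(phen, category)
    diag["n_analysis"] = int(len(phen))
    diag["seed"] = config.seed

    report = RunReport(mr_table=mr_table, smr_table=smr_table, descriptives=desc, diagnostics=diag)
    if out_dir is not None:
        report.write(out_dir)
        config.to_yaml(Path(out_dir) / "run_config.yaml")
    return report
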