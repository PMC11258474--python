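#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, under results/data/: the analysis cohort (genotype dosages,
phenotypes/covariates, 49-item deficit table), the discovery-GWAS summary
statistics for systolic and diastolic BP, and the LD reference matrix from
an independent genotype panel. Sizes: 20,000 analysis individuals, 150,000
discovery individuals, 10,000 panel individuals, 40 SNPs in 7 LD blocks.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from bpfrail import io
from bpfrail.instruments import ld_from_panel
from bpfrail.mr2sps import adjust_bp
from bpfrail.pipeline import default_gene_map
from bpfrail.synthdata import default_config, gwas_from_cohort, simulate_cohort, simulate_genotypes

SEED = 20240500
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = default_config(seed=SEED, n_individuals=20_000)

    print("discovery GWAS cohort (n=150,000) ...")
    disc_cfg = replace(base, n_individuals=150_000, seed=SEED + 1)
    disc_geno = simulate_genotypes(disc_cfg)
    disc_cohort = simulate_cohort(disc_geno, disc_cfg)
    phen = disc_cohort.phenotypes
    for exposure, cols in [("sbp", ["sbp_reading1", "sbp_reading2"]), ("dbp", ["dbp_reading1", "dbp_reading2"])]:
        adj = adjust_bp(phen[cols], phen["on_bp_med"], exposure.upper())
        gwas = gwas_from_cohort(disc_geno, adj.values.to_numpy())
        io.write_gwas_ma(gwas, OUT / f"gwas_{exposure}.ma")
        n_hits = int((gwas["p"] < 5e-8).sum())
        print(f"  {exposure.upper()}: {n_hits}/{len(gwas)} genome-wide significant SNPs")

    print("LD reference panel (n=10,000) ...")
    panel_cfg = replace(base, n_individuals=10_000, seed=SEED + 2)
    panel = simulate_genotypes(panel_cfg)
    ld = ld_from_panel(panel)
    io.write_ld_tsv(ld, OUT / "ld_reference.tsv")

    print("analysis cohort (n=20,000) ...")
    cohort_cfg = replace(base, seed=SEED + 3)
    geno = simulate_genotypes(cohort_cfg)
    cohort = simulate_cohort(geno, cohort_cfg)
    io.write_dosage_tsv(geno, OUT / "dosages.tsv", OUT / "snps.tsv")
    io.write_phenotypes(cohort, OUT / "phenotypes.tsv")
    io.write_deficits(cohort, OUT / "deficits.tsv")
    io.write_gene_regions(default_gene_map(), OUT / "gene_regions.tsv")

    on_med = cohort.phenotypes["on_bp_med"].mean()
    print(f"  {geno.n_snps} SNPs; {100 * on_med:.1f}% on antihypertensive medication")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
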