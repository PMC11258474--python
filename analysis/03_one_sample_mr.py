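#!/usr/bin/env python
"""One-sample drug-target MR of BP on frailty status.

Reads the synthetic inputs from results/data/, selects instruments per
antihypertensive drug class (ACEi, ARB, BB, CCB, thiazide) and genome-wide,
builds weighted risk scores, and runs the two-stage predictor-substitution
MR with the full covariate set. Estimates are RRRs per 10-mmHg (SBP) or
5-mmHg (DBP) genetically predicted BP decrease. Writes
results/mr/mr_estimates.tsv and first-stage diagnostics.
"""

from pathlib import Path

import pandas as pd

from bpfrail import io
from bpfrail.frailty import compute_fi
from bpfrail.grs import build_weighted_grs
from bpfrail.instruments import DRUG_CLASSES, select_instruments
from bpfrail.mr2sps import DEFAULT_COVARIATES, adjust_bp, run_two_stage_mr

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    geno = io.read_dosage_tsv(data / "dosages.tsv", data / "snps.tsv")
    phen = io.read_phenotypes(data / "phenotypes.tsv")
    deficits = io.read_deficits(data / "deficits.tsv")
    ld = io.read_ld_tsv(data / "ld_reference.tsv")
    regions = io.read_gene_regions(data / "gene_regions.tsv")
    gwas = {
        "SBP": io.read_gwas_ma(data / "gwas_sbp.ma"),
        "DBP": io.read_gwas_ma(data / "gwas_dbp.ma"),
    }

    category = compute_fi(deficits).table["category"].reset_index(drop=True)
    covariates = phen[list(DEFAULT_COVARIATES)]
    rows, diags = [], []
    for exposure in ("SBP", "DBP"):
        cols = [f"{exposure.lower()}_reading1", f"{exposure.lower()}_reading2"]
        adj = adjust_bp(phen[cols], phen["on_bp_med"], exposure)
        unit = 10.0 if exposure == "SBP" else 5.0
        for drug_class in DRUG_CLASSES:
            class_regions = [r for r in regions if r.drug_class == drug_class]
            r2 = 0.001 if drug_class == "genome_wide" else 0.4
            inst = select_instruments(
                gwas[exposure], class_regions, ld,
                exposure=exposure, drug_class=drug_class, r2_max=r2,
            )
            if inst.is_empty:
                print(f"{exposure} {drug_class}: no proxy available")
                for contrast in ("pre_frail_vs_non", "frail_vs_non"):
                    rows.append({"exposure": exposure, "drug_class": drug_class,
                                 "contrast": contrast, "note": "no proxy available"})
                continue
            score = build_weighted_grs(geno, inst)
            estimates, fs, _ = run_two_stage_mr(
                adj.values, score.values, category, covariates,
                exposure=exposure, drug_class=drug_class, unit=unit,
            )
            diags.append({"exposure": exposure, "drug_class": drug_class,
                          "n_snps": inst.n_snps, "r_squared": fs.r_squared,
                          "f_stat": fs.f_stat, "n": fs.n})
            for est in estimates:
                rows.append({
                    "exposure": exposure, "drug_class": drug_class,
                    "contrast": est.contrast, "n_snps": inst.n_snps,
                    "rrr": est.rrr, "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "p": est.p, "flag": est.flag, "note": "",
                })
            pre = estimates[0]
            print(f"{exposure} {drug_class} ({inst.n_snps} SNPs, F={fs.f_stat:.0f}): "
                  f"pre-frail RRR {pre.rrr:.2f} ({pre.ci_low:.2f}-{pre.ci_high:.2f}), "
                  f"p={pre.p:.3g} [{pre.flag}]")

    out = ROOT / "mr"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "mr_estimates.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(diags).to_csv(out / "first_stage.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"\nestimates written to {out}")


if __name__ == "__main__":
    main()
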