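"""Plain-text readers and writers for the pipeline's interchange formats.

Everything is TSV (or minimal VCF for dosages) so that inputs and outputs
stay inspectable: dosage matrices (rows = individuals, header = SNP ids,
with a side-car SNP metadata table), phenotype/covariate tables, deficit
tables (blank = missing), GWAS summary statistics in .ma-style columns
(SNP, A1, A2, freq, b, se, p, N), eQTL summary tables, LD correlation
matrices, and gene-region/drug-class maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import GeneRegion, InstrumentSet
from .synthdata import CohortPhenotypes, GenotypeMatrix

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf_dosages",
    "write_phenotypes",
    "read_phenotypes",
    "write_deficits",
    "read_deficits",
    "write_gwas_ma",
    "read_gwas_ma",
    "write_eqtl_tsv",
    "read_eqtl_tsv",
    "write_ld_tsv",
    "read_ld_tsv",
    "read_gene_regions",
    "write_gene_regions",
    "write_instruments",
    "read_instruments",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, meta_path=None) -> None:
    ids = [f"id{i:06d}" for i in range(genotypes.n_individuals)]
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snps["snp"], index=ids)
    df.index.name = "person_id"
    df.to_csv(dosage_path, sep="\t", float_format=_FLOAT_FMT)
    if meta_path is not None:
        genotypes.snps.to_csv(meta_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_dosage_tsv(dosage_path, meta_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="person_id")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    return GenotypeMatrix(dosages=df.to_numpy(dtype=float), snps=meta)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal uncompressed VCF with a DS (dosage) FORMAT field."""
    n = genotypes.n_individuals
    samples = [f"id{i:06d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, row in genotypes.snps.iterrows():
            ds = "\t".join(f"{v:g}" for v in genotypes.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Read DS dosages from a VCF. Uses cyvcf2 when available, else a plain
    text parse (sufficient for the minimal VCFs this package writes)."""
    try:
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        rows, meta = [], []
        for var in vcf:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
            rows.append(ds)
            meta.append(
                {
                    "snp": var.ID,
                    "chrom": str(var.CHROM),
                    "pos": var.POS,
                    "effect_allele": var.ALT[0],
                    "other_allele": var.REF,
                }
            )
    except ImportError:
        rows, meta = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom, pos, vid, ref, alt = parts[:5]
                rows.append(np.array(parts[9:], dtype=float))
                meta.append(
                    {
                        "snp": vid,
                        "chrom": chrom,
                        "pos": int(pos),
                        "effect_allele": alt,
                        "other_allele": ref,
                    }
                )
    dosages = np.column_stack(rows) if rows else np.empty((0, 0))
    snps = pd.DataFrame(meta)
    freq = dosages.mean(axis=0) / 2.0 if len(rows) else np.array([])
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dosages=dosages, snps=snps)


def write_phenotypes(cohort: CohortPhenotypes, path) -> None:
    cohort.phenotypes.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_deficits(cohort: CohortPhenotypes, path) -> None:
    # blank cell = missing answer
    cohort.deficits.to_csv(path, sep="\t", na_rep="", float_format="%g")


def read_deficits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gwas_ma(gwas: pd.DataFrame, path, keep_positions: bool = True) -> None:
    cols = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
    if keep_positions:
        cols = ["SNP", "chrom", "pos", "A1", "A2", "freq", "b", "se", "p", "N"]
    gwas[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gwas_ma(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_eqtl_tsv(records: pd.DataFrame, path) -> None:
    cols = [c for c in ["gene", "tissue", "snp", "chrom", "pos", "a1", "a2",
                        "b_zx", "se_zx", "p_zx", "b_zy", "se_zy", "p_zy"] if c in records.columns]
    records[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_eqtl_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_ld_tsv(ld, path, snp_ids=None) -> None:
    if not isinstance(ld, pd.DataFrame):
        ld = pd.DataFrame(ld, index=snp_ids, columns=snp_ids)
    ld.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_ld_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_regions(regions: list[GeneRegion], path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene_symbol,
                "drug_class": r.drug_class,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "flank": r.flank,
            }
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_regions(path) -> list[GeneRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneRegion(
            gene_symbol=row["gene"],
            drug_class=row["drug_class"],
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            flank=int(row.get("flank", 100_000)),
        )
        for _, row in df.iterrows()
    ]


def write_instruments(instruments: InstrumentSet, path) -> None:
    instruments.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_instruments(path, exposure: str, drug_class: str, **kwargs) -> InstrumentSet:
    table = pd.read_csv(path, sep="\t")
    return InstrumentSet(exposure=exposure, drug_class=drug_class, table=table, **kwargs)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
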