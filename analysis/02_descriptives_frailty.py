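#!/usr/bin/env python
"""Frailty index and cohort descriptives.

Reads the analysis cohort from results/data/, computes the 49-item frailty
index and its categories, and writes Table-1-style descriptive tables
(counts and percentages by frailty status) under results/descriptives/.
"""

from pathlib import Path

from bpfrail import io
from bpfrail.frailty import compute_fi
from bpfrail.pipeline import descriptives

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    deficits = io.read_deficits(ROOT / "data" / "deficits.tsv")
    phen = io.read_phenotypes(ROOT / "data" / "phenotypes.tsv")
    fi = compute_fi(deficits)

    out = ROOT / "descriptives"
    out.mkdir(parents=True, exist_ok=True)
    fi.table.to_csv(out / "frailty_index.tsv", sep="\t", float_format="%.6g")

    tables = descriptives(phen, fi.table["category"].reset_index(drop=True))
    for name, table in tables.items():
        table.to_csv(out / f"table1_{name}.tsv", sep="\t", float_format="%.6g")

    overall = tables["overall"]
    print("frailty status distribution:")
    print(overall.to_string())
    print(f"\nmean FI {fi.fi.mean():.3f}; tables written to {out}")


if __name__ == "__main__":
    main()
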