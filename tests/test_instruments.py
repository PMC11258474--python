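"""Instrument selection: windows, thresholds, greedy LD clumping, orientation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bpfrail.instruments import (
    GeneRegion,
    ld_clump,
    ld_from_panel,
    orient_weights,
    select_candidates,
    select_instruments,
)

REGION = GeneRegion("GENE", "BB", "1", 1_000_000, 1_050_000)


def clump_oracle(p_order, pos, r, r2_max):
    """Exhaustive reference for greedy clumping: the lexicographically first
    (in p-rank order) maximal admissible subset, found by enumerating all
    2^m subsets with bitmask adjacency."""
    m = len(p_order)
    compat = []
    for i in range(m):
        bits = 0
        for j in range(m):
            if i == j or r[pos[p_order[i]], pos[p_order[j]]] ** 2 < r2_max:
                bits |= 1 << j
        compat.append(bits)
    best_key, best_set = None, None
    for mask in range(1, 2**m):
        members = [i for i in range(m) if mask >> i & 1]
        if any(mask & ~compat[i] & ~(1 << i) for i in members):
            continue  # not admissible
        if any(
            not (mask >> s & 1) and (mask & ~compat[s]) == 0 for s in range(m)
        ):
            continue  # not maximal: some outside SNP could still be added
        key = tuple(members)
        if best_key is None or key < best_key:
            best_key, best_set = key, {p_order[i] for i in members}
    return best_set


def _gwas(rows):
    df = pd.DataFrame(rows, columns=["SNP", "chrom", "pos", "A1", "A2", "freq", "b", "se", "p"])
    df["N"] = 100_000
    return df


def test_window_boundary_inclusive_at_flank():
    gwas = _gwas(
        [
            ["in_edge", "1", 900_000, "A", "G", 0.3, 0.5, 0.05, 1e-10],
            ["out_edge", "1", 899_999, "A", "G", 0.3, 0.5, 0.05, 1e-10],
            ["in_right", "1", 1_150_000, "A", "G", 0.3, 0.5, 0.05, 1e-10],
            ["out_right", "1", 1_150_001, "A", "G", 0.3, 0.5, 0.05, 1e-10],
            ["other_chrom", "2", 1_000_000, "A", "G", 0.3, 0.5, 0.05, 1e-10],
        ]
    )
    kept = set(select_candidates(gwas, REGION)["SNP"])
    assert kept == {"in_edge", "in_right"}


@pytest.mark.parametrize(
    "p, freq, kept",
    [
        (4.9e-8, 0.3, True),
        (5e-8, 0.3, False),  # strict inequality on p
        (1e-9, 0.011, True),
        (1e-9, 0.01, False),  # strict inequality on MAF
        (1e-9, 0.989, True),  # MAF computed from the minor side
        (1e-9, 0.995, False),
    ],
)
def test_significance_and_maf_thresholds_strict(p, freq, kept):
    gwas = _gwas([["s1", "1", 1_000_000, "A", "G", freq, 0.5, 0.05, p]])
    assert (len(select_candidates(gwas, REGION)) == 1) == kept


def test_genome_wide_ignores_region():
    gwas = _gwas([["far", "9", 99_000_000, "A", "G", 0.3, 0.5, 0.05, 1e-10]])
    assert len(select_candidates(gwas, None)) == 1


def test_empty_selection_is_graceful():
    gwas = _gwas([["s1", "1", 1_000_000, "A", "G", 0.3, 0.5, 0.05, 0.5]])
    out = select_candidates(gwas, REGION)
    assert out.empty


class TestClump:
    @staticmethod
    def _ld(ids, r):
        return pd.DataFrame(r, index=ids, columns=ids)

    def test_perfect_ld_keeps_smaller_p(self):
        gwas = _gwas(
            [
                ["a", "1", 1_000_000, "A", "G", 0.3, 0.5, 0.05, 1e-12],
                ["b", "1", 1_001_000, "A", "G", 0.3, 0.5, 0.05, 1e-9],
            ]
        )
        ld = self._ld(["a", "b"], [[1.0, 1.0], [1.0, 1.0]])
        assert list(ld_clump(gwas, ld)["SNP"]) == ["a"]

    def test_independent_snps_all_kept(self):
        gwas = _gwas(
            [[f"s{i}", "1", 1_000_000 + i, "A", "G", 0.3, 0.5, 0.05, 1e-9] for i in range(5)]
        )
        ld = self._ld([f"s{i}" for i in range(5)], np.eye(5))
        assert len(ld_clump(gwas, ld)) == 5

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(8)]
        r = np.clip((rng.uniform(-1, 1, (8, 8)) + np.eye(8) * 2) / 2, -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        gwas = _gwas(
            [[ids[i], "1", 1_000_000 + i, "A", "G", 0.3, 0.5, 0.05, float(rng.uniform(1e-12, 1e-8))] for i in range(8)]
        )
        ld = self._ld(ids, r)
        base = list(ld_clump(gwas, ld)["SNP"])
        shuffled = gwas.sample(frac=1.0, random_state=4)
        assert list(ld_clump(shuffled, ld)["SNP"]) == base

    def test_snp_missing_from_reference_dropped(self):
        gwas = _gwas(
            [
                ["a", "1", 1_000_000, "A", "G", 0.3, 0.5, 0.05, 1e-12],
                ["ghost", "1", 1_001_000, "A", "G", 0.3, 0.5, 0.05, 1e-13],
            ]
        )
        ld = self._ld(["a"], [[1.0]])
        assert list(ld_clump(gwas, ld)["SNP"]) == ["a"]

    def test_threshold_nesting_and_validity(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(10)]
        z = rng.normal(size=(300, 10)) @ rng.normal(size=(10, 10))
        r = np.corrcoef(z, rowvar=False)
        ld = self._ld(ids, r)
        gwas = _gwas(
            [[ids[i], "1", 1_000_000 + i, "A", "G", 0.3, 0.5, 0.05, float(rng.uniform(1e-12, 1e-8))] for i in range(10)]
        )
        counts = []
        for r2 in (0.4, 0.1, 0.01):
            kept = ld_clump(gwas, ld, r2_max=r2)
            counts.append(len(kept))
            for x, y in itertools.combinations(kept["SNP"], 2):
                assert ld.loc[x, y] ** 2 < r2
        assert counts[0] >= counts[1] >= counts[2]

    def test_matches_exhaustive_oracle_on_small_windows(self):
        """Greedy output equals the lexicographically-first maximal admissible
        subset in p-order, verified by enumeration over 12-SNP windows."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            m = 12
            ids = [f"s{i}" for i in range(m)]
            z = rng.normal(size=(60, m)) @ rng.normal(size=(m, m))
            r = np.corrcoef(z, rowvar=False)
            ld = self._ld(ids, r)
            gwas = _gwas(
                [[ids[i], "1", 1_000_000 + i, "A", "G", 0.3, 0.5, 0.05, float(rng.uniform(1e-12, 1e-8))] for i in range(m)]
            )
            got = set(ld_clump(gwas, ld, r2_max=0.4)["SNP"])
            order = gwas.sort_values(["p", "pos", "SNP"])["SNP"].tolist()
            best = clump_oracle(order, {s: i for i, s in enumerate(ids)}, r, 0.4)
            assert got == best, f"seed {seed}"


class TestOrientation:
    def test_negative_beta_flipped(self):
        sel = _gwas([["s1", "1", 1_000_000, "A", "G", 0.3, -0.3, 0.05, 1e-10]])
        inst = orient_weights(sel, "SBP", "BB")
        row = inst.table.iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("G", "A")
        assert row["beta"] == pytest.approx(0.3)
        assert row["freq"] == pytest.approx(0.7)

    def test_positive_beta_unchanged(self):
        sel = _gwas([["s1", "1", 1_000_000, "A", "G", 0.3, 0.5, 0.05, 1e-10]])
        row = orient_weights(sel, "SBP", "BB").table.iloc[0]
        assert (row["effect_allele"], row["other_allele"]) == ("A", "G")
        assert row["beta"] == pytest.approx(0.5)

    def test_zero_beta_dropped(self):
        sel = _gwas(
            [
                ["s1", "1", 1_000_000, "A", "G", 0.3, 0.0, 0.05, 1e-10],
                ["s2", "1", 1_001_000, "A", "G", 0.3, 0.4, 0.05, 1e-10],
            ]
        )
        assert orient_weights(sel, "SBP", "BB").snp_ids == ["s2"]

    def test_all_weights_positive(self):
        rng = np.random.default_rng(2)
        sel = _gwas(
            [[f"s{i}", "1", 1_000_000 + i, "A", "G", 0.3, float(rng.normal()), 0.05, 1e-10] for i in range(6)]
        )
        inst = orient_weights(sel, "SBP", "BB")
        assert (inst.weights > 0).all()


def test_full_selection_pipeline_on_panel(small_genotypes, small_config):
    """End-to-end selection against a simulated panel keeps only admissible,
    oriented instruments inside the gene window."""
    from bpfrail.synthdata import gwas_from_cohort, simulate_cohort

    cohort = simulate_cohort(small_genotypes, small_config)
    gwas = gwas_from_cohort(small_genotypes, cohort.phenotypes["true_sbp"].to_numpy())
    ld = ld_from_panel(small_genotypes)
    region = GeneRegion("BLOCK1", "BB", "1", 1_000_000, 1_020_000, flank=0)
    inst = select_instruments(
        gwas, [region], ld, exposure="SBP", drug_class="BB", p_max=0.5, maf_min=0.01, r2_max=0.4
    )
    assert inst.n_snps >= 1
    assert (inst.weights > 0).all()
    block1 = set(small_genotypes.snps["snp"][small_genotypes.snps["chrom"] == "1"])
    assert set(inst.snp_ids) <= block1
    for x, y in itertools.combinations(inst.snp_ids, 2):
        assert ld.loc[x, y] ** 2 < 0.4
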