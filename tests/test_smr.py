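"""SMR ratio test, HEIDI heterogeneity test and their selection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpfrail.smr import (
    heidi_test,
    pick_top_cis_eqtl,
    run_smr,
    select_heidi_snps,
    smr_multiple_testing,
    smr_test,
)
from bpfrail.synthdata import SummaryScenarioConfig, simulate_summary_scenario


class TestSmrTest:
    def test_null_numerator(self):
        b_xy, se_xy, p = smr_test(0.5, 0.05, 0.0, 0.01)
        assert b_xy == 0.0
        assert p == pytest.approx(1.0)

    def test_direct_statistic_evaluation(self):
        # z_zx = z_zy = 6 -> T = 36*36/72 = 18
        b_xy, se_xy, p = smr_test(0.6, 0.1, 0.06, 0.01)
        assert p == pytest.approx(stats.chi2.sf(18.0, 1))
        assert b_xy == pytest.approx(0.1)
        assert se_xy == pytest.approx(0.1 / np.sqrt(18.0))

    def test_symmetry_in_z_scores(self):
        _, _, p1 = smr_test(0.8, 0.1, 0.03, 0.01)  # z = 8, 3
        _, _, p2 = smr_test(0.3, 0.1, 0.08, 0.01)  # z = 3, 8
        assert p1 == pytest.approx(p2)

    def test_scale_invariance(self):
        _, _, p1 = smr_test(0.5, 0.08, 0.02, 0.004)
        _, _, p2 = smr_test(5.0, 0.8, 0.2, 0.04)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            smr_test(0.0, 0.05, 0.1, 0.01)
        with pytest.raises(ValueError):
            smr_test(0.5, -0.05, 0.1, 0.01)

    def test_p_matches_parametric_monte_carlo(self):
        """chi2(1) reference agrees with an empirical null distribution of
        T_SMR simulated at the observed eQTL strength."""
        rng = np.random.default_rng(12)
        b_zx0, se_zx, se_zy = 0.9, 0.07, 0.005
        b_zx_obs, b_zy_obs = 0.9, 0.0105  # a moderately significant ratio
        _, _, p_analytic = smr_test(b_zx_obs, se_zx, b_zy_obs, se_zy)
        n_sim = 100_000
        bzx = rng.normal(b_zx0, se_zx, n_sim)
        bzy = rng.normal(0.0, se_zy, n_sim)  # null: no outcome effect
        zx2 = (bzx / se_zx) ** 2
        zy2 = (bzy / se_zy) ** 2
        t_null = zx2 * zy2 / (zx2 + zy2)
        zx_obs2 = (b_zx_obs / se_zx) ** 2
        zy_obs2 = (b_zy_obs / se_zy) ** 2
        t_obs = zx_obs2 * zy_obs2 / (zx_obs2 + zy_obs2)
        p_empirical = np.mean(t_null >= t_obs)
        assert p_analytic == pytest.approx(p_empirical, rel=0.10)


GENE_START, GENE_END = 10_000_000, 10_050_000


def _records(rows):
    return pd.DataFrame(
        rows, columns=["snp", "pos", "b_zx", "se_zx", "p_zx", "b_zy", "se_zy"]
    )


class TestTopCisEqtl:
    def test_single_passing_snp(self):
        rec = _records([["s1", 10_010_000, 0.8, 0.07, 1e-20, 0.01, 0.005]])
        top = pick_top_cis_eqtl(rec, GENE_START, GENE_END)
        assert top["snp"] == "s1"

    def test_cis_window_boundary(self):
        rec = _records(
            [
                ["inside", GENE_END + 1_000_000, 0.8, 0.07, 1e-20, 0.01, 0.005],
                ["outside", GENE_END + 1_000_001, 0.9, 0.07, 1e-30, 0.01, 0.005],
            ]
        )
        top = pick_top_cis_eqtl(rec, GENE_START, GENE_END)
        assert top["snp"] == "inside"

    def test_probe_without_significant_eqtl_skipped(self):
        rec = _records([["s1", 10_010_000, 0.3, 0.07, 5e-8, 0.01, 0.005]])
        assert pick_top_cis_eqtl(rec, GENE_START, GENE_END) is None

    def test_lowest_p_wins(self):
        rec = _records(
            [
                ["weak", 10_010_000, 0.5, 0.07, 1e-12, 0.01, 0.005],
                ["strong", 10_020_000, 0.9, 0.07, 1e-30, 0.01, 0.005],
            ]
        )
        assert pick_top_cis_eqtl(rec, GENE_START, GENE_END)["snp"] == "strong"


class TestHeidiSelection:
    @staticmethod
    def _ld_frame(ids, r_top):
        m = len(ids)
        r = np.eye(m)
        r[0, 1:] = r[1:, 0] = r_top
        return pd.DataFrame(r, index=ids, columns=ids)

    def test_near_perfect_proxies_excluded(self):
        rec = _records(
            [
                ["top", 1, 0.8, 0.07, 1e-20, 0.01, 0.005],
                ["proxy", 2, 0.78, 0.07, 1e-18, 0.01, 0.005],
                ["ok", 3, 0.5, 0.07, 1e-8, 0.01, 0.005],
            ]
        )
        ld = self._ld_frame(["top", "proxy", "ok"], [0.98, 0.6])
        assert select_heidi_snps(rec, ld, "top") == ["ok"]

    def test_weak_eqtl_snps_excluded(self):
        rec = _records(
            [
                ["top", 1, 0.8, 0.07, 1e-20, 0.01, 0.005],
                ["weak", 2, 0.2, 0.07, 2e-3, 0.01, 0.005],
                ["strong", 3, 0.5, 0.07, 1.6e-3, 0.01, 0.005],
            ]
        )
        ld = self._ld_frame(["top", "weak", "strong"], [0.5, 0.5])
        # the 1.6e-3 boundary itself is kept (exclusion is p > 1.6e-3)
        assert select_heidi_snps(rec, ld, "top") == ["strong"]

    def test_caps_at_twenty_smallest_p(self):
        rows = [["top", 0, 0.9, 0.07, 1e-30, 0.01, 0.005]]
        rows += [[f"s{i}", i, 0.5, 0.07, 10 ** -(20 - 0.3 * i), 0.01, 0.005] for i in range(30)]
        rec = _records(rows)
        ids = list(rec["snp"])
        ld = self._ld_frame(ids, [0.5] * 30)
        kept = select_heidi_snps(rec, ld, "top")
        assert len(kept) == 20
        expected = rec.iloc[1:].nsmallest(20, "p_zx")["snp"]
        assert set(kept) == set(expected)


def _causal_window(seed=0, se_zx=0.07, se_zy=0.005, m=15):
    idx = np.arange(m)
    r = 0.9 ** np.abs(idx[:, None] - idx[None, :])
    rng = np.random.default_rng(seed)
    c = m // 2
    b_zx_t = r[:, c] * 1.0
    b_zy_t = -0.02 * b_zx_t
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    b_zx = b_zx_t + se_zx * chol @ rng.standard_normal(m)
    b_zy = b_zy_t + se_zy * chol @ rng.standard_normal(m)
    rec = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "pos": 10_000_000 + idx * 1000,
            "b_zx": b_zx,
            "se_zx": se_zx,
            "p_zx": 2 * stats.norm.sf(np.abs(b_zx / se_zx)),
            "b_zy": b_zy,
            "se_zy": se_zy,
        }
    )
    ld = pd.DataFrame(r, index=rec["snp"], columns=rec["snp"])
    return rec, ld, f"s{c}"


class TestHeidi:
    def test_noiseless_causal_gives_zero_statistic(self):
        # estimates equal to the LD-propagated truth: every per-SNP ratio is
        # exactly b_xy, all difference terms vanish
        m = 15
        idx = np.arange(m)
        r = 0.9 ** np.abs(idx[:, None] - idx[None, :])
        b_zx = r[:, m // 2] * 1.0
        rec = pd.DataFrame(
            {
                "snp": [f"s{i}" for i in range(m)],
                "pos": 10_000_000 + idx * 1000,
                "b_zx": b_zx,
                "se_zx": 0.07,
                "p_zx": 1e-20,
                "b_zy": -0.02 * b_zx,
                "se_zy": 0.005,
            }
        )
        ld = pd.DataFrame(r, index=rec["snp"], columns=rec["snp"])
        top = f"s{m // 2}"
        res = heidi_test(rec, ld, top, n_draws=5000, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p > 0.99

    def test_snp_order_invariance(self):
        rec, ld, top = _causal_window(seed=3)
        res_a = heidi_test(rec, ld, top, n_draws=20_000, seed=5)
        perm = rec.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res_b = heidi_test(perm, ld, top, n_draws=20_000, seed=5)
        assert res_a.statistic == pytest.approx(res_b.statistic, rel=1e-10)
        assert res_a.p == pytest.approx(res_b.p, abs=0.01)

    def test_monte_carlo_agrees_with_satterthwaite(self):
        """The two tail approximations agree within a factor of 2 for
        moderate p-values across seeded windows."""
        checked = 0
        for seed in range(40):
            rec, ld, top = _causal_window(seed=seed)
            res = heidi_test(rec, ld, top, n_draws=50_000, seed=seed)
            if res is None or not (0.01 <= res.p <= 0.5):
                continue
            checked += 1
            assert res.p / res.p_satterthwaite < 2.0
            assert res.p_satterthwaite / res.p < 2.0
        assert checked >= 5

    def test_too_few_snps_returns_none(self):
        rec, ld, top = _causal_window()
        small = rec[rec["snp"].isin([top, "s0", "s1"])]
        assert heidi_test(small, ld, top, n_draws=1000) is None


@pytest.mark.parametrize(
    "p, flag",
    [(1e-4, "significant"), (0.0029, "significant"), (0.003, "suggestive"),
     (0.01, "suggestive"), (0.2, "null")],
)
def test_smr_multiple_testing_flags(p, flag):
    flags, threshold = smr_multiple_testing(p, n_genes=15)
    assert threshold == pytest.approx(0.003)
    assert flags == flag


def test_run_smr_detects_simulated_causal_gene():
    sc = simulate_summary_scenario(SummaryScenarioConfig(scenario="causal", seed=21))
    res = run_smr(sc.records, sc.ld, sc.gene_start, sc.gene_end, gene="G", heidi_seed=2,
                  heidi_draws=20_000)
    assert res is not None
    assert res.b_xy == pytest.approx(-0.02, abs=0.02)
    assert res.p_smr < 0.05
    assert res.n_heidi_snps >= 3


def test_run_smr_skips_gene_without_eqtl():
    sc = simulate_summary_scenario(SummaryScenarioConfig(scenario="null", seed=22))
    rec = sc.records.copy()
    rec["p_zx"] = 0.5  # no qualifying cis-eQTL
    assert run_smr(rec, sc.ld, sc.gene_start, sc.gene_end) is None
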