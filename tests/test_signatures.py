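import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scpotency.signatures import (
    SignedSignature,
    build_signed_signature,
    cell_cycle_scores,
    de_vs_potency,
    gsea_mc,
    mc_mean_diff_test,
    overlap_enrichment,
    signature_score,
)


def planted_de_matrix(seed=5, n_cells=500, n_genes=40, n_planted=None, slope=2.0):
    """Expression matrix where the first n_planted genes respond to a
    potency covariate with alternating sign; the rest are pure noise."""
    if n_planted is None:
        n_planted = n_genes // 2
    rng = np.random.default_rng(seed)
    sr = rng.uniform(0.2, 0.9, n_cells)
    values = rng.normal(0, 1, (n_genes, n_cells))
    signs = np.array(([1, -1] * n_planted)[:n_planted])
    for g in range(n_planted):
        values[g] += signs[g] * slope * sr
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return pd.DataFrame(values, index=genes, columns=[f"c{i}" for i in range(n_cells)]), sr, signs


class TestDeVsPotency:
    def test_planted_gene_found(self):
        expr, sr, _ = planted_de_matrix()
        de = de_vs_potency(expr, sr)
        top = de["t"].abs().idxmax()
        assert top in {f"g{i:03d}" for i in range(20)}
        assert de.loc[top, "p_bonf"] < 0.05

    def test_recovers_planted_signs(self):
        expr, sr, signs = planted_de_matrix()
        de = de_vs_potency(expr, sr)
        est = de["estimate"].to_numpy()[:20]
        assert np.all(np.sign(est) == signs)

    def test_constant_gene_excluded(self):
        expr, sr, _ = planted_de_matrix(n_genes=10)
        expr.iloc[5] = 3.0
        de = de_vs_potency(expr, sr)
        assert np.isnan(de.iloc[5]["t"])

    def test_permutation_invariance(self):
        expr, sr, _ = planted_de_matrix(n_cells=100, n_genes=10)
        perm = np.random.default_rng(0).permutation(100)
        de1 = de_vs_potency(expr, sr)
        de2 = de_vs_potency(expr.iloc[:, perm], sr[perm])
        pd.testing.assert_frame_equal(de1, de2)

    def test_drop_zeros_restricts_cells(self):
        rng = np.random.default_rng(1)
        sr = rng.uniform(0, 1, 200)
        vals = rng.normal(5, 1, (3, 200))
        floor = 0.0
        vals[0, :120] = floor  # dropouts for gene 0
        expr = pd.DataFrame(vals, index=["a", "b", "c"], columns=range(200))
        de = de_vs_potency(expr, sr, drop_zeros=True, zero_value=floor)
        assert de.loc["a", "n_cells_used"] == 80
        assert de.loc["b", "n_cells_used"] == 200

    def test_too_few_cells_reported_missing(self):
        rng = np.random.default_rng(2)
        sr = rng.uniform(0, 1, 50)
        vals = np.zeros((2, 50))
        vals[0, :5] = rng.normal(1, 1, 5)
        vals[1] = rng.normal(1, 1, 50)
        expr = pd.DataFrame(vals, index=["sparse", "dense"], columns=range(50))
        de = de_vs_potency(expr, sr, drop_zeros=True, zero_value=0.0)
        assert np.isnan(de.loc["sparse", "p"])
        assert np.isfinite(de.loc["dense", "p"])

    def test_covariate_adjustment_removes_confounded_signal(self):
        rng = np.random.default_rng(3)
        n = 400
        cc = rng.normal(0, 1, n)
        sr = 0.5 * cc + rng.normal(0, 1, n)   # potency confounded with cc
        vals = np.vstack([cc + 0.1 * rng.normal(0, 1, n)])  # gene driven by cc only
        expr = pd.DataFrame(vals, index=["g"], columns=range(n))
        raw = de_vs_potency(expr, sr)
        adj = de_vs_potency(expr, sr, covariates=[cc])
        assert abs(adj.loc["g", "t"]) < abs(raw.loc["g", "t"])

    def test_constant_response_rejected(self):
        expr, _, _ = planted_de_matrix(n_cells=50, n_genes=5)
        with pytest.raises(ValueError, match="constant"):
            de_vs_potency(expr, np.ones(50))

    def test_oracle_against_scipy_linregress(self):
        expr, sr, _ = planted_de_matrix(n_cells=120, n_genes=6)
        de = de_vs_potency(expr, sr)
        for g in expr.index:
            ref = stats.linregress(sr, expr.loc[g].to_numpy())
            assert de.loc[g, "estimate"] == pytest.approx(ref.slope, rel=1e-10)
            assert de.loc[g, "p"] == pytest.approx(ref.pvalue, rel=1e-8)


class TestCellCycleScores:
    def make_expr(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(10)]
        return pd.DataFrame(rng.normal(2, 1, (10, 30)), index=genes, columns=range(30))

    def test_mean_zero_across_cells(self):
        expr = self.make_expr()
        scores = cell_cycle_scores(expr, ["g0", "g1", "g2"], ["g5", "g6"])
        assert scores["g1s"].mean() == pytest.approx(0.0, abs=1e-12)
        assert scores["g2m"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        expr = self.make_expr()
        s1 = cell_cycle_scores(expr, ["g0", "g1"], ["g5"])
        s2 = cell_cycle_scores(2.0 * expr, ["g0", "g1"], ["g5"])
        pd.testing.assert_frame_equal(s1, s2)

    def test_cell_at_gene_means_scores_zero(self):
        expr = self.make_expr()
        expr.iloc[:, 0] = expr.iloc[:, 1:].mean(axis=1)
        # recompute means including cell 0 shifts slightly; construct exactly
        expr.iloc[:, 0] = expr.mean(axis=1)
        for _ in range(50):
            expr.iloc[:, 0] = expr.mean(axis=1)
        scores = cell_cycle_scores(expr, ["g0", "g1", "g2"], ["g5"])
        assert scores["g1s"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_genes_dropped_and_empty_errors(self):
        expr = self.make_expr()
        expr.loc["g0"] = 1.0
        scores = cell_cycle_scores(expr, ["g0", "g1"], ["g5"])
        assert np.isfinite(scores["g1s"]).all()
        with pytest.raises(ValueError, match="no usable"):
            cell_cycle_scores(expr, ["g0"], ["g5"])


class TestSignedSignature:
    def make_de(self, n_pos=5, n_neg=5):
        genes = [f"u{i}" for i in range(n_pos)] + [f"d{i}" for i in range(n_neg)]
        t = list(range(n_pos, 0, -1)) + [-(i + 1) for i in range(n_neg)]
        p = [1e-6] * (n_pos + n_neg)
        return pd.DataFrame(
            {"estimate": t, "t": t, "p": p, "p_bonf": p, "n_cells_used": 100},
            index=genes,
        )

    def test_top_n_selection(self):
        de = self.make_de()
        sig = build_signed_signature(de, n_up=3, n_dn=2)
        assert list(sig.genes[:3]) == ["u0", "u1", "u2"]
        assert (sig.signs[:3] == 1).all()
        assert (sig.signs[3:] == -1).all()

    def test_all_significant_positives_kept_when_exactly_n(self):
        de = self.make_de(n_pos=4, n_neg=6)
        sig = build_signed_signature(de, n_up=4, n_dn=6)
        assert (sig.signs == 1).sum() == 4

    def test_minimal_signature(self):
        sig = build_signed_signature(self.make_de(), n_up=1, n_dn=1)
        assert len(sig.genes) == 2
        assert set(sig.signs) == {1, -1}

    def test_tie_broken_by_gene_id(self):
        de = self.make_de(n_pos=3, n_neg=1)
        de.loc[["u0", "u1", "u2"], "t"] = 2.0
        sig = build_signed_signature(de, n_up=2, n_dn=1)
        assert list(sig.genes[:2]) == ["u0", "u1"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_signed_signature(pd.DataFrame())

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SignedSignature(genes=["a", "a"], signs=[1, -1])


class TestSignatureScore:
    def make_sig(self):
        return SignedSignature(
            genes=[f"u{i}" for i in range(5)] + [f"d{i}" for i in range(5)],
            signs=[1] * 5 + [-1] * 5,
        )

    def test_perfect_match_is_one(self):
        sig = self.make_sig()
        profile = pd.Series({g: float(s) for g, s in zip(sig.genes, sig.signs)})
        assert signature_score(profile, sig) == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        sig = self.make_sig()
        rng = np.random.default_rng(0)
        profile = pd.Series(rng.normal(0, 1, 10), index=sig.genes)
        assert signature_score(-profile, sig) == pytest.approx(
            -signature_score(profile, sig), abs=1e-12
        )

    def test_affine_invariance(self):
        sig = self.make_sig()
        profile = pd.Series(np.random.default_rng(1).normal(0, 1, 10), index=sig.genes)
        assert signature_score(3.0 * profile + 7.0, sig) == pytest.approx(
            signature_score(profile, sig), abs=1e-12
        )

    def test_missing_genes_dropped_and_minimum_enforced(self):
        sig = self.make_sig()
        profile = pd.Series([1.0, -1.0, 1.0, -1.0], index=["u0", "d0", "u1", "d1"])
        assert -1 <= signature_score(profile, sig) <= 1
        with pytest.raises(ValueError, match="fewer than 3"):
            signature_score(pd.Series([1.0, 2.0], index=["u0", "u1"]), sig)

    def test_constant_profile_rejected(self):
        sig = self.make_sig()
        with pytest.raises(ValueError, match="constant"):
            signature_score(pd.Series(np.ones(10), index=sig.genes), sig)


class TestGseaMc:
    def test_top_loaded_set_reaches_one(self):
        ranking = [f"g{i}" for i in range(100)]
        res = gsea_mc(ranking, ranking[:10], n_mc=200, seed=0)
        assert res.es_max == 1.0

    def test_curve_starts_and_ends_at_zero(self):
        rng = np.random.default_rng(0)
        ranking = [f"g{i}" for i in range(200)]
        gene_set = list(rng.choice(ranking, 20, replace=False))
        res = gsea_mc(ranking, gene_set, n_mc=200, seed=1)
        assert res.running_es[0] == 0.0
        assert res.running_es[-1] == 0.0  # exact, integer accumulation

    def test_full_set_rejected(self):
        ranking = ["a", "b", "c"]
        with pytest.raises(ValueError, match="entire"):
            gsea_mc(ranking, ranking, n_mc=200)
        with pytest.raises(ValueError, match="intersect"):
            gsea_mc(ranking, ["zzz"], n_mc=200)

    def test_nes_near_one_under_random_ranking(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(300)]
        nes = []
        for rep in range(200):  # per-replicate NES has sd ~0.5: average many
            ranking = list(rng.permutation(genes))
            res = gsea_mc(ranking, genes[:20], n_mc=100, seed=rep)
            nes.append(res.nes)
        assert np.mean(nes) == pytest.approx(1.0, abs=0.1)


class TestMcMeanDiff:
    def test_minimum_attainable_p(self):
        stat = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        top = [f"g{i}" for i in range(88, 100)]
        observed, p = mc_mean_diff_test(stat, top, n_mc=999, seed=0)
        assert observed == stat.iloc[88:].mean()
        assert p == pytest.approx(1 / 1000)

    def test_constant_stats_give_p_one(self):
        stat = pd.Series(np.ones(50), index=[f"g{i}" for i in range(50)])
        _, p = mc_mean_diff_test(stat, ["g0", "g1"], n_mc=199, seed=0)
        assert p == 1.0

    def test_null_p_values_super_uniform(self):
        rng = np.random.default_rng(3)
        stat = pd.Series(rng.normal(0, 1, 200), index=[f"g{i}" for i in range(200)])
        pvals = []
        for rep in range(200):
            gene_set = list(rng.choice(stat.index, 12, replace=False))
            _, p = mc_mean_diff_test(stat, gene_set, n_mc=199, seed=rep)
            pvals.append(p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert abs(frac - 0.05) <= 0.03
        # super-uniformity via one-sided KS
        d = stats.kstest(pvals, "uniform", alternative="greater")
        assert d.pvalue > 0.01

    def test_unknown_gene_rejected(self):
        stat = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="absent"):
            mc_mean_diff_test(stat, ["zzz"], n_mc=100)


class TestOverlapEnrichment:
    def test_hand_computed_odds_ratio(self):
        # table a=10, b=10, c=10, d=970 -> OR = (10*970)/(10*10) = 97
        set_a = set(range(20))
        set_b = set(range(10)) | set(range(100, 110))
        oddsratio, p = overlap_enrichment(set_a, set_b, universe_size=1000)
        assert oddsratio == pytest.approx(97.0)
        assert p < 1e-10

    def test_disjoint_sets_or_below_one(self):
        oddsratio, _ = overlap_enrichment(set(range(50)), set(range(50, 100)), 100)
        assert oddsratio < 1

    def test_identical_sets_maximal(self):
        or_same, p_same = overlap_enrichment(set(range(10)), set(range(10)), 100)
        or_less, _ = overlap_enrichment(set(range(10)), set(range(5, 15)), 100)
        assert or_same > or_less
        assert p_same < 1e-10

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(set(range(10)), set(range(5, 15)), 12)

    def test_p_matches_fisher_exact(self):
        set_a, set_b, n = set(range(15)), set(range(5, 30)), 200
        _, p = overlap_enrichment(set_a, set_b, n)
        a = len(set_a & set_b)
        table = [[a, len(set_a) - a], [len(set_b) - a, n - len(set_a | set_b)]]
        assert p == pytest.approx(stats.fisher_exact(table, "greater")[1], rel=1e-9)
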