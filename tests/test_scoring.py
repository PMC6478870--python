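"""L1-normalized dot-product scores: flux, in-vivo, knockdown, drugs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from trmet import scoring, synthdata
from trmet.types import AssociationMatrix


def _frame(arr, rows="r", cols="c"):
    return pd.DataFrame(arr, index=[f"{rows}{i}" for i in range(arr.shape[0])],
                        columns=[f"{cols}{j}" for j in range(arr.shape[1])])


class TestFluxCorrelation:
    def test_perfectly_aligned_metabolite(self):
        x = np.arange(6.0)
        z = _frame(x[None, :], "m", "L")
        up = pd.Series(x, index=z.columns)
        sec = pd.Series(x ** 2, index=z.columns)  # same ranks
        score = scoring.metabolite_flux_correlation(z, up, sec)
        assert score.iloc[0] == pytest.approx(1.0)

    def test_anti_monotone_gives_minus_one(self):
        x = np.arange(6.0)
        z = _frame((-x)[None, :], "m", "L")
        score = scoring.metabolite_flux_correlation(
            z, pd.Series(x, index=z.columns), pd.Series(x, index=z.columns)
        )
        assert score.iloc[0] == pytest.approx(-1.0)

    def test_matches_hand_averaged_rank_correlations(self):
        rng = np.random.default_rng(0)
        z = _frame(rng.normal(size=(3, 6)), "m", "L")
        up = pd.Series(rng.normal(size=6), index=z.columns)
        sec = pd.Series(rng.normal(size=6), index=z.columns)
        score = scoring.metabolite_flux_correlation(z, up, sec)
        for m in z.index:
            expected = 0.5 * (spearmanr(z.loc[m], up).statistic + spearmanr(z.loc[m], sec).statistic)
            assert score[m] == pytest.approx(expected, abs=1e-12)

    def test_constant_flux_rejected(self):
        z = _frame(np.random.default_rng(1).normal(size=(2, 6)), "m", "L")
        const = pd.Series(np.ones(6), index=z.columns)
        with pytest.raises(ValueError, match="constant"):
            scoring.metabolite_flux_correlation(z, const, const)


class TestTrFluxScore:
    def test_orthogonal_vectors_score_zero(self):
        R = _frame(np.array([[1.0, -1.0, 1.0, -1.0]]), "t", "m")
        f = pd.Series([1.0, 1.0, 1.0, 1.0], index=R.columns)
        assert scoring.tr_flux_score(R, f).iloc[0] == pytest.approx(0.0)

    def test_aligned_row_reaches_weighted_mean(self):
        f = pd.Series([0.5, -0.3, 0.8], index=["m0", "m1", "m2"])
        R = pd.DataFrame([[0.4, -0.24, 0.64]], index=["t0"], columns=f.index)
        score = scoring.tr_flux_score(R, f)
        expected = (R.iloc[0] * f).sum() / R.iloc[0].abs().sum()
        assert score.iloc[0] == pytest.approx(expected)

    def test_l1_bound(self):
        rng = np.random.default_rng(2)
        R = _frame(rng.uniform(-1, 1, (20, 15)), "t", "m")
        f = pd.Series(rng.uniform(-1, 1, 15), index=R.columns)
        scores = scoring.tr_flux_score(R, f)
        assert (scores.abs() <= f.abs().max() + 1e-12).all()

    def test_all_zero_row_flagged(self):
        R = _frame(np.zeros((1, 4)), "t", "m")
        f = pd.Series(np.ones(4), index=R.columns)
        assert np.isnan(scoring.tr_flux_score(R, f).iloc[0])


class TestPathwayScore:
    def test_uniform_scores_not_significant(self):
        scores = pd.Series(1.0, index=[f"t{i}" for i in range(40)])
        res = scoring.pathway_tr_score(scores, {"pw": [f"t{i}" for i in range(5)]}, n_perm=500, seed=0)
        assert res.loc["pw", "p"] > 0.5

    def test_planted_high_score_cluster_detected(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(0, 0.1, 60), index=[f"t{i}" for i in range(60)])
        scores.iloc[:6] += 2.0
        res = scoring.pathway_tr_score(
            scores, {"hot": [f"t{i}" for i in range(6)],
                     "cold": [f"t{i}" for i in range(20, 26)]},
            n_perm=2000, seed=2,
        )
        assert res.loc["hot", "p"] <= 0.01
        assert res.loc["cold", "p"] > 0.05

    def test_unmapped_pathway_rejected(self):
        scores = pd.Series([1.0], index=["t0"])
        with pytest.raises(KeyError):
            scoring.pathway_tr_score(scores, {"pw": ["absent"]}, n_perm=10)


class TestInvivo:
    def test_hand_arithmetic(self):
        ctr = pd.DataFrame([[1.0, -1.0]], index=["tr"], columns=["m1", "m2"])
        fc = pd.DataFrame([[2.0], [-2.0]], index=["m1", "m2"], columns=["p1"])
        res = scoring.invivo_tr_score(ctr, fc, n_perm=100, seed=0)
        assert res.S.loc["tr", "p1"] == pytest.approx(2.0)

    def test_zero_fold_changes_give_p_one(self):
        ctr = pd.DataFrame([[1.0, -1.0, 0.5]], index=["tr"], columns=["m1", "m2", "m3"])
        fc = pd.DataFrame(0.0, index=["m1", "m2", "m3"], columns=["p1"])
        res = scoring.invivo_tr_score(ctr, fc, n_perm=50, seed=0)
        assert res.S.loc["tr", "p1"] == 0.0
        assert res.p.loc["tr", "p1"] == 1.0  # every permuted score ties at 0

    def test_monte_carlo_matches_exhaustive_permutations(self):
        """5 metabolites: the Monte-Carlo p agrees with the exact p over all
        120 metabolite orderings within binomial error."""
        rng = np.random.default_rng(3)
        c = rng.normal(size=5)
        f = rng.normal(size=5)
        ctr = pd.DataFrame([c], index=["tr"], columns=[f"m{i}" for i in range(5)])
        fc = pd.DataFrame(f[:, None], index=ctr.columns, columns=["p1"])
        obs = c @ f / np.abs(c).sum()
        exact = np.mean([
            (c[list(perm)] @ f) / np.abs(c).sum() >= obs
            for perm in itertools.permutations(range(5))
        ])
        n_perm = 4000
        res = scoring.invivo_tr_score(ctr, fc, n_perm=n_perm, seed=1)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert res.p.loc["tr", "p1"] == pytest.approx(exact, abs=4 * se + 1e-9)

    def test_l1_bound_on_scores(self):
        rng = np.random.default_rng(4)
        ctr = _frame(rng.normal(size=(6, 20)), "t", "m")
        fc = _frame(rng.normal(size=(20, 5)), "m", "p")
        res = scoring.invivo_tr_score(ctr, fc, n_perm=10, seed=0, max_missing=5)
        bound = fc.abs().max(axis=0)
        assert (res.S.abs() <= bound + 1e-12).all().all()

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        ctr = _frame(rng.normal(size=(2, 8)), "t", "m")
        fc = pd.DataFrame(rng.normal(size=(8, 3)), index=ctr.columns,
                          columns=["p1", "p2", "p3"])
        res1 = scoring.invivo_tr_score(ctr, fc, n_perm=500, seed=6)
        perm = rng.permutation(ctr.columns)
        res2 = scoring.invivo_tr_score(ctr[perm], fc.loc[perm], n_perm=500, seed=6)
        pd.testing.assert_frame_equal(res1.S, res2.S)
        pd.testing.assert_frame_equal(res1.p, res2.p)

    def test_missingness_filter_applied(self):
        ctr = _frame(np.ones((1, 3)), "t", "m")
        fc = pd.DataFrame(np.ones((3, 12)), index=ctr.columns,
                          columns=[f"p{i}" for i in range(12)])
        fc.iloc[0, :11] = np.nan  # 11 missing > max 10
        res = scoring.invivo_tr_score(ctr, fc, n_perm=10, seed=0)
        assert res.metabolites_used == ["m1", "m2"]


class TestKnockdown:
    def test_identical_concentrations_median_equals_each(self):
        rng = np.random.default_rng(0)
        ctr = _frame(rng.normal(size=(4, 10)), "t", "m")
        col = rng.normal(size=10)
        fc = pd.DataFrame(np.tile(col[:, None], 3), index=ctr.columns,
                          columns=["c1", "c2", "c3"])
        scores, _ = scoring.knockdown_rank(ctr, fc)
        np.testing.assert_allclose(scores["median_score"], scores["c1"])

    def test_combined_p_product_and_monotonicity(self):
        p = pd.DataFrame([[0.1, 0.2, 0.5], [0.2, 0.2, 0.5]],
                         index=["m1", "m2"], columns=["c1", "c2", "c3"])
        _, combined = scoring.knockdown_rank(
            _frame(np.ones((1, 2)), "t", "m").set_axis(["m1", "m2"], axis=1),
            pd.DataFrame(np.ones((2, 3)), index=["m1", "m2"], columns=p.columns),
            p_per_conc=p,
        )
        assert combined["m1"] == pytest.approx(0.01)
        assert combined["m1"] < combined["m2"]

    def test_planted_knockdown_ranks_top(self, small_study, quantified):
        """The silenced TR ranks in the top 2-5% by median knockdown score."""
        from trmet import assoc

        _, zm, _ = quantified
        act = small_study.truth.tr_activity_true
        am = assoc.correlate(act, zm)
        ctr = am.ctr_vectors()
        target = "TR002"  # a coupled TR with real metabolite associations
        fc, p = synthdata.simulate_knockdown(ctr, small_study.config, target)
        scores, _ = scoring.knockdown_rank(ctr, fc, p)
        rank = list(scores.index).index(target)
        assert rank < max(1, int(0.05 * len(scores)))

    def test_needs_two_concentrations(self):
        ctr = _frame(np.ones((1, 2)), "t", "m")
        fc = pd.DataFrame(np.ones((2, 1)), index=ctr.columns, columns=["c1"])
        with pytest.raises(ValueError):
            scoring.knockdown_rank(ctr, fc)


class TestDrugRegression:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        lines = [f"L{i}" for i in range(20)]
        act = pd.DataFrame(rng.normal(size=(1, 20)), index=["tr"], columns=lines)
        tissue = pd.Series(["a"] * 10 + ["b"] * 10, index=lines)
        sens = pd.DataFrame(2.0 * act.to_numpy(), index=["drug"], columns=lines)
        res = scoring.drug_tr_regression(sens, act, tissue)
        row = res.iloc[0]
        assert row["lambda"] == pytest.approx(2.0, rel=1e-9)
        assert row["p"] < 1e-12
        assert row["significant"]

    def test_tissue_effect_not_mistaken_for_activity(self):
        rng = np.random.default_rng(1)
        lines = [f"L{i}" for i in range(30)]
        act = pd.DataFrame(rng.normal(size=(1, 30)), index=["tr"], columns=lines)
        tissue = pd.Series(["a"] * 15 + ["b"] * 15, index=lines)
        sens = pd.DataFrame((tissue == "a").astype(float).to_numpy()[None, :] * 3.0,
                            index=["drug"], columns=lines)
        res = scoring.drug_tr_regression(sens, act, tissue)
        assert abs(res.iloc[0]["lambda"]) < 0.5
        assert res.iloc[0]["beta_a"] - res.iloc[0]["beta_b"] == pytest.approx(3.0, abs=0.5)

    def test_bonferroni_threshold_form(self):
        rng = np.random.default_rng(2)
        lines = [f"L{i}" for i in range(12)]
        act = _frame(rng.normal(size=(3, 12)), "t").set_axis(lines, axis=1)
        sens = _frame(rng.normal(size=(4, 12)), "d").set_axis(lines, axis=1)
        tissue = pd.Series(["a"] * 6 + ["b"] * 6, index=lines)
        res = scoring.drug_tr_regression(sens, act, tissue, alpha=0.05)
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 12)

    def test_null_family_wise_error_controlled(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lines = [f"L{i}" for i in range(24)]
            act = _frame(rng.normal(size=(5, 24)), "t").set_axis(lines, axis=1)
            sens = _frame(rng.normal(size=(6, 24)), "d").set_axis(lines, axis=1)
            tissue = pd.Series(["a", "b", "c"] * 8, index=lines)
            res = scoring.drug_tr_regression(sens, act, tissue, alpha=0.05)
            hits += int(res["significant"].any())
        assert hits <= 2  # ~0.05 per family over 5 seeds

    def test_moa_cluster_enrichment_detects_planted_block(self, small_study):
        proteome, mact, panel = synthdata.simulate_proteome_drugs(
            small_study.config, small_study.truth
        )
        res = scoring.drug_tr_regression(panel.sensitivity, mact, small_study.truth.tissue)
        P = scoring.moa_cluster_enrichment(res, panel.tr_clusters, panel.moa)
        assert P.loc["c1", "moa1"] <= P.attrs["bonferroni_threshold"]
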