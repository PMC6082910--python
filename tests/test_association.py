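import numpy as np
import pandas as pd
import pytest

from latentprs.association import (
    StructuralModel,
    estimate_factor_scores,
    estimate_ipw,
    fit_structural,
    permutation_adjusted_p,
    weighted_structural,
)
from latentprs.simulate import (
    TrueModel,
    simulate_factors,
    simulate_item_responses,
)


@pytest.fixture(scope="module")
def structural_data():
    """n=2000 cohort with a known general-factor effect of 0.06."""
    model = TrueModel(seed=5, prs_betas={"GENERAL": [0.06]})
    rng = np.random.default_rng(40)
    x = rng.standard_normal(2000)
    x = (x - x.mean()) / x.std()
    eta = simulate_factors(x, model.prs_betas, seed=41)
    items = simulate_item_responses(eta, model, seed=42)
    return model, x, eta, items


class TestStructuralFit:
    def test_table_schema_matches_reporting_layout(self, structural_data):
        model, x, _, items = structural_data
        res = fit_structural(items, x, "bifactor", item_blocks=model.item_blocks)
        assert list(res.table.columns) == ["outcome", "beta", "se", "lci", "uci", "p"]
        assert res.table["outcome"].tolist()[0] == "GENERAL"
        assert len(res.table) == 5
        assert res.n_analyzed == 2000
        # CI brackets beta, p in (0, 1]
        assert (res.table["lci"] <= res.table["beta"]).all()
        assert (res.table["beta"] <= res.table["uci"]).all()
        assert ((res.table["p"] > 0) & (res.table["p"] <= 1)).all()

    def test_estimate_near_truth(self, structural_data):
        model, x, _, items = structural_data
        res = fit_structural(items, x, "bifactor", item_blocks=model.item_blocks)
        est = res.beta("GENERAL")
        se = float(res.table.set_index("outcome").loc["GENERAL", "se"])
        assert est == pytest.approx(0.06, abs=3.5 * se)

    def test_permuted_prs_gives_null_betas(self, structural_data):
        model, x, _, items = structural_data
        x_perm = np.random.default_rng(43).permutation(x)
        res = fit_structural(items, x_perm, "bifactor",
                             item_blocks=model.item_blocks)
        assert np.abs(res.gamma).max() < 0.08

    def test_correlated_structure_has_four_rows(self, structural_data):
        model, x, _, items = structural_data
        res = fit_structural(items, x, "correlated", item_blocks=model.item_blocks)
        assert len(res.table) == 4
        assert "GENERAL" not in res.table["outcome"].tolist()

    def test_unmatched_ids_rejected(self, structural_data):
        model, x, _, items = structural_data
        labelled = items.copy()
        labelled.index = [f"r{i}" for i in range(len(items))]
        prs = pd.Series(x[:100], index=[f"r{i}" for i in range(100)])
        with pytest.raises(ValueError, match="no PRS"):
            fit_structural(labelled, prs, "bifactor", item_blocks=model.item_blocks)

    def test_constant_prs_rejected(self, structural_data):
        model, _, _, items = structural_data
        with pytest.raises(ValueError, match="constant"):
            fit_structural(items, np.ones(len(items)), "bifactor",
                           item_blocks=model.item_blocks)

    def test_sklearn_estimator_wrapper(self, structural_data):
        model, x, _, items = structural_data
        sm_ = StructuralModel(structure="bifactor", item_blocks=model.item_blocks,
                              compute_se=False).fit(items, x)
        assert set(sm_.betas_.index) == {"GENERAL", *model.item_blocks.values()}
        assert sm_.get_params()["structure"] == "bifactor"


class TestFactorScores:
    def test_extreme_response_gives_tail_score(self):
        """A near-deterministic item pushes the MAP score far out, signed."""
        model = TrueModel(
            n_items_per_block=(1, 1, 1, 1),
            categories_per_block=(3, 3, 3, 3),
            general_loadings=np.full(4, 0.95),
            specific_loadings=np.zeros(4),
            thresholds=[np.array([-1.5, 1.5])] * 4,
            seed=1,
        )
        from latentprs.measurement import build_model, fit_dwls
        from latentprs.polychoric import PolychoricSummary

        lam = model.loadings_matrix()
        pop = lam @ lam.T
        np.fill_diagonal(pop, 1.0)
        fit = fit_dwls(
            PolychoricSummary.from_population(pop, model.thresholds),
            build_model("unidimensional", None, item_names=model.item_names),
            n=100,
            compute_stats=False,
        )
        top = pd.DataFrame(
            [[2, 2, 2, 2]], columns=model.item_names, dtype=float
        )
        bottom = pd.DataFrame([[0, 0, 0, 0]], columns=model.item_names, dtype=float)
        s_top = estimate_factor_scores(fit, top).iloc[0, 0]
        s_bot = estimate_factor_scores(fit, bottom).iloc[0, 0]
        assert s_top > 1.0 and s_bot < -1.0

    def test_scores_track_true_factors(self, structural_data):
        model, x, eta, items = structural_data
        res = fit_structural(items, x, "bifactor", item_blocks=model.item_blocks,
                             compute_se=False)
        scores = estimate_factor_scores(res.measurement, items)
        slope = np.polyfit(eta[:, 0], scores["GENERAL"].to_numpy(), 1)[0]
        assert slope > 0.7  # MAP shrinkage keeps it below 1

    def test_well_determined_factor_slope(self):
        """Attenuation check: unidimensional battery with strong loadings."""
        model = TrueModel(
            n_items_per_block=(13, 13, 13, 12),
            categories_per_block=(3, 3, 3, 3),
            general_loadings=np.random.default_rng(4).uniform(0.7, 0.85, 51),
            specific_loadings=np.zeros(51),
            seed=5,
        )
        eta = simulate_factors(None, np.zeros((5, 1)), n=5000, seed=6)
        items = simulate_item_responses(eta, model, seed=7)
        from latentprs.measurement import MeasurementModel

        mm = MeasurementModel(structure="unidimensional", compute_stats=False).fit(items)
        scores = estimate_factor_scores(mm.result_, items)
        slope = np.polyfit(eta[:, 0], scores.iloc[:, 0].to_numpy(), 1)[0]
        assert slope > 0.8

    def test_row_permutation_equivariance(self, structural_data):
        model, x, _, items = structural_data
        res = fit_structural(items.iloc[:300], x[:300], "bifactor",
                             item_blocks=model.item_blocks, compute_se=False)
        scores = estimate_factor_scores(res.measurement, items.iloc[:300])
        perm = np.random.default_rng(8).permutation(300)
        scores_perm = estimate_factor_scores(res.measurement, items.iloc[:300].iloc[perm])
        assert np.allclose(scores.to_numpy()[perm], scores_perm.to_numpy())

    def test_all_missing_respondent_gets_nan(self, structural_data):
        model, x, _, items = structural_data
        res = fit_structural(items.iloc[:200], x[:200], "bifactor",
                             item_blocks=model.item_blocks, compute_se=False)
        holed = items.iloc[:5].copy().astype(float)
        holed.iloc[2] = np.nan
        scores = estimate_factor_scores(res.measurement, holed)
        assert scores.iloc[2].isna().all()
        assert scores.drop(scores.index[2]).notna().all().all()


class TestPermutation:
    @pytest.fixture(scope="class")
    def scores_and_prs(self):
        rng = np.random.default_rng(50)
        n = 600
        x = rng.standard_normal(n)
        scores = rng.standard_normal((n, 5))
        scores[:, 0] += 0.4 * x  # one real signal
        return pd.DataFrame(scores, columns=list("abcde")), x

    def test_single_outcome_adjusted_equals_unadjusted(self, scores_and_prs):
        scores, x = scores_and_prs
        res = permutation_adjusted_p(scores[["a"]], x, n_perm=300, seed=1)
        assert res.table["p_adjusted"].iloc[0] == res.table["p_unadjusted"].iloc[0]

    def test_adjusted_at_least_unadjusted_and_floor(self, scores_and_prs):
        scores, x = scores_and_prs
        res = permutation_adjusted_p(scores, x, n_perm=200, seed=2)
        assert (res.table["p_adjusted"] >= res.table["p_unadjusted"] - 1e-12).all()
        assert (res.table["p_adjusted"] >= 1 / 201).all()
        # the planted signal should be detected even after adjustment
        assert res.table.set_index("outcome").loc["a", "p_adjusted"] < 0.05

    def test_seeded_determinism(self, scores_and_prs):
        scores, x = scores_and_prs
        a = permutation_adjusted_p(scores, x, n_perm=150, seed=3)
        b = permutation_adjusted_p(scores, x, n_perm=150, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_affine_scale_invariance(self, scores_and_prs):
        scores, x = scores_and_prs
        a = permutation_adjusted_p(scores, x, n_perm=150, seed=4)
        b = permutation_adjusted_p(scores * 3.2 + 1.0, x, n_perm=150, seed=4)
        assert np.allclose(a.table["p_adjusted"], b.table["p_adjusted"])

    def test_constant_prs_rejected(self, scores_and_prs):
        scores, _ = scores_and_prs
        with pytest.raises(ValueError, match="constant"):
            permutation_adjusted_p(scores, np.zeros(len(scores)), n_perm=150)

    def test_minimum_permutations(self, scores_and_prs):
        scores, x = scores_and_prs
        with pytest.raises(ValueError, match="at least 100"):
            permutation_adjusted_p(scores, x, n_perm=50)


class TestIpw:
    def test_mcar_weights_near_constant(self):
        rng = np.random.default_rng(60)
        cov = pd.DataFrame({"z": rng.standard_normal(5000)})
        inc = rng.random(5000) < 0.6
        ipw = estimate_ipw(inc, cov)
        w = ipw.weight[inc]
        assert np.nanstd(w) / np.nanmean(w) < 0.05

    def test_all_included_gives_unit_weights(self):
        cov = pd.DataFrame({"z": np.random.default_rng(61).standard_normal(500)})
        ipw = estimate_ipw(np.ones(500), cov, truncate_at=None)
        assert np.allclose(ipw.weight, 1.0, atol=1e-6)

    def test_separation_detected(self):
        z = np.linspace(-3, 3, 400)
        cov = pd.DataFrame({"z": z})
        inc = (z > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            estimate_ipw(inc, cov)

    def test_truncation_logged(self):
        rng = np.random.default_rng(62)
        z = rng.standard_normal(3000)
        from scipy.special import expit

        inc = rng.random(3000) < expit(0.5 + 2.0 * z)
        ipw = estimate_ipw(inc, pd.DataFrame({"z": z}), truncate_at=0.95)
        assert ipw.truncated.sum() > 0
        assert np.nanmax(ipw.weight) <= np.nanquantile(1.0 / ipw.probability[inc], 0.95) + 1e-9


class TestWeightedStructural:
    def test_unit_weights_reproduce_unweighted(self, structural_data):
        model, x, _, items = structural_data
        sub, xs = items.iloc[:600], x[:600]
        ru = fit_structural(sub, xs, "bifactor", item_blocks=model.item_blocks)
        rw = weighted_structural(sub, xs, "bifactor", np.ones(600),
                                 item_blocks=model.item_blocks)
        assert np.abs(ru.table["beta"].to_numpy() - rw.table["beta"].to_numpy()).max() < 1e-10
        assert np.abs(ru.table["se"].to_numpy() - rw.table["se"].to_numpy()).max() < 1e-10

    def test_weight_scale_invariance(self, structural_data):
        model, x, _, items = structural_data
        sub, xs = items.iloc[:600], x[:600]
        rng = np.random.default_rng(70)
        w = rng.uniform(0.5, 2.0, 600)
        r1 = weighted_structural(sub, xs, "bifactor", w,
                                 item_blocks=model.item_blocks, compute_se=False)
        r2 = weighted_structural(sub, xs, "bifactor", 2.0 * w,
                                 item_blocks=model.item_blocks, compute_se=False)
        assert np.abs(r1.gamma - r2.gamma).max() < 1e-8

    def test_nonpositive_weights_rejected(self, structural_data):
        model, x, _, items = structural_data
        with pytest.raises(ValueError, match="positive"):
            weighted_structural(items.iloc[:100], x[:100], "bifactor",
                                np.zeros(100), item_blocks=model.item_blocks)
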