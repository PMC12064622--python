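"""Graded response model: probabilities, scoring, curves, estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import norm

from difverse.data import (
    GroupDistribution,
    ItemParameters,
    ItemParameterSet,
    ResponseMatrix,
    StudyFrame,
    ValidationError,
)
from difverse.grm import (
    GradedResponseModel,
    MultigroupGRM,
    _log_prob_table,
    category_response_prob,
    eap_score,
    expected_item_score,
    item_information,
)
from difverse.grm import test_characteristic_curve as characteristic_curve
from difverse.grm import test_information as information_curves
from difverse.simulate import (
    GroupSpec,
    SimulationConfig,
    simulate_item_bank,
    simulate_responses,
)


class TestCategoryProbabilities:
    def test_dichotomous_item_at_its_location_splits_evenly(self):
        p = category_response_prob(ItemParameters("x", 1.0, (0.0,)), 0.0)
        assert np.allclose(p, [0.5, 0.5])

    def test_extreme_trait_concentrates_in_top_category(self):
        p = category_response_prob(ItemParameters("x", 2.0, (-1.0, 1.0)), 30.0)
        assert p[-1] > 1 - 1e-10

    def test_middle_category_probability_matches_logistic_difference(self):
        # P(X=1) = logistic(2) - logistic(-2) for a=2, b=(-1, 1), theta=0
        p = category_response_prob(ItemParameters("x", 2.0, (-1.0, 1.0)), 0.0)
        expected = 1 / (1 + np.exp(-2)) - 1 / (1 + np.exp(2))
        assert p[1] == pytest.approx(expected, abs=1e-12)
        assert p[1] == pytest.approx(0.7616, abs=5e-5)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ItemParameters("x", 1.0, (1.0, -1.0))

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValidationError):
            ItemParameters("x", 0.0, (0.0,))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.floats(0.3, 3.0),
        b1=st.floats(-3, 2),
        gaps=st.lists(st.floats(0.1, 1.5), min_size=1, max_size=4),
        theta=st.floats(-8, 8),
    )
    def test_probabilities_normalize_and_cumulative_decreases(self, a, b1, gaps, theta):
        b = tuple(b1 + np.cumsum([0] + gaps))
        item = ItemParameters("h", a, b)
        p = category_response_prob(item, theta)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12
        # survival P(X >= k) decreasing in k
        surv = 1.0 - np.cumsum(p)[:-1]
        assert np.all(np.diff(surv) <= 1e-12)

    def test_cumulative_increases_with_theta(self):
        item = ItemParameters("x", 1.5, (-0.5, 0.4, 1.2))
        th = np.linspace(-6, 6, 41)
        P = category_response_prob(item, th)
        surv_top = P[:, -1]
        assert np.all(np.diff(surv_top) > 0)


class TestEAPScoring:
    def test_all_missing_row_returns_prior(self, small_bank):
        row = pd.DataFrame(
            [[np.nan] * len(small_bank.item_ids)], columns=small_bank.item_ids, index=["p0"]
        )
        sc = eap_score(row, small_bank)
        assert sc.loc["p0", "theta"] == pytest.approx(0.0, abs=1e-10)
        assert sc.loc["p0", "se"] == pytest.approx(1.0, abs=1e-3)
        assert sc.loc["p0", "t_score"] == pytest.approx(50.0, abs=1e-8)

    def test_matches_fine_grid_integration(self, small_bank, rng):
        """EAP on the default grid equals 10,001-point numeric integration."""
        cfg = SimulationConfig(
            n_items=12, n_categories=5, groups=(GroupSpec("G", 100),), seed=5
        )
        resp, _, _ = simulate_responses(small_bank, cfg)
        sc = eap_score(resp, small_bank)
        fine = np.linspace(-8, 8, 10001)
        pm = small_bank.for_group(None)
        X = resp.values
        for pid in X.index[:100]:
            ll = np.zeros(fine.size)
            for it in X.columns:
                x = X.loc[pid, it]
                if np.isnan(x):
                    continue
                ll += _log_prob_table(pm[it].a, np.asarray(pm[it].b), fine, 1.0)[int(x)]
            w = np.exp(ll + norm.logpdf(fine))
            w /= w.sum()
            m1 = w @ fine
            sd = np.sqrt(w @ fine**2 - m1**2)
            assert sc.loc[pid, "theta"] == pytest.approx(m1, abs=1e-4)
            assert sc.loc[pid, "se"] == pytest.approx(sd, abs=1e-4)

    def test_top_pattern_scores_above_bottom_pattern(self, small_bank):
        items = small_bank.item_ids
        top = [[small_bank.n_categories(i) - 1 for i in items]]
        bottom = [[0 for _ in items]]
        df = pd.DataFrame(top + bottom, columns=items, index=["hi", "lo"])
        sc = eap_score(df, small_bank)
        assert sc.loc["hi", "theta"] > sc.loc["lo", "theta"]

    def test_t_score_is_affine_in_theta(self, small_bank, rng):
        cfg = SimulationConfig(
            n_items=12, n_categories=5, groups=(GroupSpec("G", 50),), seed=6
        )
        resp, _, _ = simulate_responses(small_bank, cfg)
        sc = eap_score(resp, small_bank)
        assert np.allclose(sc["t_score"], 50 + 10 * sc["theta"])


class TestTestLevelCurves:
    def test_expected_total_score_limits_and_monotonicity(self, small_bank):
        th = np.linspace(-30, 30, 101)
        tcc = characteristic_curve(small_bank, th)
        scores = tcc["expected_score"].to_numpy()
        max_score = sum(small_bank.n_categories(i) - 1 for i in small_bank.item_ids)
        assert scores[0] == pytest.approx(0.0, abs=1e-6)
        assert scores[-1] == pytest.approx(max_score, abs=1e-6)
        assert np.all(np.diff(scores) >= -1e-12)

    def test_single_symmetric_dichotomous_item_scores_half_at_location(self):
        params = ItemParameterSet([ItemParameters("d", 1.0, (0.0,))])
        tcc = characteristic_curve(params, [0.0])
        assert tcc["expected_score"].iloc[0] == pytest.approx(0.5)

    def test_two_item_curve_is_sum_of_item_expectations(self):
        i1 = ItemParameters("a", 1.3, (-0.7, 0.2, 0.9))
        i2 = ItemParameters("b", 2.1, (-1.2, 1.4))
        params = ItemParameterSet([i1, i2])
        th = np.linspace(-3, 3, 13)
        tcc = characteristic_curve(params, th)
        by_hand = expected_item_score(i1, th) + expected_item_score(i2, th)
        assert np.allclose(tcc["expected_score"], by_hand)

    def test_mismatched_group_item_sets_rejected(self):
        params = ItemParameterSet(
            [
                ItemParameters("a", 1.0, (0.0,), "G1"),
                ItemParameters("a", 1.0, (0.0,), "G2"),
                ItemParameters("b", 1.0, (0.0,), "G2"),
            ]
        )
        with pytest.raises(ValidationError):
            characteristic_curve(params, [0.0], groups=["G1", "G2"])

    def test_information_increases_with_discrimination_at_location(self):
        lo = item_information(ItemParameters("x", 1.0, (0.3,)), 0.3)
        hi = item_information(ItemParameters("x", 2.0, (0.3,)), 0.3)
        assert hi > lo

    def test_test_information_is_sum_of_item_informations(self, small_bank):
        th = np.linspace(-3, 3, 7)
        tif = information_curves(small_bank, th)
        total = tif[tif.item_id == "__total__"].set_index("theta")["information"]
        by_hand = sum(
            item_information(p, th) for p in small_bank.for_group(None).values()
        )
        assert np.allclose(total.loc[th].to_numpy(), by_hand)

    def test_dichotomous_information_reduces_to_2pl_closed_form(self):
        a, b = 1.7, -0.4
        th = np.linspace(-4, 4, 17)
        info = item_information(ItemParameters("x", a, (b,)), th)
        P = 1 / (1 + np.exp(-a * (th - b)))
        assert np.allclose(info, a**2 * P * (1 - P), atol=1e-12)


class TestEstimation:
    def test_parameter_recovery(self, recovery_data, recovery_fit):
        bank, _, _, _ = recovery_data
        est = recovery_fit.params.to_frame().set_index("item_id")
        tru = bank.to_frame().set_index("item_id").loc[est.index]
        assert np.corrcoef(est["a"], tru["a"])[0, 1] >= 0.90
        bcols = ["b1", "b2", "b3", "b4"]
        assert (
            np.corrcoef(
                est[bcols].to_numpy().ravel(), tru[bcols].to_numpy().ravel()
            )[0, 1]
            >= 0.95
        )

    def test_marginal_loglik_nondecreasing_over_em_cycles(self, recovery_fit):
        ll = np.asarray(recovery_fit.llf_history)
        assert np.all(np.diff(ll) >= -1e-6)

    def test_constant_item_rejected_by_name(self):
        df = pd.DataFrame(
            {"I1": [0, 0, 0, 0], "I2": [0, 1, 2, 1]},
            index=[f"p{i}" for i in range(4)],
        )
        with pytest.raises(ValidationError, match="I1"):
            GradedResponseModel(ResponseMatrix(df)).fit()

    def test_dichotomous_fit_agrees_with_direct_marginal_ml(self):
        """EM estimates match a direct joint maximizer of the marginal
        likelihood (an independent optimization route) within 0.05."""
        cfg = SimulationConfig(
            n_items=8, n_categories=2, groups=(GroupSpec("G", 1500),), seed=17,
            a_range=(0.8, 2.0), b_range=(-1.5, 1.5),
        )
        bank = simulate_item_bank(cfg)
        resp, _, _ = simulate_responses(bank, cfg)
        fit = GradedResponseModel(resp).fit()

        X = resp.values.to_numpy().astype(int)
        nodes = np.linspace(-6, 6, 61)
        logw = norm.logpdf(nodes)
        logw -= np.log(np.exp(logw).sum())

        def neg_marginal(v):
            a = np.exp(v[:8])
            b = v[8:]
            ll = np.zeros((X.shape[0], nodes.size))
            for j in range(8):
                tab = _log_prob_table(a[j], np.array([b[j]]), nodes, 1.0)
                ll += tab[X[:, j]]
            m = (ll + logw).max(axis=1, keepdims=True)
            return -float(
                np.sum(np.log(np.exp(ll + logw - m).sum(axis=1)) + m.ravel())
            )

        v0 = np.concatenate([np.zeros(8), np.zeros(8)])
        res = minimize(neg_marginal, v0, method="L-BFGS-B")
        a_ref, b_ref = np.exp(res.x[:8]), res.x[8:]
        est = fit.params.to_frame().set_index("item_id").sort_index()
        assert np.max(np.abs(est["a"].to_numpy() - a_ref)) < 0.05
        assert np.max(np.abs(est["b1"].to_numpy() - b_ref)) < 0.05


class TestMultigroupEstimation:
    def test_focal_mean_recovery(self):
        cfg = SimulationConfig(
            n_items=20,
            n_categories=5,
            groups=(GroupSpec("R", 1000), GroupSpec("F", 1000, theta_mean=0.5)),
            seed=3,
        )
        bank = simulate_item_bank(cfg)
        resp, study, _ = simulate_responses(bank, cfg)
        fit = MultigroupGRM(resp, study, reference_group="R").fit()
        assert fit.group_distributions["R"].mean == 0.0
        assert fit.group_distributions["R"].sd == 1.0
        assert abs(fit.group_distributions["F"].mean - 0.5) < 0.1

    def test_single_group_reduces_to_plain_fit(self, small_bank):
        cfg = SimulationConfig(
            n_items=12, n_categories=5, groups=(GroupSpec("Solo", 400),), seed=12
        )
        resp, study, _ = simulate_responses(small_bank, cfg)
        multi = MultigroupGRM(resp, study).fit()
        single = GradedResponseModel(resp).fit()
        a_multi = multi.params.to_frame().set_index("item_id")["a"]
        a_single = single.params.to_frame().set_index("item_id")["a"]
        assert np.allclose(a_multi, a_single, atol=1e-10)

    def test_person_order_invariance(self, small_bank):
        cfg = SimulationConfig(
            n_items=12,
            n_categories=5,
            groups=(GroupSpec("R", 300), GroupSpec("F", 300, theta_mean=0.3)),
            seed=13,
        )
        resp, study, _ = simulate_responses(small_bank, cfg)
        fit1 = MultigroupGRM(resp, study, reference_group="R").fit()
        perm = list(np.random.default_rng(0).permutation(resp.persons))
        fit2 = MultigroupGRM(
            resp.subset_persons(perm), StudyFrame(study.frame.loc[perm]), reference_group="R"
        ).fit()
        assert np.allclose(
            fit1.params.to_frame()["a"], fit2.params.to_frame()["a"], atol=1e-10
        )
        assert fit1.group_distributions["F"].mean == pytest.approx(
            fit2.group_distributions["F"].mean, abs=1e-10
        )

    def test_empty_group_rejected(self, small_bank):
        cfg = SimulationConfig(
            n_items=12, n_categories=5, groups=(GroupSpec("R", 50),), seed=14
        )
        resp, study, _ = simulate_responses(small_bank, cfg)
        with pytest.raises(ValidationError):
            study.subset(["R", "Ghost"])
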