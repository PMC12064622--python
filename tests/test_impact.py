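"""Partial invariance, score agreement and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from difverse.data import ItemParameters, ItemParameterSet, ValidationError
from difverse.grm import MultigroupGRM, eap_score
from difverse.impact import (
    DIFImpact,
    bland_altman,
    cohens_d,
    partial_invariance_fit,
    reference_weights,
    score_compare,
    weighted_icc_difference,
)
from difverse.simulate import (
    DIFSpec,
    GroupSpec,
    SimulationConfig,
    inject_dif,
    simulate_responses,
)


class TestBlandAltman:
    def test_identical_vectors_give_zero_limits(self, rng):
        x = rng.normal(size=50)
        mean_diff, lo, hi, _ = bland_altman(x, x)
        assert (mean_diff, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset_gives_degenerate_limits(self, rng):
        x = rng.normal(size=50)
        mean_diff, lo, hi, _ = bland_altman(x + 2.0, x)
        assert mean_diff == pytest.approx(2.0)
        assert hi - lo == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_example(self):
        # differences (1, 2, 3): mean 2, sd 1, limits 2 -/+ 1.96
        mean_diff, lo, hi, table = bland_altman(
            np.array([1.0, 2.0, 3.0]), np.zeros(3)
        )
        assert mean_diff == pytest.approx(2.0)
        assert lo == pytest.approx(0.04)
        assert hi == pytest.approx(3.96)
        assert table["diff"].tolist() == [1.0, 2.0, 3.0]

    def test_limits_symmetric_about_mean(self, rng):
        a, b = rng.normal(size=200), rng.normal(size=200)
        mean_diff, lo, hi, _ = bland_altman(a, b)
        assert hi - mean_diff == pytest.approx(mean_diff - lo)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestCohensD:
    def test_equal_means_give_zero(self, rng):
        x = rng.normal(size=100)
        d, lo, hi = cohens_d(x, x.copy())
        assert d == 0.0
        assert lo < 0 < hi

    def test_hand_computed_example(self, rng):
        # d = 0.5 with n1 = n2 = 100: CI half-width 1.96*sqrt(.02 + .25/396)
        x1 = rng.normal(size=100)
        x1 = (x1 - x1.mean()) / x1.std(ddof=1) * 2.0 + 1.0  # mean 1, sd 2
        x2 = rng.normal(size=100)
        x2 = (x2 - x2.mean()) / x2.std(ddof=1) * 2.0  # mean 0, sd 2
        d, lo, hi = cohens_d(x1, x2)
        assert d == pytest.approx(0.5, abs=1e-10)
        half = 1.96 * np.sqrt(0.02 + 0.25 / 396)
        assert hi - d == pytest.approx(half, abs=1e-3)

    def test_swapping_groups_negates_and_mirrors(self, rng):
        x1, x2 = rng.normal(1, 1, 80), rng.normal(0, 1, 90)
        d1, lo1, hi1 = cohens_d(x1, x2)
        d2, lo2, hi2 = cohens_d(x2, x1)
        assert d2 == pytest.approx(-d1)
        assert lo2 == pytest.approx(-hi1)
        assert hi2 == pytest.approx(-lo1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d(np.ones(10), np.ones(10))


class TestWeightedICCDifference:
    def _params(self, shift=0.0, a=2.0):
        base = ItemParameters("X", a, (-1.0, -0.3, 0.4, 1.1))
        shifted = ItemParameters("X", a, tuple(np.array(base.b) + shift))
        return ItemParameterSet([base]), ItemParameterSet([shifted])

    def test_identical_parameters_give_zero(self):
        ref, _ = self._params()
        grid = np.linspace(-4, 4, 81)
        w = np.full(grid.size, 1 / grid.size)
        out = weighted_icc_difference(ref, ref, w, grid)
        assert out["X"] == 0.0

    def test_uniform_shift_matches_fine_grid_oracle(self):
        """delta = 0.5 threshold shift: value equals brute-force integration."""
        ref, foc = self._params(shift=0.5)
        grid = np.linspace(-4, 4, 161)
        w = np.exp(-0.5 * grid**2)
        w /= w.sum()
        out = weighted_icc_difference(ref, foc, w, grid)

        from difverse.grm import expected_item_score

        r = ref.for_group(None)["X"]
        f = foc.for_group(None)["X"]
        oracle = float(
            w @ np.abs(expected_item_score(r, grid) - expected_item_score(f, grid))
        )
        assert out["X"] == pytest.approx(oracle, abs=1e-6)
        assert 0 < out["X"] <= 4  # bounded by K-1

    def test_weight_grid_mismatch_rejected(self):
        ref, foc = self._params(0.5)
        with pytest.raises(ValidationError):
            weighted_icc_difference(ref, foc, np.ones(10), np.linspace(-4, 4, 11))

    def test_reference_weights_normalize(self, rng):
        grid = np.linspace(-4, 4, 33)
        w = reference_weights(rng.normal(size=500), grid)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()


@pytest.fixture(scope="module")
def shifted_study(small_bank):
    """Two groups; one focal item with +0.5 uniform threshold shift."""
    dif = (DIFSpec("I04", "F", "uniform", 0.5),)
    cfg = SimulationConfig(
        n_items=12,
        n_categories=5,
        groups=(GroupSpec("R", 1000), GroupSpec("F", 1000)),
        seed=404,
        dif=dif,
    )
    responses, study, _ = simulate_responses(inject_dif(small_bank, dif), cfg)
    return responses, study


class TestPartialInvariance:
    def test_empty_dif_set_reduces_to_multigroup_fit(self, shifted_study):
        responses, study = shifted_study
        full = MultigroupGRM(responses, study, reference_group="R").fit()
        partial = partial_invariance_fit(responses, study, (), reference_group="R")
        assert np.allclose(
            full.params.to_frame()["a"], partial.params.to_frame()["a"], atol=1e-10
        )

    def test_freeing_all_items_rejected(self, shifted_study):
        responses, study = shifted_study
        with pytest.raises(ValidationError, match="anchor"):
            partial_invariance_fit(
                responses, study, tuple(responses.items), reference_group="R"
            )

    def test_recovers_injected_threshold_shift(self, shifted_study):
        responses, study = shifted_study
        fit = partial_invariance_fit(
            responses, study, ("I04",), reference_group="R"
        )
        recs = {r.group: r for r in fit.params if r.item_id == "I04"}
        gap = np.mean(np.array(recs["F"].b) - np.array(recs["R"].b))
        assert gap == pytest.approx(0.5, abs=0.15)

    def test_anchor_parameters_identical_across_groups(self, shifted_study):
        responses, study = shifted_study
        fit = partial_invariance_fit(responses, study, ("I04",), reference_group="R")
        for item in responses.items:
            recs = [r for r in fit.params if r.item_id == item]
            if item == "I04":
                assert {r.group for r in recs} == {"R", "F"}
            else:
                assert len(recs) == 1 and recs[0].group is None


class TestScoreComparePipeline:
    def test_identical_parameter_sets_give_zero_differences(self, shifted_study, small_bank):
        responses, study = shifted_study
        paired = score_compare(responses, study, small_bank, small_bank)
        assert np.allclose(paired["diff"], 0.0)

    def test_null_study_pipeline_with_empty_flag_set_is_exact_zero(self, small_bank):
        """No injected DIF + empty flagged set: partial == full, bit-exact."""
        cfg = SimulationConfig(
            n_items=12,
            n_categories=5,
            groups=(GroupSpec("R", 400), GroupSpec("F", 400)),
            seed=405,
        )
        responses, study, _ = simulate_responses(small_bank, cfg)
        res = DIFImpact(responses, study, (), reference_group="R").fit()
        assert np.all(res.paired_scores["diff"].to_numpy() == 0.0)
        assert (res.mean_diff, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_differences_invariant_to_person_order(self, shifted_study, small_bank):
        responses, study = shifted_study
        paired = score_compare(responses, study, small_bank, small_bank)
        perm = list(np.random.default_rng(3).permutation(responses.persons))
        paired2 = score_compare(
            responses.subset_persons(perm),
            study,
            small_bank,
            small_bank,
        )
        assert np.allclose(
            paired.loc[perm, "diff"].to_numpy(), paired2["diff"].to_numpy()
        )

    def test_impact_report_invariants(self, shifted_study):
        responses, study = shifted_study
        res = DIFImpact(responses, study, ("I04",), reference_group="R").fit()
        assert res.loa_low <= res.mean_diff <= res.loa_high
        row = res.cohens_d.iloc[0]
        assert row["ci_low"] <= row["d"] <= row["ci_high"]
        # the shifted item carries the largest weighted ICC gap
        assert res.weighted_icc_diff.idxmax() == "I04"

    def test_higher_expected_scores_imply_underestimated_trait(self, shifted_study):
        """A group whose item curves sit higher at fixed theta gets its trait
        underestimated when scored with reference parameters."""
        responses, study = shifted_study
        fit = partial_invariance_fit(responses, study, ("I04",), reference_group="R")
        recs = {r.group: r for r in fit.params if r.item_id == "I04"}
        from difverse.grm import expected_item_score

        th = np.linspace(-2, 2, 41)
        # focal thresholds are higher (+0.5), so focal expected score is LOWER
        assert np.all(
            expected_item_score(recs["F"], th) <= expected_item_score(recs["R"], th)
        )
        # score focal persons' focal-model responses with reference params:
        # their trait is over-estimated relative to group-specific scoring
        from dataclasses import replace

        focal_persons = study.frame.index[study.group_of() == "F"]
        sub = responses.subset_persons(list(focal_persons)).subset_items(["I04"])
        ref_only = ItemParameterSet([replace(recs["R"], group=None)])
        foc_only = ItemParameterSet([replace(recs["F"], group=None)])
        s_ref = eap_score(sub, ref_only)
        s_foc = eap_score(sub, foc_only)
        assert s_ref["theta"].mean() < s_foc["theta"].mean()
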