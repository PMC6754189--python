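import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curtail.engine import (
    administer_cohort,
    administer_curtailed,
    administer_full,
    administer_sc,
    administer_short_form,
    outcomes_to_frame,
)
from curtail.instrument import ResponseError
from curtail.score_model import fit_item_model

from conftest import all_vectors, uniform_model


class TestFullLength:
    def test_minimum_total(self, soappr24):
        out = administer_full([0] * 24, soappr24)
        assert (out.classification, out.administered_length, out.score_at_stop) == (
            "low", 24, 0,
        )
        assert out.stopping_reason == "completed"

    def test_maximum_total(self, soappr24):
        out = administer_full([4] * 24, soappr24)
        assert (out.classification, out.score_at_stop) == ("high", 96)

    @pytest.mark.parametrize("total,expected", [(17, "low"), (18, "high")])
    def test_cutoff_boundary(self, soappr24, total, expected):
        vec = [4] * (total // 4) + [total % 4] + [0] * (24 - total // 4 - 1)
        assert administer_full(vec, soappr24).classification == expected

    def test_incomplete_vector_rejected(self, soappr24):
        with pytest.raises(ResponseError):
            administer_full([0] * 23, soappr24)

    def test_out_of_range_score_rejected(self, soappr24):
        with pytest.raises(ResponseError, match="item_1"):
            administer_full([5] + [0] * 23, soappr24)


class TestCurtailment:
    def test_all_max_stops_once_cutoff_reached(self, soappr24):
        out = administer_curtailed([4] * 24, soappr24)
        assert out.administered_length == 5  # ceil(18 / 4)
        assert out.score_at_stop == 20
        assert (out.classification, out.stopping_reason) == ("high", "certain_high")

    def test_all_zero_stops_when_cutoff_unreachable(self, soappr24):
        out = administer_curtailed([0] * 24, soappr24)
        assert out.administered_length == 20  # 0 + 4*4 = 16 < 18
        assert (out.classification, out.stopping_reason) == ("low", "certain_low")

    def test_score_13_after_23_items_forces_low_at_item_23(self, soappr24):
        # 13 + 4 < 18: impossible to reach high risk on the last item
        vec = [4, 4, 4, 1] + [0] * 19 + [4]
        out = administer_curtailed(vec, soappr24)
        assert out.administered_length == 23
        assert out.score_at_stop == 13
        assert (out.classification, out.stopping_reason) == ("low", "certain_low")

    def test_score_14_after_23_items_runs_to_completion(self, soappr24):
        vec = [4, 4, 4, 2] + [0] * 19 + [4]
        out = administer_curtailed(vec, soappr24)
        assert out.administered_length == 24
        assert out.stopping_reason == "completed"
        assert out.classification == "high"  # 14 + 4 = 18

    def test_exhaustive_equivalence_with_full_length(self, toy4):
        """All 81 vectors of the 4-item toy: classification always agrees."""
        for vec in all_vectors(toy4):
            full = administer_full(vec, toy4)
            curt = administer_curtailed(vec, toy4)
            assert curt.classification == full.classification
            assert curt.administered_length <= toy4.n_items
            if curt.administered_length == toy4.n_items:
                assert curt.stopping_reason == "completed"

    def test_cohort_equivalence_with_full_length(self, soappr24, cohort_seed42):
        full = administer_cohort(cohort_seed42, soappr24, "full")
        curt = administer_cohort(cohort_seed42, soappr24, "curtailment")
        assert [o.classification for o in full] == [o.classification for o in curt]


class TestStochasticCurtailment:
    def test_gamma_one_identical_to_curtailment_exhaustive(self, toy4, toy4_uniform_model):
        for vec in all_vectors(toy4):
            curt = administer_curtailed(vec, toy4)
            sc = administer_sc(vec, toy4, toy4_uniform_model, gamma=1.0)
            assert sc.classification == curt.classification
            assert sc.administered_length == curt.administered_length
            assert sc.stopping_reason == curt.stopping_reason
            assert sc.score_at_stop == curt.score_at_stop

    def test_toy_probability_no_stop_below_gamma(self, toy3, toy3_uniform_model):
        # after item 1 with score 1: p = P(two uniform items sum >= 3) = 3/9
        out = administer_sc([1, 2, 2], toy3, toy3_uniform_model, gamma=0.95)
        assert out.probability_trace[0] == pytest.approx(3 / 9)
        assert out.administered_length > 1

    def test_trace_values_and_bounds(self, soappr24, cohort_seed42):
        model = fit_item_model(cohort_seed42, soappr24)
        for row in cohort_seed42.scores[:50]:
            out = administer_sc(row, soappr24, model, gamma=0.95)
            assert all(0.0 <= p <= 1.0 for p in out.probability_trace)
            assert len(out.probability_trace) == out.administered_length
            cum = 0
            for k, p in enumerate(out.probability_trace, start=1):
                if k == soappr24.n_items:
                    break
                cum += int(row[k - 1])
                if cum >= soappr24.cutoff:
                    assert p == 1.0
                if cum + soappr24.max_remaining(k) < soappr24.cutoff:
                    assert p == 0.0

    def test_stops_no_later_than_curtailment(self, soappr24, cohort_seed42):
        model = fit_item_model(cohort_seed42, soappr24)
        for row in cohort_seed42.scores[:200]:
            curt = administer_curtailed(row, soappr24)
            for gamma in (0.95, 0.99):
                sc = administer_sc(row, soappr24, model, gamma=gamma)
                assert sc.administered_length <= curt.administered_length

    def test_length_monotone_in_gamma(self, soappr24, cohort_seed42):
        model = fit_item_model(cohort_seed42, soappr24)
        for row in cohort_seed42.scores[:200]:
            l95 = administer_sc(row, soappr24, model, gamma=0.95).administered_length
            l99 = administer_sc(row, soappr24, model, gamma=0.99).administered_length
            assert l95 <= l99

    def test_certainty_stops_agree_with_curtailment_classification(
        self, toy4, toy4_uniform_model
    ):
        for vec in all_vectors(toy4):
            sc = administer_sc(vec, toy4, toy4_uniform_model, gamma=0.95)
            if sc.stopping_reason in ("certain_high", "certain_low"):
                assert (
                    sc.classification
                    == administer_curtailed(vec, toy4).classification
                )

    @pytest.mark.parametrize("gamma", [0.5, 0.2, 0.0, 1.0001])
    def test_invalid_gamma_rejected(self, toy3, toy3_uniform_model, gamma):
        with pytest.raises(ValueError, match="gamma"):
            administer_sc([0, 0, 0], toy3, toy3_uniform_model, gamma=gamma)

    def test_model_shape_mismatch_rejected(self, soappr24, toy3_uniform_model):
        with pytest.raises(Exception, match="items"):
            administer_sc([0] * 24, soappr24, toy3_uniform_model, gamma=0.95)


class TestShortForm:
    def test_identity_subset_equals_full(self, soappr24, cohort_seed42):
        subset = tuple(range(1, 25))
        for row in cohort_seed42.scores[:100]:
            sf = administer_short_form(row, soappr24, subset, 18)
            full = administer_full(row, soappr24)
            assert sf.classification == full.classification
            assert sf.administered_length == 24

    def test_twelve_item_cutoff_boundary(self, soappr24):
        subset = tuple(range(1, 13))
        low = administer_short_form([0] * 24, soappr24, subset, 9)
        assert (low.classification, low.administered_length) == ("low", 12)
        vec = [4, 4, 1] + [0] * 21  # subset total exactly 9
        high = administer_short_form(vec, soappr24, subset, 9)
        assert high.classification == "high"
        assert high.score_at_stop == 9

    def test_duplicate_indices_rejected(self, soappr24):
        with pytest.raises(ValueError, match="duplicate"):
            administer_short_form([0] * 24, soappr24, (1, 1, 2), 3)

    def test_out_of_range_index_rejected(self, soappr24):
        with pytest.raises(ValueError, match="out of range"):
            administer_short_form([0] * 24, soappr24, (0, 1), 3)


class TestCohortAdministration:
    def test_unknown_method(self, soappr24, cohort_seed42):
        with pytest.raises(ValueError, match="unknown method"):
            administer_cohort(cohort_seed42, soappr24, "adaptive")

    def test_sc_requires_model_and_gamma(self, soappr24, cohort_seed42):
        with pytest.raises(ValueError, match="requires"):
            administer_cohort(cohort_seed42, soappr24, "sc")

    def test_outcome_frame_shape(self, soappr24, cohort_seed42):
        outcomes = administer_cohort(cohort_seed42, soappr24, "curtailment")
        df = outcomes_to_frame(outcomes, "curtailment")
        assert len(df) == cohort_seed42.n
        assert set(df["classification"]) <= {"high", "low"}
        assert (df["method"] == "curtailment").all()
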