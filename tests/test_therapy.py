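import numpy as np
import pytest

import cloneviz as cv
from conftest import random_instance


@pytest.fixture
def min_rule_case():
    """A with unique CCF 50 -> 10, child B with unique CCF 20 -> 60."""
    return cv.build_evolution(
        {"A": [70, 70], "B": [20, 60]}, {"A": "normal", "B": "A"}
    )


class TestEstimateTherapyEffect:
    def test_hand_trace_min_rule(self, min_rule_case):
        out = cv.estimate_therapy_effect(
            min_rule_case, cv.TherapyWindow(interval=(0, 1))
        )
        assert out.timepoint_kind == ("measured", "therapy", "measured")
        k = out.index
        assert out.ccf[k("B"), 1] == pytest.approx(20)
        assert out.ccf[k("A"), 1] == pytest.approx(30)  # 10 + 20

    def test_constant_unique_ccf_unchanged(self):
        evo = cv.build_evolution({"A": [40, 40]}, {"A": "normal"})
        out = cv.estimate_therapy_effect(evo, cv.TherapyWindow(interval=(0, 1)))
        assert out.ccf[0, 1] == pytest.approx(40)

    def test_new_clone_zero_at_therapy_point(self):
        evo = cv.build_evolution(
            {"A": [50, 60], "B": [0, 30]}, {"A": "normal", "B": "A"}
        )
        out = cv.estimate_therapy_effect(evo, cv.TherapyWindow(interval=(0, 1)))
        assert out.ccf[out.index("B"), 1] == pytest.approx(0)

    def test_default_position_no_new_clones_is_midpoint(self, min_rule_case):
        out = cv.estimate_therapy_effect(
            min_rule_case, cv.TherapyWindow(interval=(0, 1))
        )
        assert out.timepoints[1] == pytest.approx(0.5)

    def test_explicit_position(self, min_rule_case):
        out = cv.estimate_therapy_effect(
            min_rule_case, cv.TherapyWindow(interval=(0, 1), position=0.25)
        )
        assert out.timepoints[1] == pytest.approx(0.25)

    def test_position_validation(self):
        with pytest.raises(cv.UsageError):
            cv.TherapyWindow(interval=(0, 1), position=1.5)

    def test_non_adjacent_window_rejected(self):
        evo = cv.build_evolution({"A": [40, 50, 60]}, {"A": "normal"})
        with pytest.raises(cv.UsageError):
            cv.estimate_therapy_effect(evo, cv.TherapyWindow(interval=(0, 2)))

    def test_non_measured_endpoint_rejected(self):
        evo = cv.build_evolution(
            {"A": [40, 60], "B": [0, 20], "C": [0, 8]},
            {"A": "normal", "B": "A", "C": "B"},
        )
        interpolated = cv.interpolate_between(evo, (0, 1))
        with pytest.raises(cv.UsageError):
            cv.estimate_therapy_effect(
                interpolated, cv.TherapyWindow(interval=(0, 1))
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_min_property_and_burden(self, seed):
        evo = random_instance(seed, max_timepoints=5)
        if evo.n_timepoints < 2:
            pytest.skip("needs two measured time points")
        out = cv.estimate_therapy_effect(evo, cv.TherapyWindow(interval=(0, 1)))
        uccf_in = evo.unique_ccf_matrix()
        uccf_out = out.unique_ccf_matrix()
        tol = 1e-9
        for k in range(evo.n_clones):
            if evo.ccf[k, 0] > tol:
                assert uccf_out[k, 1] <= uccf_in[k, 0] + tol
                assert uccf_out[k, 1] <= uccf_in[k, 1] + tol
        founders = [out.index(f) for f in out.founders]
        burden = out.ccf[founders].sum(axis=0)
        assert burden[1] <= burden[0] + tol
        assert burden[1] <= burden[2] + tol

    @pytest.mark.parametrize("seed", range(20))
    def test_outputs_valid_and_measured_unchanged(self, seed):
        evo = random_instance(seed, max_timepoints=5)
        if evo.n_timepoints < 2:
            pytest.skip("needs two measured time points")
        out = cv.apply_therapy(evo, cv.TherapyWindow(interval=(0, 1)))
        report = cv.check_validity(out.ccf, out.parents, out.clone_labels)
        assert report.passed, report.to_json_lines()
        measured = [
            i for i, k in enumerate(out.timepoint_kind) if k == cv.MEASURED
        ]
        np.testing.assert_array_equal(out.ccf[:, measured], evo.ccf)


class TestRecalculatedLevels:
    @pytest.fixture
    def chain_plus_founder(self):
        # NORMAL -> A -> B -> C plus independent founder D;
        # C and D appear only at the second time point
        return cv.build_evolution(
            {"A": [60, 70], "B": [40, 50], "C": [0, 20], "D": [0, 10]},
            {"A": "normal", "B": "A", "C": "B", "D": "normal"},
        )

    def test_deep_clone_with_surviving_ancestors(self, chain_plus_founder):
        recalc = cv.recalculated_nested_levels(chain_plus_founder, {"A", "B"})
        assert recalc["C"] == 0
        assert chain_plus_founder.nested_level("C") == 2

    def test_new_founder(self, chain_plus_founder):
        recalc = cv.recalculated_nested_levels(chain_plus_founder, {"A", "B"})
        assert recalc["D"] == 0

    def test_new_chain_keeps_relative_depth(self):
        evo = cv.build_evolution(
            {"A": [60, 70], "B": [40, 50], "C": [0, 20], "E": [0, 5]},
            {"A": "normal", "B": "A", "C": "B", "E": "C"},
        )
        recalc = cv.recalculated_nested_levels(evo, {"A", "B"})
        assert recalc["C"] == 0
        assert recalc["E"] == 1

    @pytest.mark.parametrize("seed", range(15))
    def test_bounded_by_nested_level(self, seed):
        evo = random_instance(seed)
        rng = np.random.default_rng(seed)
        present = {
            lab for lab in evo.clone_labels if rng.random() < 0.5
        }
        recalc = cv.recalculated_nested_levels(evo, present)
        for lab, level in recalc.items():
            assert level <= evo.nested_level(lab)
            if not any(a in present for a in evo.ancestors(lab)):
                assert level == evo.nested_level(lab)


class TestInterpolatePostTherapy:
    @pytest.fixture
    def rich_case(self):
        """Survivors A/B; new chain C -> E under B; new childless founder D."""
        return cv.build_evolution(
            {
                "A": [60, 70],
                "B": [40, 40],
                "C": [0, 20],
                "E": [0, 5],
                "D": [0, 30],
            },
            {"A": "normal", "B": "A", "C": "B", "E": "C", "D": "normal"},
        )

    def test_insertion_count_and_positions(self, rich_case):
        out = cv.apply_therapy(rich_case, cv.TherapyWindow(interval=(0, 1)))
        # therapy point + 1 interpolated point divide the interval in thirds
        assert out.timepoint_kind == (
            "measured",
            "therapy",
            "interpolated",
            "measured",
        )
        np.testing.assert_allclose(out.timepoints, [0, 1 / 3, 2 / 3, 1])

    def test_childless_new_founder_linear(self, rich_case):
        out = cv.apply_therapy(rich_case, cv.TherapyWindow(interval=(0, 1)))
        k = out.index
        # D: recalculated level 0, childless -> linear from therapy point
        assert out.ccf[k("D"), 1] == pytest.approx(0)
        assert out.ccf[k("D"), 2] == pytest.approx(15)

    def test_new_clone_with_children_holds_unique_ccf(self, rich_case):
        out = cv.apply_therapy(rich_case, cv.TherapyWindow(interval=(0, 1)))
        uccf = out.unique_ccf_matrix()
        k = out.index
        # C active at the inserted point, unique CCF pinned to its end value
        assert uccf[k("C"), 2] == pytest.approx(15)  # 20 - 5
        assert out.ccf[k("E"), 2] == pytest.approx(0)  # staged one step later

    def test_no_new_clones_is_noop(self, min_rule_case=None):
        evo = cv.build_evolution(
            {"A": [70, 70], "B": [20, 60]}, {"A": "normal", "B": "A"}
        )
        with_tp = cv.estimate_therapy_effect(
            evo, cv.TherapyWindow(interval=(0, 1))
        )
        assert cv.interpolate_post_therapy(with_tp) is with_tp

    def test_requires_therapy_point(self):
        evo = cv.build_evolution({"A": [40, 50]}, {"A": "normal"})
        with pytest.raises(cv.UsageError):
            cv.interpolate_post_therapy(evo)
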