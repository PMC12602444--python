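"""Transfer inference: ratio, detection, net bootstrap, patterns, ANOVA."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mycoflux.inference import (
    ConfigurationError,
    InferenceError,
    NetDirection,
    TransferPattern,
    UndefinedRatioError,
    classify_pattern,
    compare_groups,
    detect_transfer,
    net_transfer,
    percent_transferred,
)
from mycoflux.units import Element


class TestPercentTransferred:
    @pytest.mark.parametrize(
        "transferred, assimilated, expected",
        [
            (10.0, 190.0, 5.0),
            (0.0, 123.0, 0.0),
            (7.5, 0.0, 100.0),
        ],
    )
    def test_known_values(self, transferred, assimilated, expected):
        assert percent_transferred(transferred, assimilated) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            percent_transferred(0.0, 0.0)

    def test_flagged_negative_floored_to_zero(self):
        assert percent_transferred(-3.0, 100.0) == 0.0

    @given(st.floats(0.001, 1e6), st.floats(0.001, 1e6), st.floats(1.01, 3))
    def test_monotonicity(self, t, a, factor):
        base = percent_transferred(t, a)
        assert percent_transferred(t * factor, a) > base
        assert percent_transferred(t, a * factor) < base
        assert 0.0 <= base <= 100.0


class TestDetectTransfer:
    def test_zero_ape_never_detected(self):
        res = detect_transfer(
            [0.0, 0.0], [1.0, 1.0], [1e-6, 2e-6], 0.15, Element.N15, 0.0037
        )
        assert not res.detected
        assert res.threshold > 0

    def test_far_above_threshold_detected(self):
        res = detect_transfer(
            [5e-5], [1.0], [1e-7], 0.15, Element.C13, 0.011
        )
        assert res.detected  # ~15x the analytical-floor threshold
        assert res.weighted_mean_ape == pytest.approx(5e-5)

    def test_exactly_at_threshold_not_detected(self):
        # strict inequality tie-break: APE == T is not a detection
        ctrl_sd = 1e-6
        res = detect_transfer([2 * ctrl_sd], [1.0], [ctrl_sd], None, None, 0.0)
        assert res.threshold == pytest.approx(2 * ctrl_sd)
        assert not res.detected

    def test_threshold_is_max_of_analytical_and_control_terms(self):
        only_ctrl = detect_transfer([0.0], [1.0], [1e-5], None, None, 0.0)
        both = detect_transfer([0.0], [1.0], [1e-5], 0.15, Element.C13, 0.011)
        assert both.threshold == pytest.approx(only_ctrl.threshold)  # control dominates
        analytical = detect_transfer([0.0], [1.0], [0.0], 0.15, Element.C13, 0.011)
        assert 0 < analytical.threshold < only_ctrl.threshold

    def test_no_noise_information_is_an_error(self):
        with pytest.raises(ConfigurationError):
            detect_transfer([1e-5], [1.0], None, None, None, 0.0)


class TestNetTransfer:
    def test_identical_samples_give_zero_estimate_spanning_ci(self):
        x = [3.0, 4.0, 5.0, 4.5]
        res = net_transfer(x, x, n_boot=2000, seed=0)
        assert res.estimate_ug == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_clear_one_sided_difference_excludes_zero(self):
        res = net_transfer([10, 11, 9, 10], [0.0, 0.0, 0.0, 0.0], n_boot=2000, seed=1)
        assert res.estimate_ug == pytest.approx(10.0)
        assert res.excludes_zero
        assert res.ci_low > 0

    def test_antisymmetric_under_same_seed(self):
        a, b = [1.0, 5.0, 3.0, 2.0], [0.5, 0.1, 0.9, 0.4]
        fwd = net_transfer(a, b, n_boot=2000, seed=7)
        bwd = net_transfer(b, a, n_boot=2000, seed=7)
        assert fwd.estimate_ug == -bwd.estimate_ug
        assert fwd.ci_low == -bwd.ci_high
        assert fwd.ci_high == -bwd.ci_low

    def test_single_replicate_flags_ci_unavailable(self):
        res = net_transfer([5.0], [1.0, 2.0], seed=0)
        assert not res.ci_available
        assert not res.excludes_zero

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning):
            net_transfer([1, 2, 3], [1, 2, 3], n_boot=50, seed=0)

    def test_empty_direction_raises(self):
        with pytest.raises(InferenceError):
            net_transfer([], [1.0, 2.0])


class TestClassifyPattern:
    def _net(self, estimate, lo, hi):
        from mycoflux.inference import NetTransferResult

        return NetTransferResult(estimate, lo, hi, 1000, 0.05)

    def test_neither_detected_is_none(self):
        pat = classify_pattern(False, False, None, Element.N15)
        assert pat.pattern is TransferPattern.NONE
        assert pat.net_direction is NetDirection.NONE

    def test_single_direction_is_unidirectional(self):
        pat = classify_pattern(True, False, None, Element.N15)
        assert pat.pattern is TransferPattern.UNIDIRECTIONAL
        assert pat.net_direction is NetDirection.ORCHID_TO_PINE

    def test_both_detected_ci_spanning_zero_is_no_net(self):
        pat = classify_pattern(True, True, self._net(0.3, -1.0, 1.5), Element.N15)
        assert pat.pattern is TransferPattern.BIDIRECTIONAL_NO_NET
        assert pat.net_direction is NetDirection.NONE

    def test_both_detected_with_net_uses_sign(self):
        pat = classify_pattern(True, True, self._net(-4.0, -6.0, -2.0), Element.C13)
        assert pat.pattern is TransferPattern.BIDIRECTIONAL_NET
        assert pat.net_direction is NetDirection.PINE_TO_ORCHID

    def test_both_detected_without_net_result_raises(self):
        with pytest.raises(ConfigurationError):
            classify_pattern(True, True, None, Element.C13)

    def test_exhaustive_and_deterministic_over_verdict_space(self):
        nets = [self._net(2.0, 1.0, 3.0), self._net(0.1, -1.0, 1.0), None]
        for d_ab, d_ba, net in itertools.product([False, True], [False, True], nets):
            if d_ab and d_ba and net is None:
                continue  # covered by the error-path test
            pat1 = classify_pattern(d_ab, d_ba, net, Element.N15)
            pat2 = classify_pattern(d_ab, d_ba, net, Element.N15)
            assert pat1 == pat2
            assert pat1.pattern in TransferPattern
            if pat1.pattern in (TransferPattern.NONE, TransferPattern.BIDIRECTIONAL_NO_NET):
                assert pat1.net_direction is NetDirection.NONE
            else:
                assert pat1.net_direction is not NetDirection.NONE


class TestCompareGroups:
    def test_identical_null_groups_usually_share_letters(self):
        rng = np.random.default_rng(0)
        shared = 0
        trials = 200
        for _ in range(trials):
            groups = {k: rng.normal(0, 1, 4) for k in "abc"}
            res = compare_groups(groups)
            letters = set(res.letters.values())
            shared += len(letters) == 1
        assert shared / trials >= 0.90

    def test_separated_groups_get_distinct_letters(self):
        res = compare_groups(
            {"zero": [0.0, 0.0, 0.1, 0.0], "high": [100.0, 101.0, 99.0, 100.0]}
        )
        assert res.significant
        assert res.letters["zero"] != res.letters["high"]

    def test_duplicated_group_shares_a_letter(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        res = compare_groups(
            {"a": vals, "b": vals, "far": [50.0, 51.0, 49.0, 50.5]}
        )
        assert set(res.letters["a"]) & set(res.letters["b"])
        assert not set(res.letters["a"]) & set(res.letters["far"])

    def test_group_with_single_value_raises(self):
        with pytest.raises(InferenceError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    def test_precheck_failures_are_warnings_not_errors(self):
        # wildly unequal variances should trip Levene but still return a result
        res = compare_groups(
            {"tight": [1.0, 1.001, 0.999, 1.0], "wide": [0.0, 100.0, -100.0, 50.0]}
        )
        assert res.levene_p is not None
        assert isinstance(res.warnings, tuple)
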