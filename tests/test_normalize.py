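"""Normalization methods against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mlpacall as m
from mlpacall.errors import FitError, MethodPreconditionError


def brute_force_sum_peaks(intensities, ref_mask, scope):
    """Independent recomputation with explicit loops (no shared code).

    Replicate-free experiments only: one divisor per run.
    """
    n_probes, n_runs = intensities.shape
    out = np.empty_like(intensities)
    for j in range(n_runs):
        divisor = 0.0
        for i in range(n_probes):
            if scope == "all" or ref_mask[i]:
                divisor += intensities[i, j]
        for i in range(n_probes):
            out[i, j] = intensities[i, j] / divisor
    return out


def brute_force_slope(intensities, sizes, ref_mask):
    n_probes, n_runs = intensities.shape
    out = np.empty_like(intensities)
    xs = [sizes[i] for i in range(n_probes) if ref_mask[i]]
    for j in range(n_runs):
        ys = [intensities[i, j] for i in range(n_probes) if ref_mask[i]]
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        sxx = sum((x - mx) ** 2 for x in xs)
        b = sxy / sxx
        a = my - b * mx
        for i in range(n_probes):
            out[i, j] = intensities[i, j] / (a + b * sizes[i])
    return out


def small_experiment(values_ctrl, values_case, sizes, refs):
    return m.setup_experiment(values_ctrl, values_case, sizes, refs)


class TestSumPeaks:
    def test_hand_computed_divisor(self):
        # peaks [2, 4, 6], references {P001, P002}: divisor = 6
        exp = small_experiment([[2.0], [4.0], [6.0]], [[2.0], [4.0], [6.0]],
                               [100, 200, 300], ["P001", "P002"])
        norm = m.normalize_sum_peaks(exp, scope="reference_only")
        np.testing.assert_allclose(norm.experiment.intensities[:, 0], [1 / 3, 2 / 3, 1.0])
        assert norm.fit_params["divisors"]["control_1"] == 6.0

    def test_unit_divisor_is_identity(self):
        exp = small_experiment([[0.25], [0.75], [5.0]], [[0.25], [0.75], [5.0]],
                               [100, 200, 300], ["P001", "P002"])
        norm = m.normalize_sum_peaks(exp, scope="reference_only")
        np.testing.assert_array_equal(norm.experiment.intensities, exp.intensities)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for scope, scope_bf in (("reference_only", "ref"), ("all_probes", "all")):
            vals_c = rng.uniform(1, 100, size=(5, 2))
            vals_s = rng.uniform(1, 100, size=(5, 1))
            exp = small_experiment(vals_c, vals_s, [50, 100, 150, 200, 250], ["P001", "P004"])
            norm = m.normalize_sum_peaks(exp, scope=scope)
            expected = brute_force_sum_peaks(exp.intensities, exp.panel.is_reference, scope_bf)
            np.testing.assert_allclose(norm.experiment.intensities, expected, rtol=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_scale_invariance_per_run(self, c):
        exp = small_experiment([[2.0], [4.0], [6.0]], [[3.0], [5.0], [7.0]],
                               [100, 200, 300], ["P001", "P002"])
        scaled = exp.with_intensities(exp.intensities * np.array([c, 1.0]))
        base = m.normalize_sum_peaks(exp, scope="reference_only").experiment.intensities
        out = m.normalize_sum_peaks(scaled, scope="reference_only").experiment.intensities
        np.testing.assert_allclose(out, base, rtol=1e-12)

    def test_scale_invariance_power_of_two_bitwise(self):
        exp = small_experiment([[2.3], [4.1], [6.7]], [[3.9], [5.2], [7.1]],
                               [100, 200, 300], ["P001", "P002"])
        scaled = exp.with_intensities(exp.intensities * np.array([0.25, 64.0]))
        base = m.normalize_sum_peaks(exp, scope="all_probes").experiment.intensities
        out = m.normalize_sum_peaks(scaled, scope="all_probes").experiment.intensities
        np.testing.assert_array_equal(out, base)

    def test_replicates_share_subject_divisor(self):
        # two replicate runs of one control subject; the divisor comes from
        # the replicate-mean profile and is applied to both runs
        exp = m.setup_experiment(
            np.array([[2.0, 4.0], [6.0, 2.0]]),
            np.array([[3.0], [5.0]]),
            [100, 200],
            ["P001", "P002"],
            replicate_map={"control_1": ("c1", 1), "control_2": ("c1", 2)},
        )
        norm = m.normalize_sum_peaks(exp, scope="reference_only")
        # replicate means: [3, 4] -> divisor 7 for both runs of c1
        assert norm.fit_params["divisors"]["c1"] == 7.0
        np.testing.assert_allclose(norm.experiment.intensities[:, 0], [2 / 7, 6 / 7])
        np.testing.assert_allclose(norm.experiment.intensities[:, 1], [4 / 7, 2 / 7])

    def test_zero_divisor_raises(self):
        exp = small_experiment([[0.0], [4.0]], [[1.0], [1.0]], [100, 200], ["P001"])
        with pytest.raises(FitError, match="zero divisor"):
            m.normalize_sum_peaks(exp, scope="reference_only")

    def test_invalid_probe_excluded_from_all_probes_divisor(self):
        exp = small_experiment([[2.0], [0.0], [4.0]], [[2.0], [0.0], [4.0]],
                               [100, 200, 300], ["P001"])
        norm = m.normalize_sum_peaks(exp, scope="all_probes")
        assert norm.fit_params["divisors"]["control_1"] == 6.0

    def test_renormalizing_is_a_fixed_point(self):
        # the divisor of a sum-peaks-controls-normalized run is exactly 1
        exp, _ = m.simulate_experiment(m.SimConfig(seed=3))
        once = m.normalize_sum_peaks(exp, scope="reference_only")
        twice = m.normalize_sum_peaks(once.experiment, scope="reference_only")
        for divisor in twice.fit_params["divisors"].values():
            assert divisor == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            twice.experiment.intensities, once.experiment.intensities, rtol=1e-12
        )


class TestSlopeCorrection:
    def test_flat_reference_line_divides_by_constant(self):
        exp = small_experiment([[5.0], [5.0], [3.0]], [[5.0], [5.0], [3.0]],
                               [100, 200, 300], ["P001", "P002"])
        norm = m.normalize_slope(exp)
        np.testing.assert_allclose(norm.experiment.intensities[:, 0], [1.0, 1.0, 0.6])

    def test_noiseless_trend_removed(self):
        sizes = np.linspace(90, 500, 20)
        profile = 10.0 - 0.01 * sizes
        refs = [f"P{i + 1:03d}" for i in range(0, 20, 3)]
        exp = small_experiment(profile[:, None], profile[:, None], sizes, refs)
        norm = m.normalize_slope(exp)
        ref_mask = norm.experiment.panel.is_reference
        # oracle: refit OLS on normalized reference intensities vs size
        slope = np.polyfit(sizes[ref_mask], norm.experiment.intensities[ref_mask, 0], 1)[0]
        assert abs(slope) < 1e-8
        np.testing.assert_allclose(norm.experiment.intensities[ref_mask, 0], 1.0, rtol=1e-10)

    def test_different_trends_same_profile_agree(self):
        sizes = np.linspace(100, 400, 10)
        refs = [f"P{i + 1:03d}" for i in range(10)][::2]
        a = (20.0 - 0.02 * sizes)[:, None]
        b = (8.0 - 0.005 * sizes)[:, None]
        exp = small_experiment(np.column_stack([a, b]), a, sizes, refs)
        norm = m.normalize_slope(exp)
        np.testing.assert_allclose(
            norm.experiment.intensities[:, 0], norm.experiment.intensities[:, 1], rtol=1e-10
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(22)
        vals_c = rng.uniform(50, 100, size=(5, 2))
        vals_s = rng.uniform(50, 100, size=(5, 1))
        sizes = [50.0, 100.0, 150.0, 200.0, 250.0]
        exp = small_experiment(vals_c, vals_s, sizes, ["P001", "P003", "P005"])
        norm = m.normalize_slope(exp)
        expected = brute_force_slope(exp.intensities, np.array(sizes), exp.panel.is_reference)
        np.testing.assert_allclose(norm.experiment.intensities, expected, rtol=1e-12)

    def test_degenerate_fits_rejected(self):
        exp = small_experiment([[1.0], [2.0], [3.0]], [[1.0], [2.0], [3.0]],
                               [100, 100, 300], ["P001", "P002"])
        with pytest.raises(FitError, match="reference probe sizes"):
            m.normalize_slope(exp)
        single_ref = small_experiment([[1.0], [2.0]], [[1.0], [2.0]], [100, 200], ["P001"])
        with pytest.raises(MethodPreconditionError):
            m.normalize_slope(single_ref)

    def test_negative_fitted_value_reported_with_probe(self):
        # steep decay makes the fitted line negative at the largest probe
        sizes = [100.0, 150.0, 200.0, 800.0]
        vals = np.array([[10.0], [5.0], [0.5], [0.2]])
        exp = small_experiment(vals, vals, sizes, ["P001", "P002", "P003"])
        with pytest.raises(FitError, match="P004"):
            m.normalize_slope(exp)


class TestNonlinear:
    @staticmethod
    def _decay_experiment(amp=900.0, rate=0.005, n=12, n_ref=6, reps=2):
        sizes = np.linspace(90, 480, n)
        profile = amp * np.exp(-rate * sizes)
        refs = [f"P{i + 1:03d}" for i in np.linspace(0, n - 1, n_ref).astype(int)]
        ctrl = np.column_stack([profile] * reps)
        case = np.column_stack([profile] * reps)
        rep_map = {}
        for r in range(reps):
            rep_map[f"control_{r + 1}"] = ("c1", r + 1)
            rep_map[f"case_{r + 1}"] = ("s1", r + 1)
        return m.setup_experiment(ctrl, case, sizes, refs, replicate_map=rep_map)

    def test_parameter_recovery_on_noiseless_decay(self):
        amp, rate = 900.0, 0.005
        exp = self._decay_experiment(amp, rate)
        norm = m.normalize_nonlinear(exp)
        for unit, fit in norm.fit_params["per_unit"].items():
            assert fit["amplitude"] == pytest.approx(amp, rel=1e-6)
            assert fit["rate"] == pytest.approx(rate, rel=1e-6)
        ref_mask = norm.experiment.panel.is_reference
        np.testing.assert_allclose(norm.experiment.intensities[ref_mask, :], 1.0, rtol=1e-8)

    def test_decay_free_limit_matches_flat_slope_case(self):
        exp = self._decay_experiment(amp=50.0, rate=0.0)
        norm = m.normalize_nonlinear(exp)
        np.testing.assert_allclose(norm.experiment.intensities, exp.intensities / 50.0, rtol=1e-8)
        for fit in norm.fit_params["per_unit"].values():
            assert fit["rate"] == pytest.approx(0.0, abs=1e-10)

    def test_refused_without_replicates(self, demo_experiment):
        with pytest.raises(MethodPreconditionError, match="requires replicates"):
            m.normalize_nonlinear(demo_experiment)

    def test_requires_three_reference_probes(self):
        exp = m.setup_experiment(
            np.ones((3, 2)), np.ones((3, 1)), [100, 200, 300], ["P001", "P002"],
            replicate_map={"control_1": ("c1", 1), "control_2": ("c1", 2)},
        )
        with pytest.raises(MethodPreconditionError, match="3 reference"):
            m.normalize_nonlinear(exp)

    def test_weighted_fit_tolerates_noisy_replicates(self):
        rng = np.random.default_rng(9)
        cfg = m.SimConfig(n_replicates=3, seed=14)
        exp, _ = m.simulate_experiment(cfg)
        norm = m.normalize_nonlinear(exp)
        fits = norm.fit_params["per_unit"]
        rates = [f["rate"] for f in fits.values()]
        assert np.allclose(rates, cfg.decay_rate, rtol=0.25)
        ref_mask = norm.experiment.panel.is_reference
        ref_means = norm.experiment.intensities[ref_mask, :].mean()
        assert ref_means == pytest.approx(1.0, rel=0.05)


class TestCollapseReplicates:
    def test_hand_computed_mean_and_sd(self):
        exp = m.setup_experiment(
            np.array([[3.0, 5.0]]), np.array([[4.0]]), [100], [],
            replicate_map={"control_1": ("c1", 1), "control_2": ("c1", 2)},
        )
        means, sds = m.collapse_replicates(exp)
        assert means.loc["P001", "c1"] == 4.0
        assert sds.loc["P001", "c1"] == pytest.approx(np.sqrt(2.0))

    def test_identical_replicates_have_zero_sd(self):
        exp = m.setup_experiment(
            np.array([[5.0, 5.0]]), np.array([[4.0]]), [100], [],
            replicate_map={"control_1": ("c1", 1), "control_2": ("c1", 2)},
        )
        _, sds = m.collapse_replicates(exp)
        assert sds.loc["P001", "c1"] == 0.0

    def test_single_run_subject_flagged_undefined(self, tiny_experiment):
        means, sds = m.collapse_replicates(tiny_experiment)
        np.testing.assert_array_equal(means.to_numpy(), tiny_experiment.intensities)
        assert sds.isna().all().all()


class TestDispatcher:
    @pytest.mark.parametrize(
        "alias,canonical",
        [
            ("sum.peaks.controls", "sum_peaks_controls"),
            ("sums.peaks.controls", "sum_peaks_controls"),
            ("SUM.PEAKS.ALL", "sum_peaks_all"),
            ("slope.correction", "slope_correction"),
        ],
    )
    def test_method_aliases(self, demo_experiment, alias, canonical):
        assert m.normalize(demo_experiment, alias).method == canonical

    def test_unknown_method_lists_options(self, demo_experiment):
        with pytest.raises(m.ValidationError, match="sum.peaks.controls"):
            m.normalize(demo_experiment, "bogus")
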