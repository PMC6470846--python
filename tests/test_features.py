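import itertools

import numpy as np
import pytest

from fallkit import (AccelRecording, NormFallTemplate, SliceFeaturizer,
                     compute_rss, estimate_norm_template, extract_features,
                     max_convolution, parametric_norm_template, slice_stream)
from fallkit.features import (ContractError, Slice, compute_phase_times,
                              find_lpv, find_upv, min_temperature,
                              phase_variances_axes, phase_variances_rss,
                              posture_change)


def _recording_from_rss_spike(n=6000, spike_at=3000, spike=4.0):
    """Quiet gravity recording with a single az spike; RSS has one peak."""
    az = np.ones(n)
    az[spike_at] = spike + 1.0
    return AccelRecording(ax=np.zeros(n), ay=np.zeros(n), az=az,
                          temperature=np.full(n, 31.0))


class TestRss:
    @pytest.mark.parametrize("axes, expected", [
        ((0.0, 0.0, 1.0), 0.0),      # rest: 1 g magnitude
        ((0.0, 0.0, 0.0), -1.0),     # free fall
        ((3.0, 0.0, 4.0), 4.0),      # 3-4-5 triple
    ])
    def test_analytic_points(self, axes, expected):
        rss = compute_rss(*[np.array([v]) for v in axes])
        assert rss[0] == pytest.approx(expected)

    def test_rest_is_zero_in_any_orientation(self, rng):
        v = rng.normal(size=(50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        rss = compute_rss(v[:, 0], v[:, 1], v[:, 2])
        np.testing.assert_allclose(rss, 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            compute_rss(np.zeros(3), np.zeros(2), np.zeros(3))


class TestSlicing:
    @pytest.mark.parametrize("n, expected", [(12000, 2), (12500, 2),
                                             (5999, 0), (6000, 1)])
    def test_slice_count_drops_remainder(self, n, expected):
        rec = AccelRecording(ax=np.zeros(n), ay=np.zeros(n), az=np.ones(n),
                             temperature=np.zeros(n))
        if expected == 0:
            with pytest.warns(UserWarning):
                assert slice_stream(rec) == []
        else:
            slices = slice_stream(rec)
            assert len(slices) == expected
            assert all(s.stop - s.start == 6000 for s in slices)


class TestPeaks:
    def test_single_spike_located(self):
        rec = _recording_from_rss_spike()
        rss = compute_rss(rec.ax, rec.ay, rec.az)
        assert find_upv(rss, 0, 6000) == (3000, pytest.approx(4.0))

    def test_ties_break_to_earliest(self):
        rss = np.full(100, 0.5)
        assert find_upv(rss, 0, 100) == (0, 0.5)

    def test_upv_matches_exhaustive_scan(self, rng):
        rss = rng.normal(size=6000)
        idx, val = find_upv(rss, 0, 6000)
        best_i, best_v = 0, rss[0]
        for i in range(6000):  # brute-force oracle
            if rss[i] > best_v:
                best_i, best_v = i, rss[i]
        assert (idx, val) == (best_i, pytest.approx(best_v))

    def test_lpv_is_window_minimum(self, rng):
        rss = rng.normal(size=6000)
        idx, val = find_lpv(rss, 3000)
        window = [rss[i] for i in range(2950, 3000)]  # brute-force oracle
        assert val == pytest.approx(min(window))
        assert idx == 2950 + int(np.argmin(window))

    def test_lpv_free_fall_dip(self):
        rss = np.zeros(6000)
        rss[2980] = -0.9
        rss[3000] = 3.0
        assert find_lpv(rss, 3000)[1] == pytest.approx(-0.9)

    def test_lpv_empty_window_invalid(self):
        idx, val = find_lpv(np.zeros(100), 0)
        assert idx is None and np.isnan(val)


class TestPhaseTimes:
    def test_whole_window_in_band_gives_half_second(self):
        rss = np.zeros(6000)
        rss[3000] = 4.0
        values, valid = compute_phase_times(rss, 3000, 2990, 4.0)
        assert values["t1"] == pytest.approx(0.5) and valid["t1"]

    def test_triangular_peak_width_at_quarter_upv(self):
        # ramp 0 -> 4 g over 100 ms and back; above UPV/4 = 1 g for the
        # final 75 ms of the rise and first 75 ms of the descent
        rss = np.zeros(6000)
        for k in range(11):
            rss[3000 - 10 + k] = 0.4 * k
        for k in range(11, 21):
            rss[3000 - 10 + k] = 0.4 * (20 - k)
        values, _ = compute_phase_times(rss, 3000, 2990, 4.0)
        n_above = sum(1 for v in rss[2980:3020] if v > 1.0)  # oracle
        assert values["t3"] == pytest.approx(n_above * 0.01) == 0.15

    def test_t4_is_index_arithmetic(self):
        rss = np.zeros(6000)
        values, _ = compute_phase_times(rss, 3000, 2970, 1.0)
        assert values["t4"] == pytest.approx(0.30)

    def test_t2_last_upward_crossing(self):
        rss = np.zeros(6000)
        rss[2990:3001] = np.linspace(0.0, 2.0, 11)  # crosses 0.125 at 2991
        values, valid = compute_phase_times(rss, 3000, 2990, 2.0)
        assert valid["t2"] and values["t2"] == pytest.approx(0.09)

    def test_absent_crossings_give_valid_zeros(self):
        rss = np.full(6000, 0.5)  # never inside the ±0.125 band
        values, valid = compute_phase_times(rss, 3000, 2990, 0.5)
        assert values["t1"] == 0.0 and valid["t1"]
        assert values["t2"] == 0.0 and valid["t2"]


class TestVariances:
    def test_constant_signal_zero_variance(self):
        rss = np.full(6000, 0.3)
        values, valid = phase_variances_rss(rss, 3000)
        assert all(valid[k] for k in values)
        assert all(values[k] == pytest.approx(0.0, abs=1e-12)
                   for k in values)

    def test_alternating_post_window_unit_variance(self):
        rss = np.zeros(6000)
        rss[3100:3200] = np.tile([0.0, 2.0], 50)  # mean 1, deviations ±1
        values, _ = phase_variances_rss(rss, 3000)
        assert values["var_rss3"] == pytest.approx(1.0)

    def test_population_variance_matches_two_pass_oracle(self, rng):
        rss = rng.normal(size=6000)
        values, _ = phase_variances_rss(rss, 3000)
        for name, (lo, hi) in (("var_rss1", (2960, 3001)),
                               ("var_rss2", (2980, 3021)),
                               ("var_rss3", (3100, 3200))):
            w = rss[lo:hi]
            mu = sum(w) / len(w)
            oracle = sum((x - mu) ** 2 for x in w) / len(w)
            assert values[name] == pytest.approx(oracle)

    def test_truncated_window_flagged(self):
        values, valid = phase_variances_rss(np.zeros(6000), 10)
        assert not valid["var_rss1"] and np.isnan(values["var_rss1"])

    def test_axis_combination_three_four_five(self):
        # per-axis variances (3, 0, 4) in the post window -> combined 5
        n = 6000
        ax = np.zeros(n)
        ay = np.zeros(n)
        az = np.zeros(n)
        ax[3100:3200] = np.tile([0.0, 2 * np.sqrt(3)], 50)  # variance 3
        az[3100:3200] = np.tile([0.0, 4.0], 50)             # variance 4
        values, _ = phase_variances_axes(ax, ay, az, 3000)
        assert values["var_acc3"] == pytest.approx(5.0)

    def test_axes_match_direct_formula_oracle(self, rng):
        ax, ay, az = rng.normal(size=(3, 6000))
        values, _ = phase_variances_axes(ax, ay, az, 3000)
        lo, hi = 2980, 3021
        vs = []
        for a in (ax, ay, az):
            w = a[lo:hi]
            mu = sum(w) / len(w)
            vs.append(sum((x - mu) ** 2 for x in w) / len(w))
        oracle = (vs[0] ** 2 + vs[1] ** 2 + vs[2] ** 2) ** 0.5
        assert values["var_acc2"] == pytest.approx(oracle)


class TestPostureChange:
    def test_unchanged_posture_is_zero(self):
        ax, ay = np.zeros(6000), np.zeros(6000)
        az = np.ones(6000)
        value, valid = posture_change(ax, ay, az, 3000)
        assert valid and value == pytest.approx(0.0)

    def test_orthogonal_orientations_give_sqrt2(self):
        ax, ay, az = np.zeros(6000), np.zeros(6000), np.zeros(6000)
        az[:3000] = 1.0   # upright before
        ax[3000:] = 1.0   # lying after
        value, _ = posture_change(ax, ay, az, 3000)
        assert value == pytest.approx(np.sqrt(2.0))

    def test_matches_direct_mean_difference_oracle(self, rng):
        ax, ay, az = rng.normal(size=(3, 6000))
        value, valid = posture_change(ax, ay, az, 3000)
        total = 0.0
        for a in (ax, ay, az):
            mu1 = sum(a[2820:2850]) / 30
            mu2 = sum(a[3050:3080]) / 30
            total += (mu1 - mu2) ** 2
        assert valid and value == pytest.approx(total ** 0.5)

    def test_truncated_window_invalid(self):
        value, valid = posture_change(np.zeros(6000), np.zeros(6000),
                                      np.ones(6000), 100)
        assert not valid and np.isnan(value)

    def test_invariant_under_axis_permutation(self, rng):
        axes = rng.normal(size=(3, 6000))
        ref, _ = posture_change(*axes, 3000)
        for perm in itertools.permutations(range(3)):
            value, _ = posture_change(*axes[list(perm)], 3000)
            assert value == pytest.approx(ref)


class TestConvolution:
    def test_identity_kernel_gives_series_max(self, rng):
        series = rng.normal(size=100)
        tpl = NormFallTemplate(values=[1.0], source="loaded")
        assert max_convolution(series, tpl) == pytest.approx(series.max())

    def test_direct_evaluation_small_case(self):
        tpl = NormFallTemplate(values=[1.0, 1.0], source="loaded")
        assert max_convolution(np.array([0.0, 1.0, 2.0]), tpl) == 3.0

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=300)
        h = rng.normal(size=7)
        tpl = NormFallTemplate(values=h, source="loaded")
        best = -np.inf
        for n in range(len(x) + len(h) - 1):  # brute-force convolution
            acc = 0.0
            for i in range(len(h)):
                if 0 <= n - i < len(x):
                    acc += h[i] * x[n - i]
            best = max(best, acc)
        assert max_convolution(x, tpl) == pytest.approx(best)

    def test_template_longer_than_signal_rejected(self):
        tpl = NormFallTemplate(values=np.ones(10), source="loaded")
        with pytest.raises(ContractError):
            max_convolution(np.zeros(5), tpl)


class TestTemplate:
    def test_single_fall_is_its_own_normalized_segment(self):
        rec = _recording_from_rss_spike()
        sl = Slice(rec, 0, label="fall")
        tpl = estimate_norm_template([sl], half_width_ms=100.0)
        assert len(tpl.values) == 21
        assert np.linalg.norm(tpl.values) == pytest.approx(1.0)
        assert np.argmax(tpl.values) == 10  # aligned at the UPV

    def test_mean_of_identical_slices_is_idempotent(self):
        rec = _recording_from_rss_spike()
        sl = Slice(rec, 0, label="fall")
        one = estimate_norm_template([sl]).values
        two = estimate_norm_template([sl, sl]).values
        np.testing.assert_allclose(one, two)

    def test_templates_are_unit_norm(self, study):
        assert np.linalg.norm(study["featurizer"].template_.values
                              ) == pytest.approx(1.0)
        assert np.linalg.norm(parametric_norm_template().values
                              ) == pytest.approx(1.0)

    def test_save_load_round_trip(self, tmp_path):
        tpl = parametric_norm_template()
        tpl.save(tmp_path / "tpl.csv")
        back = NormFallTemplate.load(tmp_path / "tpl.csv")
        np.testing.assert_allclose(tpl.values, back.values)

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            estimate_norm_template([])


class TestExtraction:
    def test_degenerate_all_zero_slice(self):
        n = 6000
        rec = AccelRecording(ax=np.zeros(n), ay=np.zeros(n), az=np.zeros(n),
                             temperature=np.full(n, 31.0))
        fv = extract_features(Slice(rec, 0), parametric_norm_template())
        assert fv.values["upv"] == pytest.approx(-1.0)
        # tie-break puts the UPV at sample 0: pre-windows truncate and flag
        assert np.isnan(fv.values["var_rss1"]) and not fv.valid["var_rss1"]
        assert fv.values["var_rss3"] == 0.0
        assert np.isnan(fv.values["delta_mu_acc"])

    def test_textbook_fall_waveform(self):
        # upright 10 s, free fall 400 ms, one 4 g impact sample, lying after
        n = 6000
        ax, ay, az = np.zeros(n), np.zeros(n), np.zeros(n)
        az[:1000] = 1.0
        az[1000:1040] = 0.0
        ay[1040] = 4.0
        ax[1041:] = 1.0
        rec = AccelRecording(ax=ax, ay=ay, az=az,
                             temperature=np.full(n, 31.0))
        fv = extract_features(Slice(rec, 0), parametric_norm_template())
        assert fv.upv_index == 1040
        assert fv.values["upv"] == pytest.approx(3.0)
        assert fv.values["lpv"] == pytest.approx(-1.0)
        assert fv.values["t1"] == pytest.approx(0.10)  # 10 quiet samples
        assert fv.values["t4"] == pytest.approx(0.40)  # LPV tie at dip start
        assert fv.values["var_rss3"] == pytest.approx(0.0)
        assert fv.values["delta_mu_acc"] == pytest.approx(np.sqrt(2.0))

    def test_deterministic_and_total(self, rng):
        v = rng.normal(size=(6000, 3))
        rec = AccelRecording(ax=v[:, 0], ay=v[:, 1], az=v[:, 2],
                             temperature=np.full(6000, 28.0))
        tpl = parametric_norm_template()
        a = extract_features(Slice(rec, 0), tpl)
        b = extract_features(Slice(rec, 0), tpl)
        assert a.to_dict() == b.to_dict()

    def test_upv_invariant_under_axis_symmetry(self, rng):
        axes = rng.normal(size=(3, 6000))
        tpl = parametric_norm_template()

        def upv_of(ax, ay, az):
            rec = AccelRecording(ax=ax, ay=ay, az=az,
                                 temperature=np.full(6000, 31.0))
            return extract_features(Slice(rec, 0), tpl).values["upv"]

        ref = upv_of(*axes)
        assert upv_of(axes[1], axes[2], axes[0]) == pytest.approx(ref)
        assert upv_of(-axes[0], axes[1], -axes[2]) == pytest.approx(ref)

    def test_min_temperature_dip(self):
        temp = np.full(6000, 31.0)
        temp[3000] = 24.0
        assert min_temperature(temp, 0, 6000) == 24.0

    def test_upv_never_below_lpv(self, study):
        table = study["train"]
        both = table[["upv", "lpv"]].dropna()
        assert (both["upv"] >= both["lpv"]).all()
        assert (table["t4"].dropna() <= 0.5).all()
        for col in ("var_rss1", "var_rss2", "var_rss3",
                    "var_acc1", "var_acc2", "var_acc3",
                    "t1", "t2", "t3"):
            assert (table[col].dropna() >= 0).all()
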