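"""Amplitude time-courses, detection criterion, consecutive-bin tests,
ANOVAs, laterality, binomial and association statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formscan.io_core import ValidationError
from formscan.preprocess import Evoked
from formscan.sensor_stats import (
    AmplitudeTimecourse,
    absolute_amplitude,
    analysis_bins,
    anova_quadrant_form,
    binomial_detection_probability,
    consecutive_bin_ttest,
    detect_component,
    laterality_check,
    p100m_detection_association,
    peak_latency,
)


def make_evoked(data, groups=None, fs=1200.0, t0_ms=-500.0):
    n_ch, n_t = data.shape
    if groups is None:
        groups = ["MLO"] * n_ch
    return Evoked(
        condition="line_nasal", band="tight", data=np.asarray(data, float),
        times_ms=t0_ms + np.arange(n_t) * 1000.0 / fs, fs_hz=fs,
        channels=[(f"CH{i:02d}", g) for i, g in enumerate(groups)],
        n_epochs=10,
    )


def make_tc(amplitude, fs=1200.0, t0_ms=-500.0, baseline_mean=None,
            baseline_sd=None):
    amplitude = np.asarray(amplitude, float)
    times = t0_ms + np.arange(len(amplitude)) * 1000.0 / fs
    bmask = (times >= -200) & (times < 0)
    return AmplitudeTimecourse(
        sensor_set="all_occ", times_ms=times, amplitude_ft=amplitude,
        baseline_mean=(amplitude[bmask].mean() if baseline_mean is None
                       else baseline_mean),
        baseline_sd=(amplitude[bmask].std(ddof=1) if baseline_sd is None
                     else baseline_sd),
    )


class TestAbsoluteAmplitude:
    def test_equal_sensors_give_zero(self):
        ev = make_evoked(np.ones((4, 700)))
        tc = absolute_amplitude(ev, "left_occ")
        np.testing.assert_allclose(tc.amplitude_ft, 0.0)

    def test_antisymmetric_pair_gives_2a(self):
        data = np.zeros((2, 700))
        data[0], data[1] = 3.0, -3.0
        tc = absolute_amplitude(make_evoked(data), "left_occ")
        np.testing.assert_allclose(tc.amplitude_ft, 6.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((5, 700))
        tc = absolute_amplitude(make_evoked(data), "left_occ")
        expect = np.array([data[:, j].max() - data[:, j].min()
                           for j in range(700)])
        np.testing.assert_allclose(tc.amplitude_ft, expect)

    def test_unknown_sensor_set_rejected(self):
        with pytest.raises(ValidationError, match="sensor set"):
            absolute_amplitude(make_evoked(np.zeros((2, 700))), "frontal")

    def test_sensor_set_respects_groups(self):
        data = np.zeros((3, 700))
        data[2] = 10.0  # MRO channel, excluded from left_occ
        ev = make_evoked(data, groups=["MLO", "MLO", "MRO"])
        tc = absolute_amplitude(ev, "left_occ")
        np.testing.assert_allclose(tc.amplitude_ft, 0.0)


class TestAnalysisBins:
    def test_printed_initial_window_is_67_bins(self):
        bins = analysis_bins((15.0, 70.0), 1200.0)
        assert len(bins) == 67
        assert np.allclose(np.diff(bins), 1000.0 / 1200.0)

    def test_degenerate_window_is_one_bin(self):
        assert len(analysis_bins((0.0, 0.0), 1200.0)) == 1

    def test_main_window_is_109_bins(self):
        # samples 84..192 inclusive at 1200 Hz
        assert len(analysis_bins((70.0, 160.0), 1200.0)) == 109


class TestDetection:
    def test_flat_timecourse_not_detected(self):
        tc = make_tc(np.full(1200, 5.0), baseline_mean=5.0, baseline_sd=1.0)
        det = detect_component(tc, (15.0, 70.0))
        assert not det.detected

    def test_three_consecutive_bins_insufficient(self):
        amp = np.full(1200, 5.0)
        i40 = 600 + 48  # 40 ms
        amp[i40:i40 + 3] = 50.0
        tc = make_tc(amp, baseline_mean=5.0, baseline_sd=1.0)
        assert not detect_component(tc, (15.0, 70.0), min_run=4).detected

    def test_four_consecutive_bins_suffice(self):
        amp = np.full(1200, 5.0)
        i40 = 600 + 48
        amp[i40:i40 + 4] = 50.0
        det = detect_component(make_tc(amp, baseline_mean=5.0,
                                       baseline_sd=1.0), (15.0, 70.0))
        assert det.detected

    def test_burst_peak_latency_recovered(self):
        t = np.arange(1200) / 1.2 - 500.0
        amp = 5.0 + 40.0 * np.exp(-((t - 40.0) ** 2) / (2 * 4.0**2))
        det = detect_component(make_tc(amp, baseline_mean=5.0,
                                       baseline_sd=1.0), (15.0, 70.0))
        assert det.detected
        assert abs(det.peak_latency_ms - 40.0) < 0.5
        assert det.supra_run[0] <= 40.0 <= det.supra_run[1]

    def test_run_containing_global_max_reported(self):
        amp = np.full(1200, 5.0)
        a = 600 + 24   # 20 ms: long weak run
        amp[a:a + 6] = 20.0
        b = 600 + 60   # 50 ms: long strong run
        amp[b:b + 6] = 60.0
        det = detect_component(make_tc(amp, baseline_mean=5.0,
                                       baseline_sd=1.0), (15.0, 70.0))
        assert det.supra_run[0] >= 45.0

    def test_window_outside_timecourse_rejected(self):
        tc = make_tc(np.full(1200, 5.0))
        with pytest.raises(ValidationError):
            detect_component(tc, (900.0, 950.0))


class TestPeakLatency:
    def test_single_maximum(self):
        amp = np.zeros(1200)
        amp[600 + 114] = 10.0  # 95 ms
        assert peak_latency(make_tc(amp), (70.0, 160.0)) == 95.0

    def test_tie_breaks_to_earlier_bin(self):
        amp = np.zeros(1200)
        amp[600 + 100] = 10.0
        amp[600 + 150] = 10.0
        lat = peak_latency(make_tc(amp), (70.0, 160.0))
        assert np.isclose(lat, 100 / 1.2)


class TestConsecutiveBinTtest:
    times = np.arange(18, 85) * 1000.0 / 1200.0  # the 67-bin grid

    def test_identical_groups_give_no_windows(self):
        a = np.random.default_rng(0).standard_normal((20, 67))
        assert consecutive_bin_ttest(a, a.copy(), self.times) == []

    def test_sustained_effect_window_recovered(self):
        """A lines > rhomboids difference spanning 42-45 ms is reported
        as one positive window covering those bins."""
        rng = np.random.default_rng(1)
        a = rng.standard_normal((20, 67))
        b = rng.standard_normal((20, 67))
        effect = (self.times >= 42.0) & (self.times <= 45.0)
        a[:, effect] += 3.0
        wins = consecutive_bin_ttest(a, b, self.times)
        assert len(wins) >= 1
        w = max(wins, key=lambda w: w.end_ms - w.start_ms)
        assert w.direction == 1
        effect_times = self.times[effect]
        assert w.start_ms <= effect_times[0] + 1e-9
        assert w.end_ms >= effect_times[-1] - 1e-9

    def test_three_significant_bins_not_reported(self):
        rng = np.random.default_rng(2)
        a = 0.05 * rng.standard_normal((20, 67))
        b = 0.05 * rng.standard_normal((20, 67))
        a[:, 10:13] += 5.0  # only 3 consecutive bins
        wins = consecutive_bin_ttest(a, b, self.times)
        assert all(not (w.start_ms <= self.times[10] <= w.end_ms)
                   for w in wins)

    def test_sign_must_be_consistent(self):
        rng = np.random.default_rng(3)
        a = 0.05 * rng.standard_normal((20, 67))
        b = 0.05 * rng.standard_normal((20, 67))
        a[:, 20:22] += 5.0
        a[:, 22:24] -= 5.0  # 4 significant bins but mixed sign
        wins = consecutive_bin_ttest(a, b, self.times)
        assert wins == []

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValidationError):
            consecutive_bin_ttest(np.zeros((1, 67)), np.zeros((1, 67)),
                                  self.times)


def _balanced_table():
    # 4 subjects x 2 forms x 2 quadrants, constructed cell means
    rows = []
    vals = {
        ("line", "nasal"): [30, 32, 34, 36],
        ("line", "temporal"): [40, 42, 44, 46],
        ("rhomboid", "nasal"): [37, 38, 39, 40],
        ("rhomboid", "temporal"): [36, 37, 38, 39],
    }
    for (form, quad), v in vals.items():
        for s, x in enumerate(v):
            rows.append(dict(subject=s, form=form, quadrant=quad,
                             latency_ms=float(x)))
    return pd.DataFrame(rows)


def _oracle_univariate_balanced(df):
    """Closed-form two-way ANOVA for a balanced 2x2 design."""
    n = df.groupby(["form", "quadrant"]).size().iloc[0]
    grand = df.latency_ms.mean()
    cells = df.groupby(["form", "quadrant"]).latency_ms.mean()
    f_m = df.groupby("form").latency_ms.mean()
    q_m = df.groupby("quadrant").latency_ms.mean()
    ss_form = 2 * n * ((f_m - grand) ** 2).sum()
    ss_quad = 2 * n * ((q_m - grand) ** 2).sum()
    ss_cells = n * ((cells - grand) ** 2).sum()
    ss_int = ss_cells - ss_form - ss_quad
    ss_res = sum((g.latency_ms - g.latency_ms.mean()).pow(2).sum()
                 for _, g in df.groupby(["form", "quadrant"]))
    df_res = len(df) - 4
    return {
        "form": ss_form / (ss_res / df_res),
        "quadrant": ss_quad / (ss_res / df_res),
        "form x quadrant": ss_int / (ss_res / df_res),
    }


class TestAnova:
    def test_univariate_matches_closed_form_oracle(self):
        df = _balanced_table()
        res = anova_quadrant_form(df, "univariate")
        oracle = _oracle_univariate_balanced(df)
        for name, f_expect in oracle.items():
            assert np.isclose(res.effects[name]["F"], f_expect), name

    def test_identical_latencies_give_zero_f(self):
        df = _balanced_table()
        df["latency_ms"] = 42.0
        for design in ("univariate", "repeated_measures"):
            res = anova_quadrant_form(df, design)
            for e in res.effects.values():
                assert abs(e["F"]) < 1e-9
                assert e["p"] > 0.99

    def test_unbalanced_cells_run_with_correct_dfs(self):
        """Cell sizes like the study's detection counts (14/9/8/10)."""
        rng = np.random.default_rng(4)
        rows = []
        sizes = {("line", "nasal"): 14, ("line", "temporal"): 9,
                 ("rhomboid", "nasal"): 8, ("rhomboid", "temporal"): 10}
        s = 0
        for (form, quad), n in sizes.items():
            for _ in range(n):
                rows.append(dict(subject=s, form=form, quadrant=quad,
                                 latency_ms=40 + rng.standard_normal()))
                s += 1
        res = anova_quadrant_form(pd.DataFrame(rows), "univariate")
        for e in res.effects.values():
            assert e["df1"] == 1.0
            assert e["df2"] == sum(sizes.values()) - 4
        assert res.posthoc["nasal"]["df"] == 14 + 8 - 2
        assert res.posthoc["temporal"]["df"] == 9 + 10 - 2

    def test_repeated_measures_df_pattern(self):
        rng = np.random.default_rng(5)
        df = _balanced_table()
        df["latency_ms"] += rng.standard_normal(len(df))
        res = anova_quadrant_form(df, "repeated_measures")
        for e in res.effects.values():
            assert (e["df1"], e["df2"]) == (1.0, 3.0)  # n-1 subjects

    def test_empty_cell_rejected(self):
        df = _balanced_table()
        df = df[~((df.form == "line") & (df.quadrant == "nasal"))]
        with pytest.raises(ValidationError):
            anova_quadrant_form(df, "univariate")


class TestLaterality:
    @staticmethod
    def _subject(contra_gain=3.0, seed=0):
        rng = np.random.default_rng(seed)
        groups = ["MLO"] * 4 + ["MRO"] * 4
        out = {}
        for cond in ("line_nasal", "line_temporal",
                     "rhomboid_nasal", "rhomboid_temporal"):
            quad = cond.split("_")[1]
            data = 0.1 * rng.standard_normal((8, 1200))
            t = np.arange(1200) / 1.2 - 500.0
            burst = np.exp(-((t - 40.0) ** 2) / (2 * 5.0**2))
            contra = slice(4, 8) if quad == "nasal" else slice(0, 4)
            ipsi = slice(0, 4) if quad == "nasal" else slice(4, 8)
            pattern = np.zeros(8)
            pattern[contra] = contra_gain * np.array([1, -1, 0.5, -0.5])
            pattern[ipsi] = np.array([1, -1, 0.5, -0.5])
            data += np.outer(pattern, burst)
            out[cond] = make_evoked(data, groups=groups)
        return out

    def test_symmetric_evoked_zero_contrast(self):
        subs = [self._subject(contra_gain=1.0, seed=s) for s in range(6)]
        res = laterality_check(subs)
        pooled = res[res.condition == "pooled"].iloc[0]
        assert abs(pooled["mean_contrast_ft"]) < 0.2

    def test_contralateral_dominance_detected(self):
        subs = [self._subject(contra_gain=3.0, seed=s) for s in range(6)]
        res = laterality_check(subs)
        pooled = res[res.condition == "pooled"].iloc[0]
        assert pooled["mean_contrast_ft"] > 0
        assert pooled["p"] < 0.05


class TestBinomial:
    def test_certain_event(self):
        assert binomial_detection_probability(0, 20) == 1.0

    def test_enumeration_small_case(self):
        # n=3, p=0.5, k>=2: 4 of 8 equally likely outcomes
        assert np.isclose(binomial_detection_probability(2, 3, 0.5), 0.5)

    def test_exact_against_fraction_oracle(self):
        p = Fraction(1, 20)
        for n in (5, 10, 20, 25):
            for k in range(n + 1):
                expect = sum(
                    Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i)
                    for i in range(k, n + 1))
                got = binomial_detection_probability(k, n, 0.05)
                assert abs(got - float(expect)) <= 1e-12 * max(
                    float(expect), 1e-300)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            binomial_detection_probability(21, 20)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 30), k=st.integers(1, 30),
           p=st.floats(0.01, 0.99))
    def test_monotone_in_k_and_p(self, n, k, p):
        if k > n:
            return
        tail = binomial_detection_probability(k, n, p)
        if k >= 1:
            assert tail <= binomial_detection_probability(k - 1, n, p) + 1e-15
        assert tail <= binomial_detection_probability(k, n, min(p + 0.1,
                                                                0.999)) + 1e-15


class TestP100mAssociation:
    def test_perfect_association(self):
        flags = np.array([True] * 5 + [False] * 5)
        amps = flags.astype(float)
        res = p100m_detection_association(amps, flags)
        assert res.defined
        assert np.isclose(res.r, 1.0)

    def test_degenerate_flags_undefined(self):
        res = p100m_detection_association(np.arange(5.0),
                                          np.ones(5, dtype=bool))
        assert not res.defined
        assert res.mean_detected is not None

    def test_null_amplitudes_give_uniformish_p(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            amps = rng.standard_normal(40)
            flags = rng.random(40) < 0.5
            if flags.all() or (~flags).all():
                continue
            ps.append(p100m_detection_association(amps, flags).p)
        ps = np.array(ps)
        assert 0.25 < (ps < 0.5).mean() / 0.5 < 1.75
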