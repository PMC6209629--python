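import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erplatency import (
    ComponentSpec,
    DegenerateComponentError,
    GroupAverages,
    LatencyConfig,
    component_waveform,
    extract_group,
    extract_measures,
    find_crossings,
    find_peak,
    mean_amplitude,
    percent_amplitude_threshold,
    prepare_waveforms,
    signed_area_latency,
    validate_and_fill,
    windowed_amplitude,
)
from erplatency.extraction import (
    find_counter_peak,
    resolve_area_window,
    running_average,
)

from conftest import make_effective


def dense_area_latency(w, lo, hi, baseline, perc, factor=200):
    """Brute-force oracle: dense-grid cumulative integration of the

    linearly interpolated, rectified waveform."""
    x = np.arange(lo, hi + 1)
    xd = np.linspace(lo, hi, (hi - lo) * factor + 1)
    g = np.maximum(np.interp(xd, x, np.asarray(w, float)[lo : hi + 1]) - baseline, 0.0)
    cum = np.concatenate(([0.0], np.cumsum((g[1:] + g[:-1]) / 2)))
    total = cum[-1]
    if total <= 0:
        return None
    k = np.searchsorted(cum, perc * total)
    return xd[min(k, xd.size - 1)]


class TestPrepareWaveforms:
    def test_channel_mean(self):
        g = GroupAverages(data=np.array([[[1.0, 1.0], [3.0, 3.0]]]))
        eff = validate_and_fill(LatencyConfig(sign=1), g)
        assert prepare_waveforms(g, eff)[0, 0] == 2.0

    def test_negative_sign_flips(self):
        g = GroupAverages(data=np.full((1, 1, 3), -4.0))
        eff = validate_and_fill(LatencyConfig(sign=-1), g)
        assert prepare_waveforms(g, eff)[0, 0] == 4.0

    def test_sign_symmetry(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(3, 2, 40))
        g_pos = GroupAverages(data=data)
        g_neg = GroupAverages(data=-data)
        w_pos = prepare_waveforms(g_pos, validate_and_fill(LatencyConfig(sign=1), g_pos))
        w_neg = prepare_waveforms(g_neg, validate_and_fill(LatencyConfig(sign=-1), g_neg))
        np.testing.assert_array_equal(w_pos, w_neg)


class TestFindPeak:
    @pytest.mark.parametrize(
        "w, window, expected",
        [
            ([0, 1, 3, 1, 0], (0, 4), (2, True)),
            ([0, 1, 2, 3, 4], (0, 4), (4, False)),  # monotone: boundary fallback
            ([0, 3, 1, 3, 0], (0, 4), (1, True)),  # tie -> earliest
            ([4, 3, 2, 1, 0], (0, 4), (0, False)),
            ([0, 2, 2, 2, 0], (0, 4), (1, True)),  # plateau -> first sample
        ],
    )
    def test_examples(self, w, window, expected):
        assert find_peak(np.array(w, float), window) == expected

    def test_window_restricts_search(self):
        w = np.array([0, 9, 0, 5, 0, 0], float)
        assert find_peak(w, (2, 5)) == (3, True)

    def test_largest_local_max_wins_over_boundary_value(self):
        # boundary holds the largest value but it is not a local max
        w = np.array([9, 1, 2, 1], float)
        assert find_peak(w, (0, 3)) == (2, True)


class TestWindowedAmplitude:
    def test_examples(self):
        w = np.array([0, 2, 4, 2, 0], float)
        assert windowed_amplitude(w, 2, 1) == pytest.approx(8 / 3)
        assert windowed_amplitude(w, 2, 0) == 4.0
        assert windowed_amplitude(w, 0, 2) == pytest.approx(2.0)  # edge truncation

    @given(
        st.lists(st.floats(-5, 5), min_size=5, max_size=30),
        st.integers(0, 29),
        st.integers(0, 4),
    )
    @settings(max_examples=50, derandomize=True)
    def test_matches_running_average(self, values, idx, hw):
        w = np.array(values)
        idx = idx % w.size
        assert running_average(w, hw)[idx] == pytest.approx(
            windowed_amplitude(w, idx, hw), rel=1e-12, abs=1e-12
        )


class TestCounterPeak:
    def test_explicit_window(self):
        w = np.array([0, -2, 0, 5, 0], float)
        eff = make_effective(w, peak_win=(2, 4), c_win=(0, 2), peak_width=0)
        idx, amp, local = find_counter_peak(w, 3, eff)
        assert (idx, amp, local) == (1, -2.0, True)

    def test_width_from_peak(self):
        w = np.array([0, -2, 0, 5, 0], float)
        eff = make_effective(w, peak_win=(2, 4), c_win_start="peak", c_win_width=-2, peak_width=0)
        idx, _, _ = find_counter_peak(w, 3, eff)
        assert idx == 1

    def test_width_from_peak_win_border(self):
        w = np.array([0, -2, 0, 0, 5, 0], float)
        eff = make_effective(w, peak_win=(3, 5), c_win_width=-3, peak_width=0)
        idx, amp, _ = find_counter_peak(w, 4, eff)
        assert idx == 1 and amp == -2.0

    def test_flat_window_boundary_fallback(self):
        w = np.array([1.0, 1.0, 1.0, 5.0, 0.0])
        eff = make_effective(w, peak_win=(2, 4), c_win=(0, 2), peak_width=0)
        idx, amp, local = find_counter_peak(w, 3, eff)
        assert local is False and amp == 1.0


class TestThreshold:
    def test_examples(self):
        assert percent_amplitude_threshold(10, None, 0.3) == pytest.approx(3.0)
        assert percent_amplitude_threshold(10, -2, 0.5) == pytest.approx(4.0)
        assert percent_amplitude_threshold(10, -2, 1.0) == pytest.approx(10.0)

    def test_degenerate_component(self):
        with pytest.raises(DegenerateComponentError):
            percent_amplitude_threshold(1.0, 2.0, 0.5)


class TestCrossings:
    def test_triangle_closed_form(self):
        t = np.arange(21.0)
        w = np.where(t <= 10, t, 20 - t)
        res = find_crossings(w, 10, 3.0, (0, 20), 0)
        assert res.onset == pytest.approx(3.0)
        assert res.offset == pytest.approx(17.0)
        assert res.found_on and res.found_off

    @pytest.mark.parametrize("p", [0.2, 0.3, 0.5, 0.8])
    def test_gaussian_analytic(self, p):
        mu, sigma, dt = 0.5, 0.05, 0.001
        t = np.arange(0, 1 + dt / 2, dt)
        w = np.exp(-((t - mu) ** 2) / (2 * sigma**2))
        peak = int(round(mu / dt))
        res = find_crossings(w, peak, p * 1.0, (0, t.size - 1), 0)
        expected = (mu - sigma * np.sqrt(-2 * np.log(p))) / dt
        assert res.onset == pytest.approx(expected, abs=0.5)
        assert res.offset == pytest.approx(2 * peak - expected, abs=0.5)

    def test_pinned_to_bound_when_no_crossing(self):
        w = np.full(20, 5.0)
        w[10] = 6.0
        res = find_crossings(w, 10, 1.0, (3, 15), 0)
        assert res.onset == 3.0 and not res.found_on
        assert res.offset == 15.0 and not res.found_off


class TestAreaWindow:
    def test_peak_win_and_full_range(self):
        w = np.zeros(300)
        eff = make_effective(w, peak_win=(140, 240))
        assert resolve_area_window(eff, None, 300) == (140, 240)
        eff = make_effective(w, peak_win=(140, 240), area_win="fullRange")
        assert resolve_area_window(eff, None, 300) == (0, 299)

    def test_amp_lat_rounds_outward(self):
        from erplatency.extraction import CrossingResult

        w = np.zeros(30)
        eff = make_effective(w, peak_win=(5, 25), area_win="ampLat")
        cr = CrossingResult(3.4, 17.2, True, True, 1.0)
        assert resolve_area_window(eff, cr, 30) == (3, 18)

    def test_amp_lat_without_crossings_errors(self):
        from erplatency.extraction import CrossingResult

        w = np.zeros(30)
        eff = make_effective(w, peak_win=(5, 25), area_win="ampLat")
        cr = CrossingResult(0.0, 29.0, False, False, 1.0)
        with pytest.raises(DegenerateComponentError):
            resolve_area_window(eff, cr, 30)


class TestSignedAreaLatency:
    def test_rectangular_pulse_median(self):
        w = np.zeros(31)
        w[10:21] = 1.0
        area, lat, found = signed_area_latency(w, (10, 20), 0.0, 0.5)
        assert found and lat == pytest.approx(15.0)
        assert area == pytest.approx(11.0)

    def test_rectangular_pulse_quartile(self):
        w = np.zeros(31)
        w[10:21] = 1.0
        _, lat, _ = signed_area_latency(w, (10, 20), 0.0, 0.25)
        assert lat == pytest.approx(12.5)

    def test_negative_excursion_ignored(self):
        area, _, _ = signed_area_latency(np.array([1.0, -5.0, 1.0]), (0, 2), 0.0, 0.5)
        assert area == pytest.approx(2.0)

    def test_zero_area_flagged(self):
        area, lat, found = signed_area_latency(np.full(10, -1.0), (0, 9), 0.0, 0.5)
        assert area == 0.0 and lat == 9.0 and not found

    def test_symmetric_component_median_is_peak(self):
        t = np.arange(101.0)
        w = np.exp(-((t - 50) ** 2) / (2 * 8.0**2))
        _, lat, _ = signed_area_latency(w, (0, 100), 0.0, 0.5)
        assert lat == pytest.approx(50.0, abs=1e-9)

    def test_raised_baseline_shrinks_area(self):
        t = np.arange(101.0)
        w = np.exp(-((t - 50) ** 2) / (2 * 8.0**2))
        a0, _, _ = signed_area_latency(w, (0, 100), 0.0, 0.5)
        a1, _, _ = signed_area_latency(w, (0, 100), 0.3, 0.5)
        assert 0 < a1 < a0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_dense_grid_oracle(self, seed):
        """Mass-model split latency vs brute-force dense integration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 51))
        w = rng.uniform(-1.0, 2.0, size=n)
        w[int(rng.integers(0, n))] = 2.5  # guarantee some area
        perc = float(rng.uniform(0.2, 0.8))
        _, lat, found = signed_area_latency(w, (0, n - 1), 0.0, perc)
        oracle = dense_area_latency(w, 0, n - 1, 0.0, perc)
        assert found and oracle is not None
        assert abs(lat - oracle) <= 0.5


class TestMeanAmplitude:
    def test_examples(self):
        assert mean_amplitude(np.array([1.0, 2.0, 3.0]), (0, 2)) == 2.0
        assert mean_amplitude(np.array([1.0, 2.0, 3.0]), (1, 1)) == 2.0


class TestExtractMeasures:
    def test_noiseless_gaussian_all_oracles(self):
        mu, sigma, dt = 0.5, 0.05, 0.001
        t = np.arange(0, 1 + dt / 2, dt)
        w = 10 * np.exp(-((t - mu) ** 2) / (2 * sigma**2))
        eff = make_effective(
            w,
            times=t,
            peak_win=(0.3, 0.7),
            perc_amp=0.3,
            perc_area=0.5,
            peak_width=0,
            area_win="ampLat",
        )
        m = extract_measures(w, eff)
        assert m.peak_lat == pytest.approx(mu, abs=1e-12)
        assert m.area_lat == pytest.approx(mu, abs=dt / 2)
        assert m.onset == pytest.approx(mu - sigma * np.sqrt(-2 * np.log(0.3)), abs=dt / 2)
        assert m.width == pytest.approx(m.offset - m.onset, abs=1e-12)
        assert m.peak_amp == pytest.approx(10.0)

    def test_single_measure_request(self, gaussian_group):
        group, _ = gaussian_group
        res = extract_group(group, LatencyConfig(sign=1, extract="peakLat"))
        assert set(res.table["measure"]) == {"peakLat"}
        assert len(res.table) == group.n_subjects

    def test_ordering_invariant(self, noisy_group):
        group, _ = noisy_group
        res = extract_group(
            group,
            LatencyConfig(
                sign=1,
                extract=["onset", "peakLat", "offset", "areaLat"],
                peak_win=(0.4, 1.0),
                perc_amp=0.3,
            ),
        )
        wide = res.wide()
        flags = res.table.pivot(index="unit_id", columns="measure", values="found")
        both = flags["onset"] & flags["offset"]
        assert (wide.loc[both, "onset"] <= wide.loc[both, "peakLat"]).all()
        assert (wide.loc[both, "peakLat"] <= wide.loc[both, "offset"]).all()

    def test_sign_symmetry_exact(self, noisy_group):
        group, _ = noisy_group
        kwargs = dict(
            extract=["peakLat", "onset", "offset", "areaLat", "peakAmp", "mean", "area"],
            peak_win=(0.4, 1.0),
            perc_amp=0.3,
        )
        res_pos = extract_group(group, LatencyConfig(sign=1, **kwargs)).wide()
        flipped = GroupAverages(
            data=-group.data,
            subject_ids=group.subject_ids,
            channel_names=group.channel_names,
            time_axis=group.time_axis,
        )
        res_neg = extract_group(flipped, LatencyConfig(sign=-1, **kwargs)).wide()
        np.testing.assert_array_equal(res_pos.to_numpy(), res_neg.to_numpy())

    def test_area_lat_monotone_in_perc_area(self):
        rng = np.random.default_rng(9)
        t = np.arange(0, 1.0, 0.004)
        w = 5 * np.exp(-((t - 0.5) ** 2) / (2 * 0.1**2)) + 0.3 * rng.normal(size=t.size)
        prev = -np.inf
        for pa in (0.2, 0.35, 0.5, 0.65, 0.8):
            eff = make_effective(w, perc_area=pa, extract=["areaLat"])
            lat = extract_measures(w, eff).area_lat
            assert lat >= prev
            prev = lat

    def test_onset_monotone_in_perc_amp(self):
        t = np.arange(0, 1.0, 0.004)
        w = 5 * np.exp(-((t - 0.5) ** 2) / (2 * 0.1**2))
        prev = -np.inf
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            eff = make_effective(w, perc_amp=p, peak_width=0, extract=["onset", "offset"])
            m = extract_measures(w, eff)
            assert m.onset >= prev
            prev = m.onset

    def test_counter_peak_baseline_recovers_drifted_onset(self):
        """Peak-to-peak thresholds are immune to a constant offset."""
        t = np.arange(0, 1.0, 0.002)
        base = 10 * np.exp(-((t - 0.6) ** 2) / (2 * 0.08**2)) - 3 * np.exp(
            -((t - 0.3) ** 2) / (2 * 0.05**2)
        )
        drifted = base + 2.0  # detached from the pre-stimulus baseline
        kwargs = dict(
            peak_win=(200, 400),
            c_win_width=-150,
            perc_amp=0.5,
            peak_width=0,
            extract=["onset", "offset"],
        )
        m0 = extract_measures(base, make_effective(base, **kwargs))
        m1 = extract_measures(drifted, make_effective(drifted, **kwargs))
        assert m1.onset == pytest.approx(m0.onset, abs=1.0)

    def test_area_lat_beats_peak_lat_on_broad_noisy_component(self):
        """The std of 50%-area latency across noisy subjects stays at or

        below that of peak latency for a broad component."""
        rng = np.random.default_rng(42)
        t = np.arange(0, 1.2, 0.004)
        peaks, areas = [], []
        for _ in range(60):
            w = 6 * np.exp(-((t - 0.6) ** 2) / (2 * 0.12**2))
            w = w + 0.6 * rng.normal(size=t.size)
            eff = make_effective(w, peak_win=(50, 250), peak_width=2, extract=["peakLat", "areaLat"])
            m = extract_measures(w, eff)
            peaks.append(m.peak_lat)
            areas.append(m.area_lat)
        assert np.std(areas) <= np.std(peaks)
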