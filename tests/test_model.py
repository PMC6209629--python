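import dataclasses

import numpy as np
import pytest

from erplatency import (
    ConfigError,
    GroupAverages,
    LatencyConfig,
    TimeMap,
    extract_group,
    validate_and_fill,
)
from erplatency.model import ConflictError, WindowRangeError


def small_group(n_sub=3, n_chan=2, n_time=50, **kwargs):
    rng = np.random.default_rng(0)
    return GroupAverages(data=rng.normal(size=(n_sub, n_chan, n_time)), **kwargs)


class TestTimeMap:
    def test_axis_conversion(self):
        tm = TimeMap.from_axis(np.arange(0, 1.001, 0.001))
        assert tm.to_samples(0.14) == 140
        assert tm.to_units(140) == pytest.approx(0.14)

    def test_identity_map(self):
        tm = TimeMap.make_identity(100)
        assert tm.to_samples(37) == 37
        assert tm.to_units(37) == 37

    def test_round_trip_on_grid(self):
        tm = TimeMap.from_axis(-0.1 + np.arange(111) * 0.01)
        for idx in [0, 17, 110]:
            assert tm.to_samples(tm.to_units(idx)) == idx

    def test_out_of_range_errors(self):
        tm = TimeMap.from_axis(np.arange(0, 1.001, 0.001))
        with pytest.raises(WindowRangeError):
            tm.to_samples(2.0)

    def test_window_rounds_inward(self):
        tm = TimeMap.from_axis(np.arange(0.0, 10.5, 1.0))
        assert tm.window_to_samples((1.3, 7.8)) == (2, 7)

    def test_nonuniform_axis_rejected(self):
        with pytest.raises(ConfigError):
            TimeMap.from_axis(np.array([0.0, 1.0, 3.0]))


class TestGroupAverages:
    def test_metadata_length_checks(self):
        with pytest.raises(ConfigError):
            small_group(subject_ids=[1, 2])
        with pytest.raises(ConfigError):
            small_group(channel_names=["a"])
        with pytest.raises(ConfigError):
            small_group(time_axis=np.arange(10))

    def test_nan_rejected(self):
        data = np.zeros((2, 1, 10))
        data[0, 0, 3] = np.nan
        with pytest.raises(ConfigError):
            GroupAverages(data=data)

    def test_triple_time_axis_expansion(self):
        g = small_group(n_time=101, time_axis=(0.0, 1.0, 100.0))
        assert g.time_axis[0] == 0.0
        assert g.time_axis[-1] == pytest.approx(1.0)
        assert len(g.time_axis) == 101

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ConfigError):
            small_group(n_time=50, time_axis=(0.0, 1.0, 100.0))


class TestValidateAndFill:
    def test_defaults_fill_table(self):
        g = small_group()
        eff = validate_and_fill(LatencyConfig(sign=1), g)
        assert eff.peak_win == (0, 49)  # whole range
        assert eff.perc_amp == 0.5
        assert eff.perc_area == 0.5
        assert eff.area_win == "peakWin"
        assert eff.area_base == "zero"
        assert eff.amp_lat_win == (0, 49)
        assert eff.aggregate == "individual"
        assert eff.peak_width == 5
        assert eff.c_bound is True and eff.warnings is True
        assert "peak_win" in eff.filled and "perc_amp" in eff.filled

    def test_mean_time_defaults_to_peak_win(self):
        g = small_group()
        eff = validate_and_fill(LatencyConfig(sign=1, peak_win=(10, 30)), g)
        assert eff.mean_win == eff.peak_win == (10, 30)

    def test_missing_sign_is_config_error(self):
        with pytest.raises(ConfigError):
            validate_and_fill(LatencyConfig(), small_group())

    def test_sign_spellings(self):
        g = small_group()
        for spelling in ("pos", "+1", 1):
            assert validate_and_fill(LatencyConfig(sign=spelling), g).sign == 1
        for spelling in ("neg", "-1", -1):
            assert validate_and_fill(LatencyConfig(sign=spelling), g).sign == -1

    def test_conflicting_counter_windows(self):
        with pytest.raises(ConflictError):
            validate_and_fill(
                LatencyConfig(sign=1, c_win=(0, 10), c_win_width=-5), small_group()
            )

    def test_window_outside_range(self):
        with pytest.raises(WindowRangeError):
            validate_and_fill(LatencyConfig(sign=1, peak_win=(10, 200)), small_group())

    def test_boolean_mask_length_enforced(self):
        g = small_group(n_sub=3)
        with pytest.raises(ConfigError):
            validate_and_fill(LatencyConfig(sign=1, subs=[True, False]), g)
        eff = validate_and_fill(LatencyConfig(sign=1, subs=[True, False, True]), g)
        assert list(eff.sub_idx) == [0, 2]

    def test_subject_numbers_and_channel_names(self):
        g = small_group(subject_ids=[101, 102, 103], channel_names=["Cz", "Pz"])
        eff = validate_and_fill(
            LatencyConfig(sign=1, subs=[103, 101], chans=["Pz"]), g
        )
        assert list(eff.sub_idx) == [2, 0]
        assert list(eff.chan_idx) == [1]
        assert eff.subject_labels == [103, 101]

    def test_idempotent(self):
        g = small_group(time_axis=np.arange(50) * 0.004)
        eff = validate_and_fill(LatencyConfig(sign=1, peak_win=(0.05, 0.15)), g)
        assert validate_and_fill(eff, g) is eff
        again = validate_and_fill(eff.config, g)
        skip = {"defaulted_fields", "description"}  # bookkeeping, not parameters
        a0 = {k: v for k, v in eff.annotation().items() if k not in skip}
        a1 = {k: v for k, v in again.annotation().items() if k not in skip}
        assert a0 == a1

    def test_unknown_measure_rejected(self):
        with pytest.raises(ConfigError):
            validate_and_fill(LatencyConfig(sign=1, extract=["peakLat", "bogus"]), small_group())

    def test_peak2peak_requires_counter(self):
        with pytest.raises(ConfigError):
            validate_and_fill(LatencyConfig(sign=1, extract=["peak2peak"]), small_group())
        eff = validate_and_fill(LatencyConfig(sign=1), small_group())
        assert "peak2peak" not in eff.extract  # dropped from 'all' w/o counter

    def test_config_dict_round_trip(self):
        cfg = LatencyConfig.from_dict(
            {"sign": 1, "peakWin": [0.14, 0.24], "percAmp": 0.3, "areaWin": "ampLat"}
        )
        assert cfg.peak_win == [0.14, 0.24]
        assert cfg.perc_amp == 0.3
        back = cfg.to_dict()
        assert back["percAmp"] == 0.3 and back["areaWin"] == "ampLat"
        with pytest.raises(ConfigError):
            LatencyConfig.from_dict({"sign": 1, "nonsense": 2})


def test_latencies_in_axis_units_iff_axis_given():
    """Same data with and without a time axis: latencies convert exactly."""
    rng = np.random.default_rng(5)
    from erplatency import ComponentSpec, component_waveform

    t = np.arange(0, 0.5001, 0.002)
    w = component_waveform(ComponentSpec("gaussian", 0.25, 0.04, 5.0), t)
    w = w + 0.1 * rng.normal(size=t.size)
    data = w[None, None, :]
    cfg = dict(sign=1, extract=["peakLat", "onset", "areaLat"], peak_width=0)
    res_units = extract_group(
        GroupAverages(data=data, time_axis=t), LatencyConfig(**cfg)
    ).wide()
    res_samples = extract_group(GroupAverages(data=data), LatencyConfig(**cfg)).wide()
    for m in ("peakLat", "onset", "areaLat"):
        assert res_units[m].iloc[0] == pytest.approx(
            0.0 + res_samples[m].iloc[0] * 0.002, abs=1e-12
        )
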