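"""Band filtering, segmentation, phase extraction and PLV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch

from plvnet.connectivity import (
    ALPHA,
    BETA,
    THETA,
    BandDefinition,
    RegionTimeSeries,
    bandpass,
    connectivity_matrix,
    instantaneous_phase,
    plv,
    read_timeseries_csv,
    segment,
    write_timeseries_csv,
)


def sine_ts(freq: float, fs: float = 256.0, duration: float = 30.0, n_regions: int = 1):
    t = np.arange(int(fs * duration)) / fs
    data = np.tile(np.cos(2 * np.pi * freq * t), (n_regions, 1))
    return RegionTimeSeries([f"r{i}" for i in range(n_regions)], data, fs)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        out = bandpass(sine_ts(10.0), ALPHA)
        core = out.data[0, 512:-512]  # away from filter edges
        assert np.abs(core).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        out = bandpass(sine_ts(10.0), THETA)
        core = out.data[0, 512:-512]
        assert np.abs(core).max() < 10 ** (-20 / 20)

    def test_white_noise_power_concentrates_in_band(self, rng):
        ts = RegionTimeSeries(["r0"], rng.standard_normal((1, 256 * 60)), 256.0)
        out = bandpass(ts, ALPHA)
        f, p = welch(out.data[0], fs=256.0, nperseg=1024)
        in_band = p[(f >= ALPHA.lo) & (f <= ALPHA.hi)].sum()
        assert in_band / p.sum() > 0.9

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sine_ts(10.0, fs=50.0), BETA)

    def test_zero_phase_no_group_delay(self):
        ts = sine_ts(10.0)
        out = bandpass(ts, ALPHA)
        # cross-correlation peak at zero lag
        a = ts.data[0, 512:-512]
        b = out.data[0, 512:-512]
        lags = range(-5, 6)
        corrs = [np.dot(a, np.roll(b, lag)) for lag in lags]
        assert list(lags)[int(np.argmax(corrs))] == 0


class TestSegment:
    @pytest.mark.parametrize(
        "duration, expected",
        [(300.0, 50), (6.0, 1), (11.9, 1), (18.0, 3)],
    )
    def test_counts_floor_rule(self, duration, expected):
        segs = segment(sine_ts(10.0, fs=256.0, duration=duration), 6.0)
        assert len(segs) == expected
        assert all(s.n_samples == 1536 for s in segs)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="segment"):
            segment(sine_ts(10.0, duration=3.0), 6.0)

    def test_segments_partition_the_signal(self):
        ts = sine_ts(10.0, duration=13.0)
        segs = segment(ts, 6.0)
        joined = np.concatenate([s.data for s in segs], axis=1)
        assert np.array_equal(joined, ts.data[:, : joined.shape[1]])


class TestInstantaneousPhase:
    def test_sinusoid_phase_slope(self):
        ts = sine_ts(10.0, duration=10.0)
        ph = np.unwrap(instantaneous_phase(ts)[0])
        core = slice(256, -256)
        slope = np.polyfit(np.arange(ts.n_samples)[core] / ts.fs, ph[core], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_quadrature_offset(self):
        t = np.arange(2560) / 256.0
        ts = RegionTimeSeries(
            ["c", "s"],
            np.vstack([np.cos(2 * np.pi * 10 * t), np.sin(2 * np.pi * 10 * t)]),
            256.0,
        )
        dphi = instantaneous_phase(ts)
        diff = np.angle(np.exp(1j * (dphi[0] - dphi[1])))[256:-256]
        assert np.allclose(diff, np.pi / 2, atol=0.01)

    def test_amplitude_invariance(self):
        ts = sine_ts(10.0, duration=5.0)
        scaled = RegionTimeSeries(ts.labels, 3.7 * ts.data, ts.fs)
        assert np.allclose(instantaneous_phase(ts), instantaneous_phase(scaled))

    def test_all_zero_signal_rejected(self):
        ts = RegionTimeSeries(["z", "x"], np.vstack([np.zeros(512), np.ones(512)]), 256.0)
        with pytest.raises(ValueError, match="z"):
            instantaneous_phase(ts)


class TestPLV:
    def test_identical_series_is_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 300)
        assert plv(ph, ph) == 1.0

    def test_antipodal_alternation_is_zero(self):
        x = np.zeros(100)
        y = np.tile([0.0, np.pi], 50)
        assert plv(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths differ"):
            plv(np.zeros(5), np.zeros(6))

    def test_rayleigh_null_second_moment(self, rng):
        # independent uniform phases of length T: E[PLV^2] = 1/T
        T, reps = 128, 3000
        vals = np.array(
            [
                plv(rng.uniform(-np.pi, np.pi, T), rng.uniform(-np.pi, np.pi, T))
                for _ in range(reps)
            ]
        )
        assert (vals**2).mean() * T == pytest.approx(1.0, rel=0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        offset=st.floats(-10, 10, allow_nan=False),
        n=st.integers(2, 200),
    )
    def test_bounds_symmetry_offset_invariance(self, seed, offset, n):
        r = np.random.default_rng(seed)
        x = r.uniform(-np.pi, np.pi, n)
        y = r.uniform(-np.pi, np.pi, n)
        v = plv(x, y)
        assert 0.0 <= v <= 1.0
        assert plv(y, x) == pytest.approx(v, abs=1e-12)
        assert plv(x + offset, y) == pytest.approx(v, abs=1e-9)


class TestConnectivityMatrix:
    def test_duplicated_channels_lock_at_one(self, rng):
        sig = rng.standard_normal(256 * 30)
        ts = RegionTimeSeries(["a", "b"], np.vstack([sig, sig]), 256.0)
        cm = connectivity_matrix(ts, ALPHA)
        assert cm.values[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert cm.n_segments == 5

    def test_independent_channels_near_floor(self, rng):
        ts = RegionTimeSeries(
            ["a", "b", "c"], rng.standard_normal((3, 256 * 120)), 256.0
        )
        cm = connectivity_matrix(ts, ALPHA)
        off = cm.values[np.triu_indices(3, k=1)]
        assert np.all(off < 0.35)  # well below any real coupling
        assert np.all(off > 0.0)

    def test_pipeline_deterministic(self, rng):
        data = rng.standard_normal((4, 256 * 24))
        ts = RegionTimeSeries(list("abcd"), data, 256.0)
        cm1 = connectivity_matrix(ts, BETA)
        cm2 = connectivity_matrix(ts, BETA)
        assert np.array_equal(cm1.values, cm2.values)

    def test_matrix_contract(self, rng):
        ts = RegionTimeSeries(
            ["a", "b", "c"], rng.standard_normal((3, 256 * 12)), 256.0
        )
        cm = connectivity_matrix(ts, THETA)
        assert np.allclose(cm.values, cm.values.T)
        assert np.allclose(np.diag(cm.values), 1.0)
        assert cm.values.min() >= 0 and cm.values.max() <= 1

    def test_segment_averaging_reduces_spread(self, rng):
        # standard error of mean PLV shrinks roughly as 1/sqrt(n_segments)
        from plvnet.synthetic import OscillatorSpec, simulate_region_signals

        def spread(n_seg: int) -> float:
            vals = []
            for k in range(12):
                C = np.eye(2)
                C[0, 1] = C[1, 0] = 0.5
                spec = OscillatorSpec(
                    n_regions=2, band=ALPHA, fs=128.0, duration=n_seg * 6.0,
                    coupling=C, seed=1000 + k,
                )
                ts = simulate_region_signals(spec)
                vals.append(connectivity_matrix(ts, ALPHA).values[0, 1])
            return float(np.std(vals))

        s10, s90 = spread(10), spread(90)
        ratio = s10 / s90
        assert 1.3 < ratio < 9.0  # expect ~3, allow wide Monte-Carlo slack


def test_timeseries_csv_roundtrip(tmp_path, rng):
    ts = RegionTimeSeries(["a", "b"], rng.standard_normal((2, 100)), 128.0)
    write_timeseries_csv(ts, tmp_path / "ts.csv")
    back = read_timeseries_csv(tmp_path / "ts.csv")
    assert back.labels == ts.labels and back.fs == ts.fs
    assert np.allclose(back.data, ts.data)
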