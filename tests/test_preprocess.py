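"""Preprocessing chain: re-referencing, resampling, filtering, binning."""

import numpy as np
import pytest

from gcflow.preprocess import (
    DegenerateBinError,
    SsiSeries,
    bipolar_rereference,
    build_condition_samples,
    compute_ssi,
    detrend_zscore,
    downsample,
    exclude_noisy_bins,
    remove_line_noise,
)
from gcflow.synth import SignalRecord, simulate_recording


def _record(samples, rate=1000.0, state="awake", session="s0"):
    n = samples.shape[0]
    names = [f"e{i:03d}" for i in range(n)]
    return SignalRecord(samples=samples, rate=rate, channels=names,
                        region_of={c: "R" for c in names}, state=state,
                        session=session)


class TestBipolar:
    def test_half_channel_count_for_full_pairing(self, rng):
        rec = _record(rng.standard_normal((128, 500)))
        pairing = [(2 * i, 2 * i + 1) for i in range(64)]
        out = bipolar_rereference(rec, pairing)
        assert out.n_channels == 64
        assert np.allclose(out.samples[0], rec.samples[0] - rec.samples[1])

    def test_identical_signals_give_zero_channel(self, rng):
        x = rng.standard_normal(300)
        rec = _record(np.stack([x, x]))
        out = bipolar_rereference(rec, [(0, 1)])
        assert np.all(out.samples == 0)

    def test_electrode_reuse_raises(self, rng):
        rec = _record(rng.standard_normal((4, 100)))
        with pytest.raises(ValueError):
            bipolar_rereference(rec, [(0, 3), (3, 1)])

    def test_unpaired_electrode_dropped_with_warning(self, rng, caplog):
        rec = _record(rng.standard_normal((5, 100)))
        with caplog.at_level("WARNING"):
            out = bipolar_rereference(rec, [(0, 1), (2, 3)])
        assert out.n_channels == 2
        assert any("unpaired" in r.message for r in caplog.records)


class TestDownsample:
    def test_1khz_to_200hz_sample_count(self, rng):
        rec = _record(rng.standard_normal((3, 10_000)), rate=1000.0)
        out = downsample(rec, 200.0)
        assert out.samples.shape == (3, 2000)
        assert out.rate == 200.0

    def test_constant_preserved(self):
        rec = _record(np.full((2, 5000), 3.7), rate=1000.0)
        assert np.allclose(downsample(rec, 200.0).samples, 3.7, atol=1e-9)

    def test_in_band_sinusoid_amplitude_preserved(self):
        t = np.arange(20_000) / 1000.0
        rec = _record(np.sin(2 * np.pi * 30.0 * t)[None, :], rate=1000.0)
        out = downsample(rec, 200.0).samples[0]
        amp = np.sqrt(2) * out[100:-100].std()
        assert abs(amp - 1.0) < 0.05

    def test_non_integer_factor_raises(self, rng):
        rec = _record(rng.standard_normal((2, 1000)), rate=1000.0)
        with pytest.raises(ValueError):
            downsample(rec, 300.0)


class TestLineNoise:
    def test_pure_50hz_attenuated_20db(self):
        t = np.arange(400) / 200.0
        x = np.sin(2 * np.pi * 50.0 * t + 0.7)[None, :]
        y = remove_line_noise(x, f0=50.0, rate=200.0)
        e = np.exp(-2j * np.pi * 50.0 * t)
        before = np.abs(x[0] @ e) ** 2
        after = np.abs(y[0] @ e) ** 2
        assert 10 * np.log10(before / max(after, 1e-300)) >= 20.0

    def test_zero_input_stays_zero(self):
        assert np.all(remove_line_noise(np.zeros((3, 400))) == 0)

    def test_broadband_power_outside_notch_nearly_unchanged(self, rng):
        t = np.arange(400)
        deltas = []
        for _ in range(100):
            x = rng.standard_normal((1, 400))
            y = remove_line_noise(x)
            f = np.fft.rfftfreq(400, d=1 / 200.0)
            keep = (f < 48) | (f > 52)
            p0 = np.sum(np.abs(np.fft.rfft(x[0]))[keep] ** 2)
            p1 = np.sum(np.abs(np.fft.rfft(y[0]))[keep] ** 2)
            deltas.append(abs(p1 - p0) / p0)
        assert np.mean(deltas) < 0.05

    def test_line_frequency_at_nyquist_raises(self):
        with pytest.raises(ValueError):
            remove_line_noise(np.zeros((1, 400)), f0=100.0, rate=200.0)


class TestDetrendZscore:
    def test_output_standardized(self, rng):
        out = detrend_zscore(rng.standard_normal((5, 40)))
        assert np.allclose(out.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(out.std(axis=1), 1, atol=1e-9)

    def test_exact_line_is_degenerate(self):
        t = np.arange(40.0)
        with pytest.raises(DegenerateBinError):
            detrend_zscore((2.0 + 3.0 * t)[None, :])

    def test_quadratic_matches_ols_oracle(self):
        t = np.arange(40.0)
        x = t**2
        X = np.column_stack([np.ones(40), t])
        beta = np.linalg.lstsq(X, x, rcond=None)[0]
        r = x - X @ beta
        expected = (r - r.mean()) / r.std()
        got = detrend_zscore(x[None, :])[0]
        assert np.allclose(got, expected, atol=1e-9)

    def test_idempotent(self, rng):
        once = detrend_zscore(rng.standard_normal((3, 40)))
        assert np.allclose(detrend_zscore(once), once, atol=1e-9)


class TestNoisyBins:
    def test_clean_data_no_rejections(self, rng):
        bins = rng.standard_normal((20, 4, 400))
        kept, rejected = exclude_noisy_bins(bins)
        assert rejected == [] and len(kept) == 20

    def test_spike_bin_rejected(self, rng):
        bins = rng.standard_normal((20, 4, 400))
        bins[7, 2, 100] = 50.0
        kept, rejected = exclude_noisy_bins(bins)
        assert rejected == [7] and 7 not in kept

    def test_infinite_threshold_is_identity(self, rng):
        bins = rng.standard_normal((10, 2, 400)) * 100
        kept, rejected = exclude_noisy_bins(bins, amplitude_z_max=np.inf)
        assert rejected == []

    def test_all_rejected_raises(self, rng):
        bins = rng.standard_normal((3, 2, 400))
        bins[:, :, ::7] += 1000.0
        with pytest.raises(ValueError):
            exclude_noisy_bins(bins, amplitude_z_max=0.5)


class TestSsi:
    def test_identical_channels_give_one(self, rng):
        x = rng.standard_normal(400)
        assert compute_ssi(np.stack([x, x, x])) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self, rng):
        vals = [abs(compute_ssi(rng.standard_normal((64, 400)))) for _ in range(300)]
        assert np.percentile(vals, 95) < 0.1

    def test_global_slow_wave_admitted(self, rng):
        t = np.arange(400) / 200.0
        wave = np.sin(2 * np.pi * 2.0 * t)
        x = wave[None, :] + 0.3 * rng.standard_normal((16, 400))
        assert compute_ssi(x) > 0.25

    def test_single_channel_raises(self, rng):
        with pytest.raises(ValueError):
            compute_ssi(rng.standard_normal((1, 400)))

    def test_series_threshold_validation(self):
        with pytest.raises(ValueError):
            SsiSeries(np.array([0.1, 0.2]), threshold=1.5)
        s = SsiSeries(np.array([0.1, 0.4]))
        assert list(s.admitted()) == [False, True]


class TestConditionSamples:
    def test_default_geometry_600_short_bins(self, two_channel_net):
        recs = [simulate_recording(two_channel_net, "awake", 380, seed=1, session=f"s{i}")
                for i in range(2)]
        sets = build_condition_samples(recs, n_samples=6, bins_per_sample=60, seed=0)
        assert len(sets) == 6
        for bs in sets:
            assert bs.n_short == 600
            assert bs.bins.shape[2] == 40

    def test_disjoint_selection_and_equal_session_shares(self, two_channel_net):
        recs = [simulate_recording(two_channel_net, "awake", 380, seed=1, session=f"s{i}")
                for i in range(2)]
        sets = build_condition_samples(recs, n_samples=6, bins_per_sample=60, seed=0)
        parents = [set(bs.parent_bins) for bs in sets]
        for i in range(6):
            for j in range(i + 1, 6):
                assert not (parents[i] & parents[j])
            per_session = {s: 0 for s in ("s0", "s1")}
            for sess, _ in parents[i]:
                per_session[sess] += 1
            assert per_session == {"s0": 30, "s1": 30}

    def test_selection_reproducible(self, two_channel_net):
        recs = [simulate_recording(two_channel_net, "awake", 120, seed=2)]
        a = build_condition_samples(recs, 2, 12, seed=7)
        b = build_condition_samples(recs, 2, 12, seed=7)
        assert all(np.array_equal(x.bins, y.bins) for x, y in zip(a, b))
        assert a[0].parent_bins == b[0].parent_bins

    def test_insufficient_bins_raise_with_deficit(self, two_channel_net):
        recs = [simulate_recording(two_channel_net, "awake", 30, seed=3)]
        with pytest.raises(ValueError, match="clean bins"):
            build_condition_samples(recs, 6, 60, seed=0)

    def test_metadata_preserved(self, two_channel_net):
        recs = [simulate_recording(two_channel_net, "unconscious", 60, seed=4)]
        bs = build_condition_samples(recs, 1, 12, seed=0)[0]
        assert bs.state == "unconscious"
        assert bs.channels == recs[0].channels
        assert bs.region_of == recs[0].region_of
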