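"""Preprocessing-chain contracts: detection, repair, ICA, filter,
rejection, referencing, resampling, baseline and the full pipeline."""

import numpy as np
import pytest
from dataclasses import replace

from mmndecode.containers import EpochSet, extract_epochs
from mmndecode.preprocess import (PreprocConfig, band_power_50hz, bandpass,
                                  baseline_correct, crop_epochs,
                                  detect_bad_channels, ica_remove_artifacts,
                                  reject_epochs, repair_channels_spline,
                                  rereference, resample, run_pipeline)
from mmndecode.simulate import (ComponentTemplate, ParadigmSpec, SimConfig,
                                generate_sequence, render_recording)
from mmndecode.spline import spline_g


def _epochs(small_montage, data, fs=256.0):
    n_ep, _, n = data.shape
    labels = np.array(["standard"] * n_ep, dtype=object)
    times = (np.arange(n) - n // 8) * 1000.0 / fs
    return EpochSet(np.asarray(data, float), labels, times, fs, small_montage)


class TestBadChannels:
    def test_constant_offset_flagged(self, small_montage):
        data = np.zeros((2, 11, 256))
        data[0, 3, :] = 40000.0  # 40 mV > 35 mV
        ep = _epochs(small_montage, data)
        bad = detect_bad_channels(ep, PreprocConfig())
        assert list(bad[0]) == [3]
        assert list(bad[1]) == []

    def test_line_power_closed_form(self, small_montage):
        # One-second epoch at 256 Hz puts 50 Hz exactly on a periodogram
        # bin: integrated band power of a sinusoid of amplitude A is A^2/2.
        fs, n = 256.0, 256
        t = np.arange(n) / fs
        amp = np.sqrt(2 * 1200.0)  # band power 1200 μV² > 1000
        data = np.zeros((1, 11, n))
        data[0, 2] = amp * np.sin(2 * np.pi * 50 * t)
        ep = _epochs(small_montage, data, fs)
        power = band_power_50hz(data[0, 2], fs)
        assert power == pytest.approx(1200.0, rel=1e-6)
        bad = detect_bad_channels(ep, PreprocConfig())
        assert list(bad[0]) == [2]

    def test_clean_channel_not_flagged(self, small_montage):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 10, size=(3, 11, 256))
        ep = _epochs(small_montage, data)
        bad = detect_bad_channels(ep, PreprocConfig())
        assert all(len(b) == 0 for b in bad)

    def test_low_rate_rejected(self, small_montage):
        ep = _epochs(small_montage, np.zeros((1, 11, 16)), fs=32.0)
        with pytest.raises(ValueError, match="50 Hz"):
            detect_bad_channels(ep, PreprocConfig())


class TestSplineRepair:
    def test_spline_generated_data_recovered(self, montage):
        # Forward-generate data from the same spherical-spline model used
        # by the repair: a random spline over the good electrodes.
        rng = np.random.default_rng(3)
        eeg = montage.eeg_indices
        bad = [int(eeg[10])]
        good = [int(i) for i in eeg if i != bad[0]]
        pos = montage.positions
        c = rng.normal(size=len(good))
        c -= c.mean()  # spline weights sum to zero
        c0 = rng.normal()
        pot = lambda p: spline_g(p @ pos[good].T) @ c + c0
        n = 8
        v_good = np.tile(pot(pos[good])[:, None], (1, n))
        v_bad = pot(pos[bad])[0]
        data = np.zeros((1, len(montage), n))
        data[0, good] = v_good
        data[0, bad[0]] = 999.0  # corrupted
        ep = EpochSet(data, np.array(["standard"], dtype=object),
                      np.arange(n) * 1000 / 256, 256.0, montage)
        out = repair_channels_spline(ep, [bad])
        assert out.data[0, bad[0], 0] == pytest.approx(v_bad, rel=0.01)
        # Good channels untouched.
        np.testing.assert_array_equal(out.data[0, good], data[0, good])

    def test_zero_data_stays_zero(self, montage):
        n = 4
        data = np.zeros((1, len(montage), n))
        ep = EpochSet(data, np.array(["standard"], dtype=object),
                      np.arange(n) * 1000 / 256, 256.0, montage)
        out = repair_channels_spline(ep, [[3, 7]])
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_empty_bad_list_identity(self, small_montage):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 11, 8))
        ep = _epochs(small_montage, data)
        out = repair_channels_spline(ep, [[], []])
        np.testing.assert_array_equal(out.data, ep.data)

    def test_too_few_good_channels(self, small_montage):
        ep = _epochs(small_montage, np.zeros((1, 11, 8)))
        with pytest.raises(ValueError, match="good channels"):
            repair_channels_spline(ep, [[0, 1, 2, 3, 4]])


class TestICA:
    def _mixed_epochs(self, small_montage, seed=0, blink_gain=10.0):
        rng = np.random.default_rng(seed)
        n_ep, n = 60, 64
        k = 11
        sources = rng.laplace(size=(k, n_ep * n))
        blink = np.zeros(n_ep * n)
        for s in rng.integers(0, n_ep * n - 40, size=40):
            blink[s:s + 30] += np.hanning(30)
        sources[0] = blink * blink_gain / max(blink.std(), 1e-9)
        mixing = rng.normal(size=(11, k))
        mixing[:, 0] = np.abs(mixing[:, 0]) + 1.0  # frontal-ish projection
        X = (mixing @ sources).reshape(11, n_ep, n).transpose(1, 0, 2)
        return _epochs(small_montage, X), mixing, sources

    def test_reprojection_identity_without_removal(self, small_montage):
        ep, _, _ = self._mixed_epochs(small_montage)
        out, report = ica_remove_artifacts(ep, PreprocConfig(), remove=[])
        assert np.abs(out.data - ep.data).max() < 1e-6

    def test_high_variance_component_removed(self, small_montage):
        ep, mixing, sources = self._mixed_epochs(small_montage,
                                                 blink_gain=10.0)
        out, report = ica_remove_artifacts(ep, PreprocConfig())
        assert len(report["removed"]) >= 1
        # The cleaned data should be much closer to the blink-free mixture.
        clean = (mixing[:, 1:] @ sources[1:]).reshape(
            11, 60, 64).transpose(1, 0, 2)
        before = np.linalg.norm(ep.data - clean)
        after = np.linalg.norm(out.data - clean)
        assert after < 0.5 * before

    def test_too_few_samples(self, small_montage):
        ep = _epochs(small_montage, np.zeros((1, 11, 4)))
        with pytest.raises(ValueError, match="too few samples"):
            ica_remove_artifacts(ep, PreprocConfig())


class TestFilter:
    def test_50hz_attenuation(self, small_montage):
        # Long signal: the 0.5 Hz high-pass corner rings for seconds, so
        # the steady-state response is read from the central section.
        fs = 256.0
        t = np.arange(int(fs * 24)) / fs
        x = np.sin(2 * np.pi * 50 * t)
        data = np.tile(x, (1, 11, 1))
        ep = _epochs(small_montage, data, fs)
        out = bandpass(ep, 0.5, 13.0)
        mid = slice(3 * len(t) // 8, 5 * len(t) // 8)
        ratio = np.sqrt(np.mean(out.data[0, 0, mid] ** 2)) / np.sqrt(
            np.mean(x[mid] ** 2))
        assert ratio <= 0.01

    def test_passband_within_1db(self, small_montage):
        fs = 256.0
        t = np.arange(int(fs * 8)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        data = np.tile(x, (1, 11, 1))
        out = bandpass(_epochs(small_montage, data, fs), 0.5, 13.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = np.sqrt(np.mean(out.data[0, 0, mid] ** 2)) / np.sqrt(
            np.mean(x[mid] ** 2))
        assert 10 ** (-1 / 20) <= ratio <= 10 ** (1 / 20)

    def test_zero_phase_no_latency_shift(self, small_montage):
        fs = 256.0
        n = 1024
        x = np.zeros(n)
        # Smooth symmetric pulse in the passband.
        t = np.arange(n) / fs
        x = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)
        data = np.tile(x, (1, 11, 1))
        out = bandpass(_epochs(small_montage, data, fs), 0.5, 13.0)
        assert abs(int(np.argmax(out.data[0, 0])) - int(np.argmax(x))) <= 1

    def test_high_cutoff_above_nyquist_rejected(self, small_montage):
        ep = _epochs(small_montage, np.zeros((1, 11, 256)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ep, 0.5, 200.0)


class TestRejectionReferenceResample:
    def test_rejection_rules(self, small_montage):
        data = np.zeros((3, 11, 16))
        data[0, 2, 5] = 80.0  # eeg channel above 75 μV -> rejected
        data[1, 3, 2] = 74.9  # below threshold -> kept
        data[2, 10, 4] = 200.0  # EOG-only excursion -> kept
        ep = _epochs(small_montage, data)
        out, rejected = reject_epochs(ep, 75.0)
        assert list(rejected) == [0]
        assert out.n_epochs == 2

    def test_all_rejected_warns(self, small_montage):
        data = np.full((2, 11, 4), 100.0)
        ep = _epochs(small_montage, data)
        with pytest.warns(UserWarning, match="all epochs"):
            out, rejected = reject_epochs(ep, 75.0)
        assert out.n_epochs == 0

    def test_mastoid_reference_zeroes_mastoid_mean(self, small_montage):
        rng = np.random.default_rng(2)
        ep = _epochs(small_montage, rng.normal(size=(3, 11, 8)))
        out = rereference(ep, "mastoid")
        mast = small_montage.role_indices("mastoid")
        np.testing.assert_allclose(
            out.data[:, mast, :].mean(axis=1), 0.0, atol=1e-12)

    def test_car_zeroes_eeg_mean(self, small_montage):
        rng = np.random.default_rng(2)
        ep = _epochs(small_montage, rng.normal(size=(3, 11, 8)))
        out = rereference(ep, "CAR")
        eeg = small_montage.eeg_indices
        np.testing.assert_allclose(
            out.data[:, eeg, :].mean(axis=1), 0.0, atol=1e-12)

    def test_spatially_constant_data_zero_under_car(self, small_montage):
        data = np.ones((2, 11, 8)) * 7.5
        out = rereference(_epochs(small_montage, data), "CAR")
        eeg = small_montage.eeg_indices
        np.testing.assert_allclose(out.data[:, eeg, :], 0.0, atol=1e-12)

    def test_laplacian_kills_spatially_constant_data(self, montage):
        data = np.ones((1, len(montage), 8))
        ep = EpochSet(data, np.array(["standard"], dtype=object),
                      np.arange(8) * 1000 / 256, 256.0, montage)
        out = rereference(ep, "laplacian")
        eeg = montage.eeg_indices
        assert np.abs(out.data[0, eeg]).max() < 1e-6

    def test_resample_256_to_32(self, small_montage):
        ep = _epochs(small_montage, np.zeros((2, 11, 128)))
        out = resample(ep, 32.0)
        assert out.n == 16
        assert out.sample_rate == 32.0
        assert np.allclose(np.diff(out.times), 1000.0 / 32)

    def test_resample_band_limited_rms_error(self, small_montage):
        fs = 256.0
        t = np.arange(1024) / fs
        x = np.sin(2 * np.pi * 6 * t)
        ep = _epochs(small_montage, np.tile(x, (1, 11, 1)), fs)
        down = resample(ep, 32.0)
        t32 = t[::8]
        expected = np.sin(2 * np.pi * 6 * t32)
        mid = slice(8, -8)  # ignore polyphase edge transients
        err = np.sqrt(np.mean((down.data[0, 0, mid] - expected[mid]) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(expected[mid] ** 2))

    def test_resample_identity(self, small_montage):
        ep = _epochs(small_montage, np.ones((1, 11, 64)))
        assert resample(ep, 256.0) is ep

    def test_resample_nyquist_guard(self, small_montage):
        ep = _epochs(small_montage, np.zeros((1, 11, 128)))
        with pytest.raises(ValueError, match="Nyquist"):
            resample(ep, 16.0, band_high_hz=13.0)


class TestBaseline:
    def test_constant_offset_removed(self, small_montage):
        ep = _epochs(small_montage, np.full((2, 11, 32), 3.3))
        out = baseline_correct(ep, (-50, 0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_mean_window_unchanged(self, small_montage):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(1, 11, 32))
        ep = _epochs(small_montage, data)
        mask = (ep.times >= -50) & (ep.times <= 0)
        data -= data[:, :, mask].mean(axis=2, keepdims=True)
        ep2 = _epochs(small_montage, data)
        out = baseline_correct(ep2, (-50, 0))
        np.testing.assert_allclose(out.data, ep2.data, atol=1e-12)

    def test_window_outside_epoch_errors(self, small_montage):
        ep = _epochs(small_montage, np.zeros((1, 11, 32)))
        with pytest.raises(ValueError, match="baseline window"):
            baseline_correct(ep, (-4000, -3000))


@pytest.fixture(scope="module")
def sim_recording(montage):
    cfg = SimConfig(seed=17, montage=montage)
    spec = ParadigmSpec(n_trials=60, deviant_proportion=0.15)
    labels, onsets = generate_sequence(spec, seed=17)
    from mmndecode.simulate import default_templates
    return render_recording(labels, onsets, default_templates(montage),
                            cfg, rng=np.random.default_rng(17))


class TestPipeline:
    def test_default_pipeline_shape(self, sim_recording):
        epochs, report = run_pipeline(sim_recording, PreprocConfig())
        assert epochs.sample_rate == 32.0
        assert epochs.n == 16
        assert epochs.n_epochs > 0
        stages = [s["stage"] for s in report.stages]
        assert stages.index("bad_channel_repair") < stages.index("ica")
        assert stages.index("ica") < stages.index("filter")
        assert stages.index("filter") < stages.index("reject")
        assert stages.index("reject") < stages.index("reference")

    def test_all_stages_off_equals_raw_extraction(self, sim_recording):
        cfg = PreprocConfig(
            bad_channel_enabled=False, ica_enabled=False,
            filter_enabled=False, reject_enabled=False, reference="none",
            resample_to_hz=0.0,
        )
        epochs, _ = run_pipeline(sim_recording, cfg)
        raw = extract_epochs(sim_recording, (-50, 450))
        raw = baseline_correct(raw, (-50, 0))
        np.testing.assert_allclose(epochs.data, raw.data, atol=1e-9)

    def test_seeded_run_identical_report(self, sim_recording):
        ep1, r1 = run_pipeline(sim_recording, PreprocConfig())
        ep2, r2 = run_pipeline(sim_recording, PreprocConfig())
        assert r1.to_json() == r2.to_json()
        np.testing.assert_array_equal(ep1.data, ep2.data)

    def test_label_agnostic_epoch_permutation(self, sim_recording):
        # With the (order-sensitive) ICA fit disabled, permuting epochs
        # permutes the outputs identically: no cross-epoch leakage.
        cfg = PreprocConfig(ica_enabled=False, reject_enabled=False)
        epochs, _ = run_pipeline(sim_recording, cfg)
        ep_raw = extract_epochs(sim_recording, (-200, 600))
        perm = np.random.default_rng(0).permutation(ep_raw.n_epochs)
        ep_perm = ep_raw.select_epochs(perm)
        from mmndecode.preprocess import (bandpass as bp,
                                          baseline_correct as bc)

        def chain(e):
            e = bp(e, 0.5, 13.0)
            e = bc(e, (-50, 0))
            e = rereference(e, "mastoid")
            e = crop_epochs(e, (-50, 450))
            e = resample(e, 32.0)
            return bc(e, (-50, 0))

        a = chain(ep_raw).data[perm]
        b = chain(ep_perm).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_filter_resample_commute_for_band_limited(self, small_montage):
        fs = 256.0
        t = np.arange(int(fs * 24)) / fs
        x = (np.sin(2 * np.pi * 3 * t) + 0.5 * np.sin(2 * np.pi * 8 * t))
        ep = _epochs(small_montage, np.tile(x, (1, 11, 1)), fs)
        a = resample(bandpass(ep, 0.5, 13.0), 32.0).data[0, 0]
        b = bandpass(resample(ep, 32.0), 0.5, 13.0).data[0, 0]
        n32 = len(a)
        mid = slice(3 * n32 // 8, 5 * n32 // 8)
        rms = np.sqrt(np.mean((a[mid] - b[mid]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(a[mid] ** 2))

    def test_flat_config_roundtrip_and_unknown_key(self):
        cfg = PreprocConfig.from_flat({"filter.low_hz": 1.0,
                                       "reject.threshold_uv": 100.0})
        assert cfg.filter_low_hz == 1.0
        assert cfg.reject_threshold_uv == 100.0
        with pytest.raises(KeyError, match="unknown"):
            PreprocConfig.from_flat({"filter.lowpass": 1.0})
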