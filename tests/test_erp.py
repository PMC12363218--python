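"""EEG preprocessing: filter response, referencing, EOG regression,
baseline, artifact rejection, interpolation, labeling, averaging,
windowed means."""

import numpy as np
import pandas as pd
import pytest

from maskerp.containers import EpochSet
from maskerp.erp import (
    N170_SPEC,
    P1_SPEC,
    ComponentSpec,
    PreprocessConfig,
    RejectionSpec,
    average_reference,
    bandpass,
    baseline_correct,
    condition_average,
    eog_correct,
    interpolate_bad_channels,
    label_awareness,
    preprocess,
    reject_artifacts,
    window_mean,
)

SFREQ = 512.0


def _epochs(data, ch_names=None, ch_types=None, metadata=None):
    n_ch = data.shape[1]
    ch_names = ch_names or [f"ch{i}" for i in range(n_ch)]
    ch_types = ch_types or ["eeg"] * n_ch
    return EpochSet(data=data, sfreq=SFREQ, ch_names=ch_names, ch_types=ch_types,
                    tmin=-0.2, metadata=metadata)


class TestBandpass:
    def test_dc_removed_after_settling(self):
        # 10 minutes of constant signal: the 0.01-Hz high-pass suppresses DC
        x = np.full((1, int(600 * SFREQ)), 5.0)
        y = bandpass(x, SFREQ)
        mid = y[0, y.shape[1] // 4 : -y.shape[1] // 4]
        assert np.abs(mid).max() < 0.05 * 5.0

    def test_10hz_passband_attenuation_below_5pct(self):
        t = np.arange(int(60 * SFREQ)) / SFREQ
        x = np.sin(2 * np.pi * 10 * t)[None]
        y = bandpass(x, SFREQ)
        mid = y[0, len(t) // 4 : -len(t) // 4]
        amp = np.ptp(mid) / 2
        assert amp > 0.95

    def test_80hz_attenuation_matches_butterworth_magnitude(self):
        # zero-phase order-4 low-pass: gain |H(f)|^2 with
        # |H(f)|^2 = 1/(1+(f/fc)^8); measured by quadrature demodulation so
        # low-frequency edge transients do not contaminate the estimate
        t = np.arange(int(60 * SFREQ)) / SFREQ
        f = 80.0
        x = np.sin(2 * np.pi * f * t)[None]
        y = bandpass(x, SFREQ)
        sl = slice(len(t) // 4, -len(t) // 4)
        s, c = np.sin(2 * np.pi * f * t[sl]), np.cos(2 * np.pi * f * t[sl])
        amp = np.hypot(2 * np.mean(y[0, sl] * s), 2 * np.mean(y[0, sl] * c))
        # digital (bilinear-transformed) Butterworth: the frequency axis is
        # prewarped, ratio tan(pi f/fs) / tan(pi fc/fs)
        ratio = np.tan(np.pi * f / SFREQ) / np.tan(np.pi * 40.0 / SFREQ)
        expected = 1.0 / (1.0 + ratio**8)  # squared single-pass gain
        assert amp == pytest.approx(expected, rel=0.05)

    def test_bad_cutoffs_rejected(self):
        x = np.zeros((1, 100))
        with pytest.raises(ValueError):
            bandpass(x, SFREQ, high_hz=300.0)
        with pytest.raises(ValueError):
            bandpass(x, SFREQ, low_hz=50.0, high_hz=40.0)


class TestAverageReference:
    def test_scalp_mean_zero_everywhere(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.normal(size=(4, 6, 50)))
        out = average_reference(ep)
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_identical_channels_become_zero(self):
        base = np.random.default_rng(1).normal(size=(2, 1, 30))
        ep = _epochs(np.repeat(base, 5, axis=1))
        out = average_reference(ep)
        assert np.allclose(out.data, 0.0)

    def test_pairwise_differences_invariant(self):
        rng = np.random.default_rng(2)
        ep = _epochs(rng.normal(size=(3, 5, 40)))
        out = average_reference(ep)
        assert np.allclose(
            ep.data[:, 0] - ep.data[:, 3], out.data[:, 0] - out.data[:, 3], atol=1e-12
        )

    def test_eog_not_in_reference(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(2, 4, 20))
        ep = _epochs(data, ch_types=["eeg", "eeg", "eeg", "eog"])
        out = average_reference(ep)
        assert np.allclose(out.data[:, :3].mean(axis=1), 0.0, atol=1e-12)
        assert np.array_equal(out.data[:, 3], data[:, 3])


class TestEOGCorrect:
    def test_zero_eog_leaves_data_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 4, 60))
        data[:, 3, :] = 0.0
        ep = _epochs(data, ch_types=["eeg"] * 3 + ["eog"])
        with pytest.warns(UserWarning):
            out, B = eog_correct(ep)
        assert np.allclose(out.data[:, :3], data[:, :3])
        assert np.allclose(B, 0.0)

    def test_known_propagation_recovered(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(5, 3, 80))
        eog = rng.normal(size=(5, 1, 80)) * 50
        coefs = np.array([[0.3], [0.1], [-0.2]])
        data = np.concatenate([s + coefs[None, :, 0, None] * eog, eog], axis=1)
        ep = _epochs(data, ch_types=["eeg"] * 3 + ["eog"])
        out, B = eog_correct(ep)
        # regression on noiseless construction recovers s almost exactly
        resid = out.data[:, :3] - s
        resid -= resid.mean(axis=(0, 2), keepdims=True)  # mean offset is unidentified
        assert np.abs(resid).max() < 0.2
        assert B[:, 0] == pytest.approx(coefs[:, 0], abs=0.02)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 5, 64))
        ep = _epochs(data, ch_types=["eeg"] * 3 + ["eog", "eog"])
        _, B = eog_correct(ep)
        X = data[:, 3:, :].transpose(1, 0, 2).reshape(2, -1)
        Y = data[:, :3, :].transpose(1, 0, 2).reshape(3, -1)
        X = X - X.mean(1, keepdims=True)
        Y = Y - Y.mean(1, keepdims=True)
        B_oracle = Y @ X.T @ np.linalg.inv(X @ X.T)
        assert np.allclose(B, B_oracle, atol=1e-10)


class TestBaseline:
    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.normal(size=(3, 4, 513)))
        out = baseline_correct(ep)
        mask = out.times <= 0
        assert np.allclose(out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-12)

    def test_constant_epoch_zeroed(self):
        ep = _epochs(np.full((1, 2, 513), 5.0))
        assert np.allclose(baseline_correct(ep).data, 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 3, 513))
        a = baseline_correct(_epochs(data)).data
        b = baseline_correct(_epochs(data + 42.0)).data
        assert np.allclose(a, b, atol=1e-10)

    def test_empty_window_rejected(self):
        ep = _epochs(np.zeros((1, 1, 513)))
        with pytest.raises(ValueError):
            baseline_correct(ep, window_s=(-0.5, -0.4))


class TestRejection:
    def test_absolute_threshold(self):
        data = np.random.default_rng(0).normal(0, 5, size=(2, 3, 100))
        data[1, 0, 50] = 130.0
        keep, reasons = reject_artifacts(_epochs(data))
        assert keep[0] and not keep[1]
        assert "absolute" in reasons[1]

    def test_flat_epoch_rejected_as_low_signal(self):
        data = np.random.default_rng(0).normal(0, 5, size=(2, 3, 100))
        data[0] = 0.0
        keep, reasons = reject_artifacts(_epochs(data))
        assert not keep[0] and "low_signal" in reasons[0]

    def test_slow_large_sine_retained(self):
        # 50-uV 5-Hz sine at 512 Hz: max gradient ~3 uV/sample, well below 75
        t = np.arange(513) / SFREQ
        data = (50 * np.sin(2 * np.pi * 5 * t))[None, None] * np.ones((1, 3, 1))
        keep, _ = reject_artifacts(_epochs(data))
        assert keep[0]

    def test_gradient_threshold(self):
        t = np.arange(100)
        data = np.zeros((1, 2, 100))
        data[0, 1, 50] = 80.0  # single-sample spike: gradient 80 > 75
        keep, reasons = reject_artifacts(_epochs(data))
        assert not keep[0] and "gradient" in reasons[0]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 40, size=(50, 4, 120))
        ep = _epochs(data)
        keep_tight, _ = reject_artifacts(ep, RejectionSpec(100.0, 60.0, 0.02))
        keep_loose, _ = reject_artifacts(ep, RejectionSpec(150.0, 90.0, 0.005))
        assert (keep_loose | ~keep_tight).all()  # loosening never rejects more


class TestInterpolation:
    CHS = ["P9", "P7", "PO7", "P10", "P8", "PO8", "Oz", "POz", "Pz", "Cz", "Fz", "Fp1"]

    def _ep(self, data):
        return _epochs(data, ch_names=self.CHS, ch_types=["eeg"] * len(self.CHS))

    def test_constant_field_reproduced(self):
        data = np.full((2, len(self.CHS), 20), 7.0)
        out = interpolate_bad_channels(self._ep(data), ["PO7"])
        assert np.allclose(out.data[:, 2], 7.0, atol=0.2)

    def test_zero_field_stays_zero(self):
        data = np.zeros((1, len(self.CHS), 10))
        out = interpolate_bad_channels(self._ep(data), ["Oz"])
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_beats_inverse_distance_weighting_on_smooth_field(self):
        import mne

        montage = mne.channels.make_standard_montage("standard_1005")
        pos = {k: v for k, v in montage.get_positions()["ch_pos"].items()}
        xyz = np.array([pos[c] for c in self.CHS])
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        dipole = np.array([0.2, -0.6, 0.77])
        field = (xyz @ dipole) ** 3 + 0.5 * (xyz @ dipole)  # smooth on sphere
        data = np.tile(field[None, :, None], (1, 1, 5)) * 10
        bad = "PO7"
        bix = self.CHS.index(bad)
        out = interpolate_bad_channels(self._ep(data), [bad])
        spline_err = abs(out.data[0, bix, 0] - data[0, bix, 0])
        good = [i for i in range(len(self.CHS)) if i != bix]
        wdist = 1.0 / np.linalg.norm(xyz[good] - xyz[bix], axis=1)
        idw = (data[0, good, 0] * wdist).sum() / wdist.sum()
        idw_err = abs(idw - data[0, bix, 0])
        assert spline_err < idw_err

    def test_too_many_bads_rejected(self):
        data = np.zeros((1, len(self.CHS), 5))
        with pytest.raises(ValueError):
            interpolate_bad_channels(self._ep(data), self.CHS[:7])


class TestLabeling:
    @pytest.mark.parametrize(
        "isi,pas,expected",
        [
            (0, 1, "nonconscious"),
            (200, 3, "conscious"),
            (200, 2, "conscious"),
            (0, 4, "excluded"),
            (0, 2, "excluded"),
            (200, 1, "excluded"),
        ],
    )
    def test_awareness_mapping(self, isi, pas, expected):
        assert label_awareness([isi], [pas])[0] == expected


class TestAveragingAndWindow:
    def _labeled_epochs(self, n_per_cell, n_ch=3, n_t=513, value=1.0):
        rows, arrays = [], []
        rng = np.random.default_rng(0)
        for st in ("face", "scramble", "blank"):
            for isi, pas in ((0, 1), (200, 3)):
                for _ in range(n_per_cell):
                    rows.append({"stim_type": st, "isi_ms": isi, "pas": pas})
                    arrays.append(rng.normal(0, value, size=(n_ch, n_t)))
        return _epochs(np.stack(arrays), metadata=pd.DataFrame(rows))

    def test_min_trials_flags_participant(self):
        ep = self._labeled_epochs(39)
        _, ok39 = condition_average(ep, min_trials=40)
        _, ok_at_39 = condition_average(ep, min_trials=39)
        assert not ok39 and ok_at_39

    def test_average_matches_direct_mean(self):
        ep = self._labeled_epochs(5)
        table, _ = condition_average(ep, min_trials=1)
        md = ep.metadata
        mask = (md["stim_type"] == "face") & (md["isi_ms"] == 0)
        expected = ep.data[mask.to_numpy()].mean(axis=0)
        got = table.query("awareness == 'nonconscious' and stim_type == 'face'")["waveform"].iloc[0]
        assert np.allclose(got, expected)

    def test_identical_epochs_average_to_themselves(self):
        one = np.random.default_rng(1).normal(size=(2, 100))
        data = np.tile(one, (6, 1, 1))
        md = pd.DataFrame({"stim_type": ["face"] * 6, "isi_ms": [0] * 6, "pas": [1] * 6})
        table, _ = condition_average(_epochs(data, metadata=md), min_trials=1)
        got = table.query("awareness == 'nonconscious' and stim_type == 'face'")["waveform"].iloc[0]
        assert np.allclose(got, one)

    def test_window_mean_constant_and_ramp(self):
        times = -0.2 + np.arange(513) / SFREQ
        ch = ["P9", "P7", "PO7", "P10", "P8", "PO8"]
        const = np.full((6, 513), 3.3)
        assert window_mean(const, ch, times, P1_SPEC) == pytest.approx(3.3)
        ramp = np.tile(times[None], (6, 1))  # linear in time
        mask = (times >= 0.08) & (times <= 0.10)
        midpoint = times[mask].mean()
        assert window_mean(ramp, ch, times, P1_SPEC) == pytest.approx(midpoint)

    def test_window_mean_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        times = -0.2 + np.arange(513) / SFREQ
        ch = ["P9", "P7", "PO7", "P10", "P8", "PO8", "Oz"]
        wf = rng.normal(size=(7, 513))
        total, count = 0.0, 0
        for ci, c in enumerate(ch[:6]):
            for ti, t in enumerate(times):
                if 0.13 <= t <= 0.17:
                    total += wf[ci, ti]
                    count += 1
        assert window_mean(wf, ch, times, N170_SPEC) == pytest.approx(total / count)

    def test_missing_channel_rejected(self):
        times = -0.2 + np.arange(513) / SFREQ
        with pytest.raises(KeyError):
            window_mean(np.zeros((2, 513)), ["A", "B"], times, P1_SPEC)


def test_baseline_and_averaging_commute():
    rng = np.random.default_rng(4)
    data = rng.normal(size=(12, 3, 513))
    md = pd.DataFrame({"stim_type": ["face"] * 12, "isi_ms": [0] * 12, "pas": [1] * 12})
    ep = _epochs(data, metadata=md)
    a_then_b = baseline_correct(ep)
    tab, _ = condition_average(a_then_b, min_trials=1)
    avg1 = tab.query("awareness=='nonconscious' and stim_type=='face'")["waveform"].iloc[0]
    tab2, _ = condition_average(ep, min_trials=1)
    avg2 = tab2.query("awareness=='nonconscious' and stim_type=='face'")["waveform"].iloc[0]
    mask = ep.times <= 0
    avg2 = avg2 - avg2[:, mask].mean(axis=1, keepdims=True)
    assert np.allclose(avg1, avg2, atol=1e-10)
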