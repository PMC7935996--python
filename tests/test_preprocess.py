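"""Broadband filtering, Infomax-ICA round trips, epoch extraction."""

import numpy as np
import pytest

import eegdistract as ed
from eegdistract.signal_model import EEGRecording, TrialAnnotation


def _sine_recording(freq, fs=512.0, dur=12.0, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return EEGRecording(data=data, fs=fs,
                        channel_labels=[f"CH{i}" for i in range(n_ch)])


def _interior_rms_ratio(out, inp, fs, trim_s=2.0):
    s = slice(int(trim_s * fs), -int(trim_s * fs))
    return np.std(out.data[0, s]) / np.std(inp.data[0, s])


class TestBroadbandFilter:
    def test_passband_sine_preserved(self):
        rec = _sine_recording(10.0)
        out = ed.broadband_filter(rec)
        # oracle: realized zero-phase response at 10 Hz is 0.9999997
        assert 0.95 <= _interior_rms_ratio(out, rec, rec.fs) <= 1.0 + 1e-4

    def test_stopband_sine_attenuated(self):
        # oracle: realized zero-phase response of butter(4, [0.5, 48.5])
        # at 60 Hz is |H|^2 = 0.134
        rec = _sine_recording(60.0, dur=30.0)
        out = ed.broadband_filter(rec)
        ratio = _interior_rms_ratio(out, rec, rec.fs, trim_s=5.0)
        assert ratio < 0.2
        assert ratio == pytest.approx(0.134, rel=0.05)

    def test_zero_signal_stays_zero(self):
        rec = EEGRecording(data=np.zeros((2, 4096)), fs=512,
                           channel_labels=("A", "B"))
        out = ed.broadband_filter(rec)
        assert np.allclose(out.data, 0.0)

    def test_idempotent_on_band_limited_signal(self):
        # a signal already confined well inside the passband is (nearly)
        # unchanged, so a second application changes (nearly) nothing
        from scipy import signal as sig
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 30 * 512))
        sos = sig.butter(6, [2.0, 40.0], btype="bandpass", fs=512,
                         output="sos")
        rec = EEGRecording(data=sig.sosfiltfilt(sos, x, axis=1), fs=512,
                           channel_labels=("A", "B"))
        once = ed.broadband_filter(rec)
        twice = ed.broadband_filter(once)
        s = slice(2 * 512, -2 * 512)
        assert np.linalg.norm(once.data[:, s] - rec.data[:, s]) \
            / np.linalg.norm(rec.data[:, s]) < 0.06
        assert np.linalg.norm(twice.data[:, s] - once.data[:, s]) \
            / np.linalg.norm(once.data[:, s]) < 0.06

    def test_invalid_band_and_short_signal(self):
        rec = _sine_recording(10.0, fs=64.0, dur=4.0)
        with pytest.raises(ValueError):
            ed.broadband_filter(rec, hi_hz=48.5)  # above Nyquist at 64 Sa/s
        short = EEGRecording(data=np.zeros((2, 20)), fs=512,
                             channel_labels=("A", "B"))
        with pytest.raises(ValueError, match="warm-up"):
            ed.broadband_filter(short)


class TestInfomaxICA:
    @staticmethod
    def _mixed_supergaussian(n=20000, seed=0):
        rng = np.random.default_rng(seed)
        s = np.stack([rng.laplace(size=n), rng.laplace(size=n)])
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        return s, EEGRecording(data=A @ s, fs=512,
                               channel_labels=("A", "B"))

    def test_recovers_supergaussian_sources(self):
        s, rec = self._mixed_supergaussian()
        ica = ed.fit_infomax_ica(rec, seed=1)
        corr = np.abs(np.corrcoef(np.vstack([s, ica.source_activations]))[:2, 2:])
        # each true source matches some component up to permutation/sign
        assert corr.max(axis=1).min() > 0.95

    def test_reconstruction_identity_and_determinism(self):
        rng = np.random.default_rng(2)
        rec = EEGRecording(data=rng.standard_normal((3, 5000)), fs=512,
                           channel_labels=("A", "B", "C"))
        ica = ed.fit_infomax_ica(rec, seed=3)
        ident = ica.mixing @ ica.unmixing
        assert np.allclose(ident, np.eye(3), atol=1e-8)
        ica2 = ed.fit_infomax_ica(rec, seed=3)
        assert np.allclose(ica.unmixing, ica2.unmixing)

    def test_requires_enough_samples(self):
        rec = EEGRecording(data=np.zeros((4, 100)), fs=512,
                           channel_labels=tuple("ABCD"))
        with pytest.raises(ValueError, match="samples"):
            ed.fit_infomax_ica(rec)


class TestRemoveComponents:
    def test_empty_rejection_is_identity(self):
        rng = np.random.default_rng(4)
        rec = EEGRecording(data=rng.standard_normal((3, 6000)), fs=512,
                           channel_labels=("A", "B", "C"))
        ica = ed.fit_infomax_ica(rec, seed=0)
        out = ed.remove_components(rec, ica, reject=set())
        rms = np.sqrt(np.mean(rec.data**2))
        assert np.max(np.abs(out.data - rec.data)) < 1e-6 * rms

    def test_residual_equals_back_projection(self):
        rng = np.random.default_rng(5)
        rec = EEGRecording(data=rng.standard_normal((3, 6000)), fs=512,
                           channel_labels=("A", "B", "C"))
        ica = ed.fit_infomax_ica(rec, seed=0)
        out = ed.remove_components(rec, ica, reject={1})
        backproj = np.outer(ica.mixing[:, 1], ica.source_activations[1])
        assert np.allclose(rec.data - out.data, backproj, atol=1e-8)

    def test_rejecting_artifact_removes_its_band_power(self, small_session):
        rec, _ = small_session
        t = np.arange(rec.n_samples) / rec.fs
        artifact = 80.0 * np.sin(2 * np.pi * 2.0 * t) * (
            1 + 0.3 * np.sign(np.sin(2 * np.pi * 0.1 * t)))
        topo = np.zeros(rec.n_channels)
        topo[0] = 1.0
        topo[1] = 0.5
        dirty = EEGRecording(data=rec.data + np.outer(topo, artifact),
                             fs=rec.fs, channel_labels=rec.channel_labels)
        # a sinusoidal (sub-Gaussian) source needs the extended variant
        ica = ed.fit_infomax_ica(dirty, seed=0, extended=True)
        # best-matching component by correlation with the injected artifact
        corr = [abs(np.corrcoef(artifact, s)[0, 1])
                for s in ica.source_activations]
        cleaned = ed.remove_components(dirty, ica, {int(np.argmax(corr))})

        from scipy import signal as sig
        sos = sig.butter(4, [1.5, 2.5], btype="bandpass", fs=rec.fs,
                         output="sos")
        p_dirty = sig.sosfiltfilt(sos, dirty.data[0]).var()
        p_clean = sig.sosfiltfilt(sos, cleaned.data[0]).var()
        assert p_clean < 0.1 * p_dirty

    def test_reject_all_is_an_error(self):
        rng = np.random.default_rng(6)
        rec = EEGRecording(data=rng.standard_normal((2, 4000)), fs=512,
                           channel_labels=("A", "B"))
        ica = ed.fit_infomax_ica(rec, seed=0)
        with pytest.raises(ValueError, match="all components"):
            ed.remove_components(rec, ica, {0, 1})


class TestExtractEpochs:
    @staticmethod
    def _rec_with_trial(task_s, fs=512.0):
        n = int((task_s + 4) * fs)
        rec = EEGRecording(data=np.zeros((2, n)), fs=fs,
                           channel_labels=("A", "B"), subject_id="S01")
        ann = TrialAnnotation(trial_id=1, onset_s=2.0, duration_s=task_s,
                              condition="attentive")
        return rec, [ann]

    @pytest.mark.parametrize("task_s,cap,expected", [
        (9.5, None, 5),   # floor((9.5-3)/1.5)+1
        (9.5, 3, 3),
        (3.0, None, 1),
    ])
    def test_epoch_counts(self, task_s, cap, expected):
        rec, anns = self._rec_with_trial(task_s)
        es = ed.extract_epochs(rec, anns, max_per_trial=cap)
        assert len(es) == expected
        assert all(e.data.shape[1] == round(3.0 * rec.fs) for e in es)

    def test_window_offsets(self):
        rec, anns = self._rec_with_trial(9.5)
        rec.data[0] = np.arange(rec.n_samples)  # sample index as signal
        es = ed.extract_epochs(rec, anns)
        starts = [e.data[0, 0] for e in es]
        fs = rec.fs
        assert starts == [round((2.0 + k * 1.5) * fs) for k in range(5)]

    def test_epochs_stay_inside_task_segment(self, small_session):
        rec, anns = small_session
        es = ed.extract_epochs(rec, anns)
        by_trial = {}
        for e in es:
            by_trial.setdefault(e.trial_id, []).append(e)
        for a in anns:
            n = len(by_trial[a.trial_id])
            assert n == int(np.floor((a.duration_s - 3.0) / 1.5)) + 1
            for e in by_trial[a.trial_id]:
                assert e.label == a.condition

    def test_errors_and_empty(self):
        rec, anns = self._rec_with_trial(2.0)
        with pytest.raises(ValueError, match="trial 1"):
            ed.extract_epochs(rec, anns)
        assert len(ed.extract_epochs(rec, [])) == 0
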