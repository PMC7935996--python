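"""Core data types and the synthetic two-class EEG session generator.

The package classifies 3-s EEG epochs as *attentive* or *distracted*.
Because no public recordings accompany the study design this package
implements, every downstream stage (filtering, ICA, filter-bank CSP,
nested cross-validation) is exercised on synthetic sessions that emulate
the experimental layout: eight 10/20 channels sampled at 512 Sa/s,
sessions of 30 balanced trials, each trial a 2 s cue, a 9.5 s task
execution and a 5 s relax period, preceded by a 15 s baseline.

The synthetic class difference is a band-limited power increase with a
fixed spatial topography: distracted-trial task segments receive an extra
band-pass-filtered noise source (default 8-12 Hz, i.e. alpha) mixed into
the channels through a unit-norm topography vector, on top of a
per-channel 1/f ("pink") background plus one shared broadband source that
gives the channels realistic cross-covariance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "TrialAnnotation",
    "Epoch",
    "EpochSet",
    "SyntheticConfig",
    "DEFAULT_CHANNELS",
    "generate_session",
    "generate_epochset",
]

#: Default eight-channel 10/20 montage (AFz reference, Fpz ground).
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "C3", "C4", "P3", "P4")

ATTENTIVE = "attentive"
DISTRACTED = "distracted"
DISTRACTORS = ("none", "audio", "visual", "audio_visual")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Sa/s.
    channel_labels : tuple of str
        Ordered 10/20 electrode names, one per data row.
    reference_label, ground_label : str
        Reference (default AFz) and ground (default Fpz) electrodes; each
        channel is differential with respect to the reference and referred
        to the ground.
    subject_id : object
        Opaque subject identifier.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple = DEFAULT_CHANNELS
    reference_label: str = "AFz"
    ground_label: str = "Fpz"
    subject_id: object = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.data.shape[0] < 2:
            raise ValueError("at least 2 channels required")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialAnnotation:
    """One trial's task-execution segment.

    ``onset_s``/``duration_s`` mark the task-execution window (the labelled
    state); cue and relax periods around it carry no label.
    """

    trial_id: int
    onset_s: float
    duration_s: float
    condition: str
    distractor: str = "none"
    session_id: int = 1

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.condition not in (ATTENTIVE, DISTRACTED):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.distractor not in DISTRACTORS:
            raise ValueError(f"unknown distractor {self.distractor!r}")
        if self.condition == ATTENTIVE and self.distractor != "none":
            raise ValueError("attentive trials cannot have a distractor")


def validate_annotations(annotations, recording: EEGRecording | None = None):
    """Check trials are in-bounds and non-overlapping within a recording."""
    anns = sorted(annotations, key=lambda a: a.onset_s)
    for prev, cur in zip(anns, anns[1:]):
        if cur.onset_s < prev.onset_s + prev.duration_s:
            raise ValueError(
                f"trials {prev.trial_id} and {cur.trial_id} overlap"
            )
    if recording is not None:
        for a in anns:
            if a.onset_s + a.duration_s > recording.duration_s + 1e-9:
                raise ValueError(
                    f"trial {a.trial_id} extends past the recording end"
                )
    return anns


@dataclass
class Epoch:
    """A fixed-length labelled window — the unit of classification."""

    data: np.ndarray
    label: str
    trial_id: int
    subject_id: object
    session_id: int
    fs: float
    window_s: float = 3.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n_expected = int(round(self.window_s * self.fs))
        if self.data.shape[1] != n_expected:
            raise ValueError(
                f"epoch has {self.data.shape[1]} samples, expected "
                f"{n_expected} = round(window_s * fs)"
            )
        if self.label not in (ATTENTIVE, DISTRACTED):
            raise ValueError(f"unknown label {self.label!r}")


class EpochSet:
    """An ordered collection of epochs sharing fs, channels and window.

    Class 1 is *attentive* and class 2 is *distracted*; the distracted
    class is the positive class for precision/recall reporting.
    """

    class_order = (ATTENTIVE, DISTRACTED)

    def __init__(self, epochs):
        self.epochs = list(epochs)
        if self.epochs:
            e0 = self.epochs[0]
            for e in self.epochs:
                if (e.fs, e.data.shape[0], e.window_s) != (
                    e0.fs,
                    e0.data.shape[0],
                    e0.window_s,
                ):
                    raise ValueError(
                        "all epochs must share fs, channel count and window_s"
                    )

    def __len__(self):
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return EpochSet([self.epochs[i] for i in np.asarray(idx)])
        return self.epochs[idx]

    @property
    def fs(self):
        return self.epochs[0].fs

    @property
    def n_channels(self):
        return self.epochs[0].data.shape[0]

    def data_array(self) -> np.ndarray:
        """Stack epoch data as (n_epochs, n_channels, n_samples)."""
        return np.stack([e.data for e in self.epochs])

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs])

    def labels_int(self) -> np.ndarray:
        """0 = attentive (class 1), 1 = distracted (class 2, positive)."""
        return np.array(
            [self.class_order.index(e.label) for e in self.epochs], dtype=int
        )

    def trial_keys(self) -> np.ndarray:
        """Globally unique trial identifiers (subject, session, trial)."""
        return np.array(
            [f"{e.subject_id}/{e.session_id}/{e.trial_id}" for e in self.epochs]
        )

    def subject_ids(self) -> np.ndarray:
        return np.array([str(e.subject_id) for e in self.epochs])


def _default_topography(n_channels: int) -> np.ndarray:
    # Posterior-weighted pattern (alpha-like) on the default montage.
    w = np.zeros(n_channels)
    if n_channels == len(DEFAULT_CHANNELS):
        for i, lab in enumerate(DEFAULT_CHANNELS):
            if lab in ("Pz", "Oz", "P3", "P4"):
                w[i] = 1.0
            elif lab in ("Cz", "C3", "C4"):
                w[i] = 0.4
    else:
        w[: max(1, n_channels // 2)] = 1.0
    return w / np.linalg.norm(w)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic two-class session generator.

    Defaults reproduce the emulated study composition: 3 sessions per
    subject, 30 balanced trials per session, 2 s cue + 9.5 s task + 5 s
    relax per trial, 3 epochs kept per trial, 8 channels at 512 Sa/s.
    ``effect_amplitude`` is the ratio of the effect-source RMS to the
    in-band background RMS; 0 makes the classes statistically identical.
    """

    n_subjects: int = 17
    n_sessions_per_subject: int = 3
    n_trials_per_session: int = 30
    trial_cue_s: float = 2.0
    trial_task_s: float = 9.5
    trial_relax_s: float = 5.0
    baseline_s: float = 15.0
    epochs_per_trial: int | None = 3
    epoch_window_s: float = 3.0
    epoch_step_s: float = 1.5
    n_channels: int = 8
    fs: float = 512.0
    effect_band: tuple = (8.0, 12.0)
    effect_topography: np.ndarray | None = None
    effect_amplitude: float = 1.0
    background_exponent: float = 1.0
    background_rms_uv: float = 10.0
    shared_source_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.effect_amplitude < 0:
            raise ValueError("effect_amplitude must be >= 0")
        for name in ("trial_cue_s", "trial_task_s", "trial_relax_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.effect_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("effect_band must lie inside (0, fs/2)")
        if self.n_trials_per_session % 2:
            raise ValueError("n_trials_per_session must be even (balanced)")
        if self.effect_topography is None:
            self.effect_topography = _default_topography(self.n_channels)
        else:
            w = np.asarray(self.effect_topography, dtype=float)
            if w.shape != (self.n_channels,):
                raise ValueError("effect_topography must have n_channels entries")
            self.effect_topography = w / np.linalg.norm(w)


def _stable_index(identifier) -> int:
    if isinstance(identifier, (int, np.integer)):
        return int(identifier)
    return zlib.crc32(str(identifier).encode())


def _session_rng(config: SyntheticConfig, subject_id, session_id) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(config.seed),
        spawn_key=(_stable_index(subject_id) % 2**31, int(session_id)),
    )
    return np.random.default_rng(ss)


def _pink_noise(rng, n_samples, exponent, fs):
    """1/f^exponent amplitude-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f = np.maximum(f, 0.1)  # cap the divergence below 0.1 Hz
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    return x / np.std(x)


def generate_session(config: SyntheticConfig, subject_id, session_id: int = 1):
    """Generate one continuous session and its trial annotations.

    The session is laid out as a baseline followed by trials of
    (cue + task + relax); conditions are balanced and randomly ordered.
    Distracted-trial task segments carry an added band-limited noise
    source mixed through ``effect_topography`` at ``effect_amplitude``
    times the in-band background RMS.

    Returns
    -------
    (EEGRecording, list of TrialAnnotation)
    """
    rng = _session_rng(config, subject_id, session_id)
    fs = config.fs
    n_ch = config.n_channels
    trial_s = config.trial_cue_s + config.trial_task_s + config.trial_relax_s
    total_s = config.baseline_s + config.n_trials_per_session * trial_s
    n_samples = int(round(total_s * fs))

    # Background: per-channel pink noise + one shared broadband source
    # mixed through a fixed random column (gives cross-channel covariance).
    data = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        data[c] = _pink_noise(rng, n_samples, config.background_exponent, fs)
    mix_col = rng.standard_normal(n_ch)
    mix_col /= np.linalg.norm(mix_col)
    shared = rng.standard_normal(n_samples)
    data += config.shared_source_ratio * np.outer(mix_col, shared)
    data *= config.background_rms_uv

    # In-band background RMS (averaged over channels) sets the effect scale.
    sos = signal.butter(
        4, list(config.effect_band), btype="bandpass", fs=fs, output="sos"
    )
    n_probe = min(n_samples, int(30 * fs))
    inband = signal.sosfiltfilt(sos, data[:, :n_probe], axis=1)
    ref_rms = float(np.mean(np.std(inband, axis=1)))

    # Trial order: balanced, randomized; distractor type random per trial.
    half = config.n_trials_per_session // 2
    conditions = np.array([ATTENTIVE] * half + [DISTRACTED] * half)
    rng.shuffle(conditions)
    annotations = []
    for t, cond in enumerate(conditions):
        trial_start = config.baseline_s + t * trial_s
        task_on = trial_start + config.trial_cue_s
        distractor = (
            "none" if cond == ATTENTIVE else rng.choice(DISTRACTORS[1:])
        )
        annotations.append(
            TrialAnnotation(
                trial_id=t + 1,
                onset_s=task_on,
                duration_s=config.trial_task_s,
                condition=str(cond),
                distractor=str(distractor),
                session_id=session_id,
            )
        )
        if cond == DISTRACTED and config.effect_amplitude > 0:
            i0 = int(round(task_on * fs))
            i1 = i0 + int(round(config.trial_task_s * fs))
            src = rng.standard_normal(i1 - i0)
            src = signal.sosfiltfilt(sos, src)
            src /= np.std(src)
            data[:, i0:i1] += (
                config.effect_amplitude
                * ref_rms
                * np.outer(config.effect_topography, src)
            )

    rec = EEGRecording(
        data=data,
        fs=fs,
        channel_labels=DEFAULT_CHANNELS[:n_ch]
        if n_ch <= len(DEFAULT_CHANNELS)
        else tuple(f"CH{i+1}" for i in range(n_ch)),
        subject_id=subject_id,
    )
    return rec, annotations


def generate_epochset(config: SyntheticConfig) -> EpochSet:
    """Generate the full multi-subject epoch set.

    Composes :func:`generate_session` over subjects and sessions with the
    sliding-window epoch extraction, keeping ``epochs_per_trial`` windows
    per trial.  With the default composition (17 subjects x 3 sessions x
    30 trials x 3 epochs) this yields 4590 balanced epochs.
    """
    from .preprocess import extract_epochs

    epochs = []
    for s in range(1, config.n_subjects + 1):
        subject_id = f"S{s:02d}"
        for sess in range(1, config.n_sessions_per_subject + 1):
            rec, anns = generate_session(config, subject_id, session_id=sess)
            es = extract_epochs(
                rec,
                anns,
                window_s=config.epoch_window_s,
                step_s=config.epoch_step_s,
                max_per_trial=config.epochs_per_trial,
            )
            epochs.extend(es.epochs)
    return EpochSet(epochs)
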