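"""Broadband filtering, Infomax-ICA artifact handling and epoch extraction.

These are the stages between acquisition and feature extraction:
a zero-phase 4th-order Butterworth band-pass (0.5-48.5 Hz), an Infomax
independent-component decomposition for artifact removal, and sliding
3 s / 1.5 s-step window extraction from the labelled task segments.

Artifact-component selection is deliberately not automated: the removal
API takes explicit component indices.  An optional helper flags candidate
components by excess kurtosis, but it is never applied implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from mne.preprocessing import infomax as _mne_infomax

from .signal_model import (
    EEGRecording,
    Epoch,
    EpochSet,
    validate_annotations,
)

logger = logging.getLogger(__name__)

__all__ = [
    "broadband_filter",
    "ICADecomposition",
    "fit_infomax_ica",
    "remove_components",
    "suggest_artifact_components",
    "extract_epochs",
]


def broadband_filter(
    rec: EEGRecording, lo_hz: float = 0.5, hi_hz: float = 48.5, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    ``order`` is the design order of the one-way filter; forward-backward
    application doubles the effective order and cancels the group delay.
    """
    if not (0 < lo_hz < hi_hz < rec.fs / 2):
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) Hz invalid for fs={rec.fs} Sa/s"
        )
    sos = signal.butter(
        order, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs, output="sos"
    )
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples per edge
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"signal of {rec.n_samples} samples shorter than the filter "
            f"warm-up ({padlen} samples)"
        )
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    logger.info(
        "broadband_filter: band [%g, %g] Hz, order %d, %d ch x %d samples",
        lo_hz, hi_hz, order, rec.n_channels, rec.n_samples,
    )
    return EEGRecording(
        data=out,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        reference_label=rec.reference_label,
        ground_label=rec.ground_label,
        subject_id=rec.subject_id,
    )


@dataclass
class ICADecomposition:
    """Infomax-ICA result on one recording.

    ``unmixing`` maps (mean-removed) channel data to source activations;
    ``mixing`` is its pseudo-inverse, so mixing @ unmixing is the identity
    on the retained subspace.  Components are ordered by descending
    explained variance of their back-projection.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    source_activations: np.ndarray
    mean: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def fit_infomax_ica(
    rec: EEGRecording,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
    extended: bool = False,
) -> ICADecomposition:
    """Fit Infomax ICA (natural-gradient, sigmoid nonlinearity).

    The data are mean-removed and PCA-whitened, then unmixed with the
    Infomax natural-gradient update.  Requires n_samples >= 20 *
    n_channels**2 so the channel covariance is well estimated.  If the
    weight change does not fall below ``tol`` within ``max_iter`` sweeps
    the partial result is returned with ``converged=False``.
    """
    n_ch, n_samp = rec.data.shape
    if n_samp < 20 * n_ch**2:
        raise ValueError(
            f"need >= {20 * n_ch**2} samples for {n_ch} channels, got {n_samp}"
        )
    mean = rec.data.mean(axis=1, keepdims=True)
    x = rec.data - mean
    # PCA whitening
    cov = x @ x.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    whitener = (evecs / np.sqrt(evals)).T  # components x channels
    xw = whitener @ x

    w_ica, n_iter = _mne_infomax(
        xw.T,
        extended=extended,
        max_iter=max_iter,
        w_change=tol,
        random_state=int(seed),
        return_n_iter=True,
        verbose="error",
    )
    converged = n_iter < max_iter
    unmixing = w_ica @ whitener
    mixing = np.linalg.pinv(unmixing)
    sources = unmixing @ x

    # order components by descending back-projected variance
    var = (mixing**2).sum(axis=0) * sources.var(axis=1)
    idx = np.argsort(var)[::-1]
    unmixing, mixing, sources = unmixing[idx], mixing[:, idx], sources[idx]

    logger.info(
        "fit_infomax_ica: %d components, %d iterations, converged=%s",
        n_ch, n_iter, converged,
    )
    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        source_activations=sources,
        mean=mean,
        converged=converged,
        n_iterations=int(n_iter),
    )


def remove_components(
    rec: EEGRecording, ica: ICADecomposition, reject
) -> EEGRecording:
    """Reconstruct the recording with the rejected source rows zeroed.

    Rejecting nothing returns the back-projected signal, equal to the
    input within numerical tolerance.
    """
    reject = sorted(set(int(i) for i in reject))
    if any(i < 0 or i >= ica.n_components for i in reject):
        raise IndexError(f"component indices out of range: {reject}")
    if len(reject) == ica.n_components:
        raise ValueError("cannot reject all components")
    sources = ica.source_activations.copy()
    sources[reject] = 0.0
    out = ica.mixing @ sources + ica.mean
    logger.info("remove_components: rejected %s", reject or "nothing")
    return EEGRecording(
        data=out,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        reference_label=rec.reference_label,
        ground_label=rec.ground_label,
        subject_id=rec.subject_id,
    )


def suggest_artifact_components(
    ica: ICADecomposition,
    kurtosis_threshold: float = 5.0,
    frontal_signal: np.ndarray | None = None,
    corr_threshold: float = 0.8,
):
    """Flag candidate artifact components (helper only, never auto-applied).

    Components with excess kurtosis above ``kurtosis_threshold`` (spiky,
    blink-like activations) or whose activation correlates with a
    designated frontal channel above ``corr_threshold`` are returned.
    """
    flagged = set()
    kurt = stats.kurtosis(ica.source_activations, axis=1)
    flagged.update(np.flatnonzero(kurt > kurtosis_threshold).tolist())
    if frontal_signal is not None:
        f = np.asarray(frontal_signal, dtype=float)
        f = f - f.mean()
        for i, s in enumerate(ica.source_activations):
            c = np.corrcoef(f, s)[0, 1]
            if abs(c) > corr_threshold:
                flagged.add(i)
    return sorted(flagged)


def extract_epochs(
    rec: EEGRecording,
    annotations,
    window_s: float = 3.0,
    step_s: float = 1.5,
    max_per_trial: int | None = None,
) -> EpochSet:
    """Cut sliding windows from each trial's task segment.

    Windows start at the trial task onset and advance by ``step_s`` while
    fully inside the task segment, yielding
    ``floor((task_s - window_s) / step_s) + 1`` epochs per trial, capped
    at ``max_per_trial`` (the first windows are kept).  Windows are
    half-open in samples, onsets quantized to the nearest sample; each
    epoch inherits the trial's condition label and identity.
    """
    if not annotations:
        return EpochSet([])
    anns = validate_annotations(annotations, rec)
    n_win = int(round(window_s * rec.fs))
    epochs = []
    for a in anns:
        if window_s > a.duration_s + 1e-9:
            raise ValueError(
                f"window of {window_s} s longer than trial {a.trial_id} "
                f"task segment of {a.duration_s} s"
            )
        n_fit = int(np.floor((a.duration_s - window_s) / step_s + 1e-9)) + 1
        if max_per_trial is not None:
            n_fit = min(n_fit, max_per_trial)
        for k in range(n_fit):
            start = int(round((a.onset_s + k * step_s) * rec.fs))
            epochs.append(
                Epoch(
                    data=rec.data[:, start : start + n_win],
                    label=a.condition,
                    trial_id=a.trial_id,
                    subject_id=rec.subject_id,
                    session_id=a.session_id,
                    fs=rec.fs,
                    window_s=window_s,
                )
            )
    logger.info(
        "extract_epochs: %d epochs from %d trials (window %g s, step %g s)",
        len(epochs), len(anns), window_s, step_s,
    )
    return EpochSet(epochs)
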