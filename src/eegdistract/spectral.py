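"""Frequency-domain baseline features: absolute and relative band power.

The comparison arm of the time-domain FBCSP chain: per channel, the power
spectral density of each epoch is estimated with Welch's averaged
periodogram (1 s Hann segments, 50% overlap by default) and integrated
over the bands of a scheme.  Absolute power is the in-band integral of
the density; relative power divides by the total power over the union of
the scheme's bands, so for a tiling scheme the relative powers of each
channel sum to 1.  For the overlapping nine-band scheme the denominator
is the power over the full covered range [0, 40] Hz rather than the sum
of band powers, which would double-count.

Feature layout: absolute block then relative block, band-major within
each block ("{abs|rel}_b{band}_c{channel}"), giving 2 x n_bands x
n_channels entries — 112, 144 and 192 features for the 7-, 9- and
12-band schemes on 8 channels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .filterbank import BandScheme, make_band_scheme

logger = logging.getLogger(__name__)

__all__ = ["psd_estimate", "band_power_features", "spectral_feature_names"]


def psd_estimate(epoch_data, fs, segment_s: float = 1.0, overlap_frac: float = 0.5):
    """Welch power spectral density per channel.

    Returns
    -------
    freqs : ndarray (n_freqs,)
    psd : ndarray (n_channels, n_freqs)
        Density in signal-units**2 / Hz; integrating over the full grid
        recovers the signal variance (Parseval).
    """
    x = np.asarray(epoch_data, dtype=float)
    nperseg = int(round(segment_s * fs))
    if nperseg > x.shape[-1]:
        raise ValueError(
            f"segment of {segment_s} s ({nperseg} samples) longer than the "
            f"epoch ({x.shape[-1]} samples)"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)), detrend="constant",
        axis=-1,
    )
    return freqs, psd


def _band_masks(freqs, scheme: BandScheme):
    # half-open bins [lo, hi): each frequency belongs to exactly one band
    # of a tiling scheme, so relative powers sum to exactly 1.
    return [(freqs >= lo) & (freqs < hi) for lo, hi in scheme.bands]


def band_power_features(freqs, psd, scheme: BandScheme | str):
    """Absolute and relative band power per channel under a band scheme.

    Parameters
    ----------
    freqs, psd : output of :func:`psd_estimate` (psd: channels x freqs).
    scheme : BandScheme or scheme name.

    Returns
    -------
    ndarray, shape (2 * n_bands * n_channels,)
        Absolute block then relative block, band-major within each.
    """
    if isinstance(scheme, str):
        scheme = make_band_scheme(scheme)
    if scheme.n_bands == 0:
        raise ValueError("band power needs a scheme with at least one band")
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    df = freqs[1] - freqs[0]
    if max(hi for _, hi in scheme.bands) > freqs[-1] + df / 2:
        raise ValueError("scheme bands extend beyond the frequency grid")
    masks = _band_masks(freqs, scheme)
    absolute = np.stack([psd[:, m].sum(axis=1) * df for m in masks])  # bands x ch
    union = np.logical_or.reduce(masks)
    total = psd[:, union].sum(axis=1) * df  # per channel
    if np.any(total <= 0):
        raise ValueError(
            "zero total power in the scheme range; relative power undefined"
        )
    relative = absolute / total
    return np.concatenate([absolute.ravel(), relative.ravel()])


def spectral_feature_names(scheme: BandScheme | str, n_channels: int):
    if isinstance(scheme, str):
        scheme = make_band_scheme(scheme)
    return [
        f"{kind}_b{b + 1}_c{c + 1}"
        for kind in ("abs", "rel")
        for b in range(scheme.n_bands)
        for c in range(n_channels)
    ]
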