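"""Band schemes and the Chebyshev type-II band-pass filter bank.

Three band articulations are supported, plus a pass-through:

* ``proposed12`` — twelve contiguous non-overlapping 4 Hz bands tiling
  [0.5, 48.5] Hz, designed to keep the delta, theta and alpha bands in
  separate filters (the articulation this package is built around);
* ``overlap9`` — nine 8 Hz bands with a 4 Hz hop covering [0, 40] Hz
  (the classic FBCSP articulation; its first band is realized as a
  low-pass at 8 Hz);
* ``traditional7`` — the seven conventional EEG bands delta through
  high gamma;
* ``csp_only`` — an empty band list; the broadband signal passes through
  unchanged so CSP operates on a single "band".

Filters are Chebyshev type II (monotone passband, equiripple stopband),
specified by design order and stopband attenuation, realized as
second-order sections and applied forward-backward (zero phase).  The
band edges are used as the stopband edges, so the passband sits strictly
inside each nominal band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "BandScheme",
    "FilterBank",
    "make_band_scheme",
    "design_filter_bank",
    "apply_filter_bank",
    "SCHEME_NAMES",
]

_PROPOSED12 = [(0.5 + 4 * i, 4.5 + 4 * i) for i in range(12)]
_OVERLAP9 = [(0.0 + 4 * i, 8.0 + 4 * i) for i in range(9)]
_TRADITIONAL7 = [(1, 4), (4, 8), (8, 12), (12, 18), (18, 25), (25, 35), (35, 45)]

_SCHEMES = {
    "proposed12": _PROPOSED12,
    "overlap9": _OVERLAP9,
    "traditional7": _TRADITIONAL7,
    "csp_only": [],
}
SCHEME_NAMES = tuple(_SCHEMES)


@dataclass(frozen=True)
class BandScheme:
    """An ordered list of (lo_hz, hi_hz) frequency bands."""

    name: str
    bands: tuple

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def make_band_scheme(name: str) -> BandScheme:
    """Return one of the named band articulations."""
    if name not in _SCHEMES:
        raise ValueError(
            f"unknown band scheme {name!r}; choose from {SCHEME_NAMES}"
        )
    return BandScheme(name=name, bands=tuple(tuple(map(float, b)) for b in _SCHEMES[name]))


@dataclass
class FilterBank:
    """Realized IIR designs for one band scheme at one sampling rate."""

    scheme: BandScheme
    fs: float
    order: int
    stopband_db: float
    sos: list = field(repr=False)  # per-band second-order sections
    realized_edges: list = field(default_factory=list)

    @property
    def n_bands(self) -> int:
        return self.scheme.n_bands


def _gain_at(sos, freqs, fs):
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h)


_HALF_POWER = 10 ** (-3 / 20)  # one-way -3 dB; -6 dB after filtfilt


def _design_band(lo, hi, fs, order, stopband_db):
    """Chebyshev-II design whose one-way -3 dB points sit on (lo, hi).

    The stopband edges are pushed outward iteratively until the realized
    half-power points land on the nominal band edges (within 0.02 Hz).
    Adjacent zero-phase responses of a tiling scheme then cross at gain
    0.5 and sum to approximately 1, so the bank is near-allpass inside
    its covered range.  A band with lo <= 0 is a low-pass.
    """
    width = hi - lo if lo > 0 else hi
    ws_lo = max(lo - 0.15 * width, 0.25 * lo) if lo > 0 else 0.0
    ws_hi = min(hi + 0.15 * width, 0.499 * fs)

    def build():
        if lo <= 0:
            return signal.cheby2(order, stopband_db, ws_hi, btype="lowpass",
                                 fs=fs, output="sos")
        return signal.cheby2(order, stopband_db, [ws_lo, ws_hi],
                             btype="bandpass", fs=fs, output="sos")

    sos = build()
    for _ in range(25):
        f1, f2 = _minus3db_edges(sos, fs)
        err_hi = hi - f2
        err_lo = (lo - f1) if lo > 0 else 0.0
        if abs(err_lo) < 0.02 and abs(err_hi) < 0.02:
            break
        if lo > 0:
            ws_lo = min(max(ws_lo + err_lo, 0.2 * lo), lo - 1e-3)
        ws_hi = min(max(ws_hi + err_hi, hi + 1e-3), 0.499 * fs)
        sos = build()
    return sos


def _is_stable(sos) -> bool:
    # all poles strictly inside the unit circle
    _, p, _ = signal.sos2zpk(sos)
    return bool(np.all(np.abs(p) < 1.0 - 1e-12))


def _minus3db_edges(sos, fs):
    w, h = signal.sosfreqz(sos, worN=32768, fs=fs)
    mag = np.abs(h)
    above = mag >= 10 ** (-3 / 20)
    if not above.any():
        return (np.nan, np.nan)
    idx = np.flatnonzero(above)
    return (float(w[idx[0]]), float(w[idx[-1]]))


def design_filter_bank(
    scheme: BandScheme | str,
    fs: float,
    order: int = 8,
    stopband_db: float = 30.0,
) -> FilterBank:
    """Design one stable Chebyshev-II filter per band of the scheme.

    Band edges are the stopband edges of the design (attenuation reaches
    ``stopband_db`` there).  A band with lower edge 0 becomes a low-pass.
    If the design is numerically unstable at the requested order, the
    order is halved until a stable design is found.
    """
    if isinstance(scheme, str):
        scheme = make_band_scheme(scheme)
    sos_list, edges = [], []
    for lo, hi in scheme.bands:
        if hi >= fs / 2:
            raise ValueError(f"band edge {hi} Hz >= Nyquist ({fs / 2} Hz)")
        n = order
        while True:
            sos = _design_band(lo, hi, fs, n, stopband_db)
            if _is_stable(sos):
                break
            n //= 2
            if n < 1:
                raise ValueError(
                    f"no stable Chebyshev-II design for band ({lo}, {hi}) Hz"
                )
            logger.warning(
                "band (%g, %g) Hz unstable at order %d, retrying at %d",
                lo, hi, n * 2, n,
            )
        sos_list.append(sos)
        edges.append(_minus3db_edges(sos, fs))
    logger.info(
        "design_filter_bank: %s, %d bands, order %d, %g dB stopband, fs=%g",
        scheme.name, scheme.n_bands, order, stopband_db, fs,
    )
    return FilterBank(
        scheme=scheme, fs=fs, order=order, stopband_db=stopband_db,
        sos=sos_list, realized_edges=edges,
    )


def apply_filter_bank(epoch_data: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Decompose channels x samples data into a channels x bands x samples tensor.

    Each band filter is applied forward-backward (zero phase) along time.
    For ``csp_only`` (empty bank) the band dimension is 1 and the signal
    passes through unchanged.  With the default epoch geometry
    (8 channels, 12 bands, 3 s at 512 Sa/s) the tensor holds 96 tracks
    of 1536 samples.
    """
    x = np.asarray(epoch_data, dtype=float)
    if x.ndim != 2:
        raise ValueError("epoch data must be channels x samples")
    if bank.n_bands == 0:
        return x[:, None, :].copy()
    out = np.empty((x.shape[0], bank.n_bands, x.shape[1]))
    for b, sos in enumerate(bank.sos):
        out[:, b, :] = signal.sosfiltfilt(sos, x, axis=1)
    return out


def apply_filter_bank_batch(epochs_data: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Vectorized :func:`apply_filter_bank` over (n_epochs, channels, samples)."""
    x = np.asarray(epochs_data, dtype=float)
    n_e, n_c, n_s = x.shape
    if bank.n_bands == 0:
        return x[:, :, None, :].copy()
    out = np.empty((n_e, n_c, bank.n_bands, n_s))
    flat = x.reshape(n_e * n_c, n_s)
    for b, sos in enumerate(bank.sos):
        out[:, :, b, :] = signal.sosfiltfilt(sos, flat, axis=1).reshape(n_e, n_c, n_s)
    return out
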