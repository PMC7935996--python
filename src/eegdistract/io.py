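"""File formats: EDF recordings, annotation sidecars, feature matrices
and CSP model serialization.

Recordings travel as European Data Format (EDF) files with a delimited
sidecar holding the trial annotations (trial_id, onset_s, duration_s,
condition, distractor, session_id).  The EDF writer here is minimal but
standard-conforming: 16-bit samples, one-second data records, per-channel
physical scaling; recordings whose length is not a whole number of
records are zero-padded in the last record.  Feature matrices are
tab-separated text with a header row of feature names.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .csp import CSPModel
from .signal_model import EEGRecording, TrialAnnotation

__all__ = [
    "write_edf",
    "read_edf",
    "write_annotations",
    "read_annotations",
    "write_features",
    "read_features",
    "write_csp_model",
    "read_csp_model",
    "read_recording_txt",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path, rec: EEGRecording) -> None:
    """Write a recording as EDF (16-bit, 1 s data records)."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_records * spr))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    buf = _io.BytesIO()
    buf.write(_pad("0", 8))
    buf.write(_pad(f"subject {rec.subject_id}", 80))
    buf.write(_pad(f"ref {rec.reference_label} gnd {rec.ground_label}", 80))
    buf.write(_pad(now.strftime("%d.%m.%y"), 8))
    buf.write(_pad(now.strftime("%H.%M.%S"), 8))
    buf.write(_pad(str(256 * (1 + n_ch)), 8))
    buf.write(_pad("", 44))
    buf.write(_pad(str(n_records), 8))
    buf.write(_pad("1", 8))  # record duration, seconds
    buf.write(_pad(str(n_ch), 4))
    for lab in rec.channel_labels:
        buf.write(_pad(f"EEG {lab}", 16))
    for _ in range(n_ch):
        buf.write(_pad("", 80))  # transducer
    for _ in range(n_ch):
        buf.write(_pad("uV", 8))
    for v in pmin:
        buf.write(_pad(f"{v:.8g}"[:8], 8))
    for v in pmax:
        buf.write(_pad(f"{v:.8g}"[:8], 8))
    for _ in range(n_ch):
        buf.write(_pad(str(_DIG_MIN), 8))
    for _ in range(n_ch):
        buf.write(_pad(str(_DIG_MAX), 8))
    for _ in range(n_ch):
        buf.write(_pad("", 80))  # prefiltering
    for _ in range(n_ch):
        buf.write(_pad(str(spr), 8))
    for _ in range(n_ch):
        buf.write(_pad("", 32))
    for r in range(n_records):
        buf.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    path.write_bytes(buf.getvalue())


def read_edf(path) -> EEGRecording:
    """Read an EDF file written by :func:`write_edf` (or any plain EDF)."""
    raw = Path(path).read_bytes()
    header = raw[:256]
    n_records = int(header[236:244].decode().strip())
    record_s = float(header[244:252].decode().strip())
    n_ch = int(header[252:256].decode().strip())
    sig = raw[256 : 256 * (1 + n_ch)]

    def field(offset, width):
        start = offset * n_ch
        return [
            sig[start + i * width : start + (i + 1) * width].decode().strip()
            for i in range(n_ch)
        ]

    # per-signal field block offsets within the signal header
    labels = field(0, 16)
    off = 16 * n_ch + 80 * n_ch + 8 * n_ch
    pmin = np.array([float(v) for v in
                     [sig[off + i * 8: off + (i + 1) * 8].decode().strip()
                      for i in range(n_ch)]])
    off += 8 * n_ch
    pmax = np.array([float(v) for v in
                     [sig[off + i * 8: off + (i + 1) * 8].decode().strip()
                      for i in range(n_ch)]])
    off += 8 * n_ch
    dmin = np.array([int(v) for v in
                     [sig[off + i * 8: off + (i + 1) * 8].decode().strip()
                      for i in range(n_ch)]])
    off += 8 * n_ch
    dmax = np.array([int(v) for v in
                     [sig[off + i * 8: off + (i + 1) * 8].decode().strip()
                      for i in range(n_ch)]])
    off += 8 * n_ch + 80 * n_ch
    spr = [int(sig[off + i * 8: off + (i + 1) * 8].decode().strip())
           for i in range(n_ch)]
    if len(set(spr)) != 1:
        raise ValueError("mixed per-channel sampling rates not supported")
    spr = spr[0]
    fs = spr / record_s

    body = np.frombuffer(raw[256 * (1 + n_ch):], dtype="<i2")
    body = body[: n_records * n_ch * spr].reshape(n_records, n_ch, spr)
    digital = body.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    chan = tuple(l.removeprefix("EEG ").strip() for l in labels)
    subject = Path(path).stem
    return EEGRecording(data=data, fs=fs, channel_labels=chan,
                        subject_id=subject)


_ANN_COLS = ["trial_id", "onset_s", "duration_s", "condition", "distractor",
             "session_id"]


def write_annotations(path, annotations) -> None:
    """Write the trial-annotation sidecar as delimited text."""
    df = pd.DataFrame(
        [[a.trial_id, a.onset_s, a.duration_s, a.condition, a.distractor,
          a.session_id] for a in annotations],
        columns=_ANN_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path):
    df = pd.read_csv(path, sep="\t")
    return [
        TrialAnnotation(
            trial_id=int(r.trial_id), onset_s=float(r.onset_s),
            duration_s=float(r.duration_s), condition=str(r.condition),
            distractor=str(r.distractor), session_id=int(r.session_id),
        )
        for r in df.itertuples()
    ]


def write_features(path, X, names) -> None:
    """Feature matrix as tab-separated text with a feature-name header."""
    X = np.asarray(X)
    if X.shape[1] != len(names):
        raise ValueError("feature count does not match the name list")
    pd.DataFrame(X, columns=list(names)).to_csv(path, sep="\t", index=False)


def read_features(path):
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_csp_model(path, model: CSPModel) -> None:
    """Serialize a CSP model as structured text (matrices row-major)."""
    lines = [
        f"scheme\t{model.scheme_name}",
        f"n_bands\t{model.n_bands}",
        f"n_channels\t{model.n_channels}",
        f"log_variance\t{int(model.log_variance)}",
        "W\t" + " ".join(f"{v:.17g}" for v in model.W.ravel()),
        "eigenvalues\t" + " ".join(
            f"{v:.17g}" for v in model.eigenvalues.ravel()),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_csp_model(path) -> CSPModel:
    fields = {}
    for line in Path(path).read_text().splitlines():
        key, val = line.split("\t", 1)
        fields[key] = val
    nb, nc = int(fields["n_bands"]), int(fields["n_channels"])
    W = np.fromstring(fields["W"], sep=" ").reshape(nb, nc, nc)
    lam = np.fromstring(fields["eigenvalues"], sep=" ").reshape(nb, nc)
    return CSPModel(W=W, eigenvalues=lam, n_channels=nc,
                    scheme_name=fields["scheme"],
                    log_variance=bool(int(fields["log_variance"])))


def read_recording_txt(path, fs: float, subject_id=None) -> EEGRecording:
    """Read a delimited-text recording (channels as columns, header row)."""
    df = pd.read_csv(path, sep="\t")
    return EEGRecording(
        data=df.to_numpy(dtype=float).T, fs=fs,
        channel_labels=tuple(df.columns), subject_id=subject_id,
    )
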