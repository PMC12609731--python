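"""Minimal European Data Format (EDF) writer/reader plus event sidecars.

Implements the classic EDF layout (ASCII headers, 16-bit little-endian
samples in 1-second data records) — enough to persist synthetic or real
continuous EEG deterministically.  Physical scaling is symmetric per
channel, so the round-trip error is bounded by half a quantization step
of the declared physical range.  Events travel in a CSV sidecar
(`<stem>_events.csv`, columns ``onset_sample,label``) because classic
EDF has no annotation channel.

Fixed header dates are written (rather than wall-clock time) so that
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.csv")


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds EDF width {width}")
    return s.ljust(width).encode("ascii")


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table (``onset_sample``, ``label``) as CSV."""
    df = pd.DataFrame({
        "onset_sample": np.asarray(events["onset_sample"], dtype=int)
        if len(events) else np.array([], dtype=int),
        "label": events["label"] if len(events) else [],
    })
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"onset_sample": int, "label": str})
    if list(df.columns) != ["onset_sample", "label"]:
        raise ValueError(f"unexpected event columns {list(df.columns)} in {path}")
    return df


def write_edf(recording: Recording, events: pd.DataFrame | None,
              path: str | Path) -> Path:
    """Write a continuous recording as EDF (+ event CSV sidecar).

    The signal is padded with its last sample value to a whole number of
    1-second records; the true sample count is stored in the header's
    reserved field so :func:`read_edf` can trim the padding.
    """
    path = Path(path)
    if recording.n_samples == 0 or recording.n_channels == 0:
        raise ValueError("cannot write an empty recording")
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per record per signal (1 s records)
    n_records = int(np.ceil(recording.n_samples / spr))
    n_total = n_records * spr
    ns = recording.n_channels

    # per-channel symmetric physical range, re-parsed from its ASCII form
    # so writer and reader use the identical scale
    phys_max = np.empty(ns)
    for i in range(ns):
        pm = float(np.max(np.abs(recording.data[i]))) * 1.01
        if pm == 0.0 or not np.isfinite(pm):
            pm = 1.0
        phys_max[i] = float(f"{pm:.6G}")

    buf = io.BytesIO()
    buf.write(_ascii("0", 8))
    buf.write(_ascii(recording.subject_id or "X", 80))
    buf.write(_ascii(recording.group_label or "X", 80))
    buf.write(_ascii("01.01.00", 8))
    buf.write(_ascii("00.00.00", 8))
    buf.write(_ascii(256 * (ns + 1), 8))
    buf.write(_ascii(f"NSAMP={recording.n_samples}", 44))
    buf.write(_ascii(n_records, 8))
    buf.write(_ascii(1, 8))  # record duration, seconds
    buf.write(_ascii(ns, 4))

    for lab in recording.channel_labels:
        buf.write(_ascii(lab, 16))
    for _ in range(ns):
        buf.write(_ascii("", 80))  # transducer
    for _ in range(ns):
        buf.write(_ascii("uV", 8))
    for i in range(ns):
        buf.write(_ascii(f"{-phys_max[i]:.6G}", 8))
    for i in range(ns):
        buf.write(_ascii(f"{phys_max[i]:.6G}", 8))
    for _ in range(ns):
        buf.write(_ascii(_DIG_MIN, 8))
    for _ in range(ns):
        buf.write(_ascii(_DIG_MAX, 8))
    for _ in range(ns):
        buf.write(_ascii("", 80))  # prefiltering
    for _ in range(ns):
        buf.write(_ascii(spr, 8))
    for _ in range(ns):
        buf.write(_ascii("", 32))

    # digitize: pad with edge value, scale, interleave by record
    padded = np.empty((ns, n_total))
    padded[:, :recording.n_samples] = recording.data
    padded[:, recording.n_samples:] = recording.data[:, -1:]
    scale = 2.0 * phys_max / (_DIG_MAX - _DIG_MIN)
    dig = np.rint((padded + phys_max[:, None]) / scale[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
    # records on disk: [rec0: sig0 spr samples, sig1 ... ][rec1: ...]
    dig = dig.reshape(ns, n_records, spr).transpose(1, 0, 2)
    buf.write(dig.tobytes())

    path.write_bytes(buf.getvalue())
    if events is not None:
        write_events(events, _events_path(path))
    return path


def read_edf(path: str | Path) -> tuple[Recording, pd.DataFrame]:
    """Read an EDF file (and its event sidecar, if present)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def f(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    subject_id = f(8, 88)
    group_label = f(88, 168)
    reserved = f(192, 236)
    try:
        n_records = int(f(236, 244))
        record_dur = float(f(244, 252))
        ns = int(f(252, 256))
    except ValueError as exc:
        raise ValueError(f"{path}: corrupt EDF header") from exc
    if ns <= 0 or n_records <= 0 or record_dur <= 0:
        raise ValueError(f"{path}: corrupt EDF header")

    off = 256

    def fields(width: int) -> list[str]:
        nonlocal off
        out = [raw[off + i * width: off + (i + 1) * width]
               .decode("ascii", errors="replace").strip() for i in range(ns)]
        off += ns * width
        return out

    labels = fields(16)
    fields(80)  # transducer
    fields(8)   # dimension
    phys_min = np.array([float(v) for v in fields(8)])
    phys_max = np.array([float(v) for v in fields(8)])
    dig_min = np.array([int(v) for v in fields(8)])
    dig_max = np.array([int(v) for v in fields(8)])
    fields(80)  # prefiltering
    spr_all = [int(v) for v in fields(8)]
    fields(32)  # reserved per signal
    if len(set(spr_all)) != 1:
        raise ValueError(f"{path}: mixed per-signal rates not supported")
    spr = spr_all[0]
    rate = spr / record_dur

    expected = n_records * ns * spr * 2
    payload = raw[off:off + expected]
    if len(payload) != expected:
        raise ValueError(f"{path}: data payload truncated")
    dig = np.frombuffer(payload, dtype="<i2").reshape(n_records, ns, spr)
    dig = dig.transpose(1, 0, 2).reshape(ns, n_records * spr).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (dig - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    if reserved.startswith("NSAMP="):
        n_true = int(reserved[6:])
        data = data[:, :n_true]

    rec = Recording(data=data, rate=rate, channel_labels=labels,
                    subject_id="" if subject_id == "X" else subject_id,
                    group_label="" if group_label == "X" else group_label)
    ev_path = _events_path(path)
    events = read_events(ev_path) if ev_path.exists() else pd.DataFrame(
        {"onset_sample": np.array([], dtype=int), "label": []})
    return rec, events
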