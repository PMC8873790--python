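"""Minimal EDF+C writing for multichannel signals with event annotations.

EDF stores each channel as 16-bit integers with a per-channel linear
physical/digital calibration, so a write/read round trip is exact only up
to that quantization.  The writer emits one data record per second; signals
whose length is not a whole number of records are zero-padded at the end.
Reading goes through :mod:`mne`.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

_ANNOT_LABEL = "EDF Annotations"


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def write_edf(
    path,
    signal: np.ndarray,
    fs: float,
    channel_names,
    annotations=(),
    physical_dim: str = "uV",
) -> None:
    """Write `signal` (channels x samples, physical units) as EDF+C.

    Parameters
    ----------
    annotations
        Iterable of ``(onset_seconds, duration_seconds, text)`` events.
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per signal row required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    fs = int(round(fs))
    n_records = int(np.ceil(n_samp / fs)) if n_samp else 1

    # physical calibration per channel; guard degenerate constant channels
    pmins, pmaxs = [], []
    for ch in signal:
        lo, hi = (float(ch.min()), float(ch.max())) if ch.size else (0.0, 0.0)
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
    dmin, dmax = -32768, 32767

    # annotation payload per record: a timekeeping TAL plus events in range
    def tal(onset, duration, text):
        s = f"+{onset:g}"
        if duration is not None:
            s += f"\x15{duration:g}"
        return s.encode("ascii") + b"\x14" + text.encode("utf-8") + b"\x14\x00"

    record_tals = []
    for r in range(n_records):
        chunk = tal(float(r), None, "")
        for onset, dur, text in annotations:
            if r <= onset < r + 1:
                chunk += tal(float(onset), float(dur), str(text))
        record_tals.append(chunk)
    annot_bytes = max(len(c) for c in record_tals)
    annot_bytes += annot_bytes % 2  # int16 alignment
    annot_samples = annot_bytes // 2

    ns = n_ch + 1
    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (ns + 1)), 8),
            _field("EDF+C", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    labels = [str(c) for c in channel_names] + [_ANNOT_LABEL]
    dims = [physical_dim] * n_ch + [""]
    pmin_all = pmins + [-1.0]
    pmax_all = pmaxs + [1.0]
    spr = [fs] * n_ch + [annot_samples]
    header += b"".join(_field(s, 16) for s in labels)
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(d, 8) for d in dims)
    header += b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin_all)
    header += b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax_all)
    header += b"".join(_field(str(dmin), 8) for _ in range(ns))
    header += b"".join(_field(str(dmax), 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(str(s), 8) for s in spr)
    header += b"".join(_field("", 32) for _ in range(ns))

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = signal
    scale = np.array([(dmax - dmin) / (hi - lo) for lo, hi in zip(pmins, pmaxs)])
    offset = np.array([lo for lo in pmins])
    digital = np.clip(
        np.rint((padded - offset[:, None]) * scale[:, None]) + dmin, dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            fh.write(record_tals[r].ljust(annot_bytes, b"\x00"))


def read_edf(path):
    """Read an EDF/EDF+ file; returns (signal µV, fs, channel_names, annotations).

    Annotations are ``(onset_s, duration_s, code)`` tuples in onset order.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> microvolts
    ann = [
        (float(o), float(d), str(c))
        for o, d, c in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return signal, float(raw.info["sfreq"]), list(raw.ch_names), ann
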