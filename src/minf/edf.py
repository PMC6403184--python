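"""EDF round trip for simulated recordings.

Writing uses a minimal self-contained European Data Format (EDF) encoder:
16-bit samples in 1-s data records, one extra ``TRIG`` channel carrying the
event markers (1 = left, 2 = right, held for 0.1 s from the MI onset sample).
Reading goes through :func:`mne.io.read_raw_edf`, so any file written here is
also validated by an independent implementation of the format.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .eeg_pipeline import Recording

_EVENT_CODES = {"left": 1, "right": 2}
_CODE_EVENTS = {v: k for k, v in _EVENT_CODES.items()}
DIG_MAX = 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording (plus a TRIG marker channel) to an EDF file."""
    if rec.fs != int(rec.fs):
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(rec.fs)                       # samples per 1-s record
    trig = np.zeros(rec.n_samples)
    hold = max(int(0.1 * rec.fs), 1)
    for samp, klass in rec.events:
        trig[samp : samp + hold] = _EVENT_CODES[klass]
    signals = np.vstack([rec.signal, trig])
    labels = list(rec.channel_labels) + ["TRIG"]
    n_sig = signals.shape[0]
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : rec.n_samples] = signals

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    scale = DIG_MAX / phys_max
    digital = np.round(padded * scale[:, None]).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field(0, 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(256 * (1 + n_sig), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(1, 8),
        _field(n_sig, 4),
    ])
    per_signal = b"".join([
        b"".join(_field(l, 16) for l in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_field(-DIG_MAX, 8) for _ in labels),
        b"".join(_field(DIG_MAX, 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(spr, 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file (via MNE) back into a :class:`Recording`.

    Event markers are reconstructed from the rising edges of the TRIG channel.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6             # MNE stores volts; recordings are in uV
    names = list(raw.ch_names)
    if "TRIG" in names:
        i = names.index("TRIG")
        trig = np.round(data[i])
        data = np.delete(data, i, axis=0)
        names.pop(i)
    else:
        trig = np.zeros(data.shape[1])
    events = []
    prev = 0
    for samp, code in enumerate(trig):
        code = int(code)
        if code != 0 and prev == 0 and code in _CODE_EVENTS:
            events.append((samp, _CODE_EVENTS[code]))
        prev = code
    return Recording(data, float(raw.info["sfreq"]), names, events)
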