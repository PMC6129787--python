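"""Minimal EDF writer for continuous multichannel recordings.

Writes plain EDF (16-bit integer samples, linear physical scaling) with one
data record per second and a final shorter record when the duration is not
an integer number of seconds is avoided by using a single data record whose
duration is n_samples / sampling_rate.  Readers that honor the record
duration field (e.g. MNE) recover the sampling rate and physical values up
to the 16-bit quantization step of each channel.
"""

from __future__ import annotations

import datetime

import numpy as np


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def _num(x: float, width: int = 8) -> bytes:
    for fmt in (f"{x:.10g}", f"{x:.6g}", f"{x:.4g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return _field(fmt, width)
    return _field(f"{x:.1e}", width)


def write_edf(path, data: np.ndarray, sampling_rate: float,
              channel_names, physical_dim: str = "uV") -> None:
    """Write a channels×samples float array as 16-bit EDF.

    Physical min/max per channel are taken from the data range (widened for
    constant channels), so the quantization step is (max−min)/65535.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ns, n_samples = data.shape
    if len(channel_names) != ns:
        raise ValueError("channel_names length must match row count")
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    record_duration = n_samples / sampling_rate
    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field("1", 8),                      # one data record
        _num(record_duration, 8),
        _field(str(ns), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(name, 16) for name in channel_names),
        b"".join(_field("", 80) for _ in range(ns)),
        b"".join(_field(physical_dim, 8) for _ in range(ns)),
        b"".join(_num(v) for v in pmin),
        b"".join(_num(v) for v in pmax),
        b"".join(_field(str(dmin), 8) for _ in range(ns)),
        b"".join(_field(str(dmax), 8) for _ in range(ns)),
        b"".join(_field("", 80) for _ in range(ns)),
        b"".join(_field(str(n_samples), 8) for _ in range(ns)),
        b"".join(_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(digital.tobytes())
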