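"""File I/O: EDF continuous recordings, events and covariate tables (TSV).

The EDF writer/reader implements the 16-bit European Data Format with 1 s
data records and physical units in microvolts; recordings are therefore
preserved to EDF quantization (about 1 part in 65k of the channel range).
Events travel alongside the EDF as a BIDS-style TSV (onset_sample, onset_s,
intensity_db).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, make_event_table

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def events_path_for(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_events.tsv")


def write_recording(recording: ContinuousRecording, events: pd.DataFrame,
                    path: str | Path) -> Path:
    """Write an EDF file plus its companion events TSV.

    The recording length must be a whole number of seconds (1 s records);
    events are validated (strictly increasing onsets, no consecutive equal
    intensities) before anything touches disk.
    """
    path = Path(path)
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n_records, rem = divmod(recording.n_samples, spr)
    if rem:
        raise ValueError("recording length must be a whole number of seconds")
    # validate events before writing
    make_event_table(events["onset_sample"].to_numpy(),
                     events["intensity_db"].to_numpy(), rate)

    n_sig = len(recording.channel_labels)
    data = recording.samples
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    header = b"".join([
        _field(0, 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (1 + n_sig), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(n_sig, 4),
    ])
    sig_header = b"".join([
        b"".join(_field(lbl, 16) for lbl in recording.channel_labels),
        b"".join(_field("", 80) for _ in range(n_sig)),
        b"".join(_field("uV", 8) for _ in range(n_sig)),
        b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin),
        b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax),
        b"".join(_field(_DIG_MIN, 8) for _ in range(n_sig)),
        b"".join(_field(_DIG_MAX, 8) for _ in range(n_sig)),
        b"".join(_field("", 80) for _ in range(n_sig)),
        b"".join(_field(spr, 8) for _ in range(n_sig)),
        b"".join(_field("", 32) for _ in range(n_sig)),
    ])

    # physical values as written (8-char ASCII) define the scaling actually
    # stored, so parse them back before digitizing
    pmin_w = np.array([float(f"{v:.8g}"[:8]) for v in pmin])
    pmax_w = np.array([float(f"{v:.8g}"[:8]) for v in pmax])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax_w - pmin_w)
    digital = np.rint((data - pmin_w[:, None]) * scale[:, None]
                      + _DIG_MIN).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec_i in range(n_records):
            block = digital[:, rec_i * spr:(rec_i + 1) * spr]
            fh.write(block.tobytes())

    events.to_csv(events_path_for(path), sep="\t", index=False)
    return path


def read_recording(path: str | Path
                   ) -> tuple[ContinuousRecording, pd.DataFrame | None]:
    """Read an EDF file (and its events TSV if present)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError("not an EDF file: header truncated")

    def f(off, width):
        return raw[off:off + width].decode("ascii", "replace").strip()

    try:
        header_bytes = int(f(184, 8))
        n_records = int(f(236, 8))
        duration = float(f(244, 8))
        n_sig = int(f(252, 4))
    except ValueError as exc:
        raise ValueError("malformed EDF header") from exc
    if header_bytes != 256 * (1 + n_sig) or n_records < 0:
        raise ValueError("malformed EDF header")

    # field order: label, transducer, dim, pmin, pmax, dmin, dmax, prefilter, spr
    offsets = [16, 80, 8, 8, 8, 8, 8, 80, 8]
    starts = np.cumsum([0] + offsets[:-1])
    base = 256

    def block(k, width):
        s = base + int(starts[k]) * n_sig
        return [raw[s + i * width: s + (i + 1) * width]
                .decode("ascii", "replace").strip() for i in range(n_sig)]

    labels = block(0, 16)
    pmin = np.array([float(v) for v in block(3, 8)])
    pmax = np.array([float(v) for v in block(4, 8)])
    dmin = np.array([float(v) for v in block(5, 8)])
    dmax = np.array([float(v) for v in block(6, 8)])
    spr = [int(v) for v in block(8, 8)]
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal rates are not supported")
    spr = spr[0]
    rate = spr / duration

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expect = n_records * n_sig * spr
    if len(body) < expect:
        raise ValueError("EDF data truncated")
    body = body[:expect].reshape(n_records, n_sig, spr)
    digital = np.concatenate([body[i] for i in range(n_records)], axis=1) \
        if n_records else np.zeros((n_sig, 0), dtype="<i2")
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital.astype(float) - dmin[:, None]) * scale[:, None] \
        + pmin[:, None]
    recording = ContinuousRecording(data, rate, tuple(labels))

    ev_path = events_path_for(path)
    events = pd.read_csv(ev_path, sep="\t") if ev_path.exists() else None
    return recording, events


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "session", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns {sorted(missing)}")
    return df
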