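"""Readers and writers.

Three on-disk forms are supported:

* **EDF** (16-bit) and **BioSemi BDF** (24-bit) continuous recordings,
  with physical scaling honored.  Event markers come from a ``Status``
  trigger channel (non-zero transitions; codes preserved as opaque
  labels) or from a TSV sidecar ``<path>.events.tsv`` with columns
  ``sample_index`` and ``label``, which takes precedence when present.
* An **HDF5 container** for recordings and epoch sets that round-trips
  bit-exactly (the native interchange format of this package).
* Event tables as TSV.

The EDF/BDF support is deliberately minimal — continuous single-session
files as produced by common amplifiers — not a general EDF+ implementation.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .containers import EpochSet, Event, Recording
from .montage import Montage

__all__ = [
    "read_recording",
    "write_recording",
    "read_epochs",
    "write_epochs",
    "read_events_tsv",
    "write_events_tsv",
    "write_edf",
    "write_bdf",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the named format."""


# --------------------------------------------------------------------------
# EDF / BDF
# --------------------------------------------------------------------------

_EDF_VERSION = b"0       "
_BDF_VERSION = b"\xffBIOSEMI"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {text!r}")
    return b.ljust(width)


def _edf_header(rec: Recording, bits: int, samples_per_record: int,
                n_records: int, phys_range: float, status: bool) -> bytes:
    labels = list(rec.montage.labels) + (["Status"] if status else [])
    ns = len(labels)
    dig = 32767 if bits == 16 else 8388607
    head = b""
    head += _BDF_VERSION if bits == 24 else _EDF_VERSION
    head += _pad("X X X X", 80)  # patient id
    head += _pad("Startdate X X X X", 80)  # recording id
    head += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    head += _pad(str(256 * (ns + 1)), 8)
    head += _pad("24BIT" if bits == 24 else "EDF", 44)
    head += _pad(str(n_records), 8)
    head += _pad(str(samples_per_record / rec.sample_rate), 8)[:8].ljust(8)
    head += _pad(str(ns), 4)
    for lab in labels:
        head += _pad(lab, 16)
    for _ in labels:
        head += _pad("", 80)  # transducer
    for lab in labels:
        head += _pad("" if lab == "Status" else "uV", 8)
    for lab in labels:
        lo = 0 if lab == "Status" else -phys_range
        head += _pad(f"{int(lo)}", 8)
    for lab in labels:
        hi = dig if lab == "Status" else phys_range
        head += _pad(f"{int(hi)}", 8)
    for lab in labels:
        head += _pad("0" if lab == "Status" else str(-dig - 1), 8)
    for _ in labels:
        head += _pad(str(dig), 8)
    for _ in labels:
        head += _pad("", 80)  # prefiltering
    for _ in labels:
        head += _pad(str(samples_per_record), 8)
    for _ in labels:
        head += _pad("", 32)  # reserved
    return head


def _encode_24bit(x: np.ndarray) -> bytes:
    x = np.asarray(x, dtype=np.int32)
    out = np.empty((x.size, 3), dtype=np.uint8)
    out[:, 0] = x & 0xFF
    out[:, 1] = (x >> 8) & 0xFF
    out[:, 2] = (x >> 16) & 0xFF
    return out.tobytes()


def _decode_24bit(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    val = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
    val[val >= 1 << 23] -= 1 << 24
    return val


def _write_edf_like(path: str, rec: Recording, bits: int,
                    phys_range: float = 32768.0) -> None:
    fs = rec.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF/BDF export requires an integer sample rate")
    spr = int(round(fs))  # one-second data records
    n_rec = int(np.ceil(rec.n_samples / spr))
    total = n_rec * spr
    dig = 32767 if bits == 16 else 8388607
    # Invert exactly the affine the reader applies from the header fields:
    # phys = (digital - dig_min) * (phys_max - phys_min)/(dig_max - dig_min)
    #        + phys_min
    gain = (2 * phys_range) / (dig - (-dig - 1))
    sig = np.zeros((rec.n_channels, total))
    sig[:, : rec.n_samples] = rec.signal
    digital = np.clip(
        np.round((sig - (-phys_range)) / gain + (-dig - 1)), -dig - 1, dig
    ).astype(np.int32)
    status = np.zeros(total, dtype=np.int32)
    for ev in rec.events:
        # Opaque numeric codes; textual labels go to the TSV sidecar.
        status[ev.sample] = 1
    with open(path, "wb") as fh:
        fh.write(_edf_header(rec, bits, spr, n_rec, phys_range, status=True))
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(rec.n_channels):
                if bits == 16:
                    fh.write(digital[ch, sl].astype("<i2").tobytes())
                else:
                    fh.write(_encode_24bit(digital[ch, sl]))
            if bits == 16:
                fh.write(status[sl].astype("<i2").tobytes())
            else:
                fh.write(_encode_24bit(status[sl]))
    write_events_tsv(path + ".events.tsv", rec.events)


def write_edf(path: str, rec: Recording) -> None:
    """Write a 16-bit EDF file (plus a ``.events.tsv`` label sidecar)."""
    _write_edf_like(path, rec, bits=16)


def write_bdf(path: str, rec: Recording) -> None:
    """Write a 24-bit BioSemi BDF file (plus a label sidecar)."""
    _write_edf_like(path, rec, bits=24)


def _read_edf_like(path: str, montage: Montage | None) -> Recording:
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic == _BDF_VERSION:
            bits = 24
        elif magic == _EDF_VERSION:
            bits = 16
        else:
            raise FormatError(f"{path}: not an EDF or BDF file")
        fh.seek(0)
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated header at offset {len(fixed)}")
        n_records = int(fixed[236:244])
        record_dur = float(fixed[244:252])
        ns = int(fixed[252:256])
        var = fh.read(256 * ns)
        if len(var) < 256 * ns:
            raise FormatError(
                f"{path}: truncated header at offset {256 + len(var)}"
            )

        def fields(offset, width):
            base = offset * ns
            return [
                var[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)])
        header_bytes = 256 * (ns + 1)
        bytes_per_sample = bits // 8
        rec_bytes = int(spr.sum()) * bytes_per_sample
        expected = header_bytes + n_records * rec_bytes
        if size < expected:
            raise FormatError(
                f"{path}: truncated data at offset {size} (expected {expected})"
            )
        chans = [np.empty(n_records * s) for s in spr]
        for r in range(n_records):
            for i in range(ns):
                raw = fh.read(spr[i] * bytes_per_sample)
                if bits == 16:
                    digital = np.frombuffer(raw, dtype="<i2").astype(np.int32)
                else:
                    digital = _decode_24bit(raw)
                gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
                chans[i][r * spr[i]: (r + 1) * spr[i]] = (
                    (digital - dig_min[i]) * gain + phys_min[i]
                )
    if np.unique(spr[: len(labels)]).size > 1 and "Status" not in labels:
        raise FormatError(f"{path}: heterogeneous sample rates unsupported")
    fs = spr[0] / record_dur
    status_idx = labels.index("Status") if "Status" in labels else None
    data_idx = [i for i in range(ns) if i != status_idx]
    signal = np.stack([chans[i] for i in data_idx])
    data_labels = [labels[i] for i in data_idx]

    sidecar = path + ".events.tsv"
    if os.path.exists(sidecar):
        events = read_events_tsv(sidecar)
    elif status_idx is not None:
        trig = np.round(chans[status_idx]).astype(int)
        onsets = np.flatnonzero((trig != 0) & (np.r_[0, trig[:-1]] == 0))
        events = [Event(int(s), str(trig[s])) for s in onsets]
    else:
        raise FormatError(f"{path}: no events (no Status channel or sidecar)")
    if not events:
        raise FormatError(f"{path}: no events present")

    if montage is None:
        # Positions are unknown in plain EDF/BDF; synthesize placeholders on
        # the unit sphere and mark every channel as scalp EEG.
        n = len(data_labels)
        golden = np.pi * (3 - np.sqrt(5))
        # Distinct placements: spiral on the upper hemisphere.
        z = np.linspace(1.0, 0.2, n)
        r = np.sqrt(1 - z**2)
        theta = golden * np.arange(n)
        pos = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
        montage = Montage(tuple(data_labels), pos, tuple(["eeg"] * n))
    return Recording(
        sample_rate=fs,
        signal=signal,
        montage=montage,
        events=events,
        meta={"source": os.path.basename(path)},
    )


# --------------------------------------------------------------------------
# Event tables
# --------------------------------------------------------------------------

def write_events_tsv(path: str, events) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index\tlabel\n")
        for ev in events:
            fh.write(f"{ev.sample}\t{ev.label}\n")


def read_events_tsv(path: str) -> list[Event]:
    events = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["sample_index", "label"]:
            raise FormatError(f"{path}: expected columns sample_index, label")
        for line in fh:
            if not line.strip():
                continue
            s, label = line.rstrip("\n").split("\t")
            events.append(Event(int(s), label))
    return sorted(events, key=lambda e: e.sample)


# --------------------------------------------------------------------------
# HDF5 container
# --------------------------------------------------------------------------

def write_recording(path: str, rec: Recording) -> None:
    """Write a recording to the HDF5 container (bit-exact round-trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "recording"
        f.attrs["sample_rate"] = rec.sample_rate
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset(
            "event_samples", data=np.array([e.sample for e in rec.events])
        )
        f.create_dataset(
            "event_labels",
            data=np.array([e.label for e in rec.events], dtype="S"),
        )
        f.attrs["montage"] = json.dumps(rec.montage.to_dict())
        f.attrs["meta"] = json.dumps(rec.meta)


def _read_recording_container(path: str) -> Recording:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "recording":
            raise FormatError(f"{path}: container does not hold a recording")
        events = [
            Event(int(s), l.decode())
            for s, l in zip(f["event_samples"][()], f["event_labels"][()])
        ]
        return Recording(
            sample_rate=float(f.attrs["sample_rate"]),
            signal=f["signal"][()],
            montage=Montage.from_dict(json.loads(f.attrs["montage"])),
            events=events,
            meta=json.loads(f.attrs["meta"]),
        )


def write_epochs(path: str, epochs: EpochSet) -> None:
    """Write an epoch set to the HDF5 container (bit-exact round-trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "epochs"
        f.attrs["sample_rate"] = epochs.sample_rate
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=np.array([str(l) for l in epochs.labels], dtype="S")
        )
        f.create_dataset("times", data=epochs.times)
        f.attrs["montage"] = json.dumps(epochs.montage.to_dict())
        f.attrs["provenance"] = json.dumps(epochs.provenance)


def read_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "epochs":
            raise FormatError(f"{path}: container does not hold epochs")
        return EpochSet(
            data=f["data"][()],
            labels=np.array([l.decode() for l in f["labels"][()]], dtype=object),
            times=f["times"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            montage=Montage.from_dict(json.loads(f.attrs["montage"])),
            provenance=json.loads(f.attrs["provenance"]),
        )


def read_recording(path: str, format: str | None = None,
                   montage: Montage | None = None) -> Recording:
    """Read a continuous recording.

    Parameters
    ----------
    path : str
        File path.
    format : {"bdf", "edf", "container", None}
        ``None`` infers from the extension (.bdf/.edf/.h5/.hdf5).
    montage : Montage, optional
        Electrode geometry for EDF/BDF files (which store no positions);
        if omitted, placeholder positions are synthesized.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".bdf": "bdf", ".edf": "edf", ".h5": "container",
                  ".hdf5": "container"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from extension: {path}")
    if format in ("edf", "bdf"):
        return _read_edf_like(path, montage)
    if format == "container":
        return _read_recording_container(path)
    raise FormatError(f"unknown format {format!r}")
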