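"""File formats and run configuration.

Recordings are stored as UTF-8 tab-delimited text: a single header comment
line carrying a JSON metadata object (format version, sampling rate,
channel types/units, block annotations), a column-name row, then one row
per sample.  A compact binary container (magic bytes + JSON header +
little-endian float64 samples) is available for large recordings.  Events
are two-column text (sample_index, label).  Sample indices are 0-based;
epoch time axes are ms relative to the R-peak trigger; windows are closed
at both ends.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .epoching import MultiChannelRecording

__all__ = [
    "FORMAT_VERSION",
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "RunConfig",
]

FORMAT_VERSION = "hefpipe.recording.v1"
_BINARY_MAGIC = b"HEFREC01"


def _header_dict(rec: MultiChannelRecording) -> dict:
    return {
        "version": FORMAT_VERSION,
        "fs": rec.fs,
        "channel_types": list(rec.channel_types),
        "units": {
            lab: {"magnetometer": "fT", "gradiometer": "fT/cm"}.get(t, "a.u.")
            for lab, t in zip(rec.channel_labels, rec.channel_types)
        },
        "annotations": [[float(s), float(e), str(c)] for s, e, c in rec.annotations],
    }


def write_recording(path, rec: MultiChannelRecording, binary: bool = False) -> None:
    """Write a recording; text by default, binary with ``binary=True``."""
    path = Path(path)
    header = _header_dict(rec)
    if binary:
        raw = json.dumps(header).encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(_BINARY_MAGIC)
            fh.write(struct.pack("<Q", len(raw)))
            fh.write(raw)
            fh.write(json.dumps(list(rec.channel_labels)).encode("utf-8") + b"\n")
            fh.write(np.ascontiguousarray(rec.data, dtype="<f8").tobytes())
        return
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.10g", delimiter="\t")


def read_recording(path) -> MultiChannelRecording:
    """Read a recording written by :func:`write_recording` (either form)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(_BINARY_MAGIC))
        if magic == _BINARY_MAGIC:
            (hlen,) = struct.unpack("<Q", fh.read(8))
            header = json.loads(fh.read(hlen).decode("utf-8"))
            _check_header(header, path)
            labels = json.loads(fh.readline().decode("utf-8"))
            data = np.frombuffer(fh.read(), dtype="<f8").reshape(-1, len(labels))
            return _build_recording(header, labels, np.array(data), path)

    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        try:
            header = json.loads(first.lstrip("#").strip())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed metadata header: {exc}") from exc
        _check_header(header, path)
        labels = fh.readline().strip().split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels)} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
        data = np.asarray(rows, dtype=float)
    return _build_recording(header, labels, data, path)


def _check_header(header: dict, path) -> None:
    version = header.get("version")
    if version is None:
        raise ValueError(
            f"{path}: header has no 'version' field; expected "
            f"'{FORMAT_VERSION}' — was this file written by write_recording()?"
        )
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version {version!r}")
    if header.get("fs", 0) <= 0:
        raise ValueError(f"{path}: sampling rate must be positive")
    if "channel_types" not in header:
        raise ValueError(f"{path}: header is missing channel types")


def _build_recording(header, labels, data, path) -> MultiChannelRecording:
    types = header["channel_types"]
    if len(types) != len(labels):
        raise ValueError(f"{path}: channel type count does not match columns")
    return MultiChannelRecording(
        data=data,
        fs=float(header["fs"]),
        channel_labels=list(labels),
        channel_types=list(types),
        annotations=[tuple(a) for a in header.get("annotations", [])],
    )


def write_events(path, indices, labels) -> None:
    """Write (sample_index, label) rows as tab-delimited text."""
    indices = np.asarray(indices, dtype=int)
    if len(labels) != indices.size:
        raise ValueError("indices and labels must have equal length")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_index\tlabel\n")
        for i, lab in zip(indices, labels):
            fh.write(f"{int(i)}\t{lab}\n")


def read_events(path, n_samples: int | None = None):
    """Read events; returns (indices, labels), validated sorted/in-range.

    Duplicate indices with distinct labels are both kept.
    """
    indices, labels = [], []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() and header.strip() != "sample_index\tlabel":
            raise ValueError(f"{path}: unexpected events header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            indices.append(int(parts[0]))
            labels.append(parts[1])
    idx = np.asarray(indices, dtype=int)
    if idx.size and np.any(np.diff(idx) < 0):
        raise ValueError(f"{path}: event indices must be sorted")
    if idx.size and idx[0] < 0:
        raise ValueError(f"{path}: negative event index")
    if n_samples is not None and idx.size and idx[-1] >= n_samples:
        raise ValueError(f"{path}: event index beyond recording length")
    return idx, labels


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Stage parameters for the full pipeline, with study defaults.

    Defaults follow the analysis this package implements: 1 kHz sampling,
    [-200, +600] ms R-locked epochs, 400 fT / 4000 fT/cm peak-to-peak
    rejection, Morlet 8-24 Hz at 7 cycles, z-normalization reference over
    200-600 ms x 8-24 Hz on the seed channel in the control condition
    (a 200-400 ms power-baseline window is the configurable alternative),
    PLI over 200-500 ms in alpha (8-13 Hz) and beta (14-24 Hz), pointwise
    p < 0.01 ITC masks and p < 0.05 PLI masks.
    """

    seed: int = 0
    n_subjects: int = 8
    block_duration_s: float = 180.0
    n_blocks_per_condition: int = 2
    # cardiac / detection
    detect_min_rr_ms: float = 300.0
    detect_band: tuple = (5.0, 35.0)
    # epoching
    tmin_ms: float = -200.0
    tmax_ms: float = 600.0
    mag_thresh: float = 400.0
    grad_thresh: float = 4000.0
    baseline_correct: bool = True
    # spectral
    fmin_hz: float = 8.0
    fmax_hz: float = 24.0
    fstep_hz: float = 1.0
    n_cycles: float = 7.0
    tf_decim: int = 4  # anti-aliased downsampling before TF/PLI stages
    z_reference_channel: str = "R_ant_ventral_insula"
    z_reference_condition: str = "control"
    z_t_window_ms: tuple = (200.0, 600.0)
    z_f_window_hz: tuple = (8.0, 24.0)
    # connectivity
    pli_seed_roi: str = "R_ant_ventral_insula"
    pli_t_window_ms: tuple = (200.0, 500.0)
    pli_per_trial: bool = False
    # stats
    itc_alpha: float = 0.01
    pli_alpha: float = 0.05
    hrv_test: str = "paired"  # "paired" | "independent"
    correction: str | None = None

    conditions: tuple = ("disgust", "control")
    contrast: tuple = ("disgust", "control")  # (a, b) for a - b

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if isinstance(getattr(cls, f.name, None), tuple) or isinstance(
                    f.default, tuple
                ):
                    v = tuple(v) if isinstance(v, list) else v
                kwargs[f.name] = v
        return cls(**kwargs)
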