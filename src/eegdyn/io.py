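"""Recording container, HDF5 persistence, and BrainVision reading.

The package's native on-disk format is a small HDF5 container (one
``signal`` dataset in µV plus attributes).  BrainVision triplets
(.vhdr/.eeg/.vmrk) are supported read-only; a minimal fixture writer is
provided for round-trip testing.
"""

from __future__ import annotations

import configparser
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

VALID_STATES = ("rest_open", "rest_closed", "count_easy", "count_hard", "other")


class FormatError(ValueError):
    """Raised when an on-disk recording is malformed or unsupported."""


@dataclass
class Recording:
    """Multi-channel EEG segment.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
    state : str
        Task-state tag, one of ``VALID_STATES``.
    participant_id : str
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    state: str = "other"
    participant_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}, got {self.state!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" in kw and "meta" not in kw:
            kw["meta"] = dict(self.meta)
        return replace(self, **kw)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_hdf5(rec: Recording, path) -> None:
    """Write a Recording to the package HDF5 container (bit-exact)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=rec.data, dtype=np.float64, track_times=False)
        ds.attrs["units"] = "uV"
        f.attrs["fs"] = float(rec.fs)
        f.attrs["channel_labels"] = [s.encode() for s in rec.channel_labels]
        f.attrs["state"] = rec.state
        f.attrs["participant_id"] = rec.participant_id
        for k, v in rec.meta.items():
            f.attrs[f"meta_{k}"] = v


def read_hdf5(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise FormatError(f"{path}: missing 'signal' dataset")
        data = f["signal"][()]
        labels = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f.attrs["channel_labels"]
        )
        meta = {
            k[5:]: (v.item() if isinstance(v, np.generic) else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return Recording(
            data=data,
            fs=float(f.attrs["fs"]),
            channel_labels=labels,
            state=str(f.attrs["state"]),
            participant_id=str(f.attrs["participant_id"]),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# BrainVision (.vhdr / .eeg / .vmrk), read-only
# ---------------------------------------------------------------------------

_BV_DTYPES = {
    "INT_16": np.dtype("<i2"),
    "INT_32": np.dtype("<i4"),
    "IEEE_FLOAT_32": np.dtype("<f4"),
}


def read_brainvision(header_path, state: str = "other", participant_id: str = "") -> Recording:
    """Read a BrainVision triplet given the .vhdr path.

    Supports multiplexed binary data in INT_16, INT_32 or IEEE_FLOAT_32.
    Values are returned in µV (resolution applied for integer formats).
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file not found: {header_path}")
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str
    text = header_path.read_text(encoding="utf-8", errors="replace")
    # strip the "Brain Vision Data Exchange Header File" banner line(s)
    lines = [ln for ln in text.splitlines() if not ln.startswith(";")]
    while lines and not lines[0].startswith("["):
        lines.pop(0)
    cp.read_string("\n".join(lines))

    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise FormatError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise FormatError("only MULTIPLEXED DataOrientation is supported")
    n_ch = int(common["NumberOfChannels"])
    # SamplingInterval is in µs for time-domain data
    fs = 1e6 / float(common["SamplingInterval"])
    data_file = header_path.with_name(common["DataFile"])
    marker_file = common.get("MarkerFile")
    if marker_file is not None and not header_path.with_name(marker_file).exists():
        raise FormatError(f"missing companion marker file: {marker_file}")
    if not data_file.exists():
        raise FormatError(f"missing companion data file: {data_file.name}")

    fmt = cp["Binary Infos"]["BinaryFormat"].strip().upper()
    if fmt not in _BV_DTYPES:
        raise FormatError(f"unsupported BinaryFormat: {fmt}")
    dtype = _BV_DTYPES[fmt]

    labels = []
    resolutions = []
    for i in range(1, n_ch + 1):
        entry = cp["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] != "" else "1"
        resolutions.append(float(res))

    nbytes = os.path.getsize(data_file)
    frame = dtype.itemsize * n_ch
    if nbytes % frame != 0:
        shortfall = frame - nbytes % frame
        raise FormatError(
            f"{data_file.name}: truncated data file, {nbytes} bytes is not a "
            f"multiple of the {frame}-byte frame ({shortfall} bytes short of a full frame)"
        )
    raw = np.fromfile(data_file, dtype=dtype).reshape(-1, n_ch).T
    data = raw.astype(np.float64) * np.array(resolutions)[:, None]
    return Recording(
        data=data, fs=fs, channel_labels=tuple(labels), state=state,
        participant_id=participant_id,
    )


def write_brainvision_fixture(
    rec: Recording, header_path, binary_format: str = "IEEE_FLOAT_32"
) -> None:
    """Write a minimal BrainVision triplet (testing aid, not a full writer)."""
    header_path = Path(header_path)
    stem = header_path.stem
    data_name, marker_name = f"{stem}.eeg", f"{stem}.vmrk"
    dtype = _BV_DTYPES[binary_format]
    chan_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(rec.channel_labels)
    )
    header_path.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={data_name}\n"
        f"MarkerFile={marker_name}\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={rec.n_channels}\n"
        f"SamplingInterval={1e6 / rec.fs:g}\n"
        "[Binary Infos]\n"
        f"BinaryFormat={binary_format}\n"
        "[Channel Infos]\n"
        f"{chan_lines}\n",
        encoding="utf-8",
    )
    header_path.with_name(marker_name).write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={data_name}\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.T.astype(dtype).tofile(header_path.with_name(data_name))
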