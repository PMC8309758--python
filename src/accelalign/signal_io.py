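"""Reading, writing and resampling of raw triaxial acceleration streams.

Two plain-text/plain-binary interchange formats are supported:

* long-form CSV, either with a ``# key=value`` header carrying start time
  and sampling rate (preferred, fast) or with a per-row ``timestamp``
  column (ISO-8601 or epoch seconds);
* 2-channel WAV files carrying one vector-magnitude stream per channel,
  the format produced by exporting dual-device recordings for visual
  alignment in an audio editor.

The in-memory timebase is implicit: sample ``n`` of a recording occurs at
``start_time + n / fs``. All downstream stages assume a uniform rate, so
irregular timestamp streams are rejected rather than silently resampled.
"""
from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


class FormatError(ValueError):
    """File structure does not match a supported dialect."""


class DataError(ValueError):
    """File parsed but the data violate the recording contract."""


class WearSite(str, enum.Enum):
    hip = "hip"
    wrist = "wrist"
    thigh = "thigh"
    other = "other"


@dataclasses.dataclass
class TriaxialRecording:
    """Uniformly sampled triaxial acceleration in gravity units.

    Parameters
    ----------
    samples:
        Array of shape (n, 3) with x/y/z acceleration in g.
    fs:
        Nominal sampling rate in Hz (> 0).
    start_time:
        Absolute start time, UTC epoch seconds.
    device_id:
        Opaque device label.
    wear_site:
        Anatomical placement; the hip-worn monitor is the conventional
        reference device.
    measurement_range_g:
        Sensor full-scale range; values beyond it are rejected.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    device_id: str = ""
    wear_site: WearSite = WearSite.other
    measurement_range_g: float = 8.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError(f"samples must have shape (n, 3), got {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise DataError("recording must contain at least one sample")
        if not self.fs > 0:
            raise DataError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("acceleration values must be finite")
        amax = float(np.max(np.abs(self.samples)))
        if amax > self.measurement_range_g:
            raise DataError(
                f"|acceleration| up to {amax:.3f} g exceeds the "
                f"±{self.measurement_range_g} g measurement range"
            )
        if isinstance(self.wear_site, str):
            self.wear_site = WearSite(self.wear_site)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to ``start_time``."""
        return np.arange(self.n_samples) / self.fs

    def replace(self, **kwargs) -> "TriaxialRecording":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# CSV

_HEADER_KEYS = ("start_time", "fs", "device_id", "wear_site")


def write_csv(rec: TriaxialRecording, path: str | Path) -> None:
    """Write the header-dialect CSV (deterministic byte-for-byte output)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# start_time={rec.start_time!r}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# device_id={rec.device_id}\n")
        fh.write(f"# wear_site={rec.wear_site.value}\n")
        frame = pd.DataFrame(np.asarray(rec.samples, dtype=np.float64),
                             columns=["x", "y", "z"])
        frame.to_csv(fh, index=False, float_format="%.6f",
                     lineterminator="\n")


def _read_header_csv(path: Path) -> TriaxialRecording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        frame = pd.read_csv(fh)
    cols = {c.strip().lower(): c for c in frame.columns}
    missing = [a for a in "xyz" if a not in cols]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "fs" not in meta:
        raise FormatError(f"{path}: header dialect requires an 'fs' entry")
    return TriaxialRecording(
        samples=frame[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=np.float64),
        fs=float(meta["fs"]),
        start_time=float(meta.get("start_time", 0.0)),
        device_id=meta.get("device_id", ""),
        wear_site=WearSite(meta.get("wear_site", "other")),
    )


def _read_timestamp_csv(path: Path) -> TriaxialRecording:
    frame = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in frame.columns}
    missing = [a for a in ("timestamp", "x", "y", "z") if a not in cols]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    ts = frame[cols["timestamp"]]
    if pd.api.types.is_numeric_dtype(ts):
        t = ts.to_numpy(dtype=np.float64)
    else:
        t = pd.to_datetime(ts, utc=True).astype("int64").to_numpy() / 1e9
    if len(t) < 2:
        raise DataError(f"{path}: need at least 2 timestamped rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise DataError(f"{path}: non-monotone timestamp at row {i + 1}")
    fs = 1.0 / float(np.median(dt))
    gaps = np.flatnonzero(dt > 2.0 / fs)
    if gaps.size:
        i = int(gaps[0])
        raise DataError(
            f"{path}: timestamp gap of {dt[i]:.3f} s after row {i} "
            f"(limit 2/fs = {2.0 / fs:.3f} s)"
        )
    return TriaxialRecording(
        samples=frame[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=np.float64),
        fs=fs,
        start_time=float(t[0]),
    )


def read_csv(path: str | Path, dialect: str = "auto") -> TriaxialRecording:
    """Read a recording from CSV.

    ``dialect`` is 'header', 'timestamp' or 'auto' (sniff: a leading
    ``#`` line selects the header dialect).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline()
        dialect = "header" if first.startswith("#") else "timestamp"
    if dialect == "header":
        return _read_header_csv(path)
    if dialect == "timestamp":
        return _read_timestamp_csv(path)
    raise ValueError(f"unknown CSV dialect {dialect!r}")


# ---------------------------------------------------------------------------
# WAV (stereo vector-magnitude pairs)


def write_wav_vm(path: str | Path, fs: float, ch0: np.ndarray, ch1: np.ndarray) -> None:
    """Write two magnitude streams as a float32 stereo WAV at rate ``fs``."""
    ch0 = np.asarray(ch0, dtype=np.float32)
    ch1 = np.asarray(ch1, dtype=np.float32)
    if ch0.shape != ch1.shape or ch0.ndim != 1:
        raise ValueError("channels must be 1-D and of equal length")
    wavfile.write(str(path), int(round(fs)), np.column_stack([ch0, ch1]))


def read_wav_vm(path: str | Path, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a 2-channel WAV of vector-magnitude acceleration.

    Returns ``(ch0, ch1, fs)`` with values in g. Integer PCM data are
    divided by ``scale``; float data are taken as g directly.
    """
    fs, data = wavfile.read(str(path))
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError(f"{path}: expected a 2-channel WAV, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(scale)
    else:
        data = data.astype(np.float64)
    return data[:, 0], data[:, 1], float(fs)


# ---------------------------------------------------------------------------
# Resampling


def resample_to_working_rate(rec: TriaxialRecording, target_fs: float = 30.0) -> TriaxialRecording:
    """Resample a recording to the working rate by per-axis linear interpolation.

    Duration is preserved to within one sample period. No anti-alias
    filter is applied before downsampling: this mirrors the plain
    linear-interpolation export path of the vendor download software, at
    the cost of textbook aliasing protection (see the methods note).
    """
    if rec.n_samples < 2:
        raise DataError("cannot resample a recording with fewer than 2 samples")
    if rec.fs == target_fs:
        return rec
    t_src = rec.times()
    n_out = int(np.floor(rec.duration_s * target_fs)) + 1
    t_out = np.arange(n_out) / target_fs
    out = np.empty((n_out, 3), dtype=np.float64)
    for ax in range(3):
        out[:, ax] = np.interp(t_out, t_src, rec.samples[:, ax])
    return rec.replace(samples=out, fs=float(target_fs))
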