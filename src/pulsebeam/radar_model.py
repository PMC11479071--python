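"""Domain types for IR-UWB radar frame data and the on-disk container format.

An impulse-radio ultra-wideband (IR-UWB) radar records, at every pulse
repetition, a *frame*: a range profile sampled along the intra-pulse
("fast-time") axis.  Stacking frames over ordinary time ("slow time")
yields the complex matrix this module models.  All coordinate conventions
of the package live here:

* fast-time bin ``k`` (0-based) maps to range ``range_start + k * bin_spacing``
  in metres; bin 0 is the direct transmitter-to-receiver path used as the
  phase reference,
* slow-time frame ``t`` (0-based) maps to time ``t0 + t / fps`` in seconds.

No community standard exists for radar frame dumps, so the package defines
a small single-file container (``.rcube``): a JSON header describing the
matrix, followed by the raw array bytes (little-endian, row-major,
interleaved re/im).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_MAGIC = b"RCUBE\x00"

#: fields the .rcube header must carry
_REQUIRED_HEADER = ("fps", "range_start", "bin_spacing", "t0", "shape", "dtype")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Radar acquisition settings.

    Defaults follow a chest-monitoring configuration: 250 frames per
    second (4 ms slow-time resolution), observation window from 0.4 m
    (the direct-path reference range) to 1.5 m, 5-minute evaluations.
    ``bin_spacing_m`` derives from a 23.328 GHz fast-time sampling rate:
    c / (2 * 23.328e9) = 6.43 mm per bin.
    """

    fps: float = 250.0
    range_start_m: float = 0.4
    range_max_m: float = 1.5
    window_s: float = 300.0
    bin_spacing_m: float = 0.00643

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.range_max_m <= self.range_start_m:
            raise ValueError("range_max_m must exceed range_start_m")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.bin_spacing_m <= 0:
            raise ValueError("bin_spacing_m must be positive")

    @property
    def frame_interval_s(self) -> float:
        """Slow-time sampling interval, 1/fps seconds."""
        return 1.0 / self.fps

    @property
    def n_bins(self) -> int:
        """Number of fast-time bins spanning [range_start_m, range_max_m]."""
        return int(np.floor((self.range_max_m - self.range_start_m) / self.bin_spacing_m)) + 1

    @property
    def n_frames(self) -> int:
        return int(round(self.window_s * self.fps))


@dataclass
class RadarCube:
    """Complex fast-time x slow-time frame matrix with range/time metadata.

    ``frames[k, t]`` is the complex baseband sample of fast-time bin ``k``
    in slow-time frame ``t``.
    """

    frames: np.ndarray
    fps: float
    range_start: float = 0.4
    bin_spacing: float = 0.00643
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 2 or self.frames.shape[0] < 2 or self.frames.shape[1] < 2:
            raise ValueError(
                f"frames must be a 2-D matrix with >= 2 bins and >= 2 frames, got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.bin_spacing <= 0:
            raise ValueError("bin_spacing must be positive")

    @property
    def n_bins(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def bin_range(self, k: int | np.ndarray) -> float | np.ndarray:
        """Range in metres of fast-time bin ``k`` (0-based)."""
        return self.range_start + np.asarray(k) * self.bin_spacing

    def bin_ranges(self) -> np.ndarray:
        return self.bin_range(np.arange(self.n_bins))

    def frame_time(self, t: int | np.ndarray) -> float | np.ndarray:
        """Timestamp in seconds of slow-time frame ``t`` (0-based)."""
        return self.t0 + np.asarray(t) / self.fps

    def frame_times(self) -> np.ndarray:
        return self.frame_time(np.arange(self.n_frames))

    def nearest_bin(self, range_m: float) -> int:
        """Index of the fast-time bin closest to ``range_m``."""
        return int(np.argmin(np.abs(self.bin_ranges() - range_m)))


def write_cube(cube: RadarCube, path: str | Path) -> None:
    """Write ``cube`` to a ``.rcube`` container.

    Layout: 6-byte magic, a little-endian uint32 header length, a UTF-8
    JSON header, then the raw array bytes (C order, little-endian).  The
    array is stored in its in-memory dtype (recorded in the header), so
    ``read_cube(write_cube(c))`` is bit-exact.

    Raises
    ------
    ValueError
        If ``frames`` contains non-finite values.
    """
    frames = np.asarray(cube.frames)
    if not np.all(np.isfinite(frames.real)) or not np.all(np.isfinite(frames.imag)):
        raise ValueError("cube.frames contains non-finite values; refusing to write")
    dtype = frames.dtype.newbyteorder("<")
    header = {
        "fps": cube.fps,
        "range_start": cube.range_start,
        "bin_spacing": cube.bin_spacing,
        "t0": cube.t0,
        "shape": list(frames.shape),
        "dtype": dtype.str,
        "frame_interval_s": 1.0 / cube.fps,
        "layout": "row-major, little-endian, interleaved re/im",
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(frames.astype(dtype, copy=False)).tobytes())


def read_cube(path: str | Path) -> RadarCube:
    """Read a ``.rcube`` container written by :func:`write_cube`.

    Raises
    ------
    ValueError
        On a bad magic number, a header missing a required field, or a
        mismatch between the header shape and the stored byte count.
    """
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an .rcube container (bad magic {magic!r})")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode())
        for key in _REQUIRED_HEADER:
            if key not in header:
                raise ValueError(f"{path}: .rcube header missing required field '{key}'")
        dtype = np.dtype(header["dtype"])
        shape = tuple(header["shape"])
        raw = fh.read()
    expected = int(np.prod(shape)) * dtype.itemsize
    if len(raw) != expected:
        raise ValueError(
            f"{path}: matrix/metadata shape mismatch: header says {shape} ({expected} bytes), file holds {len(raw)}"
        )
    frames = np.frombuffer(raw, dtype=dtype).reshape(shape)
    return RadarCube(
        frames=frames.copy(),
        fps=header["fps"],
        range_start=header["range_start"],
        bin_spacing=header["bin_spacing"],
        t0=header["t0"],
    )


def write_trace_csv(cube: RadarCube, bin_index: int, path: str | Path) -> None:
    """Export one fast-time bin's slow-time trace as CSV (debug aid).

    Columns: ``t_s, re, im``.
    """
    times = cube.frame_times()
    z = cube.frames[bin_index]
    with open(path, "w") as fh:
        fh.write("t_s,re,im\n")
        for t, v in zip(times, z):
            fh.write(f"{t:.6f},{v.real:.9g},{v.imag:.9g}\n")
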