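"""Amplitude-ordered iterative peak detection.

Rather than scanning chronologically, the detector repeatedly takes the
globally largest remaining sample of a working copy of the vital signal,
records it as a candidate peak, and zeroes a +/-R window around it; the
iteration stops when no positive sample remains or a candidate limit is
reached.  Candidates are then validated against the *original* signal:
a candidate survives only if it attains the maximum of the original
signal over its own +/-R window (i.e. it is a true local maximum, not the
shoulder of an already-suppressed larger peak).  Surviving indices are
returned in chronological order.

R is the peak-detection resolution in frames: half the minimum plausible
beat spacing, derived from the fastest plausible heart rate
(:func:`default_R`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vital_select import VitalSignal


@dataclass(frozen=True)
class PeakSet:
    """Validated peak indices (chronological) with their amplitudes."""

    indices: np.ndarray
    amplitudes: np.ndarray
    R: int
    n_candidates: int
    fps: float = np.nan
    t0: float = 0.0

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))

    def __len__(self) -> int:
        return len(self.indices)

    def times(self) -> np.ndarray:
        """Peak timestamps in seconds (requires fps)."""
        if not np.isfinite(self.fps):
            raise ValueError("PeakSet carries no fps; cannot compute times")
        return self.t0 + self.indices / self.fps


def default_R(fps: float, hr_max_bpm: float = 130.0) -> int:
    """Peak-detection resolution: half the minimum plausible beat spacing.

    ``R = floor(fps * 60 / (2 * hr_max_bpm))`` frames; at 250 frames/s and
    a 130 bpm ceiling this is 57 frames (228 ms).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    return int(np.floor(fps * 60.0 / (2.0 * hr_max_bpm)))


def default_limit(duration_s: float, hr_max_bpm: float = 130.0) -> int:
    """Candidate cap: the largest plausible beat count for the window."""
    return int(np.ceil(duration_s * hr_max_bpm / 60.0))


def detect_peaks(
    vital: VitalSignal | np.ndarray,
    R: int,
    limit: int,
    strict: bool = False,
    exclude_edge: int = 0,
) -> PeakSet:
    """Run the amplitude-ordered iterative detector on a vital signal.

    Parameters
    ----------
    vital
        A :class:`~pulsebeam.vital_select.VitalSignal` or a plain array.
    R
        Suppression/validation half-window in frames (>= 1).
    limit
        Maximum number of candidates examined (>= 1).
    strict
        Validate with a strict ``>`` over a window that includes the
        candidate itself.  Since a sample can never strictly exceed a
        maximum it participates in, this mode rejects everything; the
        default ``>=`` (candidate attains its window maximum) is the
        practical reading.
    exclude_edge
        Treat the first and last ``exclude_edge`` samples as zero, to keep
        band-pass edge transients from producing spurious peaks.

    Notes
    -----
    Ties in amplitude resolve toward the lowest index.  The termination
    test is "no positive sample remains": filtered signals are signed, so
    "entirely zero" generalises to non-positivity.
    """
    v0 = np.asarray(vital.v0 if isinstance(vital, VitalSignal) else vital, dtype=float)
    if not np.all(np.isfinite(v0)):
        raise ValueError("vital signal contains non-finite samples")
    if R < 1:
        raise ValueError("R must be >= 1")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    if len(v0) <= 2 * R:
        raise ValueError(f"signal of length {len(v0)} is too short for R={R}")
    if exclude_edge > 0:
        v0 = v0.copy()
        v0[:exclude_edge] = 0.0
        v0[-exclude_edge:] = 0.0

    v = v0.copy()
    n = len(v)
    candidates: list[tuple[int, float]] = []
    while len(candidates) < limit:
        x = int(np.argmax(v))
        y = v[x]
        if y <= 0.0:
            break
        candidates.append((x, y))
        v[max(0, x - R) : min(n, x + R + 1)] = 0.0

    kept = []
    for x, y in candidates:
        window_max = v0[max(0, x - R) : min(n, x + R + 1)].max()
        ok = y > window_max if strict else y >= window_max
        if ok:
            kept.append((x, y))
    kept.sort()
    idx = np.array([x for x, _ in kept], dtype=int)
    amp = np.array([y for _, y in kept], dtype=float)
    fps = vital.fps if isinstance(vital, VitalSignal) else np.nan
    t0 = vital.t0 if isinstance(vital, VitalSignal) else 0.0
    return PeakSet(indices=idx, amplitudes=amp, R=R, n_candidates=len(candidates), fps=fps, t0=t0)
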