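"""RR-interval construction and time-/frequency-domain HRV indices.

The intervals between successive detected peaks are treated as RR
intervals.  Intervals whose time span intersects a movement-flagged
second are dropped, and the remaining intervals are concatenated without
interpolation — the series is *assumed continuous* across the gaps.  The
identical code path serves radar peak sets and reference beat-time
sequences, so method comparison is symmetric by construction.

Frequency-domain indices come from the beat-indexed spectrum of the
mean-removed interval series (Hamming taper, zero-padding to a large FFT,
squared magnitude).  The beat axis maps to Hz through the effective
sampling rate of one sample per mean RR; LF is [0.05, 0.15) Hz and HF is
[0.15, 0.40) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import rfft, rfftfreq

from .movement import MovementMask, detect_movement, movement_statistic
from .peak_detect import PeakSet, default_R, default_limit, detect_peaks
from .preprocess import FilterSpec, phase_compensate
from .radar_model import RadarCube
from .vital_select import HRBand, select_mp


@dataclass(frozen=True)
class RRSeries:
    """Retained RR intervals with their absolute time spans."""

    intervals_ms: np.ndarray
    starts_s: np.ndarray
    ends_s: np.ndarray
    n_excluded_movement: int = 0

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        st = np.asarray(self.starts_s, dtype=float)
        en = np.asarray(self.ends_s, dtype=float)
        if not (len(iv) == len(st) == len(en)):
            raise ValueError("intervals, starts and ends must have equal length")
        if np.any(iv <= 0):
            raise ValueError("RR intervals must be positive")
        if len(iv) and not np.allclose(en - st, iv / 1000.0):
            raise ValueError("interval spans inconsistent with interval durations")
        object.__setattr__(self, "intervals_ms", iv)
        object.__setattr__(self, "starts_s", st)
        object.__setattr__(self, "ends_s", en)

    def __len__(self) -> int:
        return len(self.intervals_ms)


@dataclass(frozen=True)
class HRVIndices:
    """Time- and frequency-domain HRV summary of one evaluation.

    mean RR, SDNN and RMSSD are in milliseconds; LF/HF is dimensionless.
    """

    mean_rr_ms: float
    sdnn_ms: float
    rmssd_ms: float
    lf_power: float
    hf_power: float
    lf_hf: float


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral analysis settings: FFT size, taper, LF/HF band edges.

    Band edges are half-open [lo, hi): 0.15 Hz belongs to HF only.
    ``power=False`` switches the band integrand from squared magnitude to
    plain magnitude for sensitivity checks.
    """

    fft_size: int = 2**18
    lf_band: tuple[float, float] = (0.05, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    power: bool = True

    def __post_init__(self) -> None:
        if self.fft_size & (self.fft_size - 1):
            raise ValueError("fft_size must be a power of two")
        if not self.lf_band[1] <= self.hf_band[0]:
            raise ValueError("LF and HF bands must be disjoint")


def build_rr(
    peaks: PeakSet | np.ndarray,
    mask: MovementMask | None = None,
    fps: float | None = None,
    t0: float = 0.0,
) -> RRSeries:
    """Construct RR intervals from peaks, excluding movement seconds.

    ``peaks`` is either a :class:`~pulsebeam.peak_detect.PeakSet` (frame
    indices; requires ``fps``) or an array of beat times in seconds (the
    reference path).  An interval is dropped when its [start, end] span
    overlaps any flagged second [s, s+1) with positive measure; survivors
    are concatenated without interpolation.

    Raises
    ------
    ValueError
        With fewer than 2 peaks, or when the mask is shorter than the
        record it is applied to.
    """
    if isinstance(peaks, PeakSet):
        fps = fps if fps is not None else peaks.fps
        if not np.isfinite(fps):
            raise ValueError("frame-index peaks require fps")
        times = t0 + peaks.indices / fps
    else:
        times = np.asarray(peaks, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 peaks to form an interval")
    starts, ends = times[:-1], times[1:]
    intervals = (ends - starts) * 1000.0

    if mask is not None and mask.total_movement_s > 0:
        if len(mask.flags) < int(np.floor(ends[-1])):
            raise ValueError(
                f"movement mask covers {len(mask.flags)} s but the record extends to {ends[-1]:.1f} s"
            )
        flagged = mask.flagged_seconds()
        # overlap with positive measure: start < s+1 and end > s
        drop = np.zeros(len(intervals), dtype=bool)
        for s in flagged:
            drop |= (starts < s + 1.0) & (ends > s)
        keep = ~drop
        n_excl = int(drop.sum())
    else:
        keep = np.ones(len(intervals), dtype=bool)
        n_excl = 0
    return RRSeries(
        intervals_ms=intervals[keep],
        starts_s=starts[keep],
        ends_s=ends[keep],
        n_excluded_movement=n_excl,
    )


def time_domain(rr: RRSeries | np.ndarray) -> tuple[float, float, float]:
    """Mean RR, SDNN and RMSSD of an interval series, all in ms.

    SDNN is the sample standard deviation (n-1 denominator); RMSSD is the
    root mean square of successive interval differences.
    """
    iv = np.asarray(rr.intervals_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    if len(iv) < 2:
        raise ValueError("need >= 2 intervals for mean/SDNN")
    mean = float(iv.mean())
    sdnn = float(iv.std(ddof=1))
    # RMSSD needs >= 2 successive differences to be meaningful
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2))) if len(iv) >= 3 else float("nan")
    return mean, sdnn, rmssd


def freq_domain(
    rr: RRSeries | np.ndarray, cfg: SpectralConfig | None = None
) -> tuple[float, float, float]:
    """LF power, HF power and the LF/HF ratio of an interval series.

    The mean-removed series is tapered by a Hamming window of its own
    length, zero-padded to ``fft_size`` and transformed; band powers sum
    the squared magnitude over the half-open LF and HF bands.  The beat
    axis maps to Hz through the effective rate ``1000 / mean RR``
    samples/s (no interpolation).  Returns ``lf_hf = inf`` when the HF
    band holds no power.
    """
    cfg = cfg or SpectralConfig()
    iv = np.asarray(rr.intervals_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    if len(iv) < 16:
        raise ValueError("need >= 16 intervals for spectral indices")
    if len(iv) > cfg.fft_size:
        raise ValueError("interval count exceeds fft_size")
    x = (iv - iv.mean()) * np.hamming(len(iv))
    spec = np.abs(rfft(x, n=cfg.fft_size))
    s = spec**2 if cfg.power else spec
    f_eff = 1000.0 / iv.mean()  # beats per second
    f = rfftfreq(cfg.fft_size, 1.0 / f_eff)
    lf = float(s[(f >= cfg.lf_band[0]) & (f < cfg.lf_band[1])].sum())
    hf = float(s[(f >= cfg.hf_band[0]) & (f < cfg.hf_band[1])].sum())
    ratio = lf / hf if hf > 0 else np.inf
    return lf, hf, ratio


def hrv_indices(rr: RRSeries | np.ndarray, cfg: SpectralConfig | None = None) -> HRVIndices:
    """Bundle time- and frequency-domain indices for one evaluation."""
    mean, sdnn, rmssd = time_domain(rr)
    lf, hf, ratio = freq_domain(rr, cfg)
    return HRVIndices(
        mean_rr_ms=mean, sdnn_ms=sdnn, rmssd_ms=rmssd, lf_power=lf, hf_power=hf, lf_hf=ratio
    )


def evaluate(
    cube: RadarCube,
    filter_spec: FilterSpec | None = None,
    band: HRBand | None = None,
    spectral: SpectralConfig | None = None,
    movement_alpha: float = 5.0,
    movement_trim: float = 0.1,
    hr_max_bpm: float = 130.0,
    mode: str = "phase",
    return_details: bool = False,
):
    """End-to-end HRV evaluation of one raw radar cube.

    Composition of the pipeline stages: phase compensation ->
    movement detection -> bin selection / vital extraction ->
    peak detection (edge transients excluded) -> RR construction with
    movement exclusion -> HRV indices.  Deterministic for a fixed input.

    Returns the :class:`HRVIndices`; with ``return_details=True``, a
    ``(indices, details)`` pair where details holds the intermediate
    products (mask, vital, peaks, rr).
    """
    filter_spec = filter_spec or FilterSpec()
    compensated = phase_compensate(cube)
    mask = detect_movement(movement_statistic(compensated), alpha=movement_alpha, trim=movement_trim)
    vital = select_mp(compensated, band=band, spec=filter_spec, mode=mode)
    R = default_R(cube.fps, hr_max_bpm)
    limit = default_limit(cube.duration_s, hr_max_bpm)
    edge = filter_spec.edge_frames(cube.fps)
    peaks = detect_peaks(vital, R=R, limit=limit, exclude_edge=edge)
    rr = build_rr(peaks, mask=mask, fps=cube.fps, t0=cube.t0)
    indices = hrv_indices(rr, spectral)
    if return_details:
        return indices, {"mask": mask, "vital": vital, "peaks": peaks, "rr": rr}
    return indices
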