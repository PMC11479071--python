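"""Phase compensation, slow-time band-pass filtering, and phase demodulation.

At a 250 Hz frame rate the radar's pulse-integration budget degrades and
every fast-time sample of a frame acquires a common phase error.  Because
bin 0 holds the direct transmitter-to-receiver path — a static return that
should have constant phase — rotating each frame by the negative of its
bin-0 phase cancels the frame-common error exactly
(:func:`phase_compensate`).

Respiration dominates chest displacement, so the slow-time series is then
band-limited to the heart band by a cascade of two linear-phase FIR
filters (:func:`bandpass_slowtime`): a 5 Hz low-pass smoothing filter of
order 30 and a high-pass of order 1000 whose edge is 40 beats/min
(40/60 Hz).  Both are zero-phase in effect: the group delay is removed so
peak timestamps stay unbiased.

:func:`demodulate_phase` converts a bin's complex slow-time series into a
displacement-proportional real series by removing the static clutter
phasor (least-squares circle fit in the IQ plane) and unwrapping the
residual angle — the arctangent demodulation standard in radar vital-sign
work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin, freqz

from .radar_model import RadarCube


@dataclass(frozen=True)
class FilterSpec:
    """Slow-time band-pass cascade specification.

    ``highpass_cutoff_hz`` defaults to 40/60 Hz: heart rates are quoted in
    beats per minute, and the band edge of 40 bpm converts to 0.667 Hz.
    The alternate 60 bpm edge (1.0 Hz) is selectable by passing
    ``highpass_cutoff_hz=1.0``.
    """

    lowpass_cutoff_hz: float = 5.0
    lowpass_order: int = 30
    highpass_cutoff_hz: float = 40.0 / 60.0
    highpass_order: int = 1000

    def validate(self, fps: float) -> None:
        if not (0 < self.highpass_cutoff_hz < self.lowpass_cutoff_hz < fps / 2):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_cutoff_hz}) < lowpass "
                f"({self.lowpass_cutoff_hz}) < fps/2 ({fps / 2})"
            )

    def taps(self, fps: float) -> tuple[np.ndarray, np.ndarray]:
        """Design the (lowpass, highpass) FIR taps for sampling rate ``fps``."""
        self.validate(fps)
        lp = firwin(self.lowpass_order + 1, self.lowpass_cutoff_hz, fs=fps)
        # highpass needs odd tap count for a type-I linear-phase FIR
        n_hp = self.highpass_order + 1
        if n_hp % 2 == 0:
            n_hp += 1
        hp = firwin(n_hp, self.highpass_cutoff_hz, fs=fps, pass_zero=False)
        return lp, hp

    def response(self, fps: float, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex cascade frequency response at ``freqs_hz``."""
        lp, hp = self.taps(fps)
        _, h_lp = freqz(lp, worN=freqs_hz, fs=fps)
        _, h_hp = freqz(hp, worN=freqs_hz, fs=fps)
        return h_lp * h_hp

    def edge_frames(self, fps: float) -> int:
        """Half-length of the longest filter: the edge-transient extent."""
        lp, hp = self.taps(fps)
        return max(len(lp), len(hp)) // 2


def phase_compensate(cube: RadarCube, ref_bin: int = 0) -> RadarCube:
    """Rotate every frame by the negative phase of its reference-bin sample.

    The reference bin (the direct path) is presumed free of displacement,
    so any phase it shows is frame-common distortion; after compensation
    it has zero phase in all frames and every amplitude is unchanged.

    Raises
    ------
    ValueError
        If ``ref_bin`` is out of range, or a reference sample has zero
        amplitude (reported with its frame index).
    """
    if not (0 <= ref_bin < cube.n_bins):
        raise ValueError(f"ref_bin {ref_bin} out of range [0, {cube.n_bins})")
    ref = cube.frames[ref_bin]
    zero = np.abs(ref) == 0.0
    if np.any(zero):
        raise ValueError(
            f"zero-amplitude reference sample at frame {int(np.argmax(zero))}; cannot compensate"
        )
    rotation = np.exp(-1j * np.angle(ref))
    return RadarCube(
        frames=cube.frames * rotation[None, :],
        fps=cube.fps,
        range_start=cube.range_start,
        bin_spacing=cube.bin_spacing,
        t0=cube.t0,
    )


def bandpass_series(x: np.ndarray, fps: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the FIR cascade to a one-dimensional slow-time series.

    Centred convolution (``mode='same'``) cancels the linear-phase group
    delay, so output samples align with input timestamps.  The first and
    last half-filter-length samples carry edge transients.
    """
    spec = spec or FilterSpec()
    lp, hp = spec.taps(fps)
    if len(x) <= max(len(lp), len(hp)):
        raise ValueError(f"series of length {len(x)} is shorter than the filter ({max(len(lp), len(hp))} taps)")
    return fftconvolve(fftconvolve(x, lp, mode="same"), hp, mode="same")


def bandpass_slowtime(cube: RadarCube, spec: FilterSpec | None = None) -> RadarCube:
    """Band-pass every fast-time bin's slow-time series.

    Real and imaginary parts are filtered alike (the cascade is linear
    with real taps, so filtering the complex series does exactly that).
    """
    spec = spec or FilterSpec()
    lp, hp = spec.taps(cube.fps)
    if cube.n_frames <= max(len(lp), len(hp)):
        raise ValueError(
            f"cube with {cube.n_frames} frames is shorter than the filter ({max(len(lp), len(hp))} taps)"
        )
    out = fftconvolve(fftconvolve(cube.frames, lp[None, :], mode="same", axes=1), hp[None, :], mode="same", axes=1)
    return RadarCube(
        frames=out,
        fps=cube.fps,
        range_start=cube.range_start,
        bin_spacing=cube.bin_spacing,
        t0=cube.t0,
    )


def fit_ring_center(z: np.ndarray) -> complex:
    """Least-squares (Kasa) circle fit of an IQ trajectory; returns the centre.

    A vibrating point target traces an arc of a circle in the IQ plane
    whose centre is the static clutter phasor of that bin.  Falls back to
    the sample mean if the fit is degenerate (e.g. constant input).
    """
    x, y = z.real, z.imag
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank < 3 or not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return complex(np.mean(x), np.mean(y))
    return complex(sol[0] / 2.0, sol[1] / 2.0)


def ring_coherence(z: np.ndarray, center: complex | None = None) -> float:
    """Coefficient of variation of the circle-fit radius.

    Near 0 for a bin carrying a clean vibrating return (the trajectory
    stays on its circle); near the Rayleigh CV (about 0.52) for
    noise-only bins.  Used to gate fast-time bins before demodulation.
    """
    c = fit_ring_center(z) if center is None else center
    r = np.abs(z - c)
    m = r.mean()
    if m == 0.0:
        return np.inf
    return float(r.std() / m)


def demodulate_phase(z: np.ndarray, center: complex | None = None) -> np.ndarray:
    """Arctangent demodulation of one bin's complex slow-time series.

    Subtracts the circle-fit clutter centre, takes the angle, and unwraps.
    The result is ``4 pi (R0 + d(t)) / lambda`` up to an additive
    constant, i.e. proportional to target displacement.
    """
    c = fit_ring_center(z) if center is None else center
    return np.unwrap(np.angle(z - c))
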