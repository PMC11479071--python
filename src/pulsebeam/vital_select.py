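"""Fast-time bin (MP) selection and extraction of the scalar vital signal.

The fast-time bin with the largest slow-time variance is usually
respiration-dominated, so the heartbeat-carrying bin is found instead by
examining the spectral content of each candidate bin.  Two modes are
provided:

``phase`` (default)
    Each eligible bin is arctangent-demodulated
    (:func:`pulsebeam.preprocess.demodulate_phase`) after a ring-coherence
    gate rejects bins whose IQ trajectory is not circle-like (noise or
    clutter-only bins).  Among the gated bins, the one with the most
    stable ring radius — the maximum-SNR displacement estimate — is
    selected, its demodulated phase is band-passed, and that real series
    is the vital signal.  All bins near the target observe the *same*
    displacement, so the ring coherence, not the band ratio, is the
    discriminative statistic here.

``real``
    The classical rule: the cube is band-passed and the bin maximising
    the heart-band to noise-band power ratio of the *real part* of its
    slow-time series is selected.  Simple, but blind near demodulation
    nulls (target ranges where the displacement maps into the imaginary
    quadrature) and distorted by respiration harmonics when the phase
    modulation index is large.

Expected input for both modes is the phase-compensated (not yet
band-passed) cube; band-pass filtering happens internally so each mode
can apply it at the right point.  :func:`band_ratio` itself is a public
primitive usable on any series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.fft import rfft, rfftfreq

from .preprocess import FilterSpec, bandpass_series, bandpass_slowtime, demodulate_phase, fit_ring_center, ring_coherence
from .radar_model import RadarCube


@dataclass(frozen=True)
class HRBand:
    """Heart-rate frequency band, 40-130 beats/min by default.

    The noise band used as the denominator of :func:`band_ratio` is the
    complement of the HR band within [0.05 Hz, fps/2]; the 0.05 Hz floor
    keeps residual drift out of the denominator.
    """

    lo_hz: float = 40.0 / 60.0
    hi_hz: float = 130.0 / 60.0
    noise_floor_hz: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError("need 0 < lo_hz < hi_hz")


@dataclass(frozen=True)
class VitalSignal:
    """One-dimensional slow-time vital signal at the selected bin MP."""

    v0: np.ndarray
    fps: float
    mp_bin: int
    t0: float = 0.0

    @property
    def n(self) -> int:
        return len(self.v0)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fps


def band_ratio(series: np.ndarray, fps: float, band: HRBand | None = None) -> float:
    """Heart-band to noise-band power ratio of a slow-time series.

    The periodogram is the squared magnitude of the discrete transform of
    the mean-removed series; the ratio sums periodogram power inside
    [lo, hi) and divides by the power in the complement band
    [noise_floor, fps/2) \\ [lo, hi).  Returns ``inf`` (with a warning)
    when the noise band holds no power.
    """
    band = band or HRBand()
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * fps:
        raise ValueError("series must span at least 2 seconds")
    if band.hi_hz >= fps / 2:
        raise ValueError("HR band extends past Nyquist")
    p = np.abs(rfft(x - x.mean())) ** 2
    f = rfftfreq(len(x), 1.0 / fps)
    in_band = (f >= band.lo_hz) & (f < band.hi_hz)
    noise = (f >= band.noise_floor_hz) & (f < fps / 2) & ~in_band
    p_in = p[in_band].sum()
    p_noise = p[noise].sum()
    if p_noise == 0.0:
        if p_in == 0.0:
            return 0.0  # no signal at all
        warnings.warn("noise band holds no power; band ratio undefined, returning inf")
        return np.inf
    return float(p_in / p_noise)


def select_mp(
    cube: RadarCube,
    band: HRBand | None = None,
    spec: FilterSpec | None = None,
    mode: str = "phase",
    guard_m: float = 0.02,
    coherence_max: float = 0.3,
) -> VitalSignal:
    """Select the vital fast-time bin MP and return its slow-time signal.

    ``cube`` must be phase-compensated.  Bins within ``guard_m`` metres of
    the start range are ineligible (they belong to the direct-path
    reference region).  Ties break toward the lowest bin index.

    Raises
    ------
    ValueError
        If no bin is eligible (in phase mode: no bin passes the
        ring-coherence gate).
    """
    band = band or HRBand()
    spec = spec or FilterSpec()
    first = int(np.ceil(guard_m / cube.bin_spacing))
    first = max(first, 1)
    if first >= cube.n_bins:
        raise ValueError("guard excludes every fast-time bin")

    if mode == "real":
        filtered = bandpass_slowtime(cube, spec)
        ratios = np.array(
            [band_ratio(filtered.frames[k].real, cube.fps, band) for k in range(first, cube.n_bins)]
        )
        mp = first + int(np.argmax(ratios))  # argmax returns the first (lowest) maximiser
        return VitalSignal(v0=filtered.frames[mp].real.copy(), fps=cube.fps, mp_bin=mp, t0=cube.t0)

    if mode != "phase":
        raise ValueError(f"unknown mode {mode!r}; expected 'phase' or 'real'")

    # among circle-like bins, the strongest ring (largest radius) is the
    # chest return; noise blobs fail the coherence gate, weak side lobes
    # lose on radius
    best_bin, best_radius, best_center = -1, -np.inf, 0j
    for k in range(first, cube.n_bins):
        center = fit_ring_center(cube.frames[k])
        coh = ring_coherence(cube.frames[k], center)
        if coh < coherence_max:
            radius = float(np.mean(np.abs(cube.frames[k] - center)))
            if radius > best_radius:
                best_bin, best_radius, best_center = k, radius, center
    if best_bin < 0:
        raise ValueError(
            f"no eligible bins: no IQ trajectory passed the ring-coherence gate (< {coherence_max})"
        )
    phase = demodulate_phase(cube.frames[best_bin], best_center)
    v0 = bandpass_series(phase - phase.mean(), cube.fps, spec)
    return VitalSignal(v0=v0, fps=cube.fps, mp_bin=best_bin, t0=cube.t0)
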