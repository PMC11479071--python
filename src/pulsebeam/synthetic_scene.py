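"""Synthetic radar scenes, reference beat sequences, and study tables.

Every stage of the pipeline is testable without hardware because this
module generates its inputs with known ground truth:

* :func:`generate_rr_series` draws a beat-time sequence whose RR intervals
  carry sinusoidal LF/HF modulation plus white variability,
* :func:`render_cube` turns a beat sequence into a complex radar frame
  matrix using a physical displacement model — respiration sinusoid plus a
  Gaussian chest-wall pulse per heartbeat — with static clutter, a strong
  direct-path return in bin 0, frame-common phase jitter, white complex
  noise, and optional second-scale movement bursts,
* :func:`generate_study` draws a multi-evaluation table of paired
  radar/reference HRV indices with group-dependent distributions and VAS
  scores, for the agreement and distress statistics.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radar_model import AcquisitionConfig, RadarCube

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SceneParams:
    """Physical and physiological parameters of one synthetic scene.

    RR defaults mirror a resting adult control population (mean 828 ms,
    total SD 37 ms with LF/HF sinusoidal components giving an LF/HF power
    ratio near 0.7).  Displacement amplitudes are physiological textbook
    values: ~4 mm chest excursion from respiration, ~0.3 mm from the
    heartbeat — respiration dominates, which is the premise the band-pass
    and bin-selection stages are designed around.  The carrier wavelength
    0.04 m corresponds to a 7.5 GHz centre frequency.
    """

    rr_mean_ms: float = 828.0
    rr_sd_ms: float = 37.0
    lf_mod: tuple[float, float] = (25.0, 0.10)  # (amplitude ms, frequency Hz)
    hf_mod: tuple[float, float] = (30.0, 0.30)
    resp_amp_m: float = 4e-3
    resp_freq_hz: float = 0.25
    heart_amp_m: float = 3e-4
    heart_pulse_width_s: float = 0.05
    target_range_m: float = 0.7
    carrier_wavelength_m: float = 0.04
    snr_db: float | None = 35.0  # None -> noiseless
    phase_jitter_sd_rad: float = 0.01
    clutter_amp: float = 0.2
    direct_path_amp: float = 5.0
    movement_bursts: tuple[tuple[float, float, float], ...] = ()  # (start_s, duration_s, amplitude_m)
    rr_min_ms: float = 300.0
    rr_max_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr_mean_ms <= 0:
            raise ValueError("rr_mean_ms must be positive")
        if self.heart_amp_m >= self.resp_amp_m:
            raise ValueError("heart_amp_m must be smaller than resp_amp_m (respiration dominates)")
        if self.rr_sd_ms < 0:
            raise ValueError("rr_sd_ms must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Known beat times and movement seconds of a synthetic scene."""

    beat_times_s: np.ndarray
    movement_seconds: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times_s, dtype=float)
        if bt.ndim != 1 or len(bt) < 2:
            raise ValueError("need at least two beat times")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times_s must be strictly increasing")
        object.__setattr__(self, "beat_times_s", bt)

    @property
    def rr_true_ms(self) -> np.ndarray:
        return np.diff(self.beat_times_s) * 1000.0


def generate_rr_series(params: SceneParams, duration_s: float) -> GroundTruth:
    """Draw a beat-time sequence with LF/HF-modulated RR intervals.

    The i-th interval is ``rr_mean + a_lf sin(2 pi f_lf t_i) +
    a_hf sin(2 pi f_hf t_i) + eps_i`` with ``eps_i`` white Gaussian; its SD
    is chosen so the total interval SD is approximately ``rr_sd_ms``
    (a sampled sinusoid of amplitude ``a`` contributes variance ``a^2/2``).
    Beat times are the cumulative sums.

    Raises
    ------
    ValueError
        If the parameters can produce a non-positive RR interval or the
        modulation amplitudes alone exceed the requested total SD.
    """
    if duration_s <= 2 * params.rr_mean_ms / 1000.0:
        raise ValueError("duration_s must exceed two mean RR intervals")
    a_lf, f_lf = params.lf_mod
    a_hf, f_hf = params.hf_mod
    var_mod = a_lf**2 / 2.0 + a_hf**2 / 2.0
    var_eps = params.rr_sd_ms**2 - var_mod
    if var_eps < -1e-9:
        raise ValueError(
            f"lf/hf modulation alone implies RR SD {np.sqrt(var_mod):.1f} ms > requested rr_sd_ms {params.rr_sd_ms}"
        )
    eps_sd = float(np.sqrt(max(var_eps, 0.0)))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)))
    beats = [0.2]  # first beat shortly after acquisition start
    while beats[-1] < duration_s + 2.0:
        t = beats[-1]
        rr = (
            params.rr_mean_ms
            + a_lf * np.sin(_TWO_PI * f_lf * t)
            + a_hf * np.sin(_TWO_PI * f_hf * t)
            + eps_sd * rng.standard_normal()
        )
        if rr <= 0:
            raise ValueError(f"parameters produced non-positive RR interval ({rr:.1f} ms)")
        rr = float(np.clip(rr, params.rr_min_ms, params.rr_max_ms))
        beats.append(t + rr / 1000.0)
    beat_times = np.array([b for b in beats if b < duration_s])

    movement = set()
    for start, dur, _amp in params.movement_bursts:
        movement.update(range(int(np.floor(start)), int(np.ceil(start + dur))))
    return GroundTruth(beat_times_s=beat_times, movement_seconds=frozenset(movement))


def _heart_displacement(t: np.ndarray, beats: np.ndarray, amp: float, width: float) -> np.ndarray:
    """Gaussian chest-wall pulse train: one pulse of SD ``width`` per beat."""
    d = np.zeros_like(t)
    fps = 1.0 / (t[1] - t[0])
    n = len(t)
    half = int(np.ceil(4 * width * fps))
    for b in beats:
        c = int(round((b - t[0]) * fps))
        i0, i1 = max(0, c - half), min(n, c + half + 1)
        if i0 < i1:
            d[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - b) / width) ** 2)
    return d


def _movement_displacement(
    t: np.ndarray,
    bursts: tuple[tuple[float, float, float], ...],
    rng: np.random.Generator,
    update_hz: float | None = None,
) -> np.ndarray:
    """Random-offset displacement during movement bursts.

    Sedentary shifts are modelled as the body sitting at a new random
    offset in [-amp, amp] every update (default: every frame).  A shift of
    a few millimetres is many carrier wavelengths of two-way path, so each
    update decorrelates the return completely — emulating the broadband
    frame-to-frame change that gross motion of a whole torso produces,
    which the single-point target model otherwise understates.
    """
    d = np.zeros_like(t)
    fps = 1.0 / (t[1] - t[0])
    hold = 1 if update_hz is None else max(1, int(round(fps / update_hz)))
    for start, dur, amp in bursts:
        i0 = int(round((start - t[0]) * fps))
        i1 = min(len(t), int(round((start + dur - t[0]) * fps)))
        if i1 <= i0:
            continue
        n_steps = int(np.ceil((i1 - i0) / hold))
        offsets = rng.uniform(-amp, amp, n_steps)
        d[i0:i1] += np.repeat(offsets, hold)[: i1 - i0]
    return d


def render_cube(truth: GroundTruth, params: SceneParams, cfg: AcquisitionConfig | None = None) -> RadarCube:
    """Render a complex radar frame matrix from a beat-time ground truth.

    The target's displacement ``d(t)`` (respiration + heartbeat pulses +
    movement bursts) phase-modulates a complex return
    ``env(k) * exp(j 4 pi (R_0 + d(t)) / lambda)`` whose amplitude envelope
    ``env`` is a Gaussian in range centred on the target.  Every frame is
    further rotated by a common random-walk jitter ``theta_t`` (the phase
    noise the compensation stage must cancel); bin 0 carries a strong
    static direct-path return with the same jitter; static clutter and
    white complex noise at ``snr_db`` (relative to the target-bin signal
    power) complete the scene.

    Random draws (clutter, jitter, noise, movement) come from streams
    spawned from ``params.seed``, so re-rendering with one parameter
    changed (e.g. jitter off) leaves the other draws identical.
    """
    cfg = cfg or AcquisitionConfig()
    if not (cfg.range_start_m <= params.target_range_m <= cfg.range_max_m):
        raise ValueError(
            f"target_range_m {params.target_range_m} outside [{cfg.range_start_m}, {cfg.range_max_m}]"
        )
    if truth.beat_times_s[-1] > cfg.window_s:
        raise ValueError("ground truth extends past the acquisition window")

    n = cfg.n_frames
    t = np.arange(n) / cfg.fps
    seq = np.random.SeedSequence(entropy=params.seed)
    rng_clutter, rng_jitter, rng_noise, rng_move = (
        np.random.default_rng(s) for s in seq.spawn(5)[1:]
    )

    d = params.resp_amp_m * np.sin(_TWO_PI * params.resp_freq_hz * t)
    d += _heart_displacement(t, truth.beat_times_s, params.heart_amp_m, params.heart_pulse_width_s)
    d += _movement_displacement(t, params.movement_bursts, rng_move)

    ranges = cfg.range_start_m + cfg.bin_spacing_m * np.arange(cfg.n_bins)
    envelope = np.exp(-0.5 * ((ranges - params.target_range_m) / (2.0 * cfg.bin_spacing_m)) ** 2)
    phase = 4.0 * np.pi * (params.target_range_m + d) / params.carrier_wavelength_m
    signal = envelope[:, None] * np.exp(1j * phase)[None, :]

    clutter = params.clutter_amp * (
        rng_clutter.standard_normal(cfg.n_bins) + 1j * rng_clutter.standard_normal(cfg.n_bins)
    )
    frames = signal + clutter[:, None]

    theta = np.cumsum(params.phase_jitter_sd_rad * rng_jitter.standard_normal(n))
    frames *= np.exp(1j * theta)[None, :]
    frames[0, :] = params.direct_path_amp * np.exp(1j * theta)

    if params.snr_db is not None and np.isfinite(params.snr_db):
        target_bin = int(np.argmin(np.abs(ranges - params.target_range_m)))
        p_sig = float(np.mean(np.abs(signal[target_bin]) ** 2))
        noise_sd = np.sqrt(p_sig / 10.0 ** (params.snr_db / 10.0) / 2.0)
        frames += noise_sd * (
            rng_noise.standard_normal(frames.shape) + 1j * rng_noise.standard_normal(frames.shape)
        )

    return RadarCube(
        frames=frames,
        fps=cfg.fps,
        range_start=cfg.range_start_m,
        bin_spacing=cfg.bin_spacing_m,
        t0=0.0,
    )


def match_rr(
    est_beat_times_s: np.ndarray,
    true_beat_times_s: np.ndarray,
    tol_s: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair estimated with true RR intervals by nearest-beat matching.

    Each estimated beat is matched to its nearest true beat (within
    ``tol_s``); an RR pair is kept when two consecutive estimated beats
    match two consecutive true beats.  Returns (rr_est_ms, rr_true_ms)
    arrays of equal length, for recovery scoring against ground truth.
    """
    est = np.asarray(est_beat_times_s, dtype=float)
    true = np.asarray(true_beat_times_s, dtype=float)
    if len(est) < 2 or len(true) < 2:
        return np.array([]), np.array([])
    dist = np.abs(est[:, None] - true[None, :])
    nearest = dist.argmin(axis=1)
    ok = dist.min(axis=1) <= tol_s
    good = ok[:-1] & ok[1:] & (np.diff(nearest) == 1)
    rr_est = np.diff(est)[good] * 1000.0
    rr_true = np.diff(true)[nearest[:-1][good]] * 1000.0
    return rr_est, rr_true


# --------------------------------------------------------------------------
# study-level generator


#: per-group HRV means (mean_rr_ms, sdnn_ms, rmssd_ms, lf_hf) for the
#: reference method, resting office-worker population
DEFAULT_GROUP_MEANS: dict[str, tuple[float, float, float, float]] = {
    "control1": (840.76, 34.99, 39.28, 0.71),
    "control2": (832.15, 36.31, 51.10, 0.72),
    "control3": (821.93, 33.10, 41.59, 0.73),
    "high": (727.27, 22.28, 22.76, 0.95),
}

#: radar-minus-reference systematic offsets per index (mean_rr, sdnn, rmssd, lf_hf)
DEFAULT_METHOD_BIAS: tuple[float, float, float, float] = (0.05, 3.0, 11.0, -0.14)

#: SD of the radar-minus-reference difference per index
DEFAULT_METHOD_SD: tuple[float, float, float, float] = (2.6, 6.2, 21.7, 0.24)

#: between-evaluation SDs per index within a group
DEFAULT_BETWEEN_SD: tuple[float, float, float, float] = (80.0, 12.0, 20.0, 0.25)

#: VAS bins per group; draws land on the 0.5-resolution grid inside the bin
_VAS_RANGES: dict[str, tuple[float, float]] = {
    "control1": (0.0, 2.0),
    "control2": (2.5, 4.5),
    "control3": (5.0, 7.0),
    "high": (7.5, 9.5),
}

_INDEX_NAMES = ("mean_rr_ms", "sdnn_ms", "rmssd_ms", "lf_hf")


@dataclass(frozen=True)
class StudyParams:
    """Parameters of a multi-evaluation synthetic study table.

    Each evaluation draws a latent HRV state from its group's
    distribution; the reference method reports the latent state and the
    radar reports it plus a per-index systematic bias and Gaussian
    between-method noise.  Group sample sizes default to a 102-evaluation
    layout (21/20/49 controls, 12 high-distress).
    """

    group_counts: dict[str, int] = field(
        default_factory=lambda: {"control1": 21, "control2": 20, "control3": 49, "high": 12}
    )
    group_means: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS)
    )
    between_sd: tuple[float, float, float, float] = DEFAULT_BETWEEN_SD
    method_bias: tuple[float, float, float, float] = DEFAULT_METHOD_BIAS
    method_sd: tuple[float, float, float, float] = DEFAULT_METHOD_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.group_counts.values()):
            raise ValueError("group counts must be >= 1")
        if any(s < 0 for s in self.between_sd) or any(s < 0 for s in self.method_sd):
            raise ValueError("standard deviations must be nonnegative")


def generate_study(params: StudyParams) -> pd.DataFrame:
    """Draw a per-evaluation table of paired radar/reference HRV indices.

    Returns a DataFrame with one row per evaluation and columns ``id``,
    ``group``, ``vas``, ``radar_<index>`` and ``ref_<index>`` for each of
    mean_rr_ms, sdnn_ms, rmssd_ms, lf_hf.  Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(10,)))
    rows = []
    eid = 0
    for group, count in params.group_counts.items():
        means = np.asarray(params.group_means[group], dtype=float)
        lo, hi = _VAS_RANGES[group]
        grid = np.arange(lo, hi + 0.25, 0.5)
        for _ in range(count):
            latent = means + np.asarray(params.between_sd) * rng.standard_normal(4)
            latent = np.maximum(latent, (200.0, 1.0, 1.0, 0.01))  # keep indices physical
            radar = (
                latent
                + np.asarray(params.method_bias)
                + np.asarray(params.method_sd) * rng.standard_normal(4)
            )
            radar = np.maximum(radar, (200.0, 1.0, 1.0, 0.01))
            row = {"id": eid, "group": group, "vas": float(rng.choice(grid))}
            for j, name in enumerate(_INDEX_NAMES):
                row[f"ref_{name}"] = latent[j]
                row[f"radar_{name}"] = radar[j]
            rows.append(row)
            eid += 1
    return pd.DataFrame(rows)
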