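"""Per-second sedentary-movement detection with a CFAR-style threshold.

Gross body motion swamps the millimetre-scale vital displacement, so
seconds containing movement must be excluded from RR construction.  The
movement statistic is the mean squared frame-to-frame change of the whole
(phase-compensated) frame matrix within each second, normalised by the
evaluation median; the decision threshold adapts to each evaluation as a
multiple of the trimmed mean of the full score sequence — a cell-averaging
constant-false-alarm-rate rule over the whole window, with per-second
decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .radar_model import RadarCube


@dataclass(frozen=True)
class MovementMask:
    """Per-second movement flags and the scores they were derived from."""

    flags: np.ndarray
    scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        scores = np.asarray(self.scores, dtype=float)
        if flags.shape != scores.shape:
            raise ValueError("flags and scores must have equal length")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "scores", scores)

    @property
    def total_movement_s(self) -> int:
        return int(np.count_nonzero(self.flags))

    def flagged_seconds(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


def movement_statistic(cube: RadarCube) -> np.ndarray:
    """Per-second movement score of a (phase-compensated) cube.

    ``score[s]`` is the mean over the frames of second ``s`` of the summed
    squared frame-to-frame amplitude change across all fast-time bins,
    normalised by the evaluation median so the statistic is invariant to a
    global amplitude rescale.  Runs on the compensated cube *before*
    band-pass filtering, so gross motion is not filtered away.

    Raises
    ------
    ValueError
        If the cube is shorter than 2 seconds.
    """
    n_seconds = int(np.floor(cube.duration_s))
    if n_seconds < 2:
        raise ValueError("cube must span at least 2 seconds for a movement statistic")
    fps = int(round(cube.fps))
    diffs = np.abs(np.diff(cube.frames, axis=1)) ** 2  # [bin, frame-1]
    per_frame = diffs.sum(axis=0)
    # frame t's diff (t vs t-1) belongs to the second containing frame t
    per_frame = np.concatenate([[0.0], per_frame])[: n_seconds * fps]
    scores = per_frame.reshape(n_seconds, fps).mean(axis=1)
    med = np.median(scores)
    if med > 0:
        scores = scores / med
    return scores


def detect_movement(scores: np.ndarray, alpha: float = 5.0, trim: float = 0.1) -> MovementMask:
    """Flag movement seconds by a trimmed-mean CA-CFAR threshold.

    ``threshold = alpha * mean(scores with the top `trim` fraction
    removed)``; a second is flagged when its score exceeds the threshold.
    Trimming keeps genuine bursts from inflating their own threshold.
    Deterministic; raising ``alpha`` never enlarges the flagged set.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be nonempty")
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    n_drop = int(np.floor(trim * scores.size))
    kept = np.sort(scores)[: scores.size - n_drop] if n_drop else np.sort(scores)
    threshold = alpha * float(kept.mean())
    if np.all(scores == scores[0]) and alpha <= 1.0:
        # degenerate: no contrast to threshold against; flag nothing
        warnings.warn("all movement scores equal and alpha <= 1: flagging nothing")
        flags = np.zeros(scores.shape, dtype=bool)
        return MovementMask(flags=flags, scores=scores, threshold=threshold)
    flags = scores > threshold
    return MovementMask(flags=flags, scores=scores, threshold=threshold)
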