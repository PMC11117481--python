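"""Freezing-of-gait (FOG) detection and per-minute aggregation.

Frames are classified by an RBF-kernel SVM over temporal features
(per-axis mean absolute increments and standard deviations, the three
inter-axis correlations) and spectral features (dominant-peak frequency
and magnitude, spectral skewness and kurtosis), plus the two locomotor
band energies for context.  Positive frames are merged into episodes with
a one-hop gap tolerance; because freezing is by construction a gait
phenomenon, episodes are only searched within or adjacent to detected
walking context (a configurable gate, on by default).

Per minute, the episode count (an episode is counted in the minute
containing its start) and the seconds spent frozen (split proportionally
across minute boundaries) are reported, together with the percentage of
walking time spent frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FrameSet
from .gait import WalkingBout

FOG_FEATURES = (
    "incr_x", "incr_y", "incr_z",
    "std_x", "std_y", "std_z",
    "corr_xy", "corr_xz", "corr_yz",
    "peak_freq", "peak_mag", "spec_skew", "spec_kurt",
    "e_0p1_3", "e_0p1_10",
)

GATE_MARGIN_S = 10.0


@dataclass
class FogModel:
    """Trained FOG/non-FOG frame classifier.

    The exact feature list is recorded in the artifact; standardization
    statistics live inside the sklearn pipeline.
    """

    pipeline: Pipeline
    feature_names: tuple = FOG_FEATURES
    n_frames: int = 0
    seed: int = 0

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(features[list(self.feature_names)].to_numpy())

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.decision_function(
            features[list(self.feature_names)].to_numpy())


def train_fog_svm(features: pd.DataFrame, is_fog: np.ndarray, seed: int = 0,
                  C: float = 10.0) -> FogModel:
    """Fit the FOG SVM on labeled frames (both classes required).

    Class weights are balanced: freezing frames are heavily outnumbered in
    any realistic training corpus.
    """
    y = np.asarray(is_fog, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training frames must include both FOG and non-FOG")
    X = features[list(FOG_FEATURES)].to_numpy()
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=C, gamma="scale",
                    class_weight="balanced", random_state=seed)),
    ])
    pipe.fit(X, y)
    return FogModel(pipeline=pipe, n_frames=len(y), seed=seed)


def detect_fog(frames: FrameSet, features: pd.DataFrame, model: FogModel,
               bouts: list[WalkingBout] | None = None, gate: bool = True,
               gate_margin_s: float = GATE_MARGIN_S,
               decision_threshold: float = 0.0) -> list[tuple[float, float]]:
    """Detect FOG episodes on one recording.

    Returns episode spans (start_s, end_s) as the union of the member
    frames; positive frames separated by at most one hop of non-FOG are
    merged into the same episode.  When ``gate`` is set and bouts are
    given, only frames whose centre lies within ``gate_margin_s`` of a
    detected walking bout are eligible.
    """
    if len(frames) == 0:
        return []
    pos = model.decision_function(features) > decision_threshold
    if gate and bouts is not None:
        centers = frames.start_times + frames.frame_s / 2
        in_context = np.zeros(len(frames), dtype=bool)
        for b in bouts:
            in_context |= (centers >= b.start_s - gate_margin_s) & \
                          (centers <= b.end_s + gate_margin_s)
        pos &= in_context
    idx = np.flatnonzero(pos)
    if len(idx) == 0:
        return []
    episodes: list[tuple[float, float]] = []
    splits = np.flatnonzero(np.diff(idx) > 2)  # gap tolerance: one hop
    for run in np.split(idx, splits + 1):
        start = frames.start_times[run[0]]
        end = frames.start_times[run[-1]] + frames.frame_s
        episodes.append((float(start), float(end)))
    return episodes


@dataclass
class FogMinute:
    minute_index: int
    n_episodes: int
    time_with_fog_s: float


def aggregate_fog(episodes: list[tuple[float, float]], duration_s: float,
                  walking_time_s: float | None = None, minute_s: float = 60.0
                  ) -> tuple[pd.DataFrame, int, float, float]:
    """Per-minute FOG aggregation.

    Returns ``(minutes, n_episodes_total, time_with_fog_s,
    percent_time_fog_of_walking)``.  Episode counts attach to the minute of
    the episode start; episode time is split proportionally across
    minutes.  The percentage divides total FOG time by total walking time
    and is NaN when no walking time is available.
    """
    n_min = max(int(np.ceil(duration_s / minute_s)), 1)
    counts = np.zeros(n_min, dtype=int)
    seconds = np.zeros(n_min)
    for s, e in episodes:
        s, e = max(s, 0.0), min(e, duration_s)
        if e <= s:
            continue
        counts[min(int(s // minute_s), n_min - 1)] += 1
        m0, m1 = int(s // minute_s), int(min(e, duration_s - 1e-9) // minute_s)
        for m in range(m0, min(m1, n_min - 1) + 1):
            lo, hi = m * minute_s, (m + 1) * minute_s
            seconds[m] += max(0.0, min(e, hi) - max(s, lo))
    minutes = pd.DataFrame({
        "minute_index": np.arange(n_min),
        "n_episodes": counts,
        "time_with_fog_s": seconds,
    })
    total_time = float(seconds.sum())
    if walking_time_s is None or walking_time_s <= 0:
        percent = np.nan if total_time > 0 else 0.0
    else:
        percent = 100.0 * total_time / walking_time_s
    return minutes, int(counts.sum()), total_time, percent
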