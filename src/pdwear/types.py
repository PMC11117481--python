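"""Core containers shared across the pipeline.

Axis convention for the waist-worn device (left anterior-superior iliac
spine): x = anterior (forward), y = vertical (upward), z = lateral (left).
Acceleration is expressed in g; the device full scale is +/-6 g and the
sampling rate 50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Ground-truth / detector state vocabulary, index = integer label code.
STATE_NAMES: tuple[str, ...] = ("rest", "voluntary", "walking", "dyskinesia", "fog")

REST, VOLUNTARY, WALKING, DYSKINESIA, FOG = range(5)

#: Device constants.
SAMPLING_RATE = 50.0
FULL_SCALE_G = 6.0


def state_code(name: str) -> int:
    try:
        return STATE_NAMES.index(name)
    except ValueError:
        raise ValueError(f"unknown state {name!r}; expected one of {STATE_NAMES}") from None


@dataclass
class SubjectProfile:
    """Clinical and gait parameters configuring one simulated subject.

    ``dys_rate`` is expected dyskinesia episodes per hour of static time,
    ``fog_rate`` expected freezing episodes per hour of walking.
    ``gait_speed_scale`` scales the vertical centre-of-mass excursion and
    forward acceleration amplitude (1.0 = typical).
    """

    subject_id: str
    leg_length: float = 0.85
    age: float = 67.0
    hy_stage: float = 2.5
    has_dys: bool = False
    has_fog: bool = False
    dys_rate: float = 0.0
    fog_rate: float = 0.0
    gait_cadence: float = 110.0
    gait_speed_scale: float = 1.0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.6 < self.leg_length < 1.2:
            raise ValueError(f"leg_length {self.leg_length} outside (0.6, 1.2) m")
        if not 60.0 < self.gait_cadence < 140.0:
            raise ValueError(f"gait_cadence {self.gait_cadence} outside (60, 140) steps/min")
        if self.dys_rate < 0 or self.fog_rate < 0:
            raise ValueError("episode rates must be >= 0")


@dataclass
class LabeledRecording:
    """One subject-day of triaxial acceleration with ground truth.

    ``accel`` has shape (n, 3) in g, columns (x anterior, y vertical up,
    z lateral left).  ``labels`` holds per-sample integer state codes
    (see :data:`STATE_NAMES`); it is empty for unlabeled field data.
    ``truth_events`` is a list of (state_name, start_s, end_s);
    ``truth_strides`` the planted heel-strike times in seconds.
    """

    subject_id: str
    accel: np.ndarray
    sampling_rate: float = SAMPLING_RATE
    labels: Optional[np.ndarray] = None
    truth_events: list = field(default_factory=list)
    truth_strides: np.ndarray = field(default_factory=lambda: np.empty(0))
    day: int = 0

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must have shape (n, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.accel):
                raise ValueError("labels and accel lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.accel)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def events_of(self, state: str) -> list[tuple[float, float]]:
        return [(s, e) for name, s, e in self.truth_events if name == state]


@dataclass
class CohortSpec:
    """Size and structure of a simulated cohort.

    Four disjoint groups: dyskinesia-positive/negative and FOG
    positive/negative.  ``group_params`` optionally overrides the
    module-level covariate distribution defaults.
    """

    n_dys_pos: int = 0
    n_dys_neg: int = 0
    n_fog_pos: int = 0
    n_fog_neg: int = 0
    days_per_subject: int = 5
    hours_per_day: float = 8.0
    seed: int = 0
    group_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = (self.n_dys_pos, self.n_dys_neg, self.n_fog_pos, self.n_fog_neg)
        if any(c < 0 for c in counts):
            raise ValueError("group counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.days_per_subject < 1:
            raise ValueError("days_per_subject must be >= 1")

    @property
    def n_subjects(self) -> int:
        return self.n_dys_pos + self.n_dys_neg + self.n_fog_pos + self.n_fog_neg
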