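"""Gait detection, stride segmentation and spatiotemporal gait parameters.

Gait frames are recognized by an RBF-kernel SVM over two band energies
([0.1, 3] Hz and [0.1, 10] Hz of the axis-norm signal); contiguous positive
frames are merged into walking bouts.  Within a bout, heel strikes are the
minima of the low-pass-filtered anterior (forward) acceleration; strides
span consecutive heel strikes of the same foot, so one stride = two steps
throughout.  The first two and last two strides of every bout are excluded
from analysis.

Per stride: step length from the inverted-pendulum model
``2*sqrt(2*l*h - h^2)`` (leg length l, vertical centre-of-mass excursion h
obtained by double integration of the detrended vertical acceleration),
stride speed = 2*step_length / stride duration, and stride fluidity = the
0.1-10 Hz band energy of the stride's samples.  Parameters are then
averaged per wall-clock minute; minutes with fewer than 8 steps, zero
values or missing values are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import signal
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FrameSet, frame_band_energy
from .types import LabeledRecording

G_MS2 = 9.81

GAIT_FEATURES = ("e_0p1_3", "e_0p1_10")


@dataclass
class GaitModel:
    """Trained gait/no-gait frame classifier (RBF SVM on two band energies).

    Features are standardized by statistics stored inside the sklearn
    pipeline; gamma = 0.5 corresponds to 1/(2*variance) after
    standardization, C = 1.
    """

    pipeline: Pipeline
    n_frames: int
    seed: int
    kernel_params: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(features[list(GAIT_FEATURES)].to_numpy())

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.decision_function(features[list(GAIT_FEATURES)].to_numpy())


@dataclass
class Stride:
    t_start: float
    t_end: float
    step_length: float = np.nan
    stride_speed: float = np.nan
    fluidity: float = np.nan
    contributes: bool = True

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class WalkingBout:
    start_s: float
    end_s: float
    frame_indices: np.ndarray
    heel_strikes: np.ndarray = field(default_factory=lambda: np.empty(0))
    strides: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def train_gait_svm(features: pd.DataFrame, is_gait: np.ndarray, seed: int = 0
                   ) -> GaitModel:
    """Fit the two-feature gait SVM on labeled frames."""
    y = np.asarray(is_gait, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training frames must include both gait and non-gait")
    X = features[list(GAIT_FEATURES)].to_numpy()
    params = {"kernel": "rbf", "C": 1.0, "gamma": 0.5}
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(random_state=seed, **params)),
    ])
    pipe.fit(X, y)
    return GaitModel(pipeline=pipe, n_frames=len(y), seed=seed, kernel_params=params)


def detect_gait(frames: FrameSet, features: pd.DataFrame, model: GaitModel,
                min_bout_frames: int = 3) -> list[WalkingBout]:
    """Classify frames and merge contiguous positives into walking bouts.

    Bouts shorter than ``min_bout_frames`` frames are dropped.  A bout's
    extent is the union of its frames.
    """
    if len(frames) == 0:
        return []
    pos = model.predict(features).astype(bool)
    bouts: list[WalkingBout] = []
    idx = np.flatnonzero(pos)
    if len(idx) == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        if len(run) < min_bout_frames:
            continue
        start = frames.start_times[run[0]]
        end = frames.start_times[run[-1]] + frames.frame_s
        bouts.append(WalkingBout(start_s=float(start), end_s=float(end),
                                 frame_indices=run))
    return bouts


def detect_strides(bout: WalkingBout, recording: LabeledRecording,
                   lowpass_hz: float = 10.0) -> np.ndarray:
    """Heel-strike times: minima of the low-pass forward acceleration.

    The expected heel-strike period is estimated from the dominant 0.3-3 Hz
    periodogram peak of the forward signal; candidate minima closer than
    0.4 of that period are resolved in favour of the deeper one (the
    behaviour of peak finding with a distance constraint).
    """
    fs = recording.sampling_rate
    i0, i1 = int(round(bout.start_s * fs)), int(round(bout.end_s * fs))
    x = recording.accel[i0:i1, 0]
    if len(x) < int(fs):
        return np.empty(0)
    if np.ptp(x) < 1e-12:
        return np.empty(0)
    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x - x.mean())

    freqs, p = _periodogram(xf, fs)
    band = (freqs >= 0.3) & (freqs <= 3.0)
    if not band.any() or p[band].max() <= 0:
        return np.empty(0)
    f_dom = freqs[band][int(np.argmax(p[band]))]
    min_dist = max(int(0.4 / f_dom * fs), 1)

    prom = 0.5 * xf.std()
    peaks, _ = signal.find_peaks(-xf, distance=min_dist, prominence=prom)
    # drop shallow minima (filter transients at bout edges): a heel strike
    # must be comparably deep to the typical one of this bout
    if len(peaks) >= 3:
        depth = -xf[peaks]
        med = np.median(depth)
        if med > 0:
            peaks = peaks[depth >= 0.5 * med]
    return (i0 + peaks) / fs


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    from .features import periodogram_power
    freqs, p = periodogram_power(x, remove_mean=True)
    return freqs * fs, p


def step_length_inverted_pendulum(h: float, leg_length: float) -> float:
    """Inverted-pendulum step length ``2*sqrt(2*l*h - h**2)`` (metres).

    ``h`` is the vertical centre-of-mass excursion; a non-positive or
    out-of-range excursion marks the step as not available (NaN).
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if not 0 < h <= leg_length:
        return np.nan
    return 2.0 * np.sqrt(2.0 * leg_length * h - h * h)


def vertical_excursion(stride_accel_y_g: np.ndarray, fs: float) -> float:
    """Per-stride vertical CoM excursion by double integration.

    The mean-removed vertical acceleration (converted to m/s^2) is
    integrated twice; the displacement is linearly detrended per stride to
    bound drift, and h = (max - min) / 2.
    """
    a = (np.asarray(stride_accel_y_g, dtype=float)
         - np.mean(stride_accel_y_g)) * G_MS2
    if len(a) < 4:
        return np.nan
    dt = 1.0 / fs
    v = np.concatenate(([0.0], np.cumsum((a[1:] + a[:-1]) / 2) * dt))
    d = np.concatenate(([0.0], np.cumsum((v[1:] + v[:-1]) / 2) * dt))
    d = signal.detrend(d, type="linear")
    return float(np.ptp(d) / 2)


def stride_parameters(heel_strikes: np.ndarray, recording: LabeledRecording,
                      leg_length: float) -> list[Stride]:
    """Fill per-stride parameters and apply the 2+2 trimming rule.

    One stride = two steps, so stride speed is ``2*step_length/duration``.
    Stride fluidity is the triaxial 0.1-10 Hz band energy of the stride's
    samples.
    """
    fs = recording.sampling_rate
    strides: list[Stride] = []
    n = len(heel_strikes) - 1
    for k in range(n):
        t0, t1 = float(heel_strikes[k]), float(heel_strikes[k + 1])
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = recording.accel[i0:i1]
        st = Stride(t_start=t0, t_end=t1, contributes=2 <= k < n - 2)
        if len(seg) >= 4:
            h = vertical_excursion(seg[:, 1], fs)
            st.step_length = step_length_inverted_pendulum(h, leg_length)
            if np.isfinite(st.step_length) and st.duration > 0:
                st.stride_speed = 2.0 * st.step_length / st.duration
            st.fluidity = float(frame_band_energy(seg, fs, 0.1, 10.0))
        strides.append(st)
    return strides


def cadence(bout: WalkingBout) -> float:
    """Cadence in steps/min: steps divided by walking-bout duration, x60.

    Steps = 2 per stride interval (heel strikes of one foot).  The duration
    is the span from first to last heel strike when available — the frame
    union over-pads the true bout by up to a frame at each edge — and falls
    back to the bout extent otherwise.
    """
    hs = np.asarray(bout.heel_strikes, dtype=float)
    if len(hs) >= 2:
        duration = hs[-1] - hs[0]
        steps = 2 * (len(hs) - 1)
    else:
        duration = bout.duration_s
        steps = 0
    if duration <= 0:
        raise ValueError("walking bout has non-positive duration")
    return steps / duration * 60.0


def analyze_bouts(bouts: list[WalkingBout], recording: LabeledRecording,
                  leg_length: float) -> list[WalkingBout]:
    """Run stride detection + parameters on every bout, in place."""
    for bout in bouts:
        bout.heel_strikes = detect_strides(bout, recording)
        bout.strides = stride_parameters(bout.heel_strikes, recording, leg_length)
    return bouts


@dataclass
class GaitMinute:
    minute_index: int
    n_steps: int
    means: dict
    variances: dict
    retained: bool


def aggregate_gait_minutes(bouts: list[WalkingBout]) -> pd.DataFrame:
    """Per-minute means/variances of the gait parameters.

    Contributing strides are binned by the wall-clock minute of their start.
    A minute is retained only when it contains at least 8 steps and none of
    its aggregated parameters is zero or missing (short or degenerate
    walking periods are non-representative).
    """
    rows = []
    strides = [s for b in bouts for s in b.strides if s.contributes]
    if strides:
        minutes = sorted({int(s.t_start // 60) for s in strides})
        for m in minutes:
            group = [s for s in strides if int(s.t_start // 60) == m]
            n_steps = 2 * len(group)
            vals = {
                "step_length": np.array([s.step_length for s in group]),
                "stride_speed": np.array([s.stride_speed for s in group]),
                "fluidity": np.array([s.fluidity for s in group]),
            }
            durs = np.array([s.duration for s in group])
            cad = 2 * len(group) / durs.sum() * 60.0 if durs.sum() > 0 else np.nan
            row = {"minute_index": m, "n_steps": n_steps, "cadence_mean": cad}
            ok = n_steps >= 8 and np.isfinite(cad) and cad > 0
            for name, v in vals.items():
                mean = float(np.nanmean(v)) if len(v) else np.nan
                var = float(np.nanvar(v)) if len(v) else np.nan
                row[f"{name}_mean"] = mean
                row[f"{name}_var"] = var
                if not np.isfinite(mean) or mean == 0 or np.isnan(v).any():
                    ok = False
            row["retained"] = ok
            rows.append(row)
    cols = ["minute_index", "n_steps", "cadence_mean",
            "step_length_mean", "step_length_var",
            "stride_speed_mean", "stride_speed_var",
            "fluidity_mean", "fluidity_var", "retained"]
    return pd.DataFrame(rows, columns=cols)
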