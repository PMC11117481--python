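"""Fixed-length frame segmentation and frame-level features.

Recordings are segmented into 3.2 s frames overlapped by 50% (hop 1.6 s);
every detector in the pipeline consumes features of these frames.  The
spectral estimator is the unwindowed periodogram of the mean-removed frame
(160 samples at 50 Hz, bin width 0.3125 Hz); band membership is by bin
centre, half-open ``[f_lo, f_hi)``.  Band energies and spectral features
combine the axes by summing the three per-axis periodograms of the
mean-removed axes — the total vector signal power, invariant under any
static rotation of a belt-worn device.  (Taking the spectrum of the
Euclidean *magnitude* instead would rectify oscillations, aliasing a
single-axis f Hz movement to 2f and halving its in-band energy.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import LabeledRecording

FRAME_S = 3.2
OVERLAP = 0.5

#: Canonical feature-column order of :func:`feature_table`.
FEATURE_COLUMNS = (
    "e_0p1_3", "e_0p1_10", "e_1_4", "e_0_20",
    "incr_x", "incr_y", "incr_z",
    "std_x", "std_y", "std_z",
    "corr_xy", "corr_xz", "corr_yz",
    "peak_freq", "peak_mag", "spec_skew", "spec_kurt",
)


@dataclass
class Frame:
    """One analysis window: a (L, 3) acceleration slice plus metadata."""

    start_s: float
    duration_s: float
    samples: np.ndarray
    sampling_rate: float
    index: int = 0
    features: Optional[dict] = None


class FrameSet:
    """Sequence of overlapped frames over one recording.

    Indexing yields :class:`Frame` views; :meth:`feature_table` computes
    the full feature matrix vectorized across frames.
    """

    def __init__(self, recording: LabeledRecording, frame_s: float = FRAME_S,
                 overlap: float = OVERLAP):
        if not 0 <= overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        fs = recording.sampling_rate
        L = int(round(frame_s * fs))
        if abs(L - frame_s * fs) > 1e-9:
            raise ValueError("frame_s * sampling_rate must be an integer sample count")
        H = int(round(L * (1 - overlap)))
        if H < 1:
            raise ValueError("hop must be at least one sample")
        self.recording = recording
        self.frame_s = frame_s
        self.overlap = overlap
        self.frame_len = L
        self.hop = H
        n = recording.n_samples
        if n < L:
            warnings.warn("recording shorter than one frame; no frames produced")
            self.starts = np.empty(0, dtype=int)
        else:
            self.starts = np.arange(0, n - L + 1, H)

    @property
    def fs(self) -> float:
        return self.recording.sampling_rate

    @property
    def start_times(self) -> np.ndarray:
        return self.starts / self.fs

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> Frame:
        s = int(self.starts[i])
        return Frame(start_s=s / self.fs, duration_s=self.frame_s,
                     samples=self.recording.accel[s:s + self.frame_len],
                     sampling_rate=self.fs, index=i)

    def stacked(self) -> np.ndarray:
        """All frames as one (n_frames, L, 3) array."""
        idx = self.starts[:, None] + np.arange(self.frame_len)[None, :]
        return self.recording.accel[idx]

    def majority_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame majority ground-truth state code and its purity.

        Requires a labeled recording.
        """
        if self.recording.labels is None:
            raise ValueError("recording carries no label track")
        idx = self.starts[:, None] + np.arange(self.frame_len)[None, :]
        lab = self.recording.labels[idx]
        n_states = int(lab.max(initial=0)) + 1
        counts = np.stack([(lab == k).sum(axis=1) for k in range(n_states)], axis=1)
        maj = counts.argmax(axis=1)
        purity = counts.max(axis=1) / self.frame_len
        return maj.astype(int), purity

    def feature_table(self) -> pd.DataFrame:
        return feature_table(self)


def segment_frames(recording: LabeledRecording, frame_s: float = FRAME_S,
                   overlap: float = OVERLAP) -> FrameSet:
    """Segment a recording into fixed-length overlapped frames.

    Trailing samples that do not fill a whole frame are discarded; a
    recording shorter than one frame yields an empty FrameSet (with a
    warning).
    """
    return FrameSet(recording, frame_s=frame_s, overlap=overlap)


# --- spectral machinery ----------------------------------------------------

def periodogram_power(x: np.ndarray, remove_mean: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram as *mean power per bin* (Parseval-normalized).

    ``x`` may be 1-D or (rows, L).  Returns (bin frequencies as a fraction
    of fs, power), i.e. multiply frequencies by fs.  ``sum(power)`` equals
    ``mean(x**2)`` (of the mean-removed signal when ``remove_mean``).
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[-1]
    if remove_mean:
        x = x - x.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(x, axis=-1)
    p = (np.abs(X) ** 2) / L ** 2
    # double the interior bins for the one-sided spectrum
    if L % 2 == 0:
        p[..., 1:-1] *= 2
    else:
        p[..., 1:] *= 2
    freqs = np.arange(p.shape[-1]) / L
    return freqs, p


def band_energy(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Signal energy (mean power, g^2) in the band ``[f_lo, f_hi)``.

    The frame mean is removed before the transform whenever ``f_lo > 0``;
    a band starting at 0 Hz keeps the DC bin.  Works on a 1-D signal or on
    stacked rows.
    """
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"invalid band [{f_lo}, {f_hi})")
    x = np.asarray(x, dtype=float)
    if f_hi > fs / 2 + 1e-9:
        raise ValueError("band exceeds the Nyquist frequency")
    freqs, p = periodogram_power(x, remove_mean=f_lo > 0)
    mask = (freqs * fs >= f_lo) & (freqs * fs < f_hi)
    return p[..., mask].sum(axis=-1)


def combined_spectrum(stacked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of per-axis periodograms of the mean-removed axes.

    ``stacked`` is (F, L, 3) or (L, 3).  Returns (bin frequencies as a
    fraction of fs, power (F, nbins)); the total is the summed AC power of
    the three axes (rotation-invariant).
    """
    stacked = np.asarray(stacked, dtype=float)
    single = stacked.ndim == 2
    if single:
        stacked = stacked[None]
    total = None
    for ax in range(3):
        freqs, p = periodogram_power(stacked[:, :, ax], remove_mean=True)
        total = p if total is None else total + p
    return freqs, (total[0] if single else total)


def frame_band_energy(stacked: np.ndarray, fs: float, f_lo: float,
                      f_hi: float) -> np.ndarray:
    """Triaxial band energy: per-axis band energies summed (g^2)."""
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"invalid band [{f_lo}, {f_hi})")
    freqs, p = combined_spectrum(stacked)
    mask = (freqs * fs >= f_lo) & (freqs * fs < f_hi)
    return p[..., mask].sum(axis=-1)


def temporal_features(frame: Frame) -> dict:
    """Mean absolute increment, std and inter-axis Pearson correlation.

    A constant axis has zero variance; its correlations are defined as 0 so
    feature vectors stay total.
    """
    x = np.asarray(frame.samples, dtype=float)
    d = np.abs(np.diff(x, axis=0)).mean(axis=0) if len(x) > 1 else np.zeros(3)
    sd = x.std(axis=0)
    c = x - x.mean(axis=0)
    out = {"incr_x": d[0], "incr_y": d[1], "incr_z": d[2],
           "std_x": sd[0], "std_y": sd[1], "std_z": sd[2]}
    for name, (i, j) in (("corr_xy", (0, 1)), ("corr_xz", (0, 2)), ("corr_yz", (1, 2))):
        denom = sd[i] * sd[j] * len(x)
        out[name] = float((c[:, i] * c[:, j]).sum() / denom) if denom > 0 else 0.0
    return out


def spectral_features(frame: Frame) -> dict:
    """Dominant spectral peak and the skewness/kurtosis of spectral mass.

    Computed on the summed per-axis periodogram of the mean-removed axes;
    the normalized spectrum is treated as a probability distribution over
    frequency.  A zero-power frame returns zeros by convention.
    """
    freqs, p = combined_spectrum(np.asarray(frame.samples, dtype=float))
    f_hz = freqs * frame.sampling_rate
    total = p.sum()
    if total <= 0:
        return {"peak_freq": 0.0, "peak_mag": 0.0, "spec_skew": 0.0, "spec_kurt": 0.0}
    above = f_hz >= 0.1
    k = int(np.argmax(np.where(above, p, -np.inf)))
    w = p / total
    mu = float((w * f_hz).sum())
    var = float((w * (f_hz - mu) ** 2).sum())
    if var <= 0:
        return {"peak_freq": float(f_hz[k]), "peak_mag": float(p[k]),
                "spec_skew": 0.0, "spec_kurt": 0.0}
    sd = np.sqrt(var)
    return {
        "peak_freq": float(f_hz[k]),
        "peak_mag": float(p[k]),
        "spec_skew": float((w * ((f_hz - mu) / sd) ** 3).sum()),
        "spec_kurt": float((w * ((f_hz - mu) / sd) ** 4).sum()),
    }


def feature_table(frames: FrameSet) -> pd.DataFrame:
    """Full feature matrix for every frame, vectorized.

    Columns are :data:`FEATURE_COLUMNS`; the index is the frame index and a
    ``start_s`` column gives each frame's start time.
    """
    F = len(frames)
    if F == 0:
        return pd.DataFrame(columns=("start_s",) + FEATURE_COLUMNS)
    stacked = frames.stacked()            # (F, L, 3)
    fs = frames.fs
    freqs, p = combined_spectrum(stacked)  # (F, nbins)
    f_hz = freqs * fs

    out = {"start_s": frames.start_times}
    for name, lo, hi in (("e_0p1_3", 0.1, 3.0), ("e_0p1_10", 0.1, 10.0),
                         ("e_1_4", 1.0, 4.0), ("e_0_20", 0.0, 20.0)):
        mask = (f_hz >= lo) & (f_hz < hi)
        out[name] = p[:, mask].sum(axis=1)

    d = np.abs(np.diff(stacked, axis=1)).mean(axis=1)     # (F, 3)
    sd = stacked.std(axis=1)
    out.update(incr_x=d[:, 0], incr_y=d[:, 1], incr_z=d[:, 2],
               std_x=sd[:, 0], std_y=sd[:, 1], std_z=sd[:, 2])
    c = stacked - stacked.mean(axis=1, keepdims=True)
    L = stacked.shape[1]
    for name, (i, j) in (("corr_xy", (0, 1)), ("corr_xz", (0, 2)), ("corr_yz", (1, 2))):
        denom = sd[:, i] * sd[:, j] * L
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (c[:, :, i] * c[:, :, j]).sum(axis=1) / denom
        out[name] = np.where(denom > 0, r, 0.0)

    total = p.sum(axis=1)
    safe_total = np.where(total > 0, total, 1.0)
    above = f_hz >= 0.1
    masked = np.where(above[None, :], p, -np.inf)
    k = masked.argmax(axis=1)
    out["peak_freq"] = np.where(total > 0, f_hz[k], 0.0)
    out["peak_mag"] = np.where(total > 0, p[np.arange(F), k], 0.0)
    w = p / safe_total[:, None]
    mu = (w * f_hz[None, :]).sum(axis=1)
    var = (w * (f_hz[None, :] - mu[:, None]) ** 2).sum(axis=1)
    sdev = np.sqrt(np.where(var > 0, var, 1.0))
    z = (f_hz[None, :] - mu[:, None]) / sdev[:, None]
    ok = (total > 0) & (var > 0)
    out["spec_skew"] = np.where(ok, (w * z ** 3).sum(axis=1), 0.0)
    out["spec_kurt"] = np.where(ok, (w * z ** 4).sum(axis=1), 0.0)

    df = pd.DataFrame(out)
    return df[["start_s", *FEATURE_COLUMNS]]
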