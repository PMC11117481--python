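"""Dyskinesia detection: dual band-energy rule with 6 s persistence.

A period is dyskinetic when the 1-4 Hz band energy is above a calibrated
threshold while the 0-20 Hz band energy stays below a second threshold, for
at least 6 seconds.  The low-band gate restricts the search to static
periods, suppressing false positives from voluntary movement; frames
classified as gait are never flagged.

Frames qualifying under the dual rule select candidate spans; the "at
least 6 sec" persistence is then measured at sample resolution on the
1-4 Hz amplitude envelope of the signal (Butterworth band-pass + Hilbert
transform, lightly smoothed), because the 1.6 s frame hop would otherwise
quantize the persistence boundary far from 6 s.  The envelope threshold is
the amplitude of the sinusoid that carries exactly the high-band energy
threshold, ``sqrt(2*theta_high)``.

Flagged time is aggregated on a 10-minute grid anchored at the recording
start: percent time with dyskinesia per window, and the number of
dyskinesia periods = the number of positive 10-minute windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .features import FrameSet

ENVELOPE_SMOOTH_S = 0.5
ENVELOPE_GAP_BRIDGE_S = 0.3


@dataclass
class DysThresholds:
    """Calibrated thresholds of the dual band-energy rule.

    ``theta_high``: minimum 1-4 Hz energy (g^2); ``theta_low``: maximum
    0-20 Hz energy (g^2) — the two criteria are independent;
    ``min_duration_s``: persistence requirement (default 6 s).
    """

    theta_high: float
    theta_low: float
    min_duration_s: float = 6.0

    def __post_init__(self) -> None:
        if self.theta_high <= 0 or self.theta_low <= 0 or self.min_duration_s <= 0:
            raise ValueError("thresholds and minimum duration must be positive")


def calibrate_dys_thresholds(features: pd.DataFrame, frame_states: np.ndarray,
                             min_duration_s: float = 6.0,
                             static_percentile: float = 95.0) -> DysThresholds:
    """Calibrate the two thresholds on labeled frames.

    ``frame_states`` holds state names per frame ("rest", "dyskinesia",
    "voluntary", ...).  theta_high is the log-scale midpoint between the
    rest and dyskinesia 1-4 Hz energy distributions; theta_low the upper
    percentile of the 0-20 Hz energy during static states, so energetic
    voluntary movement falls outside the search.  The percentile is taken
    per static state (rest, dyskinesia) and the maximum kept — pooling
    would let the majority state (rest) drag the threshold below the
    energy of dyskinetic-but-static frames whenever those are rare.
    """
    states = np.asarray(frame_states)
    required = {"rest", "dyskinesia", "voluntary"}
    missing = required - set(states.tolist())
    if missing:
        raise ValueError(f"calibration needs frames of states {sorted(missing)}")
    e14 = features["e_1_4"].to_numpy()
    e020 = features["e_0_20"].to_numpy()
    eps = 1e-300
    log_rest = np.log10(e14[states == "rest"] + eps)
    log_dys = np.log10(e14[states == "dyskinesia"] + eps)
    theta_high = 10 ** ((log_rest.mean() + log_dys.mean()) / 2)
    theta_low = float(max(
        np.percentile(e020[states == "rest"], static_percentile),
        np.percentile(e020[states == "dyskinesia"], static_percentile)))
    return DysThresholds(theta_high=float(theta_high), theta_low=theta_low,
                         min_duration_s=min_duration_s)


def _envelope_1_4(accel: np.ndarray, fs: float) -> np.ndarray:
    """Triaxial 1-4 Hz amplitude envelope: vector magnitude of the three
    per-axis analytic envelopes, lightly smoothed.  A single-axis sinusoid
    of amplitude A gives an envelope of A."""
    sos = signal.butter(4, (1.0, 4.0), btype="bandpass", fs=fs, output="sos")
    env_sq = np.zeros(len(accel))
    for ax in range(3):
        bp = signal.sosfiltfilt(sos, accel[:, ax] - accel[:, ax].mean())
        env_sq += np.abs(signal.hilbert(bp)) ** 2
    env = np.sqrt(env_sq)
    w = max(int(round(ENVELOPE_SMOOTH_S * fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(env, kernel, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [len(mask)]))
    return list(zip(starts.tolist(), stops.tolist()))


def detect_dyskinesia(frames: FrameSet, features: pd.DataFrame,
                      thresholds: DysThresholds,
                      gait_mask: np.ndarray | None = None
                      ) -> list[tuple[float, float]]:
    """Flag dyskinesia spans on one recording.

    ``gait_mask`` marks frames classified as gait (never searched).
    Returns maximal flagged spans (start_s, end_s), each sustained for at
    least ``thresholds.min_duration_s``.
    """
    if len(frames) == 0:
        return []
    e14 = features["e_1_4"].to_numpy()
    e020 = features["e_0_20"].to_numpy()
    qualify = (e14 > thresholds.theta_high) & (e020 < thresholds.theta_low)
    if gait_mask is not None:
        qualify &= ~np.asarray(gait_mask, dtype=bool)

    rec = frames.recording
    fs = rec.sampling_rate
    amp_thr = np.sqrt(2.0 * thresholds.theta_high)

    spans: list[tuple[float, float]] = []
    for i0, i1 in _runs(qualify):
        # candidate extent: union of qualifying frames, padded by one frame
        s0 = max(frames.start_times[i0] - frames.frame_s, 0.0)
        s1 = min(frames.start_times[i1 - 1] + 2 * frames.frame_s, rec.duration_s)
        a, b = int(s0 * fs), int(s1 * fs)
        if b - a < int(fs):
            continue
        env = _envelope_1_4(rec.accel[a:b], fs)
        supra = env >= amp_thr
        runs = _runs(supra)
        # bridge sub-gap dips so amplitude-modulated episodes stay whole
        bridged: list[list[int]] = []
        gap = int(ENVELOPE_GAP_BRIDGE_S * fs)
        for r0, r1 in runs:
            if bridged and r0 - bridged[-1][1] <= gap:
                bridged[-1][1] = r1
            else:
                bridged.append([r0, r1])
        for r0, r1 in bridged:
            if (r1 - r0) / fs >= thresholds.min_duration_s:
                spans.append(((a + r0) / fs, (a + r1) / fs))

    # merge overlaps across candidate extents
    spans.sort()
    merged: list[list[float]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def aggregate_dyskinesia(spans: list[tuple[float, float]], duration_s: float,
                         window_s: float = 600.0
                         ) -> tuple[pd.DataFrame, int, float]:
    """10-minute aggregation of flagged spans.

    Returns ``(windows, n_periods, time_with_dys_s)``: per-window percent
    time with dyskinesia (a span straddling a boundary is split
    proportionally; the final partial window is scaled by its actual
    length), the number of positive windows, and total flagged seconds.
    """
    n_win = max(int(np.ceil(duration_s / window_s)), 1)
    flagged = np.zeros(n_win)
    for s, e in spans:
        s, e = max(s, 0.0), min(e, duration_s)
        w0, w1 = int(s // window_s), int(min(e, duration_s - 1e-9) // window_s)
        for w in range(w0, min(w1, n_win - 1) + 1):
            lo, hi = w * window_s, (w + 1) * window_s
            flagged[w] += max(0.0, min(e, hi) - max(s, lo))
    lengths = np.minimum(window_s, duration_s - np.arange(n_win) * window_s)
    percent = 100.0 * flagged / lengths
    windows = pd.DataFrame({
        "window_index": np.arange(n_win),
        "percent_time_dys": percent,
        "flagged": flagged > 1e-9,
    })
    return windows, int((flagged > 1e-9).sum()), float(flagged.sum())
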