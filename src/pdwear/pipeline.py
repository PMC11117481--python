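"""End-to-end orchestration: simulate -> detect -> analyze.

The detectors (gait SVM, FOG SVM, dyskinesia thresholds) play the role of
the device's factory-trained embedded algorithms: they are trained once on
a dedicated synthetic training set (never on the analysis cohort) and then
applied unchanged to every recording.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .dyskinesia import (DysThresholds, aggregate_dyskinesia,
                         calibrate_dys_thresholds, detect_dyskinesia)
from .features import segment_frames
from .fog import FogModel, aggregate_fog, detect_fog, train_fog_svm
from .gait import (GaitModel, aggregate_gait_minutes, analyze_bouts,
                   detect_gait, train_gait_svm)
from .io import RunConfig
from .simulate import simulate_subject
from .types import STATE_NAMES, LabeledRecording, SubjectProfile

log = logging.getLogger("pdwear")


@dataclass
class Detectors:
    gait_model: GaitModel
    fog_model: FogModel
    dys_thresholds: DysThresholds


@dataclass
class DayResult:
    """Detector outputs for one subject-day."""

    subject_id: str
    day: int
    duration_s: float
    dys_spans: list
    dys_windows: pd.DataFrame
    n_dys_periods: int
    fog_episodes: list
    fog_minutes: pd.DataFrame
    gait_minutes: pd.DataFrame
    walking_time_s: float
    n_bouts: int
    n_strides: int


def train_detectors(config: RunConfig) -> Detectors:
    """Train the frame classifiers and calibrate the dyskinesia thresholds.

    Training material is a small synthetic set of subjects exhibiting all
    five states, generated from ``config.train_seed``.  Episode rates are
    deliberately much higher than any realistic cohort subject — this is a
    training corpus, not an epidemiological sample, and the rare classes
    (freezing above all) need enough frames to anchor the SVMs.  Frames
    with at least 80% label purity are used.
    """
    rng = np.random.default_rng(config.train_seed)
    feats, states = [], []
    for i in range(config.n_train_subjects):
        profile = SubjectProfile(
            subject_id=f"train{i}", has_dys=True, has_fog=True,
            dys_rate=12.0, fog_rate=40.0,
            gait_cadence=float(rng.uniform(90, 130)),
            gait_speed_scale=float(rng.uniform(0.7, 1.2)),
        )
        rec = simulate_subject(profile, config.train_duration_s,
                               seed=int(rng.integers(2 ** 31)))
        frames = segment_frames(rec, config.frame_s, config.overlap)
        table = frames.feature_table()
        maj, purity = frames.majority_labels()
        keep = purity >= 0.8
        feats.append(table[keep])
        states.append(maj[keep])
    table = pd.concat(feats, ignore_index=True)
    state_names = np.array([STATE_NAMES[k] for k in np.concatenate(states)])

    gait_model = train_gait_svm(table, state_names == "walking",
                                seed=config.train_seed)
    fog_model = train_fog_svm(table, state_names == "fog", seed=config.train_seed)
    thresholds = calibrate_dys_thresholds(
        table, state_names, min_duration_s=config.dys_min_duration_s)
    log.info("trained detectors on %d frames (theta_high=%.3g, theta_low=%.3g)",
             len(table), thresholds.theta_high, thresholds.theta_low)
    return Detectors(gait_model=gait_model, fog_model=fog_model,
                     dys_thresholds=thresholds)


def process_recording(recording: LabeledRecording, detectors: Detectors,
                      config: RunConfig, leg_length: float = 0.85) -> DayResult:
    """Run the full detector chain on one recording."""
    frames = segment_frames(recording, config.frame_s, config.overlap)
    features = frames.feature_table()

    bouts = detect_gait(frames, features, detectors.gait_model,
                        min_bout_frames=config.min_bout_frames)
    analyze_bouts(bouts, recording, leg_length)
    gait_minutes = aggregate_gait_minutes(bouts)
    walking_time = float(sum(b.duration_s for b in bouts))

    gait_mask = np.zeros(len(frames), dtype=bool)
    for b in bouts:
        gait_mask[b.frame_indices] = True
    dys_spans = detect_dyskinesia(frames, features, detectors.dys_thresholds,
                                  gait_mask=gait_mask)
    dys_windows, n_dys, _ = aggregate_dyskinesia(
        dys_spans, recording.duration_s, window_s=config.dys_window_s)

    fog_eps = detect_fog(frames, features, detectors.fog_model, bouts=bouts,
                         gate=config.gate_fog)
    fog_minutes, _, _, _ = aggregate_fog(fog_eps, recording.duration_s,
                                         walking_time_s=walking_time,
                                         minute_s=config.fog_minute_s)
    n_strides = sum(len(b.strides) for b in bouts)
    log.info("%s day %d: %d frames, %d bouts, %d strides, %d dys spans, "
             "%d fog episodes, %d/%d retained minutes",
             recording.subject_id, recording.day, len(frames), len(bouts),
             n_strides, len(dys_spans), len(fog_eps),
             int(gait_minutes["retained"].sum()) if len(gait_minutes) else 0,
             len(gait_minutes))
    return DayResult(
        subject_id=recording.subject_id, day=recording.day,
        duration_s=recording.duration_s,
        dys_spans=dys_spans, dys_windows=dys_windows, n_dys_periods=n_dys,
        fog_episodes=fog_eps, fog_minutes=fog_minutes,
        gait_minutes=gait_minutes, walking_time_s=walking_time,
        n_bouts=len(bouts), n_strides=n_strides,
    )


DYS_FEATURES = ("n_dys_periods", "time_with_dys_s", "pct_time_dys")
FOG_FEATURES_SUBJ = ("n_fog_episodes", "time_with_fog_s", "pct_time_fog")


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    reports: dict
    config: RunConfig
    config_hash: str = ""
    logs: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {"config": self.config.to_dict(), "config_hash": self.config_hash,
               "n_subjects": len(self.summaries), "reports": {}}
        for name, rep in self.reports.items():
            out["reports"][name] = {
                **{k: (None if not np.isfinite(v) else float(v))
                   for k, v in rep.summary().items()},
                "confusion": rep.confusion,
                "skipped_folds": rep.skipped_folds,
            }
        return out


def run_pipeline(config: RunConfig, recordings: list[LabeledRecording],
                 covariates: pd.DataFrame,
                 detectors: Detectors | None = None) -> PipelineResult:
    """Process every recording, summarize subjects and run LOSO contrasts.

    Deterministic for a fixed config (detector training seeds included in
    the config).  Contrasts are computed for whichever of dys / fog /
    combined have both classes present in ``covariates``.
    """
    if detectors is None:
        detectors = train_detectors(config)
    leg = covariates.set_index("subject_id")["leg_length"].to_dict() \
        if "leg_length" in covariates.columns else {}
    by_subject: dict[str, list[DayResult]] = {}
    for rec in recordings:
        try:
            day = process_recording(rec, detectors, config,
                                    leg_length=leg.get(rec.subject_id, 0.85))
        except Exception as exc:
            raise RuntimeError(
                f"detection failed for subject {rec.subject_id} "
                f"day {rec.day}: {exc}") from exc
        by_subject.setdefault(rec.subject_id, []).append(day)

    summaries = [cohort_mod.summarize_subject(sid, days)
                 for sid, days in by_subject.items()]
    table = cohort_mod.summaries_table(summaries)
    merged = table.merge(covariates, on="subject_id", how="left")

    reports: dict = {}
    if "has_dys" in merged.columns and merged["has_dys"].nunique() == 2:
        reports["dys"] = cohort_mod.loso_logistic(
            merged[list(DYS_FEATURES)], merged["has_dys"].to_numpy(dtype=int))
    if "has_fog" in merged.columns and merged["has_fog"].nunique() == 2:
        feats = merged[list(FOG_FEATURES_SUBJ)].fillna(0.0)
        reports["fog"] = cohort_mod.loso_logistic(
            feats, merged["has_fog"].to_numpy(dtype=int))
    if {"has_dys", "has_fog"} <= set(merged.columns):
        both = merged["has_dys"] & merged["has_fog"]
        neither = ~merged["has_dys"] & ~merged["has_fog"]
        sel = both | neither
        if both.any() and neither.any():
            feats = merged.loc[sel, list(DYS_FEATURES + FOG_FEATURES_SUBJ)].fillna(0.0)
            reports["combined"] = cohort_mod.loso_logistic(
                feats, both[sel].to_numpy(dtype=int))

    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
    return PipelineResult(summaries=merged, reports=reports, config=config,
                          config_hash=cfg_hash,
                          logs={"overrides": config.non_default()})
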