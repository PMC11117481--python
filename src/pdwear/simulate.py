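"""Synthetic labeled accelerometer recordings and cohort covariates.

The generator emulates what a waist-worn triaxial accelerometer sees over a
day at home: long static periods, bursts of voluntary activity, walking
bouts, and — for affected subjects — levodopa-induced dyskinesia episodes
(band-limited 1-4 Hz oscillation during otherwise static periods) and
freezing-of-gait episodes (3-8 Hz leg trembling that interrupts a walking
bout and arrests forward progression).

State timing follows a semi-Markov scheduler with exponential dwell times;
each state has an explicit additive signal model on top of a gravity
baseline (+1 g on the vertical axis) and a white noise floor.  Ground truth
is recorded sample-accurately, both as a per-sample label track and as an
event list, and planted heel-strike times are kept so stride detection can
be scored against construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    DYSKINESIA,
    FOG,
    FULL_SCALE_G,
    REST,
    SAMPLING_RATE,
    VOLUNTARY,
    WALKING,
    CohortSpec,
    LabeledRecording,
    SubjectProfile,
)

G_MS2 = 9.81

# --- state scheduler -------------------------------------------------------

# mean dwell (s), minimum dwell (s)
_DWELL = {REST: (150.0, 30.0), VOLUNTARY: (90.0, 20.0), WALKING: (45.0, 15.0)}
# transition probabilities between the three scheduled macro-states
_TRANSITIONS = {
    REST: ((VOLUNTARY, 0.5), (WALKING, 0.5)),
    VOLUNTARY: ((REST, 0.6), (WALKING, 0.4)),
    WALKING: ((REST, 0.7), (VOLUNTARY, 0.3)),
}

# dyskinesia episode model: one coherent writhing source per episode,
# projected on the axes (vertical-dominant), plus independent residue
DYS_MIN_DURATION_S = 10.0
DYS_MEAN_EXTRA_S = 20.0
DYS_GAINS = (0.03, 0.06, 0.01)  # g per axis for the shared 1-4 Hz source
DYS_RESIDUE = 0.01

# FOG episode model: coherent trembling source in the 3-8 Hz band (the
# band follows the freeze-trembling literature, it is a modelling choice)
FOG_BAND = (3.0, 8.0)
FOG_MIN_S, FOG_MAX_S = 4.0, 10.0
FOG_GAINS = (0.07, 0.06, 0.05)  # g per axis for the shared source
FOG_RESIDUE = 0.02

# gait signal model
COM_EXCURSION_M = 0.025  # vertical centre-of-mass excursion at speed scale 1
FORWARD_AMP = 0.25       # g, forward (anterior) fundamental at stride frequency

NOISE_REST = 0.008       # g per axis
NOISE_WALK = 0.02
VOLUNTARY_RMS = 0.12     # g per axis inside voluntary-activity segments
VOLUNTARY_BAND = (0.5, 12.0)


def _draw_dwell(rng: np.random.Generator, state: int) -> float:
    mean, lo = _DWELL[state]
    return lo + rng.exponential(mean - lo)


def _schedule(rng: np.random.Generator, duration_s: float) -> list[tuple[int, float, float]]:
    """Semi-Markov macro-state schedule covering [0, duration_s)."""
    segs: list[tuple[int, float, float]] = []
    t = 0.0
    state = REST
    while t < duration_s:
        dwell = min(_draw_dwell(rng, state), duration_s - t)
        segs.append((state, t, t + dwell))
        t += dwell
        nxt, probs = zip(*_TRANSITIONS[state])
        state = int(rng.choice(nxt, p=probs))
    return segs


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float], std: float) -> np.ndarray:
    """Gaussian noise band-pass filtered and rescaled to the target std."""
    if n < 30:
        x = rng.standard_normal(n)
        return std * x / max(x.std(), 1e-12)
    pad = int(2 * fs)
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[pad:-pad]
    return std * x / max(x.std(), 1e-12)


def _place_episodes(rng: np.random.Generator, seg_start: float, seg_end: float,
                    rate_per_hour: float, dur_sampler, margin: float = 2.0
                    ) -> list[tuple[float, float]]:
    """Poisson-count episodes placed without overlap inside one segment."""
    avail = seg_end - seg_start - 2 * margin
    if avail <= 0 or rate_per_hour <= 0:
        return []
    n = rng.poisson(rate_per_hour * (seg_end - seg_start) / 3600.0)
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        dur = min(dur_sampler(rng), avail)
        for _attempt in range(20):
            s = seg_start + margin + rng.uniform(0, max(avail - dur, 1e-6))
            e = s + dur
            if all(e <= ps or s >= pe for ps, pe in placed):
                placed.append((s, e))
                break
    return sorted(placed)


GAIT_RAMP_S = 0.6  # gait initiation/termination taper


_STATE_FROM_NAME = {"rest": REST, "voluntary": VOLUNTARY, "walking": WALKING}


def simulate_subject(profile: SubjectProfile, duration_s: float, seed: int,
                     fs: float = SAMPLING_RATE, noise: float = 1.0,
                     schedule: list | None = None,
                     episodes: list | None = None) -> LabeledRecording:
    """Simulate one labeled subject-day.

    Deterministic: the same profile, duration and seed give byte-identical
    output.  ``noise`` scales the additive sensor/motion noise floor
    (0 gives noise-free deterministic signal components, useful for
    parameter-recovery checks).

    ``schedule`` optionally scripts the macro states as a list of
    ``(state_name, duration_s)`` pairs (states: rest, voluntary, walking)
    instead of the semi-Markov draw; ``episodes`` optionally scripts
    dyskinesia / fog events as ``(state_name, start_s, end_s)`` — a
    dyskinesia episode must lie inside a rest segment and a fog episode
    inside a walking segment.  Unknown states are rejected.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    accel = np.zeros((n, 3))
    labels = np.full(n, REST, dtype=np.int8)
    events: list[tuple[str, float, float]] = []
    heel_strikes: list[float] = []

    # gravity on the vertical (up) axis plus slow orientation sway, below
    # the 0.1 Hz high-pass edge of the embedded features
    accel[:, 1] += 1.0
    for ax, (amp, f0) in enumerate(((0.02, 0.031), (0.015, 0.023), (0.02, 0.037))):
        accel[:, ax] += amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    accel += noise * NOISE_REST * rng.standard_normal((n, 3))

    if schedule is None:
        segs = _schedule(rng, duration_s)
    else:
        segs = []
        cursor = 0.0
        for name, dur in schedule:
            if name not in _STATE_FROM_NAME:
                raise ValueError(f"unknown state {name!r} in schedule")
            if dur <= 0:
                raise ValueError(f"non-positive duration for state {name!r}")
            segs.append((_STATE_FROM_NAME[name], cursor, min(cursor + dur, duration_s)))
            cursor += dur
            if cursor >= duration_s:
                break

    scripted_dys = scripted_fog = None
    if episodes is not None:
        scripted_dys, scripted_fog = [], []
        for name, e0, e1 in episodes:
            if name == "dyskinesia":
                host, target = REST, scripted_dys
            elif name == "fog":
                host, target = WALKING, scripted_fog
            else:
                raise ValueError(f"unknown episode state {name!r}")
            if not any(st == host and s <= e0 and e1 <= e for st, s, e in segs):
                raise ValueError(
                    f"{name} episode ({e0}, {e1}) not inside a "
                    f"{'rest' if host == REST else 'walking'} segment")
            target.append((e0, e1))

    def _sl(s: float, e: float) -> slice:
        return slice(int(round(s * fs)), int(round(e * fs)))

    for state, s0, s1 in segs:
        events.append((
            {REST: "rest", VOLUNTARY: "voluntary", WALKING: "walking"}[state], s0, s1))
        sl = _sl(s0, s1)
        m = sl.stop - sl.start
        if m <= 0:
            continue
        if state == VOLUNTARY:
            labels[sl] = VOLUNTARY
            env = 0.6 + 0.4 * np.abs(np.sin(2 * np.pi * 0.05 * (t[sl] - s0)
                                            + rng.uniform(0, 2 * np.pi)))
            for ax in range(3):
                accel[sl, ax] += env * _bandlimited_noise(
                    rng, m, fs, VOLUNTARY_BAND, VOLUNTARY_RMS)
        elif state == WALKING:
            labels[sl] = WALKING
            cadence = profile.gait_cadence * (1 + 0.02 * rng.standard_normal())
            cadence = float(np.clip(cadence, 61.0, 139.0))
            t_stride = 120.0 / cadence           # one stride = two steps
            f_step = cadence / 60.0
            h = COM_EXCURSION_M * profile.gait_speed_scale
            ts = t[sl] - s0
            seg_len = s1 - s0
            # gait initiation/termination taper
            env = np.clip(np.minimum(ts, seg_len - ts) / GAIT_RAMP_S, 0.0, 1.0)
            # vertical CoM oscillation at step frequency: displacement
            # amplitude h metres -> acceleration amplitude h * (2 pi f)^2
            w_step = 2 * np.pi * f_step
            a_vert = h * w_step ** 2 / G_MS2
            vert = a_vert * np.cos(w_step * ts) \
                + 0.1 * a_vert * np.cos(2 * w_step * ts)
            # forward axis: one sharp minimum per heel strike (stride rate);
            # phase-aligned harmonic keeps the minima exactly at the
            # planted times
            hs = np.arange(s0 + 0.5 * t_stride, s1 - 0.05, t_stride)
            w_str = 2 * np.pi / t_stride
            amp_f = FORWARD_AMP * profile.gait_speed_scale
            fwd = -amp_f * np.cos(w_str * (ts - 1.5 * t_stride)) \
                - 0.3 * amp_f * np.cos(2 * w_str * (ts - 1.5 * t_stride))
            lat = 0.1 * np.sin(w_str * ts)
            accel[sl, 0] += env * fwd
            accel[sl, 1] += env * vert
            accel[sl, 2] += env * lat
            accel[sl] += noise * NOISE_WALK * rng.standard_normal((m, 3))

            # carve freezing episodes out of the bout
            if scripted_fog is not None:
                fog_spans = sorted((a, b) for a, b in scripted_fog
                                   if s0 <= a and b <= s1)
            else:
                fog_spans = _place_episodes(
                    rng, s0, s1, profile.fog_rate if profile.has_fog else 0.0,
                    lambda r: r.uniform(FOG_MIN_S, FOG_MAX_S), margin=3.0)
            for fs0, fs1 in fog_spans:
                fsl = _sl(fs0, fs1)
                fm = fsl.stop - fsl.start
                # remove locomotion, keep gravity/sway, add trembling
                base = accel[fsl].copy()
                tt = t[fsl] - s0
                env_f = np.clip(np.minimum(tt, seg_len - tt) / GAIT_RAMP_S, 0.0, 1.0)
                base[:, 1] -= env_f * (a_vert * np.cos(w_step * tt)
                                       + 0.1 * a_vert * np.cos(2 * w_step * tt))
                base[:, 0] -= env_f * (-amp_f * np.cos(w_str * (tt - 1.5 * t_stride))
                                       - 0.3 * amp_f * np.cos(2 * w_str * (tt - 1.5 * t_stride)))
                base[:, 2] -= env_f * (0.1 * np.sin(w_str * tt))
                source = _bandlimited_noise(rng, fm, fs, FOG_BAND, 1.0)
                for ax, gain in enumerate(FOG_GAINS):
                    g = gain * (1 + 0.2 * rng.standard_normal())
                    base[:, ax] += g * source + _bandlimited_noise(
                        rng, fm, fs, FOG_BAND, FOG_RESIDUE)
                accel[fsl] = base
                labels[fsl] = FOG
                events.append(("fog", fs0, fs1))
            hs_keep = [h_ for h_ in hs
                       if all(h_ < a - 0.1 or h_ > b + 0.1 for a, b in fog_spans)]
            heel_strikes.extend(hs_keep)
        else:  # rest: dyskinesia episodes live only inside static periods
            if scripted_dys is not None:
                dys_spans = sorted((a, b) for a, b in scripted_dys
                                   if s0 <= a and b <= s1)
            else:
                dys_spans = _place_episodes(
                    rng, s0, s1, profile.dys_rate if profile.has_dys else 0.0,
                    lambda r: DYS_MIN_DURATION_S + r.exponential(DYS_MEAN_EXTRA_S))
            for ds0, ds1 in dys_spans:
                dsl = _sl(ds0, ds1)
                dm = dsl.stop - dsl.start
                source = _bandlimited_noise(rng, dm, fs, (1.0, 4.0), 1.0)
                for ax, gain in enumerate(DYS_GAINS):
                    g = gain * (1 + 0.2 * rng.standard_normal())
                    accel[dsl, ax] += g * source + _bandlimited_noise(
                        rng, dm, fs, (1.0, 4.0), DYS_RESIDUE)
                labels[dsl] = DYSKINESIA
                events.append(("dyskinesia", ds0, ds1))

    np.clip(accel, -FULL_SCALE_G, FULL_SCALE_G, out=accel)
    return LabeledRecording(
        subject_id=profile.subject_id,
        accel=accel,
        sampling_rate=fs,
        labels=labels,
        truth_events=events,
        truth_strides=np.asarray(heel_strikes),
    )


# --- cohort generation -----------------------------------------------------

# group-conditional covariate distributions; affected groups mirror the
# usual clinical picture: longer disease duration, higher motor-complication
# scores, higher levodopa-equivalent daily dose
_DEFAULT_GROUP_PARAMS: dict = {
    "age": (67.0, 8.0),
    "leg_length": (0.85, 0.06),
    "moca": (24.0, 3.0),
    "updrs3": (33.0, 10.0),
    "disease_duration_pos": (12.0, 4.0),
    "disease_duration_neg": (7.0, 3.0),
    "ledd_pos": (1125.0, 250.0),
    "ledd_neg": (602.0, 200.0),
    "updrs4_dys": (6.0, 2.0),
    "updrs4_other": (1.5, 1.2),
    "dys_rate_range": (2.0, 5.0),
    "fog_rate_range": (4.0, 10.0),
}


def _draw_profile(rng: np.random.Generator, subject_id: str, group: str,
                  params: dict) -> SubjectProfile:
    p = params
    affected = group in ("dys_pos", "fog_pos")
    dd_key = "disease_duration_pos" if affected else "disease_duration_neg"
    ledd_key = "ledd_pos" if affected else "ledd_neg"
    u4_key = "updrs4_dys" if group == "dys_pos" else "updrs4_other"
    covariates = {
        "age": float(np.clip(rng.normal(*p["age"]), 40, 90)),
        "disease_duration": float(max(rng.normal(*p[dd_key]), 1.0)),
        "updrs3": float(np.clip(rng.normal(*p["updrs3"]) + (5 if affected else 0), 5, 80)),
        "updrs4": float(max(rng.normal(*p[u4_key]), 0.0)),
        "moca": float(np.clip(rng.normal(*p["moca"]), 10, 30)),
        "ledd": float(max(rng.normal(*p[ledd_key]), 100.0)),
    }
    hy_choices = np.array([1.5, 2.0, 2.5, 3.0])
    hy_p = (np.array([0.1, 0.3, 0.4, 0.2]) if affected
            else np.array([0.3, 0.4, 0.2, 0.1]))
    return SubjectProfile(
        subject_id=subject_id,
        leg_length=float(np.clip(rng.normal(*p["leg_length"]), 0.62, 1.18)),
        age=covariates["age"],
        hy_stage=float(rng.choice(hy_choices, p=hy_p)),
        has_dys=group == "dys_pos",
        has_fog=group == "fog_pos",
        dys_rate=float(rng.uniform(*p["dys_rate_range"])) if group == "dys_pos" else 0.0,
        fog_rate=float(rng.uniform(*p["fog_rate_range"])) if group == "fog_pos" else 0.0,
        gait_cadence=float(np.clip(rng.normal(104 if group == "fog_pos" else 112, 7),
                                   62, 138)),
        gait_speed_scale=float(np.clip(
            rng.normal(0.85 if group == "fog_pos" else 1.0, 0.08), 0.6, 1.3)),
        covariates=covariates,
    )


def simulate_cohort(spec: CohortSpec):
    """Simulate a full cohort.

    Returns ``(recordings, covariates)`` where ``recordings`` is a list of
    :class:`LabeledRecording` (``days_per_subject`` entries per subject)
    and ``covariates`` a one-row-per-subject DataFrame including the group
    flags and the generator's own episode rates.
    """
    params = dict(_DEFAULT_GROUP_PARAMS)
    params.update(spec.group_params)
    rng = np.random.default_rng(spec.seed)
    groups = (["dys_pos"] * spec.n_dys_pos + ["dys_neg"] * spec.n_dys_neg
              + ["fog_pos"] * spec.n_fog_pos + ["fog_neg"] * spec.n_fog_neg)
    profiles = [_draw_profile(rng, f"S{i:03d}", g, params)
                for i, g in enumerate(groups)]

    recordings: list[LabeledRecording] = []
    rows = []
    duration_s = spec.hours_per_day * 3600.0
    for prof, group in zip(profiles, groups):
        for day in range(spec.days_per_subject):
            day_seed = int(rng.integers(2 ** 31))
            rec = simulate_subject(prof, duration_s, day_seed)
            rec.day = day
            recordings.append(rec)
        rows.append({
            "subject_id": prof.subject_id, "group": group,
            "has_dys": prof.has_dys, "has_fog": prof.has_fog,
            "leg_length": prof.leg_length, "hy_stage": prof.hy_stage,
            "dys_rate": prof.dys_rate, "fog_rate": prof.fog_rate,
            "gait_cadence": prof.gait_cadence,
            **prof.covariates,
        })
    return recordings, pd.DataFrame(rows)
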