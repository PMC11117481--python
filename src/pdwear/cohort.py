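"""Subject-level statistical layer.

Covers the study-style analysis on top of the detectors: per-subject
summaries of the primary outcomes (dyskinesia periods/time, FOG
episodes/time, both as absolute and percent measures), 0-1 min-max feature
normalization, leave-one-subject-out (LOSO) logistic-regression
classification with sensitivity/specificity/PPV/NPV/accuracy/AUC,
empirical CDFs, Mann-Whitney U with Cohen's d, Spearman correlation, and
equal-weight greedy covariate matching with a balance table.

Normalization bounds inside LOSO are computed within each training fold
and the held-out subject is clipped to [0, 1], so no information leaks
from the test subject into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from statsmodels.distributions.empirical_distribution import ECDF


@dataclass
class SubjectSummary:
    """Primary and secondary outcomes of one subject over all monitored days."""

    subject_id: str
    n_dys_periods: int = 0
    time_with_dys_s: float = 0.0
    pct_time_dys: float = 0.0
    n_fog_episodes: int = 0
    time_with_fog_s: float = 0.0
    pct_time_fog: float = np.nan
    gait_means: dict = field(default_factory=dict)
    gait_variances: dict = field(default_factory=dict)
    walking_time_s: float = 0.0
    monitored_time_s: float = 0.0
    monitoring_days: int = 0


def summarize_subject(subject_id: str, day_results: list) -> SubjectSummary:
    """Combine per-day detector outputs into one subject summary.

    ``day_results`` items need attributes ``dys_spans``, ``fog_episodes``,
    ``n_dys_periods``, ``gait_minutes`` (DataFrame), ``walking_time_s``
    and ``duration_s`` (see :mod:`pdwear.pipeline`).  Gait means/variances
    are computed over retained minutes only.
    """
    total_dys = sum(sum(e - s for s, e in d.dys_spans) for d in day_results)
    total_fog = sum(sum(e - s for s, e in d.fog_episodes) for d in day_results)
    walking = sum(d.walking_time_s for d in day_results)
    monitored = sum(d.duration_s for d in day_results)
    n_fog = sum(len(d.fog_episodes) for d in day_results)
    n_dys = sum(d.n_dys_periods for d in day_results)

    minutes = [d.gait_minutes for d in day_results
               if d.gait_minutes is not None and len(d.gait_minutes)]
    gait_means: dict = {}
    gait_vars: dict = {}
    if minutes:
        allm = pd.concat(minutes, ignore_index=True)
        kept = allm[allm["retained"]]
        for p in ("step_length", "stride_speed", "fluidity"):
            gait_means[p] = float(kept[f"{p}_mean"].mean()) if len(kept) else np.nan
            gait_vars[p] = float(kept[f"{p}_var"].mean()) if len(kept) else np.nan
        gait_means["cadence"] = float(kept["cadence_mean"].mean()) if len(kept) else np.nan

    return SubjectSummary(
        subject_id=subject_id,
        n_dys_periods=int(n_dys),
        time_with_dys_s=float(total_dys),
        pct_time_dys=100.0 * total_dys / monitored if monitored > 0 else 0.0,
        n_fog_episodes=int(n_fog),
        time_with_fog_s=float(total_fog),
        pct_time_fog=(100.0 * total_fog / walking if walking > 0
                      else (np.nan if total_fog > 0 else 0.0)),
        gait_means=gait_means,
        gait_variances=gait_vars,
        walking_time_s=float(walking),
        monitored_time_s=float(monitored),
        monitoring_days=len(day_results),
    )


def summaries_table(summaries: list[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "n_dys_periods": s.n_dys_periods,
            "time_with_dys_s": s.time_with_dys_s,
            "pct_time_dys": s.pct_time_dys,
            "n_fog_episodes": s.n_fog_episodes,
            "time_with_fog_s": s.time_with_fog_s,
            "pct_time_fog": s.pct_time_fog,
            "walking_time_s": s.walking_time_s,
            "monitoring_days": s.monitoring_days,
        }
        row.update({f"{k}_mean": v for k, v in s.gait_means.items()})
        row.update({f"{k}_var": v for k, v in s.gait_variances.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# --- normalization ---------------------------------------------------------

def normalize_features(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max normalize each column to [0, 1].

    Returns the normalized frame and a bounds table (fmin, fmax per
    column).  A constant column maps to 0.
    """
    if len(df) < 2:
        raise ValueError("need at least 2 subjects to normalize")
    fmin, fmax = df.min(), df.max()
    span = (fmax - fmin).replace(0, np.nan)
    out = (df - fmin) / span
    out = out.fillna(0.0)
    bounds = pd.DataFrame({"fmin": fmin, "fmax": fmax})
    return out, bounds


# --- LOSO classification ---------------------------------------------------

def fit_logistic(Z: np.ndarray, y: np.ndarray, C: float = 1.0,
                 balanced: bool = True, max_iter: int = 60,
                 tol: float = 1e-10) -> np.ndarray:
    """Ridge-penalized logistic regression by Newton/IRLS.

    Minimizes ``||w||^2 / (2C) + sum_i s_i * logloss_i`` (intercept
    unpenalized), the same objective as sklearn's LogisticRegression with
    ``class_weight='balanced'``; implemented directly because the
    leave-pair-out AUC below needs tens of thousands of tiny fits.
    Returns ``[w..., intercept]``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = Z.shape
    X1 = np.hstack([Z, np.ones((n, 1))])
    if balanced:
        n_pos = max(y.sum(), 1.0)
        s = np.where(y == 1, n / (2 * n_pos), n / (2 * (n - n_pos)))
    else:
        s = np.ones(n)
    beta = np.zeros(d + 1)
    P = np.eye(d + 1) / C
    P[-1, -1] = 0.0
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X1 @ beta)))
        grad = X1.T @ (s * (p - y)) + P @ beta
        w = np.maximum(s * p * (1 - p), 1e-12)
        H = (X1 * w[:, None]).T @ X1 + P
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.abs(step).max() < tol:
            break
    return beta


def _minmax_fold(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fmin, fmax = Xtr.min(axis=0), Xtr.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    Ztr = np.where(fmax > fmin, (Xtr - fmin) / span, 0.0)
    Zte = np.clip(np.where(fmax > fmin, (Xte - fmin) / span, 0.0), 0.0, 1.0)
    return Ztr, Zte


def loso_pairwise_auc(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    """Leave-pair-out AUC: unbiased cross-validated concordance.

    For every (positive, negative) subject pair, a model is fitted on the
    other n-2 subjects and the two held-out scores are compared.  Pooling
    leave-one-out scores instead would compare scores from *different*
    models, which is pessimistically biased by O(1/n) on label-shuffled
    data; scoring each pair with one common model removes that artifact.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    wins = 0.0
    for i in pos:
        for j in neg:
            tr = np.ones(len(y), dtype=bool)
            tr[[i, j]] = False
            if len(np.unique(y[tr])) < 2:
                wins += 0.5
                continue
            Ztr, Zte = _minmax_fold(X[tr], X[[i, j]])
            beta = fit_logistic(Ztr, y[tr], C=C)
            si, sj = Zte @ beta[:-1] + beta[-1]
            wins += 1.0 if si > sj else (0.5 if si == sj else 0.0)
    return wins / (len(pos) * len(neg))

@dataclass
class ClassificationReport:
    """LOSO metrics.  ``auc`` is the leave-pair-out estimate (unbiased
    under label exchange); ``pooled_auc`` is the concordance of the pooled
    per-fold probabilities, kept for reference."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float
    probabilities: np.ndarray
    y_true: np.ndarray
    confusion: dict
    pooled_auc: float = np.nan
    skipped_folds: list = field(default_factory=list)
    fold_coefs: list = field(default_factory=list)

    def summary(self) -> pd.Series:
        return pd.Series({
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "accuracy": self.accuracy, "auc": self.auc,
        })


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else np.nan


def loso_logistic(features: pd.DataFrame, labels: np.ndarray, C: float = 1.0,
                  threshold: float = 0.5) -> ClassificationReport:
    """Leave-one-subject-out logistic regression.

    Each fold min-max-normalizes features on its training subjects only,
    clips the held-out subject into [0, 1], fits a (weakly ridged)
    logistic regression and records the held-out probability.  Metrics are
    computed on the pooled probabilities at the given threshold.  AUC is
    estimated leave-pair-out (see :func:`loso_pairwise_auc`); the plain
    concordance of the pooled probabilities is kept as ``pooled_auc``.

    Class weights are balanced within each fold: holding one subject out
    tilts the training prior against that subject's class, which would
    push the pooled probabilities far below chance level on
    label-shuffled data (a known leave-one-out artifact).
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    probs = np.full(n, np.nan)
    skipped = []
    fold_coefs: list = [None] * n
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            warnings.warn(f"fold {i}: single-class training set, skipped")
            skipped.append(i)
            continue
        Ztr, Zte = _minmax_fold(X[tr], X[i][None, :])
        beta = fit_logistic(Ztr, ytr, C=C)
        fold_coefs[i] = beta
        probs[i] = 1.0 / (1.0 + np.exp(-(Zte[0] @ beta[:-1] + beta[-1])))

    ok = np.isfinite(probs)
    yv, pv = y[ok], probs[ok]
    pred = (pv >= threshold).astype(int)
    tp = int(((pred == 1) & (yv == 1)).sum())
    tn = int(((pred == 0) & (yv == 0)).sum())
    fp = int(((pred == 1) & (yv == 0)).sum())
    fn = int(((pred == 0) & (yv == 1)).sum())
    pooled = roc_auc_score(yv, pv) if len(np.unique(yv)) == 2 else np.nan
    return ClassificationReport(
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        auc=float(loso_pairwise_auc(X, y, C=C)),
        probabilities=probs, y_true=y,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        pooled_auc=float(pooled),
        skipped_folds=skipped,
        fold_coefs=fold_coefs,
    )


# --- univariate statistics -------------------------------------------------

def empirical_cdf(values) -> ECDF:
    """Right-continuous empirical CDF, P(X <= x); CDF(max) = 1."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empirical CDF of an empty sample")
    return ECDF(values)


def mann_whitney_cohen_d(group_a, group_b) -> tuple[float, float, float]:
    """Mann-Whitney U test plus Cohen's d effect size.

    U is reported as min(U_a, U_b) (midrank ties).  The p-value is exact
    when n_a*n_b <= 400 and there are no ties, otherwise a tie-corrected
    normal approximation.  Cohen's d uses the raw means and the pooled
    standard deviation; it is NaN when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(min(res.statistic, len(a) * len(b) - res.statistic))
    na, nb = len(a), len(b)
    if na + nb > 2:
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2)) if min(na, nb) > 1 else 0.0
    else:
        pooled = 0.0
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.nan
    return u, float(res.pvalue), float(d)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks, t-approximate p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# --- covariate matching ----------------------------------------------------

@dataclass
class MatchedCohort:
    pairs: list
    covariates: list
    balance: pd.DataFrame
    unmatched_cases: list = field(default_factory=list)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2) if min(len(a), len(b)) > 1 else 0.0
    return (a.mean() - b.mean()) / sd if sd > 0 else 0.0


def match_subgroups(cases: pd.DataFrame, controls: pd.DataFrame,
                    covariate_names: list[str]) -> MatchedCohort:
    """Pair each case with its most similar control, equal covariate weight.

    Distance is Euclidean on z-scored covariates (the z-scoring gives every
    covariate equal weight).  Greedy nearest-neighbour without replacement;
    cases are processed hardest-first (largest minimum distance), so
    easy-to-match cases cannot steal the only viable control of a hard
    one.  Surplus cases are listed as unmatched.  Both frames need a
    ``subject_id`` column.
    """
    for name in covariate_names:
        if cases[name].isna().any() or controls[name].isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
    pooled = pd.concat([cases[covariate_names], controls[covariate_names]])
    mu, sd = pooled.mean(), pooled.std(ddof=1).replace(0, 1.0)
    zc = ((cases[covariate_names] - mu) / sd).to_numpy()
    zk = ((controls[covariate_names] - mu) / sd).to_numpy()
    dist = cdist(zc, zk)

    order = np.argsort(-dist.min(axis=1), kind="stable")
    used = np.zeros(len(controls), dtype=bool)
    pairs: list[tuple[str, str]] = []
    unmatched = []
    pair_rows = []
    for ci in order:
        avail = np.flatnonzero(~used)
        if len(avail) == 0:
            unmatched.append(cases["subject_id"].iloc[ci])
            continue
        kj = avail[int(np.argmin(dist[ci, avail]))]
        used[kj] = True
        pairs.append((cases["subject_id"].iloc[ci], controls["subject_id"].iloc[kj]))
        pair_rows.append((ci, kj))

    rows = []
    for name in covariate_names:
        a_all = cases[name].to_numpy(dtype=float)
        b_all = controls[name].to_numpy(dtype=float)
        a_m = cases[name].to_numpy(dtype=float)[[i for i, _ in pair_rows]]
        b_m = controls[name].to_numpy(dtype=float)[[j for _, j in pair_rows]]
        rows.append({"covariate": name,
                     "smd_before": _smd(a_all, b_all),
                     "smd_after": _smd(a_m, b_m) if len(a_m) > 1 else 0.0})
    return MatchedCohort(pairs=pairs, covariates=list(covariate_names),
                         balance=pd.DataFrame(rows), unmatched_cases=unmatched)
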