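"""Validation metrics for dialysis-initiation scores.

Confusion statistics, rank-based ROC AUC with stratified-bootstrap
confidence intervals and a paired-bootstrap AUC-difference test,
Kaplan-Meier estimation and the two-group log-rank test (via lifelines),
mortality per 100 patient-years, and a nine-variable logistic comparator
with a Hosmer-Lemeshow calibration statistic (via statsmodels).

Score orientation convention: throughout this module, *higher* score means
higher predicted risk of the event (death within 36 months), and AUC is the
probability that a randomly chosen case out-scores a randomly chosen
control (ties count half). The scoring equation itself runs the other way
(higher Y = better prognosis), so use ``-Y``, or a negated eGFR via
:func:`egfr_risk_scores`, when feeding scores here; nothing is auto-flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "ConfusionMetrics",
    "RocResult",
    "AucComparison",
    "KmCurve",
    "LogrankResult",
    "LogisticComparatorResult",
    "confusion_metrics",
    "roc_auc",
    "bootstrap_auc_ci",
    "compare_auc_bootstrap",
    "km_estimate",
    "logrank_test",
    "mortality_rate_per100py",
    "hosmer_lemeshow",
    "fit_logistic_comparator",
    "egfr_risk_scores",
    "LOGISTIC_VARIABLES",
]


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int
    flags: list[str] = field(default_factory=list)


def confusion_metrics(predicted, truth) -> ConfusionMetrics:
    """Standard 2x2 sensitivity/specificity/diagnostic accuracy.

    ``predicted`` and ``truth`` are aligned 0/1 vectors (1 = event). When
    the truth contains a single class the undefined rate is NaN and a flag
    is recorded instead of raising.
    """
    p = np.asarray(predicted, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted and truth must be aligned, non-empty vectors")
    tp = int(np.sum((p == 1) & (t == 1)))
    fn = int(np.sum((p == 0) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    flags = []
    if tp + fn == 0:
        flags.append("no positives in truth: sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        flags.append("no negatives in truth: specificity undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return ConfusionMetrics(sens, spec, (tp + tn) / p.size, tp, fn, tn, fp, flags)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation, ties at half credit.

    ``labels`` are 0/1 with 1 the event; higher scores must mean higher
    predicted event risk (see the module docstring — orientation is the
    caller's responsibility and is never flipped here).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """Percentile 95% CI for the AUC from stratified case resampling.

    Cases and controls are resampled separately (so every replicate retains
    both classes) and the AUC recomputed ``n_boot`` times.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    point = roc_auc(s, y)
    rng = np.random.default_rng(seed)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    resampled = np.concatenate(
        [pos[rng.integers(0, n1, (n_boot, n1))], neg[rng.integers(0, n0, (n_boot, n0))]],
        axis=1,
    )
    boots = _auc_rows(resampled, n1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(point, float(lo), float(hi), n_boot, seed)


def _auc_rows(scores: np.ndarray, n1: int) -> np.ndarray:
    """Row-wise rank AUC for a matrix whose first n1 columns are the cases."""
    ranks = rankdata(scores, axis=1)
    n0 = scores.shape[1] - n1
    return (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    n_boot: int
    seed: int


def compare_auc_bootstrap(
    scores_a, scores_b, labels, n_boot: int = 2000, seed: int = 0
) -> AucComparison:
    """Two-sided paired-bootstrap test of an AUC difference.

    Both score vectors are evaluated against the same labels; each
    replicate resamples patients (stratified by outcome, same draw for both
    models) and the two-sided p-value is read off the bootstrap distribution
    of the difference against zero.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must be aligned")
    auc_a, auc_b = roc_auc(a, y), roc_auc(b, y)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n1, n0 = len(idx_pos), len(idx_neg)
    take = np.concatenate(
        [
            idx_pos[rng.integers(0, n1, (n_boot, n1))],
            idx_neg[rng.integers(0, n0, (n_boot, n0))],
        ],
        axis=1,
    )
    deltas = _auc_rows(a[take], n1) - _auc_rows(b[take], n1)
    p_le = (np.sum(deltas <= 0) + 1) / (n_boot + 1)
    p_ge = (np.sum(deltas >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return AucComparison(auc_a, auc_b, auc_a - auc_b, float(p), n_boot, seed)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class KmCurve:
    """Product-limit survival curve on the observed event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate (censoring = event indicator 0)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("follow-up times must be non-negative")
    kmf = KaplanMeierFitter().fit(t, e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    return KmCurve(grid, surv, at_risk)


@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    flags: list[str] = field(default_factory=list)


def logrank_test(times_1, events_1, times_2, events_2) -> LogrankResult:
    """Two-group log-rank test; symmetric in the group labels."""
    t1, e1 = np.asarray(times_1, float), np.asarray(events_1, int)
    t2, e2 = np.asarray(times_2, float), np.asarray(events_2, int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        return LogrankResult(0.0, 1.0, ["no events in either group"])
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def mortality_rate_per100py(times, events, cap_months: float = 36.0) -> float:
    """Deaths per 100 patient-years; follow-up capped at ``cap_months``."""
    t = np.minimum(np.asarray(times, dtype=float), cap_months)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("follow-up times must be positive")
    person_years = t.sum() / 12.0
    if person_years == 0:
        raise ValueError("zero total follow-up")
    return float(100.0 * e.sum() / person_years)


# ---------------------------------------------------------------------------
# Logistic comparator + calibration
# ---------------------------------------------------------------------------

#: The nine covariates of the final score, as used by the logistic comparator.
LOGISTIC_VARIABLES = [
    "scr_mgdl",
    "age",
    "alb_gdl",
    "hb_gdl",
    "bun_mgdl",
    "phosphate_mmoll",
    "heart_failure",
    "diabetes",
    "female",
]


def hosmer_lemeshow(y, probs, n_groups: int = 10) -> tuple[float, float, int]:
    """Hosmer-Lemeshow goodness-of-fit: chi2 statistic, p-value and df.

    Observations are grouped into ``n_groups`` risk deciles of the predicted
    probability; df = groups - 2.
    """
    y = np.asarray(y, dtype=float)
    probs = np.asarray(probs, dtype=float)
    groups = pd.qcut(probs, q=n_groups, labels=False, duplicates="drop")
    stat = 0.0
    n_eff = 0
    for g in np.unique(groups):
        mask = groups == g
        n_g = int(mask.sum())
        obs = y[mask].sum()
        exp = probs[mask].sum()
        denom = exp * (1.0 - exp / n_g)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
        n_eff += 1
    df = max(n_eff - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df)), df


@dataclass
class LogisticComparatorResult:
    table: pd.DataFrame  # coefficient, p, odds ratio with 95% CI per variable
    calibration_stat: float
    calibration_p: float
    calibration_df: int
    predicted_risk: np.ndarray = field(repr=False)
    flags: list[str] = field(default_factory=list)


def fit_logistic_comparator(
    cohort, variables: list[str] | None = None, outcome=None
) -> LogisticComparatorResult:
    """Maximum-likelihood logistic regression of 36-month poor survival.

    Covariates default to the nine score variables. Exponentiated
    coefficients are reported as odds ratios with Wald 95% CIs, and
    calibration as the 10-decile Hosmer-Lemeshow statistic. Constant
    covariates are dropped with a flag; (quasi-)separation is flagged
    rather than raising.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    variables = list(variables or LOGISTIC_VARIABLES)
    if outcome is None:
        from .cohort import good_survival_outcome

        outcome = 1 - good_survival_outcome(df)  # 1 = poor survival
    y = np.asarray(outcome, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")

    flags = []
    kept = []
    for v in variables:
        if df[v].nunique() < 2:
            flags.append(f"constant covariate dropped: {v}")
        else:
            kept.append(v)
    X = sm.add_constant(df[kept].astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely here
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        flags.append("maximum-likelihood fit did not converge")
    if np.any(np.abs(fit.params.to_numpy()) > 20) or np.any(fit.bse.to_numpy() > 100):
        flags.append("possible separation: extreme coefficient or standard error")

    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "coefficient": fit.params,
            "p_value": fit.pvalues,
            "odds_ratio": np.exp(fit.params),
            "or_ci_low": np.exp(ci[0]),
            "or_ci_high": np.exp(ci[1]),
        }
    )
    probs = np.asarray(fit.predict(X), dtype=float)
    hl_stat, hl_p, hl_df = hosmer_lemeshow(y, probs)
    return LogisticComparatorResult(table, hl_stat, hl_p, hl_df, probs, flags)


def egfr_risk_scores(df: pd.DataFrame, equation: str = "cmdrd") -> np.ndarray:
    """Negated eGFR as a mortality-risk score (lower filtration = higher risk),
    so AUC orientation matches the other models in this module."""
    from .egfr import egfr_ckdepi, egfr_cmdrd

    df = df.df if hasattr(df, "df") else df
    female = df["female"].to_numpy(dtype=bool)
    if equation == "cmdrd":
        e = egfr_cmdrd(
            df["scr_mgdl"].to_numpy(float),
            df["age"].to_numpy(float),
            df["bun_mgdl"].to_numpy(float),
            df["alb_gdl"].to_numpy(float),
            female=female,
        )
    elif equation == "ckdepi":
        e = egfr_ckdepi(df["scr_mgdl"].to_numpy(float), df["age"].to_numpy(float), female)
    else:
        raise ValueError(f"unknown eGFR equation {equation!r}")
    return -np.asarray(e, dtype=float)
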