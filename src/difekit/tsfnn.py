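"""Fitting the score's parameters by particle swarm optimisation (PSO).

The printed closed form of the Takagi-Sugeno-type fuzzy network (the score
``Y`` with its sigmoid weighting multiplier ``W``, see :mod:`difekit.dife`)
is fitted directly: a particle is the 19 equation parameters plus two link
parameters ``(c, log s)``, and the swarm minimises the cross-entropy between
``sigmoid((Y - c)/s)`` and the binary 36-month outcome (1 = survived >= 36
months, the good-survival group). A squared-error loss on the same link is
available as an alternative.

Ten-fold cross-validation is used as early stopping: one PSO run per
training fold tracks the held-out loss of the running global best, the
iteration budget minimising the mean held-out loss is selected, and the
final swarm is refit on all data with that budget.

Also here: outlier removal ahead of fitting, and candidate-threshold
selection producing the sensitivity/specificity/accuracy/mortality table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .cohort import CONTINUOUS_VARS, Cohort, good_survival_outcome
from .dife import PARAM_NAMES, DifeParameters, dife_scores
from .evaluation import mortality_rate_per100py

__all__ = [
    "PsoConfig",
    "ThresholdReport",
    "DifeModel",
    "remove_outliers",
    "fit_dife",
    "select_threshold",
    "DEFAULT_THRESHOLD_GRID",
]

#: Candidate decision thresholds examined during development.
DEFAULT_THRESHOLD_GRID = (29.0, 30.0, 31.0, 32.0, 33.0)

_N_PARAMS = len(PARAM_NAMES)  # 19 equation parameters
_EXPONENTS = {"p3", "p4", "p5", "p6", "p7", "p8"}


def _default_bounds() -> np.ndarray:
    """Per-dimension [low, high] for the 19 parameters plus (c, log s).

    Consequent and gate parameters live in [-50, 50]; the six exponents are
    restricted to [-5, 5] to keep the power-law terms numerically stable.
    """
    lows, highs = [], []
    for name in PARAM_NAMES:
        if name in _EXPONENTS:
            lows.append(-5.0), highs.append(5.0)
        else:
            lows.append(-50.0), highs.append(50.0)
    lows += [-200.0, -3.0]  # c, log s
    highs += [200.0, 5.0]
    return np.array([lows, highs]).T


@dataclass
class PsoConfig:
    """Swarm hyper-parameters and loss/CV choices for equation fitting."""

    swarm_size: int = 60
    inertia: float = 0.72
    cognitive_coef: float = 1.49
    social_coef: float = 1.49
    max_iterations: int = 500
    bounds: np.ndarray | None = None
    loss: str = "cross_entropy"
    n_folds: int = 10
    cv_early_stop: bool = True
    anchor: tuple[float, float] | None = (30.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if min(self.inertia, self.cognitive_coef, self.social_coef) < 0:
            raise ValueError("PSO coefficients must be >= 0")
        if self.loss not in ("cross_entropy", "mse"):
            raise ValueError("loss must be 'cross_entropy' or 'mse'")
        b = self.bounds if self.bounds is not None else _default_bounds()
        b = np.asarray(b, dtype=float)
        if b.shape != (_N_PARAMS + 2, 2) or not np.all(np.isfinite(b)) or np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("bounds must be a finite (n_params + 2, 2) array with low < high")
        self.bounds = b

    @classmethod
    def from_json(cls, path: str | Path) -> "PsoConfig":
        payload = json.loads(Path(path).read_text())
        if "bounds" in payload and payload["bounds"] is not None:
            payload["bounds"] = np.asarray(payload["bounds"], dtype=float)
        return cls(**payload)


# ---------------------------------------------------------------------------
# Outlier removal
# ---------------------------------------------------------------------------


def remove_outliers(
    cohort: Cohort, rule: str = "zscore", cutoff: float = 4.0
) -> tuple[Cohort, list[str]]:
    """Drop records with any extreme continuous covariate; log removed ids.

    ``zscore`` flags |x - mean| / SD > cutoff (default 4); ``iqr`` flags
    values outside [Q1 - cutoff*IQR, Q3 + cutoff*IQR].
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if rule not in ("zscore", "iqr"):
        raise ValueError(f"unknown outlier rule {rule!r}")
    df = cohort.df
    cols = [c for c in CONTINUOUS_VARS if c in df.columns]
    flagged = np.zeros(len(df), dtype=bool)
    for col in cols:
        x = df[col].to_numpy(dtype=float)
        if rule == "zscore":
            sd = x.std()
            if sd == 0:
                continue
            flagged |= np.abs(x - x.mean()) / sd > cutoff
        else:
            q1, q3 = np.percentile(x, [25, 75])
            iqr = q3 - q1
            flagged |= (x < q1 - cutoff * iqr) | (x > q3 + cutoff * iqr)
    removed = df.loc[flagged, "patient_id"].tolist()
    out = Cohort(df.loc[~flagged].reset_index(drop=True), label=cohort.label)
    return out, removed


# ---------------------------------------------------------------------------
# Vectorised score evaluation over a swarm
# ---------------------------------------------------------------------------


def _design_arrays(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "scr": df["scr_mgdl"].to_numpy(dtype=float),
        "lnage": np.log(df["age"].to_numpy(dtype=float)),
        "alb": df["alb_gdl"].to_numpy(dtype=float),
        "hb": df["hb_gdl"].to_numpy(dtype=float),
        "lnbun": np.log(df["bun_mgdl"].to_numpy(dtype=float)),
        "phos": df["phosphate_mmoll"].to_numpy(dtype=float),
        "e_hf": np.exp(df["heart_failure"].to_numpy(dtype=float)),
        "e_dm": np.exp(df["diabetes"].to_numpy(dtype=float)),
        "e_fem": np.exp(df["female"].to_numpy(dtype=float)),
    }


def _swarm_scores(theta: np.ndarray, arr: dict[str, np.ndarray]) -> np.ndarray:
    """Score matrix (particles x patients) for equation-parameter block theta.

    Extreme particles can overflow the power product to inf; those particles
    simply receive a large loss, so overflow is silenced rather than raised.
    """
    p = {name: theta[:, i, None] for i, name in enumerate(PARAM_NAMES)}
    eta = (
        p["t1"]
        + p["t2"] * arr["scr"]
        + p["t3"] * arr["alb"]
        + p["t4"] * arr["hb"]
        + p["t5"] * arr["lnbun"]
        + p["t6"] * arr["phos"]
    )
    w = expit(-eta)
    with np.errstate(over="ignore", invalid="ignore"):
        product = (
            p["p2"]
            * np.power(arr["scr"], p["p3"])
            * np.power(arr["lnage"], p["p4"])
            * np.power(arr["alb"], p["p5"])
            * np.power(arr["hb"], p["p6"])
            * np.power(arr["lnbun"], p["p7"])
            * np.power(arr["phos"], p["p8"])
        )
        inner = (
            product
            + p["p9"] * arr["e_hf"]
            + p["p10"] * arr["e_dm"]
            + p["p11"] * arr["e_fem"]
            + p["p16"]
        )
        return p["p15"] + p["p1"] * w * inner


def _swarm_loss(particles: np.ndarray, arr: dict[str, np.ndarray], y: np.ndarray, loss: str) -> np.ndarray:
    """Loss per particle; particles carry [19 params, c, log s]."""
    scores = _swarm_scores(particles[:, :_N_PARAMS], arr)
    c = particles[:, _N_PARAMS, None]
    s = np.exp(particles[:, _N_PARAMS + 1, None])
    with np.errstate(invalid="ignore"):
        prob_good = expit((scores - c) / s)
        if loss == "mse":
            out = ((prob_good - y) ** 2).mean(axis=1)
        else:
            prob_good = np.clip(prob_good, 1e-12, 1 - 1e-12)
            out = -(y * np.log(prob_good) + (1 - y) * np.log1p(-prob_good)).mean(axis=1)
    # particles whose scores degenerate to NaN are simply non-competitive
    return np.where(np.isfinite(out), out, np.inf)


def _calibrate_link(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid((Y - c)/s) to the outcome by 1-D logistic regression."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(max_iter=1000).fit(scores[:, None], y)
    a, b = float(lr.coef_[0, 0]), float(lr.intercept_[0])
    if a <= 1e-9:
        return float(np.median(scores)), 1.0
    return -b / a, 1.0 / a


def _warm_particle(arr: dict[str, np.ndarray], y: np.ndarray) -> np.ndarray | None:
    """Equation parameters linearised from a logistic fit on log-covariates.

    The product term is exp-linear in (ln Scr, ln ln age, ln Alb, ln Hb,
    ln ln BUN, ln P): with exponents eps*beta and weight 1/eps it equals
    (1/eps) * exp(eps * beta'u) ~ const + beta'u, so a maximum-likelihood
    logistic solution maps onto a nearby point of the equation's parameter
    space. Gives the swarm one particle that already carries the signal.
    """
    from sklearn.linear_model import LogisticRegression

    F = np.column_stack(
        [
            np.log(arr["scr"]),
            np.log(arr["lnage"]),
            np.log(arr["alb"]),
            np.log(arr["hb"]),
            np.log(arr["lnbun"]),
            np.log(arr["phos"]),
            arr["e_hf"],
            arr["e_dm"],
            arr["e_fem"],
        ]
    )
    try:
        lr = LogisticRegression(max_iter=2000, C=100.0).fit(F, y)
    except Exception:
        return None
    beta = lr.coef_[0]
    eps = 0.5
    particle = np.zeros(_N_PARAMS + 2)
    idx = {n: i for i, n in enumerate(PARAM_NAMES)}
    particle[idx["p1"]] = 2.0
    particle[idx["p2"]] = 1.0 / eps
    for j, name in enumerate(("p3", "p4", "p5", "p6", "p7", "p8")):
        particle[idx[name]] = eps * beta[j]
    particle[idx["p9"]], particle[idx["p10"]], particle[idx["p11"]] = beta[6:9]
    scores = _swarm_scores(particle[None, :_N_PARAMS], arr)[0]
    if not np.all(np.isfinite(scores)):
        return None
    c, s = _calibrate_link(scores, y)
    particle[_N_PARAMS] = c
    particle[_N_PARAMS + 1] = np.log(max(s, 1e-6))
    return particle


def _run_pso(
    arr: dict[str, np.ndarray],
    y: np.ndarray,
    config: PsoConfig,
    seed: int,
    n_iterations: int,
    val: tuple[dict[str, np.ndarray], np.ndarray] | None = None,
):
    """One swarm run. Returns (best_particle, train_trace, val_trace)."""
    rng = np.random.default_rng(seed)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    span = hi - lo
    P = config.swarm_size
    # random particles start in a tight sub-box around zero: most of the full
    # box saturates the power terms and carries no gradient for the swarm
    init_lo = np.maximum(lo, -3.0)
    init_hi = np.minimum(hi, 3.0)
    X = init_lo + rng.random((P, _N_PARAMS + 2)) * (init_hi - init_lo)
    # one particle at the constant-score baseline: Y = 0,
    # sigmoid((0 - c)/s) = outcome base rate
    base = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    X[0] = 0.0
    X[0, _N_PARAMS] = float(np.clip(-logit(base), lo[_N_PARAMS], hi[_N_PARAMS]))
    X[0, _N_PARAMS + 1] = 0.0
    # one particle warm-started from a linearised logistic fit
    warm = _warm_particle(arr, y)
    if warm is not None:
        X[1] = np.clip(warm, lo, hi)
    V = np.zeros_like(X)
    vmax = 0.2 * span

    pbest = X.copy()
    pbest_loss = _swarm_loss(X, arr, y, config.loss)
    g = int(np.argmin(pbest_loss))
    gbest, gbest_loss = pbest[g].copy(), float(pbest_loss[g])
    train_trace, val_trace = [], []

    for _ in range(n_iterations):
        r1 = rng.random((P, _N_PARAMS + 2))
        r2 = rng.random((P, _N_PARAMS + 2))
        V = (
            config.inertia * V
            + config.cognitive_coef * r1 * (pbest - X)
            + config.social_coef * r2 * (gbest - X)
        )
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, lo, hi)
        loss = _swarm_loss(X, arr, y, config.loss)
        improved = loss < pbest_loss
        pbest[improved] = X[improved]
        pbest_loss[improved] = loss[improved]
        g = int(np.argmin(pbest_loss))
        if pbest_loss[g] < gbest_loss:
            gbest, gbest_loss = pbest[g].copy(), float(pbest_loss[g])
        train_trace.append(gbest_loss)
        if val is not None:
            val_trace.append(float(_swarm_loss(gbest[None, :], val[0], val[1], config.loss)[0]))
    return gbest, np.array(train_trace), np.array(val_trace)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class DifeModel(BaseEstimator):
    """Scoring-equation estimator fitted by particle swarm optimisation.

    ``fit`` takes a cohort table (canonical column names) and the binary
    good-survival outcome (1 = survived >= 36 months). ``decision_function``
    returns the score Y; ``predict_proba`` the linked probability of good
    survival; ``predict`` thresholds Y (default: the conventional threshold
    of 30 is *not* assumed — pass one, or the fitted link's midpoint ``c_``
    is used).

    Fitted attributes: ``params_`` (:class:`DifeParameters`), link ``c_``
    and ``s_``, ``loss_trace_`` (global-best training loss per iteration,
    non-increasing), ``cv_val_traces_`` and ``n_iter_``.
    """

    def __init__(self, config: PsoConfig | None = None):
        self.config = config

    def fit(self, df: pd.DataFrame, y=None):
        df = df.df if hasattr(df, "df") else df
        config = self.config or PsoConfig()
        if y is None:
            y = good_survival_outcome(df)
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ValueError("outcome must contain both good and poor survival")
        arr = _design_arrays(df)

        n_iter = config.max_iterations
        self.cv_val_traces_ = None
        if config.cv_early_stop:
            splitter = StratifiedKFold(
                n_splits=config.n_folds, shuffle=True, random_state=config.seed
            )
            traces = []
            for k, (tr, te) in enumerate(splitter.split(y, y)):
                arr_tr = {name: a[tr] for name, a in arr.items()}
                arr_te = {name: a[te] for name, a in arr.items()}
                _, _, vtrace = _run_pso(
                    arr_tr, y[tr], config, config.seed + 17 * (k + 1),
                    config.max_iterations, val=(arr_te, y[te]),
                )
                traces.append(vtrace)
            self.cv_val_traces_ = np.vstack(traces)
            n_iter = int(np.argmin(self.cv_val_traces_.mean(axis=0))) + 1

        best, trace, _ = _run_pso(arr, y, config, config.seed, n_iter)
        params = best[:_N_PARAMS].copy()
        c = float(best[_N_PARAMS])
        s = float(np.exp(best[_N_PARAMS + 1]))
        if config.anchor is not None:
            # The score scale is only identified up to an affine map, which
            # the form absorbs exactly (p15 -> a*p15 + b, p1 -> a*p1): report
            # Y on the conventional scale where the link midpoint sits at the
            # anchor centre (30) with anchor_s score units per link unit.
            anchor_c, anchor_s = config.anchor
            a = anchor_s / s
            i15, i1 = PARAM_NAMES.index("p15"), PARAM_NAMES.index("p1")
            params[i15] = (params[i15] - c) * a + anchor_c
            params[i1] = params[i1] * a
            c, s = anchor_c, anchor_s
        self.params_ = DifeParameters.from_array(params)
        self.c_ = c
        self.s_ = s
        self.loss_trace_ = trace
        self.n_iter_ = n_iter
        return self

    def decision_function(self, df: pd.DataFrame) -> np.ndarray:
        df = df.df if hasattr(df, "df") else df
        return dife_scores(df, self.params_)

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        scores = self.decision_function(df)
        p_good = expit((scores - self.c_) / self.s_)
        return np.column_stack([1 - p_good, p_good])

    def predict(self, df: pd.DataFrame, threshold: float | None = None) -> np.ndarray:
        scores = self.decision_function(df)
        thr = self.c_ if threshold is None else threshold
        return (scores >= thr).astype(int)


def fit_dife(cohort, config: PsoConfig | None = None) -> tuple[DifeParameters, dict]:
    """Fit the equation to a development cohort; return parameters and
    training diagnostics (loss trace, link, iteration budget)."""
    model = DifeModel(config=config).fit(cohort)
    diagnostics = {
        "loss_trace": model.loss_trace_,
        "cv_val_traces": model.cv_val_traces_,
        "n_iter": model.n_iter_,
        "link_c": model.c_,
        "link_s": model.s_,
    }
    return model.params_, diagnostics


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------


@dataclass
class ThresholdReport:
    """Per-candidate-threshold performance table plus the chosen threshold."""

    table: pd.DataFrame
    chosen_threshold: float
    sensitivity_floor: float
    floor_met: bool = True


def select_threshold(
    scores,
    outcomes_poor,
    candidates: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    times=None,
    events=None,
    sensitivity_floor: float = 0.40,
) -> ThresholdReport:
    """Tabulate threshold performance and pick the working threshold.

    At each candidate ``t`` patients with score < t are predicted poor
    survivors (start at once) and score >= t predicted good (prepare and
    wait). Sensitivity is the fraction of true poor survivors flagged.
    The chosen threshold maximises diagnostic accuracy among candidates with
    sensitivity >= ``sensitivity_floor`` (ties -> smaller threshold); if no
    candidate meets the floor the unconstrained maximiser is returned with
    ``floor_met=False``. When follow-up ``times``/``events`` are supplied the
    table also reports deaths per 100 patient-years in each predicted group.
    """
    scores = np.asarray(scores, dtype=float)
    y_poor = np.asarray(outcomes_poor, dtype=int)
    if scores.shape != y_poor.shape:
        raise ValueError("scores and outcomes must be aligned")
    if len(list(candidates)) == 0:
        raise ValueError("candidate list must be non-empty")
    with_rates = times is not None and events is not None
    if with_rates:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)

    rows = []
    for t in candidates:
        pred_poor = scores < t
        tp = int(np.sum(pred_poor & (y_poor == 1)))
        fn = int(np.sum(~pred_poor & (y_poor == 1)))
        tn = int(np.sum(~pred_poor & (y_poor == 0)))
        fp = int(np.sum(pred_poor & (y_poor == 0)))
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        acc = (tp + tn) / len(scores)
        row = {
            "threshold": float(t),
            "n_pred_poor": int(pred_poor.sum()),
            "n_pred_good": int((~pred_poor).sum()),
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": acc,
        }
        if with_rates:
            for grp, mask in (("poor", pred_poor), ("good", ~pred_poor)):
                row[f"mortality_per100py_pred_{grp}"] = (
                    mortality_rate_per100py(times[mask], events[mask]) if mask.any() else np.nan
                )
        rows.append(row)
    table = pd.DataFrame(rows)

    eligible = table[table["sensitivity"] >= sensitivity_floor]
    floor_met = not eligible.empty
    pool = eligible if floor_met else table
    pool = pool.sort_values(["accuracy", "threshold"], ascending=[False, True])
    chosen = float(pool.iloc[0]["threshold"])
    return ThresholdReport(table, chosen, sensitivity_floor, floor_met)
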