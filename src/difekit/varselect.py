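"""Variable selection with an RBM-initialised kernel logistic network (KLNN-RBM).

Candidate covariate subsets are ranked by their mean cross-validated accuracy
at a three-class survival classification task (survival after haemodialysis
initiation: <12 months, 12-36 months, >36 months). The classifier is a small
neural network: an explicit kernel feature map (RBF against training
landmarks, median-heuristic bandwidth, or the identity for a linear kernel),
a sigmoid hidden layer whose weights are pretrained as a Gaussian-Bernoulli
restricted Boltzmann machine (contrastive divergence), and a softmax output
trained by stochastic gradient descent on the multinomial log-likelihood.

The default search keeps the five MDRD-equation variables (age, sex, serum
creatinine, blood urea nitrogen, serum albumin) in every subset and
enumerates the 2^8 combinations of the eight further clinical factors; a
full exhaustive search and greedy forward selection are also available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SURVIVAL_CLASSES",
    "CANDIDATE_VARS",
    "CORE_VARS",
    "ADDON_VARS",
    "KlnnRbmConfig",
    "SubsetResult",
    "GaussianBernoulliRBM",
    "KlnnRbmClassifier",
    "survival_class",
    "pretrain_rbm",
    "train_klnn",
    "cv_accuracy",
    "search_subsets",
]

#: Three-class survival outcome labels, in order of increasing survival.
SURVIVAL_CLASSES = ["lt12", "m12to36", "gt36"]

#: The 13 candidate covariates considered for inclusion in the score.
CANDIDATE_VARS = [
    "age",
    "female",
    "scr_mgdl",
    "bun_mgdl",
    "alb_gdl",
    "hb_gdl",
    "potassium_mmoll",
    "phosphate_mmoll",
    "heart_failure",
    "vomiting",
    "oedema2plus",
    "uraemic_encephalopathy",
    "diabetes",
]

#: MDRD-equation variables, always retained by the default search strategy.
CORE_VARS = ["age", "female", "scr_mgdl", "bun_mgdl", "alb_gdl"]

#: The eight further clinical factors the default strategy enumerates over.
ADDON_VARS = [v for v in CANDIDATE_VARS if v not in CORE_VARS]


def survival_class(survival_months, died_within_36m) -> np.ndarray:
    """Three-level survival outcome from follow-up time and event indicator.

    <12 months -> 0 (``lt12``); 12 to <36 months, and a death recorded at
    exactly 36 months -> 1 (``m12to36``); censored alive at 36 months -> 2
    (``gt36``). Returns integer codes indexing :data:`SURVIVAL_CLASSES`.
    """
    m = np.asarray(survival_months, dtype=float)
    e = np.asarray(died_within_36m, dtype=int)
    out = np.where(m < 12, 0, 1)
    out = np.where((m >= 36) & (e == 0), 2, out)
    return out.astype(int)


# ---------------------------------------------------------------------------
# Gaussian-Bernoulli RBM (CD-1)
# ---------------------------------------------------------------------------


class GaussianBernoulliRBM:
    """Gaussian-visible / Bernoulli-hidden RBM trained by 1-step contrastive
    divergence, used only to pretrain the hidden layer of the classifier.

    Visible units are assumed z-scored (unit variance Gaussians); a warning
    is emitted when a column's SD departs from 1 by more than 0.1.
    """

    def __init__(
        self,
        hidden_units: int = 10,
        n_iterations: int = 100,
        learning_rate: float = 0.01,
        batch_size: int = 32,
        random_state: int | None = None,
    ):
        self.hidden_units = int(hidden_units)
        self.n_iterations = int(n_iterations)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.random_state = random_state

    def fit(self, X: np.ndarray) -> "GaussianBernoulliRBM":
        X = check_array(X, ensure_min_features=1)
        if X.shape[0] == 0:
            raise ValueError("cannot pretrain an RBM on an empty matrix")
        sd = X.std(axis=0)
        if np.any(np.abs(sd - 1.0) > 0.1):
            warnings.warn(
                "RBM visible units expect z-scored input; some column SDs "
                "depart from 1 by more than 0.1",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        W = rng.normal(0.0, 0.01, size=(d, self.hidden_units))
        b_vis = np.zeros(d)
        b_hid = np.zeros(self.hidden_units)
        self.reconstruction_errors_ = []

        for epoch in range(self.n_iterations):
            order = rng.permutation(n)
            sq_err = 0.0
            for start in range(0, n, self.batch_size):
                v0 = X[order[start : start + self.batch_size]]
                ph0 = expit(v0 @ W + b_hid)
                h0 = (rng.random(ph0.shape) < ph0).astype(float)
                v1 = h0 @ W.T + b_vis  # Gaussian visibles: mean-field reconstruction
                ph1 = expit(v1 @ W + b_hid)
                m = v0.shape[0]
                lr = self.learning_rate
                W += lr * (v0.T @ ph0 - v1.T @ ph1) / m
                b_vis += lr * (v0 - v1).mean(axis=0)
                b_hid += lr * (ph0 - ph1).mean(axis=0)
                sq_err += float(((v0 - v1) ** 2).sum())
            self.reconstruction_errors_.append(sq_err / n)

        self.weights_ = W
        self.visible_bias_ = b_vis
        self.hidden_bias_ = b_hid
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return expit(np.asarray(X, dtype=float) @ self.weights_ + self.hidden_bias_)


def pretrain_rbm(X: np.ndarray, config: "KlnnRbmConfig") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pretrain a Gaussian-Bernoulli RBM on a standardised feature matrix.

    Returns ``(weights, visible_bias, hidden_bias)`` with weights shaped
    ``(n_features, hidden_units)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 columns")
    rbm = GaussianBernoulliRBM(
        hidden_units=config.hidden_units,
        n_iterations=config.rbm_iterations,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        random_state=config.seed,
    ).fit(X)
    return rbm.weights_, rbm.visible_bias_, rbm.hidden_bias_


# ---------------------------------------------------------------------------
# Softmax network trained by SGD (the "logistic" head of the KLNN)
# ---------------------------------------------------------------------------


class _SoftmaxNet:
    """Sigmoid hidden layer + softmax output, trained by minibatch SGD on the
    multinomial log-likelihood with a 1/epoch learning-rate decay."""

    def __init__(self, W1, b1, n_classes, learning_rate, n_iterations, batch_size, rng):
        self.W1 = W1.copy()
        self.b1 = b1.copy()
        hidden = W1.shape[1]
        self.W2 = rng.normal(0.0, 0.01, size=(hidden, n_classes))
        self.b2 = np.zeros(n_classes)
        self.learning_rate = learning_rate
        self.n_iterations = n_iterations
        self.batch_size = batch_size
        self.rng = rng

    def _forward(self, F):
        H = expit(F @ self.W1 + self.b1)
        logits = H @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        return H, P

    def fit(self, F, y_onehot):
        n = F.shape[0]
        for epoch in range(self.n_iterations):
            # harmonic decay, tempered so late epochs still learn
            lr = self.learning_rate / (1.0 + epoch / 10.0)
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Fb, Yb = F[idx], y_onehot[idx]
                H, P = self._forward(Fb)
                m = len(idx)
                dlogits = (P - Yb) / m
                dW2 = H.T @ dlogits
                db2 = dlogits.sum(axis=0)
                dH = dlogits @ self.W2.T
                dZ = dH * H * (1.0 - H)
                dW1 = Fb.T @ dZ
                db1 = dZ.sum(axis=0)
                self.W2 -= lr * dW2
                self.b2 -= lr * db2
                self.W1 -= lr * dW1
                self.b1 -= lr * db1
        return self

    def predict_proba(self, F):
        return self._forward(F)[1]


def train_klnn(X, y3, init, config: "KlnnRbmConfig") -> _SoftmaxNet:
    """Train the softmax network on a (kernel) feature matrix.

    ``init`` is the ``(weights, visible_bias, hidden_bias)`` triple from
    :func:`pretrain_rbm`; its weight rows must match ``X``'s columns.
    """
    X = np.asarray(X, dtype=float)
    y3 = np.asarray(y3, dtype=int)
    classes = np.unique(y3)
    if classes.size < 2:
        raise ValueError("labels must cover at least 2 classes")
    W1, _, b_hid = init[0], init[1], init[2]
    if W1.shape[0] != X.shape[1]:
        raise ValueError(
            f"init weights have {W1.shape[0]} input rows but X has {X.shape[1]} columns"
        )
    onehot = np.zeros((len(y3), 3))
    onehot[np.arange(len(y3)), y3] = 1.0
    rng = np.random.default_rng(config.seed)
    net = _SoftmaxNet(
        W1, b_hid, 3, config.learning_rate, config.sgd_iterations, config.batch_size, rng
    )
    return net.fit(X, onehot)


# ---------------------------------------------------------------------------
# The sklearn estimator
# ---------------------------------------------------------------------------


class KlnnRbmClassifier(ClassifierMixin, BaseEstimator):
    """Kernel logistic neural network with RBM-pretrained hidden layer.

    Pipeline inside ``fit``: explicit kernel feature map (RBF against up to
    ``n_landmarks`` training points with median-heuristic bandwidth, or the
    raw covariates for ``kernel='linear'``) -> per-feature z-scoring ->
    Gaussian-Bernoulli RBM pretraining of the hidden layer -> minibatch SGD
    on the multinomial log-likelihood.

    Parameters
    ----------
    hidden_units : int
        Hidden-layer width.
    kernel : {'rbf', 'linear'}
    bandwidth : float or None
        RBF bandwidth; ``None`` uses the median pairwise distance of the
        training covariates.
    rbm_iterations, sgd_iterations : int
        Contrastive-divergence and SGD epochs (both default 100).
    learning_rate : float
        Initial SGD/CD learning rate, decayed as 1/epoch during SGD.
    """

    def __init__(
        self,
        hidden_units: int = 10,
        kernel: str = "rbf",
        bandwidth: float | None = None,
        n_landmarks: int = 50,
        rbm_iterations: int = 100,
        sgd_iterations: int = 100,
        learning_rate: float = 0.01,
        batch_size: int = 32,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.n_landmarks = n_landmarks
        self.rbm_iterations = rbm_iterations
        self.sgd_iterations = sgd_iterations
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    # kernel feature map -----------------------------------------------------

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return X
        d2 = cdist(X, self.landmarks_, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.bandwidth_**2))

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("y must contain at least 2 classes")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        rng = np.random.default_rng(self.random_state)

        self._input_scaler = StandardScaler().fit(X)
        Xs = self._input_scaler.transform(X)
        if self.kernel == "rbf":
            n_land = min(self.n_landmarks, Xs.shape[0])
            self.landmarks_ = Xs[rng.choice(Xs.shape[0], size=n_land, replace=False)]
            if self.bandwidth is not None:
                self.bandwidth_ = float(self.bandwidth)
            else:
                d = pdist(Xs[: min(len(Xs), 500)])
                med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
                self.bandwidth_ = med if med > 0 else 1.0
        F = self._features(Xs)
        self._feature_scaler = StandardScaler().fit(F)
        # constant features carry no information; leave them at zero
        self._feature_scaler.scale_[self._feature_scaler.scale_ == 0] = 1.0
        Fs = self._feature_scaler.transform(F)

        cfg = KlnnRbmConfig(
            hidden_units=self.hidden_units,
            rbm_iterations=self.rbm_iterations,
            sgd_iterations=self.sgd_iterations,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            # z-scored features: the RBM standardisation warning cannot trip
            warnings.simplefilter("ignore")
            init = pretrain_rbm(Fs, cfg) if Fs.shape[1] >= 2 else None
        if init is None:
            raise ValueError("classifier needs at least 2 feature columns")
        y_idx = np.searchsorted(self.classes_, y)
        # pad label space to 3 outputs only when fewer classes are present
        onehot_classes = max(3, self.classes_.size)
        onehot = np.zeros((len(y_idx), onehot_classes))
        onehot[np.arange(len(y_idx)), y_idx] = 1.0
        net = _SoftmaxNet(
            init[0],
            init[2],
            onehot_classes,
            self.learning_rate,
            self.sgd_iterations,
            self.batch_size,
            np.random.default_rng(cfg.seed + 1),
        )
        self._net = net.fit(Fs, onehot)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_net")
        X = check_array(X)
        Fs = self._feature_scaler.transform(self._features(self._input_scaler.transform(X)))
        P = self._net.predict_proba(Fs)[:, : self.classes_.size]
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Cross-validation harness and subset search
# ---------------------------------------------------------------------------


@dataclass
class KlnnRbmConfig:
    """Configuration for the classifier and its CV harness."""

    hidden_units: int = 10
    kernel: str = "rbf"
    bandwidth: float | None = None
    n_landmarks: int = 50
    rbm_iterations: int = 100
    sgd_iterations: int = 100
    learning_rate: float = 0.01
    batch_size: int = 32
    n_simulations: int = 20
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_units", "rbm_iterations", "sgd_iterations", "n_simulations", "n_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def make_classifier(self, random_state: int) -> KlnnRbmClassifier:
        return KlnnRbmClassifier(
            hidden_units=self.hidden_units,
            kernel=self.kernel,
            bandwidth=self.bandwidth,
            n_landmarks=self.n_landmarks,
            rbm_iterations=self.rbm_iterations,
            sgd_iterations=self.sgd_iterations,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            random_state=random_state,
        )


def cv_accuracies(X, y3, config: KlnnRbmConfig) -> np.ndarray:
    """Per-simulation cross-validated accuracies.

    Each simulation reshuffles the folds and reinitialises the network; a
    simulation's accuracy is the fraction of records classified correctly in
    their (unique) test fold.
    """
    X = np.asarray(X, dtype=float)
    y3 = np.asarray(y3, dtype=int)
    if len(X) < config.n_folds:
        raise ValueError("need at least as many records as folds")
    accs = np.empty(config.n_simulations)
    for sim in range(config.n_simulations):
        seed = config.seed + 1000 * sim
        splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
        correct = 0
        for k, (tr, te) in enumerate(splitter.split(X, y3)):
            clf = config.make_classifier(random_state=seed + k)
            clf.fit(X[tr], y3[tr])
            correct += int((clf.predict(X[te]) == y3[te]).sum())
        accs[sim] = correct / len(y3)
    return accs


def cv_accuracy(X, y3, config: KlnnRbmConfig) -> float:
    """Mean accuracy over ``n_simulations`` independent CV runs."""
    return float(cv_accuracies(X, y3, config).mean())


@dataclass
class SubsetResult:
    variables: tuple[str, ...]
    mean_accuracy: float
    accuracies: np.ndarray = field(repr=False)


def _subsets_for_strategy(candidates: Sequence[str], strategy: str):
    core = [v for v in CORE_VARS if v in candidates]
    addons = [v for v in candidates if v not in core]
    if strategy == "exhaustive_over_addons":
        for r in range(len(addons) + 1):
            for combo in itertools.combinations(addons, r):
                yield tuple(core) + combo
    elif strategy == "full_exhaustive":
        for r in range(2, len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                yield combo
    else:
        raise ValueError(f"unknown strategy {strategy!r}")


def search_subsets(
    cohort,
    candidates: Sequence[str] | None = None,
    strategy: str = "exhaustive_over_addons",
    config: KlnnRbmConfig | None = None,
) -> list[SubsetResult]:
    """Rank candidate-variable subsets by mean cross-validated accuracy.

    ``strategy`` is one of ``exhaustive_over_addons`` (default: the core
    MDRD variables always included, all combinations of the remaining
    factors), ``full_exhaustive`` (every subset of >= 2 candidates) or
    ``greedy`` (forward selection from the core). Ties are broken in favour
    of the smaller subset, then lexicographically.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    candidates = list(candidates or CANDIDATE_VARS)
    missing = [c for c in candidates if c not in df.columns]
    if missing:
        raise ValueError(f"candidates not present in cohort: {missing}")
    config = config or KlnnRbmConfig()
    y3 = survival_class(df["survival_months"], df["died_within_36m"])

    def evaluate(subset: tuple[str, ...]) -> SubsetResult:
        accs = cv_accuracies(df[list(subset)].to_numpy(dtype=float), y3, config)
        return SubsetResult(subset, float(accs.mean()), accs)

    if strategy == "greedy":
        core = tuple(v for v in CORE_VARS if v in candidates)
        addons = [v for v in candidates if v not in core]
        current = evaluate(core)
        results = [current]
        remaining = list(addons)
        while remaining:
            trials = [evaluate(current.variables + (v,)) for v in remaining]
            best = max(trials, key=lambda r: r.mean_accuracy)
            results.extend(trials)
            if best.mean_accuracy <= current.mean_accuracy:
                break
            current = best
            remaining = [v for v in remaining if v not in best.variables]
    else:
        results = [evaluate(s) for s in _subsets_for_strategy(candidates, strategy)]

    results.sort(key=lambda r: (-r.mean_accuracy, len(r.variables), tuple(sorted(r.variables))))
    return results
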