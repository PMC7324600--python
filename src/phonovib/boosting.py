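"""Boosted depth-1 decision trees (stumps), implemented from scratch.

Three two-class algorithms share the same exhaustive stump search:

* **AdaBoost** — discrete AdaBoost: the stump minimizes weighted
  misclassification, the stage weight is ``lr * 0.5 * ln((1-err)/err)``
  (shrinkage via the learning rate), and observation weights are
  re-exponentiated each round.
* **LogitBoost** — Newton steps on the binomial log-likelihood: each round
  fits a weighted least-squares regression stump to the working response
  ``z = (y* - p) / (p(1-p))`` (clipped to +/-4) with weights ``p(1-p)``,
  and adds ``lr * 0.5 * stump`` to the additive score; probabilities are
  clipped to [1e-10, 1-1e-10].
* **RUSBoost** — AdaBoost in which each round's stump is fit on a random
  undersample of the majority class down to the minority size (seeded);
  the error and weight update use the full sample.

Class imbalance is absorbed by a *uniform prior*: initial observation
weights ``1 / (2 n_class(y_i))`` so both classes carry equal total weight.

The stump search scans every feature and every midpoint between adjacent
distinct observed values; ties are broken toward the lowest feature index,
then the lowest threshold, making training bit-reproducible.  Each stump
records its split gain (criterion reduction versus the no-split root),
which accumulates into feature importance: per-feature summed gain divided
by the number of stumps, reported max-normalized.

Model assessment uses repeated stratified k-fold cross-validation with the
fold AUC computed by the Mann-Whitney rank formulation and accuracy,
sensitivity and specificity taken at score threshold 0 (probability 0.5
under the uniform prior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Tuple

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "BoostConfig",
    "Stump",
    "StumpEnsemble",
    "PerformanceSummary",
    "ImportanceVector",
    "BaseStumpBooster",
    "AdaBoostStumps",
    "LogitBoostStumps",
    "RUSBoostStumps",
    "fit_stump",
    "train",
    "predict_scores",
    "feature_importance",
    "crossval_evaluate",
    "make_estimator",
    "roc_auc",
    "StratifiedKFold",
]

_P_CLIP = 1e-10
_Z_CLIP = 4.0


# --------------------------------------------------------------------------
# Config / containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoostConfig:
    """Training configuration shared by the three algorithms."""

    algorithm: str = "LogitBoost"    # 'AdaBoost' | 'LogitBoost' | 'RUSBoost'
    n_stumps: int = 300
    learning_rate: float = 0.1
    prior: str = "uniform"           # 'uniform' | 'empirical'
    seed: int = 0

    def validate(self):
        if self.algorithm not in ("AdaBoost", "LogitBoost", "RUSBoost"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_stumps < 1:
            raise ValueError("n_stumps must be >= 1")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.prior not in ("uniform", "empirical"):
            raise ValueError("prior must be 'uniform' or 'empirical'")


@dataclass(frozen=True)
class Stump:
    """One depth-1 tree: x[feature] <= threshold -> left value, else right."""

    feature: int
    threshold: float
    left: float
    right: float
    gain: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(X[:, self.feature] <= self.threshold,
                        self.left, self.right)


@dataclass
class StumpEnsemble:
    """Ordered boosted stumps with per-stump gain records."""

    stumps: List[Stump]
    algorithm: str
    n_features: int
    classes: Tuple
    config: BoostConfig

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
                f"ensemble expects {self.n_features}")
        scores = np.zeros(X.shape[0])
        for st in self.stumps:
            scores += st.predict(X)
        return scores

    def to_json(self) -> str:
        return json.dumps({
            "algorithm": self.algorithm, "n_features": self.n_features,
            "classes": list(self.classes), "config": asdict(self.config),
            "stumps": [asdict(s) for s in self.stumps]})

    @classmethod
    def from_json(cls, s: str) -> "StumpEnsemble":
        d = json.loads(s)
        return cls(stumps=[Stump(**x) for x in d["stumps"]],
                   algorithm=d["algorithm"], n_features=d["n_features"],
                   classes=tuple(d["classes"]),
                   config=BoostConfig(**d["config"]))


@dataclass
class PerformanceSummary:
    """Cross-validated performance: mean/std over folds x repeats."""

    auc_mean: float
    auc_std: float
    acc_mean: float
    acc_std: float
    sens_mean: float
    sens_std: float
    spec_mean: float
    spec_std: float
    n_folds: int = 0

    def as_dict(self):
        return asdict(self)


@dataclass
class ImportanceVector:
    """Raw and max-normalized per-feature importance."""

    raw: np.ndarray
    normalized: np.ndarray


# --------------------------------------------------------------------------
# Stump search
# --------------------------------------------------------------------------

def _presort(X: np.ndarray):
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    valid = Xs[1:] > Xs[:-1]                      # (n-1, F) admissible splits
    thresholds = 0.5 * (Xs[1:] + Xs[:-1])
    return order, thresholds, valid


def _best_split(crit: np.ndarray, valid: np.ndarray):
    """Global argmin with ties to lowest feature index, lowest threshold."""
    crit = np.where(valid, crit, np.inf)
    per_feat_idx = np.argmin(crit, axis=0)        # first (lowest threshold)
    per_feat_val = crit[per_feat_idx, np.arange(crit.shape[1])]
    f = int(np.argmin(per_feat_val))              # first (lowest feature)
    if not np.isfinite(per_feat_val[f]):
        return None
    return f, int(per_feat_idx[f]), float(per_feat_val[f])


def _fit_regression_stump(X, z, w, presorted) -> Stump:
    """Weighted least-squares stump (LogitBoost base learner)."""
    order, thresholds, valid = presorted
    tw = float(np.sum(w))
    twz = float(np.sum(w * z))
    twz2 = float(np.sum(w * z * z))
    root = twz2 - twz ** 2 / tw if tw > 0 else 0.0
    if not valid.any():
        v = twz / tw if tw > 0 else 0.0
        return Stump(0, -np.inf, v, v, 0.0)
    ws = w[order]
    wzs = (w * z)[order]
    cw = np.cumsum(ws, axis=0)[:-1]
    cwz = np.cumsum(wzs, axis=0)[:-1]
    rw = tw - cw
    rwz = twz - cwz
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = twz2 - np.where(cw > 0, cwz ** 2 / cw, 0.0) \
            - np.where(rw > 0, rwz ** 2 / rw, 0.0)
    best = _best_split(sse, valid)
    if best is None:
        v = twz / tw if tw > 0 else 0.0
        return Stump(0, -np.inf, v, v, 0.0)
    f, i, val = best
    lw, lwz = cw[i, f], cwz[i, f]
    rww, rwzz = tw - lw, twz - lwz
    left = lwz / lw if lw > 0 else 0.0
    right = rwzz / rww if rww > 0 else 0.0
    return Stump(f, float(thresholds[i, f]), float(left), float(right),
                 max(root - val, 0.0))


def _fit_classification_stump(X, y_pm, w, presorted) -> Stump:
    """Weighted misclassification stump (AdaBoost/RUSBoost base learner).

    Leaf values are class votes in {-1, +1}.
    """
    order, thresholds, valid = presorted
    tw = float(np.sum(w))
    twy = float(np.sum(w * y_pm))
    root = 0.5 * (tw - abs(twy))
    if not valid.any():
        v = 1.0 if twy >= 0 else -1.0
        return Stump(0, -np.inf, v, v, 0.0)
    ws = w[order]
    wys = (w * y_pm)[order]
    cw = np.cumsum(ws, axis=0)[:-1]
    cwy = np.cumsum(wys, axis=0)[:-1]
    err = 0.5 * (tw - np.abs(cwy) - np.abs(twy - cwy))
    best = _best_split(err, valid)
    if best is None:
        v = 1.0 if twy >= 0 else -1.0
        return Stump(0, -np.inf, v, v, 0.0)
    f, i, val = best
    left = 1.0 if cwy[i, f] >= 0 else -1.0
    right = 1.0 if (twy - cwy[i, f]) >= 0 else -1.0
    return Stump(f, float(thresholds[i, f]), left, right,
                 max(root - val, 0.0))


def fit_stump(X, y, weights=None, criterion: str = "classification") -> Stump:
    """Fit a single decision stump.

    ``criterion='classification'`` minimizes weighted misclassification of
    labels in {-1, +1}; ``'regression'`` minimizes weighted squared error of
    a real-valued working response.  Ties break to the lowest feature
    index, then the lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    w = np.ones(X.shape[0]) if weights is None \
        else np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    presorted = _presort(X)
    if criterion == "regression":
        return _fit_regression_stump(X, y, w, presorted)
    if criterion == "classification":
        return _fit_classification_stump(X, y, w, presorted)
    raise ValueError(f"unknown criterion {criterion!r}")


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

class BaseStumpBooster:
    """Shared sklearn-style plumbing for the three boosting algorithms."""

    _algorithm = "?"

    def __init__(self, n_stumps: int = 300, learning_rate: float = 0.1,
                 prior: str = "uniform", seed: int = 0):
        self.n_stumps = n_stumps
        self.learning_rate = learning_rate
        self.prior = prior
        self.seed = seed

    # -- sklearn protocol --------------------------------------------------
    def get_params(self, deep: bool = True):
        return {"n_stumps": self.n_stumps,
                "learning_rate": self.learning_rate,
                "prior": self.prior, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    def _config(self) -> BoostConfig:
        cfg = BoostConfig(algorithm=self._algorithm, n_stumps=self.n_stumps,
                          learning_rate=self.learning_rate, prior=self.prior,
                          seed=self.seed)
        cfg.validate()
        return cfg

    def _validate_fit_input(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two classes required, got "
                             f"{classes.size}")
        y_pm = np.where(y == classes[1], 1.0, -1.0)
        return X, y_pm, tuple(classes.tolist())

    def _prior_weights(self, y_pm: np.ndarray) -> np.ndarray:
        n = y_pm.size
        if self.prior == "uniform":
            n_pos = int(np.sum(y_pm > 0))
            n_neg = n - n_pos
            w = np.where(y_pm > 0, 1.0 / (2 * n_pos), 1.0 / (2 * n_neg))
        else:
            w = np.full(n, 1.0 / n)
        return w

    def fit(self, X, y) -> "BaseStumpBooster":
        X, y_pm, classes = self._validate_fit_input(X, y)
        cfg = self._config()
        stumps = self._boost(X, y_pm, np.random.default_rng(self.seed))
        self.classes_ = np.asarray(classes)
        self.n_features_in_ = X.shape[1]
        self.ensemble_ = StumpEnsemble(stumps=stumps,
                                       algorithm=self._algorithm,
                                       n_features=X.shape[1],
                                       classes=classes, config=cfg)
        raw = np.zeros(X.shape[1])
        for st in stumps:
            if np.isfinite(st.threshold):
                raw[st.feature] += st.gain
        self.feature_importances_ = raw / max(len(stumps), 1)
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self.ensemble_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])

    def _check_fitted(self):
        if not hasattr(self, "ensemble_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    def _boost(self, X, y_pm, rng) -> List[Stump]:
        raise NotImplementedError


class AdaBoostStumps(BaseStumpBooster):
    """Discrete AdaBoost over decision stumps with shrinkage."""

    _algorithm = "AdaBoost"

    def _boost(self, X, y_pm, rng):
        presorted = _presort(X)
        w = self._prior_weights(y_pm)
        stumps: List[Stump] = []
        for _ in range(self.n_stumps):
            w = w / w.sum()
            st = _fit_classification_stump(X, y_pm, w, presorted)
            pred = st.predict(X)
            err = float(np.sum(w[pred != y_pm]))
            err = min(max(err, _P_CLIP), 1 - _P_CLIP)
            if err >= 0.5:
                break
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            stumps.append(Stump(st.feature, st.threshold,
                                alpha * st.left, alpha * st.right, st.gain))
            w = w * np.exp(-alpha * y_pm * pred)
        return stumps


class LogitBoostStumps(BaseStumpBooster):
    """LogitBoost: Newton steps on the binomial deviance."""

    _algorithm = "LogitBoost"

    def _boost(self, X, y_pm, rng):
        presorted = _presort(X)
        prior_w = self._prior_weights(y_pm)
        y01 = (y_pm > 0).astype(float)
        F = np.zeros(X.shape[0])
        stumps: List[Stump] = []
        for _ in range(self.n_stumps):
            p = 1.0 / (1.0 + np.exp(-2.0 * F))
            p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
            z = np.clip((y01 - p) / (p * (1 - p)), -_Z_CLIP, _Z_CLIP)
            w = prior_w * p * (1 - p)
            st = _fit_regression_stump(X, z, w, presorted)
            scale = self.learning_rate * 0.5
            st = Stump(st.feature, st.threshold, scale * st.left,
                       scale * st.right, st.gain)
            stumps.append(st)
            F = F + st.predict(X)
        return stumps


class RUSBoostStumps(BaseStumpBooster):
    """AdaBoost on per-round random undersamples of the majority class."""

    _algorithm = "RUSBoost"

    def _boost(self, X, y_pm, rng):
        w = self._prior_weights(y_pm)
        pos = np.flatnonzero(y_pm > 0)
        neg = np.flatnonzero(y_pm < 0)
        minority, majority = (pos, neg) if pos.size <= neg.size \
            else (neg, pos)
        stumps: List[Stump] = []
        for _ in range(self.n_stumps):
            w = w / w.sum()
            sel = rng.choice(majority, size=minority.size, replace=False)
            idx = np.sort(np.concatenate([minority, sel]))
            st = fit_stump(X[idx], y_pm[idx], w[idx],
                           criterion="classification")
            pred = st.predict(X)
            err = float(np.sum(w[pred != y_pm]))
            err = min(max(err, _P_CLIP), 1 - _P_CLIP)
            if err >= 0.5:
                continue      # resample and try again next round
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            stumps.append(Stump(st.feature, st.threshold,
                                alpha * st.left, alpha * st.right, st.gain))
            w = w * np.exp(-alpha * y_pm * pred)
        return stumps


_ESTIMATORS = {"AdaBoost": AdaBoostStumps, "LogitBoost": LogitBoostStumps,
               "RUSBoost": RUSBoostStumps}


def make_estimator(config: BoostConfig) -> BaseStumpBooster:
    config.validate()
    cls = _ESTIMATORS[config.algorithm]
    return cls(n_stumps=config.n_stumps, learning_rate=config.learning_rate,
               prior=config.prior, seed=config.seed)


# --------------------------------------------------------------------------
# Functional wrappers
# --------------------------------------------------------------------------

def train(X, y, config: BoostConfig) -> StumpEnsemble:
    """Train a stump ensemble (thin wrapper over the estimator classes)."""
    est = make_estimator(config)
    est.fit(X, y)
    return est.ensemble_


def predict_scores(ensemble: StumpEnsemble, X):
    """Additive scores and class labels at threshold 0.

    A zero score (e.g. empty ensemble) maps to the first (negative) class.
    """
    scores = ensemble.decision_function(np.asarray(X, dtype=float))
    labels = np.where(scores > 0, ensemble.classes[1], ensemble.classes[0])
    return scores, labels


def feature_importance(ensemble_or_estimator) -> ImportanceVector:
    """Per-feature summed split gain / number of stumps, max-normalized."""
    if isinstance(ensemble_or_estimator, StumpEnsemble):
        ens = ensemble_or_estimator
        raw = np.zeros(ens.n_features)
        for st in ens.stumps:
            if np.isfinite(st.threshold):
                raw[st.feature] += st.gain
        raw = raw / max(len(ens.stumps), 1)
    else:
        raw = np.asarray(ensemble_or_estimator.feature_importances_,
                         dtype=float)
    m = raw.max()
    norm = raw / m if m > 0 else np.zeros_like(raw)
    return ImportanceVector(raw=raw, normalized=norm)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

class StratifiedKFold:
    """Seeded stratified k-fold splitter (class proportions preserved)."""

    def __init__(self, k: int, seed: int = 0):
        self.k = k
        self.seed = seed

    def split(self, y):
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        folds = [[] for _ in range(self.k)]
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for i, chunk in enumerate(np.array_split(idx, self.k)):
                folds[i].extend(chunk.tolist())
        all_idx = np.arange(y.size)
        for f in folds:
            test = np.sort(np.asarray(f, dtype=int))
            train_idx = np.setdiff1d(all_idx, test)
            yield train_idx, test


def roc_auc(y_true_pm: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation (ties averaged)."""
    pos = y_true_pm > 0
    n1 = int(np.sum(pos))
    n0 = y_true_pm.size - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    u = float(np.sum(ranks[pos])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def crossval_evaluate(X, y, config: BoostConfig, k: int = 10,
                      repeats: int = 10, seed: int = 0
                      ) -> PerformanceSummary:
    """Repeated stratified k-fold evaluation of one configuration.

    AUC is computed per test fold from the additive scores and averaged;
    accuracy, sensitivity (positive = second class) and specificity use the
    score-0 threshold.  Every class must have at least ``k`` members.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    counts = [int(np.sum(y == c)) for c in classes]
    if min(counts) < k:
        raise ValueError(
            f"smallest class has {min(counts)} members < k={k}; "
            "use a smaller k")
    y_pm = np.where(y == classes[1], 1.0, -1.0)

    ss = np.random.SeedSequence([seed, config.seed])
    fold_seeds = ss.generate_state(repeats * 2) % (2 ** 31 - 1)
    aucs, accs, sens, spec = [], [], [], []
    for r in range(repeats):
        splitter = StratifiedKFold(k, seed=int(fold_seeds[2 * r]))
        model_seed = int(fold_seeds[2 * r + 1])
        for train_idx, test_idx in splitter.split(y):
            est = make_estimator(config)
            est.seed = model_seed
            est.fit(X[train_idx], y[train_idx])
            scores = est.decision_function(X[test_idx])
            yt = y_pm[test_idx]
            aucs.append(roc_auc(yt, scores))
            pred = np.where(scores > 0, 1.0, -1.0)
            accs.append(float(np.mean(pred == yt)))
            p = yt > 0
            sens.append(float(np.mean(pred[p] == 1.0)) if p.any() else np.nan)
            spec.append(float(np.mean(pred[~p] == -1.0)) if (~p).any()
                        else np.nan)

    def ms(v):
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        return (float(np.mean(v)), float(np.std(v, ddof=1))
                if v.size > 1 else 0.0)

    (am, asd), (cm, csd) = ms(aucs), ms(accs)
    (sm, ssd), (pm, psd) = ms(sens), ms(spec)
    return PerformanceSummary(auc_mean=am, auc_std=asd, acc_mean=cm,
                              acc_std=csd, sens_mean=sm, sens_std=ssd,
                              spec_mean=pm, spec_std=psd,
                              n_folds=k * repeats)
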