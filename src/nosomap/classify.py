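"""LDA reference classifier, RF/SVM baselines, and bootstrap evaluation.

LDA is implemented in-package (class means, pooled ridge-regularized
covariance, Gaussian posteriors) so its calibration can be checked
against closed-form Bayes error independently of scikit-learn; RF and
SVM are thin adapters over scikit-learn exposing the same per-class
posterior interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

#: gb and me collapse onto the aggressive superclass in both tasks.
SUPERCLASS = {"gb": "agg", "me": "agg"}


@dataclass(frozen=True)
class ClassTask:
    """An ordered-label classification task."""

    name: str
    classes: tuple[str, ...]

    def map_label(self, label: str) -> str | None:
        """Task class for a raw diagnostic label, or None if excluded."""
        mapped = SUPERCLASS.get(label, label)
        return mapped if mapped in self.classes else None


FOUR_CLASS = ClassTask("four_class", ("mm", "lgg", "agg", "no"))
THREE_CLASS = ClassTask("three_class", ("mm", "agg", "no"))
TASKS = {t.name: t for t in (FOUR_CLASS, THREE_CLASS)}


@dataclass
class LDAModel:
    classes: tuple[str, ...]
    means: np.ndarray  # (C, d)
    covariance: np.ndarray  # (d, d), pooled + ridge
    priors: np.ndarray  # (C,)
    feature_indices: tuple[int, ...] | None = None
    _chol: Any = field(default=None, repr=False)

    def predict_posteriors(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return lda_predict(self, X)


def lda_fit(
    X: np.ndarray,
    y: Sequence[str],
    priors: "dict[str, float] | str | None" = None,
    ridge: float = 1e-6,
    feature_indices: tuple[int, ...] | None = None,
) -> LDAModel:
    """Fit LDA with pooled within-class covariance + diagonal ridge.

    *priors*: None/"empirical" for class frequencies, "uniform", or an
    explicit mapping.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    d = X.shape[1]
    means = np.zeros((len(classes), d))
    pooled = np.zeros((d, d))
    n_total = 0
    for ci, c in enumerate(classes):
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples")
        means[ci] = Xc.mean(axis=0)
        diff = Xc - means[ci]
        pooled += diff.T @ diff
        n_total += len(Xc)
    pooled /= n_total - len(classes)
    if ridge > 0:
        pooled = pooled + ridge * float(np.mean(np.diag(pooled))) * np.eye(d)

    if priors is None or priors == "empirical":
        pr = np.array([np.mean(y == c) for c in classes])
    elif priors == "uniform":
        pr = np.full(len(classes), 1.0 / len(classes))
    else:
        pr = np.array([priors[c] for c in classes], dtype=float)
        pr = pr / pr.sum()

    try:
        chol = cho_factor(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance; increase ridge") from exc
    return LDAModel(
        classes=classes,
        means=means,
        covariance=pooled,
        priors=pr,
        feature_indices=feature_indices,
        _chol=chol,
    )


def lda_predict(
    model: LDAModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class posteriors (rows sum to 1) and winning labels."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.means.shape[1]} "
            f"features, got {X.shape[1]}"
        )
    chol = model._chol if model._chol is not None else cho_factor(model.covariance)
    log_post = np.empty((X.shape[0], len(model.classes)))
    for ci in range(len(model.classes)):
        diff = X - model.means[ci]
        maha = np.sum(diff * cho_solve(chol, diff.T).T, axis=1)
        log_post[:, ci] = np.log(model.priors[ci]) - 0.5 * maha
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    winners = np.array([model.classes[i] for i in np.argmax(post, axis=1)])
    return post, winners


def ber(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> float:
    """Balanced error rate: mean per-class misclassification fraction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    errors = []
    for c in classes:
        mask = y_true == c
        if not mask.any():
            raise ValueError(f"class {c!r} absent from y_true")
        errors.append(float(np.mean(y_pred[mask] != c)))
    return float(np.mean(errors))


def auc_ovr(
    y_true: Sequence[str], scores: np.ndarray, positive: str
) -> float:
    """One-vs-rest AUC of *scores* ranking (Mann-Whitney, ties 0.5)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"class {positive!r} lacks positives or negatives")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class MetricsSummary:
    """Bootstrap replicate metrics plus aggregates and ratios."""

    classes: tuple[str, ...]
    ber_train: np.ndarray  # (reps,)
    ber_test: np.ndarray
    auc_train: np.ndarray  # (reps, C)
    auc_test: np.ndarray

    def _agg(self, arr: np.ndarray) -> dict[str, float]:
        # NaN marks per-class AUCs for classes absent from the test set
        with np.errstate(all="ignore"):
            return {
                "mean": float(np.nanmean(arr)),
                "min": float(np.nanmin(arr)),
                "max": float(np.nanmax(arr)),
            }

    @property
    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "ber_train": self._agg(self.ber_train),
            "ber_test": self._agg(self.ber_test),
            "auc_train": {
                c: self._agg(self.auc_train[:, i])
                for i, c in enumerate(self.classes)
            },
            "auc_test": {
                c: self._agg(self.auc_test[:, i])
                for i, c in enumerate(self.classes)
            },
        }
        out["auc_ratio"] = self.auc_ratio
        out["ber_ratio"] = self.ber_ratio
        return out

    @property
    def auc_ratio(self) -> float:
        """Mean over classes of AUC_test / AUC_train (aggregate means);
        classes absent from the test set are skipped."""
        tr = self.auc_train.mean(axis=0)
        te = np.nanmean(self.auc_test, axis=0)
        with np.errstate(all="ignore"):
            return float(np.nanmean(te / np.where(tr == 0, np.nan, tr)))

    @property
    def ber_ratio(self) -> float:
        tr = float(self.ber_train.mean())
        return float(self.ber_test.mean() / tr) if tr > 0 else float("inf")


def fit_classifier(
    X: np.ndarray,
    y: Sequence[str],
    method: str = "lda",
    seed: int = 0,
    params: dict | None = None,
):
    """Fit lda/rf/svm; every model exposes ``predict_posteriors``."""
    params = dict(params or {})
    if method == "lda":
        return lda_fit(X, y, **params)
    return baseline_classifiers(X, y, method, seed=seed, params=params)


@dataclass
class _SKAdapter:
    estimator: Any
    classes: tuple[str, ...]

    def predict_posteriors(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        proba = self.estimator.predict_proba(np.atleast_2d(X))
        # reorder sklearn's class order onto ours
        order = [list(self.estimator.classes_).index(c) for c in self.classes]
        proba = proba[:, order]
        winners = np.array(
            [self.classes[i] for i in np.argmax(proba, axis=1)]
        )
        return proba, winners


def baseline_classifiers(
    X: np.ndarray,
    y: Sequence[str],
    method: str,
    seed: int = 0,
    params: dict | None = None,
) -> _SKAdapter:
    """Random forest / SVM baselines behind the posterior interface."""
    params = dict(params or {})
    y = np.asarray(y)
    if method == "rf":
        est = RandomForestClassifier(
            n_estimators=int(params.pop("n_estimators", 200)),
            random_state=seed,
            n_jobs=1,
            **params,
        )
    elif method == "svm":
        est = SVC(
            probability=True,
            random_state=seed,
            **params,
        )
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    est.fit(X, y)
    return _SKAdapter(estimator=est, classes=tuple(sorted(set(y.tolist()))))


def _stratified_resample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Within-class resampling with replacement; no class can vanish."""
    idx = []
    for c in sorted(set(y.tolist())):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_evaluate(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    y_test: Sequence[str],
    method: str = "lda",
    params: dict | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    resample: bool = True,
) -> MetricsSummary:
    """Bootstrap the training set, refit, and score train (in-bag) + test."""
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    classes = tuple(sorted(set(y_train.tolist())))
    # test grids may lack some training classes (e.g. single-case grids):
    # test BER restricts to present classes, absent-class test AUC is NaN
    test_classes = [c for c in classes if (y_test == c).any()]
    if not test_classes:
        raise ValueError("no training class present in y_test")
    rng = np.random.default_rng(seed)
    bt, be = [], []
    at = np.empty((n_reps, len(classes)))
    ae = np.empty((n_reps, len(classes)))
    for rep in range(n_reps):
        if resample:
            idx = _stratified_resample(y_train, rng)
        else:
            idx = np.arange(len(y_train))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        model = fit_classifier(
            X_train[idx], y_train[idx], method=method, seed=rep_seed,
            params=params,
        )
        post_tr, pred_tr = model.predict_posteriors(X_train[idx])
        post_te, pred_te = model.predict_posteriors(X_test)
        bt.append(ber(y_train[idx], pred_tr, classes))
        be.append(ber(y_test, pred_te, test_classes))
        for ci, c in enumerate(classes):
            at[rep, ci] = auc_ovr(y_train[idx], post_tr[:, ci], c)
            ae[rep, ci] = (
                auc_ovr(y_test, post_te[:, ci], c)
                if c in test_classes and (y_test != c).any()
                else np.nan
            )
    return MetricsSummary(
        classes=classes,
        ber_train=np.asarray(bt),
        ber_test=np.asarray(be),
        auc_train=at,
        auc_test=ae,
    )


def select_best_model(
    candidates: Sequence[tuple[Any, MetricsSummary]]
) -> Any:
    """Pick the config whose test/train AUC ratio is closest to 1.

    Lexicographic: (1) smallest mean over classes of |1 - AUC_te/AUC_tr|,
    (2) largest mean test AUC, (3) smallest mean test BER; ties keep the
    earliest candidate.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best_key, best_config = None, None
    for config, ms in candidates:
        tr = ms.auc_train.mean(axis=0)
        with np.errstate(all="ignore"):
            te = np.nanmean(ms.auc_test, axis=0)
            ratio_dev = float(np.nanmean(np.abs(1.0 - te / tr)))
            te_mean = float(np.nanmean(te))
        key = (
            round(ratio_dev, 12),
            round(-te_mean, 12),
            round(float(ms.ber_test.mean()), 12),
        )
        if best_key is None or key < best_key:
            best_key, best_config = key, config
    return best_config
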