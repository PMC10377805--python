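"""Feature selection on the [0, 4.2] ppm grid.

Reference path is floating forward selection (SFFS) with an LDA wrapper
under stratified cross-validated balanced accuracy; Chi / K-best / Lasso
/ Boruta rankings are baselines.  Every method passes its output through
Pearson-correlation redundancy dropping (the higher-ppm member of a
correlated pair is discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier

from nosomap import grid
from nosomap.classify import ber, lda_fit, lda_predict

METHODS = ("sffs", "chi", "kbest", "lasso", "boruta")
K_RANGE = (3, 20)
BORUTA_DROP_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class FeatureSet:
    """Selected feature-grid column indices with their ppm values."""

    indices: tuple[int, ...]
    method: str
    k: int
    cv_score: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("feature indices must be unique")
        for i in self.indices:
            if not (0 <= i < len(grid.FEATURE_PPM)):
                raise ValueError(f"feature index {i} outside the grid")

    @property
    def ppm_values(self) -> tuple[float, ...]:
        return tuple(float(grid.FEATURE_PPM[i]) for i in self.indices)


def validate_k(k: int) -> int:
    """Experiment-grid feature counts are restricted to 3..20."""
    lo, hi = K_RANGE
    if not (lo <= k <= hi):
        raise ValueError(f"requested k={k} outside {lo}..{hi}")
    return k


def drop_correlated(
    X: np.ndarray,
    candidate_indices: "list[int] | np.ndarray",
    threshold: float = 0.80,
) -> list[int]:
    """Iteratively drop the higher-ppm member of pairs with r > threshold.

    Candidates are column indices on the feature grid (lower column index
    = higher ppm).  Pairs are scanned in descending-ppm order; the left
    (higher-ppm) feature of the first offending pair is removed, and the
    scan restarts until no pair exceeds the threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    cols = sorted(int(i) for i in candidate_indices)  # descending ppm
    sub = X[:, cols]
    sd = sub.std(axis=0)
    ok = sd > 0
    corr = np.zeros((len(cols), len(cols)))
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(sub[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = corr_ok
    np.fill_diagonal(corr, 0.0)  # constant features stay uncorrelated

    # scanning pairs in descending-ppm order; dropping position ai leaves
    # all earlier (already clean) pairs untouched, so no restart is needed
    retained = list(range(len(cols)))
    ai = 0
    while ai < len(retained):
        dropped = False
        for bi in range(ai + 1, len(retained)):
            if corr[retained[ai], retained[bi]] > threshold:
                del retained[ai]  # higher-ppm member of the pair
                dropped = True
                break
        if not dropped:
            ai += 1
    return [cols[i] for i in retained]


def _cv_balanced_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    indices: list[int],
    folds: list[tuple[np.ndarray, np.ndarray]],
    classes: list[str],
) -> float:
    scores = []
    for train_idx, test_idx in folds:
        model = lda_fit(X[np.ix_(train_idx, indices)], y[train_idx])
        _, pred = lda_predict(model, X[np.ix_(test_idx, indices)])
        scores.append(1.0 - ber(y[test_idx], pred, classes))
    return float(np.mean(scores))


def sffs_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    cv_folds: int = 5,
    seed: int = 0,
    candidates: "list[int] | None" = None,
    drop_threshold: float | None = 0.80,
) -> FeatureSet:
    """Sequential floating forward selection with an LDA wrapper.

    Greedy additions maximizing cross-validated balanced accuracy, with
    conditional backward removals whenever dropping a feature improves on
    the best score previously seen at the smaller subset size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < cv_folds:
        raise ValueError("a class has fewer members than cv folds")
    if candidates is None:
        candidates = list(range(X.shape[1]))
        if drop_threshold is not None:
            candidates = drop_correlated(X, candidates, drop_threshold)
    candidates = [int(c) for c in candidates]
    if k > len(candidates):
        raise ValueError("k exceeds candidate feature count")

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]

    def crit(subset: list[int]) -> float:
        return _cv_balanced_accuracy(X, y, subset, folds, classes)

    # CV-score ties (easy problems saturate at 1.0) are broken by the
    # univariate F statistic, steering ties toward the most prominent
    # class-discriminating peaks
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.nan_to_num(f_classif(X, y)[0])

    current: list[int] = []
    best_at_size: dict[int, tuple[float, list[int]]] = {}
    while len(current) < k:
        # forward step
        best_score, best_feat = -np.inf, None
        for f in candidates:
            if f in current:
                continue
            s = crit(current + [f])
            if s > best_score or (
                s == best_score and f_stat[f] > f_stat[best_feat]
            ):
                best_score, best_feat = s, f
        current = current + [best_feat]
        size = len(current)
        if size not in best_at_size or best_score > best_at_size[size][0]:
            best_at_size[size] = (best_score, list(current))
        # floating backward steps
        while len(current) > 2:
            size = len(current)
            best_rm_score, best_rm = -np.inf, None
            for f in current:
                s = crit([g for g in current if g != f])
                if s > best_rm_score:
                    best_rm_score, best_rm = s, f
            smaller = size - 1
            prev = best_at_size.get(smaller, (-np.inf, None))[0]
            if best_rm_score > prev:
                current = [g for g in current if g != best_rm]
                best_at_size[smaller] = (best_rm_score, list(current))
            else:
                break

    score, subset = best_at_size[k]
    return FeatureSet(
        indices=tuple(subset), method="sffs", k=k, cv_score=score
    )


def _boruta_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 100,
    alpha: float = 0.05,
    n_estimators: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shadow-feature RF procedure; returns (confirmed mask, hit counts)."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    for it in range(n_iter):
        shadows = X.copy()
        for j in range(p):
            shadows[:, j] = rng.permutation(shadows[:, j])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(np.hstack([X, shadows]), y)
        imp = rf.feature_importances_
        real, shadow = imp[:p], imp[p:]
        hits += real > shadow.max()
    # one-sided binomial test: more hits than chance at level alpha
    confirmed = binom.sf(hits - 1, n_iter, 0.5) < alpha
    return confirmed, hits


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    k: int | None = None,
    drop_threshold: float = 0.80,
    params: dict | None = None,
) -> FeatureSet:
    """Rank features with a filter/embedded/Boruta method, take the top-k,
    then drop correlated ones (fewer than k may remain)."""
    params = dict(params or {})
    seed = int(params.pop("seed", 0))
    y = np.asarray(y)
    if method == "sffs":
        return sffs_select(
            X, y, k, seed=seed, drop_threshold=drop_threshold, **params
        )
    if method == "chi":
        shifted = X - np.minimum(X.min(axis=0), 0.0)[None, :]
        stat, _ = chi2(shifted, y)
        order = np.argsort(-np.nan_to_num(stat))
    elif method == "kbest":
        stat, _ = f_classif(X, y)
        order = np.argsort(-np.nan_to_num(stat))
    elif method == "lasso":
        C = float(params.pop("C", 1.0))
        clf = OneVsRestClassifier(
            LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", random_state=seed,
                max_iter=2000,
            )
        )
        clf.fit(X, y)
        coef = np.vstack([est.coef_ for est in clf.estimators_])
        weight = np.max(np.abs(coef), axis=0)
        nonzero = np.flatnonzero(weight > 0)
        order = nonzero[np.argsort(-weight[nonzero])]
    elif method == "boruta":
        confirmed, hits = _boruta_rank(X, y, seed=seed, **params)
        eligible = np.flatnonzero(confirmed)
        if eligible.size == 0:  # fall back to hit-count ranking
            eligible = np.arange(X.shape[1])
        order = eligible[np.argsort(-hits[eligible], kind="stable")]
    else:
        raise ValueError(f"unknown feature selection method {method!r}")

    top = order.tolist() if k is None else order[:k].tolist()
    retained = drop_correlated(X, top, drop_threshold)
    return FeatureSet(
        indices=tuple(retained),
        method=method,
        k=k if k is not None else len(retained),
    )
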