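"""Voxel quality control: SNR thresholding and convex-NMF artifact screening.

Convex NMF follows the rows-as-spectra transpose of Ding, Li & Jordan's
formulation: X ~= G W^T X with W, G >= 0, so each extracted source is a
convex combination of observed spectra.  On min-shifted (nonnegative)
input the multiplicative updates are monotone in the reconstruction
error, which is asserted on every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from nosomap import grid
from nosomap.processing import CanonicalSpectrum

SNR_THRESHOLD = 10.0

STATUS_KEPT = "kept"
STATUS_SNR = "discarded_snr"
STATUS_ARTIFACT = "discarded_artifact"
STATUS_VENTRICLE = "excluded_ventricle"
STATUSES = (STATUS_KEPT, STATUS_SNR, STATUS_ARTIFACT, STATUS_VENTRICLE)


def estimate_snr(spectrum: CanonicalSpectrum | np.ndarray) -> float:
    """(max - median) of [0.5, 4.1] ppm over the noise SD of [-2.7, -1.0]."""
    values = (
        spectrum.values
        if isinstance(spectrum, CanonicalSpectrum)
        else np.asarray(spectrum, dtype=np.float64)
    )
    signal = values[grid.SNR_SIGNAL_INDICES]
    noise_sd = float(np.std(values[grid.SNR_NOISE_INDICES]))
    if noise_sd == 0.0:
        raise ValueError("zero noise SD in the [-2.7, -1.0] ppm region")
    return float((signal.max() - np.median(signal)) / noise_sd)


@dataclass
class CNMFModel:
    """Fitted convex NMF factorization."""

    k: int
    sources: np.ndarray  # (k, p), unit L2 norm each
    mixing: np.ndarray  # (n, k), nonnegative
    objective_trace: np.ndarray
    shifts: np.ndarray  # per-spectrum min-shift applied to make X nonneg
    artifact_flags: np.ndarray | None = None  # (k,) bool, set by label_sources

    def winning_sources(self) -> np.ndarray:
        """Argmax of each spectrum's mixing vector (ties: lowest index)."""
        return np.argmax(self.mixing, axis=1)


def nonneg_shift(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift each row by its minimum so all entries are nonnegative."""
    X = np.asarray(X, dtype=np.float64)
    shifts = np.minimum(X.min(axis=1), 0.0)
    return X - shifts[:, None], -shifts


def cnmf_fit(
    X: np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> CNMFModel:
    """Fit a k-source convex NMF to nonnegative spectra rows.

    Rows of *X* must already be nonnegative (see :func:`nonneg_shift`);
    negative input is shifted here and the shift recorded.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of spectra ({n})")
    X, shifts = nonneg_shift(X)

    A = X @ X.T  # nonnegative Gram matrix
    rng = np.random.default_rng(seed)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    H = np.zeros((n, k))
    H[np.arange(n), labels] = 1.0
    G = H + 0.2
    counts = np.maximum(H.sum(axis=0), 1.0)
    W = (H + 0.2) / counts[None, :]

    norm_x2 = float(np.sum(X * X))

    def objective(W, G):
        # ||X - G W^T X||^2 = tr(A) - 2 tr(G W^T A) + tr(W^T A W G^T G)
        AW = A @ W
        return float(
            norm_x2 - 2.0 * np.sum(G * AW) + np.sum((W.T @ AW) * (G.T @ G))
        )

    eps = 1e-12
    trace = [objective(W, G)]
    for _ in range(max_iter):
        AW = A @ W
        G = G * np.sqrt((AW + eps) / (G @ (W.T @ AW) + eps))
        AG = A @ G
        W = W * np.sqrt((AG + eps) / ((A @ W) @ (G.T @ G) + eps))
        obj = objective(W, G)
        trace.append(obj)
        if trace[-2] - obj < tol * max(trace[-2], eps):
            break

    trace_arr = np.asarray(trace)
    drops = np.diff(trace_arr)
    if np.any(drops > 1e-9 * max(trace_arr[0], 1.0)):
        raise AssertionError("cNMF objective increased during fit")

    sources = W.T @ X  # (k, p) convex combinations of spectra
    norms = np.linalg.norm(sources, axis=1)
    norms[norms == 0] = 1.0
    sources = sources / norms[:, None]
    mixing = G * norms[None, :]
    return CNMFModel(
        k=k,
        sources=sources,
        mixing=mixing,
        objective_trace=trace_arr,
        shifts=shifts,
    )


def label_sources(
    model: CNMFModel,
    templates: dict[str, np.ndarray] | None = None,
    manual: dict[int, bool] | None = None,
    corr_threshold: float = 0.3,
) -> np.ndarray:
    """Flag artifactual sources; sets ``model.artifact_flags``.

    Heuristic: a source is artifactual when its median-centered pattern
    has |min| > |max| (flipped-down shape) or when it correlates < 0.3
    with every class template.  *manual* overrides win.
    """
    flags = np.zeros(model.k, dtype=bool)
    for i, src in enumerate(model.sources):
        centered = src - np.median(src)
        flipped = abs(centered.min()) > abs(centered.max())
        uncorrelated = False
        if templates:
            uncorrelated = True
            for tpl in templates.values():
                if np.std(src) > 0 and np.std(tpl) > 0:
                    r = float(np.corrcoef(src, tpl)[0, 1])
                    if r >= corr_threshold:
                        uncorrelated = False
                        break
        flags[i] = flipped or uncorrelated
    if manual:
        for idx, val in manual.items():
            flags[idx] = bool(val)
    model.artifact_flags = flags
    return flags


@dataclass
class QCResult:
    """Per-voxel keep/discard decision with reason."""

    status: np.ndarray  # str array over STATUSES
    snr: np.ndarray
    winning_source: np.ndarray  # int, -1 where not applicable

    def __post_init__(self) -> None:
        if not (len(self.status) == len(self.snr) == len(self.winning_source)):
            raise ValueError("QCResult arrays must have equal length")

    @property
    def kept(self) -> np.ndarray:
        return self.status == STATUS_KEPT

    @property
    def excluded(self) -> np.ndarray:
        return self.status != STATUS_KEPT

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.status == s)) for s in STATUSES}


def qc_screen(
    feature_matrix: np.ndarray,
    canonical_matrix: np.ndarray,
    model: CNMFModel,
    mask: np.ndarray | None = None,
    snr_threshold: float = SNR_THRESHOLD,
) -> QCResult:
    """Screen voxel spectra: ventricles out, then SNR < threshold, then
    winning-source artifact screening (keep-at-threshold boundary)."""
    n = feature_matrix.shape[0]
    if canonical_matrix.shape[0] != n:
        raise ValueError("feature/canonical spectra count mismatch")
    if mask is not None and len(mask) != n:
        raise ValueError("mask/spectra dimension mismatch")
    if model.artifact_flags is None:
        raise ValueError("cNMF model sources not labeled; run label_sources")

    status = np.full(n, STATUS_KEPT, dtype=object)
    snr = np.array([estimate_snr(canonical_matrix[i]) for i in range(n)])
    Xs, _ = nonneg_shift(feature_matrix)
    # mixing of each spectrum against the fitted sources (NNLS-free
    # projection: sources are unit-norm; use nonneg least-squares fallback
    # only if the model was fit on different data)
    if model.mixing.shape[0] == n:
        winning = model.winning_sources()
    else:
        coeffs = np.clip(Xs @ model.sources.T, 0.0, None)
        winning = np.argmax(coeffs, axis=1)

    for i in range(n):
        if mask is not None and mask[i] == "ventricle":
            status[i] = STATUS_VENTRICLE
        elif snr[i] < snr_threshold:
            status[i] = STATUS_SNR
        elif model.artifact_flags[winning[i]]:
            status[i] = STATUS_ARTIFACT

    winning_out = winning.astype(int).copy()
    winning_out[status == STATUS_VENTRICLE] = -1
    winning_out[status == STATUS_SNR] = -1
    return QCResult(status=status, snr=snr, winning_source=winning_out)
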