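"""Nosological maps: voxel-wise classification, STI/Dice scoring, rendering.

Color convention: blue = normal brain, red = aggressive, green = lgg,
yellow = mm; excluded voxels render black at 0.5 alpha; color intensity
encodes the winning-class posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from nosomap.classify import ClassTask, SUPERCLASS, auc_ovr, ber
from nosomap.qc import QCResult

CLASS_COLORS = {
    "no": (0.0, 0.0, 1.0),
    "agg": (1.0, 0.0, 0.0),
    "lgg": (0.0, 1.0, 0.0),
    "mm": (1.0, 1.0, 0.0),
}
EXCLUDED_COLOR = (0.0, 0.0, 0.0)
EXCLUDED_ALPHA = 0.5


@dataclass
class NosologicalMap:
    """Per-voxel winning class / posterior / exclusion reason."""

    dims: tuple[int, int, int]
    task: ClassTask
    winning: np.ndarray  # object array: class label or None
    posterior: np.ndarray  # float, NaN where excluded
    exclusion_reason: np.ndarray  # object array: reason or None
    colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(CLASS_COLORS)
    )

    def __post_init__(self) -> None:
        n = int(np.prod(self.dims))
        for arr in (self.winning, self.posterior, self.exclusion_reason):
            if len(arr) != n:
                raise ValueError("map arrays must match dims product")
        task_colors = {c: self.colors[c] for c in self.task.classes}
        if len(set(task_colors.values())) != len(task_colors):
            raise ValueError("color map must be a bijection on task classes")

    @property
    def excluded(self) -> np.ndarray:
        return np.array([w is None for w in self.winning])


def classify_grid(
    model: Any,
    feature_matrix: np.ndarray,
    qc: QCResult,
    task: ClassTask,
    dims: tuple[int, int, int],
) -> NosologicalMap:
    """Classify kept voxels; excluded ones carry their QC reason."""
    n = feature_matrix.shape[0]
    if len(qc.status) != n or int(np.prod(dims)) != n:
        raise ValueError("qc/spectra/dims dimension mismatch")
    winning = np.full(n, None, dtype=object)
    posterior = np.full(n, np.nan)
    reason = np.full(n, None, dtype=object)
    kept = qc.kept
    if kept.any():
        post, pred = model.predict_posteriors(feature_matrix[kept])
        kept_idx = np.flatnonzero(kept)
        winning[kept_idx] = pred
        posterior[kept_idx] = post.max(axis=1)
    for i in np.flatnonzero(~kept):
        reason[i] = str(qc.status[i])
    return NosologicalMap(
        dims=dims,
        task=task,
        winning=winning,
        posterior=posterior,
        exclusion_reason=reason,
    )


def _task_class_of(case_class: str, task: ClassTask) -> str:
    mapped = task.map_label(case_class)
    if mapped is None:
        raise ValueError(
            f"case class {case_class!r} not part of task {task.name!r}"
        )
    return mapped


def sti(
    nmap: NosologicalMap, truth_mask: np.ndarray, case_class: str
) -> float:
    """Solid Tumor Index: correctly classified solid voxels over
    non-excluded solid voxels."""
    target = _task_class_of(case_class, nmap.task)
    solid = np.asarray(truth_mask) == "solid"
    if not solid.any():
        raise ValueError("empty solid region")
    excluded = nmap.excluded
    denom = int(np.sum(solid & ~excluded))
    if denom == 0:
        raise ValueError("all solid-region voxels excluded")
    correct = int(np.sum(solid & ~excluded & (nmap.winning == target)))
    return correct / denom


STI_SUCCESS_THRESHOLD = 0.50


def default_pairing(task: ClassTask, case_class: str) -> dict[str, str]:
    """Truth-region -> predicted-class pairing for Dice.

    normal<->no, solid<->the case's task class; the abnormal ring pairs
    with lgg in the 4-class task and with the case class in the 3-class
    task.
    """
    target = _task_class_of(case_class, task)
    pairing = {"normal": "no", "solid": target}
    pairing["abnormal"] = "lgg" if "lgg" in task.classes else target
    return pairing


def dice(
    nmap: NosologicalMap,
    truth_mask: np.ndarray,
    pairing: dict[str, str],
) -> dict[str, float | None]:
    """Dice 2|A&B|/(|A|+|B|) per paired region over non-excluded voxels.

    Empty-vs-empty comparisons are reported as None (missing), not 0.
    """
    truth = np.asarray(truth_mask)
    valid = ~nmap.excluded
    out: dict[str, float | None] = {}
    for region, pred_class in pairing.items():
        A = (truth == region) & valid
        B = (nmap.winning == pred_class) & valid
        total = int(A.sum() + B.sum())
        if total == 0:
            out[region] = None
        else:
            out[region] = 2.0 * int((A & B).sum()) / total
    return out


def grid_metrics(
    nmap: NosologicalMap,
    truth_mask: np.ndarray,
    case_class: str,
    posteriors: np.ndarray | None = None,
) -> dict[str, Any]:
    """Per-grid BER and per-class AUC on solid + normal voxels only.

    Abnormal, ventricle, and QC-excluded voxels are omitted.  BER is
    computed over the classes present among the eligible voxels; AUC per
    class needs *posteriors* (full per-class posterior matrix aligned to
    the grid) and is reported as None for classes without both positives
    and negatives.
    """
    truth = np.asarray(truth_mask)
    target = _task_class_of(case_class, nmap.task)
    eligible = (
        np.isin(truth, ("solid", "normal"))
        & ~nmap.excluded
    )
    if not eligible.any():
        raise ValueError("no eligible voxels for grid metrics")
    y_true = np.where(truth[eligible] == "solid", target, "no")
    y_pred = nmap.winning[eligible].astype(str)
    present = sorted(set(y_true.tolist()))
    out: dict[str, Any] = {
        "ber": ber(y_true, y_pred, present),
        "n_eligible": int(eligible.sum()),
        "classes": present,
    }
    if posteriors is not None:
        aucs: dict[str, float | None] = {}
        for ci, c in enumerate(nmap.task.classes):
            if c in present and len(present) > 1:
                aucs[c] = auc_ovr(y_true, posteriors[eligible, ci], c)
            else:
                aucs[c] = None
        out["auc"] = aucs
    return out


def per_slice_metrics(
    nmap: NosologicalMap,
    truth_mask: np.ndarray,
    case_class: str,
) -> list[dict[str, Any]]:
    """One grid_metrics entry per z slice (multi-slice phantoms)."""
    nx, ny, nz = nmap.dims
    per = nx * ny
    results = []
    for z in range(nz):
        sl = slice(z * per, (z + 1) * per)
        sub = NosologicalMap(
            dims=(nx, ny, 1),
            task=nmap.task,
            winning=nmap.winning[sl],
            posterior=nmap.posterior[sl],
            exclusion_reason=nmap.exclusion_reason[sl],
        )
        try:
            entry = grid_metrics(sub, np.asarray(truth_mask)[sl], case_class)
        except ValueError:
            entry = {"ber": None, "n_eligible": 0, "classes": []}
        entry["z"] = z
        results.append(entry)
    return results


def render_map(
    nmap: NosologicalMap,
    z: int = 0,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """RGBA uint8 raster of one slice; intensity = winning posterior.

    With *background* (ny, nx) grayscale in [0, 1], voxel colors are
    alpha-blended over it.  Deterministic.
    """
    nx, ny, nz = nmap.dims
    if not (0 <= z < nz):
        raise ValueError(f"slice {z} outside 0..{nz - 1}")
    rgba = np.zeros((ny, nx, 4), dtype=np.float64)
    for y in range(ny):
        for x in range(nx):
            i = (z * ny + y) * nx + x
            w = nmap.winning[i]
            if w is None:
                rgba[y, x, :3] = EXCLUDED_COLOR
                rgba[y, x, 3] = EXCLUDED_ALPHA
            else:
                intensity = float(nmap.posterior[i])
                rgba[y, x, :3] = np.array(nmap.colors[w]) * intensity
                rgba[y, x, 3] = 1.0
    if background is not None:
        bg = np.asarray(background, dtype=np.float64)
        if bg.shape != (ny, nx):
            raise ValueError("background shape must be (ny, nx)")
        alpha = rgba[:, :, 3:4]
        rgba[:, :, :3] = alpha * rgba[:, :, :3] + (1 - alpha) * bg[:, :, None]
        rgba[:, :, 3] = 1.0
    return np.clip(np.round(rgba * 255), 0, 255).astype(np.uint8)
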