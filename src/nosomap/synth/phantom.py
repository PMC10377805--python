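"""Multivoxel phantom simulation: spatial grids with ground-truth masks.

Voxel order is row-major over (z, y, x): flat index = (z * ny + y) * nx + x.
Truth labels are the four region labels used for mask ground truth:
normal / solid / abnormal / ventricle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from nosomap.synth.fid import FID, AcquisitionConfig, DEFAULT_ACQ, simulate_fid
from nosomap.synth.profiles import (
    ArtifactSpec,
    ClassProfile,
    CLASS_LABELS,
    abnormal_profile,
    blend_profiles,
    build_class_profiles,
    ventricle_profile,
)

TRUTH_LABELS = ("normal", "solid", "abnormal", "ventricle")

#: Spatial bleed direction: more malignant tissue contaminates its
#: surroundings, not the other way around.
_PRIORITY = {"solid": 3, "abnormal": 2, "normal": 1, "ventricle": 0}


@dataclass(frozen=True)
class PhantomGeometry:
    """Elliptical solid core + surrounding abnormal ring, in voxel units.

    ``center`` defaults to the grid center; radii are fractions of the
    smaller in-plane half-dimension, so the default geometry fits any grid.
    An optional ventricle patch is an axis-aligned rectangle
    ((x0, x1), (y0, y1)), inclusive bounds.
    """

    center: tuple[float, float] | None = None
    solid_radius_frac: float = 0.30
    abnormal_radius_frac: float = 0.55
    ventricle: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.solid_radius_frac < self.abnormal_radius_frac):
            raise ValueError(
                "need 0 < solid_radius_frac < abnormal_radius_frac"
            )
        if self.abnormal_radius_frac > 1.0:
            raise ValueError("abnormal_radius_frac must be <= 1")


@dataclass
class Phantom:
    """Spatial array of voxel FIDs plus ground truth."""

    dims: tuple[int, int, int]  # (nx, ny, nz)
    case_class: str
    fids: list[FID]
    truth_mask: np.ndarray  # flat array of TRUTH_LABELS strings
    artifact_log: list[dict[str, Any]]
    seed: int

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def label_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.truth_mask, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def flat_index(self, x: int, y: int, z: int) -> int:
        nx, ny, _ = self.dims
        return (z * ny + y) * nx + x


def _label_grid(
    dims: tuple[int, int, int], case_class: str, geometry: PhantomGeometry
) -> np.ndarray:
    nx, ny, nz = dims
    labels = np.full((nz, ny, nx), "normal", dtype=object)
    if case_class != "no":
        cx, cy = geometry.center or ((nx - 1) / 2.0, (ny - 1) / 2.0)
        half = min(nx, ny) / 2.0
        r_solid = geometry.solid_radius_frac * half
        r_abn = geometry.abnormal_radius_frac * half
        if r_solid >= max(nx, ny) or not (
            0 <= cx < nx and 0 <= cy < ny
        ):
            raise ValueError("geometry exceeds dims")
        xs = np.arange(nx)[None, :]
        ys = np.arange(ny)[:, None]
        dist = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
        plane = np.full((ny, nx), "normal", dtype=object)
        plane[dist <= r_abn] = "abnormal"
        plane[dist <= r_solid] = "solid"
        if not (plane == "solid").any():
            raise ValueError("geometry produces empty solid region")
        # multi-slice phantoms shrink the lesion toward the outer slices
        for z in range(nz):
            if nz == 1:
                scale = 1.0
            else:
                scale = 1.0 - 0.6 * abs(z - (nz - 1) / 2.0) / ((nz - 1) / 2.0)
            pl = np.full((ny, nx), "normal", dtype=object)
            pl[dist <= r_abn * scale] = "abnormal"
            pl[dist <= max(r_solid * scale, 1.0)] = "solid"
            labels[z] = pl
    if geometry.ventricle is not None:
        (x0, x1), (y0, y1) = geometry.ventricle
        if not (0 <= x0 <= x1 < nx and 0 <= y0 <= y1 < ny):
            raise ValueError("ventricle patch exceeds dims")
        labels[:, y0 : y1 + 1, x0 : x1 + 1] = "ventricle"
    return labels


def simulate_mv_phantom(
    dims: tuple[int, int, int],
    case_class: str,
    geometry: PhantomGeometry | None = None,
    artifacts: ArtifactSpec | None = None,
    seed: int = 0,
    snr_range: tuple[float, float] = (15.0, 40.0),
    profiles: dict[str, ClassProfile] | None = None,
    acq: AcquisitionConfig = DEFAULT_ACQ,
) -> Phantom:
    """Simulate an MV phantom grid for one case.

    Each voxel's FID is drawn from the tissue profile of its true label;
    voxels at region boundaries use a 0.5/0.5 partial-volume blend with
    the differing neighbor's profile ("voxel bleeding").
    """
    nx, ny, nz = dims
    if min(dims) < 1:
        raise ValueError("dims must be positive")
    if case_class not in CLASS_LABELS:
        raise ValueError(f"unknown case class {case_class!r}")
    geometry = geometry or PhantomGeometry()
    profiles = profiles or build_class_profiles()

    labels = _label_grid(dims, case_class, geometry)
    tissue: dict[str, ClassProfile] = {
        "normal": profiles["no"],
        "solid": profiles[case_class] if case_class != "no" else profiles["no"],
        "abnormal": (
            abnormal_profile(case_class, profiles)
            if case_class != "no"
            else profiles["no"]
        ),
        "ventricle": ventricle_profile(),
    }

    rng = np.random.default_rng(seed)
    fids: list[FID] = []
    log: list[dict[str, Any]] = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lbl = labels[z, y, x]
                prof = tissue[lbl]
                # partial-volume mixing: lesion signal bleeds outward, so
                # the boundary voxel on the lower-priority side takes a
                # 0.5 blend with its more-malignant neighbor
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    xx, yy = x + dx, y + dy
                    if 0 <= xx < nx and 0 <= yy < ny:
                        nb = labels[z, yy, xx]
                        if _PRIORITY[nb] > _PRIORITY[lbl]:
                            prof = blend_profiles(
                                prof, tissue[nb], 0.5, label=lbl
                            )
                            break
                snr = float(rng.uniform(*snr_range))
                fid, rec = simulate_fid(
                    prof, snr, artifacts, seed=rng, acq=acq
                )
                fids.append(fid)
                log.append(rec)

    return Phantom(
        dims=dims,
        case_class=case_class,
        fids=fids,
        truth_mask=labels.reshape(-1),
        artifact_log=log,
        seed=seed,
    )
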