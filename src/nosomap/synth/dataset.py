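"""Labeled single-voxel training-set simulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from nosomap.synth.fid import FID, AcquisitionConfig, DEFAULT_ACQ, simulate_fid
from nosomap.synth.profiles import (
    ArtifactSpec,
    ClassProfile,
    CLASS_LABELS,
    SUPERCLASS,
    build_class_profiles,
)

#: Training-set class counts of the reference SV database
#: (22 normal, 62 meningioma, 123 aggressive = 85 gb + 38 me, 35 lgg).
INTERPRET_COUNTS = {"no": 22, "mm": 62, "agg": 123, "lgg": 35}
_AGG_SPLIT = {"gb": 85, "me": 38}  # proportions used to split an "agg" request


@dataclass
class SVDataset:
    """A list of simulated FIDs with true class labels."""

    fids: list[FID]
    labels: list[str]
    artifact_records: list[dict[str, Any]]
    seed: int

    def __len__(self) -> int:
        return len(self.fids)

    def superclass_labels(self) -> list[str]:
        """Labels with gb/me collapsed onto agg."""
        return [SUPERCLASS.get(lbl, lbl) for lbl in self.labels]


def _split_agg(n: int) -> dict[str, int]:
    total = sum(_AGG_SPLIT.values())
    gb = int(round(n * _AGG_SPLIT["gb"] / total))
    return {"gb": gb, "me": n - gb}


def simulate_sv_dataset(
    n_per_class: dict[str, int],
    snr_range: tuple[float, float] = (15.0, 40.0),
    seed: int = 0,
    profiles: dict[str, ClassProfile] | None = None,
    artifacts: ArtifactSpec | None = None,
    acq: AcquisitionConfig = DEFAULT_ACQ,
) -> SVDataset:
    """Simulate a labeled SV set.

    Keys of *n_per_class* may be individual classes (mm, gb, me, lgg, no)
    or the superclass ``agg``, which is split gb:me in the reference
    database's 85:38 proportion.  ``INTERPRET_COUNTS`` reproduces the
    reference class imbalance.
    """
    if not n_per_class:
        raise ValueError("empty class list")
    counts: dict[str, int] = {}
    for label, n in n_per_class.items():
        if n < 1:
            raise ValueError(f"n_per_class[{label!r}] must be >= 1")
        if label == "agg":
            for sub, m in _split_agg(n).items():
                counts[sub] = counts.get(sub, 0) + m
        elif label in CLASS_LABELS:
            counts[label] = counts.get(label, 0) + n
        else:
            raise ValueError(f"unknown class name {label!r}")

    profiles = profiles or build_class_profiles()
    rng = np.random.default_rng(seed)
    fids: list[FID] = []
    labels: list[str] = []
    records: list[dict[str, Any]] = []
    for label in sorted(counts):  # sorted for determinism
        for _ in range(counts[label]):
            snr = float(rng.uniform(*snr_range))
            fid, rec = simulate_fid(
                profiles[label], snr, artifacts, seed=rng, acq=acq
            )
            fids.append(fid)
            labels.append(label)
            records.append(rec)
    return SVDataset(fids=fids, labels=labels, artifact_records=records,
                     seed=seed if isinstance(seed, int) else -1)
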