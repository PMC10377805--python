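"""Noiseless class-template spectra on the feature grid.

Used by source labelling (correlation heuristic) and sanity checks.
Templates are computed by pushing an artifact-free, noise-free rendering
of each class profile through the canonicalization chain (HLSVD skipped:
there is nothing to remove and the exact Lorentzian model makes it a
no-op up to numerics).
"""

from __future__ import annotations

import numpy as np

from nosomap.processing import (
    ProcessingConfig,
    process_pipeline,
)
from nosomap.synth.fid import DEFAULT_ACQ, FID, profile_fid_samples
from nosomap.synth.profiles import ClassProfile, build_class_profiles

_TEMPLATE_CONFIG = ProcessingConfig(hlsvd_enabled=False, align_enabled=False)


def class_template(profile: ClassProfile) -> np.ndarray:
    """Feature-grid rendering of one class profile (unit L2 norm)."""
    samples = profile_fid_samples(profile, DEFAULT_ACQ)
    fid = FID(
        samples=samples,
        dwell_time=DEFAULT_ACQ.dwell_time,
        transmitter_frequency=DEFAULT_ACQ.transmitter_frequency,
        reference_ppm=DEFAULT_ACQ.reference_ppm,
    )
    return process_pipeline(fid, _TEMPLATE_CONFIG).feature.values


def class_templates(
    profiles: dict[str, ClassProfile] | None = None,
) -> dict[str, np.ndarray]:
    profiles = profiles or build_class_profiles()
    return {label: class_template(p) for label, p in profiles.items()}
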