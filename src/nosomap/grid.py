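"""Canonical 512-point ppm grid shared by every pipeline stage.

The interchange grid runs from 7.1 ppm (index 0) down to -2.7 ppm
(index 511): ``ppm(i) = 7.1 - i * (9.8 / 511)``.  All band constants
below are expressed on this grid.
"""

from __future__ import annotations

import numpy as np

N_POINTS = 512
PPM_MAX = 7.1
PPM_MIN = -2.7
PPM_STEP = (PPM_MAX - PPM_MIN) / (N_POINTS - 1)

#: Descending ppm axis, index 0 at 7.1 ppm.
PPM_AXIS = PPM_MAX - np.arange(N_POINTS) * PPM_STEP
PPM_AXIS.setflags(write=False)

WATER_PPM = 4.7
#: Residual-water band zeroed on the canonical spectrum.
WATER_ZERO_BAND = (4.2, 5.1)
#: HLSVD water-removal frequency window.
HLSVD_WATER_BAND = (4.31, 5.11)
#: Clinically classified sub-range, re-extracted and renormalized.
CLINICAL_BAND = (0.0, 4.2)
#: Signal band used by the SNR estimator.
SNR_SIGNAL_BAND = (0.5, 4.1)
#: Signal-free band used to estimate the noise SD.
SNR_NOISE_BAND = (-2.7, -1.0)

_EPS = 1e-9


def band_indices(lo: float, hi: float) -> np.ndarray:
    """Canonical-grid indices i with lo <= ppm(i) <= hi (ascending i)."""
    mask = (PPM_AXIS >= lo - _EPS) & (PPM_AXIS <= hi + _EPS)
    return np.flatnonzero(mask)


def nearest_index(ppm: float) -> int:
    """Index of the canonical grid point closest to *ppm*."""
    return int(np.argmin(np.abs(PPM_AXIS - ppm)))


WATER_ZERO_INDICES = band_indices(*WATER_ZERO_BAND)
CLINICAL_INDICES = band_indices(*CLINICAL_BAND)
SNR_SIGNAL_INDICES = band_indices(*SNR_SIGNAL_BAND)
SNR_NOISE_INDICES = band_indices(*SNR_NOISE_BAND)

#: ppm values of the clinical feature grid ([0, 4.2] extraction).
FEATURE_PPM = PPM_AXIS[CLINICAL_INDICES]
FEATURE_PPM.setflags(write=False)
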