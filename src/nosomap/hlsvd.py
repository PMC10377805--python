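"""Time-domain water removal via Hankel-matrix SVD (HTLS estimation).

Fits the FID as a sum of damped complex sinusoids using the state-space
method: SVD of the Hankel data matrix, signal poles from the
shift-invariance of the truncated left singular subspace, complex
amplitudes by linear least squares.  Components whose frequency falls in
the water region are subtracted from the FID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel, lstsq, svd

from nosomap.grid import HLSVD_WATER_BAND
from nosomap.synth.fid import FID

#: Max FID samples used to build the Hankel matrix.
_MAX_HANKEL_SAMPLES = 512


@dataclass(frozen=True)
class DampedSinusoid:
    """One estimated component: x[n] = amplitude * pole**n."""

    frequency_hz: float
    damping: float  # per-sample log-magnitude of the pole (<0 decays)
    amplitude: complex
    ppm: float


def hlsvd_components(
    fid: FID, model_order: int = 25
) -> list[DampedSinusoid]:
    """Estimate *model_order* damped sinusoids from the FID."""
    n_use = min(_MAX_HANKEL_SAMPLES, fid.n_points)
    if fid.n_points < 2 * model_order:
        raise ValueError(
            f"model_order {model_order} too large for {fid.n_points} points"
        )
    x = fid.samples[:n_use]
    rows = n_use // 2
    if rows <= model_order:
        raise ValueError("model_order too large for Hankel dimensions")
    H = hankel(x[:rows], x[rows - 1 : n_use])
    U, _, _ = svd(H, full_matrices=False)
    Uk = U[:, :model_order]
    # shift invariance: Uk[:-1] @ Z ~= Uk[1:]
    Z, *_ = lstsq(Uk[:-1], Uk[1:], lapack_driver="gelsd")
    poles = np.linalg.eigvals(Z)
    # amplitudes over the full record
    n = fid.n_points
    exponents = np.arange(n)[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        V = poles[None, :] ** exponents
    V = np.nan_to_num(V, nan=0.0, posinf=0.0, neginf=0.0)
    amps, *_ = lstsq(V, fid.samples, lapack_driver="gelsd")

    dt = fid.dwell_time
    out = []
    for pole, amp in zip(poles, amps):
        freq_hz = float(np.angle(pole) / (2 * np.pi * dt))
        ppm = fid.reference_ppm + freq_hz / fid.transmitter_frequency
        out.append(
            DampedSinusoid(
                frequency_hz=freq_hz,
                damping=float(np.log(np.abs(pole) + 1e-300)),
                amplitude=complex(amp),
                ppm=ppm,
            )
        )
    return out


def hlsvd_filter(
    fid: FID,
    region: tuple[float, float] = HLSVD_WATER_BAND,
    max_components: int = 10,
    model_order: int = 25,
) -> tuple[FID, list[DampedSinusoid]]:
    """Subtract fitted components whose frequency lies in *region* (ppm).

    At most *max_components* are removed, largest |amplitude| first.
    Returns the residual FID and the removed components.
    """
    lo, hi = region
    components = hlsvd_components(fid, model_order=model_order)
    in_region = [c for c in components if lo <= c.ppm <= hi]
    in_region.sort(key=lambda c: -abs(c.amplitude))
    removed = in_region[:max_components]
    if not removed:
        return fid, []
    n = fid.n_points
    exponents = np.arange(n)
    water = np.zeros(n, dtype=np.complex128)
    for c in removed:
        pole = np.exp(c.damping + 1j * 2 * np.pi * c.frequency_hz * fid.dwell_time)
        water += c.amplitude * pole**exponents
    residual = FID(
        samples=fid.samples - water,
        dwell_time=fid.dwell_time,
        transmitter_frequency=fid.transmitter_frequency,
        reference_ppm=fid.reference_ppm,
    )
    return residual, removed
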