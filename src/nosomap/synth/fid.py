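"""Forward model: class profiles -> complex time-domain FIDs.

A spectrum is a sum of exponentially damped complex sinusoids (Lorentzian
lines in the frequency domain) referenced to water at 4.7 ppm, plus
complex white noise scaled so the frequency-domain peak height over noise
SD equals the requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from nosomap.grid import (
    PPM_MIN,
    PPM_MAX,
    WATER_PPM,
    SNR_SIGNAL_BAND,
)
from nosomap.synth.profiles import ArtifactSpec, ClassProfile, Resonance


@dataclass(frozen=True)
class AcquisitionConfig:
    """Simulated acquisition metadata (defaults: 1024 points, 2404 Hz)."""

    n_points: int = 1024
    bandwidth_hz: float = 2404.0
    transmitter_frequency: float = 127.7  # MHz
    reference_ppm: float = WATER_PPM

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.bandwidth_hz

    def __post_init__(self) -> None:
        span = self.bandwidth_hz / self.transmitter_frequency  # ppm
        lo = self.reference_ppm - span / 2.0
        hi = self.reference_ppm + span / 2.0
        if lo > PPM_MIN or hi < PPM_MAX:
            raise ValueError(
                f"acquisition ppm coverage [{lo:.2f}, {hi:.2f}] does not "
                f"contain [{PPM_MIN}, {PPM_MAX}]"
            )


DEFAULT_ACQ = AcquisitionConfig()


@dataclass(frozen=True)
class FID:
    """Complex free induction decay plus acquisition metadata."""

    samples: np.ndarray
    dwell_time: float
    transmitter_frequency: float  # MHz
    reference_ppm: float = WATER_PPM

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.complex128)
        )

    @property
    def n_points(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time


def _component(
    times: np.ndarray,
    center_ppm: float,
    linewidth_ppm: float,
    amplitude: float,
    acq: AcquisitionConfig,
) -> np.ndarray:
    """Damped complex sinusoid for one Lorentzian line."""
    f0 = acq.transmitter_frequency  # MHz -> ppm * MHz = Hz
    freq_hz = (center_ppm - acq.reference_ppm) * f0
    fwhm_hz = linewidth_ppm * f0
    damping = np.pi * fwhm_hz
    return amplitude * np.exp((1j * 2 * np.pi * freq_hz - damping) * times)


#: Broad macromolecule/lipid baseline humps (center ppm, FWHM ppm, weight),
#: scaled by a profile's baseline_level.  Short-TE in vivo spectra carry a
#: substantial baseline across [0.7, 3.3] ppm; it is what keeps a
#: flipped-down spectrum's (max - median) SNR statistic high enough to
#: pass the SNR filter, as observed in real data.
BASELINE_HUMPS = (
    (0.90, 0.55, 1.00),
    (1.35, 0.55, 0.95),
    (1.90, 0.60, 0.85),
    (2.45, 0.60, 0.75),
    (3.00, 0.55, 0.60),
)


def profile_fid_samples(
    profile: ClassProfile, acq: AcquisitionConfig
) -> np.ndarray:
    """Noiseless FID of a profile (resonances + macromolecule baseline)."""
    times = np.arange(acq.n_points) * acq.dwell_time
    samples = np.zeros(acq.n_points, dtype=np.complex128)
    for r in profile.resonances:
        samples += _component(times, r.center, r.linewidth, r.amplitude, acq)
    if profile.baseline_level > 0:
        for center, lw, weight in BASELINE_HUMPS:
            samples += _component(
                times, center, lw, profile.baseline_level * weight, acq
            )
    return samples


def _noiseless_peak_height(samples: np.ndarray, acq: AcquisitionConfig) -> float:
    """Max real spectrum height in the SNR signal band [0.5, 4.1] ppm."""
    n = len(samples)
    spec = np.fft.fftshift(np.fft.fft(samples))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, acq.dwell_time))
    ppm = acq.reference_ppm + freqs / acq.transmitter_frequency
    lo, hi = SNR_SIGNAL_BAND
    band = (ppm >= lo) & (ppm <= hi)
    return float(np.max(spec.real[band]))


def simulate_fid(
    profile: ClassProfile,
    snr_target: float,
    artifacts: ArtifactSpec | None = None,
    seed: int | np.random.Generator = 0,
    acq: AcquisitionConfig = DEFAULT_ACQ,
    sample_subject: bool = True,
) -> tuple[FID, dict[str, Any]]:
    """Simulate one FID; returns the FID and its artifact record.

    The artifact record maps artifact names to the injected parameters;
    absent keys mean the artifact did not fire.
    """
    if snr_target <= 0:
        raise ValueError("snr_target must be > 0")
    artifacts = artifacts or ArtifactSpec()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    record: dict[str, Any] = {}

    subject = profile.sample(rng) if sample_subject else profile
    samples = profile_fid_samples(subject, acq)
    times = np.arange(acq.n_points) * acq.dwell_time

    if rng.random() < artifacts.residual_water_prob:
        amp = rng.uniform(4.0, 12.0)
        lw = rng.uniform(0.06, 0.12)
        samples += _component(times, WATER_PPM, lw, amp, acq)
        record["residual_water"] = {"amplitude": amp, "linewidth": lw}

    if rng.random() < artifacts.ghosting_prob:
        ghost_ppm = rng.uniform(3.4, 4.1)
        amp = rng.uniform(0.3, 0.8)
        samples += _component(times, ghost_ppm, 0.08, amp, acq)
        record["ghost"] = {"center": ghost_ppm, "amplitude": amp}

    if artifacts.shift_sd > 0:
        shift_ppm = float(rng.normal(0.0, artifacts.shift_sd))
        shift_hz = shift_ppm * acq.transmitter_frequency
        samples = samples * np.exp(1j * 2 * np.pi * shift_hz * times)
        record["shift"] = {"ppm": shift_ppm}

    effective_snr = snr_target
    if rng.random() < artifacts.low_snr_prob:
        effective_snr = float(rng.uniform(2.0, 6.0))
        record["low_snr"] = {"snr_target": effective_snr}

    peak = _noiseless_peak_height(profile_fid_samples(subject, acq), acq)
    if peak <= 0:  # pure-noise degenerate profile
        peak = 1.0
    sigma = peak / (effective_snr * np.sqrt(acq.n_points))
    noise = sigma * (
        rng.standard_normal(acq.n_points)
        + 1j * rng.standard_normal(acq.n_points)
    )
    samples = samples + noise

    if rng.random() < artifacts.flip_prob:
        samples = -samples
        record["flip"] = True

    fid = FID(
        samples=samples,
        dwell_time=acq.dwell_time,
        transmitter_frequency=acq.transmitter_frequency,
        reference_ppm=acq.reference_ppm,
    )
    return fid, record
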