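"""Metabolite resonance templates for the five diagnostic classes.

Amplitudes are informed defaults reproducing the qualitative patterns the
analysis relies on (normal brain: NAA at 2.01 ppm is the highest peak;
aggressive tumors: necrotic pattern with lipids at 0.9/1.28 ppm above NAA;
meningioma: high choline and the 2.38 ppm region; low-grade glioma:
preserved NAA with elevated choline).  Everything is config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from nosomap.grid import PPM_MIN, PPM_MAX

#: Individual diagnostic labels the simulator knows about.
CLASS_LABELS = ("mm", "gb", "me", "lgg", "no")
#: gb and me are distinct profiles mapped to the aggressive superclass.
SUPERCLASS = {"gb": "agg", "me": "agg"}

NAA_PPM = 2.01
CHO_PPM = 3.21
CR_PPM = 3.03
LIP09_PPM = 0.9
LIP13_PPM = 1.28
GLX_MM_PPM = 2.38
MI_PPM = 3.55


@dataclass(frozen=True)
class Resonance:
    """A single Lorentzian line."""

    name: str
    center: float  # ppm
    linewidth: float  # ppm, FWHM
    amplitude: float  # relative height

    def __post_init__(self) -> None:
        if not (PPM_MIN <= self.center <= PPM_MAX):
            raise ValueError(
                f"resonance {self.name!r} center {self.center} outside "
                f"[{PPM_MIN}, {PPM_MAX}] ppm"
            )
        if self.linewidth <= 0:
            raise ValueError(f"resonance {self.name!r} linewidth must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"resonance {self.name!r} amplitude must be >= 0")


@dataclass(frozen=True)
class ClassProfile:
    """Per-class resonance set with between-subject variability."""

    class_label: str
    resonances: tuple[Resonance, ...]
    amplitude_cv: float = 0.15
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        names = {r.name for r in self.resonances}
        for required in ("NAA", "Cho", "Cr"):
            if required not in names:
                raise ValueError(
                    f"profile {self.class_label!r} missing required "
                    f"resonance {required!r}"
                )

    def amplitude_of(self, name: str) -> float:
        for r in self.resonances:
            if r.name == name:
                return r.amplitude
        raise KeyError(name)

    def sample(self, rng: np.random.Generator) -> "ClassProfile":
        """Draw a subject-level profile with log-normal amplitude jitter."""
        if self.amplitude_cv == 0:
            return self
        sigma = self.amplitude_cv
        jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                               size=len(self.resonances))
        res = tuple(
            replace(r, amplitude=r.amplitude * j)
            for r, j in zip(self.resonances, jitter)
        )
        return replace(self, resonances=res)


@dataclass(frozen=True)
class ArtifactSpec:
    """Probabilities and magnitudes of the injected artifact types."""

    flip_prob: float = 0.0
    low_snr_prob: float = 0.0
    residual_water_prob: float = 0.0
    shift_sd: float = 0.0  # ppm
    ghosting_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("flip_prob", "low_snr_prob", "residual_water_prob",
                     "ghosting_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.shift_sd < 0:
            raise ValueError("shift_sd must be >= 0")


NO_ARTIFACTS = ArtifactSpec()


def _triplet(naa, cho, cr, lw=0.05):
    return [
        Resonance("NAA", NAA_PPM, lw, naa),
        Resonance("Cho", CHO_PPM, lw, cho),
        Resonance("Cr", CR_PPM, lw, cr),
    ]


def _default_profiles() -> dict[str, ClassProfile]:
    profiles = {}
    profiles["no"] = ClassProfile(
        "no",
        tuple(
            _triplet(1.0, 0.55, 0.62)
            + [
                Resonance("Cr2", 3.93, 0.05, 0.35),
                Resonance("mI", MI_PPM, 0.06, 0.30),
                Resonance("Glx", GLX_MM_PPM, 0.10, 0.22),
                Resonance("Lip13", LIP13_PPM, 0.09, 0.08),
                Resonance("Lip09", LIP09_PPM, 0.09, 0.06),
            ]
        ),
        baseline_level=5.5,
    )
    # Necrotic pattern: lipids dominate, NAA collapsed.
    profiles["gb"] = ClassProfile(
        "gb",
        tuple(
            _triplet(0.25, 0.70, 0.28)
            + [
                Resonance("Lip13", LIP13_PPM, 0.10, 1.60),
                Resonance("Lip09", LIP09_PPM, 0.10, 1.00),
                Resonance("Glx", GLX_MM_PPM, 0.11, 0.35),
            ]
        ),
        amplitude_cv=0.25,
        baseline_level=6.5,
    )
    profiles["me"] = ClassProfile(
        "me",
        tuple(
            _triplet(0.12, 0.60, 0.18)
            + [
                Resonance("Lip13", LIP13_PPM, 0.10, 1.85),
                Resonance("Lip09", LIP09_PPM, 0.10, 1.25),
            ]
        ),
        amplitude_cv=0.25,
        baseline_level=6.5,
    )
    # High choline, depleted Cr/NAA, prominent 2.38 ppm region.
    profiles["mm"] = ClassProfile(
        "mm",
        tuple(
            _triplet(0.10, 1.20, 0.15)
            + [
                Resonance("Ala", 1.47, 0.07, 0.30),
                Resonance("GlxMM", GLX_MM_PPM, 0.09, 0.55),
            ]
        ),
        amplitude_cv=0.20,
        baseline_level=6.0,
    )
    # Preserved NAA, elevated Cho/mI, moderate 2.3-2.4 region.
    profiles["lgg"] = ClassProfile(
        "lgg",
        tuple(
            _triplet(0.72, 0.78, 0.50)
            + [
                Resonance("mI", MI_PPM, 0.06, 0.48),
                Resonance("Glx", GLX_MM_PPM, 0.10, 0.32),
                Resonance("Lip13", LIP13_PPM, 0.09, 0.12),
            ]
        ),
        amplitude_cv=0.20,
        baseline_level=5.0,
    )
    return profiles


def build_class_profiles(config: dict | None = None) -> dict[str, ClassProfile]:
    """Return the five class profiles (mm, gb, me, lgg, no).

    *config* may override per-class amplitudes:
    ``{"gb": {"amplitudes": {"NAA": 0.1, ...}, "amplitude_cv": 0.3,
    "baseline_level": 0.2}}``.  Unknown class names raise.
    """
    profiles = _default_profiles()
    if not config:
        return profiles
    for label, overrides in config.items():
        if label not in profiles:
            raise ValueError(f"unknown class name {label!r}")
        prof = profiles[label]
        amps = overrides.get("amplitudes", {})
        known = {r.name for r in prof.resonances}
        unknown = set(amps) - known
        if unknown:
            raise ValueError(
                f"unknown resonance names {sorted(unknown)} for class {label!r}"
            )
        res = tuple(
            replace(r, amplitude=float(amps.get(r.name, r.amplitude)))
            for r in prof.resonances
        )
        profiles[label] = replace(
            prof,
            resonances=res,
            amplitude_cv=float(overrides.get("amplitude_cv", prof.amplitude_cv)),
            baseline_level=float(
                overrides.get("baseline_level", prof.baseline_level)
            ),
        )
    return profiles


def blend_profiles(a: ClassProfile, b: ClassProfile, weight: float,
                   label: str | None = None) -> ClassProfile:
    """Convex combination ``weight * a + (1 - weight) * b`` over the union
    of resonances (amplitude-wise); used for partial-volume mixing."""
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must be in [0, 1]")
    merged: dict[str, Resonance] = {}
    for r in a.resonances:
        merged[r.name] = replace(r, amplitude=r.amplitude * weight)
    for r in b.resonances:
        if r.name in merged:
            prev = merged[r.name]
            merged[r.name] = replace(
                prev, amplitude=prev.amplitude + r.amplitude * (1.0 - weight)
            )
        else:
            merged[r.name] = replace(r, amplitude=r.amplitude * (1.0 - weight))
    return ClassProfile(
        label or a.class_label,
        tuple(merged.values()),
        amplitude_cv=weight * a.amplitude_cv + (1 - weight) * b.amplitude_cv,
        baseline_level=(
            weight * a.baseline_level + (1 - weight) * b.baseline_level
        ),
    )


def abnormal_profile(case_class: str,
                     profiles: dict[str, ClassProfile]) -> ClassProfile:
    """Tissue profile of the abnormal ring around the solid region.

    Glial cases (gb, lgg) get an infiltrative mix of tumor and normal
    tissue; mm/me get normal tissue with an oedema-like raised baseline.
    """
    normal = profiles["no"]
    if case_class in ("gb", "lgg"):
        return blend_profiles(profiles[case_class], normal, 0.5,
                              label=f"abnormal_{case_class}")
    oedema = replace(normal, class_label=f"abnormal_{case_class}",
                     baseline_level=normal.baseline_level * 1.35)
    return blend_profiles(oedema, profiles[case_class], 0.85,
                          label=f"abnormal_{case_class}")


def ventricle_profile() -> ClassProfile:
    """CSF-like: almost no metabolites, strong residual water handled by
    the artifact machinery; kept minimal since ventricles are excluded."""
    return ClassProfile(
        "ventricle",
        tuple(_triplet(0.05, 0.04, 0.04, lw=0.07)),
        amplitude_cv=0.3,
        baseline_level=1.0,
    )
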