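"""Synthetic gastric-wall CT phantoms and a covariate-linked recurrence cohort.

Real abdominal CT of the stomach shows an irregular annular wall: a bright
contrast-enhancing ring (the gastric wall) around a darker lumen, embedded in a
darker background.  No patient data ships with this package, so every consumer
is exercised on phantoms that emulate exactly that geometry: an annulus whose
inner and outer contours carry a smooth sinusoidal-plus-random radial
perturbation ("irregular wall"), with configurable tissue intensities and
within-wall heterogeneity noise that drives the texture features.

The cohort generator additionally emits categorical covariates (age group, sex,
tumor diameter, TNM stage, chemotherapy, location) with per-arm frequencies
defaulting to the published recurrence/no-recurrence cross-tabulations of an
86-patient gastric-cancer series, so the downstream contingency statistics have
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Phase",
    "CTSlice",
    "MaskPair",
    "PhantomParams",
    "PatientRecord",
    "InvalidGeometryError",
    "ConfigurationError",
    "generate_phantom",
    "generate_cohort",
    "default_covariate_probs",
    "simulate_logistic_cohort",
    "PORTAL_WALL_FACTOR",
]

#: Deterministic wall-intensity multiplier for the portal-venous acquisition.
#: The second contrast phase (~70 s post-injection) enhances the wall more than
#: the arterial phase (~30 s); modelled as a fixed scale, no pharmacokinetics.
PORTAL_WALL_FACTOR = 1.25


class Phase(str, Enum):
    """Contrast-enhancement phase of a CT acquisition."""

    ARTERIAL = "arterial"
    PORTAL = "portal"


class InvalidGeometryError(ValueError):
    """Phantom geometry violates its invariants (e.g. wall thicker than radius)."""


class ConfigurationError(ValueError):
    """A parameter table (e.g. covariate probabilities) is malformed."""


@dataclass(frozen=True)
class CTSlice:
    """A single 2-D CT-like slice.

    Parameters
    ----------
    pixels
        Real-valued intensity grid, HU-like arbitrary units.
    phase
        Contrast phase the slice emulates.
    pixel_spacing
        In-plane spacing in mm (metadata only; no physics depends on it).
    patient_id
        Opaque identifier linking the slice to a cohort record.
    """

    pixels: np.ndarray
    phase: Phase = Phase.ARTERIAL
    pixel_spacing: float = 0.7
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"slice must be at least 16x16, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "phase", Phase(self.phase))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MaskPair:
    """Ground-truth binary mask and soft predicted mask over the same grid."""

    ground_truth: np.ndarray
    predicted: np.ndarray | None = None

    def __post_init__(self) -> None:
        gt = np.asarray(self.ground_truth)
        if not np.isin(gt, (0, 1)).all():
            raise ValueError("ground_truth must contain only 0/1 values")
        gt = gt.astype(np.uint8)
        object.__setattr__(self, "ground_truth", gt)
        if self.predicted is not None:
            pr = np.asarray(self.predicted, dtype=float)
            if pr.shape != gt.shape:
                raise ValueError(
                    f"predicted shape {pr.shape} != ground_truth shape {gt.shape}"
                )
            if pr.min() < 0 or pr.max() > 1:
                raise ValueError("predicted values must lie in [0, 1]")
            object.__setattr__(self, "predicted", pr)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one annular phantom.

    ``boundary_irregularity`` is the relative amplitude of the radial
    perturbation applied independently to the inner and outer contours;
    ``heterogeneity_sd`` is the standard deviation of i.i.d. Gaussian intensity
    noise added inside the wall only (the texture signal).
    """

    size: int = 512
    outer_radius: float = 150.0
    wall_thickness: float = 25.0
    boundary_irregularity: float = 0.05
    wall_intensity: float = 130.0
    lumen_intensity: float = 40.0
    background_intensity: float = 10.0
    heterogeneity_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise InvalidGeometryError("size must be >= 16")
        if self.outer_radius <= 0 or self.wall_thickness <= 0:
            raise InvalidGeometryError("radii must be positive")
        if self.wall_thickness >= self.outer_radius:
            raise InvalidGeometryError(
                f"wall_thickness ({self.wall_thickness}) must be smaller than "
                f"outer_radius ({self.outer_radius})"
            )
        if self.boundary_irregularity < 0 or self.heterogeneity_sd < 0:
            raise InvalidGeometryError("noise amplitudes must be non-negative")
        for v in (self.wall_intensity, self.lumen_intensity, self.background_intensity):
            if not np.isfinite(v):
                raise InvalidGeometryError("intensities must be finite")


AgeGroup = Literal["under60", "ge60"]
Sex = Literal["male", "female"]
DiameterGroup = Literal["lt6cm", "ge6cm"]
TnmGroup = Literal["I_II", "III_IV"]
Location = Literal["esophagogastric", "distal", "whole"]


@dataclass(frozen=True)
class PatientRecord:
    """Categorical covariates and recurrence outcome for one patient."""

    patient_id: str
    age_group: AgeGroup
    sex: Sex
    diameter_group: DiameterGroup
    tnm_group: TnmGroup
    chemo: bool
    location: Location
    recurrence: bool

    _AGE = ("under60", "ge60")
    _SEX = ("male", "female")
    _DIAM = ("lt6cm", "ge6cm")
    _TNM = ("I_II", "III_IV")
    _LOC = ("esophagogastric", "distal", "whole")

    def __post_init__(self) -> None:
        checks = [
            (self.age_group, self._AGE, "age_group"),
            (self.sex, self._SEX, "sex"),
            (self.diameter_group, self._DIAM, "diameter_group"),
            (self.tnm_group, self._TNM, "tnm_group"),
            (self.location, self._LOC, "location"),
        ]
        for value, allowed, name in checks:
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")


def _radial_perturbation(theta: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth 2π-periodic perturbation: a few random-phase low harmonics."""
    if amplitude == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    harmonics = (2, 3, 5)
    coeffs = rng.normal(size=len(harmonics))
    coeffs /= max(1.0, np.abs(coeffs).sum())  # keep total relative amplitude <= `amplitude`
    phases = rng.uniform(0, 2 * np.pi, size=len(harmonics))
    for k, c, p in zip(harmonics, coeffs, phases):
        out += c * np.sin(k * theta + p)
    return amplitude * out


def generate_phantom(
    params: PhantomParams, phase: Phase | str = Phase.ARTERIAL
) -> tuple[CTSlice, np.ndarray]:
    """Generate one annular gastric-wall phantom and its ground-truth wall mask.

    The wall is the set of pixels whose radius lies between the perturbed inner
    and outer contours; the mask returned is exactly that set.  Same ``params``
    (including seed) and phase give bit-identical output.

    Returns
    -------
    (CTSlice, ndarray)
        The slice and the binary wall mask (uint8, same shape).
    """
    phase = Phase(phase)
    rng = np.random.default_rng(params.seed)
    n = params.size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    r_out = params.outer_radius * (
        1.0 + _radial_perturbation(theta, params.boundary_irregularity, rng)
    )
    r_in = (params.outer_radius - params.wall_thickness) * (
        1.0 + _radial_perturbation(theta, params.boundary_irregularity, rng)
    )
    wall = (r <= r_out) & (r > r_in)
    lumen = r <= r_in

    wall_int = params.wall_intensity * (
        PORTAL_WALL_FACTOR if phase is Phase.PORTAL else 1.0
    )
    pixels = np.full((n, n), params.background_intensity, dtype=float)
    pixels[lumen] = params.lumen_intensity
    pixels[wall] = wall_int
    if params.heterogeneity_sd > 0:
        pixels[wall] += rng.normal(0.0, params.heterogeneity_sd, size=int(wall.sum()))

    # keep the mask strictly inside the image border
    wall[0, :] = wall[-1, :] = False
    wall[:, 0] = wall[:, -1] = False

    slc = CTSlice(pixels=pixels, phase=phase)
    return slc, wall.astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Per-arm category probabilities mirroring the published 56/30 recurrence /
# no-recurrence cross-tabulations (fractions of each arm).
def default_covariate_probs() -> dict[str, dict[str, dict[str, float]]]:
    """Default per-arm covariate probabilities (recurrence / no_recurrence arms)."""
    return {
        "age_group": {
            "recurrence": {"under60": 12 / 56, "ge60": 44 / 56},
            "no_recurrence": {"under60": 23 / 30, "ge60": 7 / 30},
        },
        "sex": {
            "recurrence": {"male": 40 / 56, "female": 16 / 56},
            "no_recurrence": {"male": 22 / 30, "female": 8 / 30},
        },
        "diameter_group": {
            "recurrence": {"lt6cm": 6 / 56, "ge6cm": 50 / 56},
            "no_recurrence": {"lt6cm": 27 / 30, "ge6cm": 3 / 30},
        },
        "tnm_group": {
            "recurrence": {"I_II": 9 / 56, "III_IV": 47 / 56},
            "no_recurrence": {"I_II": 26 / 30, "III_IV": 4 / 30},
        },
        "chemo": {
            "recurrence": {"yes": 7 / 56, "no": 49 / 56},
            "no_recurrence": {"yes": 13 / 30, "no": 17 / 30},
        },
        "location": {
            "recurrence": {
                "esophagogastric": 20 / 56,
                "distal": 31 / 56,
                "whole": 5 / 56,
            },
            "no_recurrence": {
                "esophagogastric": 10 / 30,
                "distal": 17 / 30,
                "whole": 3 / 30,
            },
        },
    }


def _validate_probs(probs: dict) -> None:
    required = {"age_group", "sex", "diameter_group", "tnm_group", "chemo", "location"}
    missing = required - probs.keys()
    if missing:
        raise ConfigurationError(f"covariate_probs missing factors: {sorted(missing)}")
    for factor, arms in probs.items():
        for arm in ("recurrence", "no_recurrence"):
            if arm not in arms:
                raise ConfigurationError(f"factor {factor!r} missing arm {arm!r}")
            p = arms[arm]
            vals = list(p.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ConfigurationError(
                    f"probabilities for {factor}/{arm} must lie in [0, 1]"
                )
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"probabilities for {factor}/{arm} must sum to 1, got {sum(vals)}"
                )


def _allocate_exact(n: int, probs: dict[str, float], rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of n items across categories,
    returned in a seeded random order (order varies, counts do not)."""
    cats = list(probs)
    raw = np.array([probs[c] * n for c in cats])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    labels = [c for c, k in zip(cats, counts) for _ in range(k)]
    rng.shuffle(labels)
    return labels


def _sample(n: int, probs: dict[str, float], rng: np.random.Generator) -> list[str]:
    cats = list(probs)
    return list(rng.choice(cats, size=n, p=[probs[c] for c in cats]))


def generate_cohort(
    n_recurrence: int,
    n_no_recurrence: int,
    covariate_probs: dict | None = None,
    texture_effect: float = 5.0,
    seed: int = 0,
    exact: bool = False,
    phantom_params: PhantomParams | None = None,
    phase: Phase | str = Phase.ARTERIAL,
    with_images: bool = True,
) -> tuple[list[PatientRecord], list[tuple[CTSlice, MaskPair]]]:
    """Generate a synthetic recurrence cohort and (optionally) one phantom per patient.

    Recurrence-arm phantoms get ``heterogeneity_sd`` increased by
    ``texture_effect`` so the texture separation between arms is recoverable.
    With ``exact=True`` category counts follow deterministic largest-remainder
    allocation instead of sampling, so the cross-tabs hit their expected counts
    precisely (at the default probabilities and n=56/30 this reproduces the
    published tables).
    """
    if n_recurrence < 1 or n_no_recurrence < 1:
        raise ValueError("both arm sizes must be >= 1")
    probs = covariate_probs if covariate_probs is not None else default_covariate_probs()
    _validate_probs(probs)
    rng = np.random.default_rng(seed)
    base = phantom_params if phantom_params is not None else PhantomParams()

    records: list[PatientRecord] = []
    images: list[tuple[CTSlice, MaskPair]] = []
    alloc = _allocate_exact if exact else _sample

    for arm, n_arm, recurrence in (
        ("recurrence", n_recurrence, True),
        ("no_recurrence", n_no_recurrence, False),
    ):
        cols = {
            factor: alloc(n_arm, probs[factor][arm], rng)
            for factor in ("age_group", "sex", "diameter_group", "tnm_group", "chemo", "location")
        }
        het = base.heterogeneity_sd + (texture_effect if recurrence else 0.0)
        for i in range(n_arm):
            pid = f"{'R' if recurrence else 'N'}{i:04d}"
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age_group=cols["age_group"][i],  # type: ignore[arg-type]
                    sex=cols["sex"][i],  # type: ignore[arg-type]
                    diameter_group=cols["diameter_group"][i],  # type: ignore[arg-type]
                    tnm_group=cols["tnm_group"][i],  # type: ignore[arg-type]
                    chemo=cols["chemo"][i] == "yes",
                    location=cols["location"][i],  # type: ignore[arg-type]
                    recurrence=recurrence,
                )
            )
            if with_images:
                p = replace(
                    base,
                    heterogeneity_sd=het,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                slc, gt = generate_phantom(p, phase)
                slc = replace(slc, patient_id=pid)
                images.append((slc, MaskPair(ground_truth=gt)))
    return records, images


def simulate_logistic_cohort(
    n: int,
    betas: Sequence[float],
    intercept: float = -0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate binary covariates and a logistic recurrence outcome.

    Covariates are i.i.d. Bernoulli(0.5); the outcome follows
    ``logit P(y=1) = intercept + X @ betas``.  Used for parameter-recovery
    checks of the logistic fit.

    Returns
    -------
    (X, y) : design matrix (n, len(betas)) and 0/1 outcome vector.
    """
    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, dtype=float)
    X = rng.integers(0, 2, size=(n, betas.size)).astype(float)
    eta = intercept + X @ betas
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    return X, y
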