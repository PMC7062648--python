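"""Synthetic AIS cohorts: anthropometrics, curve geometry and landmarks.

The generator emulates a 24-patient cohort of adolescents with mild to
moderate idiopathic scoliosis (age 13.8 SD 1.8 y, height 161.2 SD 12.3 cm,
mass 47.5 SD 8.0 kg, Cobb 22.1 SD 4.4 deg, mixed left/right convexity with
thoracic and thoracolumbar apices, 21:3 female:male).  Every quantity is
drawn reproducibly from a single integer seed, and the landmark synthesis is
the exact inverse of the extraction in :mod:`scoliosim.geometry`, so that a
zero-noise round trip recovers the generating geometry to numerical
precision.

The frontal curve model is a single structural curve: a derivative-of-
Gaussian lateral tilt profile centred on the apex, scaled so that the
end-vertebra tilt difference equals the requested Cobb angle.  Axial rotation
is coupled to the curve with a Gaussian profile peaking at the apex, directed
so the spinous process deviates toward the concavity (the typical AIS
pattern).  The sagittal profile is a piecewise-cosine kyphosis/lordosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .frames import LEVELS, level_index, vertebral_rotation
from .geometry import (
    DEFAULT_SPINOUS_DEPTH_MM,
    REFERENCE_HEIGHT_CM,
    SpineGeometry,
    VertebraLandmarks,
    VertebralPose,
    compute_cobb,
    find_apex,
)

#: Nominal centre-to-centre vertebral heights (mm) at the reference stature,
#: T1..L5; they include the disc share and sum to ~386 mm of T1-L5 spine.
NOMINAL_HEIGHTS_MM = np.array(
    [18, 18, 19, 19, 20, 20, 21, 21, 22, 23, 24, 25, 26, 27, 28, 28, 27],
    dtype=float,
)


def scaled_spinous_depth(height_cm: float) -> float:
    """Nominal pedicle-to-spinous depth (mm) scaled linearly with stature."""
    return DEFAULT_SPINOUS_DEPTH_MM * height_cm / REFERENCE_HEIGHT_CM


def sagittal_profile(
    kyphosis_deg: float = 30.0, lordosis_deg: float = 45.0
) -> np.ndarray:
    """Per-level sagittal endplate angles (deg) for a neutral adolescent spine.

    Piecewise-cosine: the thoracic tilt sweeps -K/2 (T1, flexed) to +K/2
    (T12), the lumbar tilt continues from +K/2 down to +K/2 - L at L5, so the
    T1-T12 difference equals the kyphosis and the L1-L5 sweep approximates the
    lordosis.
    """
    thoracic = -0.5 * kyphosis_deg * np.cos(np.pi * np.arange(12) / 11.0)
    j = np.arange(1, 6)
    lumbar = 0.5 * kyphosis_deg - lordosis_deg * 0.5 * (1.0 - np.cos(np.pi * j / 5.0))
    return np.concatenate([thoracic, lumbar])


def generate_curve(
    apex: str = "T8",
    cobb_target: float = 22.1,
    convexity: str = "right",
    axial_coupling: float = 0.3,
    sagittal_angles_deg: Optional[Sequence[float]] = None,
    kyphosis_deg: float = 30.0,
    lordosis_deg: float = 45.0,
    height_cm: float = REFERENCE_HEIGHT_CM,
    width_levels: float = 4.0,
    heights_mm: Optional[Sequence[float]] = None,
) -> SpineGeometry:
    """Construct a single-curve scoliotic spine geometry.

    The lateral tilt follows a derivative-of-Gaussian profile centred at
    ``apex`` with width ``width_levels``; the discrete end-vertebra tilt
    difference equals ``cobb_target`` exactly.  Vertebral centres are the
    chained integration of heights along the per-level orientations.
    """
    apex_idx = level_index(apex)
    if not 1 <= apex_idx <= len(LEVELS) - 2:
        raise ValueError(f"apex {apex} must lie strictly inside T2..L4")
    if cobb_target < 0:
        raise ValueError("cobb_target must be >= 0")
    if convexity not in ("left", "right"):
        raise ValueError("convexity must be 'left' or 'right'")

    s = np.arange(len(LEVELS), dtype=float)
    sigma = float(width_levels)
    if cobb_target > 0:
        g = ((apex_idx - s) / sigma) * np.exp(-((s - apex_idx) ** 2) / (2 * sigma**2))
        spread = g.max() - g.min()
        amp = cobb_target / spread
        frontal = amp * g if convexity == "left" else -amp * g
    else:
        frontal = np.zeros_like(s)
    if np.max(np.abs(frontal)) >= 90.0:
        raise ValueError("cobb_target implies lateral tilts beyond 90 deg")

    if sagittal_angles_deg is None:
        sagittal = sagittal_profile(kyphosis_deg, lordosis_deg)
    else:
        sagittal = np.asarray(sagittal_angles_deg, dtype=float)
        if sagittal.shape != (len(LEVELS),):
            raise ValueError("sagittal_angles_deg must have one entry per level")

    if cobb_target > 0:
        bump = np.exp(-((s - apex_idx) ** 2) / (2 * sigma**2))
        tilt_amp = np.max(np.abs(frontal))
        sign = -1.0 if convexity == "left" else 1.0
        axial = sign * axial_coupling * tilt_amp * bump
    else:
        axial = np.zeros_like(s)

    if heights_mm is None:
        heights = NOMINAL_HEIGHTS_MM * height_cm / REFERENCE_HEIGHT_CM
    else:
        heights = np.asarray(heights_mm, dtype=float)
        if heights.shape != (len(LEVELS),):
            raise ValueError("heights_mm must have one entry per level")

    # Chain disc nodes from the bottom (node below L5 at the origin) upward.
    up_axes = [
        vertebral_rotation(sagittal[i], frontal[i], axial[i])[:, 1]
        for i in range(len(LEVELS))
    ]
    nodes = np.zeros((len(LEVELS) + 1, 3))
    for i in range(len(LEVELS) - 1, -1, -1):
        nodes[i] = nodes[i + 1] + heights[i] * up_axes[i]

    poses = []
    for i, lvl in enumerate(LEVELS):
        center = 0.5 * (nodes[i] + nodes[i + 1])
        h_total = float(heights[i])
        h_sag = h_total * float(np.cos(np.deg2rad(frontal[i])))
        poses.append(
            VertebralPose(
                level=lvl,
                center=center,
                sagittal_rot=float(sagittal[i]),
                frontal_rot=float(frontal[i]),
                axial_rot=float(axial[i]),
                h_sagittal=h_sag,
                h_total=h_total,
            )
        )
    cobb, upper, lower = compute_cobb(frontal)
    geom = SpineGeometry(poses=poses, cobb_deg=cobb, upper_end=upper, lower_end=lower)
    if cobb > 1e-9:
        geom.apex_level, geom.convexity = find_apex(geom)
    return geom


def landmarks_from_geometry(
    geom: SpineGeometry,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
    spinous_depth_mm: float = DEFAULT_SPINOUS_DEPTH_MM,
    half_gap_mm: float = 1.5,
    sagittal_halfwidth_mm: float = 15.0,
    frontal_halfwidth_mm: float = 20.0,
) -> list[VertebraLandmarks]:
    """Synthesize the 9-landmark biplanar sets from a spine geometry.

    Corners are placed on each vertebra's oriented box projected to the two
    planes, with the facing endplate corner pairs of adjacent vertebrae
    symmetric about the shared disc node, so the landmark->geometry
    extraction is the exact inverse at zero noise.  Isotropic Gaussian noise
    of ``noise_sd`` mm is added per coordinate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(LEVELS)
    up_axes, sag_angles = [], []
    for p in geom.poses:
        R = vertebral_rotation(p.sagittal_rot, p.frontal_rot, p.axial_rot)
        up_axes.append(R[:, 1])
        sag_angles.append(np.deg2rad(p.sagittal_rot))
    # Shared disc nodes: midpoints of the adjacent vertebrae's own endplate
    # node estimates (identical for chain-consistent geometry).
    tops = [geom.poses[i].center + 0.5 * geom.poses[i].h_total * up_axes[i] for i in range(n)]
    bots = [geom.poses[i].center - 0.5 * geom.poses[i].h_total * up_axes[i] for i in range(n)]
    nodes = [tops[0]]
    for i in range(1, n):
        nodes.append(0.5 * (bots[i - 1] + tops[i]))
    nodes.append(bots[-1])

    out = []
    for i, p in enumerate(geom.poses):
        s_hat = np.array([np.cos(sag_angles[i]), np.sin(sag_angles[i])])
        n_hat = np.array([-np.sin(sag_angles[i]), np.cos(sag_angles[i])])
        a = sagittal_halfwidth_mm

        # Upper endplate: offset from the node above, along the normal of the
        # vertebra above (so the 4 facing corners centre on the node exactly).
        if i == 0:
            up_center = nodes[0][:2]
        else:
            sa = sag_angles[i - 1]
            up_center = nodes[i][:2] - half_gap_mm * np.array([-np.sin(sa), np.cos(sa)])
        if i == n - 1:
            lo_center = nodes[n][:2]
        else:
            lo_center = nodes[i + 1][:2] + half_gap_mm * n_hat

        sag = {
            "UA": up_center + a * s_hat,
            "UP": up_center - a * s_hat,
            "LA": lo_center + a * s_hat,
            "LP": lo_center - a * s_hat,
        }

        phi = np.deg2rad(p.frontal_rot)
        f_hat = np.array([np.cos(phi), np.sin(phi)])
        f_perp = np.array([-np.sin(phi), np.cos(phi)])
        c_front = np.array([p.center[2], p.center[1]])
        e = 0.4 * p.h_total
        w = frontal_halfwidth_mm
        fro = {
            "UL": c_front + e * f_perp + w * f_hat,
            "UR": c_front + e * f_perp - w * f_hat,
            "LL": c_front - e * f_perp + w * f_hat,
            "LR": c_front - e * f_perp - w * f_hat,
        }
        spinous = np.array(
            [p.center[2] + spinous_depth_mm * np.sin(np.deg2rad(p.axial_rot)), p.center[1]]
        )
        if noise_sd > 0:
            for d in (sag, fro):
                for k in d:
                    d[k] = d[k] + rng.normal(0.0, noise_sd, size=2)
            spinous = spinous + rng.normal(0.0, noise_sd, size=2)
        out.append(VertebraLandmarks(level=p.level, sagittal=sag, frontal=fro, spinous=spinous))
    return out


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

DEFAULT_APEX_CHOICES: dict[str, float] = {
    "T7": 0.15,
    "T8": 0.30,
    "T9": 0.20,
    "T10": 0.10,
    "T11": 0.10,
    "T12": 0.10,
    "L1": 0.05,
}


@dataclass
class CohortParams:
    """Sampling parameters for a synthetic AIS cohort.

    Defaults reproduce the modeled 24-patient cohort's summary statistics;
    anthropometric draws are truncated normals (+-3 sd with physiologic
    floors) so n stays fixed.
    """

    n: int = 24
    seed: int = 0
    age_mean: float = 13.8
    age_sd: float = 1.8
    height_mean: float = 161.2
    height_sd: float = 12.3
    mass_mean: float = 47.5
    mass_sd: float = 8.0
    cobb_mean: float = 22.1
    cobb_sd: float = 4.4
    apex_level_choices: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APEX_CHOICES)
    )
    convexity_prob_left: float = 11.0 / 24.0
    female_prob: float = 21.0 / 24.0
    axial_coupling: float = 0.3
    landmark_noise_sd: float = 0.5
    kyphosis_mean: float = 30.0
    kyphosis_sd: float = 6.0
    lordosis_mean: float = 45.0
    lordosis_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("age_sd", "height_sd", "mass_sd", "cobb_sd", "kyphosis_sd", "lordosis_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = sum(self.apex_level_choices.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("apex_level_choices probabilities must sum to 1")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")


@dataclass
class SyntheticSubject:
    """One synthetic patient: anthropometrics, true geometry and landmarks."""

    subject_id: str
    sex: str
    age_y: float
    height_cm: float
    mass_kg: float
    true_geometry: SpineGeometry
    landmarks: list[VertebraLandmarks]
    spinous_depth_mm: float

    @property
    def convexity(self) -> Optional[str]:
        return self.true_geometry.convexity

    @property
    def apex_level(self) -> Optional[str]:
        return self.true_geometry.apex_level

    @property
    def cobb_deg(self) -> float:
        return self.true_geometry.cobb_deg


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    if sd == 0:
        return max(mean, floor)
    v = stats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, random_state=rng)
    return float(max(v, floor))


def generate_cohort(params: CohortParams) -> list[SyntheticSubject]:
    """Draw a fully reproducible synthetic cohort from ``params``."""
    rng = np.random.default_rng(params.seed)
    apex_levels = list(params.apex_level_choices.keys())
    apex_probs = np.array(list(params.apex_level_choices.values()), dtype=float)
    subjects = []
    for i in range(params.n):
        sex = "Female" if rng.random() < params.female_prob else "Male"
        age = _draw_truncnorm(rng, params.age_mean, params.age_sd, 8.0)
        height = _draw_truncnorm(rng, params.height_mean, params.height_sd, 120.0)
        mass = _draw_truncnorm(rng, params.mass_mean, params.mass_sd, 25.0)
        cobb = _draw_truncnorm(rng, params.cobb_mean, params.cobb_sd, 5.0)
        apex = str(rng.choice(apex_levels, p=apex_probs))
        convexity = "left" if rng.random() < params.convexity_prob_left else "right"
        kyph = _draw_truncnorm(rng, params.kyphosis_mean, params.kyphosis_sd, 10.0)
        lord = _draw_truncnorm(rng, params.lordosis_mean, params.lordosis_sd, 15.0)
        geom = generate_curve(
            apex=apex,
            cobb_target=cobb,
            convexity=convexity,
            axial_coupling=params.axial_coupling,
            kyphosis_deg=kyph,
            lordosis_deg=lord,
            height_cm=height,
        )
        depth = scaled_spinous_depth(height)
        lms = landmarks_from_geometry(
            geom,
            noise_sd=params.landmark_noise_sd,
            seed=rng,
            spinous_depth_mm=depth,
        )
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i + 1:02d}",
                sex=sex,
                age_y=age,
                height_cm=height,
                mass_kg=mass,
                true_geometry=geom,
                landmarks=lms,
                spinous_depth_mm=depth,
            )
        )
    return subjects


def cohort_manifest(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Demographics table of a cohort (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "age_y": [s.age_y for s in subjects],
            "height_cm": [s.height_cm for s in subjects],
            "mass_kg": [s.mass_kg for s in subjects],
            "cobb_deg": [s.cobb_deg for s in subjects],
            "apex_level": [s.apex_level for s in subjects],
            "convexity": [s.convexity for s in subjects],
        }
    )


def load_reference_cohort() -> pd.DataFrame:
    """The packaged demographics of the 24-patient AIS cohort the generator
    emulates (age, stature, mass, curve type, Cobb angle, convexity)."""
    with resources.files("scoliosim.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh)
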