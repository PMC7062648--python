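"""Vertebral geometry from biplanar radiographic landmarks.

Nine landmarks are digitized per vertebra on two spatially calibrated planes:
four corners of the vertebral body in the sagittal plane, four in the frontal
plane, and the spinous-process point in the frontal plane.  From these the
module computes 3D vertebral orientations, projection-corrected body heights,
the Cobb angle of the frontal curve, and the curve apex with its convexity.

Sagittal and frontal orientations are the mean slope of the upper- and
lower-corner lines in the respective plane.  The axial rotation is a geometric
surrogate: it is recovered from the lateral offset of the spinous-process
landmark relative to the frontal body centre, assuming a nominal
pedicle-to-spinous depth (the original radiographic workflow fits a reference
anatomic mesh instead, which requires data this package does not carry).

Vertebral height is measured between the centroids of the proximal and distal
intervertebral disc spaces in the sagittal plane (H_sagittal) and corrected
for the out-of-plane projection error caused by the frontal tilt:
H_total = H_sagittal / cos(frontal_rot) -- the unique correction that restores
the true length of a laterally tilted segment from its sagittal projection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .frames import LEVELS, level_index

#: Default pedicle-to-spinous-process depth used by the axial-rotation
#: surrogate, in mm, at the reference stature of 161.2 cm.
DEFAULT_SPINOUS_DEPTH_MM = 40.0

#: Stature (cm) at which the nominal depth and vertebral heights are defined.
REFERENCE_HEIGHT_CM = 161.2

SAGITTAL_ROLES = ("UA", "UP", "LA", "LP")  # upper/lower x anterior/posterior
FRONTAL_ROLES = ("UL", "UR", "LL", "LR")  # upper/lower x left/right


class InvalidLandmarkError(ValueError):
    """Raised for degenerate or incomplete landmark sets."""


class NoCurveError(ValueError):
    """Raised when an apex is requested for a spine without a frontal curve."""


@dataclass
class VertebraLandmarks:
    """The nine digitized 2D points of one vertebra.

    ``sagittal`` maps corner roles UA/UP/LA/LP to (x, y) mm; ``frontal`` maps
    UL/UR/LL/LR to (z, y) mm; ``spinous`` is the frontal (z, y) point of the
    spinous process.  Upper corners must lie strictly above lower corners.
    """

    level: str
    sagittal: dict[str, np.ndarray]
    frontal: dict[str, np.ndarray]
    spinous: np.ndarray

    def __post_init__(self) -> None:
        level_index(self.level)
        if set(self.sagittal) != set(SAGITTAL_ROLES):
            raise InvalidLandmarkError(
                f"{self.level}: sagittal roles {sorted(self.sagittal)} != {SAGITTAL_ROLES}"
            )
        if set(self.frontal) != set(FRONTAL_ROLES):
            raise InvalidLandmarkError(
                f"{self.level}: frontal roles {sorted(self.frontal)} != {FRONTAL_ROLES}"
            )
        self.sagittal = {k: np.asarray(v, dtype=float) for k, v in self.sagittal.items()}
        self.frontal = {k: np.asarray(v, dtype=float) for k, v in self.frontal.items()}
        self.spinous = np.asarray(self.spinous, dtype=float)
        # Steeply tilted vertebrae (e.g. L5 under a strong lordosis) can have
        # individual corner y-ranges overlap, so the containment check uses
        # the endplate midpoints.
        for plane, upper, lower in (
            (self.sagittal, ("UA", "UP"), ("LA", "LP")),
            (self.frontal, ("UL", "UR"), ("LL", "LR")),
        ):
            up_mid = np.mean([plane[u][1] for u in upper])
            lo_mid = np.mean([plane[l][1] for l in lower])
            if up_mid <= lo_mid - 1e-9:
                raise InvalidLandmarkError(
                    f"{self.level}: upper endplate does not lie above the lower endplate"
                )


@dataclass
class VertebralPose:
    """3D position, orientation and corrected height of one vertebra."""

    level: str
    center: np.ndarray  # mm, global frame
    sagittal_rot: float  # deg, extension positive
    frontal_rot: float  # deg, left endplate edge up positive
    axial_rot: float  # deg, spinous toward subject's left positive
    h_sagittal: float  # mm
    h_total: float  # mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (0.0 < self.h_sagittal <= self.h_total + 1e-9):
            raise ValueError(
                f"{self.level}: require h_total >= h_sagittal > 0, "
                f"got {self.h_sagittal}, {self.h_total}"
            )
        for name in ("sagittal_rot", "frontal_rot", "axial_rot"):
            a = getattr(self, name)
            if not -90.0 < a < 90.0:
                raise ValueError(f"{self.level}: {name} = {a} outside (-90, 90) deg")


@dataclass
class SpineGeometry:
    """Ordered T1->L5 vertebral poses plus curve-level descriptors."""

    poses: list[VertebralPose]
    cobb_deg: float = 0.0
    apex_level: Optional[str] = None
    convexity: Optional[str] = None  # "left" | "right"
    upper_end: Optional[str] = None
    lower_end: Optional[str] = None

    def __post_init__(self) -> None:
        if [p.level for p in self.poses] != list(LEVELS):
            raise ValueError("poses must cover T1..L5 in cranial-to-caudal order")
        if self.cobb_deg < 0:
            raise ValueError("cobb_deg must be >= 0")

    def pose(self, level: str) -> VertebralPose:
        return self.poses[level_index(level)]

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.poses])

    @property
    def frontal_rots(self) -> np.ndarray:
        return np.array([p.frontal_rot for p in self.poses])

    def mirrored(self) -> "SpineGeometry":
        """The left-right mirror image (z negated, lateral angles flipped)."""
        poses = [
            VertebralPose(
                level=p.level,
                center=p.center * np.array([1.0, 1.0, -1.0]),
                sagittal_rot=p.sagittal_rot,
                frontal_rot=-p.frontal_rot,
                axial_rot=-p.axial_rot,
                h_sagittal=p.h_sagittal,
                h_total=p.h_total,
            )
            for p in self.poses
        ]
        conv = {"left": "right", "right": "left"}.get(self.convexity)
        return SpineGeometry(
            poses=poses,
            cobb_deg=self.cobb_deg,
            apex_level=self.apex_level,
            convexity=conv,
            upper_end=self.upper_end,
            lower_end=self.lower_end,
        )


def _line_angle_deg(p_from: np.ndarray, p_to: np.ndarray, what: str) -> float:
    d = np.asarray(p_to, float) - np.asarray(p_from, float)
    n = float(np.hypot(d[0], d[1]))
    if n < 1e-9:
        raise InvalidLandmarkError(f"degenerate (coincident) corner pair in {what}")
    return math.degrees(math.atan2(d[1], d[0]))


def extract_orientation(
    lm: VertebraLandmarks, spinous_depth_mm: float = DEFAULT_SPINOUS_DEPTH_MM
) -> tuple[float, float, float]:
    """(sagittal_rot, frontal_rot, axial_rot) in degrees from one landmark set.

    Planar rotations are the mean of the upper- and lower-corner line angles.
    Axial rotation is asin(spinous z-offset from the frontal body centre /
    nominal depth); the spinous process deviates toward +z (left) for positive
    axial rotation.
    """
    up_sag = _line_angle_deg(lm.sagittal["UP"], lm.sagittal["UA"], f"{lm.level} sagittal upper")
    lo_sag = _line_angle_deg(lm.sagittal["LP"], lm.sagittal["LA"], f"{lm.level} sagittal lower")
    sagittal = 0.5 * (up_sag + lo_sag)

    up_fro = _line_angle_deg(lm.frontal["UR"], lm.frontal["UL"], f"{lm.level} frontal upper")
    lo_fro = _line_angle_deg(lm.frontal["LR"], lm.frontal["LL"], f"{lm.level} frontal lower")
    frontal = 0.5 * (up_fro + lo_fro)

    center_z = float(np.mean([lm.frontal[r][0] for r in FRONTAL_ROLES]))
    offset = float(lm.spinous[0]) - center_z
    ratio = np.clip(offset / spinous_depth_mm, -1.0, 1.0)
    axial = math.degrees(math.asin(ratio))
    return sagittal, frontal, axial


def _disc_centroid_sagittal(
    lm: VertebraLandmarks, neighbor: Optional[VertebraLandmarks], side: str
) -> np.ndarray:
    """Sagittal-plane centroid of the disc space above ("up") or below ("down").

    Uses the facing endplate corners of both vertebrae; at the spine ends the
    vertebra's own endplate corner centroid is used.
    """
    own = ("UA", "UP") if side == "up" else ("LA", "LP")
    pts = [lm.sagittal[r] for r in own]
    if neighbor is not None:
        other = ("LA", "LP") if side == "up" else ("UA", "UP")
        pts += [neighbor.sagittal[r] for r in other]
    return np.mean(np.asarray(pts, dtype=float), axis=0)


def extract_height(
    lm: VertebraLandmarks,
    above: Optional[VertebraLandmarks] = None,
    below: Optional[VertebraLandmarks] = None,
    frontal_rot_deg: Optional[float] = None,
) -> tuple[float, float]:
    """(H_sagittal, H_total) in mm for one vertebra.

    H_sagittal is the sagittal-plane distance between the centroids of the
    proximal and distal disc spaces; H_total corrects it for the frontal tilt.
    """
    if frontal_rot_deg is None:
        _, frontal_rot_deg, _ = extract_orientation(lm)
    top = _disc_centroid_sagittal(lm, above, "up")
    bot = _disc_centroid_sagittal(lm, below, "down")
    h_sag = float(np.linalg.norm(top - bot))
    if h_sag <= 0:
        raise InvalidLandmarkError(f"{lm.level}: zero sagittal height")
    h_total = h_sag / math.cos(math.radians(frontal_rot_deg))
    return h_sag, h_total


def compute_cobb(
    frontal_rots_deg: Sequence[float],
) -> tuple[float, str, str]:
    """Cobb angle and end vertebrae from per-level frontal tilt angles.

    The Cobb angle is the maximal absolute tilt difference over all
    superior-inferior level pairs; the maximizing pair are the end vertebrae.
    For a straight spine the extremes T1/L5 are reported with a 0 angle.
    """
    f = np.asarray(frontal_rots_deg, dtype=float)
    if f.size < 3:
        raise ValueError("need at least 3 levels to measure a Cobb angle")
    if f.size != len(LEVELS):
        raise ValueError("expected one frontal tilt per level T1..L5")
    diff = np.abs(f[:, None] - f[None, :])
    diff = np.triu(diff, k=1)
    cobb = float(diff.max())
    if cobb <= 1e-12:
        return 0.0, LEVELS[0], LEVELS[-1]
    i, j = np.unravel_index(int(diff.argmax()), diff.shape)
    return cobb, LEVELS[i], LEVELS[j]


def find_apex(geom: SpineGeometry) -> tuple[str, str]:
    """Apex level and convexity side of the (single) frontal curve.

    The apex is the vertebra, strictly between the end vertebrae, whose centre
    deviates most laterally (z) from the T1-L5 chord; ties break caudally.
    Convexity is the side of that deviation ("left" = +z).
    """
    cobb, upper, lower = compute_cobb(geom.frontal_rots)
    if cobb <= 1e-9:
        raise NoCurveError("straight spine has no curve apex")
    centers = geom.centers
    c0, c1 = centers[0], centers[-1]
    chord = c1 - c0
    chord = chord / np.linalg.norm(chord)
    i0, i1 = level_index(upper), level_index(lower)
    best_idx, best_dev = None, -np.inf
    for i in range(i0 + 1, i1):
        rel = centers[i] - c0
        dev = rel - np.dot(rel, chord) * chord
        dz = abs(float(dev[2]))
        if dz >= best_dev - 1e-9:  # ties resolve to the most caudal level
            best_idx, best_dev = i, max(dz, best_dev)
            best_sign = float(dev[2])
    if best_idx is None:
        raise NoCurveError("no interior level between the end vertebrae")
    return LEVELS[best_idx], ("left" if best_sign > 0 else "right")


def extract_geometry(
    landmarks: Sequence[VertebraLandmarks],
    spinous_depth_mm: float = DEFAULT_SPINOUS_DEPTH_MM,
) -> SpineGeometry:
    """Full spine geometry from the 17 per-vertebra landmark sets."""
    by_level = {lm.level: lm for lm in landmarks}
    if set(by_level) != set(LEVELS):
        missing = sorted(set(LEVELS) - set(by_level), key=level_index)
        raise InvalidLandmarkError(f"landmarks missing for levels {missing}")
    poses: list[VertebralPose] = []
    for i, lvl in enumerate(LEVELS):
        lm = by_level[lvl]
        above = by_level[LEVELS[i - 1]] if i > 0 else None
        below = by_level[LEVELS[i + 1]] if i < len(LEVELS) - 1 else None
        sag, fro, axi = extract_orientation(lm, spinous_depth_mm)
        h_sag, h_total = extract_height(lm, above, below, frontal_rot_deg=fro)
        top = _disc_centroid_sagittal(lm, above, "up")
        bot = _disc_centroid_sagittal(lm, below, "down")
        mid_sag = 0.5 * (top + bot)
        center_z = float(np.mean([lm.frontal[r][0] for r in FRONTAL_ROLES]))
        poses.append(
            VertebralPose(
                level=lvl,
                center=np.array([mid_sag[0], mid_sag[1], center_z]),
                sagittal_rot=sag,
                frontal_rot=fro,
                axial_rot=axi,
                h_sagittal=h_sag,
                h_total=h_total,
            )
        )
    cobb, upper, lower = compute_cobb([p.frontal_rot for p in poses])
    geom = SpineGeometry(poses=poses, cobb_deg=cobb, upper_end=upper, lower_end=lower)
    if cobb > 1e-9:
        geom.apex_level, geom.convexity = find_apex(geom)
    return geom


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

_ROLE_PLANE = {r: "sagittal" for r in SAGITTAL_ROLES}
_ROLE_PLANE.update({r: "frontal" for r in FRONTAL_ROLES})
_ROLE_PLANE["SP"] = "frontal"


def landmarks_to_frame(subject_id: str, landmarks: Sequence[VertebraLandmarks]) -> pd.DataFrame:
    """Long-format landmark table (one row per digitized point)."""
    rows = []
    for lm in landmarks:
        for role in SAGITTAL_ROLES:
            p = lm.sagittal[role]
            rows.append((subject_id, lm.level, "sagittal", role, p[0], p[1]))
        for role in FRONTAL_ROLES:
            p = lm.frontal[role]
            rows.append((subject_id, lm.level, "frontal", role, p[0], p[1]))
        rows.append((subject_id, lm.level, "frontal", "SP", lm.spinous[0], lm.spinous[1]))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "level", "plane", "point_role", "coord1_mm", "coord2_mm"],
    )


def write_landmarks_csv(path: str | Path, subject_id: str, landmarks: Sequence[VertebraLandmarks]) -> None:
    landmarks_to_frame(subject_id, landmarks).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> dict[str, list[VertebraLandmarks]]:
    """Read a landmark CSV, validating the 9-point-per-vertebra contract.

    Returns a mapping subject_id -> list of VertebraLandmarks.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "level", "plane", "point_role", "coord1_mm", "coord2_mm"}
    if not required.issubset(df.columns):
        raise InvalidLandmarkError(f"landmark CSV missing columns {sorted(required - set(df.columns))}")
    out: dict[str, list[VertebraLandmarks]] = {}
    for (subject, level), grp in df.groupby(["subject_id", "level"], sort=False):
        pts = {}
        for _, row in grp.iterrows():
            role = row["point_role"]
            if role in pts:
                raise InvalidLandmarkError(f"{subject}/{level}: duplicate point role {role}")
            if _ROLE_PLANE.get(role) != row["plane"]:
                raise InvalidLandmarkError(f"{subject}/{level}: role {role} in wrong plane")
            pts[role] = np.array([row["coord1_mm"], row["coord2_mm"]], dtype=float)
        if set(pts) != set(_ROLE_PLANE):
            raise InvalidLandmarkError(
                f"{subject}/{level}: expected the 9 roles {sorted(_ROLE_PLANE)}, got {sorted(pts)}"
            )
        lm = VertebraLandmarks(
            level=str(level),
            sagittal={r: pts[r] for r in SAGITTAL_ROLES},
            frontal={r: pts[r] for r in FRONTAL_ROLES},
            spinous=pts["SP"],
        )
        out.setdefault(str(subject), []).append(lm)
    for subject, lms in out.items():
        lms.sort(key=lambda lm: level_index(lm.level))
    return out


def geometry_to_frame(geom: SpineGeometry) -> pd.DataFrame:
    rows = [
        (
            p.level,
            *p.center,
            p.sagittal_rot,
            p.frontal_rot,
            p.axial_rot,
            p.h_sagittal,
            p.h_total,
        )
        for p in geom.poses
    ]
    return pd.DataFrame(
        rows,
        columns=["level", "x", "y", "z", "sagittal_rot", "frontal_rot", "axial_rot", "h_sagittal", "h_total"],
    )


def export_geometry(geom: SpineGeometry, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Per-level CSV plus a JSON curve summary (cobb, apex, convexity)."""
    geometry_to_frame(geom).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "cobb_deg": geom.cobb_deg,
            "apex_level": geom.apex_level,
            "convexity": geom.convexity,
            "upper_end": geom.upper_end,
            "lower_end": geom.lower_end,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))
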