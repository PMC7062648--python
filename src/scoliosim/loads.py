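"""External load conditions for simulated load carrying.

Loads of 10, 15 or 20% of body weight are applied at the scapula attachment
points: a regular backpack pulls 20 deg dorsally angled (split equally
between sides), a frontpack 25 deg ventrally angled, and a sidepack 5 deg
dorsally plus 10 deg laterally angled at the single shoulder on the concave
or convex side of the curve.  Angles tilt the force vector away from
straight-down: sagittal tilt first, then lateral tilt away from the body
midline on the carrying side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2, exactly

MODES = ("unloaded", "backpack", "frontpack", "sidepack_concave", "sidepack_convex")

#: Per-mode geometry: sagittal tilt (deg; + = ventral/anterior), lateral
#: tilt (deg, away from the midline), and whether both shoulders carry.
MODE_GEOMETRY: dict[str, dict] = {
    "backpack": {"sagittal_deg": -20.0, "lateral_deg": 0.0, "bilateral": True},
    "frontpack": {"sagittal_deg": 25.0, "lateral_deg": 0.0, "bilateral": True},
    "sidepack_concave": {"sagittal_deg": -5.0, "lateral_deg": 10.0, "bilateral": False},
    "sidepack_convex": {"sagittal_deg": -5.0, "lateral_deg": 10.0, "bilateral": False},
}


@dataclass
class LoadCondition:
    """One carrying condition: point forces in the global frame (N)."""

    mode: str
    pct_bw: float
    forces: list[tuple[str, np.ndarray]] = field(default_factory=list)
    # each entry: (scapula side "left"/"right", 3D force vector N)

    @property
    def total_magnitude(self) -> float:
        return float(sum(np.linalg.norm(f) for _, f in self.forces))


def _tilted_down(sagittal_deg: float, lateral_deg: float, lateral_sign: float) -> np.ndarray:
    """Unit force direction: gravity-down tilted sagittally then laterally."""
    sag = math.radians(sagittal_deg)
    lat = math.radians(lateral_deg)
    # sagittal tilt in the x-y plane, then lateral tilt toward +-z
    v = np.array([math.sin(sag), -math.cos(sag), 0.0])
    c, s = math.cos(lat), math.sin(lat)
    # rotate the downward component toward the carrying side (+-z)
    return np.array([v[0], v[1] * c, -v[1] * s * lateral_sign])


def make_load(
    mode: str,
    pct_bw: float,
    mass_kg: float,
    convexity: Optional[str] = None,
) -> LoadCondition:
    """Build the load condition for one carrying mode.

    ``convexity`` ("left"/"right") is required for the sidepack modes: the
    single force acts at the scapula point on the concave or convex side.
    Total force magnitude is pct_bw/100 * mass * g.
    """
    if mode not in MODES:
        raise ValueError(f"unknown carrying mode {mode!r}")
    if mode == "unloaded" or pct_bw == 0:
        return LoadCondition(mode="unloaded", pct_bw=0.0, forces=[])
    if pct_bw not in (10.0, 15.0, 20.0):
        logger.warning("non-standard load magnitude %s%% BW", pct_bw)
    total = pct_bw / 100.0 * mass_kg * GRAVITY
    geo = MODE_GEOMETRY[mode]
    if geo["bilateral"]:
        forces = []
        for side in ("left", "right"):
            u = _tilted_down(geo["sagittal_deg"], 0.0, 0.0)
            forces.append((side, 0.5 * total * u))
        return LoadCondition(mode=mode, pct_bw=pct_bw, forces=forces)
    if convexity not in ("left", "right"):
        raise ValueError("sidepack modes require the curve convexity")
    concave = "right" if convexity == "left" else "left"
    side = concave if mode == "sidepack_concave" else convexity
    lateral_sign = 1.0 if side == "left" else -1.0  # away from midline
    u = _tilted_down(geo["sagittal_deg"], geo["lateral_deg"], lateral_sign)
    return LoadCondition(mode=mode, pct_bw=pct_bw, forces=[(side, total * u)])
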