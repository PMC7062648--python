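"""Coordinate conventions and vertebral level bookkeeping.

Global frame (right-handed): x = anterior, y = superior, z = subject's left.
Sagittal plane = x-y, frontal plane = z-y; both radiographic planes share the
calibrated y (superior) axis.

Vertebral orientation is a body-fixed Z-X-Y sequence:
Rz(sagittal) -> Rx(-frontal) -> Ry(axial), so that

* sagittal_rot > 0 tips the anterior endplate edge up (extension),
  sagittal_rot < 0 is flexion;
* frontal_rot > 0 raises the subject's left endplate edge (the endplate line
  in the frontal plane makes angle +frontal_rot with the z axis);
* axial_rot > 0 rotates the anterior body toward the right, carrying the
  spinous process toward the subject's left (+z).

Angles are degrees at every interface and radians only inside formulas.
"""

from __future__ import annotations

import numpy as np

#: T1..L5 in cranial-to-caudal order (the 17 modeled vertebrae).
LEVELS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)

_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}

THORACIC_LEVELS = LEVELS[:12]
LUMBAR_LEVELS = LEVELS[12:]


def level_index(level: str) -> int:
    """Index of a vertebral label in cranial-to-caudal order (T1 -> 0)."""
    try:
        return _LEVEL_INDEX[level]
    except KeyError:
        raise ValueError(f"unknown vertebral level {level!r}") from None


def level_at(index: int) -> str:
    if not 0 <= index < len(LEVELS):
        raise ValueError(f"vertebral index {index} outside T1..L5")
    return LEVELS[index]


def rot_z(a_rad: float) -> np.ndarray:
    c, s = np.cos(a_rad), np.sin(a_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(a_rad: float) -> np.ndarray:
    c, s = np.cos(a_rad), np.sin(a_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(a_rad: float) -> np.ndarray:
    c, s = np.cos(a_rad), np.sin(a_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def vertebral_rotation(sagittal_deg: float, frontal_deg: float, axial_deg: float) -> np.ndarray:
    """Rotation matrix of a vertebra from its three interface angles."""
    return (
        rot_z(np.deg2rad(sagittal_deg))
        @ rot_x(-np.deg2rad(frontal_deg))
        @ rot_y(np.deg2rad(axial_deg))
    )
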