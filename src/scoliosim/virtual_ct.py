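"""Virtual CT scan: equivalent muscle cross-sectional areas per mid-plane.

Each fascicle's equivalent cross-sectional area is its maximum force
capacity divided by a uniform maximal muscle stress (MMS, 100 N/cm^2 by
default).  The group CSA at a vertebral mid-plane -- the transverse plane
through the vertebra's centre with the vertebra's local superior axis as
normal -- is the sum over the group's fascicles whose path crosses that
plane (consecutive path points on opposite sides; touching counts).  This
makes the model's muscle geometry comparable with imaging studies, via
convex-to-concave asymmetry ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .frames import LEVELS
from .model import ModelSpec

GROUPS = ("ES", "MF", "RA", "EO", "IO", "TR", "PS", "QL", "IC", "LD")


@dataclass
class CSATable:
    """Per (level, group, side) equivalent CSA in cm^2."""

    table: pd.DataFrame  # columns: level, group, side, csa_cm2
    mms_n_per_cm2: float

    def csa(self, level: str, group: str, side: str) -> float:
        df = self.table
        sel = df[(df.level == level) & (df.group == group) & (df.side == side)]
        return float(sel.csa_cm2.iloc[0]) if len(sel) else 0.0


def virtual_ct_scan(model: ModelSpec) -> CSATable:
    """Group CSAs per side at every thoracic and lumbar vertebral mid-plane."""
    mms = float(model.config.get("mms_n_per_cm2", 100.0))
    rows = []
    for lvl in LEVELS:
        acc: dict[tuple[str, str], float] = {}
        for fas in model.fascicles:
            if model.fascicle_crosses_level(fas, lvl):
                key = (fas.group, fas.side)
                acc[key] = acc.get(key, 0.0) + fas.fmax / mms
        for group in GROUPS:
            for side in ("left", "right"):
                rows.append((lvl, group, side, acc.get((group, side), 0.0)))
    return CSATable(
        table=pd.DataFrame(rows, columns=["level", "group", "side", "csa_cm2"]),
        mms_n_per_cm2=mms,
    )


def asymmetry_ratio(table: CSATable, group: str, level: str, convexity: str) -> float:
    """Convex-side CSA divided by concave-side CSA at one level.

    Returns NaN when the concave-side CSA is zero (undefined sentinel).
    """
    if convexity not in ("left", "right"):
        raise ValueError("convexity must be 'left' or 'right'")
    concave = "right" if convexity == "left" else "left"
    num = table.csa(level, group, convexity)
    den = table.csa(level, group, concave)
    if den == 0.0:
        return float("nan")
    return num / den


def csa_frame(model: ModelSpec, subject_id: str = "") -> pd.DataFrame:
    """Long-format CSA export (subject_id, level, group, side, csa_cm2)."""
    df = virtual_ct_scan(model).table.copy()
    df.insert(0, "subject_id", subject_id)
    return df
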