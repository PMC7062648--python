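"""Joint reaction analysis: intersegmental compressive forces.

For each intervertebral joint the transmitted force is the sum of gravity,
external loads, support forces and muscle forces acting on all bodies
superior to the joint -- the load the cranial chain passes to the caudal
body.  The axial compressive component is its projection on the caudal
vertebra's local superior axis at the reference pose (not the global
vertical), with compression positive; this projection is what makes the
deformed-versus-undeformed comparison nontrivial.

"Level" maps to the joint immediately caudal to the named vertebra (the
apical vertebra's inferior disc).  Reported levels of interest are the apex
and one and two levels above and below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import LEVELS, level_index
from .loads import LoadCondition
from .model import ModelSpec
from .optimization import Posture, SolveResult, _external_forces, _gravity_loads

LEVEL_OFFSETS = (-2, -1, 0, 1, 2)  # apex-2 .. apex+2 (negative = above)


@dataclass
class ReactionResult:
    """Per-joint transmitted forces and axial compressive components."""

    joint_names: list[str]
    cranial_levels: list[str]
    reaction_local: np.ndarray  # (n_joints, 3), caudal-frame components, N
    axial_compression: np.ndarray  # N, positive = compression

    def compression_at_level(self, level: str) -> float:
        """Axial compression at the joint immediately caudal to ``level``."""
        return float(self.axial_compression[self.cranial_levels.index(level)])

    def levels_of_interest(self, apex_level: str) -> dict[int, float]:
        """Compression at apex-2 .. apex+2 keyed by level offset."""
        idx = level_index(apex_level)
        out = {}
        for off in LEVEL_OFFSETS:
            j = idx + off
            if 0 <= j < len(LEVELS):
                out[off] = self.compression_at_level(LEVELS[j])
        return out


def compute_reactions(
    model: ModelSpec,
    posture: Posture,
    loads: LoadCondition | None,
    result: SolveResult,
    residual_tol: float = 1e-6,
) -> ReactionResult:
    """Transmitted joint forces from an accepted static-optimization solve."""
    if result.residual_norm > residual_tol:
        raise ValueError(
            f"solve residual {result.residual_norm:.3e} exceeds {residual_tol}; "
            "reactions require an equilibrated model"
        )
    ranks = {name: seg.rank for name, seg in model.segments.items()}
    grav = _gravity_loads(model, posture)
    ext = _external_forces(model, loads)
    sup_forces = [
        (seg, point, force)
        for (seg, point), force in zip(posture.supports, result.support_forces)
    ]

    names, cranial, local_vecs, axial = [], [], [], []
    for joint in model.joints:
        sup_rank = joint.cranial_rank
        f_sum = np.zeros(3)
        for seg, point, force in grav + ext + sup_forces:
            if ranks[seg] >= sup_rank:
                f_sum += force
        line_elements = [
            (fas.path, result.activations[fas.name] * fas.fmax) for fas in model.fascicles
        ] + [(s.path, result.strut_forces[s.name]) for s in model.struts]
        for path, f in line_elements:
            if f == 0.0:
                continue
            for (seg_a, p_a), (seg_b, p_b) in zip(path[:-1], path[1:]):
                ra, rb = ranks[seg_a], ranks[seg_b]
                if (ra >= sup_rank) == (rb >= sup_rank):
                    continue
                p_sup, p_inf = (p_a, p_b) if ra >= sup_rank else (p_b, p_a)
                u = p_inf - p_sup
                u = u / np.linalg.norm(u)
                f_sum += f * u
        r_caudal = (
            model.vertebra_rotation(joint.caudal) if joint.caudal != "S1" else np.eye(3)
        )
        local = r_caudal.T @ f_sum
        names.append(joint.name)
        cranial.append(joint.cranial)
        local_vecs.append(local)
        axial.append(-local[1])  # minus the superior-axis component
    return ReactionResult(
        joint_names=names,
        cranial_levels=cranial,
        reaction_local=np.array(local_vecs),
        axial_compression=np.array(axial),
    )


def percent_of(
    current: ReactionResult,
    reference: ReactionResult,
    apex_level: str,
) -> dict[int, float]:
    """Compression at apex+-2 as a percentage of a reference condition.

    A non-positive reference yields NaN (undefined sentinel, excluded from
    cohort medians).
    """
    cur = current.levels_of_interest(apex_level)
    ref = reference.levels_of_interest(apex_level)
    out = {}
    for off, value in cur.items():
        r = ref.get(off)
        out[off] = float("nan") if r is None or r <= 0 else 100.0 * value / r
    return out
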