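"""Inverse-dynamics based static optimization at the reference pose.

At a fixed (neutral) posture the required moment at every intervertebral
degree of freedom equals minus the moment of gravity and external loads on
all bodies superior to the joint.  The muscle redundancy is resolved by
minimizing the sum of squared activations, subject to exact moment
equilibrium per degree of freedom, activation bounds [0, 1], axial-rotation
reserve actuators, and ground/table support actuators with an optimal force
of 10 kN.  Muscle force-length and force-velocity properties are not
modeled: fascicle force is simply activation times Fmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .frames import LUMBAR_LEVELS, THORACIC_LEVELS
from .loads import LoadCondition
from .model import ModelSpec
from .qp import InfeasibleError, solve_box_eq_qp

AXIS_NAMES = ("flexion", "lateral", "axial")

__all__ = [
    "Posture",
    "EquilibriumSystem",
    "SolveResult",
    "standing_posture",
    "prone_posture",
    "assemble_system",
    "solve",
    "activity_ratio",
    "InfeasibleError",
]


@dataclass
class Posture:
    """A static simulation posture: gravity direction and support contacts."""

    name: str
    gravity_dir: np.ndarray  # unit vector, global frame
    supports: list[tuple[str, np.ndarray]]  # (segment, global contact point)

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_dir, dtype=float)
        n = np.linalg.norm(g)
        if n == 0:
            raise ValueError("gravity direction must be a nonzero vector")
        self.gravity_dir = g / n
        if not self.supports:
            raise ValueError("at least one support point is required")


def standing_posture(model: ModelSpec) -> Posture:
    """Neutral upright standing: gravity -y, four foot contacts (heel/toe
    per foot) on the pelvis support path."""
    h = model.height_cm / 100.0
    pts = [
        np.array([sx * 0.06 * h, -0.53 * h, sz * 0.05 * h])
        for sx in (-1.0, 1.0)
        for sz in (-1.0, 1.0)
    ]
    return Posture("standing", np.array([0.0, -1.0, 0.0]), [("pelvis", p) for p in pts])


def prone_posture(model: ModelSpec) -> Posture:
    """Prone lying: gravity along the body's anterior (+x) axis, support
    contacts on the anterior thorax (rib carrier) and the pelvis."""
    h = model.height_cm / 100.0
    t6 = model.vertebra_center("T6")
    supports = [
        ("carrier_T6", t6 + np.array([0.07 * h, 0.0, 0.04 * h])),
        ("carrier_T6", t6 + np.array([0.07 * h, 0.0, -0.04 * h])),
        ("pelvis", np.array([0.06 * h, -0.08 * h, 0.05 * h])),
        ("pelvis", np.array([0.06 * h, -0.08 * h, -0.05 * h])),
    ]
    return Posture("prone", np.array([1.0, 0.0, 0.0]), supports)


@dataclass
class EquilibriumSystem:
    """Linear equilibrium system at the reference pose.

    Rows: 3 dofs per intervertebral joint (flexion, lateral, axial) followed
    by the 6 whole-body equations (net force, net moment about the origin).
    Columns: fascicle activations, axial reserve activations, support force
    components -- all dimensionless, scaled by Fmax, the reserve optimal
    moment and the support optimal force respectively.
    """

    dof_labels: list[str]
    A: np.ndarray
    required: np.ndarray  # N*m (joint rows) / N (global force rows)
    n_fascicles: int
    n_reserves: int
    n_struts: int
    n_supports: int  # number of support force components (3 per point)
    lb: np.ndarray
    ub: np.ndarray
    model: ModelSpec
    posture: Posture
    loads: Optional[LoadCondition]

    @property
    def n_joint_dofs(self) -> int:
        return 3 * len(self.model.joints)


@dataclass
class SolveResult:
    activations: dict[str, float]
    reserve_moments: dict[str, float]  # N*m per axial dof (joint name keyed)
    strut_forces: dict[str, float]  # N, signed (positive = pulling endpoints together)
    support_forces: list[np.ndarray]  # N, one 3-vector per support point
    objective: float
    residual_norm: float  # max |equilibrium residual|, N*m / N
    x: np.ndarray = field(repr=False, default=None)

    def activation(self, fascicle_name: str) -> float:
        return self.activations[fascicle_name]


def _gravity_loads(model: ModelSpec, posture: Posture) -> list[tuple[str, np.ndarray, np.ndarray]]:
    g = 9.81 * posture.gravity_dir
    return [(s.name, s.com, s.mass * g) for s in model.segments.values() if s.mass > 0]


def _external_forces(
    model: ModelSpec, loads: Optional[LoadCondition]
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    if loads is None:
        return []
    out = []
    for side, force in loads.forces:
        seg, point = model.scapula_points[side]
        out.append((seg, point, np.asarray(force, dtype=float)))
    return out


def assemble_system(
    model: ModelSpec,
    posture: Posture,
    loads: Optional[LoadCondition] = None,
) -> EquilibriumSystem:
    """Build the equilibrium system for a model at its reference pose.

    The neutral-pose-only contract is enforced: every bushing must produce
    zero moment at the model's reference angles.
    """
    for b in model.bushings:
        ref = model.reference_joint_angles(b.joint)
        if np.any(np.abs(b.moment(ref)) > 1e-9):
            raise ValueError(
                f"bushing {b.joint} has nonzero passive moment at the reference "
                "pose (non-neutral configuration); only neutral-pose "
                "simulations are supported"
            )

    ranks = {name: seg.rank for name, seg in model.segments.items()}
    joints = model.joints
    nj = len(joints)
    grav = _gravity_loads(model, posture)
    ext = _external_forces(model, loads)

    n_f = len(model.fascicles)
    n_r = nj  # one axial reserve per joint
    n_t = len(model.struts)
    n_s = 3 * len(posture.supports)
    ncol = n_f + n_r + n_t + n_s
    nrow = 3 * nj + 6
    A = np.zeros((nrow, ncol))
    required = np.zeros(nrow)
    labels: list[str] = []

    r_opt = model.reserve_opt_nm
    s_opt = model.support_opt_n
    eye = np.eye(3)

    def line_moment(path, sup_rank: int, c: np.ndarray) -> np.ndarray:
        """Moment per unit tension on the superior chain about point c."""
        col = np.zeros(3)
        for (seg_a, p_a), (seg_b, p_b) in zip(path[:-1], path[1:]):
            ra, rb = ranks[seg_a], ranks[seg_b]
            if (ra >= sup_rank) == (rb >= sup_rank):
                continue
            p_sup, p_inf = (p_a, p_b) if ra >= sup_rank else (p_b, p_a)
            u = p_inf - p_sup
            u = u / np.linalg.norm(u)
            col += np.cross(p_sup - c, u)
        return col

    for k, joint in enumerate(joints):
        sup_rank = joint.cranial_rank
        c = joint.position
        for axis_name in AXIS_NAMES:
            labels.append(f"{joint.name}:{axis_name}")
        axes = joint.axes  # columns flexion, lateral, axial
        # required moments from gravity + external loads on the superior chain
        m_ext = np.zeros(3)
        for seg, point, force in grav + ext:
            if ranks[seg] >= sup_rank:
                m_ext += np.cross(point - c, force)
        required[3 * k : 3 * k + 3] = -(axes.T @ m_ext)
        for fi, fas in enumerate(model.fascicles):
            col = line_moment(fas.path, sup_rank, c)
            if np.any(col):
                A[3 * k : 3 * k + 3, fi] = fas.fmax * (axes.T @ col)
        # axial reserve column for this joint
        A[3 * k + 2, n_f + k] = r_opt
        # rib-cage strut columns (signed tension)
        for ti, strut in enumerate(model.struts):
            col = line_moment(strut.path, sup_rank, c)
            if np.any(col):
                A[3 * k : 3 * k + 3, n_f + n_r + ti] = strut.opt_force * (axes.T @ col)
        # support columns for supports attached above the joint
        for si, (seg, point) in enumerate(posture.supports):
            if ranks[seg] >= sup_rank:
                for ci in range(3):
                    A[3 * k : 3 * k + 3, n_f + n_r + n_t + 3 * si + ci] = s_opt * (
                        axes.T @ np.cross(point - c, eye[ci])
                    )

    # Whole-body equations: net force and net moment about the origin.
    labels += [f"global:force_{ax}" for ax in "xyz"]
    labels += [f"global:moment_{ax}" for ax in "xyz"]
    f_tot = np.zeros(3)
    m_tot = np.zeros(3)
    for seg, point, force in grav + ext:
        f_tot += force
        m_tot += np.cross(point, force)
    required[3 * nj : 3 * nj + 3] = -f_tot
    required[3 * nj + 3 :] = -m_tot
    for si, (seg, point) in enumerate(posture.supports):
        for ci in range(3):
            col = n_f + n_r + n_t + 3 * si + ci
            A[3 * nj + ci, col] = s_opt
            A[3 * nj + 3 :, col] = s_opt * np.cross(point, eye[ci])

    strut_mult = np.array([s.max_mult for s in model.struts]) if n_t else np.zeros(0)
    lb = np.concatenate(
        [np.zeros(n_f), -50.0 * np.ones(n_r), -strut_mult, -2.0 * np.ones(n_s)]
    )
    ub = np.concatenate(
        [np.ones(n_f), 50.0 * np.ones(n_r), strut_mult, 2.0 * np.ones(n_s)]
    )
    return EquilibriumSystem(
        dof_labels=labels,
        A=A,
        required=required,
        n_fascicles=n_f,
        n_reserves=n_r,
        n_struts=n_t,
        n_supports=n_s,
        lb=lb,
        ub=ub,
        model=model,
        posture=posture,
        loads=loads,
    )


def solve(system: EquilibriumSystem, weights: Optional[dict] = None) -> SolveResult:
    """Minimize sum(a^2) + sum((reserve/R_opt)^2) + sum((support/10kN)^2)
    subject to exact equilibrium on every degree of freedom."""
    w = {"activation": 1.0, "reserve": 1.0, "strut": 1.0, "support": 1.0}
    if weights:
        w.update(weights)
    h = np.concatenate(
        [
            2.0 * w["activation"] * np.ones(system.n_fascicles),
            2.0 * w["reserve"] * np.ones(system.n_reserves),
            2.0 * w["strut"] * np.ones(system.n_struts),
            2.0 * w["support"] * np.ones(system.n_supports),
        ]
    )
    x, _ = solve_box_eq_qp(
        h,
        system.A,
        system.required,
        system.lb,
        system.ub,
        residual_tol=1e-6,
        row_labels=system.dof_labels,
    )
    resid = system.A @ x - system.required
    model = system.model
    n_f, n_r, n_t = system.n_fascicles, system.n_reserves, system.n_struts
    activations = {f.name: float(x[i]) for i, f in enumerate(model.fascicles)}
    reserves = {
        j.name: float(x[n_f + k] * model.reserve_opt_nm) for k, j in enumerate(model.joints)
    }
    struts = {
        s.name: float(x[n_f + n_r + ti] * s.opt_force) for ti, s in enumerate(model.struts)
    }
    base = n_f + n_r + n_t
    sup = [
        model.support_opt_n * x[base + 3 * si : base + 3 * si + 3]
        for si in range(len(system.posture.supports))
    ]
    obj = float(np.sum(x**2))
    return SolveResult(
        activations=activations,
        reserve_moments=reserves,
        strut_forces=struts,
        support_forces=sup,
        objective=obj,
        residual_norm=float(np.max(np.abs(resid))),
        x=x,
    )


REGIONS = {"thoracic": list(THORACIC_LEVELS), "lumbar": list(LUMBAR_LEVELS)}


def activity_ratio(
    result: SolveResult,
    model: ModelSpec,
    group: str,
    levels: list[str] | str,
    convexity: str,
) -> float:
    """Convex-to-concave ratio of mean group activation over selected levels.

    ``levels`` is a list of vertebral labels or a named region ("thoracic",
    "lumbar").  A fascicle counts toward a level when its path crosses that
    vertebra's mid-plane.  Returns NaN when the concave-side mean is zero
    (undefined-ratio sentinel, excluded from cohort medians).
    """
    if isinstance(levels, str):
        levels = REGIONS[levels]
    if convexity not in ("left", "right"):
        raise ValueError("convexity must be 'left' or 'right'")
    concave = "right" if convexity == "left" else "left"
    sides = {convexity: [], concave: []}
    for fas in model.fascicles:
        if fas.group != group:
            continue
        if any(model.fascicle_crosses_level(fas, lvl) for lvl in levels):
            sides[fas.side].append(result.activations[fas.name])
    if not sides[convexity] or not sides[concave]:
        return float("nan")
    num = float(np.mean(sides[convexity]))
    den = float(np.mean(sides[concave]))
    if den == 0.0:
        return float("nan")
    return num / den
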