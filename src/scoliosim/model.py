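"""Parametric musculoskeletal spine model and subject-specific construction.

The model is a chain of rigid bodies -- pelvis (with lumped lower limbs),
sacrum, the 17 vertebrae L5..T1, a lumped head+neck segment, two arms, and
per-level soft-tissue carriers (rib cage mass over T1-T12, abdominal mass
over L1-L5) -- connected by 17 intervertebral joints (T1/T2 .. L5/S1), each
with three rotational degrees of freedom.  Trunk muscles are straight-line
fascicles with a maximum isometric force (Fmax): erector spinae (ES),
multifidus (MF), rectus abdominis (RA) and external/internal obliques
(EO/IO).  Passive bushing elements produce moments for rotations away from
the reference pose, and reserve actuators absorb axial-rotation residuals.

Subject-specific models are built in four steps: (1) scale the base model by
stature and body mass, (2) impose the subject's 3D vertebral orientations
(flexion/extension, lateral bending, axial rotation), (3) scale the
intersegmental joint distances by the measured vertebral body heights, and
(4) re-neutralize the head+neck, arms and rib/abdominal carriers so their
global orientation is upright regardless of the underlying curve.  The
bushing neutral pose is reset to the deformed reference angles, so passive
moments vanish identically in the simulated (neutral) posture.

All positions are metres in the global frame of :mod:`scoliosim.frames`;
masses kg, forces N.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .frames import LEVELS, THORACIC_LEVELS, level_index, vertebral_rotation
from .geometry import REFERENCE_HEIGHT_CM, SpineGeometry, VertebralPose
from .synthetic import generate_curve

MM_TO_M = 1e-3

#: Default model configuration.  Segment mass fractions and the fascicle
#: table are standard-anthropometry stand-ins: the exact values are
#: configuration, not contract.
DEFAULT_MODEL_CONFIG: dict = {
    "mass_fractions": {
        "head_neck": 0.08,
        "arm": 0.05,  # each
        "thorax": 0.20,  # distributed over T1-T12 slices
        "abdomen": 0.12,  # distributed over L1-L5 slices
        "pelvis": 0.12,
        "sacrum": 0.03,
        "lower_limbs": 0.35,  # lumped into the pelvis support path
    },
    "soft_tissue_fraction": 0.7,  # slice mass share on the carrier
    "offsets": {  # fractions of stature
        "rib_carrier_anterior": 0.030,
        "abd_carrier_anterior": 0.020,
        "head_up": 0.10,
        "head_anterior": 0.010,
        "arm_down": 0.12,
        "scapula_lateral": 0.065,
        "scapula_posterior": 0.02,
    },
    "sagittal": {"kyphosis_deg": 30.0, "lordosis_deg": 45.0},
    "muscles": {
        "ES": {"csa_cm2": 3.8, "ins_posterior": 0.028, "ins_lateral": 0.022,
               "ins_lateral_thoracic": 0.038, "origin": (-0.030, -0.030, 0.022)},
        "MF": {"csa_cm2": 1.8, "ins_posterior": 0.025, "ins_lateral": 0.008,
               "span": 3, "sacrum_origin": (-0.028, -0.020, 0.010)},
        "RA": {"csa_cm2": 6.0, "origin": (0.055, -0.080, 0.018),
               "ins_level": "T8", "ins_anterior": 0.065, "ins_lateral": 0.018},
        "EO": {"csa_cm2": 6.5, "origin": (0.010, -0.060, 0.055),
               "ins_level": "T10", "ins_anterior": 0.045, "ins_lateral": 0.032},
        "IO": {"csa_cm2": 5.5, "origin": (0.030, -0.070, 0.045),
               "ins_level": "T12", "ins_anterior": 0.050, "ins_lateral": 0.022},
        # Trapezius-like shoulder-girdle fascicles: the muscular path that
        # routes scapular loads into the upper/mid thoracic spine.
        "TR": {"csa_cm2": 1.6, "ins_posterior": 0.028, "ins_lateral": 0.015,
               "levels": ["T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8"]},
        # Psoas-like per-level lumbar flexors (anterolateral of the bodies).
        "PS": {"csa_cm2": 1.6, "ins_anterior": 0.010, "ins_lateral": 0.025,
               "origin": (0.040, -0.120, 0.030),
               "levels": ["L1", "L2", "L3", "L4", "L5"]},
        # Quadratus-lumborum-like per-level lateral benders.
        "QL": {"csa_cm2": 1.8, "ins_posterior": 0.005, "ins_lateral": 0.030,
               "origin": (-0.010, -0.050, 0.045),
               "levels": ["T12", "L1", "L2", "L3", "L4"]},
        # Intercostal-like single-joint fascicles between adjacent rib/
        # abdominal carriers: the local anterior/lateral path each thoracic
        # joint needs (the anatomical rib cage couples levels the same way).
        "IC": {"csa_cm2": 3.0, "anterior": 0.050, "lateral": 0.062},
        # Latissimus-like shoulder-to-pelvis sling: the long wide-arm path
        # that counters one-sided shoulder loads across the whole trunk.
        "LD": {"csa_cm2": 4.0, "pelvis": (-0.020, -0.050, 0.050)},
    },
    # Passive rib-cage / trunk-wall struts: the bony cage and the abdominal
    # wall transmit sustained one-sided bending as push-pull structural pairs
    # (muscles can only pull).  Long spans carry a uniform moment across all
    # crossed joints at a single cost, but cannot serve the small
    # alternating intersegmental demands, which stay with the muscles.
    "rib_cage": {"strut_opt_n": 500.0, "anterior": 0.0, "lateral": 0.070,
                 "pelvis_lateral": 0.055, "max_mult": 4.0,
                 "spans": [["T1", "T2"], ["T2", "T3"], ["T3", "T4"], ["T4", "T5"],
                            ["T5", "T6"], ["T6", "T7"]]},
    "mms_n_per_cm2": 100.0,
    "bushing": {"type": "linear", "flex_ext_nm_per_deg": 1.5, "lateral_nm_per_deg": 1.7},
    "reserve_opt_nm": 25.0,
    "support_opt_n": 10000.0,
}


class ModelBuildError(ValueError):
    """Raised for inconsistent model configuration or geometry."""


@dataclass
class BodySegment:
    name: str
    mass: float  # kg
    com: np.ndarray  # m, global frame
    rank: int  # position along the support chain (pelvis=0 .. head)

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ModelBuildError(f"segment {self.name}: negative mass")
        self.com = np.asarray(self.com, dtype=float)


@dataclass
class MuscleFascicle:
    name: str
    group: str  # ES | MF | RA | EO | IO
    side: str  # left | right
    path: list[tuple[str, np.ndarray]]  # (segment name, global point)
    fmax: float  # N

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ModelBuildError(f"fascicle {self.name}: needs >= 2 path points")
        if self.fmax <= 0:
            raise ModelBuildError(f"fascicle {self.name}: fmax must be > 0")
        self.path = [(seg, np.asarray(p, dtype=float)) for seg, p in self.path]


@dataclass
class Joint:
    """One 3-DOF intervertebral joint.

    ``axes`` columns are the flexion/extension, lateral-bending and axial
    unit axes -- the caudal vertebra's local z, x and y at the reference pose.
    """

    name: str
    cranial: str  # cranial vertebra level
    caudal: str  # caudal segment label (vertebra or S1)
    position: np.ndarray  # m
    axes: np.ndarray  # 3x3, columns = (flexion, lateral, axial)
    cranial_rank: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)


@dataclass
class BushingElement:
    """Passive moment element of one joint, zero at the neutral pose."""

    joint: str
    flex_ext_nm_per_deg: float
    lateral_nm_per_deg: float
    neutral_deg: np.ndarray  # (flexion, lateral, axial) reference angles
    curve: str = "linear"  # linear | cubic

    def __post_init__(self) -> None:
        self.neutral_deg = np.asarray(self.neutral_deg, dtype=float)

    def moment(self, angles_deg: Sequence[float]) -> np.ndarray:
        """Passive (flexion, lateral) moments in N*m at the given joint angles;
        odd-symmetric about the neutral pose, axial handled by reserves."""
        d = np.asarray(angles_deg, dtype=float) - self.neutral_deg
        if self.curve == "cubic":
            flex = self.flex_ext_nm_per_deg * d[0] ** 3
            lat = self.lateral_nm_per_deg * d[1] ** 3
        else:
            flex = self.flex_ext_nm_per_deg * d[0]
            lat = self.lateral_nm_per_deg * d[1]
        return np.array([flex, lat])


@dataclass
class RibStrut:
    """Passive rib-cage force element between two carrier points.

    Carries a signed axial force (push or pull) along the line between its
    endpoints, with a quadratic cost normalized by ``opt_force`` in the
    static optimization.
    """

    name: str
    side: str
    path: list[tuple[str, np.ndarray]]
    opt_force: float  # N
    max_mult: float = 4.0  # force bounds = +- max_mult * opt_force

    def __post_init__(self) -> None:
        self.path = [(seg, np.asarray(p, dtype=float)) for seg, p in self.path]


@dataclass
class ModelSpec:
    """A fully assembled subject model at its static reference pose."""

    age_y: float
    sex: str
    height_cm: float
    mass_kg: float
    geometry: SpineGeometry
    segments: dict[str, BodySegment]
    joints: list[Joint]  # caudal-to-cranial: L5/S1 first, T1/T2 last
    fascicles: list[MuscleFascicle]
    bushings: list[BushingElement]
    scapula_points: dict[str, tuple[str, np.ndarray]]
    struts: list[RibStrut] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    @property
    def reserve_opt_nm(self) -> float:
        return float(self.config.get("reserve_opt_nm", 2.0))

    @property
    def support_opt_n(self) -> float:
        return float(self.config.get("support_opt_n", 10000.0))

    def joint_for_level(self, level: str) -> Joint:
        """The joint immediately caudal to a vertebra (its inferior disc)."""
        for j in self.joints:
            if j.cranial == level:
                return j
        raise KeyError(level)

    def vertebra_rotation(self, level: str) -> np.ndarray:
        p = self.geometry.pose(level)
        return vertebral_rotation(p.sagittal_rot, p.frontal_rot, p.axial_rot)

    def vertebra_center(self, level: str) -> np.ndarray:
        return self.segments[level].com  # vertebra segment com is the centre

    def midplane(self, level: str) -> tuple[np.ndarray, np.ndarray]:
        """(point, unit normal) of the vertebra's transverse mid-plane."""
        return self.vertebra_center(level), self.vertebra_rotation(level)[:, 1]

    def fascicle_crosses_level(self, fas: MuscleFascicle, level: str) -> bool:
        """True iff consecutive path points straddle (or touch) the mid-plane.

        Points within 1e-9 m of the plane count as on it, so attachment
        points lying exactly on a mid-plane register despite rounding.
        """
        c, n = self.midplane(level)
        s = [float(np.dot(p - c, n)) for _, p in fas.path]
        s = [0.0 if abs(v) < 1e-9 else v for v in s]
        return any(s[k] * s[k + 1] <= 0.0 for k in range(len(s) - 1))

    def reference_joint_angles(self, joint_name: str) -> np.ndarray:
        """Intervertebral (flexion, lateral, axial) reference angles, deg."""
        joint = next(j for j in self.joints if j.name == joint_name)
        pc = self.geometry.pose(joint.cranial)
        if joint.caudal == "S1":
            return np.array([pc.sagittal_rot, pc.frontal_rot, pc.axial_rot])
        pd = self.geometry.pose(joint.caudal)
        return np.array(
            [
                pc.sagittal_rot - pd.sagittal_rot,
                pc.frontal_rot - pd.frontal_rot,
                pc.axial_rot - pd.axial_rot,
            ]
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "age_y": self.age_y,
            "sex": self.sex,
            "height_cm": self.height_cm,
            "mass_kg": self.mass_kg,
            "geometry": [
                {
                    "level": p.level,
                    "center_mm": list(p.center),
                    "sagittal_rot": p.sagittal_rot,
                    "frontal_rot": p.frontal_rot,
                    "axial_rot": p.axial_rot,
                    "h_sagittal": p.h_sagittal,
                    "h_total": p.h_total,
                }
                for p in self.geometry.poses
            ],
            "curve": {
                "cobb_deg": self.geometry.cobb_deg,
                "apex_level": self.geometry.apex_level,
                "convexity": self.geometry.convexity,
            },
            "segments": [
                {"name": s.name, "mass": s.mass, "com": list(s.com), "rank": s.rank}
                for s in self.segments.values()
            ],
            "joints": [
                {
                    "name": j.name,
                    "cranial": j.cranial,
                    "caudal": j.caudal,
                    "position": list(j.position),
                    "axes": j.axes.tolist(),
                    "cranial_rank": j.cranial_rank,
                }
                for j in self.joints
            ],
            "fascicles": [
                {
                    "name": f.name,
                    "group": f.group,
                    "side": f.side,
                    "path": [[seg, list(p)] for seg, p in f.path],
                    "fmax": f.fmax,
                }
                for f in self.fascicles
            ],
            "bushings": [
                {
                    "joint": b.joint,
                    "flex_ext_nm_per_deg": b.flex_ext_nm_per_deg,
                    "lateral_nm_per_deg": b.lateral_nm_per_deg,
                    "neutral_deg": list(b.neutral_deg),
                    "curve": b.curve,
                }
                for b in self.bushings
            ],
            "scapula_points": {
                side: [seg, list(p)] for side, (seg, p) in self.scapula_points.items()
            },
            "struts": [
                {
                    "name": s.name,
                    "side": s.side,
                    "path": [[seg, list(p)] for seg, p in s.path],
                    "opt_force": s.opt_force,
                    "max_mult": s.max_mult,
                }
                for s in self.struts
            ],
            "config": self.config,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        poses = [
            VertebralPose(
                level=g["level"],
                center=np.array(g["center_mm"]),
                sagittal_rot=g["sagittal_rot"],
                frontal_rot=g["frontal_rot"],
                axial_rot=g["axial_rot"],
                h_sagittal=g["h_sagittal"],
                h_total=g["h_total"],
            )
            for g in d["geometry"]
        ]
        geom = SpineGeometry(
            poses=poses,
            cobb_deg=d["curve"]["cobb_deg"],
            apex_level=d["curve"]["apex_level"],
            convexity=d["curve"]["convexity"],
        )
        return cls(
            age_y=d["age_y"],
            sex=d["sex"],
            height_cm=d["height_cm"],
            mass_kg=d["mass_kg"],
            geometry=geom,
            segments={
                s["name"]: BodySegment(s["name"], s["mass"], np.array(s["com"]), s["rank"])
                for s in d["segments"]
            },
            joints=[
                Joint(
                    name=j["name"],
                    cranial=j["cranial"],
                    caudal=j["caudal"],
                    position=np.array(j["position"]),
                    axes=np.array(j["axes"]),
                    cranial_rank=j["cranial_rank"],
                )
                for j in d["joints"]
            ],
            fascicles=[
                MuscleFascicle(
                    name=f["name"],
                    group=f["group"],
                    side=f["side"],
                    path=[(seg, np.array(p)) for seg, p in f["path"]],
                    fmax=f["fmax"],
                )
                for f in d["fascicles"]
            ],
            bushings=[
                BushingElement(
                    joint=b["joint"],
                    flex_ext_nm_per_deg=b["flex_ext_nm_per_deg"],
                    lateral_nm_per_deg=b["lateral_nm_per_deg"],
                    neutral_deg=np.array(b["neutral_deg"]),
                    curve=b["curve"],
                )
                for b in d["bushings"]
            ],
            scapula_points={
                side: (seg, np.array(p)) for side, (seg, p) in d["scapula_points"].items()
            },
            struts=[
                RibStrut(
                    name=s["name"],
                    side=s["side"],
                    path=[(seg, np.array(p)) for seg, p in s["path"]],
                    opt_force=s["opt_force"],
                    max_mult=s["max_mult"],
                )
                for s in d.get("struts", [])
            ],
            config=d["config"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _merge_config(config: Optional[dict]) -> dict:
    merged = copy.deepcopy(DEFAULT_MODEL_CONFIG)
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
    return merged


def _rank_of_level(level: str) -> int:
    # pelvis 0, sacrum 1, L5 2 .. T1 18, head_neck 19
    return 18 - level_index(level)


def _recentred(geometry: SpineGeometry) -> SpineGeometry:
    """Shift the geometry so the node below L5 sits at the origin."""
    p5 = geometry.poses[-1]
    up = vertebral_rotation(p5.sagittal_rot, p5.frontal_rot, p5.axial_rot)[:, 1]
    bottom = p5.center - 0.5 * p5.h_total * up
    geom = copy.deepcopy(geometry)
    for p in geom.poses:
        p.center = p.center - bottom
    return geom


def _assemble(
    geometry: SpineGeometry,
    age_y: float,
    sex: str,
    height_cm: float,
    mass_kg: float,
    config: dict,
) -> ModelSpec:
    if len(geometry.poses) != len(LEVELS):
        raise ModelBuildError("geometry must carry all 17 poses T1..L5")
    frac = config["mass_fractions"]
    total_frac = (
        frac["head_neck"] + 2 * frac["arm"] + frac["thorax"] + frac["abdomen"]
        + frac["pelvis"] + frac["sacrum"] + frac["lower_limbs"]
    )
    if abs(total_frac - 1.0) > 1e-9:
        raise ModelBuildError(f"segment mass fractions sum to {total_frac}, not 1")

    geometry = _recentred(geometry)
    h = height_cm / 100.0  # stature in metres
    off = config["offsets"]
    soft = config["soft_tissue_fraction"]

    centers = {p.level: p.center * MM_TO_M for p in geometry.poses}
    rots = {
        p.level: vertebral_rotation(p.sagittal_rot, p.frontal_rot, p.axial_rot)
        for p in geometry.poses
    }
    heights_m = {p.level: p.h_total * MM_TO_M for p in geometry.poses}

    segments: dict[str, BodySegment] = {}
    segments["pelvis"] = BodySegment(
        "pelvis", (frac["pelvis"] + frac["lower_limbs"]) * mass_kg,
        np.array([0.0, -0.10 * h, 0.0]), 0,
    )
    segments["sacrum"] = BodySegment(
        "sacrum", frac["sacrum"] * mass_kg, np.array([0.0, -0.04 * h, 0.0]), 1
    )
    for lvl in LEVELS:
        rank = _rank_of_level(lvl)
        slice_mass = (
            frac["thorax"] * mass_kg / 12.0
            if lvl in THORACIC_LEVELS
            else frac["abdomen"] * mass_kg / 5.0
        )
        anterior = (
            off["rib_carrier_anterior"] if lvl in THORACIC_LEVELS else off["abd_carrier_anterior"]
        )
        segments[lvl] = BodySegment(lvl, (1.0 - soft) * slice_mass, centers[lvl], rank)
        # Carriers are re-neutralized (step 4): purely global anterior offset.
        segments[f"carrier_{lvl}"] = BodySegment(
            f"carrier_{lvl}", soft * slice_mass,
            centers[lvl] + np.array([anterior * h, 0.0, 0.0]), rank,
        )
    t1, t3 = centers["T1"], centers["T3"]
    segments["head_neck"] = BodySegment(
        "head_neck", frac["head_neck"] * mass_kg,
        t1 + np.array([off["head_anterior"] * h, off["head_up"] * h, 0.0]), 19,
    )
    scapula_points = {
        "left": ("T3", t3 + np.array([-off["scapula_posterior"] * h, 0.0, off["scapula_lateral"] * h])),
        "right": ("T3", t3 + np.array([-off["scapula_posterior"] * h, 0.0, -off["scapula_lateral"] * h])),
    }
    for side in ("left", "right"):
        _, sp = scapula_points[side]
        # hanging arm: com in line with T3 anteroposteriorly
        segments[f"arm_{side}"] = BodySegment(
            f"arm_{side}", frac["arm"] * mass_kg,
            np.array([t3[0], sp[1] - off["arm_down"] * h, sp[2]]), _rank_of_level("T3"),
        )

    # Joints: node below each vertebra; axes from the caudal segment.
    joints: list[Joint] = []
    for idx in range(len(LEVELS) - 1, -1, -1):
        lvl = LEVELS[idx]
        caudal = LEVELS[idx + 1] if idx + 1 < len(LEVELS) else "S1"
        pos = centers[lvl] - 0.5 * heights_m[lvl] * rots[lvl][:, 1]
        r_caudal = rots[caudal] if caudal != "S1" else np.eye(3)
        axes = np.column_stack([r_caudal[:, 2], r_caudal[:, 0], r_caudal[:, 1]])
        joints.append(
            Joint(
                name=f"{lvl}/{caudal}",
                cranial=lvl,
                caudal=caudal,
                position=pos,
                axes=axes,
                cranial_rank=_rank_of_level(lvl),
            )
        )

    # Bushings: neutral pose = the subject's intervertebral reference angles,
    # so passive moments vanish identically at the simulated pose.
    bush_cfg = config["bushing"]
    bushings = []
    for j in joints:
        pc = geometry.pose(j.cranial)
        if j.caudal == "S1":
            ref = np.array([pc.sagittal_rot, pc.frontal_rot, pc.axial_rot])
        else:
            pd = geometry.pose(j.caudal)
            ref = np.array(
                [
                    pc.sagittal_rot - pd.sagittal_rot,
                    pc.frontal_rot - pd.frontal_rot,
                    pc.axial_rot - pd.axial_rot,
                ]
            )
        bushings.append(
            BushingElement(
                joint=j.name,
                flex_ext_nm_per_deg=bush_cfg["flex_ext_nm_per_deg"],
                lateral_nm_per_deg=bush_cfg["lateral_nm_per_deg"],
                neutral_deg=ref,
                curve=bush_cfg["type"],
            )
        )

    # Muscle fascicles; attachment points on vertebrae are bone-fixed (rotate
    # with the deformity), rib/abdominal carrier attachments are neutral.
    mus = config["muscles"]
    mms = config["mms_n_per_cm2"]
    # Fascicle CSA scales with body mass: gravity and %BW-load demands grow
    # with mass x stature, muscle moment capacity with CSA x stature, so
    # mass scaling keeps strength relative to demand anthropometrics-free.
    scale2 = mass_kg / 47.5
    fascicles: list[MuscleFascicle] = []

    def zsign(side: str) -> float:
        return 1.0 if side == "left" else -1.0

    def paraspinal_point(lvl: str, posterior: float, lateral: float, zs: float) -> np.ndarray:
        local = np.array([-posterior * h, 0.0, zs * lateral * h])
        return centers[lvl] + rots[lvl] @ local

    # ES fascicles: straight chords from the sacral origin to each level's
    # paraspinal insertion.  On a deformed spine the chord strays from the
    # curved column, which is what makes the deformity cost muscular effort.
    es = mus["ES"]
    for side in ("left", "right"):
        zs = zsign(side)
        ox, oy, oz = es["origin"]
        origin = np.array([ox * h, oy * h, zs * oz * h])
        for lvl in LEVELS:
            lat = (
                es.get("ins_lateral_thoracic", es["ins_lateral"])
                if lvl in THORACIC_LEVELS
                else es["ins_lateral"]
            )
            fascicles.append(
                MuscleFascicle(
                    name=f"ES_{side}_{lvl}",
                    group="ES",
                    side=side,
                    path=[("sacrum", origin), (lvl, paraspinal_point(lvl, es["ins_posterior"], lat, zs))],
                    fmax=es["csa_cm2"] * scale2 * mms,
                )
            )
    mf = mus["MF"]
    for side in ("left", "right"):
        zs = zsign(side)
        for idx in range(0, len(LEVELS) - 2):  # origins T1..L3
            lvl = LEVELS[idx]
            tgt = idx + int(mf["span"])
            path = [(lvl, paraspinal_point(lvl, mf["ins_posterior"], mf["ins_lateral"], zs))]
            if tgt < len(LEVELS):
                path.append(
                    (LEVELS[tgt], paraspinal_point(LEVELS[tgt], mf["ins_posterior"], mf["ins_lateral"], zs))
                )
            else:
                sx, sy, sz = mf["sacrum_origin"]
                path.append(("sacrum", np.array([sx * h, sy * h, zs * sz * h])))
            fascicles.append(
                MuscleFascicle(
                    name=f"MF_{side}_{lvl}",
                    group="MF",
                    side=side,
                    path=path,
                    fmax=mf["csa_cm2"] * scale2 * mms,
                )
            )
    for grp in ("PS", "QL"):
        g = mus[grp]
        sign_x = 1.0 if "ins_anterior" in g else -1.0
        ins_x = g.get("ins_anterior", g.get("ins_posterior"))
        for side in ("left", "right"):
            zs = zsign(side)
            ox, oy, oz = g["origin"]
            origin = np.array([ox * h, oy * h, zs * oz * h])
            for lvl in g["levels"]:
                ins_local = np.array([sign_x * ins_x * h, 0.0, zs * g["ins_lateral"] * h])
                ins = centers[lvl] + rots[lvl] @ ins_local
                fascicles.append(
                    MuscleFascicle(
                        name=f"{grp}_{side}_{lvl}",
                        group=grp,
                        side=side,
                        path=[("pelvis", origin), (lvl, ins)],
                        fmax=g["csa_cm2"] * scale2 * mms,
                    )
                )
    ic = mus["IC"]
    for side in ("left", "right"):
        zs = zsign(side)
        for idx in range(12):  # joints T1/T2 .. T12/L1
            top, bot = LEVELS[idx], LEVELS[idx + 1]
            off_vec = np.array([ic["anterior"] * h, 0.0, zs * ic["lateral"] * h])
            fascicles.append(
                MuscleFascicle(
                    name=f"IC_{side}_{top}",
                    group="IC",
                    side=side,
                    path=[(f"carrier_{top}", centers[top] + off_vec),
                          (f"carrier_{bot}", centers[bot] + off_vec)],
                    fmax=ic["csa_cm2"] * scale2 * mms,
                )
            )
    ld = mus["LD"]
    for side in ("left", "right"):
        zs = zsign(side)
        _, scap = scapula_points[side]
        px, py, pz = ld["pelvis"]
        fascicles.append(
            MuscleFascicle(
                name=f"LD_{side}",
                group="LD",
                side=side,
                path=[("T3", scap), ("pelvis", np.array([px * h, py * h, zs * pz * h]))],
                fmax=ld["csa_cm2"] * scale2 * mms,
            )
        )
    tr = mus["TR"]
    for side in ("left", "right"):
        zs = zsign(side)
        _, scap = scapula_points[side]
        for lvl in tr["levels"]:
            ins_local = np.array([-tr["ins_posterior"] * h, 0.0, zs * tr["ins_lateral"] * h])
            ins = centers[lvl] + rots[lvl] @ ins_local
            fascicles.append(
                MuscleFascicle(
                    name=f"TR_{side}_{lvl}",
                    group="TR",
                    side=side,
                    path=[(lvl, ins), ("T3", scap)],
                    fmax=tr["csa_cm2"] * scale2 * mms,
                )
            )
    for grp in ("RA", "EO", "IO"):
        g = mus[grp]
        for side in ("left", "right"):
            zs = zsign(side)
            ox, oy, oz = g["origin"]
            origin = np.array([ox * h, oy * h, zs * oz * h])
            lvl = g["ins_level"]
            ins = centers[lvl] + np.array([g["ins_anterior"] * h, 0.0, zs * g["ins_lateral"] * h])
            fascicles.append(
                MuscleFascicle(
                    name=f"{grp}_{side}",
                    group=grp,
                    side=side,
                    path=[("pelvis", origin), (f"carrier_{lvl}", ins)],
                    fmax=g["csa_cm2"] * scale2 * mms,
                )
            )

    # Trunk-wall struts: long spans between carriers (or down to the
    # pelvis), re-neutralized like the carriers themselves.
    cage = config["rib_cage"]
    struts: list[RibStrut] = []
    for side in ("left", "right"):
        zs = zsign(side)
        off_vec = np.array([cage["anterior"] * h, 0.0, zs * cage["lateral"] * h])
        for top, bot in cage["spans"]:
            p_top = (f"carrier_{top}", centers[top] + off_vec)
            if bot == "pelvis":
                p_bot = ("pelvis", np.array([0.0, -0.06 * h, zs * cage["pelvis_lateral"] * h]))
            else:
                p_bot = (f"carrier_{bot}", centers[bot] + off_vec)
            struts.append(
                RibStrut(
                    name=f"cage_{side}_{top}_{bot}",
                    side=side,
                    path=[p_top, p_bot],
                    opt_force=cage["strut_opt_n"],
                    max_mult=cage["max_mult"],
                )
            )

    model = ModelSpec(
        age_y=age_y,
        sex=sex,
        height_cm=height_cm,
        mass_kg=mass_kg,
        geometry=geometry,
        segments=segments,
        joints=joints,
        fascicles=fascicles,
        bushings=bushings,
        scapula_points=scapula_points,
        struts=struts,
        config=config,
    )
    if abs(model.total_mass - mass_kg) > 1e-6:
        raise ModelBuildError("segment masses do not sum to total body mass")
    return model


def build_base_model(
    age_y: float,
    sex: str,
    height_cm: float,
    mass_kg: float,
    config: Optional[dict] = None,
) -> ModelSpec:
    """Undeformed base model at the given anthropometrics.

    The spine follows the configured default sagittal alignment with zero
    frontal and axial deviation; left/right structures are exact mirrors.
    """
    if height_cm <= 0 or mass_kg <= 0:
        raise ModelBuildError("height and mass must be positive")
    cfg = _merge_config(config)
    geometry = generate_curve(
        cobb_target=0.0,
        kyphosis_deg=cfg["sagittal"]["kyphosis_deg"],
        lordosis_deg=cfg["sagittal"]["lordosis_deg"],
        height_cm=height_cm,
    )
    return _assemble(geometry, age_y, sex, height_cm, mass_kg, cfg)


def apply_subject(
    model: ModelSpec,
    geometry: SpineGeometry,
    height_cm: Optional[float] = None,
    mass_kg: Optional[float] = None,
) -> ModelSpec:
    """Subject-specific model from a base model and measured spine geometry.

    Applies the 4-step construction: anthropometric scaling, 3D vertebral
    orientations, joint distances from measured vertebral heights, and
    re-neutralized head/arms/carriers.
    """
    return _assemble(
        geometry,
        model.age_y,
        model.sex,
        height_cm if height_cm is not None else model.height_cm,
        mass_kg if mass_kg is not None else model.mass_kg,
        _merge_config(model.config),
    )


def make_undeformed_twin(model: ModelSpec) -> ModelSpec:
    """The same subject without spinal deformity.

    Keeps the anthropometric scaling and the measured vertebral heights,
    zeroes the frontal and axial deviations, and restores the base model's
    default sagittal alignment.
    """
    cfg = _merge_config(model.config)
    heights = [p.h_total for p in model.geometry.poses]
    geometry = generate_curve(
        cobb_target=0.0,
        kyphosis_deg=cfg["sagittal"]["kyphosis_deg"],
        lordosis_deg=cfg["sagittal"]["lordosis_deg"],
        height_cm=model.height_cm,
        heights_mm=heights,
    )
    return _assemble(geometry, model.age_y, model.sex, model.height_cm, model.mass_kg, cfg)
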