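"""Cohort-level statistics and study orchestration.

Implements the study's reporting layer: demographics summaries (mean, sample
SD, median, IQR), two-sided Wilcoxon signed-rank tests against a reference
value (exact null distribution by dynamic programming up to n=25, normal
approximation with tie correction above), Pearson correlations, and the full
simulation sweep: for every subject, an AIS model and its undeformed twin
are solved in unloaded standing, the AIS model additionally under four
carrying modes at 10/15/20% of body weight and in a prone posture, and
apical compressive forces are expressed as percentages of the undeformed
(unloaded) and unloaded (loaded) references.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from .geometry import extract_geometry
from .loads import make_load
from .model import ModelSpec, apply_subject, build_base_model, make_undeformed_twin
from .optimization import activity_ratio, assemble_system, prone_posture, solve, standing_posture
from .qp import InfeasibleError
from .reactions import LEVEL_OFFSETS, compute_reactions, percent_of
from .synthetic import SyntheticSubject, cohort_manifest
from .virtual_ct import asymmetry_ratio, virtual_ct_scan

logger = logging.getLogger(__name__)

LOADED_MODES = ("backpack", "frontpack", "sidepack_concave", "sidepack_convex")
PCT_BW_LEVELS = (10.0, 15.0, 20.0)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize_cohort(values: pd.DataFrame | Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Mean, sample SD (n-1), median, IQR and n per numeric column.

    Accepts a demographics DataFrame or a list of synthetic subjects.
    Quartiles use linear interpolation between order statistics; IQR is the
    single width Q3 - Q1.
    """
    if not isinstance(values, pd.DataFrame):
        values = cohort_manifest(values)
    num = values.select_dtypes("number")
    if num.shape[1] == 0 or len(num) < 2:
        raise ValueError("need a cohort of >= 2 subjects with numeric columns")
    rows = []
    for col in num.columns:
        v = num[col].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])
        rows.append(
            {
                "variable": col,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)),
                "median": float(np.median(v)),
                "iqr": float(q3 - q1),
                "n": len(v),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic via subset-sum DP.

    ``ranks2`` are the (midrank) ranks doubled to integers; ``w2`` the
    doubled observed positive-rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[:-r]
    n_patterns = counts.sum()
    lo = counts[: int(np.floor(w2 + 1e-9)) + 1].sum() / n_patterns
    hi = counts[int(np.ceil(w2 - 1e-9)) :].sum() / n_patterns
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_vs(values: Sequence[float], reference: float = 100.0) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of ``values`` against a constant.

    Differences exactly equal to the reference are dropped; tied absolute
    differences receive midranks.  Exact null distribution for n <= 25,
    normal approximation with tie correction and continuity correction
    above.  With no non-zero differences, p = 1 and n_effective = 0.
    """
    d = np.asarray(values, dtype=float) - reference
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n_effective=0)
    ranks = sstats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(2.0 * ranks).astype(int)
        p = _wilcoxon_exact_p(ranks2, 2.0 * w_pos)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sstats.norm.sf(abs(z))))
    return TestResult(statistic=w_pos, p_value=p, n_effective=n)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p (t transform, n-2 df).

    Returns (nan, nan) when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SubjectOutputs:
    subject_id: str
    apex_level: str
    convexity: str
    cobb_deg: float
    pct_of_undeformed: dict[int, float]  # level offset -> %
    pct_of_unloaded: dict[tuple[str, float], dict[int, float]]  # (mode, pct_bw)
    absolute_unloaded: dict[int, float]  # N at apex+-2
    es_activity_ratios: dict[str, float]
    mf_prone_apex_ratio: float
    csa_ratios: dict[str, float]


@dataclass
class StudyResult:
    subjects: list[SubjectOutputs]
    failed: list[tuple[str, str]]
    cohort_summary: pd.DataFrame
    forces_long: pd.DataFrame
    percents_long: pd.DataFrame
    ratios: pd.DataFrame
    tests: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort_summary.to_csv(out / "cohort_summary.csv")
        self.forces_long.to_csv(out / "forces_long.csv", index=False)
        self.percents_long.to_csv(out / "percents_long.csv", index=False)
        self.ratios.to_csv(out / "ratios.csv", index=False)
        self.tests.to_csv(out / "tests.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _analyze_subject(subject: SyntheticSubject, config: Optional[dict]) -> SubjectOutputs:
    geom = extract_geometry(subject.landmarks, spinous_depth_mm=subject.spinous_depth_mm)
    if geom.apex_level is None:
        raise ValueError("subject has no measurable curve")
    base = build_base_model(
        subject.age_y, subject.sex, subject.height_cm, subject.mass_kg, config
    )
    ais = apply_subject(base, geom)
    twin = make_undeformed_twin(ais)
    apex, conv = geom.apex_level, geom.convexity

    standing = standing_posture(ais)
    res_ais = solve(assemble_system(ais, standing, None))
    react_ais = compute_reactions(ais, standing, None, res_ais)
    standing_twin = standing_posture(twin)
    res_twin = solve(assemble_system(twin, standing_twin, None))
    react_twin = compute_reactions(twin, standing_twin, None, res_twin)

    pct_undeformed = percent_of(react_ais, react_twin, apex)
    absolute = react_ais.levels_of_interest(apex)

    pct_unloaded: dict[tuple[str, float], dict[int, float]] = {}
    for mode in LOADED_MODES:
        for pct in PCT_BW_LEVELS:
            load = make_load(mode, pct, subject.mass_kg, convexity=conv)
            res = solve(assemble_system(ais, standing, load))
            react = compute_reactions(ais, standing, load, res)
            pct_unloaded[(mode, pct)] = percent_of(react, react_ais, apex)

    es_ratios = {
        "thoracic": activity_ratio(res_ais, ais, "ES", "thoracic", conv),
        "lumbar": activity_ratio(res_ais, ais, "ES", "lumbar", conv),
        "apex": activity_ratio(res_ais, ais, "ES", [apex], conv),
        "upper_limit": activity_ratio(res_ais, ais, "ES", _offset_levels(apex, -2), conv),
        "lower_limit": activity_ratio(res_ais, ais, "ES", _offset_levels(apex, 2), conv),
    }

    prone = prone_posture(ais)
    res_prone = solve(assemble_system(ais, prone, None))
    mf_prone = activity_ratio(res_prone, ais, "MF", [apex], conv)

    csa = virtual_ct_scan(ais)
    csa_ratios = {
        "ES_apex": asymmetry_ratio(csa, "ES", apex, conv),
        "MF_T8": asymmetry_ratio(csa, "MF", "T8", conv),
        "MF_L1": asymmetry_ratio(csa, "MF", "L1", conv),
        "MF_L4": asymmetry_ratio(csa, "MF", "L4", conv),
        "MF_apex": asymmetry_ratio(csa, "MF", apex, conv),
    }
    return SubjectOutputs(
        subject_id=subject.subject_id,
        apex_level=apex,
        convexity=conv,
        cobb_deg=geom.cobb_deg,
        pct_of_undeformed=pct_undeformed,
        pct_of_unloaded=pct_unloaded,
        absolute_unloaded=absolute,
        es_activity_ratios=es_ratios,
        mf_prone_apex_ratio=mf_prone,
        csa_ratios=csa_ratios,
    )


def _offset_levels(apex: str, offset: int) -> list[str]:
    from .frames import LEVELS, level_index

    i = level_index(apex) + offset
    return [LEVELS[i]] if 0 <= i < len(LEVELS) else []


def run_study(
    subjects: Sequence[SyntheticSubject],
    config: Optional[dict] = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Run the full simulation study on a cohort.

    Subjects whose models fail to solve are logged, excluded and reported in
    the manifest.  The result is deterministic for a fixed cohort and
    configuration.
    """
    outputs: list[SubjectOutputs] = []
    failed: list[tuple[str, str]] = []
    for subject in subjects:
        try:
            out = _analyze_subject(subject, config)
            outputs.append(out)
            logger.info("subject %s solved", subject.subject_id)
        except (InfeasibleError, ValueError) as exc:
            logger.warning("subject %s excluded: %s", subject.subject_id, exc)
            failed.append((subject.subject_id, str(exc)))
    if not outputs:
        raise RuntimeError("no subject could be solved")

    cohort_summary = summarize_cohort(cohort_manifest(subjects))

    force_rows, pct_rows, ratio_rows = [], [], []
    for o in outputs:
        for off, val in o.absolute_unloaded.items():
            force_rows.append((o.subject_id, "unloaded", 0.0, off, val))
        for off, val in o.pct_of_undeformed.items():
            pct_rows.append((o.subject_id, "unloaded_vs_undeformed", 0.0, off, val))
        for (mode, pct), m in o.pct_of_unloaded.items():
            for off, val in m.items():
                pct_rows.append((o.subject_id, mode, pct, off, val))
        for name, val in o.es_activity_ratios.items():
            ratio_rows.append((o.subject_id, "ES_activity", name, val))
        ratio_rows.append((o.subject_id, "MF_activity_prone", "apex", o.mf_prone_apex_ratio))
        for name, val in o.csa_ratios.items():
            grp, loc = name.split("_", 1)
            ratio_rows.append((o.subject_id, f"{grp}_csa", loc, val))
    forces_long = pd.DataFrame(
        force_rows, columns=["subject_id", "condition", "pct_bw", "level_offset", "axial_compression_n"]
    )
    percents_long = pd.DataFrame(
        pct_rows, columns=["subject_id", "condition", "pct_bw", "level_offset", "pct_of_reference"]
    )
    ratios = pd.DataFrame(ratio_rows, columns=["subject_id", "family", "location", "ratio"])

    # Wilcoxon tests against 100% per condition and level offset
    test_rows = []
    for (cond, pct, off), grp in percents_long.groupby(["condition", "pct_bw", "level_offset"]):
        vals = grp.pct_of_reference.dropna().to_numpy()
        if len(vals) == 0:
            continue
        t = wilcoxon_vs(vals, 100.0)
        test_rows.append(
            (cond, pct, off, float(np.median(vals)),
             float(np.percentile(vals, 75) - np.percentile(vals, 25)),
             t.statistic, t.p_value, t.n_effective)
        )
    tests = pd.DataFrame(
        test_rows,
        columns=["condition", "pct_bw", "level_offset", "median_pct", "iqr_pct", "statistic", "p_value", "n_effective"],
    )

    # Correlations: apex force increase vs apex level and curve severity
    apex_pct = {o.subject_id: o.pct_of_undeformed.get(0, float("nan")) for o in outputs}
    from .frames import level_index as _li

    ok = [o for o in outputs if np.isfinite(apex_pct[o.subject_id])]
    corr_rows = []
    if len(ok) >= 3:
        incr = [apex_pct[o.subject_id] for o in ok]
        for label, x in (
            ("apex_level_index", [_li(o.apex_level) for o in ok]),
            ("cobb_deg", [o.cobb_deg for o in ok]),
        ):
            r, p = pearson_r(x, incr)
            corr_rows.append((f"apex_pct_undeformed_vs_{label}", r, p, len(ok)))
    correlations = pd.DataFrame(corr_rows, columns=["pair", "r", "p_value", "n"])

    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    manifest = {
        "package_version": __version__,
        "n_subjects": len(subjects),
        "n_solved": len(outputs),
        "failed": [{"subject_id": s, "reason": r} for s, r in failed],
        "config_sha256": cfg_hash,
    }
    result = StudyResult(
        subjects=outputs,
        failed=failed,
        cohort_summary=cohort_summary,
        forces_long=forces_long,
        percents_long=percents_long,
        ratios=ratios,
        tests=tests,
        correlations=correlations,
        manifest=manifest,
    )
    if out_dir is not None:
        result.save(out_dir)
    return result
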