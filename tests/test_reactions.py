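"""Joint reaction analysis: transmitted forces and percentage comparisons."""

import numpy as np
import pytest

import scoliosim as ss
from scoliosim.optimization import SolveResult, assemble_system, solve, standing_posture
from scoliosim.reactions import compute_reactions, percent_of


def gravity_only_result(model):
    """A fabricated equilibrated result with no muscle or support activity,
    for checking the pure-gravity reaction arithmetic."""
    return SolveResult(
        activations={f.name: 0.0 for f in model.fascicles},
        reserve_moments={j.name: 0.0 for j in model.joints},
        strut_forces={s.name: 0.0 for s in model.struts},
        support_forces=[np.zeros(3) for _ in range(4)],
        objective=0.0,
        residual_norm=0.0,
    )


class TestComputeReactions:
    def test_gravity_only_compression_equals_projected_weight(self, twin_model):
        """With all actuators off, axial compression at each joint is the
        superincumbent weight projected on the caudal superior axis."""
        posture = standing_posture(twin_model)
        react = compute_reactions(twin_model, posture, None, gravity_only_result(twin_model))
        ranks = {n: s.rank for n, s in twin_model.segments.items()}
        for k, joint in enumerate(twin_model.joints):
            weight = sum(
                s.mass for s in twin_model.segments.values() if ranks[s.name] >= joint.cranial_rank
            ) * 9.81
            r_caudal = (
                twin_model.vertebra_rotation(joint.caudal)
                if joint.caudal != "S1"
                else np.eye(3)
            )
            expected = weight * r_caudal[:, 1][1]  # cos(tilt from vertical)
            assert react.axial_compression[k] == pytest.approx(expected, abs=1e-9)

    def test_active_extensor_increases_compression(self, twin_model):
        posture = standing_posture(twin_model)
        base = compute_reactions(twin_model, posture, None, gravity_only_result(twin_model))
        active = gravity_only_result(twin_model)
        active.activations["ES_left_T1"] = 0.5
        react = compute_reactions(twin_model, posture, None, active)
        # the fascicle runs sacrum -> T1, compressing every joint it crosses
        assert np.all(react.axial_compression >= base.axial_compression - 1e-9)
        assert react.compression_at_level("T8") > base.compression_at_level("T8")

    def test_solved_standing_compression_positive_everywhere(self, ais_model, standing_result):
        posture, result = standing_result
        react = compute_reactions(ais_model, posture, None, result)
        assert np.all(react.axial_compression > 0)

    def test_mirrored_subject_same_compression(self, ais_model, standing_result):
        posture, result = standing_result
        react = compute_reactions(ais_model, posture, None, result)
        mirror = ss.apply_subject(ais_model, ais_model.geometry.mirrored())
        m_post = standing_posture(mirror)
        m_res = solve(assemble_system(mirror, m_post, None))
        m_react = compute_reactions(mirror, m_post, None, m_res)
        assert np.allclose(react.axial_compression, m_react.axial_compression, atol=1e-6)

    def test_unsolved_result_rejected(self, ais_model, standing_result):
        posture, result = standing_result
        bad = SolveResult(
            activations=result.activations,
            reserve_moments=result.reserve_moments,
            strut_forces=result.strut_forces,
            support_forces=result.support_forces,
            objective=result.objective,
            residual_norm=1.0,
        )
        with pytest.raises(ValueError, match="residual"):
            compute_reactions(ais_model, posture, None, bad)

    def test_compression_broadly_increases_caudally(self, twin_model, twin_standing_result):
        """More superincumbent weight caudally; local reversals of a few
        percent occur where multi-level muscles terminate and where the
        tilted local axes change the axial projection, so the check is a
        windowed trend rather than strict per-joint monotonicity."""
        posture, result = twin_standing_result
        react = compute_reactions(twin_model, posture, None, result)
        c = react.axial_compression  # caudal -> cranial order
        for lower, upper in zip(c[:-1], c[1:]):
            assert upper <= lower * 1.07
        # strong global trend: top of the chain carries far less than the base
        assert c[-1] < 0.25 * c[0]
        assert np.all(c[:3] > np.max(c[8:]))


class TestPercentOf:
    def test_identity_is_100(self, ais_model, standing_result):
        posture, result = standing_result
        react = compute_reactions(ais_model, posture, None, result)
        pct = percent_of(react, react, ais_model.geometry.apex_level)
        assert all(v == pytest.approx(100.0) for v in pct.values())

    def test_scaling(self, ais_model, standing_result):
        posture, result = standing_result
        react = compute_reactions(ais_model, posture, None, result)
        import copy

        scaled = copy.deepcopy(react)
        scaled.axial_compression = 1.5 * scaled.axial_compression
        pct = percent_of(scaled, react, ais_model.geometry.apex_level)
        assert all(v == pytest.approx(150.0) for v in pct.values())

    def test_nonpositive_reference_yields_nan(self, ais_model, standing_result):
        posture, result = standing_result
        react = compute_reactions(ais_model, posture, None, result)
        import copy

        zeroed = copy.deepcopy(react)
        zeroed.axial_compression = 0.0 * zeroed.axial_compression
        pct = percent_of(react, zeroed, ais_model.geometry.apex_level)
        assert all(np.isnan(v) for v in pct.values())

    def test_pct_of_unloaded_nondecreasing_in_load(self, ais_model, standing_result):
        posture, base_result = standing_result
        base = compute_reactions(ais_model, posture, None, base_result)
        conv = ais_model.geometry.convexity
        apex = ais_model.geometry.apex_level
        for mode in ("backpack", "frontpack", "sidepack_concave", "sidepack_convex"):
            prev = None
            for pct_bw in (10.0, 15.0, 20.0):
                load = ss.make_load(mode, pct_bw, ais_model.mass_kg, convexity=conv)
                res = solve(assemble_system(ais_model, posture, load))
                react = compute_reactions(ais_model, posture, load, res)
                cur = percent_of(react, base, apex)
                if prev is not None:
                    for off in cur:
                        assert cur[off] >= prev[off] - 1e-9
                prev = cur
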