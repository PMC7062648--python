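"""Static optimization: system assembly, equilibrium, symmetry, ratios."""

import numpy as np
import pytest

import scoliosim as ss
from scoliosim.optimization import assemble_system, prone_posture, solve, standing_posture


class TestAssembly:
    def test_required_flexion_matches_hand_statics(self, base_model):
        """Required flexion moment = -sum of gravity moments of superior bodies,
        recomputed here directly from segment masses and positions."""
        posture = standing_posture(base_model)
        system = assemble_system(base_model, posture, None)
        joint = base_model.joints[0]  # L5/S1
        ranks = {n: s.rank for n, s in base_model.segments.items()}
        expected = 0.0
        for seg in base_model.segments.values():
            if ranks[seg.name] >= joint.cranial_rank:
                r = seg.com - joint.position
                f = seg.mass * 9.81 * np.array([0.0, -1.0, 0.0])
                expected += -np.dot(np.cross(r, f), joint.axes[:, 0])
        assert system.required[0] == pytest.approx(expected, abs=1e-9)

    def test_lateral_and_axial_rows_vanish_for_symmetric_model(self, base_model):
        system = assemble_system(base_model, standing_posture(base_model), None)
        nj = len(base_model.joints)
        req = system.required[: 3 * nj].reshape(nj, 3)
        assert np.allclose(req[:, 1], 0.0, atol=1e-9)  # lateral
        assert np.allclose(req[:, 2], 0.0, atol=1e-9)  # axial

    def test_mirrored_loads_flip_lateral_moments(self, ais_model):
        posture = standing_posture(ais_model)
        conv = ais_model.geometry.convexity
        load = ss.make_load("sidepack_convex", 10.0, ais_model.mass_kg, convexity=conv)
        system = assemble_system(ais_model, posture, load)

        mirror_geom = ais_model.geometry.mirrored()
        mirror = ss.apply_subject(ais_model, mirror_geom)
        m_load = ss.make_load("sidepack_convex", 10.0, mirror.mass_kg, convexity=mirror_geom.convexity)
        m_system = assemble_system(mirror, standing_posture(mirror), m_load)

        nj = len(ais_model.joints)
        a = system.required[: 3 * nj].reshape(nj, 3)
        b = m_system.required[: 3 * nj].reshape(nj, 3)
        assert np.allclose(a[:, 0], b[:, 0], atol=1e-8)  # flexion identical
        assert np.allclose(a[:, 1], -b[:, 1], atol=1e-8)  # lateral flipped
        assert np.allclose(a[:, 2], -b[:, 2], atol=1e-8)  # axial flipped

    def test_non_neutral_bushing_rejected(self, ais_model):
        import copy

        bad = copy.deepcopy(ais_model)
        bad.bushings[3].neutral_deg = bad.bushings[3].neutral_deg + 5.0
        with pytest.raises(ValueError, match="neutral"):
            assemble_system(bad, standing_posture(bad), None)


class TestSolve:
    def test_equilibrium_residual_below_tolerance(self, standing_result):
        _, result = standing_result
        assert result.residual_norm <= 1e-6

    def test_vertical_supports_carry_body_weight(self, ais_model, standing_result):
        _, result = standing_result
        total_up = sum(f[1] for f in result.support_forces)
        assert total_up == pytest.approx(ais_model.total_mass * 9.81, abs=1e-6)

    def test_supports_carry_weight_plus_load(self, ais_model):
        posture = standing_posture(ais_model)
        load = ss.make_load("backpack", 15.0, ais_model.mass_kg)
        result = solve(assemble_system(ais_model, posture, load))
        ext_y = sum(f[1] for _, f in load.forces)
        assert sum(f[1] for f in result.support_forces) == pytest.approx(
            ais_model.total_mass * 9.81 - ext_y, abs=1e-6
        )

    def test_symmetric_model_has_symmetric_activations(self, base_model):
        posture = standing_posture(base_model)
        for load in (None, ss.make_load("backpack", 10.0, base_model.mass_kg),
                     ss.make_load("frontpack", 20.0, base_model.mass_kg)):
            result = solve(assemble_system(base_model, posture, load))
            for f in base_model.fascicles:
                if f.side != "left":
                    continue
                twin = f.name.replace("left", "right")
                assert abs(result.activations[f.name] - result.activations[twin]) < 1e-9

    def test_objective_monotone_in_load_magnitude(self, ais_model):
        posture = standing_posture(ais_model)
        conv = ais_model.geometry.convexity
        for mode in ("backpack", "frontpack", "sidepack_concave", "sidepack_convex"):
            objs = []
            for pct in (10.0, 15.0, 20.0):
                load = ss.make_load(mode, pct, ais_model.mass_kg, convexity=conv)
                objs.append(solve(assemble_system(ais_model, posture, load)).objective)
            assert objs[0] <= objs[1] + 1e-9 <= objs[2] + 2e-9

    def test_prone_posture_solves(self, ais_model):
        result = solve(assemble_system(ais_model, prone_posture(ais_model), None))
        assert result.residual_norm <= 1e-6

    def test_activations_within_bounds(self, standing_result):
        _, result = standing_result
        acts = np.array(list(result.activations.values()))
        assert np.all(acts >= -1e-12) and np.all(acts <= 1 + 1e-12)


class TestActivityRatio:
    def test_symmetric_model_unit_ratio(self, base_model):
        result = solve(assemble_system(base_model, standing_posture(base_model), None))
        ratio = ss.activity_ratio(result, base_model, "ES", "lumbar", "right")
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_ratio_is_mirror_invariant(self, ais_model, standing_result):
        _, result = standing_result
        conv = ais_model.geometry.convexity
        ratio = ss.activity_ratio(result, ais_model, "ES", "lumbar", conv)

        mirror_geom = ais_model.geometry.mirrored()
        mirror = ss.apply_subject(ais_model, mirror_geom)
        m_res = solve(assemble_system(mirror, standing_posture(mirror), None))
        m_ratio = ss.activity_ratio(m_res, mirror, "ES", "lumbar", mirror_geom.convexity)
        if np.isnan(ratio):
            assert np.isnan(m_ratio)
        else:
            assert m_ratio == pytest.approx(ratio, rel=1e-6)

    def test_arithmetic(self, base_model):
        # two convex-side activations {0.2, 0.4} vs concave {0.1, 0.2} -> 2.0
        from scoliosim.optimization import SolveResult

        acts = {f.name: 0.0 for f in base_model.fascicles}
        crossing = [f for f in base_model.fascicles if f.group == "ES"
                    and base_model.fascicle_crosses_level(f, "L3")]
        left = [f for f in crossing if f.side == "left"][:2]
        right = [f for f in crossing if f.side == "right"][:2]
        acts[left[0].name], acts[left[1].name] = 0.2, 0.4
        acts[right[0].name], acts[right[1].name] = 0.1, 0.2
        fake = SolveResult(
            activations=acts, reserve_moments={}, strut_forces={},
            support_forces=[], objective=0.0, residual_norm=0.0,
        )
        # restrict to the two loaded fascicles per side by zeroing the rest;
        # means include zero-activation crossers, so compare the ratio of means
        num = np.mean([acts[f.name] for f in crossing if f.side == "left"])
        den = np.mean([acts[f.name] for f in crossing if f.side == "right"])
        got = ss.activity_ratio(fake, base_model, "ES", ["L3"], "left")
        assert got == pytest.approx(num / den)
        assert got == pytest.approx(2.0)
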