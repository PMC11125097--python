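"""Line constructions and the 16-case plant-center computation."""

import numpy as np
import pytest

from fluoroloc import (
    Blob,
    CaseId,
    Config,
    LineSeg,
    ParallelLinesError,
    RegionAssignment,
    intersect_lines,
    locate_center,
    perpendicular_through,
    render_frames,
    sample_scene,
)
from fluoroloc.workflow import frame_assignment


def _cross2(u, v):
    return u[0] * v[1] - u[1] * v[0]


def make_assignment(entries):
    """Build a RegionAssignment from (region, (col, row)) pairs."""
    by_region = {}
    for region, pos in entries:
        blob = Blob(
            centroid=(float(pos[0]), float(pos[1])), area=100,
            mean_intensity=50.0, max_intensity=200, min_intensity=5,
            bbox=(int(pos[1]) - 2, int(pos[0]) - 2, int(pos[1]) + 2, int(pos[0]) + 2),
        )
        by_region.setdefault(region, []).append(blob)
    return RegionAssignment(
        by_region=by_region, primary={r: bs[0] for r, bs in by_region.items()}
    )


class TestIntersectLines:
    def test_symmetric_cross_through_origin(self):
        l1 = LineSeg((0, 0), (1, 1))
        l2 = LineSeg((0, 0), (1, -1))
        assert intersect_lines(l1, l2) == pytest.approx((0.0, 0.0))

    def test_diagonals_of_a_square(self):
        l1 = LineSeg((0, 0), (100, 100))
        l2 = LineSeg((100, 0), (0, 100))
        assert intersect_lines(l1, l2) == pytest.approx((50.0, 50.0))

    def test_random_lines_satisfy_both_equations(self, rng):
        for _ in range(50):
            p = rng.uniform(-50, 50, 2)
            q = rng.uniform(-50, 50, 2)
            d1 = rng.uniform(-1, 1, 2)
            d2 = rng.uniform(-1, 1, 2)
            if min(np.linalg.norm(d1), np.linalg.norm(d2)) < 1e-3:
                continue
            sin_angle = abs(d1[0] * d2[1] - d1[1] * d2[0]) / (
                np.linalg.norm(d1) * np.linalg.norm(d2)
            )
            if sin_angle < 1e-3:
                continue
            pt = np.asarray(intersect_lines(LineSeg(p, p + d1), LineSeg(q, q + d2)))
            # substitute back: (pt - p) parallel to d1, (pt - q) parallel to d2
            assert abs(_cross2(pt - p, d1)) < 1e-6 * max(1.0, np.linalg.norm(pt))
            assert abs(_cross2(pt - q, d2)) < 1e-6 * max(1.0, np.linalg.norm(pt))

    def test_parallel_lines_rejected(self):
        with pytest.raises(ParallelLinesError):
            intersect_lines(LineSeg((0, 0), (1, 1)), LineSeg((5, 0), (6, 1)))


class TestPerpendicular:
    def test_horizontal_edge_gives_vertical_line(self):
        perp = perpendicular_through((10, 10), LineSeg((0, 0), (1, 0)))
        d = perp.direction
        assert abs(d[0]) < 1e-12 and abs(abs(d[1]) - 1) < 1e-12
        assert perp.p0 == (10.0, 10.0)

    def test_point_on_edge_is_foot(self):
        perp = perpendicular_through((5, 0), LineSeg((0, 0), (10, 0)))
        assert perp.p0 == (5.0, 0.0)

    def test_diagonal_edge_dot_product_zero(self):
        edge = LineSeg((0, 0), (1, 1))
        perp = perpendicular_through((0, 10), edge)
        assert float(np.dot(perp.direction, edge.direction)) == pytest.approx(0.0, abs=1e-12)


class TestConstructionCases:
    def test_case1_direct_extraction(self, layout, rig):
        assign = make_assignment([("MC", (512.0, 512.0))])
        res = locate_center(assign, layout, rig)
        assert res.case_id == CaseId.CASE_1
        assert res.center_px == pytest.approx((512.0, 512.0))
        assert res.success

    def test_case2_cross_of_diagonals(self, layout, rig):
        assign = make_assignment(
            [("TL", (100, 100)), ("BR", (900, 900)), ("TR", (900, 100)), ("BL", (100, 900))]
        )
        res = locate_center(assign, layout, rig)
        assert res.case_id == CaseId.CASE_2
        assert res.center_px == pytest.approx((500.0, 500.0))

    def test_missing_second_frame_flagged(self, layout, rig):
        assign = make_assignment([("TL", (150, 150))])
        res = locate_center(assign, layout, rig)
        assert res.case_id == CaseId.CASE_13
        assert res.status == "missing_second_frame"
        assert res.center_px is None

    def test_not_found_has_no_center(self, layout, rig):
        res = locate_center(make_assignment([]), layout, rig)
        assert res.case_id == CaseId.NOT_FOUND
        assert res.center_px is None
        assert res.status == "not_found"

    def test_parallel_construction_flagged(self, layout, rig):
        # both diagonals along (1, 1): unlocalizable, not a crash
        assign = make_assignment(
            [("TL", (100, 100)), ("BR", (900, 900)), ("TR", (200, 200)), ("BL", (300, 300))]
        )
        res = locate_center(assign, layout, rig)
        assert res.status == "parallel_lines"
        assert res.center_px is None

    def test_out_of_frame_intersection_flagged_not_clipped(self, layout, rig):
        # nearly parallel diagonals meeting far outside the frame
        assign = make_assignment(
            [("TL", (10, 10)), ("BR", (1010, 1010)), ("TR", (1000, 900)), ("BL", (100, 10))]
        )
        res = locate_center(assign, layout, rig)
        assert res.status == "out_of_frame"
        assert res.center_px is not None
        col, row = res.center_px
        assert not (0 <= col <= 1024 and 0 <= row <= 1024)

    def test_degenerate_opposite_observation_flagged(self, layout, rig):
        # offsets chosen so both pair coordinates coincide (x = x1 = 2 cm):
        # the system is unsolvable and must be rejected, not inverted
        r2 = 0.5**0.5
        top = (512 + 240 * r2, 512 - 240 * r2)  # o_top = +240 px along the TR axis
        bot = (512 - 192 * r2, 512 + 192 * r2)  # o_bot = -192 px
        assign = make_assignment([("TR", top), ("BL", bot)])
        res = locate_center(assign, layout, rig)
        assert res.case_id == CaseId.CASE_11
        assert res.status == "degenerate"


SCENARIO_CASES = {
    "central": {CaseId.CASE_1},
    "four": {CaseId.CASE_2},
    "three": {CaseId.CASE_3, CaseId.CASE_4, CaseId.CASE_5, CaseId.CASE_6},
    "two_nonopposite": {CaseId.CASE_7, CaseId.CASE_8, CaseId.CASE_9, CaseId.CASE_10},
    "two_opposite": {CaseId.CASE_11, CaseId.CASE_12},
    "one": {CaseId.CASE_13, CaseId.CASE_14, CaseId.CASE_15, CaseId.CASE_16},
}


class TestEndToEndNoiseFree:
    @pytest.mark.parametrize("scenario", list(SCENARIO_CASES))
    def test_exact_blob_positions_recover_truth(self, scenario, config, layout):
        """With exact forward-consistent blob positions (no rendering), every
        case inverts to the true center to numerical precision."""
        rng = np.random.default_rng(986)
        for k in range(6):
            scene = sample_scene(scenario, layout, config, rng, scene_id=f"{scenario}_{k}")
            assigns = [make_assignment(list(fb)) for fb in scene.frame_blobs]
            res = locate_center(
                assigns[0], layout, config.rig,
                second_frame_assign=assigns[1] if len(assigns) > 1 else None,
                l=scene.travel_cm,
            )
            assert res.case_id in SCENARIO_CASES[scenario]
            assert res.success
            err = np.hypot(
                res.center_px[0] - scene.truth_center_px[0],
                res.center_px[1] - scene.truth_center_px[1],
            )
            assert err <= 1e-6, f"{scenario} scene {k}: error {err:.3g} px"

    # rendered frames quantize blob profiles to 8 bits; the sub-pixel
    # centroiding error this induces is ~0.05 px, but the two-frame parallax
    # solve amplifies it by roughly x/(x2-x1), hence the looser bound there
    @pytest.mark.parametrize("scenario", list(SCENARIO_CASES))
    def test_noise_free_renders_localize_within_tolerance(self, scenario, config, layout):
        tol = 5.0 if scenario == "one" else 1.0
        rng = np.random.default_rng(987)
        for k in range(6):
            scene = sample_scene(scenario, layout, config, rng, scene_id=f"{scenario}_{k}")
            frames = render_frames(scene, config, noise_sigma=0.0)
            assigns = [frame_assignment(fr, layout, config) for fr in frames]
            res = locate_center(
                assigns[0], layout, config.rig,
                second_frame_assign=assigns[1] if len(assigns) > 1 else None,
                l=scene.travel_cm,
            )
            assert res.case_id in SCENARIO_CASES[scenario]
            assert res.success
            err = np.hypot(
                res.center_px[0] - scene.truth_center_px[0],
                res.center_px[1] - scene.truth_center_px[1],
            )
            assert err <= tol, f"{scenario} scene {k}: error {err:.3f} px"

    def test_solver_cases_recover_height(self, config, layout):
        """Opposite-pair scenes recover the fluorescence height b as well."""
        rng = np.random.default_rng(321)
        for k in range(6):
            scene = sample_scene("two_opposite", layout, config, rng, scene_id=f"op_{k}")
            frames = render_frames(scene, config, noise_sigma=0.0)
            assign = frame_assignment(frames[0], layout, config)
            res = locate_center(assign, layout, config.rig)
            assert res.solver_output is not None
            assert res.solver_output.b == pytest.approx(scene.b_cm, abs=0.05)

    def test_redundant_information_agrees(self, config, layout):
        """With MC and all mirrors occupied, the direct answer and the
        diagonal-cross answer agree on noise-free geometry."""
        rng = np.random.default_rng(555)
        for k in range(4):
            scene = sample_scene("four", layout, config, rng, scene_id=f"red_{k}")
            entries = list(scene.frame_blobs[0]) + [("MC", scene.truth_center_px)]
            with_mc = make_assignment(entries)
            without_mc = make_assignment(list(scene.frame_blobs[0]))
            res1 = locate_center(with_mc, layout, config.rig)
            res2 = locate_center(without_mc, layout, config.rig)
            assert res1.case_id == CaseId.CASE_1
            assert res2.case_id == CaseId.CASE_2
            d = np.hypot(
                res1.center_px[0] - res2.center_px[0], res1.center_px[1] - res2.center_px[1]
            )
            assert d <= 2.0


def rotate_entries(entries, center=(512.0, 512.0)):
    from fluoroloc.regions import OPPOSITE

    out = []
    for region, (col, row) in entries:
        new_region = OPPOSITE.get(region, region)
        out.append((new_region, (2 * center[0] - col, 2 * center[1] - row)))
    return out


class TestEquivariance:
    """Rotating a scene 180 degrees about the frame center rotates the estimate."""

    @pytest.mark.parametrize("scenario", ["four", "three", "two_nonopposite"])
    def test_construction_cases(self, scenario, config, layout):
        rng = np.random.default_rng(77)
        for k in range(4):
            scene = sample_scene(scenario, layout, config, rng, scene_id=f"eq_{k}")
            entries = list(scene.frame_blobs[0])
            res = locate_center(make_assignment(entries), layout, config.rig)
            rot = locate_center(make_assignment(rotate_entries(entries)), layout, config.rig)
            assert res.success and rot.success
            assert rot.center_px[0] == pytest.approx(1024 - res.center_px[0], abs=1e-6)
            assert rot.center_px[1] == pytest.approx(1024 - res.center_px[1], abs=1e-6)

    def test_single_mirror_cases(self, config, layout):
        rng = np.random.default_rng(78)
        for k in range(4):
            scene = sample_scene("one", layout, config, rng, scene_id=f"eq1_{k}")
            f1, f2 = [list(fb) for fb in scene.frame_blobs]
            res = locate_center(
                make_assignment(f1), layout, config.rig,
                second_frame_assign=make_assignment(f2), l=scene.travel_cm,
            )
            rot = locate_center(
                make_assignment(rotate_entries(f1)), layout, config.rig,
                second_frame_assign=make_assignment(rotate_entries(f2)), l=scene.travel_cm,
            )
            assert res.success and rot.success
            assert rot.center_px[0] == pytest.approx(1024 - res.center_px[0], abs=1e-6)
            assert rot.center_px[1] == pytest.approx(1024 - res.center_px[1], abs=1e-6)

    def test_opposite_pair_under_symmetric_variant(self, layout):
        # the as-printed opposing-view equation is asymmetric between the two
        # mirrors, so exact equivariance is a property of the symmetric variant
        cfg = Config.default()
        cfg = cfg.replace(rig=cfg.rig.replace(eq4_variant="symmetric"))
        rng = np.random.default_rng(79)
        for k in range(4):
            scene = sample_scene("two_opposite", layout, cfg, rng, scene_id=f"eqo_{k}")
            entries = list(scene.frame_blobs[0])
            res = locate_center(make_assignment(entries), layout, cfg.rig)
            rot = locate_center(make_assignment(rotate_entries(entries)), layout, cfg.rig)
            assert res.success and rot.success
            assert rot.center_px[0] == pytest.approx(1024 - res.center_px[0], abs=1e-6)
            assert rot.center_px[1] == pytest.approx(1024 - res.center_px[1], abs=1e-6)
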