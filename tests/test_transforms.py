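"""Linear transform engine vs. the homogeneous-matrix oracle."""
import numpy as np
import pytest

import spatalign as sa
from spatalign.transforms import compute_center, scale_image, scale_points

from .oracles import apply_hom, compose_ops, hom_flip, hom_rotate


class TestCenter:
    @pytest.mark.parametrize("xy, expected", [
        ([(0, 0), (2, 0), (0, 4)], (1, 2)),
        ([(5, 7)], (5, 7)),
    ])
    def test_bounding_box_midpoint(self, xy, expected):
        pts = sa.PointSet(ids=np.arange(len(xy)),
                          x=[p[0] for p in xy], y=[p[1] for p in xy])
        assert compute_center(pts) == expected

    def test_matches_brute_force_minmax(self, rng):
        x, y = rng.uniform(0, 10, 1000), rng.uniform(0, 10, 1000)
        pts = sa.PointSet(ids=np.arange(1000), x=x, y=y)
        cx = (min(x) + max(x)) / 2
        cy = (min(y) + max(y)) / 2
        assert compute_center(pts) == (cx, cy)

    def test_includes_invisible_points(self):
        pts = sa.PointSet(ids=[0, 1], x=[0.0, 10.0], y=[0.0, 10.0],
                          visible=[True, False])
        assert compute_center(pts) == (5.0, 5.0)


class TestScaling:
    def test_equal_scales_are_identity(self, unit_spec):
        pts = sa.PointSet(ids=[0], x=[100.0], y=[50.0])
        out = scale_points(pts, unit_spec)
        assert out.x[0] == 100.0 and out.y[0] == 50.0

    def test_micron_conserving_conversion(self):
        # 100 raw px at 2 μm/px span 200 μm = 200 display px at 1 μm/px
        spec = sa.ScaleSpec(data_scale=2.0, image_scale=1.0, display_scale=1.0)
        pts = sa.PointSet(ids=[0], x=[100.0], y=[100.0])
        assert scale_points(pts, spec).x[0] == 200.0

    def test_round_trip(self, random_points):
        a = sa.ScaleSpec(1.0, 1.0, 0.7)
        b = sa.ScaleSpec(0.7, 1.0, 1.0)
        out = scale_points(scale_points(random_points, a), b)
        np.testing.assert_allclose(out.x, random_points.x, atol=1e-12)
        np.testing.assert_allclose(out.y, random_points.y, atol=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(sa.ValidationError):
            sa.ScaleSpec(data_scale=0.0, image_scale=1.0, display_scale=1.0)

    @pytest.mark.parametrize("img_scale, display, expected_w", [
        (1.0, 1.0, 1000),
        (0.5, 1.0, 500),  # physical width 500 μm must stay 500 μm
    ])
    def test_image_width(self, img_scale, display, expected_w):
        img = sa.ImageRaster(np.zeros((10, 1000), dtype=np.uint8),
                             pixel_size=img_scale)
        spec = sa.ScaleSpec(1.0, img_scale, display)
        assert scale_image(img, spec).width == expected_w

    def test_image_physical_extent_conserved(self, rng):
        for _ in range(10):
            w = int(rng.integers(50, 800))
            px = float(rng.uniform(0.2, 3.0))
            disp = float(rng.uniform(0.2, 3.0))
            img = sa.ImageRaster(np.zeros((8, w), dtype=np.uint8),
                                 pixel_size=px)
            out = scale_image(img, sa.ScaleSpec(1.0, px, disp))
            # extent in μm conserved to within one output pixel
            assert abs(out.width * disp - w * px) <= disp


class TestRigidOps:
    def test_zero_rotation_identity(self, session):
        x0 = session.display.x.copy()
        session.rotate(0.0)
        np.testing.assert_array_equal(session.display.x, x0)

    def test_unit_rotation(self):
        pts = sa.PointSet(ids=[0], x=[1.0], y=[0.0])
        s = sa.Session(pts, sa.ScaleSpec(1, 1, 1), center=(0.0, 0.0))
        s.rotate(90.0)
        assert abs(s.display.x[0]) < 1e-12 and abs(s.display.y[0] - 1) < 1e-12

    def test_rotation_composition_matches_matrix(self, session):
        session.rotate(17.0)
        session.rotate(25.5)
        m = hom_rotate(42.5, session.state.center)
        ex, ey = apply_hom(m, session._scaled_full.x, session._scaled_full.y)
        np.testing.assert_allclose(session.display.x, ex, atol=1e-9)
        np.testing.assert_allclose(session.display.y, ey, atol=1e-9)

    def test_translate_formula_and_inverse(self, session):
        x0 = session.display.x.copy()
        session.translate(3.0, -2.0)
        np.testing.assert_array_equal(session.display.x, x0 + 3.0)
        session.translate(-3.0, 2.0)
        np.testing.assert_array_equal(session.display.x, x0)

    def test_pure_mirror_at_zero_angle(self):
        pts = sa.PointSet(ids=[0], x=[3.0], y=[5.0])
        s = sa.Session(pts, sa.ScaleSpec(1, 1, 1), center=(0.0, 0.0))
        s.flip("v")
        assert s.display.x[0] == -3.0 and s.display.y[0] == 5.0

    @pytest.mark.parametrize("axis", ["v", "h"])
    @pytest.mark.parametrize("theta", [0.0, 33.0, -121.0])
    def test_flip_is_involution(self, random_points, unit_spec, axis, theta):
        s = sa.Session(random_points, unit_spec)
        s.rotate(theta)
        before_x, before_y = s.display.x.copy(), s.display.y.copy()
        s.flip(axis)
        s.flip(axis)
        np.testing.assert_allclose(s.display.x, before_x, atol=1e-9)
        np.testing.assert_allclose(s.display.y, before_y, atol=1e-9)

    def test_flip_at_angle_matches_three_step_matrix(self, session):
        session.rotate(90.0)
        x0, y0 = session.display.x.copy(), session.display.y.copy()
        session.flip("v")
        m = hom_flip("vertical", 90.0, session.state.center)
        ex, ey = apply_hom(m, x0, y0)
        np.testing.assert_allclose(session.display.x, ex, atol=1e-9)
        np.testing.assert_allclose(session.display.y, ey, atol=1e-9)
        # the widget angle is concurrently negated
        assert session.state.theta_deg == -90.0

    def test_distances_preserved_and_area_sign(self, session, rng):
        idx = rng.integers(0, session.display.n, size=(50, 2))

        def pairwise(s):
            return np.hypot(s.display.x[idx[:, 0]] - s.display.x[idx[:, 1]],
                            s.display.y[idx[:, 0]] - s.display.y[idx[:, 1]])

        def tri_area(s):
            x, y = s.display.x[:3], s.display.y[:3]
            return 0.5 * ((x[1] - x[0]) * (y[2] - y[0])
                          - (x[2] - x[0]) * (y[1] - y[0]))

        d0, a0 = pairwise(session), tri_area(session)
        session.rotate(31.0)
        session.translate(5.0, 9.0)
        np.testing.assert_allclose(pairwise(session), d0, atol=1e-9)
        assert np.sign(tri_area(session)) == np.sign(a0)
        session.flip("h")
        np.testing.assert_allclose(pairwise(session), d0, atol=1e-9)
        assert np.sign(tri_area(session)) == -np.sign(a0)


class TestRandomSequencesMatchMatrixOracle:
    """Any op sequence equals the ordered homogeneous-matrix product."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sequence(self, random_points, unit_spec, seed):
        rng = np.random.default_rng(seed)
        s = sa.Session(random_points, unit_spec)
        ops = []
        for _ in range(30):
            kind = rng.choice(["rotate", "translate", "flip", "scale"])
            if kind == "rotate":
                th = float(rng.uniform(-180, 180))
                s.rotate(th)
                ops.append(("rotate", th))
            elif kind == "translate":
                tx, ty = rng.uniform(-50, 50, 2)
                s.translate(tx, ty)
                ops.append(("translate", float(tx), float(ty)))
            elif kind == "flip":
                axis = str(rng.choice(["v", "h"]))
                s.flip(axis)
                ops.append(("flip", "vertical" if axis == "v"
                            else "horizontal"))
            else:
                f = float(rng.uniform(0.5, 2.0))
                s.rescale(s.spec.display_scale / f)
                ops.append(("scale", f))
        m = compose_ops(ops, s.state.center)
        ex, ey = apply_hom(m, s._scaled_full.x, s._scaled_full.y)
        np.testing.assert_allclose(s.display.x, ex, atol=1e-9)
        np.testing.assert_allclose(s.display.y, ey, atol=1e-9)


class TestUndoRedo:
    def test_single_undo_restores(self, session):
        x0 = session.display.x.copy()
        session.rotate(30.0)
        assert session.undo()
        np.testing.assert_allclose(session.display.x, x0, atol=1e-9)

    def test_three_undos_restore_origin(self, session):
        x0, y0 = session.display.x.copy(), session.display.y.copy()
        session.rotate(21.0)
        session.translate(4.0, -7.0)
        session.flip("h")
        for _ in range(3):
            session.undo()
        np.testing.assert_allclose(session.display.x, x0, atol=1e-9)
        np.testing.assert_allclose(session.display.y, y0, atol=1e-9)

    def test_undo_empty_warns(self, session):
        x0 = session.display.x.copy()
        with pytest.warns(sa.SpatalignWarning):
            assert not session.undo()
        np.testing.assert_array_equal(session.display.x, x0)

    def test_redo_restores_exactly(self, session):
        session.rotate(13.0)
        after = session.display.x.copy()
        session.undo()
        session.redo()
        np.testing.assert_array_equal(session.display.x, after)

    def test_new_op_discards_redo_branch(self, session):
        session.rotate(10.0)
        session.undo()
        session.translate(1.0, 1.0)
        with pytest.warns(sa.SpatalignWarning):
            assert not session.redo()
        assert [e.op for e in session.log.applied] == ["translate"]

    def test_interleaved_undo_redo_matches_replay(self, random_points,
                                                  unit_spec):
        """Random ops with undo/redo agree with a from-scratch replay."""
        rng = np.random.default_rng(7)
        s = sa.Session(random_points, unit_spec)
        for _ in range(50):
            action = rng.choice(["rotate", "translate", "flip", "undo",
                                 "redo"])
            if action == "rotate":
                s.rotate(float(rng.uniform(-90, 90)))
            elif action == "translate":
                s.translate(*rng.uniform(-10, 10, 2))
            elif action == "flip":
                s.flip(str(rng.choice(["v", "h"])))
            elif action == "undo":
                if s.log.can_undo:
                    s.undo()
            else:
                if s.log.can_redo:
                    s.redo()
        from spatalign.transforms import replay_entries
        x, y, _ = replay_entries(s._scaled_full.x, s._scaled_full.y,
                                 s.log.applied, s.state.center)
        np.testing.assert_array_equal(s.display.x, x)
        np.testing.assert_array_equal(s.display.y, y)

    def test_replay_bit_consistent_at_every_cursor(self, session):
        """entries[0:cursor] reproduce live coordinates bit-for-bit."""
        from spatalign.transforms import replay_entries
        snapshots = [session.display.x.copy()]
        session.rotate(12.0)
        snapshots.append(session.display.x.copy())
        session.translate(3.0, 4.0)
        snapshots.append(session.display.x.copy())
        session.flip("v")
        snapshots.append(session.display.x.copy())
        for cursor, snap in enumerate(snapshots):
            x, _, _ = replay_entries(session._scaled_full.x,
                                     session._scaled_full.y,
                                     session.log.entries[:cursor],
                                     session.state.center)
            np.testing.assert_array_equal(x, snap)


class TestReplayFull:
    def test_empty_log_is_scaling_only(self, random_points):
        spec = sa.ScaleSpec(2.0, 1.0, 1.0)
        s = sa.Session(random_points, spec)
        full = s.replay_full()
        np.testing.assert_array_equal(full.x, random_points.x * 2.0)

    def test_displayed_points_match_live_exactly(self, rng, unit_spec):
        n = 1000
        pts = sa.PointSet(ids=np.arange(n), x=rng.uniform(0, 100, n),
                          y=rng.uniform(0, 100, n),
                          annotation=rng.choice(list("abc"), n))
        s = sa.Session(pts, unit_spec)
        idx = s.downsample_display(100, seed=3)
        s.rotate(17.0)
        s.translate(5.0, -4.0)
        full = s.replay_full()
        np.testing.assert_array_equal(full.x[idx], s.display.x)
        np.testing.assert_array_equal(full.y[idx], s.display.y)

    def test_hidden_points_match_direct_map(self, rng, unit_spec):
        n = 1000
        pts = sa.PointSet(ids=np.arange(n), x=rng.uniform(0, 100, n),
                          y=rng.uniform(0, 100, n),
                          annotation=rng.choice(list("abc"), n))
        s = sa.Session(pts, unit_spec)
        idx = set(s.downsample_display(100, seed=3))
        s.rotate(17.0)
        s.translate(5.0, -4.0)
        full = s.replay_full()
        m = compose_ops([("rotate", 17.0), ("translate", 5.0, -4.0)],
                        s.state.center)
        ex, ey = apply_hom(m, pts.x, pts.y)
        hidden = np.array([i for i in range(n) if i not in idx])
        np.testing.assert_allclose(full.x[hidden], ex[hidden], atol=1e-9)
        np.testing.assert_allclose(full.y[hidden], ey[hidden], atol=1e-9)

    def test_replay_full_after_rescale(self, random_points):
        spec = sa.ScaleSpec(1.0, 1.0, 2.0)
        s = sa.Session(random_points, spec)
        s.rescale(0.5)  # display scale 2 → 0.5 μm/px: coords ×4
        s.translate(10.0, 0.0)
        full = s.replay_full()
        np.testing.assert_allclose(full.x, random_points.x / 2.0 * 4 + 10,
                                   atol=1e-9)


def test_empty_pointset_rejected():
    with pytest.raises(sa.ValidationError):
        sa.PointSet(ids=np.array([]), x=np.array([]), y=np.array([]))
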