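import numpy as np
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

from elastigate.bspline import DeformationField
from elastigate.errors import InputError
from elastigate.gate_transform import (
    TransformOptions,
    interpolate_vertices,
    simplify_vertices,
    transform_gate,
)
from elastigate.model import (
    ROOT,
    GateNode,
    PlotSpec,
    Polygon,
    Quad,
    Range,
    Rectangle,
)

PLOT = PlotSpec("x", "y", 256, 256)
PLOT1D = PlotSpec("x", None, 256, 256)

UNIT_SQUARE = Polygon(((0.2, 0.2), (0.7, 0.2), (0.7, 0.7), (0.2, 0.7)))


def identity_field():
    return DeformationField("training->target", (4, 4), (256, 256))


def constant_field(dx, dy):
    f = identity_field()
    f.coeff_x[:] = dx
    f.coeff_y[:] = dy
    return f


def identity_field_1d():
    return DeformationField("training->target", (4,), (256,))


class TestInterpolate:
    def test_square_spacing_half_side_gives_eight_vertices(self):
        square = Polygon(((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)))
        out = interpolate_vertices(square, 0.5)
        assert len(out.vertices) == 8

    def test_spacing_above_longest_edge_unchanged(self):
        out = interpolate_vertices(UNIT_SQUARE, 10.0)
        assert out.as_array().shape == UNIT_SQUARE.as_array().shape

    def test_per_edge_count_arithmetic(self):
        tri = Polygon(((0.0, 0.0), (0.9, 0.0), (0.0, 0.3)))
        lengths = [0.9, np.hypot(0.9, 0.3), 0.3]
        spacing = 0.3
        expected = sum(int(np.ceil(le / spacing)) for le in lengths)
        out = interpolate_vertices(tri, spacing)
        assert len(out.vertices) == expected

    def test_orientation_and_originals_preserved(self):
        out = interpolate_vertices(UNIT_SQUARE, 0.1)
        assert np.sign(out.signed_area) == np.sign(UNIT_SQUARE.signed_area)
        ov = {tuple(np.round(v, 12)) for v in UNIT_SQUARE.as_array()}
        nv = {tuple(np.round(v, 12)) for v in out.as_array()}
        assert ov <= nv


class TestSimplify:
    def test_collinear_midpoint_removed(self):
        sq = Polygon(((0.2, 0.2), (0.45, 0.2), (0.7, 0.2), (0.7, 0.7), (0.2, 0.7)))
        out = simplify_vertices(sq, 0.0, PLOT)
        assert len(out.vertices) == 4

    def test_zero_tolerance_keeps_non_collinear(self):
        out = simplify_vertices(UNIT_SQUARE, 0.0, PLOT)
        assert len(out.vertices) == 4

    def test_hausdorff_bound(self):
        rng = np.random.default_rng(0)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 24))
        r = 0.3 + 0.05 * rng.standard_normal(24)
        poly = Polygon(tuple(zip(0.5 + r * np.cos(theta), 0.5 + r * np.sin(theta))))
        tol_px = 2.0
        out = simplify_vertices(poly, tol_px, PLOT)
        a = ShapelyPolygon(poly.as_array() * 256)
        b = ShapelyPolygon(out.as_array() * 256)
        assert a.exterior.hausdorff_distance(b.exterior) <= tol_px + 1e-9


class TestTransformGate:
    @pytest.mark.parametrize(
        "shape,plot",
        [
            (UNIT_SQUARE, PLOT),
            (Rectangle(0.2, 0.6, 0.3, 0.8), PLOT),
            (Quad(0.5, 0.5, "Q1"), PLOT),
            (Range(0.25, 0.75), PLOT1D),
        ],
    )
    def test_identity_field_leaves_gate_unchanged(self, shape, plot):
        g = GateNode("g", ROOT, plot, shape)
        field = identity_field_1d() if plot.is_1d else identity_field()
        out = transform_gate(g, field, TransformOptions())
        if isinstance(shape, Polygon):
            assert np.allclose(out.shape.as_array(), shape.as_array(), atol=1e-9)
        else:
            assert out.shape == shape

    def test_constant_shift_in_normalized_units(self):
        g = GateNode("g", ROOT, PLOT, Rectangle(0.2, 0.6, 0.3, 0.8))
        out = transform_gate(g, constant_field(3.0, 0.0), TransformOptions())
        assert out.shape.x_min == pytest.approx(0.2 + 3.0 / 256, abs=1e-9)
        assert out.shape.x_max == pytest.approx(0.6 + 3.0 / 256, abs=1e-9)
        assert out.shape.y_min == pytest.approx(0.3, abs=1e-12)

    def test_quad_preserved_centre_moves_quadrant_axis_aligned(self):
        g = GateNode("g", ROOT, PLOT, Quad(0.5, 0.5, "Q2"))
        out = transform_gate(g, constant_field(3.0, -3.0), TransformOptions())
        assert isinstance(out.shape, Quad)
        assert out.shape.cx == pytest.approx(0.5 + 3.0 / 256, abs=1e-9)
        assert out.shape.cy == pytest.approx(0.5 - 3.0 / 256, abs=1e-9)
        assert out.shape.quadrant == "Q2"

    def test_preserve_off_splits_into_polygons(self):
        opts = TransformOptions(preserve_rect_quad=False)
        rect = GateNode("r", ROOT, PLOT, Rectangle(0.2, 0.6, 0.3, 0.8))
        quad = GateNode("q", ROOT, PLOT, Quad(0.5, 0.5, "Q3"))
        assert isinstance(transform_gate(rect, identity_field(), opts).shape, Polygon)
        assert isinstance(transform_gate(quad, identity_field(), opts).shape, Polygon)

    def test_range_bounds_ordered_after_mapping(self):
        g = GateNode("g", ROOT, PLOT1D, Range(0.25, 0.75))
        f = identity_field_1d()
        f.coeff_x[:] = 2.0
        out = transform_gate(g, f, TransformOptions())
        assert out.shape.x_min == pytest.approx(0.25 + 2.0 / 256, abs=1e-9)
        assert out.shape.x_max == pytest.approx(0.75 + 2.0 / 256, abs=1e-9)

    def test_mismatched_field_size_rejected(self):
        g = GateNode("g", ROOT, PLOT, UNIT_SQUARE)
        small = DeformationField("training->target", (4, 4), (128, 128))
        with pytest.raises(InputError):
            transform_gate(g, small, TransformOptions())

    def test_wrong_direction_rejected(self):
        g = GateNode("g", ROOT, PLOT, UNIT_SQUARE)
        f = DeformationField("target->training", (4, 4), (256, 256))
        with pytest.raises(InputError):
            transform_gate(g, f, TransformOptions())

    def test_interpolate_then_simplify_round_trip_exact(self):
        """Densify, map through the identity, simplify: the inserted collinear
        vertices must all be removed again."""
        g = GateNode("g", ROOT, PLOT, UNIT_SQUARE)
        opts = TransformOptions(
            interpolate_vertices=True, interpolation_spacing=1 / 32,
            simplify_tolerance=0.5,
        )
        out = transform_gate(g, identity_field(), opts)
        assert np.allclose(
            np.sort(out.shape.as_array(), axis=0),
            np.sort(UNIT_SQUARE.as_array(), axis=0),
            atol=1e-9,
        )


class TestGeometricInvariants:
    def _random_polygon(self, rng, n_max=12):
        n = rng.integers(3, n_max + 1)
        theta = np.sort(rng.uniform(0, 2 * np.pi, n))
        if len(np.unique(theta)) < 3:
            theta = np.linspace(0, 2 * np.pi, 5)[:-1]
        r = rng.uniform(0.05, 0.28, len(theta))
        cx, cy = rng.uniform(0.35, 0.65, 2)  # keep the polygon inside the plot
        return Polygon(tuple(zip(cx + r * np.cos(theta), cy + r * np.sin(theta))))

    def test_round_trip_and_clamping_on_500_random_polygons(self):
        rng = np.random.default_rng(12345)
        opts = TransformOptions(
            interpolate_vertices=True, interpolation_spacing=1 / 32,
            simplify_tolerance=0.5,
        )
        field = identity_field()
        for _ in range(500):
            poly = self._random_polygon(rng)
            g = GateNode("g", ROOT, PLOT, poly)
            out = transform_gate(g, field, opts)
            arr = out.shape.as_array()
            assert np.all((arr >= 0.0) & (arr <= 1.0)), "vertices must be clamped"
            a = ShapelyPolygon(poly.as_array() * 256).buffer(0)
            b = ShapelyPolygon(arr * 256).buffer(0)
            sym = a.symmetric_difference(b).area
            perimeter = a.length
            assert sym < 2.0 * opts.simplify_tolerance * perimeter + 1e-6

    def test_quad_group_partition_preserved(self):
        field = constant_field(7.0, -4.0)
        opts = TransformOptions(preserve_rect_quad=True)
        gates = [
            GateNode(q, ROOT, PLOT, Quad(0.45, 0.55, q)) for q in ("Q1", "Q2", "Q3", "Q4")
        ]
        out = [transform_gate(g, field, opts) for g in gates]
        centres = {(o.shape.cx, o.shape.cy) for o in out}
        assert len(centres) == 1  # still one crosshair
        from elastigate.engine import events_in_gate
        from elastigate.model import EventTable

        rng = np.random.default_rng(3)
        ev = EventTable("s", ["x", "y"], rng.random((2000, 2)))
        masks = np.stack([events_in_gate(ev, o) for o in out])
        assert np.all(masks.sum(axis=0) == 1), "quadrants must partition the plane"

    def test_membership_equivariant_under_pure_translation(self):
        rng = np.random.default_rng(9)
        pts = rng.random((3000, 2)) * 0.8
        from elastigate.engine import events_in_gate
        from elastigate.model import EventTable

        poly = self._random_polygon(rng)
        g = GateNode("g", ROOT, PLOT, poly)
        shift_px = np.array([12.0, 7.0])
        field = constant_field(*shift_px)
        out = transform_gate(g, field, TransformOptions())
        ev = EventTable("s", ["x", "y"], pts)
        ev_shifted = EventTable("s", ["x", "y"], pts + shift_px / 256.0)
        base = events_in_gate(ev, g)
        moved = events_in_gate(ev_shifted, out)
        assert np.array_equal(base, moved)
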