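"""Map training gates through a deformation field into target plot space.

Gate vertices live in normalized plot units; they are converted to
bin-centre pixel coordinates (v * W - 0.5), pushed through the
training->target deformation field, converted back, and clamped to the
plot.  Polygon gates can be densified beforehand (so the outline follows
local deformation) and are simplified afterwards with Douglas-Peucker;
rectangle and quad gates can either be preserved (axis-aligned, defined by
their mapped corners / centre) or split into polygons for full freedom of
movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import LineString

from .bspline import DeformationField
from .errors import InputError
from .model import GateNode, PlotSpec, Polygon, Quad, Range, Rectangle

logger = logging.getLogger(__name__)

__all__ = [
    "TransformOptions",
    "interpolate_vertices",
    "simplify_vertices",
    "transform_gate",
]


@dataclass
class TransformOptions:
    interpolate_vertices: bool = False
    interpolation_spacing: float = 1.0 / 32.0  # fraction of plot width
    simplify_tolerance: float = 0.5  # pixels
    preserve_rect_quad: bool = True

    def __post_init__(self):
        if self.interpolation_spacing <= 0:
            raise ValueError("interpolation_spacing must be > 0")
        if self.simplify_tolerance < 0:
            raise ValueError("simplify_tolerance must be >= 0")


def interpolate_vertices(poly: Polygon, spacing: float) -> Polygon:
    """Subdivide every polygon edge longer than ``spacing``.

    Each edge of length ``len`` is split into ``ceil(len / spacing)``
    equal segments; original vertices are retained and orientation is
    preserved.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    v = poly.as_array()
    out = []
    for a, b in zip(v, np.roll(v, -1, axis=0)):
        out.append(a)
        length = float(np.hypot(*(b - a)))
        nseg = int(np.ceil(length / spacing))
        for k in range(1, nseg):
            out.append(a + (b - a) * (k / nseg))
    return Polygon(tuple(map(tuple, out)))


def simplify_vertices(
    poly: Polygon, tolerance: float, plot: PlotSpec | None = None
) -> Polygon:
    """Douglas-Peucker removal of redundant vertices.

    ``tolerance`` is in pixels; vertices are scaled to pixel coordinates of
    ``plot`` (or a 256 px square when omitted) before simplifying, so the
    boundary moves by at most ``tolerance`` pixels.  The result always
    keeps at least 3 vertices.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    W = plot.image_width if plot else 256
    H = plot.image_height if plot else 256
    v = poly.as_array() * np.array([W, H])
    ring = np.vstack([v, v[:1]])
    simplified = np.asarray(LineString(ring).simplify(tolerance).coords)[:-1]
    if len(simplified) < 3:
        return poly
    out = simplified / np.array([W, H])
    try:
        return Polygon(tuple(map(tuple, out)))
    except Exception:  # degenerate after simplification: keep the input
        return poly


def _to_px(v: np.ndarray, W: int, H: int | None = None) -> np.ndarray:
    if H is None:
        return v * W - 0.5
    return v * np.array([W, H]) - 0.5


def _from_px(p: np.ndarray, W: int, H: int | None = None) -> np.ndarray:
    if H is None:
        return (p + 0.5) / W
    return (p + 0.5) / np.array([W, H])


def _map_points(
    points_norm: np.ndarray, field: DeformationField, plot: PlotSpec, gate_id: str
) -> np.ndarray:
    """Normalized (k, 2) vertices -> field -> normalized, clamped to [0, 1]^2."""
    W, H = plot.image_width, plot.image_height
    px = _to_px(np.atleast_2d(points_norm), W, H)
    mapped = field.evaluate(px)
    out = _from_px(mapped, W, H)
    clamped = np.clip(out, 0.0, 1.0)
    n_clamped = int(np.any(clamped != out, axis=1).sum())
    if n_clamped > 0.05 * len(out):
        logger.warning(
            "gate %r: %d/%d transformed vertices clamped to the plot; review placement",
            gate_id, n_clamped, len(out),
        )
    return clamped


def _check_field(g: GateNode, field: DeformationField):
    if field.direction != "training->target":
        raise InputError("gate transfer requires a training->target field")
    expect = (
        (g.plot.image_width,)
        if g.plot.is_1d
        else (g.plot.image_width, g.plot.image_height)
    )
    if tuple(field.image_size) != expect:
        raise InputError(
            f"gate {g.gate_id!r}: plot size {expect} does not match "
            f"field image size {tuple(field.image_size)}"
        )


def transform_gate(
    g: GateNode, field: DeformationField, opts: TransformOptions | None = None
) -> GateNode:
    """Apply a training->target deformation to one gate's geometry."""
    opts = opts or TransformOptions()
    _check_field(g, field)
    shape = g.shape

    if isinstance(shape, Range):
        W = g.plot.image_width
        lo, hi = field.evaluate(_to_px(np.array([shape.x_min, shape.x_max]), W))
        lo, hi = float(np.clip(_from_px(lo, W), 0, 1)), float(np.clip(_from_px(hi, W), 0, 1))
        lo, hi = min(lo, hi), max(lo, hi)
        if hi <= lo:  # collapsed after clamping: keep a sliver at the boundary
            lo, hi = max(0.0, hi - 1e-9), min(1.0, lo + 1e-9)
        return replace(g, shape=Range(lo, hi))

    if isinstance(shape, Rectangle) and opts.preserve_rect_quad:
        corners = np.array([[shape.x_min, shape.y_min], [shape.x_max, shape.y_max]])
        mapped = _map_points(corners, field, g.plot, g.gate_id)
        x0, x1 = sorted(mapped[:, 0])
        y0, y1 = sorted(mapped[:, 1])
        if x1 <= x0 or y1 <= y0:
            logger.warning("gate %r collapsed under the deformation; kept original", g.gate_id)
            return replace(g)
        return replace(g, shape=Rectangle(x0, x1, y0, y1))

    if isinstance(shape, Quad) and opts.preserve_rect_quad:
        centre = _map_points(np.array([[shape.cx, shape.cy]]), field, g.plot, g.gate_id)[0]
        return replace(g, shape=Quad(float(centre[0]), float(centre[1]), shape.quadrant))

    # everything else moves vertex-wise as a polygon
    if isinstance(shape, (Rectangle, Quad)):
        poly = shape.as_polygon()
    else:
        poly = shape
    if opts.interpolate_vertices:
        poly = interpolate_vertices(poly, opts.interpolation_spacing)
    mapped = _map_points(poly.as_array(), field, g.plot, g.gate_id)
    try:
        out = Polygon(tuple(map(tuple, mapped)))
    except Exception:
        logger.warning("gate %r degenerated under the deformation; kept original", g.gate_id)
        return replace(g)
    if opts.simplify_tolerance > 0 or opts.interpolate_vertices:
        out = simplify_vertices(out, opts.simplify_tolerance, g.plot)
    return replace(g, shape=out)
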