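"""Data model: events, plots, gates, hierarchies, and their JSON/CSV I/O.

All event values and gate vertices live in normalized plot units: after the
per-parameter display transform every coordinate is in [0, 1].  Pixel
coordinates are derived from the plot's image size when needed and are
never stored in gates, so a single template applies to any image size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SchemaError
from .transforms import TransformConfig

logger = logging.getLogger(__name__)

ROOT = "ROOT"

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


# ---------------------------------------------------------------------------
# events


@dataclass
class EventTable:
    """Events-by-parameters matrix in normalized plot units."""

    sample_id: str
    parameters: list[str]
    values: np.ndarray  # (n_events, n_parameters) float64

    def __post_init__(self):
        if len(set(self.parameters)) != len(self.parameters) or any(
            not p for p in self.parameters
        ):
            raise ConfigurationError("parameter names must be unique and non-empty")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.parameters))
        if self.values.shape[1] != len(self.parameters):
            raise ConfigurationError(
                f"values have {self.values.shape[1]} columns for "
                f"{len(self.parameters)} parameters"
            )
        if not np.isfinite(self.values).all():
            raise ConfigurationError("EventTable values must be finite")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, param: str) -> np.ndarray:
        try:
            j = self.parameters.index(param)
        except ValueError:
            raise ConfigurationError(
                f"parameter {param!r} not present in sample {self.sample_id!r}"
            ) from None
        return self.values[:, j]

    def subset(self, mask: np.ndarray) -> "EventTable":
        return EventTable(self.sample_id, list(self.parameters), self.values[mask])


# ---------------------------------------------------------------------------
# plots and gate shapes


@dataclass(frozen=True)
class PlotSpec:
    """A 2-D dot plot or, when ``y_param`` is None, a 1-D histogram."""

    x_param: str
    y_param: str | None
    image_width: int = 256
    image_height: int = 256

    def __post_init__(self):
        if self.image_width < 16 or (self.y_param is not None and self.image_height < 16):
            raise SchemaError("plot image dimensions must be at least 16 pixels")

    @property
    def is_1d(self) -> bool:
        return self.y_param is None

    def axis_key(self) -> tuple:
        return (self.x_param, self.y_param, self.image_width, self.image_height)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Polygon:
    vertices: tuple  # ordered ((x, y), ...) in normalized units

    def __post_init__(self):
        v = self.as_array()
        if v.shape[0] < 3:
            raise SchemaError("polygon needs at least 3 vertices")
        if abs(_polygon_area(v)) <= 0.0:
            raise SchemaError("polygon has zero area")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float).reshape(-1, 2)

    @property
    def signed_area(self) -> float:
        return _polygon_area(self.as_array())


@dataclass(frozen=True)
class Rectangle:
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise SchemaError("rectangle bounds must satisfy min < max")

    def as_polygon(self) -> Polygon:
        return Polygon(
            (
                (self.x_min, self.y_min),
                (self.x_max, self.y_min),
                (self.x_max, self.y_max),
                (self.x_min, self.y_max),
            )
        )


@dataclass(frozen=True)
class Quad:
    """One quadrant of a crosshair at (cx, cy).

    Q1 = upper-right, Q2 = upper-left, Q3 = lower-left, Q4 = lower-right;
    x >= cx falls right of the crosshair and y >= cy above it, so the four
    quadrants partition the plane.
    """

    cx: float
    cy: float
    quadrant: str

    def __post_init__(self):
        if self.quadrant not in QUADRANTS:
            raise SchemaError(f"quadrant must be one of {QUADRANTS}")

    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the quadrant clipped to the unit plot."""
        right = self.quadrant in ("Q1", "Q4")
        upper = self.quadrant in ("Q1", "Q2")
        x0, x1 = (self.cx, 1.0) if right else (0.0, self.cx)
        y0, y1 = (self.cy, 1.0) if upper else (0.0, self.cy)
        return (x0, x1, y0, y1)

    def as_polygon(self) -> Polygon:
        x0, x1, y0, y1 = self.bounds()
        return Polygon(((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


@dataclass(frozen=True)
class Range:
    x_min: float
    x_max: float

    def __post_init__(self):
        if not self.x_min < self.x_max:
            raise SchemaError("range bounds must satisfy min < max")


Shape = Polygon | Rectangle | Quad | Range


@dataclass
class GateNode:
    gate_id: str
    parent_id: str  # another gate_id or ROOT
    plot: PlotSpec
    shape: Shape
    elastigate_enabled: bool = True
    density_level_override: int | None = None

    def __post_init__(self):
        if not self.gate_id:
            raise SchemaError("gate_id must be non-empty")
        if isinstance(self.shape, Range) != self.plot.is_1d:
            raise SchemaError(
                f"gate {self.gate_id!r}: range gates require a 1-D plot and vice versa"
            )
        if self.density_level_override is not None and self.density_level_override < 0:
            raise SchemaError(f"gate {self.gate_id!r}: density level must be >= 0")


@dataclass
class TemplateOptions:
    density_level: int = 0
    gray_levels: int = 256
    interpolate_vertices: bool = False
    interpolation_spacing: float = 1.0 / 32.0
    preserve_rect_quad: bool = True
    simplify_tolerance: float = 0.5  # pixels

    def __post_init__(self):
        if self.density_level < 0:
            raise SchemaError("density_level must be >= 0")
        if not 2 <= self.gray_levels <= 256:
            raise SchemaError("gray_levels must be in [2, 256]")
        if self.interpolation_spacing <= 0:
            raise SchemaError("interpolation_spacing must be > 0")
        if self.simplify_tolerance < 0:
            raise SchemaError("simplify_tolerance must be >= 0")

    def to_dict(self) -> dict:
        return {
            "density_level": self.density_level,
            "gray_levels": self.gray_levels,
            "interpolate_vertices": self.interpolate_vertices,
            "interpolation_spacing": self.interpolation_spacing,
            "preserve_rect_quad": self.preserve_rect_quad,
            "simplify_tolerance": self.simplify_tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateOptions":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


@dataclass
class GateTemplate:
    """A gating hierarchy plus the transforms and global options it assumes."""

    nodes: list[GateNode]
    transform: TransformConfig
    options: TemplateOptions = field(default_factory=TemplateOptions)

    def __post_init__(self):
        self._validate_tree()
        self._validate_transform_coverage()
        self._validate_quad_groups()

    # -- validation ------------------------------------------------------

    def _validate_tree(self):
        ids = [n.gate_id for n in self.nodes]
        dupes = {g for g in ids if ids.count(g) > 1}
        if dupes:
            raise SchemaError(f"duplicate gate ids: {sorted(dupes)}")
        known = set(ids)
        for n in self.nodes:
            if n.parent_id != ROOT and n.parent_id not in known:
                raise SchemaError(
                    f"gate {n.gate_id!r} references missing parent {n.parent_id!r}"
                )
        # cycle check by walking to ROOT from every node
        parent = {n.gate_id: n.parent_id for n in self.nodes}
        for gid in ids:
            seen = set()
            cur = gid
            while cur != ROOT:
                if cur in seen:
                    raise SchemaError(f"cycle in gate hierarchy at {gid!r}")
                seen.add(cur)
                cur = parent[cur]

    def _validate_transform_coverage(self):
        for n in self.nodes:
            for p in (n.plot.x_param, n.plot.y_param):
                if p is not None and p not in self.transform:
                    raise ConfigurationError(
                        f"gate {n.gate_id!r} plots parameter {p!r} "
                        "which has no transform"
                    )

    def _validate_quad_groups(self):
        for parent_id, key, group in self.quad_groups():
            centers = {(g.shape.cx, g.shape.cy) for g in group}
            if len(centers) > 1:
                raise SchemaError(
                    f"quad gates under {parent_id!r} on plot {key[:2]} "
                    "must share one (cx, cy)"
                )
            quads = [g.shape.quadrant for g in group]
            if len(set(quads)) != len(quads):
                raise SchemaError(
                    f"duplicate quadrant among quad gates under {parent_id!r}"
                )

    # -- traversal -------------------------------------------------------

    def node(self, gate_id: str) -> GateNode:
        for n in self.nodes:
            if n.gate_id == gate_id:
                return n
        raise KeyError(gate_id)

    def children_of(self, parent_id: str) -> list[GateNode]:
        return [n for n in self.nodes if n.parent_id == parent_id]

    def quad_groups(self):
        """Yield (parent_id, plot_axis_key, [quad GateNodes]) per quad crosshair."""
        groups: dict[tuple, list[GateNode]] = {}
        for n in self.nodes:
            if isinstance(n.shape, Quad):
                groups.setdefault((n.parent_id, n.plot.axis_key()), []).append(n)
        for (parent_id, key), group in groups.items():
            yield parent_id, key, group

    def depth_order(self) -> list[GateNode]:
        """Nodes in breadth-first order from ROOT."""
        out: list[GateNode] = []
        frontier = [ROOT]
        while frontier:
            nxt = []
            for pid in frontier:
                for n in self.children_of(pid):
                    out.append(n)
                    nxt.append(n.gate_id)
            frontier = nxt
        return out


@dataclass
class TrainingSample:
    """A manually gated sample: events plus per-gate boolean membership."""

    sample_id: str
    events: EventTable
    membership: dict[str, np.ndarray]

    def validate_against(self, template: GateTemplate) -> None:
        n = self.events.n_events
        for node in template.nodes:
            mask = self.membership.get(node.gate_id)
            if mask is None:
                raise ConfigurationError(
                    f"training sample {self.sample_id!r} lacks membership for "
                    f"gate {node.gate_id!r}"
                )
            if len(mask) != n:
                raise ConfigurationError(
                    f"membership mask for {node.gate_id!r} has length {len(mask)}, "
                    f"expected {n}"
                )
            if node.parent_id != ROOT:
                parent = self.membership[node.parent_id]
                if np.any(mask & ~parent):
                    raise ConfigurationError(
                        f"gate {node.gate_id!r} mask is not a subset of its parent "
                        f"in sample {self.sample_id!r}"
                    )

    def parent_mask(self, parent_id: str) -> np.ndarray:
        if parent_id == ROOT:
            return np.ones(self.events.n_events, dtype=bool)
        return np.asarray(self.membership[parent_id], dtype=bool)


# ---------------------------------------------------------------------------
# template JSON I/O


def _shape_to_dict(shape: Shape) -> dict:
    if isinstance(shape, Polygon):
        return {"type": "polygon", "vertices": [list(map(float, v)) for v in shape.vertices]}
    if isinstance(shape, Rectangle):
        return {
            "type": "rectangle",
            "x_min": shape.x_min,
            "x_max": shape.x_max,
            "y_min": shape.y_min,
            "y_max": shape.y_max,
        }
    if isinstance(shape, Quad):
        return {"type": "quad", "cx": shape.cx, "cy": shape.cy, "quadrant": shape.quadrant}
    if isinstance(shape, Range):
        return {"type": "range", "x_min": shape.x_min, "x_max": shape.x_max}
    raise TypeError(f"unknown shape {shape!r}")


def _shape_from_dict(d: dict, gate_id: str) -> Shape:
    t = d.get("type")
    try:
        if t == "polygon":
            return Polygon(tuple(tuple(map(float, v)) for v in d["vertices"]))
        if t == "rectangle":
            return Rectangle(
                float(d["x_min"]), float(d["x_max"]), float(d["y_min"]), float(d["y_max"])
            )
        if t == "quad":
            return Quad(float(d["cx"]), float(d["cy"]), str(d["quadrant"]))
        if t == "range":
            return Range(float(d["x_min"]), float(d["x_max"]))
    except SchemaError as e:
        raise SchemaError(f"gate {gate_id!r}: {e}") from None
    raise SchemaError(f"gate {gate_id!r}: unknown shape type {t!r}")


def template_to_dict(template: GateTemplate) -> dict:
    gates = []
    for n in template.nodes:
        plot = {
            "x": n.plot.x_param,
            "y": n.plot.y_param,
            "width": n.plot.image_width,
            "height": n.plot.image_height,
        }
        gates.append(
            {
                "id": n.gate_id,
                "parent": n.parent_id,
                "plot": plot,
                "shape": _shape_to_dict(n.shape),
                "elastigate": n.elastigate_enabled,
                "density_level": n.density_level_override,
            }
        )
    return {
        "transforms": template.transform.to_dict(),
        "options": template.options.to_dict(),
        "gates": gates,
    }


def template_from_dict(d: dict) -> GateTemplate:
    try:
        transform = TransformConfig.from_dict(d["transforms"])
    except KeyError:
        raise SchemaError("template is missing 'transforms'") from None
    options = TemplateOptions.from_dict(d.get("options", {}))
    nodes = []
    for g in d.get("gates", []):
        gid = g.get("id", "<missing id>")
        p = g.get("plot", {})
        plot = PlotSpec(
            x_param=p["x"],
            y_param=p.get("y"),
            image_width=int(p.get("width", 256)),
            image_height=int(p.get("height", 256)),
        )
        nodes.append(
            GateNode(
                gate_id=gid,
                parent_id=g.get("parent", ROOT),
                plot=plot,
                shape=_shape_from_dict(g["shape"], gid),
                elastigate_enabled=bool(g.get("elastigate", True)),
                density_level_override=g.get("density_level"),
            )
        )
    return GateTemplate(nodes=nodes, transform=transform, options=options)


def load_template(path) -> GateTemplate:
    with open(path, encoding="utf-8") as fh:
        return template_from_dict(json.load(fh))


def save_template(template: GateTemplate, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(template_to_dict(template), fh, sort_keys=True, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CSV reports


def write_report(result, path) -> None:
    """Write a GatingResult, list of GatingResults, or F1Report as RFC-4180 CSV."""
    import pandas as pd

    from .evaluation import F1Report

    if isinstance(result, F1Report):
        df = result.rows.copy()
    else:
        results = result if isinstance(result, (list, tuple)) else [result]
        rows = []
        for r in results:
            for gate_id in r.gate_ids:
                rows.append(
                    {
                        "sample_id": r.sample_id,
                        "gate_id": gate_id,
                        "count": r.counts[gate_id],
                        "pct_parent": r.pct_parent[gate_id],
                    }
                )
        df = pd.DataFrame(
            rows, columns=["sample_id", "gate_id", "count", "pct_parent"]
        )
    df.to_csv(path, index=False, lineterminator="\r\n")
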