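"""Hierarchical automated gating: orchestrate imaging, training-plot
selection, registration, gate transfer and event classification.

The gating tree is walked breadth-first.  For each plot (a parent
population viewed on one axis pair), density images are built from the
parent-gated events of every training sample and of the target; the
training plot with minimum L2 error against the target plot is chosen; a
single deformation field is estimated for that plot and shared by all its
elastic child gates; transformed gates then classify the target events to
form the child populations, which condition the next level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .gate_transform import TransformOptions, transform_gate
from .imaging import UpsampleConfig, bin_events, counts_to_gray, upsample_if_sparse
from .model import (
    ROOT,
    EventTable,
    GateNode,
    GateTemplate,
    Polygon,
    Quad,
    Range,
    Rectangle,
    TrainingSample,
)
from .registration import RegistrationConfig, register, register_1d

logger = logging.getLogger(__name__)

__all__ = ["EngineConfig", "GatingResult", "select_training", "events_in_gate", "apply_hierarchy"]


@dataclass
class EngineConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    upsample: UpsampleConfig = field(default_factory=UpsampleConfig)
    transform_options: TransformOptions | None = None  # None: use template options
    density_level: int | None = None  # None: use template options
    gray_levels: int | None = None


@dataclass
class GatingResult:
    sample_id: str
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    pct_parent: dict[str, float] = field(default_factory=dict)
    transformed_gates: dict[str, GateNode] = field(default_factory=dict)
    chosen_training: dict[tuple, str] = field(default_factory=dict)
    plot_ssd: dict[tuple, float] = field(default_factory=dict)
    field_checksums: dict[tuple, str] = field(default_factory=dict)

    @property
    def gate_ids(self) -> list[str]:
        return list(self.masks)


def select_training(target, candidates) -> int:
    """Index of the candidate density image with minimum L2 error vs target.

    The error is the summed squared gray-value difference; ties break to
    the lowest index.
    """
    if not candidates:
        raise InputError("candidate list is empty")
    t = np.asarray(target.gray, dtype=np.int64)
    errs = []
    for c in candidates:
        g = np.asarray(c.gray, dtype=np.int64)
        if g.shape != t.shape:
            raise InputError("candidate and target images must share dimensions")
        if (c.density_level, c.gray_levels) != (target.density_level, target.gray_levels):
            raise InputError("candidates must share density_level and gray_levels")
        errs.append(int(np.sum((g - t) ** 2)))
    return int(np.argmin(errs))


# ---------------------------------------------------------------------------
# event classification


def _points_in_polygon(x: np.ndarray, y: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) test, boundary-inclusive.

    Vectorized over events; O(events x vertices).  Points within 1e-12 of
    an edge count as inside.
    """
    vx, vy = vertices[:, 0], vertices[:, 1]
    vx2, vy2 = np.roll(vx, -1), np.roll(vy, -1)
    inside = np.zeros(len(x), dtype=bool)
    on_edge = np.zeros(len(x), dtype=bool)
    eps = 1e-12
    for x1, y1, x2, y2 in zip(vx, vy, vx2, vy2):
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xi)
        # boundary: |cross product| small and within the segment's bbox
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        seg2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
        bbox = (
            (x >= min(x1, x2) - eps)
            & (x <= max(x1, x2) + eps)
            & (y >= min(y1, y2) - eps)
            & (y <= max(y1, y2) + eps)
        )
        on_edge |= bbox & (cross * cross <= eps * max(seg2, eps))
    return inside | on_edge


def events_in_gate(events: EventTable, g: GateNode) -> np.ndarray:
    """Boolean membership of each event in a gate's region.

    Polygons use the even-odd rule with boundary points inside; rectangles
    and ranges are closed intervals; the four quadrants of a quad split
    half-open (x >= cx right, y >= cy up) so they partition the plane.
    """
    x = events.column(g.plot.x_param)
    shape = g.shape
    if isinstance(shape, Range):
        return (x >= shape.x_min) & (x <= shape.x_max)
    y = events.column(g.plot.y_param)
    if isinstance(shape, Rectangle):
        return (
            (x >= shape.x_min) & (x <= shape.x_max)
            & (y >= shape.y_min) & (y <= shape.y_max)
        )
    if isinstance(shape, Quad):
        right = x >= shape.cx
        upper = y >= shape.cy
        return {
            "Q1": right & upper,
            "Q2": ~right & upper,
            "Q3": ~right & ~upper,
            "Q4": right & ~upper,
        }[shape.quadrant]
    if isinstance(shape, Polygon):
        return _points_in_polygon(x, y, shape.as_array())
    raise ConfigurationError(f"unsupported shape for gate {g.gate_id!r}")


# ---------------------------------------------------------------------------
# hierarchy application


def _density_image(events: EventTable, mask: np.ndarray, plot, d: int, L: int,
                   up: UpsampleConfig):
    grid = bin_events(events.subset(mask), plot)
    grid = upsample_if_sparse(grid, up)
    return counts_to_gray(grid, d, L)


def apply_hierarchy(
    training: list[TrainingSample],
    target: EventTable,
    template: GateTemplate,
    cfg: EngineConfig | None = None,
) -> GatingResult:
    """Gate a target sample by adapting the template from the training set."""
    cfg = cfg or EngineConfig()
    if not training:
        raise InputError("at least one training sample is required")
    for ts in training:
        ts.validate_against(template)
    for node in template.nodes:
        for p in (node.plot.x_param, node.plot.y_param):
            if p is not None and p not in target.parameters:
                raise ConfigurationError(
                    f"target sample lacks parameter {p!r} needed by gate {node.gate_id!r}"
                )

    opts = cfg.transform_options or TransformOptions(
        interpolate_vertices=template.options.interpolate_vertices,
        interpolation_spacing=template.options.interpolation_spacing,
        simplify_tolerance=template.options.simplify_tolerance,
        preserve_rect_quad=template.options.preserve_rect_quad,
    )
    base_d = cfg.density_level if cfg.density_level is not None else template.options.density_level
    L = cfg.gray_levels if cfg.gray_levels is not None else template.options.gray_levels

    result = GatingResult(sample_id=target.sample_id)
    target_masks: dict[str, np.ndarray] = {ROOT: np.ones(target.n_events, dtype=bool)}

    frontier = [ROOT]
    while frontier:
        next_frontier = []
        for parent_id in frontier:
            children = template.children_of(parent_id)
            next_frontier.extend(c.gate_id for c in children)
            if not children:
                continue
            parent_mask = target_masks[parent_id]
            # group children by plot and effective density level: one
            # registration per (plot, density) pair, shared by its gates
            groups: dict[tuple, list[GateNode]] = {}
            for c in children:
                d_eff = c.density_level_override if c.density_level_override is not None else base_d
                groups.setdefault((c.plot.axis_key(), d_eff), []).append(c)

            for (axis_key, d_eff), gates in groups.items():
                plot = gates[0].plot
                enabled = [g for g in gates if g.elastigate_enabled]
                fwd_field = None
                if enabled and parent_mask.sum() == 0:
                    logger.warning(
                        "sample %r: empty parent population %r; children set empty",
                        target.sample_id, parent_id,
                    )
                elif enabled:
                    tgt_img = _density_image(
                        target, parent_mask, plot, d_eff, L, cfg.upsample
                    )
                    cand_imgs = [
                        _density_image(
                            ts.events, ts.parent_mask(parent_id), plot, d_eff, L, cfg.upsample
                        )
                        for ts in training
                    ]
                    k = select_training(tgt_img, cand_imgs)
                    key = (parent_id,) + axis_key + (d_eff,)
                    result.chosen_training[key] = training[k].sample_id
                    reg = (register_1d if plot.is_1d else register)(
                        cand_imgs[k], tgt_img, cfg.registration
                    )
                    result.plot_ssd[key] = reg.final_ssd
                    fwd_field = reg.field
                    result.field_checksums[key] = fwd_field.checksum()
                    logger.debug(
                        "plot %s under %r: training %r, final ssd %.4g",
                        axis_key, parent_id, training[k].sample_id, reg.final_ssd,
                    )

                for g in gates:
                    if g.elastigate_enabled and fwd_field is not None:
                        new_gate = transform_gate(g, fwd_field, opts)
                    else:
                        new_gate = g
                    result.transformed_gates[g.gate_id] = new_gate
                    if parent_mask.sum() == 0:
                        mask = np.zeros(target.n_events, dtype=bool)
                    else:
                        mask = events_in_gate(target, new_gate) & parent_mask
                    target_masks[g.gate_id] = mask
                    result.masks[g.gate_id] = mask
                    result.counts[g.gate_id] = int(mask.sum())
                    denom = int(parent_mask.sum())
                    result.pct_parent[g.gate_id] = (
                        100.0 * mask.sum() / denom if denom else 0.0
                    )
        frontier = next_frontier
    return result
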