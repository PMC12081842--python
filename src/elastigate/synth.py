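"""Seeded synthetic flow-like datasets with known structure and oracle gates.

Samples are drawn from 2-D (or higher) Gaussian mixtures whose components
stand in for cell populations.  Per-sample perturbations — translation of
component means, scaling of covariances, abundance changes — emulate the
instrument drift and biological variability that make fixed template gates
fail on real panels.  Because the generating parameters are known, every
sample comes with oracle gates (polygons covering each perturbed
component) and oracle membership (the component labels), so gating
accuracy can be scored without any external data.

Three presets mirror common assay archetypes at toy scale:

* ``scatter`` — three scatter-like populations (lymphocyte / monocyte /
  granulocyte analogue) on one 2-D plot;
* ``beads``   — a five-peak 1-D intensity histogram with range gates;
* ``hier``    — a two-level hierarchy: a scatter polygon gate, then a quad
  on two marker axes within it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fcs import write_fcs_file
from .model import (
    ROOT,
    EventTable,
    GateNode,
    GateTemplate,
    PlotSpec,
    Polygon,
    Quad,
    Range,
    TemplateOptions,
    TrainingSample,
)
from .transforms import LinearTransform, TransformConfig

__all__ = [
    "Drift",
    "Population",
    "PanelSpec",
    "generate_sample",
    "generate_panel",
    "write_fcs",
    "scatter_panel",
    "beads_panel",
    "hier_panel",
    "preset_panel",
]

# Mahalanobis radius of oracle gates: a 16-gon inscribed at 3.5 sigma keeps
# > 99.7% of a Gaussian component inside its gate.
ORACLE_RADIUS = 3.5
ORACLE_VERTICES = 16


@dataclass(frozen=True)
class Drift:
    """Per-sample perturbation of one population."""

    translation: tuple = (0.0, 0.0)  # added to the mean (per parameter)
    scale: float = 1.0  # multiplies the standard deviation
    abundance: float = 1.0  # multiplies the mixture weight


@dataclass
class Population:
    name: str
    weight: float
    mean: np.ndarray  # (n_params,)
    cov: np.ndarray  # (n_params, n_params)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.weight <= 0:
            raise ValueError(f"population {self.name!r}: weight must be > 0")
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise ValueError(f"population {self.name!r}: covariance must be positive-definite")


@dataclass
class PanelSpec:
    """Mixture panel plus the per-sample drift schedule.

    ``drifts[k][name]`` gives the Drift of population ``name`` in sample
    ``k``; missing entries mean no perturbation.  Sample 0 conventionally
    serves as the (undrifted) training sample.
    """

    populations: list[Population]
    parameters: list[str]
    n_events: int = 5000
    seed: int = 0
    drifts: list[dict[str, Drift]] = dc_field(default_factory=list)
    # (x_param, y_param or None) of each gated plot, with the population
    # names gated on it; used to build the oracle template
    plots: list[tuple] = dc_field(default_factory=list)
    image_size: int = 128

    def __post_init__(self):
        w = np.array([p.weight for p in self.populations])
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("population weights must sum to 1")

    def drift_for(self, sample_index: int, name: str) -> Drift:
        if sample_index < len(self.drifts):
            return self.drifts[sample_index].get(name, Drift())
        return Drift()


def random_drifts(
    n_samples: int,
    pop_names: list[str],
    rng: np.random.Generator,
    max_translation: float = 0.08,
    scale_range: tuple[float, float] = (0.95, 1.05),
    abundance_range: tuple[float, float] = (0.7, 1.3),
    n_params: int = 2,
    shared_translation: bool = True,
) -> list[dict[str, Drift]]:
    """Drift schedule: sample 0 is undrifted; later samples drift randomly.

    With ``shared_translation`` the translation is common to all
    populations of a sample (instrument-level drift) while scale and
    abundance remain per-population.
    """
    out: list[dict[str, Drift]] = [{}]
    for _ in range(1, n_samples):
        shift = rng.uniform(-max_translation, max_translation, size=n_params)
        entry = {}
        for name in pop_names:
            t = shift if shared_translation else rng.uniform(
                -max_translation, max_translation, size=n_params
            )
            entry[name] = Drift(
                translation=tuple(t),
                scale=float(rng.uniform(*scale_range)),
                abundance=float(rng.uniform(*abundance_range)),
            )
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# sample generation


def _perturbed(pop: Population, drift: Drift) -> tuple[np.ndarray, np.ndarray, float]:
    t = np.zeros_like(pop.mean)
    k = min(len(drift.translation), len(t))
    t[:k] = drift.translation[:k]
    return pop.mean + t, pop.cov * drift.scale ** 2, pop.weight * drift.abundance


def _ellipse_polygon(mean2: np.ndarray, cov2: np.ndarray) -> Polygon:
    """Oracle gate: ORACLE_RADIUS-sigma ellipse polygonized at 16 vertices."""
    vals, vecs = np.linalg.eigh(cov2)
    theta = np.linspace(0.0, 2.0 * np.pi, ORACLE_VERTICES, endpoint=False)
    circ = np.stack([np.cos(theta), np.sin(theta)], axis=0)
    pts = mean2[:, None] + ORACLE_RADIUS * vecs @ (np.sqrt(vals)[:, None] * circ)
    pts = np.clip(pts, 0.0, 1.0)
    return Polygon(tuple(map(tuple, pts.T)))


def generate_sample(
    spec: PanelSpec, sample_index: int
) -> tuple[EventTable, GateTemplate, dict[str, np.ndarray]]:
    """Draw one perturbed sample with its oracle gates and membership.

    Returns (events, oracle template, oracle per-gate membership masks).
    Reproducible: the RNG is seeded from (spec.seed, sample_index) only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, sample_index]))
    params = list(spec.parameters)
    perturbed = {}
    weights = []
    for pop in spec.populations:
        m, c, w = _perturbed(pop, spec.drift_for(sample_index, pop.name))
        perturbed[pop.name] = (m, c)
        weights.append(w)
    weights = np.asarray(weights)
    probs = weights / weights.sum()
    labels = rng.choice(len(spec.populations), size=spec.n_events, p=probs)
    values = np.empty((spec.n_events, len(params)))
    for i, pop in enumerate(spec.populations):
        idx = np.nonzero(labels == i)[0]
        if len(idx) == 0:
            continue
        m, c = perturbed[pop.name]
        values[idx] = rng.multivariate_normal(m, c, size=len(idx), method="cholesky")
    values = np.clip(values, 0.0, 1.0)
    events = EventTable(f"sample_{sample_index:03d}", params, values)

    template = _oracle_template(spec, perturbed)
    membership = _oracle_membership(spec, labels, events, template)
    return events, template, membership


def _oracle_template(spec: PanelSpec, perturbed: dict) -> GateTemplate:
    transform = TransformConfig({p: LinearTransform(0.0, 1.0) for p in spec.parameters})
    nodes: list[GateNode] = []
    sz = spec.image_size
    for plot_def in spec.plots:
        x_param, y_param, parent_id, gated = plot_def
        plot = PlotSpec(x_param, y_param, sz, sz)
        ix = spec.parameters.index(x_param)
        if y_param is None:
            for name in gated:
                m, c = perturbed[name]
                s = np.sqrt(c[ix, ix])
                nodes.append(
                    GateNode(
                        gate_id=name,
                        parent_id=parent_id,
                        plot=plot,
                        shape=Range(
                            max(0.0, m[ix] - ORACLE_RADIUS * s),
                            min(1.0, m[ix] + ORACLE_RADIUS * s),
                        ),
                    )
                )
        elif isinstance(gated, dict) and gated.get("quad"):
            iy = spec.parameters.index(y_param)
            cx, cy = gated["centre"]
            for quadrant, name in gated["quad"].items():
                nodes.append(
                    GateNode(
                        gate_id=name,
                        parent_id=parent_id,
                        plot=plot,
                        shape=Quad(cx, cy, quadrant),
                    )
                )
        else:
            iy = spec.parameters.index(y_param)
            sel = np.ix_((ix, iy), (ix, iy))
            for name in gated:
                if isinstance(name, tuple):  # (gate_id, [component names])
                    gate_id, members = name
                    ms = [perturbed[n] for n in members]
                    mean2 = np.mean([m[[ix, iy]] for m, _ in ms], axis=0)
                    # envelope: inflate to cover all member components
                    cov2 = np.mean([c[sel] for _, c in ms], axis=0)
                    spread = np.max(
                        [np.outer(m[[ix, iy]] - mean2, m[[ix, iy]] - mean2) for m, _ in ms],
                        axis=0,
                    )
                    cov2 = cov2 + spread
                else:
                    gate_id = name
                    m, c = perturbed[name]
                    mean2, cov2 = m[[ix, iy]], c[sel]
                nodes.append(
                    GateNode(
                        gate_id=gate_id,
                        parent_id=parent_id,
                        plot=plot,
                        shape=_ellipse_polygon(np.asarray(mean2), np.asarray(cov2)),
                    )
                )
    return GateTemplate(nodes=nodes, transform=transform, options=TemplateOptions())


def _oracle_membership(
    spec: PanelSpec, labels: np.ndarray, events: EventTable, template: GateTemplate
) -> dict[str, np.ndarray]:
    """Component labels -> per-gate truth masks, respecting the hierarchy."""
    name_to_idx = {p.name: i for i, p in enumerate(spec.populations)}
    membership: dict[str, np.ndarray] = {}
    for node in template.depth_order():
        parent = (
            np.ones(events.n_events, dtype=bool)
            if node.parent_id == ROOT
            else membership[node.parent_id]
        )
        comp = _gate_components(spec, node.gate_id)
        if comp is not None:
            mask = np.isin(labels, [name_to_idx[n] for n in comp])
        else:
            # composite/quad gates not tied to single components: geometric truth
            from .engine import events_in_gate

            mask = events_in_gate(events, node)
        membership[node.gate_id] = mask & parent
    return membership


def _gate_components(spec: PanelSpec, gate_id: str):
    """Population names whose labels define a gate's truth, if any."""
    names = {p.name for p in spec.populations}
    if gate_id in names:
        return [gate_id]
    for plot_def in spec.plots:
        gated = plot_def[3]
        if isinstance(gated, dict):
            comp = gated.get("components", {}).get(gate_id)
            if comp is not None:
                return comp
        else:
            for entry in gated:
                if isinstance(entry, tuple) and entry[0] == gate_id:
                    return entry[1]
    return None


def generate_panel(
    spec: PanelSpec, n_samples: int
) -> tuple[TrainingSample, GateTemplate, list[tuple[EventTable, dict[str, np.ndarray]]]]:
    """Training sample (index 0, its oracle template) plus drifted targets."""
    ev0, template0, mem0 = generate_sample(spec, 0)
    training = TrainingSample(ev0.sample_id, ev0, mem0)
    targets = []
    for k in range(1, n_samples):
        ev, _, mem = generate_sample(spec, k)
        targets.append((ev, mem))
    return training, template0, targets


def write_fcs(events: EventTable, path) -> None:
    """Write an EventTable as a minimal FCS 3.1 float file.

    Values are stored as-is (normalized plot units); reading the file back
    with an identity linear(0, 1) transform reproduces the table within
    float32 precision.
    """
    write_fcs_file(path, list(events.parameters), events.values)


# ---------------------------------------------------------------------------
# presets


def scatter_panel(seed: int = 0, n_samples: int = 21, n_events: int = 5000,
                  max_translation: float = 0.08, image_size: int = 128) -> PanelSpec:
    """Three scatter-like populations on one FSC/SSC-style plot."""
    pops = [
        Population("lymphocytes", 0.45, [0.28, 0.22],
                   [[0.0016, 0.0003], [0.0003, 0.0012]]),
        Population("monocytes", 0.20, [0.52, 0.45],
                   [[0.0020, -0.0004], [-0.0004, 0.0025]]),
        Population("granulocytes", 0.35, [0.30, 0.75],
                   [[0.0030, 0.0005], [0.0005, 0.0022]]),
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 987654321]))
    spec = PanelSpec(
        populations=pops,
        parameters=["FSC-A", "SSC-A"],
        n_events=n_events,
        seed=seed,
        plots=[("FSC-A", "SSC-A", ROOT, ["lymphocytes", "monocytes", "granulocytes"])],
        image_size=image_size,
    )
    spec.drifts = random_drifts(
        n_samples, [p.name for p in pops], rng, max_translation=max_translation
    )
    return spec


def beads_panel(seed: int = 0, n_samples: int = 11, n_events: int = 5000,
                max_translation: float = 0.04, image_size: int = 256) -> PanelSpec:
    """Five-peak 1-D beads histogram with range gates."""
    centres = [0.15, 0.325, 0.5, 0.675, 0.85]
    pops = [
        Population(f"peak{i + 1}", 0.2, [c], [[0.018 ** 2]])
        for i, c in enumerate(centres)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 123456789]))
    spec = PanelSpec(
        populations=pops,
        parameters=["FL1-A"],
        n_events=n_events,
        seed=seed,
        plots=[("FL1-A", None, ROOT, [p.name for p in pops])],
        image_size=image_size,
    )
    spec.drifts = random_drifts(
        n_samples, [p.name for p in pops], rng,
        max_translation=max_translation, n_params=1,
    )
    return spec


def hier_panel(seed: int = 0, n_samples: int = 11, n_events: int = 6000,
               max_translation: float = 0.05, image_size: int = 128) -> PanelSpec:
    """Two-level hierarchy: scatter 'cells' polygon, then a CD4/CD8 quad."""
    pops = [
        Population("debris", 0.15, [0.12, 0.10, 0.18, 0.16],
                   np.diag([0.0016, 0.0016, 0.004, 0.004])),
        Population("cd4_t", 0.40, [0.45, 0.40, 0.75, 0.22],
                   np.diag([0.0022, 0.0022, 0.0025, 0.0020])),
        Population("cd8_t", 0.30, [0.45, 0.40, 0.22, 0.75],
                   np.diag([0.0022, 0.0022, 0.0020, 0.0025])),
        Population("dn_t", 0.15, [0.45, 0.40, 0.22, 0.22],
                   np.diag([0.0022, 0.0022, 0.0020, 0.0020])),
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 555555555]))
    cells = ("cells", ["cd4_t", "cd8_t", "dn_t"])
    spec = PanelSpec(
        populations=pops,
        parameters=["FSC-A", "SSC-A", "CD4", "CD8"],
        n_events=n_events,
        seed=seed,
        plots=[
            ("FSC-A", "SSC-A", ROOT, [cells]),
            (
                "CD4", "CD8", "cells",
                {
                    "quad": {"Q4": "cd4_pos", "Q2": "cd8_pos", "Q3": "dn", "Q1": "dp"},
                    "centre": (0.5, 0.5),
                    "components": {
                        "cd4_pos": ["cd4_t"],
                        "cd8_pos": ["cd8_t"],
                        "dn": ["dn_t"],
                        "dp": [],
                    },
                },
            ),
        ],
        image_size=image_size,
    )
    spec.drifts = random_drifts(
        n_samples, [p.name for p in pops], rng,
        max_translation=max_translation, n_params=4,
    )
    return spec


PRESETS = {"scatter": scatter_panel, "beads": beads_panel, "hier": hier_panel}


def preset_panel(name: str, seed: int = 0, n_samples: int | None = None, **kw) -> PanelSpec:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if n_samples is not None:
        kw["n_samples"] = n_samples
    return factory(seed=seed, **kw)
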