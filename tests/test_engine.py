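import numpy as np
import pytest

from elastigate.engine import (
    apply_hierarchy,
    events_in_gate,
    select_training,
)
from elastigate.errors import InputError
from elastigate.evaluation import build_report, summarize
from elastigate.imaging import DensityImage
from elastigate.model import (
    ROOT,
    EventTable,
    GateNode,
    PlotSpec,
    Polygon,
    Quad,
    Rectangle,
    TrainingSample,
)
from elastigate.synth import generate_panel, hier_panel, scatter_panel

PLOT = PlotSpec("x", "y", 64, 64)


def _img(a):
    a = np.asarray(a, dtype=np.uint8)
    plot = PlotSpec("x", "y", max(16, a.shape[1]), max(16, a.shape[0]))
    pad = np.zeros((plot.image_height, plot.image_width), dtype=np.uint8)
    pad[: a.shape[0], : a.shape[1]] = a
    return DensityImage(pad, plot, 0, 256)


class TestSelectTraining:
    def test_exact_match_wins(self):
        rng = np.random.default_rng(0)
        a = _img(rng.integers(0, 255, (16, 16)))
        b = _img(rng.integers(0, 255, (16, 16)))
        assert select_training(a, [b, a]) == 1

    def test_hand_computed_l2_ordering(self):
        A = _img([[0, 10], [0, 0]])
        B = _img([[0, 0], [0, 10]])
        target = _img([[0, 8], [0, 0]])
        # L2(A) = (10-8)^2 = 4; L2(B) = 8^2 + 10^2 = 164
        assert select_training(target, [A, B]) == 0
        assert select_training(target, [B, A]) == 1

    def test_tie_breaks_to_lowest_index(self):
        a = _img(np.full((16, 16), 3))
        assert select_training(_img(np.zeros((16, 16))), [a, a]) == 0

    def test_empty_candidates_rejected(self):
        with pytest.raises(InputError):
            select_training(_img(np.zeros((16, 16))), [])


class TestEventsInGate:
    def test_centroid_of_convex_polygon_inside(self):
        poly = Polygon(((0.2, 0.2), (0.8, 0.25), (0.5, 0.9)))
        centroid = poly.as_array().mean(axis=0)
        ev = EventTable("s", ["x", "y"], centroid[None, :])
        g = GateNode("g", ROOT, PLOT, poly)
        assert events_in_gate(ev, g)[0]

    def test_boundary_points_count_inside(self):
        poly = Polygon(((0.2, 0.2), (0.8, 0.2), (0.8, 0.8), (0.2, 0.8)))
        ev = EventTable("s", ["x", "y"], np.array([[0.5, 0.2], [0.2, 0.5], [0.2, 0.2]]))
        g = GateNode("g", ROOT, PLOT, poly)
        assert events_in_gate(ev, g).all()

    def test_quad_centre_belongs_to_upper_right_only(self):
        ev = EventTable("s", ["x", "y"], np.array([[0.5, 0.5]]))
        hits = [
            events_in_gate(ev, GateNode(q, ROOT, PLOT, Quad(0.5, 0.5, q)))[0]
            for q in ("Q1", "Q2", "Q3", "Q4")
        ]
        assert hits == [True, False, False, False]

    def test_polygon_matches_per_point_bruteforce_on_square(self):
        rng = np.random.default_rng(7)
        pts = rng.random((10, 2))
        square = Polygon(((0.25, 0.25), (0.75, 0.25), (0.75, 0.75), (0.25, 0.75)))
        ev = EventTable("s", ["x", "y"], pts)
        got = events_in_gate(ev, GateNode("g", ROOT, PLOT, square))
        expect = np.array(
            [0.25 <= x <= 0.75 and 0.25 <= y <= 0.75 for x, y in pts]
        )
        assert np.array_equal(got, expect)

    def test_rectangle_closed_intervals(self):
        ev = EventTable("s", ["x", "y"], np.array([[0.3, 0.3], [0.3, 0.61]]))
        g = GateNode("g", ROOT, PLOT, Rectangle(0.3, 0.6, 0.3, 0.6))
        assert events_in_gate(ev, g).tolist() == [True, False]


class TestApplyHierarchy:
    def test_self_gating_reproduces_membership(self, scatter_fixture):
        _, training, template, _ = scatter_fixture
        res = apply_hierarchy([training], training.events, template)
        rep = build_report(res, {training.sample_id: training.membership})
        assert (rep.rows["F1"] >= 0.99).all()
        # transformed gates should sit within a pixel of the template gates
        for node in template.nodes:
            out = res.transformed_gates[node.gate_id].shape.as_array()
            ref = node.shape.as_array()
            assert np.abs(out - ref).max() < 1.0 / 128

    def test_distinct_shift_training_selection_by_construction(self):
        spec = scatter_panel(seed=11, n_samples=4)
        training, template, targets = generate_panel(spec, 4)
        samples = [training]
        for ev, mem in targets[:2]:
            samples.append(TrainingSample(ev.sample_id, ev, mem))
        target_ev, _ = targets[1]  # identical to samples[2]'s distribution
        res = apply_hierarchy(samples, target_ev, template)
        assert set(res.chosen_training.values()) == {samples[2].sample_id}

    def test_adding_own_gated_copy_makes_it_selected_with_zero_ssd(self, scatter_fixture):
        _, training, template, targets = scatter_fixture
        ev, mem = targets[0]
        own = TrainingSample(ev.sample_id, ev, mem)
        res = apply_hierarchy([training, own], ev, template)
        assert set(res.chosen_training.values()) == {own.sample_id}
        assert all(s == pytest.approx(0.0, abs=1e-9) for s in res.plot_ssd.values())

    def test_determinism(self, scatter_fixture):
        _, training, template, targets = scatter_fixture
        ev, _ = targets[0]
        r1 = apply_hierarchy([training], ev, template)
        r2 = apply_hierarchy([training], ev, template)
        for g in r1.gate_ids:
            assert np.array_equal(r1.masks[g], r2.masks[g])

    def test_child_masks_subsets_and_quad_partition(self):
        spec = hier_panel(seed=3, n_samples=2)
        training, template, targets = generate_panel(spec, 2)
        ev, mem = targets[0]
        res = apply_hierarchy([training], ev, template)
        for node in template.nodes:
            if node.parent_id != ROOT:
                parent = res.masks[node.parent_id]
                assert not np.any(res.masks[node.gate_id] & ~parent)
        quads = [res.masks[g] for g in ("cd4_pos", "cd8_pos", "dn", "dp")]
        assert np.array_equal(np.sum(quads, axis=0), res.masks["cells"].astype(int))
        rep = build_report(res, {ev.sample_id: mem})
        _, overall, _ = summarize(rep, min_cells=40)
        assert overall >= 0.95

    def test_empty_parent_short_circuits(self):
        spec = scatter_panel(seed=5, n_samples=2, n_events=500)
        training, template, targets = generate_panel(spec, 2)
        # child gate under an always-empty parent region
        lymph = template.node("lymphocytes")
        sub = GateNode("sub", "lymphocytes", lymph.plot,
                       Rectangle(0.9, 0.99, 0.9, 0.99))
        template.nodes.append(sub)
        template.__post_init__()
        for m in (training.membership,):
            m["sub"] = np.zeros(training.events.n_events, dtype=bool)
        ev, _ = targets[0]
        # make the lymphocyte gate empty on the target by shrinking it away
        template.node("lymphocytes").shape = Polygon(
            ((0.96, 0.96), (0.99, 0.96), (0.99, 0.99))
        )
        training.membership["lymphocytes"] = np.zeros(training.events.n_events, bool)
        res = apply_hierarchy([training], ev, template)
        assert res.counts["sub"] == 0
        assert res.pct_parent["sub"] == 0.0

    def test_missing_parameter_rejected(self, scatter_fixture):
        _, training, template, _ = scatter_fixture
        bad = EventTable("t", ["FSC-A"], np.random.default_rng(0).random((10, 1)))
        from elastigate.errors import ConfigurationError

        with pytest.raises(ConfigurationError, match="SSC-A"):
            apply_hierarchy([training], bad, template)

    def test_disabled_gates_copied_verbatim(self, scatter_fixture):
        _, training, template, targets = scatter_fixture
        for n in template.nodes:
            n.elastigate_enabled = False
        ev, _ = targets[0]
        res = apply_hierarchy([training], ev, template)
        for node in template.nodes:
            assert res.transformed_gates[node.gate_id].shape == node.shape
        for n in template.nodes:
            n.elastigate_enabled = True
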