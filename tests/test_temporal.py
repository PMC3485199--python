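"""Ego networks, activity masks, frames, and frame export."""

import logging

import networkx as nx
import numpy as np
import pytest

from hubcycle import (
    SmoothedMatrix,
    activity_mask,
    ego_network,
    export_frames,
    frame_at,
    read_frames,
)


def bfs_depths(graph, source):
    """Hand-rolled breadth-first search oracle."""
    depth = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in depth:
                    depth[v] = depth[u] + 1
                    nxt.append(v)
        frontier = nxt
    return depth


def smoothed(values, genes=None, times=None):
    values = np.atleast_2d(np.asarray(values, float))
    return SmoothedMatrix(
        experiment_id="e",
        genes=genes or [f"G{i}" for i in range(values.shape[0])],
        times=np.arange(values.shape[1], dtype=float) * 10 if times is None else times,
        values=values,
        missing=np.zeros_like(values, dtype=bool),
    )


class TestEgoNetwork:
    def test_star_one_step(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        ego = ego_network(g, "N0", 1)
        assert set(ego.nodes) == set(g.nodes)
        assert ego.number_of_edges() == 5

    def test_path_two_steps(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        ego = ego_network(g, "A", 2)
        assert set(ego.nodes) == {"A", "B", "C"}
        assert set(map(frozenset, ego.edges)) == {frozenset("AB"), frozenset("BC")}

    def test_missing_hub_named(self):
        with pytest.raises(KeyError, match="ZZZ9"):
            ego_network(nx.Graph([("A", "B")]), "ZZZ9", 1)

    def test_matches_bfs_oracle_and_nesting(self, rng):
        g = nx.gnp_random_graph(50, 0.1, seed=4)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        depths = bfs_depths(g, "N00")
        for steps in (1, 2):
            ego = ego_network(g, "N00", steps)
            assert set(ego.nodes) == {n for n, d in depths.items() if d <= steps}
        assert set(ego_network(g, "N00", 1).nodes) <= set(ego_network(g, "N00", 2).nodes)
        assert set(map(frozenset, ego_network(g, "N00", 1).edges)) <= set(
            map(frozenset, ego_network(g, "N00", 2).edges)
        )


class TestActivityMask:
    def test_boundary_inclusive(self):
        mask = activity_mask(smoothed([[-0.2, -0.21, 0.0]]))
        assert mask.active[0].tolist() == [True, False, True]

    def test_override_raises_threshold(self):
        # a value of -0.15 passes the default -0.2 but not a -0.1 override
        sm = smoothed([[-0.15, -0.15]], genes=["CLA4"])
        assert activity_mask(sm).active.all()
        assert not activity_mask(sm, overrides={"CLA4": -0.1}).active.any()

    def test_extreme_threshold_all_active(self, rng):
        sm = smoothed(rng.normal(size=(4, 6)))
        assert activity_mask(sm, threshold=-10).active.all()

    def test_missing_values_inactive(self):
        sm = smoothed([[1.0, 1.0]])
        sm.missing[0, 1] = True
        mask = activity_mask(sm)
        assert mask.active[0].tolist() == [True, False]

    def test_unknown_override_warned_and_ignored(self, caplog):
        with caplog.at_level(logging.WARNING):
            mask = activity_mask(smoothed([[0.0]]), overrides={"NOPE": 0.5})
        assert "NOPE" in caplog.text
        assert mask.overrides == {}


class TestFrames:
    def _setup(self):
        g = nx.Graph([("H", "A"), ("H", "B"), ("A", "B"), ("B", "C")])
        sm = smoothed(
            [[0.5, -0.5], [0.1, 0.1], [0.3, -0.3], [0.2, 0.2]],
            genes=["H", "A", "B", "C"],
            times=np.array([0.0, 10.0]),
        )
        return g, activity_mask(sm)

    def test_all_active_equals_network(self):
        g, mask = self._setup()
        fr = frame_at(g, mask, 0.0)
        assert fr.visible_nodes == frozenset("HABC")
        assert len(fr.visible_edges) == 4

    def test_inactive_hub_hides_incident_edges(self):
        g, mask = self._setup()
        fr = frame_at(g, mask, 10.0)  # H and B below threshold
        assert "H" not in fr.visible_nodes
        assert all("H" not in e and "B" not in e for e in fr.visible_edges)

    def test_unsampled_time_rejected(self):
        g, mask = self._setup()
        with pytest.raises(ValueError, match="sampled"):
            frame_at(g, mask, 5.0)

    def test_edge_rule_matches_bruteforce(self, rng):
        g = nx.gnp_random_graph(30, 0.15, seed=9)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        sm = smoothed(rng.normal(scale=0.3, size=(30, 8)), genes=sorted(g.nodes))
        mask = activity_mask(sm)
        for t in mask.times:
            fr = frame_at(g, mask, t)
            expected = {
                tuple(sorted((u, v)))
                for u, v in g.edges()
                if mask.is_active(u, t) and mask.is_active(v, t)
            }
            assert fr.visible_edges == frozenset(expected)

    def test_threshold_monotonicity(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        sm = smoothed(rng.normal(scale=0.3, size=(20, 6)), genes=sorted(g.nodes))
        hi = activity_mask(sm, threshold=-0.1)
        lo = activity_mask(sm, threshold=-0.4)
        for t in sm.times:
            f_hi, f_lo = frame_at(g, hi, t), frame_at(g, lo, t)
            assert f_hi.visible_nodes <= f_lo.visible_nodes
            assert f_hi.visible_edges <= f_lo.visible_edges


class TestExport:
    @pytest.mark.parametrize("fmt", ["json-lines", "graphml-stack"])
    def test_roundtrip(self, tmp_path, rng, fmt):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        sm = smoothed(rng.normal(scale=0.3, size=(3, 3)), genes=["A", "B", "C"])
        mask = activity_mask(sm)
        dest = tmp_path / ("frames.jsonl" if fmt == "json-lines" else "stack")
        export_frames(g, mask, dest, format=fmt)
        back = read_frames(dest, format=fmt)
        assert len(back) == 3
        for fr, t in zip(back, mask.times):
            orig = frame_at(g, mask, t)
            assert fr.time == orig.time
            assert fr.visible_nodes == orig.visible_nodes
            assert fr.visible_edges == orig.visible_edges
            for n, v in orig.node_values.items():
                assert fr.node_values[n] == pytest.approx(v)

    def test_empty_frame_still_recorded(self, tmp_path):
        g = nx.Graph([("A", "B")])
        sm = smoothed([[-5.0, 0.1], [-5.0, 0.1]], genes=["A", "B"])
        mask = activity_mask(sm)
        out = tmp_path / "f.jsonl"
        export_frames(g, mask, out)
        frames = read_frames(out)
        assert len(frames) == 2
        assert frames[0].visible_nodes == frozenset()
        assert frames[1].visible_nodes == frozenset({"A", "B"})
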