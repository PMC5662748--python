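"""Differential sub-network extraction, projections and stars."""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from pbdsn.differential import (
    differential_subnetwork_static,
    differential_subnetwork_timeseries,
    edge_behavior_differs,
    project_subnetwork,
    required_count,
    star_subnetwork,
)
from pbdsn.errors import ParameterError
from conftest import differential_oracle, make_network


class TestEdgeBehavior:
    def test_same_sign_same_behavior(self):
        other = make_network("B", {("a", "b"): 1})
        assert not edge_behavior_differs(("a", "b"), 1, other)

    def test_disappearance_differs(self):
        other = make_network("B", {("c", "d"): 1}, vertices={"a", "b"})
        assert edge_behavior_differs(("a", "b"), 1, other)

    def test_sign_flip_differs(self):
        other = make_network("B", {("a", "b"): -1})
        assert edge_behavior_differs(("a", "b"), 1, other)


class TestRequiredCount:
    @pytest.mark.parametrize(
        "fraction,n,expected",
        [
            (2 / 3, 3, 2),   # "two of the other three networks"
            (2 / 3, 4, 3),   # ceil(8/3)
            (2 / 3, 1, 1),
            (2 / 3, 2, 2),
            (1.0, 5, 5),
            (0.5, 4, 2),
        ],
    )
    def test_values(self, fraction, n, expected):
        assert required_count(fraction, n) == expected

    def test_domain(self):
        with pytest.raises(ParameterError):
            required_count(0.0, 3)
        with pytest.raises(ParameterError):
            required_count(1.5, 3)
        with pytest.raises(ParameterError):
            required_count(0.5, 0)


def _random_family(rng, n_labels, n_vertices=8, max_edges=12):
    """Random signed networks on a shared vertex universe."""
    verts = {f"v{i}" for i in range(n_vertices)}
    pairs = [
        (f"v{i}", f"v{j}") for i in range(n_vertices) for j in range(i + 1, n_vertices)
    ]
    nets = []
    for t in range(n_labels):
        n_edges = int(rng.integers(0, max_edges + 1))
        chosen = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
        edges = {pairs[c]: int(rng.choice([-1, 1])) for c in chosen}
        nets.append(make_network(f"L{t}", edges, vertices=verts))
    return nets


class TestStaticRule:
    def test_edge_same_everywhere_is_excluded(self):
        nets = [make_network(l, {("a", "b"): 1}) for l in "WXYZ"]
        dsn = differential_subnetwork_static(nets, "W", fraction=2 / 3)
        assert dsn.n_edges == 0
        assert dsn.vertex_set == frozenset()

    def test_flip_and_disappearance_count(self):
        target = make_network("T", {("a", "b"): 1, ("c", "d"): 1})
        o1 = make_network("O1", {("a", "b"): -1, ("c", "d"): 1})
        o2 = make_network("O2", {("c", "d"): 1}, vertices={"a", "b"})
        o3 = make_network("O3", {("a", "b"): 1, ("c", "d"): 1})
        dsn = differential_subnetwork_static([target, o1, o2, o3], "T", fraction=2 / 3)
        assert set(dsn.edges) == {("a", "b")}
        assert dsn.per_edge_difference_count[("a", "b")] == 2
        assert dsn.required_count == 2

    def test_identical_networks_give_empty_subnetwork(self):
        rng = np.random.default_rng(0)
        nets = _random_family(rng, 1)
        clones = [
            make_network(f"L{k}", {key: (e.sign, e.pcc) for key, e in nets[0].edges.items()},
                         vertices=nets[0].vertices)
            for k in range(4)
        ]
        assert differential_subnetwork_static(clones, "L0").n_edges == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_labels = int(rng.integers(3, 7))
        nets = _random_family(rng, n_labels)
        dsn = differential_subnetwork_static(nets, "L0", fraction=2 / 3)
        expected = differential_oracle(nets[0], nets[1:], Fraction(2, 3))
        assert set(dsn.edges) == expected
        for key in dsn.edges:
            assert dsn.edges[key] == nets[0].edges[key]

    def test_lowering_fraction_never_removes_edges(self):
        rng = np.random.default_rng(4)
        nets = _random_family(rng, 5)
        kept = [
            set(differential_subnetwork_static(nets, "L0", fraction=f).edges)
            for f in (1.0, 0.75, 0.5, 0.25)
        ]
        for strict, loose in zip(kept, kept[1:]):
            assert strict <= loose

    def test_errors(self):
        nets = _random_family(np.random.default_rng(1), 3)
        with pytest.raises(ParameterError):
            differential_subnetwork_static(nets, "nope")
        with pytest.raises(ParameterError):
            differential_subnetwork_static(nets, "L0", fraction=0.0)


class TestTimeSeriesRule:
    def test_only_earlier_networks_compared(self):
        # edge flips at the last time point: differs from both earlier nets
        nets = [
            make_network("S1", {("a", "b"): 1}),
            make_network("S2", {("a", "b"): 1}),
            make_network("S3", {("a", "b"): -1}),
        ]
        dsn = differential_subnetwork_timeseries(nets, 2, fraction=1 / 2)
        assert set(dsn.edges) == {("a", "b")}
        assert dsn.comparison_labels == ("S1", "S2")

    def test_required_count_at_fifth_time_point(self):
        rng = np.random.default_rng(8)
        nets = _random_family(rng, 5)
        dsn = differential_subnetwork_timeseries(nets, 4, fraction=2 / 3)
        assert dsn.required_count == 3  # ceil(2/3 * 4)

    def test_edge_absent_at_every_earlier_point_is_retained(self):
        nets = [
            make_network("S1", {}, vertices={"a", "b"}),
            make_network("S2", {}, vertices={"a", "b"}),
            make_network("S3", {("a", "b"): 1}),
        ]
        dsn = differential_subnetwork_timeseries(nets, 2, fraction=2 / 3)
        assert set(dsn.edges) == {("a", "b")}
        assert dsn.per_edge_difference_count[("a", "b")] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        nets = _random_family(rng, 6)
        t = int(rng.integers(1, 6))
        dsn = differential_subnetwork_timeseries(nets, t, fraction=2 / 3)
        expected = differential_oracle(nets[t], nets[:t], Fraction(2, 3))
        assert set(dsn.edges) == expected

    def test_first_time_point_rejected(self):
        nets = _random_family(np.random.default_rng(2), 3)
        with pytest.raises(ParameterError):
            differential_subnetwork_timeseries(nets, 0)


class TestProjection:
    def _dsn(self):
        target = make_network("T", {("a", "b"): 1, ("c", "d"): 1})
        others = [make_network(l, {}, vertices={"a", "b", "c", "d"}) for l in ("X", "Y")]
        return differential_subnetwork_static([target] + others, "T"), target

    def test_intersection_with_other_signs(self):
        dsn, _ = self._dsn()
        other = make_network("R", {("a", "b"): (-1, -0.8)}, vertices={"c", "d"})
        proj = project_subnetwork(dsn, other)
        assert proj.vertex_set == dsn.vertex_set
        assert set(proj.edges) == {("a", "b")}
        assert proj.edges[("a", "b")].sign == -1
        assert proj.edges[("a", "b")].pcc == pytest.approx(-0.8)

    def test_disjoint_other_gives_empty_projection(self):
        dsn, _ = self._dsn()
        other = make_network("R", {("a", "c"): 1}, vertices={"b", "d"})
        proj = project_subnetwork(dsn, other)
        assert proj.edges == {} and proj.vertex_set == dsn.vertex_set

    def test_projecting_into_target_recovers_dsn_edges(self):
        dsn, target = self._dsn()
        proj = project_subnetwork(dsn, target)
        assert proj.edges == dsn.edges

    def test_matches_naive_set_intersection(self):
        rng = np.random.default_rng(77)
        nets = _random_family(rng, 4)
        dsn = differential_subnetwork_static(nets, "L0")
        proj = project_subnetwork(dsn, nets[2])
        assert set(proj.edges) == set(dsn.edges) & set(nets[2].edges)


class TestStar:
    def test_isolated_center(self):
        net = make_network("G", {("a", "b"): 1}, vertices={"z"})
        star = star_subnetwork(net, "z")
        assert star.edges == {} and star.vertices == frozenset({"z"})

    def test_path_center(self):
        net = make_network("G", {("a", "b"): 1, ("b", "c"): -1})
        star = star_subnetwork(net, "b")
        assert set(star.edges) == {("a", "b"), ("b", "c")}
        assert star.vertices == frozenset({"a", "b", "c"})

    def test_star_size_equals_degree_for_every_vertex(self):
        rng = np.random.default_rng(13)
        net = _random_family(rng, 1, n_vertices=7, max_edges=12)[0]
        for v in sorted(net.vertices):
            assert star_subnetwork(net, v).n_edges == net.degree(v)

    def test_unknown_center(self):
        net = make_network("G", {("a", "b"): 1})
        with pytest.raises(ParameterError):
            star_subnetwork(net, "nope")

    def test_handshake_identity_on_dsn(self):
        rng = np.random.default_rng(21)
        nets = _random_family(rng, 4)
        dsn = differential_subnetwork_static(nets, "L0", fraction=0.5)
        total = sum(star_subnetwork(dsn, v).n_edges for v in dsn.vertex_set)
        assert total == 2 * dsn.n_edges
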