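"""Degree census, weighted mean degree and geodesic analysis."""

import networkx as nx
import numpy as np
import pytest

import solvgraph as sg
from solvgraph.errors import AnalysisError
from solvgraph.metrics import UNREACHABLE


def _chain_graphs(pattern, site="O9"):
    """Graphs where the site has the given degree sequence over frames."""
    sv = sg.SiteVertex(0, site, 1)
    out = []
    for t, deg in enumerate(pattern):
        partners = [sg.SiteVertex(1 + k, "H1", 10 + 3 * k) for k in range(deg)]
        edges = [sg.GraphEdge(sv, p, 0.2) for p in partners]
        out.append(sg.FrameGraph(t, [sv] + partners, edges))
    return out


class TestDegreeCensus:
    def test_constant_degree(self):
        census = sg.degree_census(_chain_graphs([1] * 10), ["O9"])
        assert census.counts["O9"] == {1: 10}
        assert sum(census.counts["O9"].values()) == 10

    def test_empty_sequence(self):
        census = sg.degree_census([], ["O9"])
        assert census.total_frames == 0
        assert census.counts["O9"] == {}

    def test_unknown_site_raises(self):
        with pytest.raises(AnalysisError, match="Oxx"):
            sg.degree_census(_chain_graphs([1]), ["Oxx"])

    def test_conservation_on_synthetic_run(self, small_graphs):
        """Sum_i N(i) equals the frame count for every site, always."""
        census = sg.degree_census(small_graphs, sg.SITE_LABELS)
        census.validate()
        for site in sg.SITE_LABELS:
            assert sum(census.counts[site].values()) == len(small_graphs)

    def test_mean_degree_tracks_stationary_occupancy(self):
        """With Markov exchange the long-run mean raw degree approaches the
        chain's stationary occupancy."""
        params = sg.SyntheticParams(n_waters=40, n_frames=4000, seed=9)
        truth = sg.simulate_occupancy(params)
        graphs = sg.graphs_from_states(truth)
        census = sg.degree_census(graphs, sg.SITE_LABELS)
        means = sg.weighted_mean_degree(census)
        target = truth.expected["stationary_occupancy"]
        grand = np.mean(list(means.values()))
        assert grand == pytest.approx(target, abs=0.05)


class TestWeightedMeanDegree:
    def test_halving_convention(self):
        census = sg.DegreeCensus({"O9": {2: 10}}, 10)
        assert sg.weighted_mean_degree(census, halve=True)["O9"] == 1.0

    def test_plain_arithmetic(self):
        census = sg.DegreeCensus({"O9": {0: 5, 2: 5}}, 10)
        assert sg.weighted_mean_degree(census)["O9"] == 1.0

    def test_empty_census_is_undefined(self):
        with pytest.raises(AnalysisError):
            sg.weighted_mean_degree(sg.DegreeCensus({"O9": {}}, 0))

    def test_equals_expanded_per_frame_mean(self):
        """The census-weighted mean equals a brute-force mean over the
        expanded per-frame degree list."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            pattern = rng.integers(0, 5, size=30).tolist()
            census = sg.degree_census(_chain_graphs(pattern), ["O9"])
            got = sg.weighted_mean_degree(census)["O9"]
            assert got == pytest.approx(np.mean(pattern))

    def test_halved_census_equals_molecule_level_degree(self):
        """When every bound water engages both hydrogens, halving the
        hydrogen-resolved mean reproduces the count of interacting water
        molecules."""
        params = sg.SyntheticParams(n_waters=30, n_frames=300, seed=5,
                                    both_hydrogens_inside=True)
        res = sg.generate_trajectory(params)
        graphs = [sg.build_frame_graph(fr, res.topology) for fr in res.frames]
        census = sg.degree_census(graphs, sg.SITE_LABELS)
        halved = sg.weighted_mean_degree(census, halve=True)
        for s, site in enumerate(sg.SITE_LABELS):
            molecule_mean = np.mean(res.truth.bound_water[s] >= 0)
            assert halved[site] == pytest.approx(molecule_mean)

    def test_degree_sum_is_twice_edge_count(self, small_graphs):
        """Tallied over all vertices, the degree histogram total equals twice
        the edge count (each edge contributes to two vertices)."""
        for g in small_graphs:
            assert sum(g.degrees().values()) == 2 * g.n_edges


class TestGeodesics:
    def _graph_from_nx(self, G):
        vs = {n: sg.SiteVertex(n, "s", n + 1) for n in G.nodes}
        edges = [sg.GraphEdge(*sorted((vs[a], vs[b])), 1.0) for a, b in G.edges]
        return sg.FrameGraph(0, [vs[n] for n in sorted(G.nodes)],
                             sorted(edges)), vs

    def test_path_graph(self):
        fg, vs = self._graph_from_nx(nx.path_graph(3))
        gm = sg.geodesic_matrix(fg)
        assert gm.distance(vs[0], vs[2]) == 2
        assert gm.path(vs[0], vs[2]) == [vs[0], vs[1], vs[2]]

    def test_disconnected_components_unreachable(self):
        G = nx.Graph([(0, 1), (2, 3)])
        fg, vs = self._graph_from_nx(G)
        gm = sg.geodesic_matrix(fg)
        assert gm.distance(vs[0], vs[2]) == UNREACHABLE
        assert gm.distance(vs[0], vs[1]) == 1

    def test_matches_bfs_on_random_graphs(self):
        """Floyd-Warshall equals per-vertex BFS on 100 random graphs."""
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(2, 51))
            p = rng.uniform(0.02, 0.3)
            G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
            fg, vs = self._graph_from_nx(G)
            gm = sg.geodesic_matrix(fg)
            lengths = dict(nx.all_pairs_shortest_path_length(G))
            for i in G.nodes:
                for j in G.nodes:
                    expect = lengths[i].get(j, UNREACHABLE)
                    assert gm.distance(vs[i], vs[j]) == expect

    def test_matrix_invariants(self):
        rng = np.random.default_rng(1)
        G = nx.gnp_random_graph(30, 0.1, seed=4)
        fg, _ = self._graph_from_nx(G)
        gm = sg.geodesic_matrix(fg)
        d = gm.dist
        assert (np.diag(d) == 0).all()
        assert (d == d.T).all()
        finite = d != UNREACHABLE
        # triangle inequality over finite triples
        for _ in range(200):
            i, j, k = rng.integers(0, 30, 3)
            if finite[i, k] and finite[k, j]:
                assert finite[i, j] and d[i, j] <= d[i, k] + d[k, j]

    def test_reconstructed_paths_are_valid_and_shortest(self):
        G = nx.gnp_random_graph(25, 0.12, seed=8)
        fg, vs = self._graph_from_nx(G)
        gm = sg.geodesic_matrix(fg)
        adj = fg.adjacency()
        for u, v, d in gm.finite_pairs():
            p = gm.path(u, v)
            assert p[0] == u and p[-1] == v and len(p) == d + 1
            assert all(b in adj[a] for a, b in zip(p, p[1:]))


class TestMoleculeProjection:
    def test_water_bridge_gives_geodesic_two(self, water_topology):
        """A single water bridging two sites yields a shortest hydrogen-bond
        pathway of two edges after collapsing the water to one vertex."""
        sol = sg.MoleculeTemplate("SOL", ["O", "O"], bonds=[],
                                  sites={"O9": 0, "O9p": 1})
        wat = sg.MoleculeTemplate("WAT", ["O", "H", "H"],
                                  bonds=[(0, 1), (0, 2)],
                                  sites={"O": 0, "H1": 1, "H2": 2})
        top = sg.SystemTopology({"SOL": sol, "WAT": wat},
                                [("SOL", 1), ("WAT", 1)], box_edge=3.0)
        coords = np.array([
            [1.20, 1.5, 1.5],   # O9
            [1.90, 1.5, 1.5],   # O9p
            [1.55, 1.55, 1.5],  # water O
            [1.40, 1.52, 1.5],  # H1, 0.2 nm from O9
            [1.70, 1.52, 1.5],  # H2, 0.2 nm from O9p
        ])
        fr = sg.Frame(["O", "O", "O", "H", "H"], coords, box_edge=3.0)
        g = sg.build_frame_graph(fr, top, include_water_water=True)
        # atom-level: no path through the water (its O and H are separate)
        gm_atom = sg.geodesic_matrix(g)
        assert gm_atom.distance(g.find_site("O9"), g.find_site("O9p")) == -1
        proj = sg.project_to_molecules(g)
        gm = sg.geodesic_matrix(proj)
        assert gm.distance(proj.find_site("O9"), proj.find_site("O9p")) == 2

    def test_projection_merges_parallel_edges(self):
        sv = sg.SiteVertex(0, "O9", 1)
        h1 = sg.SiteVertex(1, "H1", 11)
        h2 = sg.SiteVertex(1, "H2", 12)
        g = sg.FrameGraph(0, [sv, h1, h2],
                          [sg.GraphEdge(sv, h1, 0.25), sg.GraphEdge(sv, h2, 0.2)])
        proj = sg.project_to_molecules(g)
        assert proj.n_edges == 1
        assert proj.edges[0].distance == pytest.approx(0.2)


class TestGeodesicPersistence:
    def test_constant_connection_single_run(self):
        graphs = _chain_graphs([1] * 20)
        # make the partner vertex identical across frames
        sv, pv = sg.SiteVertex(0, "O9", 1), sg.SiteVertex(1, "H1", 10)
        graphs = [sg.FrameGraph(t, [sv, pv], [sg.GraphEdge(sv, pv, 0.2)])
                  for t in range(20)]
        series, runs = sg.geodesic_persistence(graphs, "O9", "H1",
                                               frame_interval=0.5)
        assert (series == 1).all()
        assert len(runs) == 1 and runs[0].duration == pytest.approx(10.0)

    def test_alternating_connection_unit_runs(self):
        sv, pv = sg.SiteVertex(0, "O9", 1), sg.SiteVertex(1, "H1", 10)
        graphs = [sg.FrameGraph(t, [sv, pv],
                                [sg.GraphEdge(sv, pv, 0.2)] if t % 2 == 0 else [])
                  for t in range(10)]
        series, runs = sg.geodesic_persistence(graphs, "O9", "H1",
                                               frame_interval=0.5)
        assert all(r.length == 1 for r in runs)
        assert len(runs) == 5

    def test_mean_run_matches_switching_process(self):
        """A Bernoulli on/off edge gives geometric run lengths."""
        rng = np.random.default_rng(6)
        sv, pv = sg.SiteVertex(0, "O9", 1), sg.SiteVertex(1, "H1", 10)
        stay = 0.8
        on = False
        graphs = []
        for t in range(20000):
            on = (rng.random() < stay) if on else (rng.random() < 0.5)
            graphs.append(sg.FrameGraph(
                t, [sv, pv], [sg.GraphEdge(sv, pv, 0.2)] if on else []))
        _, runs = sg.geodesic_persistence(graphs, "O9", "H1", 0.5)
        mean_len = np.mean([r.length for r in runs])
        assert mean_len == pytest.approx(1.0 / (1 - stay), rel=0.05)
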