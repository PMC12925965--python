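"""Cubical cover, preimage clustering, nerve construction, contraction."""

import itertools

import numpy as np
import pytest

from topomet.lens import CompositeLens
from topomet.mapper import (
    build_cover,
    build_nerve,
    cluster_preimage,
    contract_graph,
    run_mapper,
)
from topomet.pipeline import preprocess
from topomet.synthdata import make_fixture


def _composite(coords, ids=None):
    coords = np.asarray(coords, float)
    ids = ids or [f"s{i:02d}" for i in range(coords.shape[0])]
    origin = [("B", 0), ("B", 1)][: coords.shape[1]]
    if coords.shape[1] > 2:
        origin = [("B%d" % (j // 2), j % 2) for j in range(coords.shape[1])]
    return CompositeLens(coords=coords, sample_ids=ids, column_origin=origin)


class TestCover:
    def test_uniform_interval_formula(self):
        comp = _composite([[0.0], [1.0], [0.3]], ["a", "b", "c"])
        comp.column_origin = [("B", 0)]
        cover = build_cover(comp, n_intervals=3, overlap_frac=0.3)
        intervals = cover.per_axis[0].intervals
        expected = [(0.0, 0.41667), (0.29167, 0.70833), (0.58333, 1.0)]
        for (lo, hi), (elo, ehi) in zip(intervals, expected):
            assert lo == pytest.approx(elo, abs=1e-5)
            assert hi == pytest.approx(ehi, abs=1e-5)
        # a point at 0.3 lies in the first two intervals
        assert cover.per_axis[0].containing(0.3) == [0, 1]
        assert cover.membership["c"] == {(0,), (1,)}

    def test_single_interval_identity_cover(self):
        comp = _composite([[0.1, 5.0], [0.9, -2.0], [0.5, 0.0], [0.2, 1.0]])
        cover = build_cover(comp, n_intervals=1, overlap_frac=0.3)
        assert all(m == {(0, 0)} for m in cover.membership.values())

    def test_degenerate_axis_single_interval(self):
        comp = _composite([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]], ["a", "b", "c"])
        cover = build_cover(comp, 3, 0.3)
        assert cover.per_axis[0].intervals == [(0.0, 0.0)]
        assert all(len(m) >= 1 for m in cover.membership.values())

    def test_invalid_params_rejected(self):
        comp = _composite([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            build_cover(comp, 0, 0.3)
        with pytest.raises(ValueError):
            build_cover(comp, 3, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_membership_matches_exhaustive_containment(self, seed):
        rng = np.random.default_rng(seed)
        n, d = rng.integers(5, 30), rng.integers(1, 4)
        comp = _composite(rng.normal(size=(int(n), int(d) * 2)))
        K, p = int(rng.integers(1, 5)), float(rng.uniform(0, 0.6))
        cover = build_cover(comp, K, p)
        for i, s in enumerate(comp.sample_ids):
            per_axis = [
                [
                    k
                    for k, (lo, hi) in enumerate(ax.intervals)
                    if lo <= comp.coords[i, j] <= hi
                ]
                for j, ax in enumerate(cover.per_axis)
            ]
            assert cover.membership[s] == set(itertools.product(*per_axis))

    def test_overlap_monotonicity(self):
        rng = np.random.default_rng(11)
        comp = _composite(rng.normal(size=(25, 4)))
        counts = [
            build_cover(comp, 3, p).n_memberships for p in (0.0, 0.1, 0.3, 0.5, 0.7)
        ]
        assert counts == sorted(counts)


class TestClusterPreimage:
    def test_singleton_subset(self):
        assert cluster_preimage(["s1"], np.zeros((1, 1))) == [["s1"]]

    def test_two_tight_pairs_split_at_gap(self):
        # pairs (a,b) and (c,d): internal distance 0.01, 100x separation
        D = np.array(
            [
                [0.0, 0.01, 1.0, 1.0],
                [0.01, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.01],
                [1.0, 1.0, 0.01, 0.0],
            ]
        )
        out = cluster_preimage(["a", "b", "c", "d"], D)
        assert out == [["a", "b"], ["c", "d"]]

    def test_equidistant_triple_stays_together(self):
        D = np.ones((3, 3)) - np.eye(3)
        assert cluster_preimage(["a", "b", "c"], D) == [["a", "b", "c"]]

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_preimage(["a", "b"], D)

    def test_singleton_method_isolates_everything(self):
        D = np.zeros((3, 3))
        assert cluster_preimage(["c", "a", "b"], D, method="singleton") == [
            ["a"],
            ["b"],
            ["c"],
        ]


class TestNerve:
    def test_shared_sample_edge(self):
        g = build_nerve({(0,): [["s1", "s2"]], (1,): [["s2", "s3"]]})
        assert g.n_nodes == 2
        edges = list(g.graph.edges(data=True))
        assert len(edges) == 1 and edges[0][2]["shared_count"] == 1

    def test_disjoint_nodes_two_components(self):
        g = build_nerve({(0,): [["s1"]], (1,): [["s2"]]})
        assert g.graph.number_of_edges() == 0
        assert len(g.components) == 2

    def test_empty_input_empty_graph(self):
        g = build_nerve({})
        assert g.n_nodes == 0 and g.components == {}

    def test_component_labels_by_size_then_sample(self):
        g = build_nerve(
            {
                (0,): [["s5"]],  # lone node -> smaller component
                (1,): [["s1", "s2"]],
                (2,): [["s2", "s3"]],
            }
        )
        comp_sizes = {lab: len(nodes) for lab, nodes in g.components.items()}
        assert comp_sizes == {"A": 2, "B": 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_edges_match_bruteforce_intersection(self, seed):
        rng = np.random.default_rng(100 + seed)
        samples = [f"s{i}" for i in range(rng.integers(5, 20))]
        clusters = {}
        for c in range(rng.integers(2, 12)):
            size = rng.integers(1, max(2, len(samples) // 2))
            clusters[(c,)] = [
                sorted(rng.choice(samples, size=size, replace=False).tolist())
            ]
        g = build_nerve(clusters)
        sets = {n: set(g.samples_of(n)) for n in g.node_ids}
        expected = {
            (u, v): len(sets[u] & sets[v])
            for u, v in itertools.combinations(g.node_ids, 2)
            if sets[u] & sets[v]
        }
        got = {
            tuple(sorted((u, v))): d["shared_count"]
            for u, v, d in g.graph.edges(data=True)
        }
        assert got == expected


class TestContraction:
    def test_subset_and_duplicate_nodes_removed(self):
        g = build_nerve(
            {
                (0,): [["s1", "s2", "s3"]],
                (1,): [["s2", "s3"]],  # strict subset
                (2,): [["s1", "s2", "s3"]],  # duplicate
                (3,): [["s4"]],
            }
        )
        gc = contract_graph(g)
        kept = sorted(tuple(gc.samples_of(n)) for n in gc.node_ids)
        assert kept == [("s1", "s2", "s3"), ("s4",)]
        assert gc.all_samples == g.all_samples


class TestRunMapper:
    def test_every_sample_covered_and_deterministic_labels(self):
        ds = preprocess(*_fixture_parts("two_cluster"))
        g1 = run_mapper(ds, embed_method="mds", random_state=0)
        g2 = run_mapper(ds, embed_method="mds", random_state=0)
        assert g1.all_samples == set(ds.sample_ids)
        assert g1.component_of == g2.component_of

    def test_degenerate_four_sample_input_runs(self):
        # one sample per condition: neighborhood size must clamp to n - 1
        import pandas as pd

        from topomet.datamodel import OmicsBlock, SampleTable

        rng = np.random.default_rng(0)
        ids = ["s1", "s2", "s3", "s4"]
        samples = SampleTable(
            pd.DataFrame(
                {
                    "treatment": ["untreated", "DMSO", "DOXO_1uM", "DOXO_5uM"],
                    "timepoint": ["0h", "24h", "24h", "48h"],
                    "foc": [100.0, 110.0, 70.0, 40.0],
                    "dsdna_total": [100.0] * 4,
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )
        block = OmicsBlock(
            "B1",
            pd.DataFrame(
                rng.lognormal(10, 1, (4, 5)),
                index=ids,
                columns=[f"m{j}" for j in range(5)],
            ),
            "raw",
        )
        ds = preprocess([block], samples)
        g = run_mapper(ds, random_state=0)  # UMAP with clamped neighborhood
        assert g.n_nodes >= 1
        assert g.all_samples == set(ids)


def _fixture_parts(name):
    ds = make_fixture(name)
    return ds.blocks, ds.samples
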