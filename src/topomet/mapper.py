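"""Mapper: cubical cover, preimage clustering, and the TCN nerve graph.

The composite filtered space is covered by axis-aligned hypercubes: each
axis gets K equal-length intervals with fractional overlap p (K = 3,
p = 0.30 by default), so for an axis of data range R the interval length is
L = R / (K - p (K - 1)) and interval i starts at min + i L (1 - p).
Interval containment is closed on both ends, so boundary points belong to
every covering interval.

Samples falling into one hypercube are clustered (single linkage cut at the
largest gap of the merge-distance sequence, on the correlation distance of
the concatenated Z-score matrix) and each cluster becomes a node of the
topological connectivity network (TCN). Two nodes are joined by an edge iff
they share at least one sample; connected components are labeled ``A``,
``B``, ... in decreasing node-count order.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .datamodel import AnnotatedDataset
from .lens import (
    CompositeLens,
    LensEmbedding,
    concatenate_lenses,
    embed_block,
    pairwise_distances,
    rescale_unit,
)

__all__ = [
    "IntervalCover1D",
    "HypercubeCover",
    "TCNGraph",
    "build_cover",
    "cluster_preimage",
    "build_nerve",
    "contract_graph",
    "MapperTCN",
    "run_mapper",
]

logger = logging.getLogger(__name__)


@dataclass
class IntervalCover1D:
    """K equal-length overlapping closed intervals covering one lens axis."""

    n_intervals: int
    overlap_frac: float
    intervals: list[tuple[float, float]]

    def containing(self, v: float) -> list[int]:
        return [i for i, (lo, hi) in enumerate(self.intervals) if lo <= v <= hi]


def _cover_axis(values: np.ndarray, K: int, p: float) -> IntervalCover1D:
    lo, hi = float(values.min()), float(values.max())
    R = hi - lo
    if R == 0.0:
        logger.warning("degenerate lens axis (zero range); using a single interval")
        return IntervalCover1D(1, p, [(lo, hi)])
    L = R / (K - p * (K - 1))
    step = L * (1.0 - p)
    intervals = [(lo + i * step, lo + i * step + L) for i in range(K)]
    # the last interval's upper end is exactly the data max in exact
    # arithmetic; clamp so rounding never lets the extreme sample escape
    last_lo, last_hi = intervals[-1]
    intervals[-1] = (last_lo, max(last_hi, hi))
    return IntervalCover1D(K, p, intervals)


@dataclass
class HypercubeCover:
    """Cubical cover of the composite lens, with sample membership.

    ``membership`` maps each sample id to the set of hypercube index tuples
    (one per-axis interval index per axis) whose closed product contains the
    sample's lens point. Every sample belongs to at least one hypercube.
    """

    per_axis: list[IntervalCover1D]
    membership: dict[str, set[tuple[int, ...]]]

    @property
    def samples_by_hypercube(self) -> dict[tuple[int, ...], list[str]]:
        out: dict[tuple[int, ...], list[str]] = {}
        for s, cubes in self.membership.items():
            for c in cubes:
                out.setdefault(c, []).append(s)
        return {c: out[c] for c in sorted(out)}

    @property
    def n_memberships(self) -> int:
        return sum(len(c) for c in self.membership.values())


def build_cover(
    composite: CompositeLens, n_intervals: int = 3, overlap_frac: float = 0.30
) -> HypercubeCover:
    """Build the uniform cubical cover of a composite lens."""
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    axes = [
        _cover_axis(composite.coords[:, j], n_intervals, overlap_frac)
        for j in range(composite.coords.shape[1])
    ]
    membership: dict[str, set[tuple[int, ...]]] = {}
    for i, s in enumerate(composite.sample_ids):
        per_axis_hits = [ax.containing(composite.coords[i, j]) for j, ax in enumerate(axes)]
        membership[s] = set(itertools.product(*per_axis_hits))
        if not membership[s]:  # cannot happen for a true cover; defensive
            raise AssertionError(f"sample {s!r} escaped the cover")
    return HypercubeCover(per_axis=axes, membership=membership)


def cluster_preimage(
    sample_subset: Sequence[str],
    distances: np.ndarray,
    method: str = "single_gap",
    gap_frac: float = 0.5,
    tol: float = 1e-12,
) -> list[list[str]]:
    """Partition one hypercube's samples into clusters.

    Default ``single_gap``: single-linkage agglomeration whose sorted merge
    distances are cut at the largest gap, provided that gap exceeds both
    ``tol`` and ``gap_frac`` times the merge-distance spread; otherwise one
    cluster. ``singleton`` puts each sample in its own cluster (useful for
    the exactness limit of node enrichment).

    ``distances`` is the pairwise matrix over ``sample_subset`` (symmetric,
    zero diagonal).
    """
    subset = list(sample_subset)
    if not subset:
        raise ValueError("sample subset must be nonempty")
    if method == "singleton":
        return [[s] for s in sorted(subset)]
    if method != "single_gap":
        raise ValueError(f"unknown clustering method {method!r}")
    n = len(subset)
    if n == 1:
        return [subset]
    D = np.asarray(distances, dtype=float)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape must match the subset")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    Z = linkage(squareform(D, checks=False), method="single")
    heights = Z[:, 2]
    labels = None
    if heights.size >= 2:
        gaps = np.diff(heights)
        i = int(np.argmax(gaps))  # first largest gap
        spread = heights[-1] - heights[0]
        if gaps[i] > max(tol, gap_frac * spread):
            cut = 0.5 * (heights[i] + heights[i + 1])
            labels = fcluster(Z, cut, criterion="distance")
    if labels is None:
        return [sorted(subset)]
    clusters: dict[int, list[str]] = {}
    for s, lab in zip(subset, labels):
        clusters.setdefault(int(lab), []).append(s)
    return sorted((sorted(c) for c in clusters.values()), key=lambda c: c[0])


@dataclass
class TCNGraph:
    """Topological connectivity network.

    Wraps a :class:`networkx.Graph` whose nodes carry ``samples`` (sorted
    tuple of sample ids) and ``hypercube`` (index tuple of origin) and whose
    edges carry ``shared_count``. ``component_of`` labels each node with its
    connected component (``A`` = most nodes, ties by lexicographically
    smallest sample id).
    """

    graph: nx.Graph
    component_of: dict[int, str]
    meta: dict = field(default_factory=dict)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def samples_of(self, node_id: int) -> tuple[str, ...]:
        return self.graph.nodes[node_id]["samples"]

    @property
    def all_samples(self) -> set[str]:
        return {s for n in self.graph.nodes for s in self.graph.nodes[n]["samples"]}

    @property
    def components(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for n, lab in sorted(self.component_of.items()):
            out.setdefault(lab, []).append(n)
        return dict(sorted(out.items()))

    def to_node_link(self) -> dict:
        return {
            "meta": self.meta,
            "nodes": [
                {
                    "id": n,
                    "samples": list(self.graph.nodes[n]["samples"]),
                    "hypercube": list(self.graph.nodes[n]["hypercube"]),
                    "component": self.component_of[n],
                    **{
                        k: v
                        for k, v in self.graph.nodes[n].items()
                        if k not in ("samples", "hypercube")
                    },
                }
                for n in self.node_ids
            ],
            "edges": [
                {"source": u, "target": v, "shared_count": d["shared_count"]}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_node_link(), indent=2, default=str))

    def write_graphml(self, path: str | Path) -> None:
        G = nx.Graph()
        for n in self.node_ids:
            d = self.graph.nodes[n]
            attrs = {
                "samples": ";".join(d["samples"]),
                "hypercube": ";".join(map(str, d["hypercube"])),
                "component": self.component_of[n],
                "size": len(d["samples"]),
            }
            for k, v in d.items():
                if k not in ("samples", "hypercube") and np.isscalar(v):
                    attrs[k] = float(v) if isinstance(v, (int, float, np.floating)) else v
            G.add_node(n, **attrs)
        for u, v, d in self.graph.edges(data=True):
            G.add_edge(u, v, shared_count=int(d["shared_count"]))
        nx.write_graphml(G, path)


def _label_components(G: nx.Graph) -> dict[int, str]:
    comps = list(nx.connected_components(G))
    def key(c):
        smallest = min(min(G.nodes[n]["samples"]) for n in c) if c else ""
        return (-len(c), smallest)
    comps.sort(key=key)
    labels: dict[int, str] = {}
    for i, comp in enumerate(comps):
        # A, B, ..., Z, AA, AB, ... for large graphs
        lab = ""
        k = i
        while True:
            lab = chr(ord("A") + k % 26) + lab
            k = k // 26 - 1
            if k < 0:
                break
        for n in comp:
            labels[n] = lab
    return labels


def build_nerve(
    clusters_by_hypercube: Mapping[tuple[int, ...], Sequence[Sequence[str]]],
    meta: dict | None = None,
) -> TCNGraph:
    """Convert per-hypercube sample clusters into the nerve graph.

    One node per (hypercube, cluster); an edge joins two nodes iff their
    sample sets intersect, weighted by the intersection size.
    """
    G = nx.Graph()
    node_sets: list[tuple[int, frozenset[str]]] = []
    nid = 0
    for cube in sorted(clusters_by_hypercube):
        for cluster in clusters_by_hypercube[cube]:
            if not cluster:
                raise ValueError("clusters must be nonempty")
            samples = tuple(sorted(cluster))
            G.add_node(nid, samples=samples, hypercube=tuple(cube))
            node_sets.append((nid, frozenset(samples)))
            nid += 1
    for (u, su), (v, sv) in itertools.combinations(node_sets, 2):
        shared = len(su & sv)
        if shared:
            G.add_edge(u, v, shared_count=shared)
    return TCNGraph(graph=G, component_of=_label_components(G), meta=dict(meta or {}))


def contract_graph(tcn: TCNGraph) -> TCNGraph:
    """Remove nodes whose sample set is contained in another node's.

    Overlapping cover cells produce many nodes with identical or nested
    sample sets; keeping only maximal, distinct sets (reference-Mapper node
    contraction) leaves the covered sample set unchanged while making the
    node count an honest basis for node-level inference. Among identical
    sets the node from the lexicographically smallest hypercube is kept.
    """
    ids = tcn.node_ids
    sets = {n: frozenset(tcn.graph.nodes[n]["samples"]) for n in ids}
    keep: list[int] = []
    seen: set[frozenset[str]] = set()
    for n in ids:
        s = sets[n]
        if s in seen or any(s < sets[m] for m in ids if m != n):
            continue
        seen.add(s)
        keep.append(n)
    G = nx.Graph()
    for new_id, n in enumerate(keep):
        d = tcn.graph.nodes[n]
        G.add_node(new_id, samples=d["samples"], hypercube=d["hypercube"])
    for (u, su), (v, sv) in itertools.combinations(
        [(i, sets[n]) for i, n in enumerate(keep)], 2
    ):
        shared = len(su & sv)
        if shared:
            G.add_edge(u, v, shared_count=shared)
    meta = dict(tcn.meta)
    meta["contracted"] = True
    return TCNGraph(graph=G, component_of=_label_components(G), meta=meta)


class MapperTCN(BaseEstimator):
    """Mapper estimator: dataset in, topological connectivity network out.

    Composes per-block lens embedding, lens concatenation and unit
    rescaling, the cubical cover, preimage clustering on the correlation
    distance of the concatenated Z-score matrix, and nerve construction.

    Parameters mirror the pipeline stages; fitted attributes are
    ``lenses_``, ``composite_``, ``cover_``, ``distances_`` and ``graph_``.
    """

    def __init__(
        self,
        n_intervals: int = 3,
        overlap_frac: float = 0.30,
        embed_method: str = "umap",
        metric: str = "correlation",
        n_neighbors: int | None = None,
        min_dist: float = 0.1,
        cluster_method: str = "single_gap",
        gap_frac: float = 0.5,
        contract: bool = True,
        random_state: int = 0,
    ):
        self.n_intervals = n_intervals
        self.overlap_frac = overlap_frac
        self.embed_method = embed_method
        self.metric = metric
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.cluster_method = cluster_method
        self.gap_frac = gap_frac
        self.contract = contract
        self.random_state = random_state

    def fit(self, dataset: AnnotatedDataset, y=None):
        if dataset.stage != "zscored":
            raise ValueError("MapperTCN requires a fully Z-scored dataset")
        self.lenses_ = [
            embed_block(
                b,
                metric=self.metric,
                seed=self.random_state,
                method=self.embed_method,
                n_neighbors=self.n_neighbors,
                min_dist=self.min_dist,
            )
            for b in dataset.blocks
        ]
        self.composite_ = rescale_unit(concatenate_lenses(self.lenses_))
        self.cover_ = build_cover(self.composite_, self.n_intervals, self.overlap_frac)
        Z = dataset.concat_values()
        ids = list(Z.index)
        self.distances_ = pairwise_distances(Z.to_numpy(), self.metric, ids)
        pos = {s: i for i, s in enumerate(ids)}
        clusters: dict[tuple[int, ...], list[list[str]]] = {}
        for cube, members in self.cover_.samples_by_hypercube.items():
            idx = [pos[s] for s in members]
            D_sub = self.distances_[np.ix_(idx, idx)]
            clusters[cube] = cluster_preimage(
                members, D_sub, method=self.cluster_method, gap_frac=self.gap_frac
            )
        meta = {"config": self.get_params(), "seed": self.random_state}
        self.nerve_ = build_nerve(clusters, meta=meta)
        self.graph_ = contract_graph(self.nerve_) if self.contract else self.nerve_
        return self

    def fit_transform(self, dataset: AnnotatedDataset, y=None) -> TCNGraph:
        return self.fit(dataset).graph_


def run_mapper(dataset: AnnotatedDataset, config: dict | None = None, **kw) -> TCNGraph:
    """One-call Mapper run; ``config``/keyword args are MapperTCN parameters."""
    params = dict(config or {})
    params.update(kw)
    return MapperTCN(**params).fit_transform(dataset)
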