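"""End-to-end orchestration: preprocess -> lens -> Mapper -> TNE -> screen.

``run_all`` executes the whole workflow from block CSVs (or the synthetic
generator), writes every intermediate and final product under an output
directory, and records a JSON manifest (config, seed, package version) from
which the run is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .datamodel import (
    AnnotatedDataset,
    OmicsBlock,
    SampleTable,
    assemble_dataset,
    normalize_by_dsdna,
    read_block,
    read_samples,
    write_block,
    zscore_block,
)
from .lens import write_lenses_csv
from .mapper import MapperTCN, TCNGraph
from .screen import (
    build_chords,
    chords_to_frame,
    detect_sas,
    hierarchical_cluster,
    sas_to_frame,
    three_step_filter,
)
from .synthdata import DesignSpec, EffectSpec, generate_dataset
from .tne import benchmark_against_ground_truth, build_node_matrix, spearman_nodes

__all__ = ["RunConfig", "RunReport", "preprocess", "run_all", "export_html"]

logger = logging.getLogger(__name__)


def preprocess(blocks: Sequence[OmicsBlock], samples: SampleTable) -> AnnotatedDataset:
    """dsDNA-normalize, Z-score and assemble raw blocks into a dataset."""
    processed = [zscore_block(normalize_by_dsdna(b, samples)) for b in blocks]
    return assemble_dataset(processed, samples)


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    block_paths: tuple[str, ...] = ()
    block_ids: tuple[str, ...] = ()
    meta_path: str | None = None
    synthetic: bool = False
    n_intervals: int = 3
    overlap_frac: float = 0.30
    embed_method: str = "umap"
    metric: str = "correlation"
    n_neighbors: int | None = None
    min_dist: float = 0.1
    cluster_method: str = "single_gap"
    gap_frac: float = 0.5
    contract: bool = True
    p_thresh: float = 0.05
    rho_thresh: float = 0.60
    chord_thresh: float = 0.60
    filter_mode: str = "joint"
    seed: int = 0
    outdir: str = "topomet_out"

    def __post_init__(self) -> None:
        if not (0 < self.p_thresh < 1):
            raise ValueError("p_thresh must be in (0, 1)")
        for t in (self.rho_thresh, self.chord_thresh):
            if not (0 <= t < 1):
                raise ValueError("correlation thresholds must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        for key in ("block_paths", "block_ids"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class RunReport:
    outdir: str
    n_samples: int
    n_metabolites: int
    n_nodes: int
    n_components: int
    n_retained: int
    n_sas: int
    agreement: dict[str, float]
    manifest_path: str


def _load_inputs(config: RunConfig):
    if config.synthetic:
        dataset_raw, truth = generate_dataset(DesignSpec(seed=config.seed), EffectSpec())
        return list(dataset_raw.blocks), dataset_raw.samples, truth
    if not config.block_paths or config.meta_path is None:
        raise ValueError("provide block and metadata paths, or synthetic=True")
    ids = config.block_ids or tuple(Path(p).stem for p in config.block_paths)
    blocks = [read_block(p, bid) for p, bid in zip(config.block_paths, ids)]
    samples = read_samples(config.meta_path)
    return blocks, samples, None


def run_all(config: RunConfig) -> RunReport:
    """Execute the full workflow and write all products under ``config.outdir``."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    def log(stage: str, msg: str) -> None:
        logger.info("[%s] seed=%d %s", stage, config.seed, msg)

    blocks, samples, truth = _load_inputs(config)
    log("datamodel", f"{len(blocks)} blocks, {len(samples.sample_ids)} samples")
    dataset = preprocess(blocks, samples)
    for b in dataset.blocks:
        write_block(b, out / f"{b.block_id}_zscored.csv")
    samples.write_csv(out / "samples.csv")
    if truth is not None:
        truth.write_json(out / "ground_truth.json")

    mapper = MapperTCN(
        n_intervals=config.n_intervals,
        overlap_frac=config.overlap_frac,
        embed_method=config.embed_method,
        metric=config.metric,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        cluster_method=config.cluster_method,
        gap_frac=config.gap_frac,
        contract=config.contract,
        random_state=config.seed,
    )
    graph = mapper.fit_transform(dataset)
    log("mapper", f"{graph.n_nodes} nodes, {len(graph.components)} components")
    write_lenses_csv(mapper.lenses_, out / "lenses.csv")

    node_matrix = build_node_matrix(graph, dataset)
    table = spearman_nodes(node_matrix)
    node_matrix.values.to_csv(out / "node_matrix.csv", index_label="node_id")
    table.rho.to_csv(out / "correlation_rho.csv", index_label="metabolite")
    table.pval.to_csv(out / "correlation_pval.csv", index_label="metabolite")

    # graph exports carry all enrichment values per node
    for n in graph.node_ids:
        for var in node_matrix.values.columns:
            graph.graph.nodes[n][str(var)] = float(node_matrix.values.loc[n, var])
    graph.write_graphml(out / "tcn.graphml")
    graph.write_json(out / "tcn.json")
    export_html(graph, node_matrix.values, out / "tcn.html")

    bench = benchmark_against_ground_truth(graph, dataset)
    bench.write_csv(out / "benchmark_scatter.csv")
    (out / "benchmark_agreement.json").write_text(json.dumps(bench.agreement, indent=2))
    log("tne", f"agreement per block: {bench.agreement}")

    filtered = three_step_filter(
        table,
        p_thresh=config.p_thresh,
        rho_thresh=config.rho_thresh,
        mode=config.filter_mode,
    )
    filtered.values.to_csv(out / "filtered_rho.csv", index_label="metabolite")
    filtered.audit.to_csv(out / "filter_audit.csv", index=False)
    clustergram = hierarchical_cluster(filtered)
    (out / "clustergram.json").write_text(json.dumps(clustergram.to_json_dict()))

    conditions = dataset.samples.conditions
    chord_frames, sas_frames = [], []
    for cond in conditions:
        chords = build_chords(table, ["foc", cond], chord_thresh=config.chord_thresh)
        df = chords_to_frame(chords)
        df.insert(0, "diagram", cond)
        chord_frames.append(df)
        sas_frames.append(sas_to_frame(detect_sas(table, cond, config.chord_thresh)))
    pd.concat(chord_frames, ignore_index=True).to_csv(out / "chords.csv", index=False)
    sas_all = pd.concat(sas_frames, ignore_index=True)
    sas_all.to_csv(out / "sas.csv", index=False)
    n_sas = int(sas_all["sas"].sum())
    log("screen", f"{len(filtered.retained)} retained, {n_sas} SAS records")

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "topomet_version": __version__,
        "n_samples": len(dataset.sample_ids),
        "n_metabolites": len(dataset.metabolite_ids),
        "n_nodes": graph.n_nodes,
        "components": {k: len(v) for k, v in graph.components.items()},
        "runtime_s": round(time.time() - t0, 3),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    return RunReport(
        outdir=str(out),
        n_samples=len(dataset.sample_ids),
        n_metabolites=len(dataset.metabolite_ids),
        n_nodes=graph.n_nodes,
        n_components=len(graph.components),
        n_retained=len(filtered.retained),
        n_sas=n_sas,
        agreement=bench.agreement,
        manifest_path=str(manifest_path),
    )


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Topological connectivity network</title>
<style>
 body {{ font-family: sans-serif; margin: 1em; }}
 circle {{ stroke: #333; stroke-width: 0.5; }}
 line {{ stroke: #999; }}
 text.lbl {{ font-size: 9px; fill: #222; }}
</style></head>
<body>
<h3>Topological connectivity network</h3>
<label>Color nodes by:
 <select id="var" onchange="recolor()"></select></label>
<span id="range"></span>
<svg id="net" width="900" height="650"></svg>
<script>
const data = {payload};
const svg = document.getElementById("net");
const sel = document.getElementById("var");
for (const v of data.variables) {{
  const o = document.createElement("option"); o.value = v; o.textContent = v;
  sel.appendChild(o);
}}
const xs = data.nodes.map(n => n.x), ys = data.nodes.map(n => n.y);
const sx = v => 40 + 820 * (v - Math.min(...xs)) / (Math.max(...xs) - Math.min(...xs) + 1e-12);
const sy = v => 30 + 580 * (v - Math.min(...ys)) / (Math.max(...ys) - Math.min(...ys) + 1e-12);
for (const e of data.edges) {{
  const a = data.nodes[e.source], b = data.nodes[e.target];
  const l = document.createElementNS("http://www.w3.org/2000/svg", "line");
  l.setAttribute("x1", sx(a.x)); l.setAttribute("y1", sy(a.y));
  l.setAttribute("x2", sx(b.x)); l.setAttribute("y2", sy(b.y));
  l.setAttribute("stroke-width", Math.sqrt(e.shared_count));
  svg.appendChild(l);
}}
const circles = [];
for (const n of data.nodes) {{
  const c = document.createElementNS("http://www.w3.org/2000/svg", "circle");
  c.setAttribute("cx", sx(n.x)); c.setAttribute("cy", sy(n.y));
  c.setAttribute("r", 4 + 2 * Math.sqrt(n.samples.length));
  const t = document.createElementNS("http://www.w3.org/2000/svg", "title");
  c.appendChild(t); circles.push([c, t]); svg.appendChild(c);
}}
function color(t) {{  // blue (low) -> white -> red (high)
  const r = Math.round(255 * Math.min(1, 2 * t));
  const b = Math.round(255 * Math.min(1, 2 * (1 - t)));
  const g = Math.round(255 * (1 - Math.abs(2 * t - 1)));
  return `rgb(${{r}},${{g}},${{b}})`;
}}
function recolor() {{
  const v = sel.value, vals = data.nodes.map(n => n.values[v]);
  const lo = Math.min(...vals), hi = Math.max(...vals);
  document.getElementById("range").textContent =
    ` range: ${{lo.toFixed(3)}} .. ${{hi.toFixed(3)}}`;
  data.nodes.forEach((n, i) => {{
    const t = hi > lo ? (n.values[v] - lo) / (hi - lo) : 0.5;
    circles[i][0].setAttribute("fill", color(t));
    circles[i][1].textContent =
      `node ${{n.id}} (${{n.component}}) ${{v}}=${{n.values[v].toFixed(3)}}\\n` +
      n.samples.join(", ");
  }});
}}
recolor();
</script></body></html>
"""


def export_html(graph: TCNGraph, node_values: pd.DataFrame, path: str | Path) -> None:
    """Write a self-contained interactive TCN (dropdown recolors nodes).

    Node positions come from a seeded force-directed layout computed here;
    no external JavaScript libraries are required.
    """
    import networkx as nx

    pos = nx.spring_layout(graph.graph, seed=0)
    ids = graph.node_ids
    index = {n: i for i, n in enumerate(ids)}
    payload = {
        "variables": [str(c) for c in node_values.columns],
        "nodes": [
            {
                "id": n,
                "x": float(pos[n][0]),
                "y": float(pos[n][1]),
                "component": graph.component_of[n],
                "samples": list(graph.samples_of(n)),
                "values": {
                    str(c): float(node_values.loc[n, c]) for c in node_values.columns
                },
            }
            for n in ids
        ],
        "edges": [
            {
                "source": index[u],
                "target": index[v],
                "shared_count": int(d["shared_count"]),
            }
            for u, v, d in graph.graph.edges(data=True)
        ],
    }
    Path(path).write_text(_HTML_TEMPLATE.format(payload=json.dumps(payload)))
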