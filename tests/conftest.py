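"""Shared fixtures: micro datasets and the multi-seed study-design runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from topomet import (
    DesignSpec,
    EffectSpec,
    OmicsBlock,
    SampleTable,
    assemble_dataset,
    benchmark_against_ground_truth,
    build_node_matrix,
    generate_dataset,
    make_fixture,
    run_mapper,
    spearman_nodes,
)
from topomet.pipeline import preprocess
from topomet.screen import detect_sas
from topomet.tne import CorrelationTable


@pytest.fixture(scope="session")
def study_dataset():
    """One preprocessed default study-design dataset with ground truth."""
    raw, truth = generate_dataset(DesignSpec(seed=1), EffectSpec())
    return preprocess(raw.blocks, raw.samples), truth


@pytest.fixture(scope="session")
def study_runs():
    """Full default pipeline over seeds 1-10; per-seed summaries.

    Each entry holds the minimum block-wise TNE-vs-ground-truth agreement,
    the set of SAS-flagged metabolites (union over conditions), and the
    planted coupled set.
    """
    out = []
    for seed in range(1, 11):
        raw, truth = generate_dataset(DesignSpec(seed=seed), EffectSpec())
        ds = preprocess(raw.blocks, raw.samples)
        graph = run_mapper(ds, random_state=seed)  # defaults: UMAP lens, K=3, 30%
        bench = benchmark_against_ground_truth(graph, ds)
        table = spearman_nodes(build_node_matrix(graph, ds))
        flagged = set()
        for cond in ds.samples.conditions:
            for rec in detect_sas(table, cond):
                if rec.sas:
                    flagged.add(rec.metabolite)
        out.append(
            {
                "seed": seed,
                "min_agreement": min(bench.agreement.values()),
                "flagged": flagged,
                "planted": truth.coupled,
                "n_nodes": graph.n_nodes,
            }
        )
    return out


@pytest.fixture()
def tiny_block():
    data = pd.DataFrame(
        [[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]],
        index=["s1", "s2", "s3"],
        columns=["lactate", "pyruvate"],
    )
    return OmicsBlock("B1", data, "raw")


@pytest.fixture()
def tiny_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "treatment": ["untreated", "DMSO", "DOXO_5uM"],
                "timepoint": ["0h", "24h", "48h"],
                "foc": [100.0, 110.0, 40.0],
                "dsdna_total": [2.0, 5.0, 4.0],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


def make_table(rho: dict, pval: dict, index: list[str]) -> CorrelationTable:
    """Hand-built correlation table for screen tests."""
    rho_df = pd.DataFrame(rho, index=index, dtype=float)
    pval_df = pd.DataFrame(pval, index=index, dtype=float)
    return CorrelationTable(rho=rho_df, pval=pval_df, n_nodes=10, degenerate=[])
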