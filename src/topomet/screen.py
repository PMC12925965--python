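"""Downstream screen on the node-level correlation table.

Three-step filter: (1) keep metabolites with p < 0.05 in at least one
condition, (2) of those, keep only metabolites reaching |rho| > 0.60, and
(3) zero out the remaining cells that fail either criterion. By default
steps (1) and (2) are read jointly per condition (the same condition must
pass both thresholds); the marginal reading is selectable. Thresholds are
strict inequalities.

Retained correlation profiles are hierarchically clustered (average
linkage, Euclidean, deterministic leaf order) for clustergram display;
strong associations (|rho| > 0.60) become chord records; a switch of
association sign (SAS) flags metabolites strongly associated with the
functional readout and, with opposite sign, with a dose-time condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .tne import CorrelationTable

__all__ = [
    "FilteredCorrelationTable",
    "ClustergramData",
    "ChordRecord",
    "SASRecord",
    "three_step_filter",
    "hierarchical_cluster",
    "build_chords",
    "detect_sas",
]


@dataclass
class FilteredCorrelationTable:
    """Output of the 3-step filter.

    ``values`` holds the rho matrix restricted to retained metabolites with
    suppressed cells set to 0; ``audit`` records, per suppressed cell or
    dropped row, which filter step acted.
    """

    retained: list[str]
    values: pd.DataFrame
    audit: pd.DataFrame  # columns: metabolite, target, rho, pval, action, step
    p_thresh: float
    rho_thresh: float


def three_step_filter(
    table: CorrelationTable,
    p_thresh: float = 0.05,
    rho_thresh: float = 0.60,
    columns: Sequence[str] | None = None,
    mode: str = "joint",
) -> FilteredCorrelationTable:
    """Filter the correlation table down to condition-associated metabolites.

    ``columns`` selects the condition columns screened (default: every
    target except ``foc``). ``mode="joint"`` (default) retains a metabolite
    iff some condition passes p < p_thresh AND |rho| > rho_thresh;
    ``mode="marginal"`` lets the two criteria be met in different columns.
    Within retained rows, individual cells failing either criterion are set
    to zero and audited.
    """
    if mode not in ("joint", "marginal"):
        raise ValueError(f"mode must be 'joint' or 'marginal', got {mode!r}")
    cols = [c for c in table.cols if c != "foc"] if columns is None else list(columns)
    unknown = [c for c in cols if c not in table.cols]
    if unknown:
        raise ValueError(f"unknown columns {unknown}; table has {table.cols}")
    rho = table.rho[cols]
    pval = table.pval[cols]
    pass_p = pval < p_thresh
    pass_r = rho.abs() > rho_thresh
    if mode == "joint":
        keep = (pass_p & pass_r).any(axis=1)
    else:
        keep = pass_p.any(axis=1) & pass_r.any(axis=1)
    retained = [m for m in rho.index if keep[m]]
    audit_rows = []
    for m in rho.index:
        if not keep[m]:
            audit_rows.append(
                {
                    "metabolite": m,
                    "target": "*",
                    "rho": float(rho.loc[m].abs().max()),
                    "pval": float(pval.loc[m].min()),
                    "action": "row_dropped",
                    "step": 1 if not pass_p.loc[m].any() else 2,
                }
            )
    values = rho.loc[retained].copy()
    for m in retained:
        for c in cols:
            fails_p = not pass_p.loc[m, c]
            fails_r = not pass_r.loc[m, c]
            if fails_p or fails_r:
                audit_rows.append(
                    {
                        "metabolite": m,
                        "target": c,
                        "rho": float(rho.loc[m, c]),
                        "pval": float(pval.loc[m, c]),
                        "action": "cell_zeroed",
                        "step": 1 if fails_p else 2,
                    }
                )
                values.loc[m, c] = 0.0
    audit = pd.DataFrame(
        audit_rows, columns=["metabolite", "target", "rho", "pval", "action", "step"]
    )
    return FilteredCorrelationTable(
        retained=retained,
        values=values,
        audit=audit,
        p_thresh=p_thresh,
        rho_thresh=rho_thresh,
    )


@dataclass
class ClustergramData:
    """Row/column dendrograms and leaf orders for clustergram display."""

    matrix: pd.DataFrame  # reordered rho matrix
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def to_json_dict(self) -> dict:
        return {
            "row_order": self.row_order,
            "col_order": self.col_order,
            "matrix": self.matrix.to_numpy().tolist(),
            "row_linkage": None
            if self.row_linkage is None
            else self.row_linkage.tolist(),
            "col_linkage": None
            if self.col_linkage is None
            else self.col_linkage.tolist(),
        }


def _ordered(labels: list[str], X: np.ndarray, method: str, metric: str):
    if len(labels) < 2:
        return labels, None
    Z = linkage(X, method=method, metric=metric)
    order = [labels[i] for i in leaves_list(Z)]
    return order, Z


def hierarchical_cluster(
    filtered: FilteredCorrelationTable,
    method: str = "average",
    metric: str = "euclidean",
) -> ClustergramData:
    """Agglomeratively cluster metabolite rows and condition columns.

    Rows and columns are pre-sorted by name so the leaf order is a
    deterministic function of the matrix values with ties broken by name.
    Fewer than 2 retained rows yields the identity ordering with a warning.
    """
    M = filtered.values.sort_index(axis=0).sort_index(axis=1)
    if M.shape[0] < 2:
        warnings.warn("fewer than 2 retained metabolites; identity ordering")
        return ClustergramData(
            matrix=M,
            row_order=list(M.index),
            col_order=list(M.columns),
            row_linkage=None,
            col_linkage=None,
        )
    row_order, row_Z = _ordered(list(M.index), M.to_numpy(), method, metric)
    col_order, col_Z = _ordered(list(M.columns), M.to_numpy().T, method, metric)
    return ClustergramData(
        matrix=M.loc[row_order, col_order],
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
    )


@dataclass
class ChordRecord:
    """One strong metabolite-target association (|rho| > threshold)."""

    entity_a: str
    entity_b: str
    weight: float
    sign: str  # "positive" | "negative"


def build_chords(
    table: CorrelationTable,
    targets: Sequence[str],
    chord_thresh: float = 0.60,
) -> list[ChordRecord]:
    """Chord records for every (metabolite, target) with |rho| > threshold."""
    unknown = [t for t in targets if t not in table.cols]
    if unknown:
        raise ValueError(f"unknown targets {unknown}; table has {table.cols}")
    records = []
    for t in targets:
        for m in table.rows:
            r = float(table.rho.loc[m, t])
            if abs(r) > chord_thresh:
                records.append(
                    ChordRecord(
                        entity_a=m,
                        entity_b=t,
                        weight=abs(r),
                        sign="positive" if r > 0 else "negative",
                    )
                )
    return records


@dataclass
class SASRecord:
    """Switch-of-association-sign assessment for one metabolite at one condition."""

    metabolite: str
    condition: str
    rho_foc: float
    rho_condition: float
    sas: bool


def detect_sas(
    table: CorrelationTable,
    condition: str,
    chord_thresh: float = 0.60,
    foc_col: str = "foc",
) -> list[SASRecord]:
    """Flag metabolites strongly tied to FoC and oppositely to a condition.

    ``sas`` is true iff both |rho(metabolite, foc)| and |rho(metabolite,
    condition)| exceed the chord threshold and the two signs differ.
    """
    for col in (foc_col, condition):
        if col not in table.cols:
            raise ValueError(f"column {col!r} not in table; has {table.cols}")
    out = []
    for m in table.rows:
        rf = float(table.rho.loc[m, foc_col])
        rc = float(table.rho.loc[m, condition])
        sas = bool(
            abs(rf) > chord_thresh
            and abs(rc) > chord_thresh
            and np.sign(rf) != np.sign(rc)
        )
        out.append(
            SASRecord(
                metabolite=m, condition=condition, rho_foc=rf, rho_condition=rc, sas=sas
            )
        )
    return out


def chords_to_frame(records: Sequence[ChordRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in records],
        columns=["entity_a", "entity_b", "weight", "sign"],
    )


def sas_to_frame(records: Sequence[SASRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in records],
        columns=["metabolite", "condition", "rho_foc", "rho_condition", "sas"],
    )
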