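"""Typed containers and preprocessing for multi-block metabolomics.

A *block* is one targeted LC-MS panel (e.g. the TEA, TBA or AA method of a
central-carbon-metabolism assay): a samples x metabolites matrix of peak
areas. Several blocks measured on the same tissues share one sample axis and
are combined, together with per-sample metadata (force of contraction,
dsDNA content, treatment, time point), into an :class:`AnnotatedDataset`.

Preprocessing follows the standard targeted-metabolomics route for
tissue-on-pillar extracts: peak areas are divided by the sample's total
dsDNA content (a proxy for tissue amount), then each metabolite is
Z-scored across samples.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsBlock",
    "SampleTable",
    "AnnotatedDataset",
    "read_block",
    "write_block",
    "read_samples",
    "normalize_by_dsdna",
    "zscore_block",
    "assemble_dataset",
]

#: tokens treated as a missing measurement when parsing delimited text
MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}

STAGES = ("raw", "normalized", "zscored")


def _check_unique(names: Sequence[str], what: str, where: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for n in names:
        if n in seen and n not in dups:
            dups.append(n)
        seen.add(n)
    if dups:
        raise ValueError(f"duplicate {what} in {where}: {dups}")


@dataclass
class OmicsBlock:
    """One samples x metabolites intensity matrix with a block identity.

    Parameters
    ----------
    block_id:
        Short label for the LC-MS method / panel (e.g. ``"TEA"``).
    data:
        DataFrame indexed by sample id, one float column per metabolite.
        NaN encodes a missing measurement.
    stage:
        ``"raw"`` or ``"normalized"`` (non-negative intensities) or
        ``"zscored"`` (each non-constant column has mean 0, population sd 1).
    constant_metabolites:
        Metabolites whose column had zero variance at Z-scoring time; their
        Z-score columns are all zero by convention.
    """

    block_id: str
    data: pd.DataFrame
    stage: str = "raw"
    constant_metabolites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        self.data = self.data.astype(float)
        _check_unique(list(self.data.index), "sample ids", f"block {self.block_id!r}")
        _check_unique(
            list(self.data.columns), "metabolite names", f"block {self.block_id!r}"
        )
        vals = self.data.to_numpy()
        if self.stage in ("raw", "normalized"):
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(
                    f"block {self.block_id!r}: negative intensity in stage={self.stage}"
                )
        else:  # zscored: non-constant columns standardized (population sd)
            for j, m in enumerate(self.data.columns):
                col = vals[:, j]
                col = col[~np.isnan(col)]
                if col.size == 0 or m in self.constant_metabolites:
                    continue
                if abs(col.mean()) > 1e-6 or abs(col.std() - 1.0) > 1e-6:
                    raise ValueError(
                        f"block {self.block_id!r}: column {m!r} is not Z-scored"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def missingness(self) -> pd.Series:
        """Per-metabolite count of missing cells."""
        return self.data.isna().sum()

    def reindex_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        missing = set(sample_ids) ^ set(self.data.index)
        if missing:
            raise ValueError(
                f"block {self.block_id!r}: sample mismatch {sorted(missing)}"
            )
        return replace(self, data=self.data.loc[list(sample_ids)])

    def rename_metabolites(self, mapping: dict[str, str]) -> "OmicsBlock":
        consts = tuple(mapping.get(m, m) for m in self.constant_metabolites)
        return replace(
            self, data=self.data.rename(columns=mapping), constant_metabolites=consts
        )


@dataclass
class SampleTable:
    """Per-sample metadata sharing the sample axis of the omics blocks.

    ``data`` is indexed by sample id and must provide numeric columns
    ``foc`` (force of contraction, uN) and ``dsdna_total`` (ng) and
    categorical columns ``treatment`` and ``timepoint``. The derived
    ``condition`` label is canonicalized to ``"treatment@timepoint"``.
    """

    data: pd.DataFrame

    REQUIRED = ("treatment", "timepoint", "foc", "dsdna_total")

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample ids", "sample table")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        dsdna = self.data["dsdna_total"].astype(float)
        bad = list(self.data.index[~(dsdna > 0)])
        if bad:
            raise ValueError(f"dsdna_total must be > 0; offending samples: {bad}")
        self.data = self.data.copy()
        self.data["condition"] = (
            self.data["treatment"].astype(str)
            + "@"
            + self.data["timepoint"].astype(str)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition(self) -> pd.Series:
        return self.data["condition"]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: list[str] = []
        for c in self.data["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def numeric(self, name: str) -> pd.Series:
        return self.data[name].astype(float)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="sample_id")


@dataclass
class AnnotatedDataset:
    """Aligned multi-block dataset plus sample metadata.

    All blocks share one ordered sample axis equal to ``samples.sample_ids``
    and metabolite names are globally unique across blocks.
    """

    blocks: list[OmicsBlock]
    samples: SampleTable

    def __post_init__(self) -> None:
        order = self.samples.sample_ids
        for b in self.blocks:
            if b.sample_ids != order:
                raise ValueError(
                    f"block {b.block_id!r} sample order differs from sample table"
                )
        all_mets = [m for b in self.blocks for m in b.metabolite_ids]
        _check_unique(all_mets, "metabolite names", "dataset")

    @property
    def sample_ids(self) -> list[str]:
        return self.samples.sample_ids

    @property
    def metabolite_ids(self) -> list[str]:
        return [m for b in self.blocks for m in b.metabolite_ids]

    @property
    def block_of(self) -> dict[str, str]:
        return {m: b.block_id for b in self.blocks for m in b.metabolite_ids}

    @property
    def stage(self) -> str:
        stages = {b.stage for b in self.blocks}
        return stages.pop() if len(stages) == 1 else "mixed"

    def concat_values(self) -> pd.DataFrame:
        """Horizontal concatenation of all block matrices (samples x all metabolites)."""
        return pd.concat([b.data for b in self.blocks], axis=1)

    def manifest(self) -> dict:
        return {
            "n_samples": len(self.sample_ids),
            "blocks": [
                {
                    "block_id": b.block_id,
                    "n_metabolites": len(b.metabolite_ids),
                    "stage": b.stage,
                    "missing_cells": int(b.data.isna().sum().sum()),
                }
                for b in self.blocks
            ],
            "conditions": self.samples.conditions,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for b in self.blocks:
            write_block(b, outdir / f"{b.block_id}.csv")
        self.samples.write_csv(outdir / "samples.csv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    return ","


def read_block(path: str | Path, block_id: str, sep: str | None = None) -> OmicsBlock:
    """Read a samples x metabolites delimited-text matrix as a raw block.

    The file must have a header row of metabolite names (first column is the
    sample-id column) and one row per sample. Empty cells and NA-like tokens
    become missing values. Duplicated names or non-numeric cells raise with
    the offending coordinates.
    """
    path = Path(path)
    sep = sep or _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    metabolites = [h.strip() for h in header[1:]]
    _check_unique(metabolites, "metabolite names", str(path))
    sample_ids = [r[0].strip() for r in rows[1:]]
    _check_unique(sample_ids, "sample ids", str(path))
    values = np.full((len(sample_ids), len(metabolites)), np.nan)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )
        for j, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok.lower() in MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} at sample "
                    f"{sample_ids[i]!r}, metabolite {metabolites[j]!r}"
                ) from None
    data = pd.DataFrame(values, index=sample_ids, columns=metabolites)
    return OmicsBlock(block_id=block_id, data=data, stage="raw")


def write_block(block: OmicsBlock, path: str | Path) -> None:
    """Write a block as CSV (full float precision, round-trips with read_block)."""
    block.data.to_csv(path, index_label="sample_id")


def read_samples(path: str | Path, sep: str | None = None) -> SampleTable:
    """Read the sample metadata CSV.

    ``dsdna_total`` may be given directly, or as the two raw measurements
    ``dsdna_extract`` + ``dsdna_tissue`` (extract and residual tissue) which
    are summed into a single per-sample scalar.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sniff_delimiter(path), index_col="sample_id")
    if "dsdna_total" not in df.columns:
        if {"dsdna_extract", "dsdna_tissue"} <= set(df.columns):
            df["dsdna_total"] = df["dsdna_extract"].astype(float) + df[
                "dsdna_tissue"
            ].astype(float)
        else:
            raise ValueError(
                f"{path}: need dsdna_total or dsdna_extract + dsdna_tissue columns"
            )
    df.index = df.index.astype(str)
    return SampleTable(df)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize_by_dsdna(block: OmicsBlock, samples: SampleTable) -> OmicsBlock:
    """Divide each sample's peak areas by its total dsDNA content (ng)."""
    if block.stage != "raw":
        raise ValueError(f"normalize_by_dsdna expects a raw block, got {block.stage}")
    dsdna = samples.data["dsdna_total"].astype(float)
    missing = [s for s in block.sample_ids if s not in dsdna.index]
    if missing:
        raise ValueError(f"no dsdna_total for samples: {missing}")
    denom = dsdna.loc[block.sample_ids]
    if not (denom > 0).all():
        bad = list(denom.index[~(denom > 0)])
        raise ValueError(f"dsdna_total must be > 0; offending samples: {bad}")
    data = block.data.div(denom, axis=0)
    return replace(block, data=data, stage="normalized")


def zscore_block(block: OmicsBlock) -> OmicsBlock:
    """Z-score each metabolite across samples (population sd, divisor n).

    Missing values are excluded from mean/sd and stay missing. Zero-variance
    columns map to all-zeros and are recorded in ``constant_metabolites``.
    """
    if block.stage != "normalized":
        raise ValueError(f"zscore_block expects a normalized block, got {block.stage}")
    if block.shape[0] < 2:
        raise ValueError("zscore_block requires at least 2 samples")
    vals = block.values.copy()
    constants: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)  # population sd (ddof=0)
    for j, m in enumerate(block.metabolite_ids):
        if not np.isfinite(sd[j]) or sd[j] == 0.0:
            constants.append(m)
            vals[:, j] = np.where(np.isnan(vals[:, j]), np.nan, 0.0)
        else:
            vals[:, j] = (vals[:, j] - mean[j]) / sd[j]
    data = pd.DataFrame(vals, index=block.sample_ids, columns=block.metabolite_ids)
    return replace(
        block, data=data, stage="zscored", constant_metabolites=tuple(constants)
    )


def assemble_dataset(
    blocks: Iterable[OmicsBlock], samples: SampleTable
) -> AnnotatedDataset:
    """Align blocks onto the sample-table order and enforce global name uniqueness.

    Each block's samples must be a permutation of the sample table's; a
    metabolite name occurring in more than one block is prefixed with its
    block id (``"AA.pyruvate"``).
    """
    blocks = list(blocks)
    order = samples.sample_ids
    aligned = []
    for b in blocks:
        diff = set(b.sample_ids) ^ set(order)
        if diff:
            raise ValueError(
                f"block {b.block_id!r}: sample set differs from metadata "
                f"(symmetric difference {sorted(diff)})"
            )
        aligned.append(b.reindex_samples(order))
    counts: dict[str, int] = {}
    for b in aligned:
        for m in b.metabolite_ids:
            counts[m] = counts.get(m, 0) + 1
    collisions = {m for m, c in counts.items() if c > 1}
    if collisions:
        aligned = [
            b.rename_metabolites(
                {m: f"{b.block_id}.{m}" for m in b.metabolite_ids if m in collisions}
            )
            for b in aligned
        ]
    return AnnotatedDataset(blocks=aligned, samples=samples)
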