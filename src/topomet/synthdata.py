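"""Synthetic multi-block metabolomics with the dose-time study structure.

The generator emulates a 21-tissue cardiotoxicity experiment: 3 replicates
per condition over 7 (treatment, timepoint) conditions — untreated at 0 h
and DMSO / 1 uM DOXO / 5 uM DOXO at 24 h and 48 h — with 48 metabolites
split over three LC-MS blocks (TEA/TBA/AA analogs). Doxorubicin exposure
is modeled as dose level (0 for untreated and the DMSO vehicle, 1 for
1 uM, 2 for 5 uM) times hours / 24, so exposure spans 0..4.

Per-sample force of contraction declines multiplicatively with dose and
time (vehicle controls instead gain about 10 % per day) and raw peak areas
are log-normal with a planted exposure effect on coupled metabolite
subsets, a per-block per-sample batch factor, and a dsDNA (tissue amount)
factor that the normalization step removes. Ground truth (coupled sets,
signs, exposure covariate) is returned alongside the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AnnotatedDataset, OmicsBlock, SampleTable, assemble_dataset

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "GroundTruth",
    "generate_dataset",
    "make_fixture",
    "DEFAULT_CONDITIONS",
    "DOSE_LEVEL",
]

DEFAULT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("untreated", "0h"),
    ("DMSO", "24h"),
    ("DOXO_1uM", "24h"),
    ("DOXO_5uM", "24h"),
    ("DMSO", "48h"),
    ("DOXO_1uM", "48h"),
    ("DOXO_5uM", "48h"),
)

DOSE_LEVEL = {"untreated": 0, "DMSO": 0, "DOXO_1uM": 1, "DOXO_5uM": 2}
HOURS = {"0h": 0.0, "24h": 24.0, "48h": 48.0}

#: multiplicative FoC effect per condition: vehicle controls gain ~10 %/day,
#: DOXO declines with dose and time, strongest at 5 uM / 48 h
DEFAULT_FOC_MULTIPLIERS = {
    ("untreated", "0h"): 1.00,
    ("DMSO", "24h"): 1.10,
    ("DMSO", "48h"): 1.21,
    ("DOXO_1uM", "24h"): 0.75,
    ("DOXO_5uM", "24h"): 0.70,
    ("DOXO_1uM", "48h"): 0.55,
    ("DOXO_5uM", "48h"): 0.35,
}


def exposure_of(treatment: str, timepoint: str) -> float:
    """Dose-time exposure covariate: dose level x hours / 24."""
    return DOSE_LEVEL[treatment] * HOURS[timepoint] / 24.0


@dataclass
class DesignSpec:
    """Study design: replicates, conditions, block sizes, seed."""

    n_replicates: int = 3
    conditions: tuple[tuple[str, str], ...] = DEFAULT_CONDITIONS
    block_sizes: tuple[int, ...] = (16, 16, 16)
    block_ids: tuple[str, ...] = ("TEA", "TBA", "AA")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or any(s < 1 for s in self.block_sizes):
            raise ValueError("replicates and block sizes must be >= 1")
        if len(self.block_ids) != len(self.block_sizes):
            raise ValueError("block_ids and block_sizes must align")
        for t, tp in self.conditions:
            if t not in DOSE_LEVEL or tp not in HOURS:
                raise ValueError(f"unknown condition {(t, tp)!r}")

    @property
    def n_samples(self) -> int:
        return self.n_replicates * len(self.conditions)


@dataclass
class EffectSpec:
    """Planted effects: FoC trajectory, coupled metabolites, noise levels.

    ``effect_size`` is the standardized log-intensity shift per exposure
    unit for coupled metabolites; ``noise_sd`` the residual log-scale sd;
    ``batch_sd`` the per-block per-sample multiplicative batch noise (log
    sd). Coupled index sets default to the first quarter (up) and second
    quarter (down) of each block.
    """

    foc_baseline: float = 100.0  # uN
    foc_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_FOC_MULTIPLIERS)
    )
    foc_noise_sd: float = 0.08  # log-normal sigma
    coupled_up: tuple[str, ...] | None = None  # metabolite names; None = default
    coupled_down: tuple[str, ...] | None = None
    effect_size: float = 1.5
    noise_sd: float = 1.0
    batch_sd: float = 0.2
    dsdna_mean: float = 100.0  # ng
    dsdna_log_sd: float = 0.15
    baseline_log_range: tuple[float, float] = (np.log(1e4), np.log(1e6))

    def __post_init__(self) -> None:
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if self.coupled_up and self.coupled_down:
            if set(self.coupled_up) & set(self.coupled_down):
                raise ValueError("coupled_up and coupled_down must be disjoint")


@dataclass
class GroundTruth:
    """What was planted: coupled sets, per-metabolite sign, exposure covariate."""

    coupled_up: tuple[str, ...]
    coupled_down: tuple[str, ...]
    direction: dict[str, int]  # metabolite -> {-1, 0, +1}
    exposure: pd.Series  # per sample
    foc_multiplier: pd.Series  # per sample
    seed: int

    @property
    def coupled(self) -> set[str]:
        return set(self.coupled_up) | set(self.coupled_down)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "coupled_up": list(self.coupled_up),
                    "coupled_down": list(self.coupled_down),
                    "direction": self.direction,
                    "exposure": self.exposure.to_dict(),
                    "foc_multiplier": self.foc_multiplier.to_dict(),
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def _metabolite_names(block_id: str, size: int) -> list[str]:
    return [f"{block_id.lower()}_met{j + 1:02d}" for j in range(size)]


def generate_dataset(
    design: DesignSpec | None = None, effects: EffectSpec | None = None
) -> tuple[AnnotatedDataset, GroundTruth]:
    """Draw one synthetic study (raw-stage blocks + metadata) with ground truth.

    Identical specs (including the seed) give bit-identical output.
    """
    design = design or DesignSpec()
    effects = effects or EffectSpec()
    rng = np.random.default_rng(design.seed)
    n = design.n_samples

    sample_ids, treatments, timepoints = [], [], []
    k = 0
    for t, tp in design.conditions:
        for _ in range(design.n_replicates):
            k += 1
            sample_ids.append(f"EHT_{k:02d}")
            treatments.append(t)
            timepoints.append(tp)
    exposure = pd.Series(
        [exposure_of(t, tp) for t, tp in zip(treatments, timepoints)],
        index=sample_ids,
        name="exposure",
    )
    mult = pd.Series(
        [effects.foc_multipliers[(t, tp)] for t, tp in zip(treatments, timepoints)],
        index=sample_ids,
        name="foc_multiplier",
    )
    dsdna = effects.dsdna_mean * np.exp(rng.normal(0.0, effects.dsdna_log_sd, n))
    foc = (
        effects.foc_baseline
        * mult.to_numpy()
        * np.exp(rng.normal(0.0, effects.foc_noise_sd, n))
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "treatment": treatments,
                "timepoint": timepoints,
                "foc": foc,
                "dsdna_total": dsdna,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # default coupled sets: first quarter up, second quarter down, per block
    direction: dict[str, int] = {}
    blocks: list[OmicsBlock] = []
    for bid, size in zip(design.block_ids, design.block_sizes):
        names = _metabolite_names(bid, size)
        q = size // 4
        for j, m in enumerate(names):
            if effects.coupled_up is not None or effects.coupled_down is not None:
                d = 0
                if effects.coupled_up and m in effects.coupled_up:
                    d = 1
                if effects.coupled_down and m in effects.coupled_down:
                    d = -1
            else:
                d = 1 if j < q else (-1 if j < 2 * q else 0)
            direction[m] = d
        baseline = rng.uniform(*effects.baseline_log_range, size)
        batch = rng.normal(0.0, effects.batch_sd, n)  # per block, per sample
        noise = rng.normal(0.0, effects.noise_sd, (n, size))
        dirs = np.array([direction[m] for m in names], dtype=float)
        log_int = (
            baseline[None, :]
            + dirs[None, :]
            * effects.effect_size
            * effects.noise_sd
            * exposure.to_numpy()[:, None]
            + batch[:, None]
            + noise
        )
        raw = np.exp(log_int) * (dsdna / effects.dsdna_mean)[:, None]
        blocks.append(
            OmicsBlock(
                block_id=bid,
                data=pd.DataFrame(raw, index=sample_ids, columns=names),
                stage="raw",
            )
        )

    dataset = assemble_dataset(blocks, samples)
    truth = GroundTruth(
        coupled_up=tuple(m for m, d in direction.items() if d > 0),
        coupled_down=tuple(m for m, d in direction.items() if d < 0),
        direction=direction,
        exposure=exposure,
        foc_multiplier=mult,
        seed=design.seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Micro fixtures for unit tests
# ---------------------------------------------------------------------------

FIXTURES = ("two_cluster", "singleton_limit", "null")


def make_fixture(name: str, seed: int = 0) -> AnnotatedDataset:
    """Deterministic micro-datasets (<= 12 samples, <= 6 metabolites).

    ``two_cluster``
        12 samples in two well-separated condition groups (untreated vs
        5 uM DOXO at 48 h), 6 metabolites in 2 blocks; the group mean shift
        is ~6 residual sd, so the TCN splits the groups cleanly.
    ``singleton_limit``
        8 samples with spread FoC, 4 metabolites in 1 block; meant to be
        run with ``n_intervals=1`` and the ``singleton`` preimage clusterer
        so Mapper yields exactly one node per sample.
    ``null``
        12 samples (2 replicates x 6 dose-time conditions), 6 metabolites
        in 3 blocks, no planted effects (effect_size = 0).
    """
    if name == "null":
        design = DesignSpec(
            n_replicates=2,
            conditions=tuple(c for c in DEFAULT_CONDITIONS if c[1] != "0h"),
            block_sizes=(2, 2, 2),
            seed=seed,
        )
        dataset, _ = generate_dataset(design, EffectSpec(effect_size=0.0))
        return dataset
    if name == "two_cluster":
        rng = np.random.default_rng(seed)
        n_per = 6
        ids = [f"EHT_{i + 1:02d}" for i in range(2 * n_per)]
        group = np.array([0] * n_per + [1] * n_per)
        treatments = ["untreated"] * n_per + ["DOXO_5uM"] * n_per
        timepoints = ["0h"] * n_per + ["48h"] * n_per
        foc = np.where(group == 0, 110.0, 35.0) * np.exp(rng.normal(0, 0.05, 2 * n_per))
        samples = SampleTable(
            pd.DataFrame(
                {
                    "treatment": treatments,
                    "timepoint": timepoints,
                    "foc": foc,
                    "dsdna_total": 100.0 * np.exp(rng.normal(0, 0.1, 2 * n_per)),
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )
        blocks = []
        for bid, size in (("B1", 3), ("B2", 3)):
            names = _metabolite_names(bid, size)
            signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(size)])
            shift = 6.0 * 0.5  # 6 x residual sd (0.5)
            log_int = (
                np.log(1e5)
                + signs[None, :] * shift * group[:, None]
                + rng.normal(0, 0.5, (2 * n_per, size))
            )
            raw = np.exp(log_int) * (samples.numeric("dsdna_total").to_numpy() / 100.0)[
                :, None
            ]
            blocks.append(
                OmicsBlock(bid, pd.DataFrame(raw, index=ids, columns=names), "raw")
            )
        return assemble_dataset(blocks, samples)
    if name == "singleton_limit":
        rng = np.random.default_rng(seed)
        n = 8
        ids = [f"EHT_{i + 1:02d}" for i in range(n)]
        foc = np.linspace(30.0, 120.0, n) * np.exp(rng.normal(0, 0.02, n))
        samples = SampleTable(
            pd.DataFrame(
                {
                    "treatment": ["DOXO_5uM"] * (n // 2) + ["DMSO"] * (n // 2),
                    "timepoint": ["48h"] * (n // 2) + ["48h"] * (n // 2),
                    "foc": foc,
                    "dsdna_total": np.full(n, 100.0),
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )
        names = _metabolite_names("B1", 4)
        slopes = np.array([2.0, -2.0, 1.0, 0.0])
        log_int = (
            np.log(1e5)
            + slopes[None, :] * np.linspace(-1, 1, n)[:, None]
            + rng.normal(0, 0.4, (n, 4))
        )
        block = OmicsBlock(
            "B1", pd.DataFrame(np.exp(log_int), index=ids, columns=names), "raw"
        )
        return assemble_dataset([block], samples)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
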