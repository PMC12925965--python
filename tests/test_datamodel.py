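"""Containers, IO round-trips, dsDNA normalization and Z-scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from topomet.datamodel import (
    OmicsBlock,
    SampleTable,
    assemble_dataset,
    normalize_by_dsdna,
    read_block,
    write_block,
    read_samples,
    zscore_block,
)


def _write(tmp_path, text, name="block.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadBlock:
    def test_parses_shape_and_order(self, tmp_path):
        p = _write(tmp_path, "sample_id,lactate,pyruvate\nA,1,4\nB,2,5\nC,3,6\n")
        b = read_block(p, "B1")
        assert b.shape == (3, 2)
        assert b.sample_ids == ["A", "B", "C"]
        assert b.metabolite_ids == ["lactate", "pyruvate"]
        assert b.stage == "raw"
        assert b.values[2, 1] == 6.0

    def test_duplicate_metabolite_named(self, tmp_path):
        p = _write(tmp_path, "sample_id,lactate,lactate\nA,1,2\n")
        with pytest.raises(ValueError, match="lactate"):
            read_block(p, "B1")

    def test_duplicate_sample_named(self, tmp_path):
        p = _write(tmp_path, "sample_id,lactate\nA,1\nA,2\n")
        with pytest.raises(ValueError, match="'A'"):
            read_block(p, "B1")

    def test_na_cell_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "sample_id,lactate,pyruvate\nA,NA,4\nB,2,\n")
        b = read_block(p, "B1")
        assert np.isnan(b.values[0, 0]) and np.isnan(b.values[1, 1])
        assert b.missingness()["lactate"] == 1

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = _write(tmp_path, "sample_id,lactate\nA,1\nB,oops\n")
        with pytest.raises(ValueError, match=r"'oops'.*'B'.*'lactate'"):
            read_block(p, "B1")

    def test_tsv_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(
            rng.lognormal(10, 2, (5, 4)),
            index=[f"s{i}" for i in range(5)],
            columns=[f"m{j}" for j in range(4)],
        )
        b = OmicsBlock("B1", data, "raw")
        path = tmp_path / "out.csv"
        write_block(b, path)
        b2 = read_block(path, "B1")
        assert np.array_equal(b.values, b2.values)
        assert b2.sample_ids == b.sample_ids


class TestNormalize:
    def test_divides_by_dsdna(self, tiny_block, tiny_samples):
        out = normalize_by_dsdna(tiny_block, tiny_samples)
        assert out.stage == "normalized"
        assert out.data.loc["s1", "lactate"] == pytest.approx(0.5)  # 1 / 2
        assert out.data.loc["s2", "pyruvate"] == pytest.approx(4.0)  # 20 / 5

    def test_zero_intensity_stays_zero(self, tiny_samples):
        b = OmicsBlock(
            "B1",
            pd.DataFrame({"m": [0.0, 1.0, 2.0]}, index=["s1", "s2", "s3"]),
            "raw",
        )
        assert normalize_by_dsdna(b, tiny_samples).data.loc["s1", "m"] == 0.0

    def test_nonpositive_dsdna_rejected(self):
        with pytest.raises(ValueError, match="dsdna_total must be > 0"):
            SampleTable(
                pd.DataFrame(
                    {
                        "treatment": ["untreated"],
                        "timepoint": ["0h"],
                        "foc": [1.0],
                        "dsdna_total": [0.0],
                    },
                    index=pd.Index(["s1"], name="sample_id"),
                )
            )

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, c):
        # scaling one sample's raw row and its dsDNA by c leaves its
        # normalized row unchanged
        data = pd.DataFrame(
            {"m1": [3.0, 6.0], "m2": [1.0, 8.0]}, index=["s1", "s2"]
        )
        meta = pd.DataFrame(
            {
                "treatment": ["untreated"] * 2,
                "timepoint": ["0h"] * 2,
                "foc": [1.0, 1.0],
                "dsdna_total": [2.0, 4.0],
            },
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
        base = normalize_by_dsdna(
            OmicsBlock("B", data, "raw"), SampleTable(meta.copy())
        )
        scaled_data = data.copy()
        scaled_data.loc["s1"] *= c
        scaled_meta = meta.copy()
        scaled_meta.loc["s1", "dsdna_total"] *= c
        scaled = normalize_by_dsdna(
            OmicsBlock("B", scaled_data, "raw"), SampleTable(scaled_meta)
        )
        np.testing.assert_allclose(
            scaled.data.loc["s1"], base.data.loc["s1"], rtol=1e-12
        )


class TestZscore:
    def test_population_sd_values(self, tiny_samples):
        b = OmicsBlock(
            "B1",
            pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=["s1", "s2", "s3"]),
            "normalized",
        )
        z = zscore_block(b)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z.data["m"].to_numpy(), expected, atol=1e-12)
        # matches the scipy population-Z convention
        np.testing.assert_allclose(
            z.data["m"].to_numpy(), stats.zscore([1.0, 2.0, 3.0]), atol=1e-12
        )

    def test_constant_column_zeroed_and_flagged(self):
        b = OmicsBlock(
            "B1",
            pd.DataFrame({"m": [5.0, 5.0, 5.0]}, index=["a", "b", "c"]),
            "normalized",
        )
        z = zscore_block(b)
        assert list(z.data["m"]) == [0.0, 0.0, 0.0]
        assert z.constant_metabolites == ("m",)

    def test_output_standardized_and_idempotent(self):
        rng = np.random.default_rng(3)
        b = OmicsBlock(
            "B1",
            pd.DataFrame(
                rng.lognormal(1, 1, (9, 3)),
                index=[f"s{i}" for i in range(9)],
                columns=list("xyz"),
            ),
            "normalized",
        )
        z = zscore_block(b).values
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)
        z2 = (z - z.mean(axis=0)) / z.std(axis=0)
        assert np.abs(z2 - z).max() < 1e-9

    def test_missing_values_excluded_and_preserved(self):
        b = OmicsBlock(
            "B1",
            pd.DataFrame({"m": [1.0, np.nan, 3.0]}, index=["a", "b", "c"]),
            "normalized",
        )
        z = zscore_block(b)
        assert np.isnan(z.data.loc["b", "m"])
        np.testing.assert_allclose(
            z.data.loc[["a", "c"], "m"], [-1.0, 1.0], atol=1e-12
        )

    def test_single_sample_rejected(self):
        b = OmicsBlock(
            "B1", pd.DataFrame({"m": [1.0]}, index=["a"]), "normalized"
        )
        with pytest.raises(ValueError, match="at least 2 samples"):
            zscore_block(b)


class TestAssemble:
    def test_reorders_shuffled_blocks(self, tiny_samples):
        data = pd.DataFrame({"m1": [1.0, 2.0, 3.0]}, index=["s3", "s1", "s2"])
        ds = assemble_dataset([OmicsBlock("B1", data, "raw")], tiny_samples)
        assert ds.blocks[0].sample_ids == ["s1", "s2", "s3"]
        assert ds.blocks[0].data.loc["s3", "m1"] == 1.0

    def test_missing_sample_named(self, tiny_samples):
        data = pd.DataFrame({"m1": [1.0, 2.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s3"):
            assemble_dataset([OmicsBlock("B1", data, "raw")], tiny_samples)

    def test_name_collision_prefixed_with_block_id(self, tiny_samples):
        idx = ["s1", "s2", "s3"]
        b1 = OmicsBlock("TBA", pd.DataFrame({"pyruvate": [1.0, 2, 3]}, index=idx), "raw")
        b2 = OmicsBlock("AA", pd.DataFrame({"pyruvate": [4.0, 5, 6]}, index=idx), "raw")
        ds = assemble_dataset([b1, b2], tiny_samples)
        assert ds.metabolite_ids == ["TBA.pyruvate", "AA.pyruvate"]


def test_read_samples_sums_split_dsdna(tmp_path):
    p = tmp_path / "meta.csv"
    p.write_text(
        "sample_id,treatment,timepoint,foc,dsdna_extract,dsdna_tissue\n"
        "s1,untreated,0h,90.0,30.0,70.0\n"
        "s2,DMSO,24h,100.0,20.0,60.0\n"
    )
    t = read_samples(p)
    assert t.data.loc["s1", "dsdna_total"] == 100.0
    assert t.data.loc["s2", "condition"] == "DMSO@24h"
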