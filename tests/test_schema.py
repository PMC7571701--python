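import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscrepair import (
    DEFAULT_SCALES,
    EncodingConfig,
    ScoreScale,
    SpeciesGeometry,
    TherapyRecord,
    derive_properties,
    normalize_score,
    read_table,
    write_table,
)
from mscrepair.schema import HIGHER_IS_HEALTHIER, HIGHER_IS_WORSE, read_dataset, write_dataset
from mscrepair.synth import SynthConfig, generate_table


class TestNormalizeScore:
    @pytest.mark.parametrize(
        "raw, scale, expected",
        [
            (12, ScoreScale("ICRS", 0, 12, HIGHER_IS_HEALTHIER), 1.0),
            (0, ScoreScale("VAS", 0, 10, HIGHER_IS_WORSE), 1.0),  # no pain = healthy
            (6, ScoreScale("ICRS", 0, 12, HIGHER_IS_HEALTHIER), 0.5),
            (5, ScoreScale("VAS", 0, 10, HIGHER_IS_WORSE), 0.5),
            (48, ScoreScale("WOMAC", 0, 96, HIGHER_IS_WORSE), 0.5),
        ],
    )
    def test_linear_endpoints_and_midpoint(self, raw, scale, expected):
        assert normalize_score(raw, scale) == pytest.approx(expected)

    def test_out_of_range_names_the_scale(self):
        with pytest.raises(ValueError, match="ICRS"):
            normalize_score(13, DEFAULT_SCALES["ICRS"])

    def test_degenerate_scale_rejected_at_construction(self):
        with pytest.raises(ValueError, match="degenerate"):
            ScoreScale("broken", 5, 5, HIGHER_IS_HEALTHIER)

    def test_missing_raw_propagates(self):
        assert math.isnan(normalize_score(float("nan"), DEFAULT_SCALES["ICRS"]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 99.999), min_size=2, max_size=2, unique=True),
           st.sampled_from([HIGHER_IS_HEALTHIER, HIGHER_IS_WORSE]))
    def test_monotone(self, raws, direction):
        scale = ScoreScale("gen", 0, 100, direction)
        a, b = sorted(raws)
        sa, sb = normalize_score(a, scale), normalize_score(b, scale)
        if direction == HIGHER_IS_HEALTHIER:
            assert sa < sb
        else:
            assert sa > sb


class TestDeriveProperties:
    def test_volume_and_percentage_arithmetic(self):
        rec = TherapyRecord(species="rabbit", defect_area_mm2=10.0, defect_depth_mm=2.0)
        refs = {"rabbit": SpeciesGeometry(600.0, 3.0)}
        out = derive_properties(rec, refs)
        assert out.defect_volume_mm3 == pytest.approx(20.0)
        rec2 = TherapyRecord(species="rabbit", defect_area_mm2=6.0)
        out2 = derive_properties(rec2, refs)
        assert out2.defect_area_pct == pytest.approx(1.0)

    def test_cell_number_from_concentration_and_volume(self):
        rec = TherapyRecord(cell_concentration_per_ml=2e6, delivery_volume_ml=3.0)
        assert derive_properties(rec).cell_number == pytest.approx(6e6)

    def test_no_derivation_inputs_is_a_noop(self):
        rec = TherapyRecord(species="rat")
        assert derive_properties(rec) == rec

    def test_present_fields_never_overwritten(self):
        rec = TherapyRecord(defect_area_mm2=10.0, defect_depth_mm=2.0,
                            defect_volume_mm3=99.0)
        assert derive_properties(rec).defect_volume_mm3 == 99.0

    def test_idempotent(self):
        rec = TherapyRecord(species="rabbit", defect_area_mm2=10.0, defect_depth_mm=2.0)
        refs = {"rabbit": SpeciesGeometry(600.0, 3.0)}
        once = derive_properties(rec, refs)
        assert derive_properties(once, refs) == once

    def test_nonpositive_operand_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            derive_properties(TherapyRecord(defect_area_mm2=-1.0, defect_depth_mm=2.0))


class TestEncoding:
    @pytest.fixture
    def table(self):
        df, _truth, _enc = generate_table(SynthConfig(n=20, seed=3))
        return df

    def test_mask_matches_missing_fields(self, table):
        df = table.copy()
        df.loc[0, "cell_number"] = np.nan
        enc = EncodingConfig.fit(df, ["defect_area_pct", "cell_number", "tissue_source"])
        ds = enc.encode_frame(df)
        assert not ds.mask[0, ds.columns.index("cell_number")]
        assert ds.mask[1, ds.columns.index("cell_number")]
        # one masked slot per missing source field mapped into the vector
        assert int((~ds.mask[0]).sum()) == 1

    def test_continuous_slots_unit_interval(self, table):
        enc = EncodingConfig.fit(table)
        ds = enc.encode_frame(table)
        cont = [i for i, s in enumerate(enc.specs) if s.kind == "continuous"]
        vals = ds.values[:, cont]
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0

    def test_round_trip_recovers_known_fields(self, table):
        cols = ["defect_area_pct", "defect_depth_pct", "cell_number",
                "body_weight_kg", "tissue_source", "damage_type"]
        enc = EncodingConfig.fit(table, cols)
        back = enc.decode_frame(enc.encode_frame(table))
        for c in ["defect_area_pct", "cell_number", "body_weight_kg"]:
            np.testing.assert_allclose(back[c].to_numpy(float),
                                       table[c].to_numpy(float), rtol=1e-9)
        assert (back["tissue_source"] == table["tissue_source"]).all()
        np.testing.assert_allclose(back["repair_score"], table["repair_score"])

    def test_unseen_level_configurable(self, table):
        enc = EncodingConfig.fit(table, ["tissue_source"])
        df = table.iloc[:1].copy()
        df.loc[df.index[0], "tissue_source"] = "XX"
        with pytest.raises(ValueError, match="unseen"):
            enc.encode_frame(df)
        enc.unseen_category_error = False
        ds = enc.encode_frame(df)
        assert (ds.values[0, :-1] == 0).all()

    def test_consolidated_tissue_indicator(self, table):
        enc = EncodingConfig.fit(table, ["tissue_source"], consolidate_bm_ad=True)
        ds = enc.encode_frame(table)
        j = ds.columns.index("tissue_BM_or_AD")
        expect = table["tissue_source"].isin(["BM", "AD"]).to_numpy()
        np.testing.assert_array_equal(ds.values[:, j] == 1.0, expect)


class TestCsvRoundTrip:
    def test_read_counts_and_missing_cells(self, tmp_path):
        df, _t, _e = generate_table(SynthConfig(n=3, seed=5))
        df.loc[1, "defect_area_pct"] = np.nan
        path = tmp_path / "db.csv"
        write_table(df, path)
        back = read_table(path)
        assert len(back) == 3
        assert pd.isna(back.loc[1, "defect_area_pct"])
        # empty-string and NA spellings both read as missing
        text = path.read_text().replace(",,", ",NA,", 1)
        path.write_text(text)
        assert read_table(path).isna().sum().sum() >= back.isna().sum().sum()

    def test_dataset_round_trip(self, tmp_path):
        df, _t, enc = generate_table(SynthConfig(n=8, seed=2))
        df.loc[2, "cell_number"] = np.nan
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_table(df, p1)
        ds, enc2 = read_dataset(p1, cfg=enc)
        assert ds.n_entries == 8
        assert not ds.mask[2, ds.columns.index("cell_number")]
        write_dataset(ds, enc2, p2)
        ds2, _ = read_dataset(p2, cfg=enc2)
        np.testing.assert_allclose(
            np.nan_to_num(ds.values, nan=-1), np.nan_to_num(ds2.values, nan=-1),
            rtol=1e-9, atol=1e-12,
        )
        np.testing.assert_array_equal(ds.mask, ds2.mask)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,bogus\nrat,1\n")
        with pytest.raises(ValueError, match="bogus"):
            read_table(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,body_weight_kg\nrat,heavy\n")
        with pytest.raises(ValueError, match="body_weight_kg"):
            read_table(path)

    def test_score_normalization_on_read(self, tmp_path):
        path = tmp_path / "scores.csv"
        path.write_text(
            "species,score_name,score_raw,repair_score\n"
            "human,IKDC,75,\n"
            "rat,VAS,2,\n"
        )
        df = read_table(path)
        assert df.loc[0, "repair_score"] == pytest.approx(0.75)
        assert df.loc[1, "repair_score"] == pytest.approx(0.8)
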