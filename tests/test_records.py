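"""Occurrence ingestion, time-layer pooling, incidence and status partition."""

import numpy as np
import pandas as pd
import pytest

from mothdrift import records
from mothdrift.records import (
    SchemaError,
    TimeLayer,
    TimeLayerScheme,
    default_scheme,
)


def _write(tmp_path, text, name="occ.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadOccurrences:
    def test_well_formed_file_ingested_identically(self, tmp_path):
        p = _write(tmp_path, "species_id,year,source\na,1940,m\nb,1999,s\nc,2011,s\n")
        tab = records.load_occurrences(p)
        assert len(tab) == 3
        assert list(tab["year"]) == [1940, 1999, 2011]
        assert tab["year"].dtype.kind == "i"

    def test_malformed_year_strict_raises_naming_row(self, tmp_path):
        p = _write(tmp_path, "species_id,year,source\na,1940,m\nb,19xx,s\n")
        with pytest.raises(ValueError, match="line 3"):
            records.load_occurrences(p, strict=True)

    def test_malformed_year_lenient_drops_row(self, tmp_path, caplog):
        p = _write(tmp_path, "species_id,year,source\na,1940,m\nb,19xx,s\n")
        tab = records.load_occurrences(p)
        assert list(tab["species_id"]) == ["a"]

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "species_id,source\na,m\n")
        with pytest.raises(SchemaError, match="year"):
            records.load_occurrences(p)

    def test_column_mapping(self, tmp_path):
        p = _write(tmp_path, "taxon,yr,coll\na,1940,m\n")
        tab = records.load_occurrences(
            p, column_map={"species_id": "taxon", "year": "yr", "source": "coll"}
        )
        assert list(tab.columns) == ["species_id", "year", "source"]

    def test_duplicate_rows_retained_then_deduplicated_by_incidence(self, tmp_path, scheme):
        p = _write(tmp_path, "species_id,year,source\na,1940,m\na,1940,m\n")
        tab = records.load_occurrences(p)
        assert len(tab) == 2
        inc = records.build_incidence(records.assign_time_layers(tab, scheme), scheme)
        assert inc.shape == (1, 1)
        assert inc.iloc[0, 0] == 1


class TestPhenologicalFilter:
    def test_flagged_species_removed_with_reason(self, tiny_records, tiny_traits):
        kept, log = records.apply_phenological_filter(tiny_records, tiny_traits)
        removed = set(log["species_id"])
        assert removed == {"migrant_hawkmoth", "pine_processionary"}
        assert "long_distance_migrant" in set(log["reason"])
        assert not kept["species_id"].isin(removed).any()

    def test_no_flags_is_identity(self, tiny_records, tiny_traits):
        clean = tiny_traits.copy()
        for f in records.CLEANING_FLAGS:
            clean[f] = False
        kept, log = records.apply_phenological_filter(tiny_records, clean)
        pd.testing.assert_frame_equal(kept, tiny_records)
        assert log.empty

    def test_all_flagged_yields_empty_table(self, tiny_records, tiny_traits):
        allflag = tiny_traits.copy()
        allflag["strictly_diurnal"] = True
        kept, _ = records.apply_phenological_filter(tiny_records, allflag)
        assert kept.empty

    def test_unknown_species_policy(self, tiny_records, tiny_traits):
        missing = tiny_traits[tiny_traits["species_id"] != "reed_borer"]
        with pytest.raises(KeyError):
            records.apply_phenological_filter(tiny_records, missing, missing_species="error")
        kept, log = records.apply_phenological_filter(tiny_records, missing)
        assert "reed_borer" not in set(kept["species_id"])
        assert (log["reason"] == "absent_from_trait_table").any()

    @pytest.mark.parametrize("flag", records.CLEANING_FLAGS)
    def test_adding_a_flag_never_increases_survivors(self, tiny_records, tiny_traits, flag):
        base, _ = records.apply_phenological_filter(tiny_records, tiny_traits)
        flagged = tiny_traits.copy()
        flagged.loc[flagged["species_id"] == "oak_leafroller", flag] = True
        fewer, _ = records.apply_phenological_filter(tiny_records, flagged)
        assert len(fewer) <= len(base)


class TestTimeLayers:
    @pytest.mark.parametrize("year,label", [
        (1940, "1940s"), (1933, "1940s"), (1949, "1940s"),
        (1950, "1960s"), (1976, "1960s"),
        (1977, "1970s"), (1985, "1980s"), (1996, "1980s"),
        (2011, "2011"), (1997, "1997"),
    ])
    def test_default_scheme_assignment(self, scheme, year, label):
        df = pd.DataFrame({"species_id": ["a"], "year": [year], "source": ["x"]})
        out = records.assign_time_layers(df, scheme)
        assert out["layer"].iloc[0] == label

    def test_year_outside_all_layers_rejected(self, scheme):
        df = pd.DataFrame({"species_id": ["a", "b"], "year": [1920, 1940], "source": ["x", "x"]})
        out = records.assign_time_layers(df, scheme)
        assert list(out["species_id"]) == ["b"]

    def test_overlapping_layers_rejected(self):
        with pytest.raises(SchemaError, match="overlap"):
            TimeLayerScheme([TimeLayer("a", 1930, 1950), TimeLayer("b", 1950, 1960)])

    def test_inverted_layer_rejected(self):
        with pytest.raises(SchemaError):
            TimeLayer("bad", 1950, 1940)

    def test_scheme_from_dict_roundtrip(self):
        spec = {
            "layers": [{"label": "1940s", "year_min": 1933, "year_max": 1949}],
            "survey_years": [1997, 1998],
        }
        s = records.scheme_from_dict(spec)
        assert s.labels == ["1940s", "1997", "1998"]


class TestIncidence:
    def test_repeated_sightings_pool_to_single_cell(self, scheme):
        df = pd.DataFrame({"species_id": ["a"] * 3, "year": [1940, 1941, 1948], "source": ["m"] * 3})
        inc = records.build_incidence(records.assign_time_layers(df, scheme), scheme)
        assert inc.to_numpy().tolist() == [[1]]

    def test_identity_pattern(self, scheme):
        df = pd.DataFrame({"species_id": ["a", "b"], "year": [1940, 1999], "source": ["m", "s"]})
        inc = records.build_incidence(records.assign_time_layers(df, scheme), scheme)
        assert inc.loc["a", "1940s"] == 1 and inc.loc["b", "1999"] == 1
        assert inc.loc["a", "1999"] == 0 and inc.loc["b", "1940s"] == 0

    def test_record_order_invariance(self, tiny_records, scheme, rng):
        lab = records.assign_time_layers(tiny_records, scheme)
        inc1 = records.build_incidence(lab, scheme)
        shuffled = lab.sample(frac=1.0, random_state=7).reset_index(drop=True)
        inc2 = records.build_incidence(shuffled, scheme)
        pd.testing.assert_frame_equal(inc1, inc2)

    def test_columns_chronological(self, tiny_records, scheme):
        inc = records.build_incidence(records.assign_time_layers(tiny_records, scheme), scheme)
        order = [scheme.labels.index(c) for c in inc.columns]
        assert order == sorted(order)

    def test_empty_input_errors(self, scheme):
        with pytest.raises(ValueError):
            records.build_incidence(pd.DataFrame(columns=["species_id", "year", "source", "layer"]), scheme)


class TestStatus:
    def _inc(self, scheme, rows):
        df = pd.DataFrame(rows, columns=["species_id", "year", "source"])
        return records.build_incidence(records.assign_time_layers(df, scheme), scheme)

    def test_only_pre_cut_is_lost(self, scheme):
        inc = self._inc(scheme, [("a", 1940, "m"), ("b", 1999, "s")])
        st = records.assign_status(inc, scheme).set_index("species_id")["status"]
        assert st["a"] == "lost"
        assert st["b"] == "previously_unrecorded"

    def test_both_sides_is_persistent(self, scheme):
        inc = self._inc(scheme, [("a", 1986, "m"), ("a", 2011, "s")])
        st = records.assign_status(inc, scheme).set_index("species_id")["status"]
        assert st["a"] == "persistent"

    def test_cut_year_itself_counts_post(self, scheme):
        inc = self._inc(scheme, [("a", 1997, "s")])
        st = records.assign_status(inc, scheme, cut_year=1997)
        assert st["status"].iloc[0] == "previously_unrecorded"

    def test_categories_partition_species(self, small_pool, scheme, rng):
        rows = []
        for sp in small_pool["species_id"]:
            for y in rng.choice([1940, 1963, 1980, 1990, 1998, 2011], size=rng.integers(1, 5), replace=False):
                rows.append((sp, int(y), "x"))
        inc = self._inc(scheme, rows)
        st = records.assign_status(inc, scheme)
        assert len(st) == inc.shape[0]
        assert set(st["status"]).issubset(set(records.STATUSES))

    def test_straddling_layer_is_configuration_error(self):
        bad = TimeLayerScheme([TimeLayer("old", 1930, 1996), TimeLayer("mix", 1997, 2012)])
        df = pd.DataFrame({"species_id": ["a"], "year": [1940], "source": ["m"]})
        inc = records.build_incidence(records.assign_time_layers(df, bad), bad)
        with pytest.raises(SchemaError, match="straddles"):
            records.assign_status(inc, bad, cut_year=2000)

    def test_invariant_to_layer_merging_on_same_side(self, scheme):
        rows = [("a", 1940, "m"), ("a", 1963, "m"), ("b", 1999, "s"), ("c", 1940, "m"), ("c", 2011, "s")]
        st1 = records.assign_status(self._inc(scheme, rows), scheme).set_index("species_id")["status"]
        merged = TimeLayerScheme(
            [TimeLayer("historic", 1933, 1996)] + [TimeLayer(str(y), y, y) for y in records.DEFAULT_SURVEY_YEARS]
        )
        st2 = records.assign_status(self._inc(merged, rows), merged).set_index("species_id")["status"]
        pd.testing.assert_series_equal(st1, st2)
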