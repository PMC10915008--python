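"""Extract-Transform: header reporting, concatenation, joins, harmonization."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldpipe import etl_core
from fieldpipe.config_schema import EtlConfig
from fieldpipe.errors import DataError
from fieldpipe.etl_core import (
    SOURCE_COLUMN,
    apply_column_transforms,
    column_report,
    concatenate_files,
    discover_input_files,
    finalize_standard_table,
    join_additional_info,
    standardize_measurement,
    update_keys_and_rows,
)
from tests.conftest import write_csv


class TestDiscoverInputFiles:
    def test_lexicographic_order(self, tmp_path):
        write_csv(tmp_path / "b.csv", "x\n1")
        write_csv(tmp_path / "a.csv", "x\n1")
        assert [p.name for p in discover_input_files(tmp_path)] == ["a.csv", "b.csv"]

    def test_empty_directory_is_an_error(self, tmp_path):
        with pytest.raises(DataError, match="no CSV files"):
            discover_input_files(tmp_path)

    def test_non_csv_files_are_ignored(self, tmp_path):
        (tmp_path / "notes.txt").write_text("hello", encoding="utf-8")
        with pytest.raises(DataError, match="no CSV files"):
            discover_input_files(tmp_path)


class TestColumnReport:
    def test_shared_and_unique_partition(self, tmp_path):
        f1 = write_csv(tmp_path / "f1.csv", "A,B,C\n1,2,3")
        f2 = write_csv(tmp_path / "f2.csv", "A,B,D\n1,2,4")
        report = column_report([f1, f2])
        assert report.shared == {"A", "B"}
        assert report.per_file_unique == {"f1.csv": {"C"}, "f2.csv": {"D"}}

    def test_identical_headers_all_shared(self, tmp_path):
        files = [write_csv(tmp_path / f"f{i}.csv", "A,B\n1,2") for i in range(3)]
        report = column_report(files)
        assert report.shared == {"A", "B"}
        assert all(not s for s in report.per_file_unique.values())

    def test_single_file_everything_shared(self, tmp_path):
        report = column_report([write_csv(tmp_path / "only.csv", "A,B\n1,2")])
        assert report.shared == {"A", "B"}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    headers=st.lists(
        st.sets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=6), min_size=1, max_size=5
    )
)
def test_column_report_matches_set_algebra_oracle(tmp_path_factory, headers):
    """Independent oracle: shared = intersection of all header sets; unique = rest."""
    tmp = tmp_path_factory.mktemp("cols")
    files = []
    for i, cols in enumerate(headers):
        ordered = sorted(cols)
        files.append(write_csv(tmp / f"f{i}.csv", ",".join(ordered) + "\n" + ",".join("1" * len(ordered))))
    report = column_report(files)
    expected_shared = set.intersection(*headers)
    assert report.shared == expected_shared
    union = set.union(*headers)
    assert expected_shared | set.union(*report.per_file_unique.values(), set()) == union
    for unique in report.per_file_unique.values():
        assert not (unique & report.shared)


class TestConcatenateFiles:
    def test_row_counts_add_up(self, tmp_path):
        f1 = write_csv(tmp_path / "f1.csv", "x\n1\n2\n3")
        f2 = write_csv(tmp_path / "f2.csv", "x\n4\n5\n6\n7\n8")
        work = concatenate_files([f1, f2])
        assert len(work) == 8
        assert work[SOURCE_COLUMN].tolist() == ["f1.csv"] * 3 + ["f2.csv"] * 5

    def test_disjoint_value_columns_have_exactly_one_value_per_row(self, tmp_path):
        f1 = write_csv(tmp_path / "f1.csv", "plot,temp_C\n101,31.2\n102,30.8")
        f2 = write_csv(tmp_path / "f2.csv", "plot,spad\n101,44\n102,46")
        work = concatenate_files([f1, f2])
        counts = work[["temp_C", "spad"]].notna().sum(axis=1)
        assert (counts == 1).all()

    def test_header_only_file_contributes_columns_not_rows(self, tmp_path):
        f1 = write_csv(tmp_path / "f1.csv", "plot,height\n101,12")
        f2 = write_csv(tmp_path / "f2.csv", "plot,width")
        work = concatenate_files([f1, f2])
        assert len(work) == 1
        assert "width" in work.columns

    def test_permuting_input_order_preserves_row_multiset(self, tmp_path):
        files = [
            write_csv(tmp_path / "f1.csv", "plot,v\n101,1\n102,2"),
            write_csv(tmp_path / "f2.csv", "plot,v\n103,3"),
            write_csv(tmp_path / "f3.csv", "plot,v\n104,4\n105,5"),
        ]
        frames = []
        for order in itertools.permutations(files):
            frame = concatenate_files(list(order)).sort_values(["plot"]).reset_index(drop=True)
            frames.append(frame)
        for other in frames[1:]:
            pd.testing.assert_frame_equal(frames[0], other)


class TestJoinAdditionalInfo:
    @pytest.fixture
    def work(self, tmp_path):
        f = write_csv(
            tmp_path / "w.csv",
            "plot,v\n" + "\n".join(f"10{i},{i}" for i in range(8)),
        )
        return concatenate_files([f])

    def test_left_join_fills_lookup_columns(self, tmp_path, work):
        lookup = write_csv(
            tmp_path / "geno.csv", "plot,genotype\n" + "\n".join(f"10{i},G{i}" for i in range(8))
        )
        joined = join_additional_info(work, lookup, ["plot"])
        assert len(joined) == 8
        assert joined["genotype"].notna().all()

    def test_unmatched_lookup_rows_are_unused(self, tmp_path, work):
        lookup = write_csv(tmp_path / "geno.csv", "plot,genotype\n101,G1\n999,G9")
        joined = join_additional_info(work, lookup, ["plot"])
        assert len(joined) == 8
        assert "G9" not in set(joined["genotype"].dropna())

    def test_duplicate_key_in_lookup_is_an_error(self, tmp_path, work):
        lookup = write_csv(tmp_path / "geno.csv", "plot,genotype\n101,G1\n101,G2")
        with pytest.raises(DataError, match="101"):
            join_additional_info(work, lookup, ["plot"])


class TestStandardizeMeasurement:
    def test_moves_source_into_value_and_tags(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,temp_C\n101,31.2")])
        out = standardize_measurement(
            work, {"source_column": "temp_C", "variable_name": "canopy_temperature", "units": "C"}
        )
        assert "temp_C" not in out.columns
        assert out["value"].tolist() == ["31.2"]
        assert out["variable"].tolist() == ["canopy_temperature"]
        assert out["units"].tolist() == ["C"]

    def test_empty_block_is_a_no_op(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,v\n101,1")])
        pd.testing.assert_frame_equal(standardize_measurement(work, {}), work)

    def test_two_source_columns_cite_single_variable_limitation(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,a,b\n101,1,2")])
        with pytest.raises(DataError, match="separate steps"):
            standardize_measurement(
                work, {"source_column": ["a", "b"], "variable_name": "x", "units": "u"}
            )

    def test_conflicting_populated_value_column_is_an_error(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,value,temp\n101,9,31")])
        with pytest.raises(DataError, match="already present"):
            standardize_measurement(
                work, {"source_column": "temp", "variable_name": "x", "units": "u"}
            )


class TestApplyColumnTransforms:
    def test_divergent_spellings_unify_to_one_column(self, tmp_path):
        spellings = ["LAI", "Leaf Area Index", "lai", "leaf area index"]
        files = [
            write_csv(tmp_path / f"f{i}.csv", f"plot,{s}\n1{i}1,{i}.5")
            for i, s in enumerate(spellings)
        ]
        work = concatenate_files(files)
        config = EtlConfig(
            files_to_process=str(tmp_path),
            update_column_names={s: "leaf_area_index" for s in spellings},
        )
        out = apply_column_transforms(work, config)
        trait_cols = [c for c in out.columns if "lai" in c.lower() or "leaf" in c.lower()]
        assert trait_cols == ["leaf_area_index"]
        assert out["leaf_area_index"].notna().all()

    def test_drop_removes_column_and_tolerates_absent_names(self, tmp_path, caplog):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,bag dry weight,net\n101,12,9")])
        config = EtlConfig(
            files_to_process=str(tmp_path), columns_to_drop=["bag dry weight", "ghost"]
        )
        out = apply_column_transforms(work, config)
        assert "bag dry weight" not in out.columns
        assert "net" in out.columns

    def test_add_constant_column(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot\n101\n102")])
        config = EtlConfig(files_to_process=str(tmp_path), new_columns={"season": "2022"})
        out = apply_column_transforms(work, config)
        assert out["season"].tolist() == ["2022", "2022"]

    def test_rename_onto_untouched_existing_column_is_an_error(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,a,b\n101,1,2")])
        config = EtlConfig(files_to_process=str(tmp_path), update_column_names={"a": "b"})
        with pytest.raises(DataError, match="collides"):
            apply_column_transforms(work, config)

    def test_rename_is_idempotent_on_its_own_output(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,LAI\n101,2.5")])
        config = EtlConfig(
            files_to_process=str(tmp_path), update_column_names={"LAI": "leaf_area_index"}
        )
        once = apply_column_transforms(work, config)
        twice = apply_column_transforms(once, config)
        pd.testing.assert_frame_equal(once, twice)

    def test_untouched_columns_are_byte_identical(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "plot,keep,old\n007,x y,1")])
        config = EtlConfig(files_to_process=str(tmp_path), update_column_names={"old": "new"})
        out = apply_column_transforms(work, config)
        assert out["keep"].tolist() == work["keep"].tolist()
        assert out["plot"].tolist() == ["007"]


class TestUpdateKeysAndRows:
    def test_substring_replacement_on_primary_key(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "id,v\nPLT_101_1,3")])
        config = EtlConfig(
            files_to_process=str(tmp_path),
            primary_key_column="id",
            update_primary_key_values={"PLT": "PLOT"},
        )
        out = update_keys_and_rows(work, config)
        assert out["id"].tolist() == ["PLOT_101_1"]

    def test_row_values_replaced_whole_cell_only(self, tmp_path):
        work = concatenate_files(
            [write_csv(tmp_path / "f.csv", "id,treatment\n1,EP\n2,DEEP\n3,EP")]
        )
        config = EtlConfig(
            files_to_process=str(tmp_path),
            primary_key_column="id",
            update_row_values={"treatment": {"EP": "early_planting"}},
        )
        out = update_keys_and_rows(work, config)
        assert out["treatment"].tolist() == ["early_planting", "DEEP", "early_planting"]

    def test_replacement_causing_key_collision_is_an_error(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "id,v\nA1,1\nB1,2")])
        config = EtlConfig(
            files_to_process=str(tmp_path),
            primary_key_column="id",
            update_primary_key_values={"A": "B"},
        )
        with pytest.raises(DataError, match="duplicate"):
            update_keys_and_rows(work, config)

    def test_replacements_apply_in_document_order(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "id,v\nAB_1,1")])
        config = EtlConfig(
            files_to_process=str(tmp_path),
            primary_key_column="id",
            update_primary_key_values={"AB": "C", "C": "D"},
        )
        out = update_keys_and_rows(work, config)
        assert out["id"].tolist() == ["D_1"]


class TestFinalizeStandardTable:
    def test_writes_named_output_without_provenance(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "in" / "f.csv", "id,v\n101_1,3\n101_2,4")])
        config = EtlConfig(
            files_to_process=str(tmp_path / "in"),
            primary_key_column="id",
            output_file_name=["wheat", "canopy_temperature", "2022"],
        )
        out = finalize_standard_table(work, config, tmp_path / "out")
        assert out.name == "wheat_canopy_temperature_2022.csv"
        back = pd.read_csv(out, dtype=str)
        assert SOURCE_COLUMN not in back.columns
        assert len(back) == 2

    def test_duplicate_primary_key_names_the_offender(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "id,v\nX_1,3\nX_1,4")])
        config = EtlConfig(files_to_process=str(tmp_path), primary_key_column="id")
        with pytest.raises(DataError, match="X_1"):
            finalize_standard_table(work, config, tmp_path / "out")

    def test_value_without_units_is_an_error(self, tmp_path):
        work = concatenate_files([write_csv(tmp_path / "f.csv", "id,value,variable\n1,3,height")])
        config = EtlConfig(files_to_process=str(tmp_path), primary_key_column="id")
        with pytest.raises(DataError, match="units"):
            finalize_standard_table(work, config, tmp_path / "out")


def test_run_etl_conserves_rows_end_to_end(tmp_path):
    """With empty transforms the output row count equals the sum of the inputs'."""
    in_dir = tmp_path / "in"
    write_csv(in_dir / "a.csv", "id,v\n" + "\n".join(f"A{i},{i}" for i in range(5)))
    write_csv(in_dir / "b.csv", "id,v\n" + "\n".join(f"B{i},{i}" for i in range(7)))
    config = EtlConfig(
        files_to_process=str(in_dir), primary_key_column="id", output_file_name=["merged"]
    )
    out = etl_core.run_etl(config, tmp_path / "out")
    assert len(pd.read_csv(out)) == 12
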