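import logging

import pandas as pd
import pytest

import bfhc
from bfhc.dataset import (
    CARCINOGENICITY_LABELS,
    PAHRecord,
    cross_validate,
    decode_carcinogenicity,
    encode_carcinogenicity,
    read_table,
    summarize,
    write_table,
)
from bfhc.errors import DatasetError
from bfhc.structure_io import write_xyz

from conftest import analyzed, built


def record_for(name, xyz_file="", **extra):
    res = analyzed(name)
    bay, fjord, harbor, canyon = res.bfhc()
    return PAHRecord(
        id=name, iupac_name=name, xyz_file=xyz_file,
        n_carbon=res.n_carbon, n_hydrogen=res.n_hydrogen,
        bay=bay, fjord=fjord, harbor=harbor, canyon=canyon,
        topology=res.topology, **extra,
    )


@pytest.fixture
def structure_dir(tmp_path):
    names = ["phenanthrene", "pyrene", "hexahelicene"]
    for name in names:
        write_xyz(built(name).molecule, tmp_path / f"{name}.xyz")
    return tmp_path, names


class TestEncoding:
    @pytest.mark.parametrize(
        "label, ordinal",
        [("-", 0), ("±", 1), ("L", 2), ("LM", 3), ("M", 4), ("HM", 5), ("H", 6)],
    )
    def test_seven_level_order(self, label, ordinal):
        assert encode_carcinogenicity(label) == ordinal

    def test_plus_alias_maps_to_lm(self):
        assert encode_carcinogenicity("+") == 3

    def test_unicode_dash_variants(self):
        assert encode_carcinogenicity("–") == 0  # en dash
        assert encode_carcinogenicity("−") == 0  # minus sign

    def test_collapse_l_to_negative(self):
        assert encode_carcinogenicity("L", collapse_L_to_negative=True) == 0
        assert encode_carcinogenicity("LM", collapse_L_to_negative=True) == 3

    def test_unknown_label(self):
        with pytest.raises(DatasetError, match="unknown carcinogenicity"):
            encode_carcinogenicity("X")

    def test_encode_decode_identity_and_monotone(self):
        ordinals = [encode_carcinogenicity(l) for l in CARCINOGENICITY_LABELS]
        assert ordinals == sorted(ordinals) == list(range(7))
        for label in CARCINOGENICITY_LABELS:
            assert decode_carcinogenicity(encode_carcinogenicity(label)) == label


class TestReadWriteTable:
    def test_two_row_toy_table(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "id,carcinogenicity,log_p\n"
            "bp,-,6.5\n"
            "dbalp,H,\n"
        )
        records = read_table(path)
        assert len(records) == 2
        assert records[0].carcinogenicity == "-"
        assert records[1].carcinogenicity == "H"
        assert records[1].log_p is None

    def test_unknown_label_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,carcinogenicity\na,-\nb,X\n")
        with pytest.raises(DatasetError, match="row 3"):
            read_table(path)

    def test_plus_alias_logged(self, tmp_path, caplog):
        path = tmp_path / "alias.csv"
        path.write_text("id,carcinogenicity\na,+\n")
        with caplog.at_level(logging.INFO, logger="bfhc.dataset"):
            records = read_table(path)
        assert records[0].carcinogenicity == "LM"
        assert any("alias" in r.message for r in caplog.records)

    def test_missing_required_columns(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("iupac_name,log_p\nx,1.0\n")
        with pytest.raises(DatasetError, match="missing required"):
            read_table(path)

    def test_non_integer_bfhc_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,carcinogenicity,bay\na,-,1.5\n")
        with pytest.raises(DatasetError, match="non-integer bay"):
            read_table(path)

    def test_header_spacing_and_case_insensitive(self, tmp_path):
        path = tmp_path / "odd.csv"
        path.write_text("ID,Carcinogenicity,Log P,Number of Carbons\na,M,3.1,20\n")
        record = read_table(path)[0]
        assert record.log_p == pytest.approx(3.1)
        assert record.n_carbon == 20

    def test_column_map_override(self, tmp_path):
        path = tmp_path / "deposited.csv"
        path.write_text("Compound ID,Potency,B count\na,HM,2\n")
        records = read_table(
            path,
            column_map={
                "compound_id": "id", "potency": "carcinogenicity",
                "b_count": "bay",
            },
        )
        assert records[0].bay == 2
        assert records[0].carcinogenicity == "HM"

    def test_round_trip(self, tmp_path):
        records = [
            record_for("phenanthrene", carcinogenicity="LM", log_p=4.46),
            record_for("pyrene", carcinogenicity="-"),
        ]
        path = tmp_path / "t.csv"
        write_table(records, path)
        assert read_table(path) == records

    def test_xlsx_ingest(self, tmp_path):
        frame = pd.DataFrame(
            {"id": ["a"], "carcinogenicity": ["M"], "log_iball": [1.9]}
        )
        path = tmp_path / "t.xlsx"
        frame.to_excel(path, index=False)
        records = read_table(path)
        assert records[0].log_iball == pytest.approx(1.9)


class TestCrossValidate:
    def test_self_consistent_table(self, structure_dir):
        directory, names = structure_dir
        records = [record_for(n, xyz_file=f"{n}.xyz") for n in names]
        report = cross_validate(records, directory)
        assert report.ok()
        assert report.n_valid == len(names)

    def test_fault_injection(self, structure_dir):
        directory, names = structure_dir
        records = [record_for(n, xyz_file=f"{n}.xyz") for n in names]
        records[0].bay += 1
        report = cross_validate(records, directory)
        assert len(report.count_mismatches) == 1
        rec_id, field_name, recorded, recomputed = report.count_mismatches[0]
        assert (rec_id, field_name) == (names[0], "bay")
        assert recorded == recomputed + 1

    def test_missing_structure_is_not_fatal(self, structure_dir):
        directory, names = structure_dir
        records = [record_for(n, xyz_file=f"{n}.xyz") for n in names]
        records[1].xyz_file = "nowhere.xyz"
        report = cross_validate(records, directory)
        assert report.unreadable == [names[1]]
        assert report.n_valid == len(names) - 1

    def test_never_mutates_records(self, structure_dir):
        directory, names = structure_dir
        records = [record_for(n, xyz_file=f"{n}.xyz") for n in names]
        records[0].canyon = 9
        cross_validate(records, directory)
        assert records[0].canyon == 9


class TestSummarize:
    def test_missing_counts(self):
        records = [
            record_for("phenanthrene", log_p=4.46),
            record_for("pyrene", log_p=4.88, log_iball=1.0),
            record_for("hexahelicene"),
        ]
        stats = summarize(records)
        assert stats["n_records"] == 3
        assert stats["n_log_p"] == 2
        assert stats["n_log_iball"] == 1

    def test_distinct_labels(self):
        records = [
            record_for("phenanthrene", carcinogenicity="-"),
            record_for("pyrene", carcinogenicity="±"),
            record_for("hexahelicene", carcinogenicity="H"),
        ]
        assert summarize(records)["distinct_carcinogenicity_labels"] == 3

    def test_permutation_invariant(self):
        records = [
            record_for("phenanthrene", carcinogenicity="-"),
            record_for("pyrene", log_p=4.88),
            record_for("hexahelicene", carcinogenicity="H"),
        ]
        assert summarize(records) == summarize(records[::-1])

    def test_empty_rejected(self):
        with pytest.raises(DatasetError):
            summarize([])
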