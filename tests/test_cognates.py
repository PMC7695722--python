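"""Cognate curation, binarization and matrix I/O."""

import numpy as np
import pytest

import phylolex as px
from phylolex.cognates import (ClassLabel, CognateDataset, MISSING,
                               compress_patterns, exclude_taxa,
                               multistate_to_binary, read_binary_nexus,
                               read_cognate_table, remove_loans,
                               write_binary_nexus, write_cognate_table)

TOY_CSV = """language,concept,cognate_class,is_loan
Lang1,hand,A,0
Lang2,hand,A,0
Lang3,hand,B,0
Lang4,hand,B,1
Lang1,water,W1,0
Lang2,water,W1,0
Lang3,water,W2,0
Lang4,water,W2,0
"""


class TestReadCognateTable:
    def test_toy_csv_readback(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(TOY_CSV)
        ds = read_cognate_table(path, "csv")
        assert ds.languages == ["Lang1", "Lang2", "Lang3", "Lang4"]
        assert ds.concepts == ["hand", "water"]
        assert ds.n_loans == 1
        assert ds.classes("Lang4", "hand") == frozenset(
            [ClassLabel("B", True)])

    def test_empty_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_cognate_table(path, "csv")

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("language,concept,cognate_class,is_loan\n"
                        "A,hand,x,0\nA,hand,x,0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cognate_table(path, "csv")

    def test_unparseable_loan_flag_raises_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("language,concept,cognate_class,is_loan\n"
                        "A,hand,x,maybe\n")
        with pytest.raises(ValueError, match=":2"):
            read_cognate_table(path, "csv")

    def test_nexus_multistate_dialect(self, tmp_path):
        path = tmp_path / "multi.nex"
        path.write_text(
            "#NEXUS\nBEGIN DATA;\n"
            "DIMENSIONS NTAX=3 NCHAR=2;\n"
            "FORMAT DATATYPE=STANDARD SYMBOLS=\"0123\" MISSING=?;\n"
            "MATRIX\nLa 01\nLb 0?\nLc 21\n;\nEND;\n")
        ds = read_cognate_table(path, "nexus-multistate",
                                tip_dates={"La": 1.5})
        assert ds.languages == ["La", "Lb", "Lc"]
        assert len(ds.concepts) == 2
        assert ds.classes("La", ds.concepts[1]) == frozenset(
            [ClassLabel("1")])
        assert ds.classes("Lb", ds.concepts[1]) == frozenset()  # missing
        assert ds.tip_dates["La"] == 1.5

    def test_synthetic_round_trip(self, tmp_path):
        cfg = px.SimulationConfig(seed=5, n_concepts=8, root_age=3.0,
                                  fbd=px.FBDParams(1.2, 0.2, 0.3, 0.9),
                                  loan_rate=0.1, synonym_rate=0.1,
                                  missing_rate=0.1)
        ds, _ = px.make_cognate_dataset(cfg)
        path = tmp_path / "sim.csv"
        write_cognate_table(ds, path)
        back = read_cognate_table(path, "csv", tip_dates=dict(ds.tip_dates))
        assert back == ds


class TestExcludeTaxa:
    @pytest.fixture
    def six_lang(self):
        langs = [f"L{i}" for i in range(6)]
        entries = {(l, "hand"): frozenset([ClassLabel("A")]) for l in langs}
        return CognateDataset(langs, ["hand"], entries)

    def test_remove_two_of_six(self, six_lang):
        out = exclude_taxa(six_lang, ["L0", "L5"])
        assert out.languages == ["L1", "L2", "L3", "L4"]
        assert out.excluded_taxa == ["L0", "L5"]
        assert ("L0", "hand") not in out.entries

    def test_remove_none_is_identity(self, six_lang):
        assert exclude_taxa(six_lang, []) == six_lang

    def test_duplicate_name_errors(self, six_lang):
        with pytest.raises(ValueError, match="duplicate"):
            exclude_taxa(six_lang, ["L1", "L1"])

    def test_unknown_name_errors(self, six_lang):
        with pytest.raises(ValueError, match="Lx"):
            exclude_taxa(six_lang, ["Lx"])


class TestRemoveLoans:
    def test_loan_dropped_from_mixed_entry(self):
        ds = CognateDataset(
            ["L1"], ["hand"],
            {("L1", "hand"): frozenset([ClassLabel("A", True),
                                        ClassLabel("B")])})
        out = remove_loans(ds)
        assert out.classes("L1", "hand") == frozenset([ClassLabel("B")])

    def test_loan_only_entry_becomes_missing(self):
        ds = CognateDataset(
            ["L1"], ["hand"],
            {("L1", "hand"): frozenset([ClassLabel("A", True)])})
        out = remove_loans(ds)
        assert ("L1", "hand") not in out.entries

    def test_no_flags_identity_and_idempotence(self, toy_dataset):
        once = remove_loans(toy_dataset)
        assert once == toy_dataset
        assert remove_loans(once) == once


class TestBinarization:
    def test_worked_example_columns(self, toy_dataset):
        bm = multistate_to_binary(toy_dataset)
        assert bm.columns == [("hand", "A"), ("hand", "B")]
        assert bm.column("hand", "A").tolist() == [1, 1, 0, 1, MISSING]
        assert bm.column("hand", "B").tolist() == [0, 0, 1, 1, MISSING]

    def test_shared_class_gives_all_ones(self):
        langs = ["L1", "L2", "L3"]
        ds = CognateDataset(
            langs, ["hand"],
            {(l, "hand"): frozenset([ClassLabel("A")]) for l in langs})
        bm = multistate_to_binary(ds)
        assert bm.n_cognate_sets == 1
        assert bm.values.tolist() == [[1], [1], [1]]

    def test_empty_dataset_errors(self):
        ds = CognateDataset(["L1"], ["hand"], {})
        with pytest.raises(ValueError):
            multistate_to_binary(ds)

    def test_binarization_conserves_multistate_assignment(self):
        cfg = px.SimulationConfig(seed=3, n_concepts=10, root_age=3.0,
                                  fbd=px.FBDParams(1.2, 0.2, 0.3, 0.9),
                                  loan_rate=0.0, synonym_rate=0.1,
                                  missing_rate=0.1)
        ds, _ = px.make_cognate_dataset(cfg)
        bm = multistate_to_binary(ds)
        for i, lang in enumerate(bm.languages):
            for con in ds.concepts:
                ones = {lbl for j, (c, lbl) in enumerate(bm.columns)
                        if c == con and bm.values[i, j] == 1}
                expect = {c.label for c in ds.classes(lang, con)}
                assert ones == expect

    def test_column_count_invariant_under_language_reorder(self, toy_dataset):
        ds = toy_dataset
        reordered = CognateDataset(list(reversed(ds.languages)), ds.concepts,
                                   ds.entries)
        assert (multistate_to_binary(ds).n_cognate_sets
                == multistate_to_binary(reordered).n_cognate_sets)


class TestCompressPatterns:
    def test_duplicate_columns_merge(self):
        bm = px.BinaryMatrix(["a", "b"], [("c", "x"), ("c", "y")],
                             np.array([[1, 1], [0, 0]], dtype=np.int8))
        pats = compress_patterns(bm)
        assert pats.n_patterns == 1
        assert pats.weights.tolist() == [2]
        assert pats.n_sites == 2

    def test_distinct_columns_weight_one(self, toy_dataset):
        pats = compress_patterns(multistate_to_binary(toy_dataset))
        assert pats.n_patterns == 2
        assert all(w == 1 for w in pats.weights)


class TestBinaryNexus:
    def test_round_trip_with_missing(self, tmp_path):
        values = np.array([[1, 0], [0, MISSING], [1, 1]], dtype=np.int8)
        bm = px.BinaryMatrix(["La", "Lb", "Lc"],
                             [("c1", "A"), ("c1", "B")], values)
        path = tmp_path / "m.nex"
        write_binary_nexus(bm, path)
        back = read_binary_nexus(path)
        assert back.languages == bm.languages
        assert np.array_equal(back.values, bm.values)

    def test_external_parser_reads_synthetic_matrix(self, tmp_path):
        # independent reader: Biopython's NEXUS module, not dendropy
        from Bio.Nexus import Nexus
        cfg = px.SimulationConfig(seed=1, n_concepts=20, root_age=4.0,
                                  fbd=px.FBDParams(1.0, 0.2, 0.2, 0.9),
                                  missing_rate=0.1)
        ds, _ = px.make_cognate_dataset(cfg)
        bm = multistate_to_binary(remove_loans(ds))
        path = tmp_path / "sim.nex"
        write_binary_nexus(bm, path)
        nex = Nexus.Nexus(str(path))
        assert len(nex.taxlabels) == len(bm.languages)
        assert nex.nchar == bm.n_cognate_sets
        row = str(nex.matrix[nex.taxlabels[0]])
        expected = "".join({0: "0", 1: "1", MISSING: "?"}[v]
                           for v in bm.values[0])
        assert row == expected
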