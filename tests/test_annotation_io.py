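"""Parser behaviour across the supported annotation dialects."""

from __future__ import annotations

import gzip
import random

import pytest

from mycoenrich.annotation_io import (
    ColumnConfigError,
    FormatError,
    normalize_go_accession,
    normalize_namespace,
    parse_eggnog_annotation,
    parse_go_annotation,
    parse_kegg_annotation,
    parse_ko_link,
    parse_kog_annotation,
    parse_obo,
)

KOG_HEADER = ["#proteinId", "kogid", "kogdefline", "kogClass", "kogLetter"]
GO_HEADER = ["#proteinId", "gotermId", "goName", "gotermType"]
KEGG_HEADER = ["#proteinId", "ecNum", "definition", "pathway", "pathway_class", "pathway_type"]


class TestKogParser:
    def test_single_row(self, write_tsv):
        path = write_tsv("kog.tsv", [KOG_HEADER, ["p1", "KOG1", "def", "Metabolism", "E"]])
        records = parse_kog_annotation(path)
        assert len(records) == 1
        r = records[0]
        assert (r.protein_id, r.category_id, r.category_group) == ("p1", "E", "Metabolism")
        assert r.source == "kog"

    def test_duplicate_rows_collapse(self, write_tsv):
        rows = [KOG_HEADER] + [["p1", "KOG1", "def", "Metabolism", "E"]] * 2
        assert len(parse_kog_annotation(write_tsv("kog.tsv", rows))) == 1

    def test_multi_letter_protein_yields_two_records(self, write_tsv):
        rows = [KOG_HEADER,
                ["p1", "KOG1", "d1", "Metabolism", "E"],
                ["p1", "KOG2", "d2", "Metabolism", "G"]]
        records = parse_kog_annotation(write_tsv("kog.tsv", rows))
        assert {(r.protein_id, r.category_id) for r in records} == {("p1", "E"), ("p1", "G")}

    def test_missing_required_column_names_it(self, write_tsv):
        path = write_tsv("kog.tsv", [["#proteinId", "kogid"], ["p1", "KOG1"]])
        with pytest.raises(ColumnConfigError, match="kog_letter"):
            parse_kog_annotation(path)

    def test_column_map_override(self, write_tsv):
        rows = [["#prot", "letter"], ["p1", "E"]]
        records = parse_kog_annotation(
            write_tsv("kog.tsv", rows),
            column_map={"prot": "protein_id", "letter": "kog_letter"},
        )
        assert records[0].category_id == "E"
        # class falls back to the canonical letter table when absent
        assert records[0].category_group == "Metabolism"

    def test_empty_file_yields_empty_sequence(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_kog_annotation(path) == []

    def test_gzip_input(self, tmp_path):
        path = tmp_path / "kog.tsv.gz"
        content = "\t".join(KOG_HEADER) + "\np1\tKOG1\td\tMetabolism\tE\n"
        with gzip.open(path, "wt") as fh:
            fh.write(content)
        assert len(parse_kog_annotation(path)) == 1

    def test_row_shuffle_invariance(self, write_tsv):
        data = [["p%d" % i, "KOG1", "d", "Metabolism", letter]
                for i, letter in enumerate("EGCQPE")]
        records_a = parse_kog_annotation(write_tsv("a.tsv", [KOG_HEADER] + data))
        random.Random(0).shuffle(data)
        records_b = parse_kog_annotation(write_tsv("b.tsv", [KOG_HEADER] + data))
        assert set(records_a) == set(records_b)


class TestGoParser:
    def test_numeric_id_normalized_to_root_accession(self, write_tsv):
        path = write_tsv("go.tsv", [GO_HEADER, ["p1", "8150", "bp root", "biological_process"]])
        records, skipped = parse_go_annotation(path)
        assert skipped == 0
        assert records[0].category_id == "GO:0008150"
        assert records[0].category_group == "biological_process"

    def test_namespace_with_space_normalized(self, write_tsv):
        path = write_tsv("go.tsv", [GO_HEADER, ["p1", "GO:0005575", "cc root", "cellular component"]])
        records, _ = parse_go_annotation(path)
        assert records[0].category_group == "cellular_component"

    def test_malformed_accession_skipped_and_counted(self, write_tsv):
        rows = [GO_HEADER,
                ["p1", "GO:0008150", "a", "biological_process"],
                ["p2", "not-a-go", "b", "biological_process"],
                ["p3", "3674", "c", "molecular_function"],
                ["p4", "GO:0005575", "d", "cellular_component"]]
        records, skipped = parse_go_annotation(write_tsv("go.tsv", rows))
        assert (len(records), skipped) == (3, 1)

    @pytest.mark.parametrize("raw,expected", [
        ("GO:0008150", "GO:0008150"),
        ("8150", "GO:0008150"),
        ("0008150", "GO:0008150"),
        ("go:0003674", "GO:0003674"),
        ("banana", None),
        ("GO:12345678", None),
        ("", None),
    ])
    def test_accession_normalization(self, raw, expected):
        assert normalize_go_accession(raw) == expected

    def test_namespace_normalization(self):
        assert normalize_namespace("Biological Process") == "biological_process"
        assert normalize_namespace("MF") == "molecular_function"
        assert normalize_namespace("nonsense") is None


class TestKeggParser:
    FULL_ROW = ["p1", "1.1.1.1", "alcohol dehydrogenase", "Glycolysis",
                "Carbohydrate metabolism", "Metabolism"]

    def test_full_row_yields_four_axis_records(self, write_tsv):
        records = parse_kegg_annotation(write_tsv("k.tsv", [KEGG_HEADER, self.FULL_ROW]))
        by_axis = {r.category_group: r for r in records}
        assert set(by_axis) == {"pathway_type", "pathway_class", "pathway_name", "enzyme"}
        assert by_axis["pathway_name"].category_id == "Glycolysis"
        assert by_axis["enzyme"].category_id == "1.1.1.1"
        assert by_axis["enzyme"].category_label == "alcohol dehydrogenase"

    def test_ec_only_row_yields_enzyme_record_only(self, write_tsv):
        row = ["p1", "1.1.1.1", "alcohol dehydrogenase", "", "", ""]
        records = parse_kegg_annotation(write_tsv("k.tsv", [KEGG_HEADER, row]))
        assert len(records) == 1
        assert records[0].category_group == "enzyme"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "k.tsv"
        path.write_text("")
        assert parse_kegg_annotation(path) == []


class TestKoLinkParser:
    def test_prefix_stripping(self, tmp_path):
        path = tmp_path / "link.tsv"
        path.write_text("tre:TRIREDRAFT_1\tko:K00001\n")
        assert parse_ko_link(path) == [("TRIREDRAFT_1", "K00001")]

    def test_duplicate_pairs_collapse(self, tmp_path):
        path = tmp_path / "link.tsv"
        path.write_text("tre:g1\tko:K00001\ntre:g1\tko:K00001\n")
        assert len(parse_ko_link(path)) == 1

    def test_malformed_line_skipped(self, tmp_path):
        path = tmp_path / "link.tsv"
        path.write_text("tre:g1\tko:K00001\nno-tab-here\ntre:g2\tko:K00002\ntre:g3\tko:K00003\n")
        assert len(parse_ko_link(path)) == 3


class TestEggnogParser:
    HEADER = "#query\tseed_ortholog\tevalue\tscore\tCOG_category\tGOs\tEC\tKEGG_ko\tKEGG_Pathway"

    def _write(self, tmp_path, rows):
        path = tmp_path / "x.emapper.annotations"
        path.write_text("## comment\n" + self.HEADER + "\n" + "\n".join(rows) + "\n")
        return path

    def test_multi_letter_cog_explodes(self, tmp_path):
        path = self._write(tmp_path, ["q1\to\t1e-5\t10\tEG\t-\t-\t-\t-"])
        rec = parse_eggnog_annotation(path)[0]
        assert set(rec.cog_letters) == {"E", "G"}
        assert len(rec.cog_letters) == len(set(rec.cog_letters))

    def test_dash_sentinel_yields_empty_sets(self, tmp_path):
        path = self._write(tmp_path, ["q1\to\t1e-5\t10\t-\t-\t-\t-\t-"])
        rec = parse_eggnog_annotation(path)[0]
        assert rec.go_ids == frozenset()
        assert rec.kegg_kos == frozenset()
        assert rec.ec_numbers == frozenset()
        assert "-" not in rec.kegg_pathways

    def test_ko_prefix_split_and_strip(self, tmp_path):
        path = self._write(tmp_path, ["q1\to\t1e-5\t10\t-\t-\t-\tko:K00001,ko:K00002\t-"])
        rec = parse_eggnog_annotation(path)[0]
        assert rec.kegg_kos == {"K00001", "K00002"}

    def test_missing_header_is_format_error(self, tmp_path):
        path = tmp_path / "bad.annotations"
        path.write_text("q1\to\t1e-5\t10\tE\t-\t-\t-\t-\n")
        with pytest.raises(FormatError):
            parse_eggnog_annotation(path)


class TestOboParser:
    CHAIN = """format-version: 1.2

[Term]
id: GO:0000001
name: A
namespace: biological_process

[Term]
id: GO:0000002
name: B
namespace: biological_process
is_a: GO:0000001 ! A

[Term]
id: GO:0000003
name: C
namespace: biological_process
is_a: GO:0000002 ! B
"""

    def test_chain_parses_to_three_node_dag(self, tmp_path):
        path = tmp_path / "chain.obo"
        path.write_text(self.CHAIN)
        dag = parse_obo(path)
        assert dag.terms == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert sum(len(v) for v in dag.parent_edges.values()) == 2

    def test_obsolete_term_excluded(self, tmp_path):
        path = tmp_path / "obs.obo"
        path.write_text(self.CHAIN + "\n[Term]\nid: GO:0000004\nname: dead\n"
                        "namespace: biological_process\nis_obsolete: true\n")
        assert "GO:0000004" not in parse_obo(path).terms

    def test_part_of_relationship_edge(self, tmp_path):
        path = tmp_path / "po.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: A\n"
            "namespace: biological_process\n\n[Term]\nid: GO:0000002\nname: B\n"
            "namespace: biological_process\nrelationship: part_of GO:0000001 ! A\n"
        )
        dag = parse_obo(path)
        assert dag.parent_edges["GO:0000002"] == {("GO:0000001", "part_of")}

    def test_alt_id_becomes_alias(self, tmp_path):
        path = tmp_path / "alias.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: A\n"
            "namespace: biological_process\nalt_id: GO:0009999\n"
        )
        dag = parse_obo(path)
        assert dag.resolve("GO:0009999") == "GO:0000001"

    def test_cycle_is_hard_error(self, tmp_path):
        path = tmp_path / "cycle.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: A\n"
            "namespace: biological_process\nis_a: GO:0000002 ! B\n\n"
            "[Term]\nid: GO:0000002\nname: B\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! A\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            parse_obo(path)
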