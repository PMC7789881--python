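from collections import Counter

import networkx as nx
import pytest

from formularank import data_io
from formularank.data_io import (ComponentRecord, DiseaseGeneTable, ParseError,
                                 SchemaError, normalize_name, read_component_table,
                                 read_disease_genes, read_edge_list, read_gene_sets,
                                 read_target_map)

HEADER = "record_id\tname\therb\trole\tmw\talogp\thdon\thacc\tcaco2\tob\tdl\n"


def _write(tmp_path, body, name="table.tsv", header=HEADER):
    p = tmp_path / name
    p.write_text(header + body, encoding="utf-8")
    return p


class TestComponentTable:
    def test_identity_parse_preserves_row_order(self, tmp_path):
        p = _write(tmp_path,
                   "r1\tAlpha\tH1\t\t100\t1.2\t2\t3\t0.5\t40\t0.5\n"
                   "r2\tBeta\tH1\t\t200\t0.1\t0\t1\t0.9\t35\t0.2\n"
                   "r3\tGamma\tH2\t\t300\t2.0\t1\t2\t0.1\t60\t0.8\n")
        records = read_component_table(p)
        assert [r.name for r in records] == ["Alpha", "Beta", "Gamma"]
        assert records[0].mw == 100 and records[0].hdon == 2
        assert records[2].herb == "H2"

    def test_missing_column_is_schema_error_naming_it(self, tmp_path):
        p = _write(tmp_path, "x\tH1\t1\t1\t1\t1\t1\t40\n",
                   header="name\therb\tmw\talogp\thdon\thacc\tcaco2\tob\n")
        with pytest.raises(SchemaError, match="dl"):
            read_component_table(p)

    def test_unparseable_cell_cites_row_number(self, tmp_path):
        rows = "".join(f"r{i}\tC{i}\tH\t\t\t\t\t\t\t40\t0.5\n" for i in range(1, 4))
        rows += "r4\tC4\tH\t\t\t\t\t\t\t40\tabc\n"
        p = _write(tmp_path, rows)
        with pytest.raises(ParseError, match="row 5"):
            read_component_table(p)

    def test_missing_optional_descriptors_allowed(self, tmp_path):
        p = _write(tmp_path, "r1\tA\tH\t\t\t\t\t\t\t40\t0.5\n")
        (rec,) = read_component_table(p)
        assert rec.mw is None and rec.caco2 is None
        assert rec.ob == 40 and rec.dl == 0.5

    def test_round_trip(self, tmp_path, fixture_records):
        out = tmp_path / "rt.tsv"
        data_io.write_component_table(fixture_records, out)
        assert read_component_table(out) == fixture_records

    def test_csv_dialect(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,herb,mw,alogp,hdon,hacc,caco2,ob,dl\nA,H,,,,,,40,0.5\n")
        assert len(read_component_table(p)) == 1


class TestPackagedFixture:
    def test_record_and_herb_counts(self, fixture_records):
        assert len(fixture_records) == 114
        counts = Counter(r.herb for r in fixture_records)
        assert counts == {"Huanglian": 15, "Huangqin": 39, "Huangbo": 40, "Zhizi": 20}

    def test_role_labels_follow_herbs(self, fixture_records):
        roles = {r.herb: r.role_label for r in fixture_records}
        assert roles == {"Huanglian": "Jun", "Huangqin": "Chen",
                         "Huangbo": "Chen", "Zhizi": "Zuo"}


class TestComponentRecordValidation:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(name=" ", herb="H", ob=1, dl=0.5), "name"),
        (dict(name="A", herb="", ob=1, dl=0.5), "herb"),
        (dict(name="A", herb="H", ob=-1, dl=0.5), "ob"),
        (dict(name="A", herb="H", ob=1, dl=1.5), "dl"),
        (dict(name="A", herb="H", ob=1, dl=0.5, hdon=-2), "hdon"),
    ])
    def test_invariants_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            ComponentRecord(record_id="x", **kwargs)

    def test_name_normalization(self):
        assert normalize_name("  Berberine ") == normalize_name("berberine")
        assert normalize_name("Oroxylin  A") == "oroxylin a"


class TestEdgeList:
    def test_basic_graph(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tC\n")
        g = read_edge_list(p)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_self_loop_dropped(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tA\nA\tB\n")
        g = read_edge_list(p)
        assert set(g.nodes) == {"A", "B"} and g.number_of_edges() == 1

    def test_duplicate_edges_collapse_to_max_weight(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0.5\nA\tB\t0.5\nB\tA\t0.9\n")
        g = read_edge_list(p)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 0.9

    def test_nonpositive_weight_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0\n")
        with pytest.raises(ValueError, match="weight"):
            read_edge_list(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("\n")
        with pytest.raises(data_io.DataError):
            read_edge_list(p)

    def test_sif_format(self, tmp_path):
        p = tmp_path / "e.sif"
        p.write_text("A\tpp\tB\tC\n")
        g = read_edge_list(p)
        assert set(g.edges) == {("A", "B"), ("A", "C")}

    def test_round_trip(self, tmp_path):
        g = nx.Graph()
        g.add_edge("A", "B", weight=2.0)
        g.add_edge("B", "C", weight=1.0)
        nx.set_node_attributes(g, "protein", "kind")
        out = tmp_path / "g.tsv"
        data_io.write_edge_list(g, out)
        g2 = read_edge_list(out)
        assert nx.utils.graphs_equal(g, g2)


class TestGeneSets:
    def test_basic_gmt(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("P1\tdesc\ta\tB\n")
        coll = read_gene_sets(p)
        assert coll["P1"].genes == {"A", "B"}

    def test_duplicate_id_last_wins(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("P1\td\tA\nP1\td\tB\n")
        assert read_gene_sets(p)["P1"].genes == {"B"}

    def test_empty_gene_field_dropped(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("P1\td\tA\t\n")
        assert read_gene_sets(p)["P1"].genes == {"A"}

    def test_short_line_is_format_error_with_line_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("P1\td\tA\nP2\tdesc-only\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gene_sets(p)


class TestDiseaseGenes:
    def test_basic(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("TP53\t12.5\nINS\t6.9\n")
        table = read_disease_genes(p)
        assert len(table) == 2 and table.scores["TP53"] == 12.5

    def test_duplicate_keeps_max(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("TP53\t3\ntp53\t5\n")
        table = read_disease_genes(p)
        assert table.scores == {"TP53": 5.0}

    def test_negative_score_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("GENE\t-1\n")
        with pytest.raises(ValueError):
            read_disease_genes(p)

    def test_table_invariant(self):
        with pytest.raises(ValueError):
            DiseaseGeneTable(scores={"A": -0.1})


class TestTargetMap:
    def test_grouping_and_normalization(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("component\ttarget\nBerberine \ttp53\nberberine\tINS\nOther\tEGFR\n")
        tm = read_target_map(p)
        assert tm["berberine"] == {"TP53", "INS"}
        assert tm["other"] == {"EGFR"}

    def test_round_trip(self, tmp_path):
        tm = {"a": frozenset({"X", "Y"}), "b": frozenset({"Z"})}
        out = tmp_path / "tm.tsv"
        data_io.write_target_map(tm, out)
        assert read_target_map(out) == tm
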