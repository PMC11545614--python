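"""Regulatory-network filtering against an independent brute-force refilter."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from isotrace.regnet import (
    RegulatoryNetwork,
    export_network,
    filter_network,
    load_association_table,
    load_expression_summary,
)


def toy_tables():
    assoc = pd.DataFrame(
        {
            "regulator": ["TF1"] * 5 + ["TF2"] * 3 + ["TF3"] * 5,
            "gene": [f"G{i}" for i in range(5)]
            + ["G0", "G1", "G2"]
            + [f"G{i}" for i in range(5)],
            "confidence": "high",
        }
    )
    expr = {"TF1": 11.0, "TF2": 12.0, "TF3": 6.0}
    expr.update({f"G{i}": 10.5 for i in range(5)})
    patients = pd.Series(expr)
    lines = pd.Series(expr)
    return assoc, patients, lines


def brute_force_refilter(assoc, patients, lines, gene_floor, tf_floor, min_degree):
    """Independent re-implementation: restart the whole filter from scratch
    after every removal until nothing changes."""
    edges = sorted(set(zip(assoc["regulator"], assoc["gene"])))

    def ok(node, floor):
        return (
            node in patients.index
            and node in lines.index
            and patients[node] >= floor
            and lines[node] >= floor
        )

    edges = [(r, g) for r, g in edges if ok(g, gene_floor) and ok(r, tf_floor)]
    while True:
        counts = {}
        for r, _ in edges:
            counts[r] = counts.get(r, 0) + 1
        pruned = [(r, g) for r, g in edges if counts[r] >= min_degree]
        if pruned == edges:
            return set(edges)
        edges = pruned


class TestFilter:
    def test_tf_with_five_genes_retained(self):
        assoc, patients, lines = toy_tables()
        net = filter_network(assoc, patients, lines, 10.0, 7.5, 5)
        assert "TF1" in net.regulators
        assert "TF2" not in net.regulators  # degree 3 < 5
        assert "TF3" not in net.regulators  # expression floor

    def test_min_degree_six_drops_tf_and_reports_stage(self):
        assoc, patients, lines = toy_tables()
        net = filter_network(assoc, patients, lines, 10.0, 7.5, 6)
        assert net.regulators == []
        assert net.stage_report["degree_filter"]["kept_regulators"] == 0
        # expression stage kept TF1 and TF2; the degree filter removed them
        assert net.stage_report["regulator_expression_filter"]["kept"] == 2

    def test_stage_counts_self_consistent(self):
        assoc, patients, lines = toy_tables()
        net = filter_network(assoc, patients, lines, 10.0, 7.5, 5)
        rep = net.stage_report
        assert (
            rep["gene_expression_filter"]["kept"] + rep["gene_expression_filter"]["removed"]
            == rep["input"]["genes"]
        )
        assert (
            rep["regulator_expression_filter"]["kept"]
            + rep["regulator_expression_filter"]["removed"]
            == rep["input"]["regulators"]
        )

    def test_missing_expression_excluded_with_warning(self):
        assoc, patients, lines = toy_tables()
        patients = patients.drop("G0")
        with pytest.warns(UserWarning, match="G0"):
            net = filter_network(assoc, patients, lines, 10.0, 7.5, 4)
        assert "G0" not in net.genes

    def test_empty_association_rejected(self):
        _, patients, lines = toy_tables()
        with pytest.raises(ValueError, match="empty"):
            filter_network(pd.DataFrame(columns=["regulator", "gene"]), patients, lines)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_tf, n_gene = 12, 20
        rows = []
        for tf in range(n_tf):
            for g in rng.choice(n_gene, size=rng.integers(1, 9), replace=False):
                rows.append((f"TF{tf}", f"G{g}"))
        assoc = pd.DataFrame(rows, columns=["regulator", "gene"])
        nodes = [f"TF{i}" for i in range(n_tf)] + [f"G{i}" for i in range(n_gene)]
        patients = pd.Series(rng.uniform(5, 14, len(nodes)), index=nodes)
        lines = pd.Series(rng.uniform(5, 14, len(nodes)), index=nodes)
        net = filter_network(assoc, patients, lines, 9.0, 7.0, 3)
        expected = brute_force_refilter(assoc, patients, lines, 9.0, 7.0, 3)
        assert net.edges == expected

    def test_idempotent_fixed_point(self):
        """Re-filtering the retained network changes nothing."""
        rng = np.random.default_rng(42)
        rows = [
            (f"TF{t}", f"G{g}")
            for t in range(10)
            for g in rng.choice(15, size=rng.integers(2, 8), replace=False)
        ]
        assoc = pd.DataFrame(rows, columns=["regulator", "gene"])
        nodes = sorted({n for row in rows for n in row})
        patients = pd.Series(rng.uniform(6, 13, len(nodes)), index=nodes)
        lines = pd.Series(rng.uniform(6, 13, len(nodes)), index=nodes)
        net = filter_network(assoc, patients, lines, 8.0, 7.0, 3)
        if not net.edges:
            pytest.skip("fixture emptied by filters")
        assoc2 = pd.DataFrame(sorted(net.edges), columns=["regulator", "gene"])
        net2 = filter_network(assoc2, patients, lines, 8.0, 7.0, 3)
        assert net2.edges == net.edges


class TestExport:
    def _network(self):
        assoc, patients, lines = toy_tables()
        return filter_network(assoc, patients, lines, 10.0, 7.5, 5)

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.graphml"
        export_network(net, str(path), fmt="graphml")
        g = nx.read_graphml(str(path))
        assert set(map(frozenset, g.edges())) == set(map(frozenset, net.graph.edges()))
        for node, data in net.graph.nodes(data=True):
            assert g.nodes[node]["kind"] == data["kind"]
            assert g.nodes[node]["median_patients"] == pytest.approx(data["median_patients"])
            assert g.nodes[node]["degree"] == data["degree"]

    def test_sif_round_trip_edges(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.sif"
        export_network(net, str(path), fmt="sif")
        edges = {
            (parts[0], parts[2])
            for parts in (line.split("\t") for line in path.read_text().splitlines())
        }
        assert edges == net.edges

    def test_empty_network_refused(self):
        assoc, patients, lines = toy_tables()
        net = filter_network(assoc, patients, lines, gene_floor=99.0, tf_floor=7.5, min_degree=1)
        with pytest.raises(ValueError, match="empty"):
            export_network(net, "/tmp/never.sif", fmt="sif")

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            export_network(self._network(), str(tmp_path / "x"), fmt="gexf")


class TestLoaders:
    def test_association_loader_dedups(self, tmp_path):
        p = tmp_path / "assoc.tsv"
        p.write_text("regulator\tgene\tconfidence\nTF1\tG1\thigh\nTF1\tG1\thigh\n")
        df = load_association_table(str(p))
        assert len(df) == 1

    def test_expression_loader_schema(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tmedian_log2\nG1\t10.5\n")
        s = load_expression_summary(str(p))
        assert s["G1"] == 10.5
        p2 = tmp_path / "bad.tsv"
        p2.write_text("gene\tvalue\nG1\t1\n")
        with pytest.raises(ValueError, match="median_log2"):
            load_expression_summary(str(p2))
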