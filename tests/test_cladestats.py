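import numpy as np
import pandas as pd
import pytest

from foldphylo.cladestats import (
    CladeMap,
    EmptyScopeError,
    SchemaError,
    clades_recovered,
    load_clade_map,
    load_table,
    matrix_from_table,
    summarize,
    table_from_dataframe,
)
from foldphylo.disttree import PhyloTree, fitch_tree
from foldphylo.synthetic import clade_tree, make_distance_fixture

TSV_3ROWS = """\
id_a\tid_b\trmsd\tn_aligned\tsas\tone_minus_q
s1\ts2\t1.0\t100\t1.0\t0.2
s1\ts3\t2.0\t80\t2.5\t0.5
s2\ts3\t1.5\t50\t3.0\t0.4
"""


class TestLoadTable:
    def test_hand_written_tsv(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text(TSV_3ROWS)
        t = load_table(p)
        assert t.n_rows == 3
        assert t.labels == ["s1", "s2", "s3"]
        assert t.flags == []

    def test_header_synonyms(self, tmp_path):
        p = tmp_path / "pairs.csv"
        p.write_text(
            "Structure1,Structure2,RMSD,Superimposed residues,SAS,1-Qscore\n"
            "a,b,1.0,100,1.0,0.4\n"
        )
        t = load_table(p)
        assert t.labels == ["a", "b"]
        assert t.df["n_aligned"][0] == 100

    def test_xlsx_dialect(self, tmp_path, twin):
        table, _, _ = twin
        p = tmp_path / "supp.xlsx"
        table.head(20).to_excel(p, index=False)
        t = load_table(p)
        assert t.n_rows == 20

    def test_inconsistent_sas_flagged_not_dropped(self):
        df = pd.DataFrame(
            {
                "id_a": ["x"], "id_b": ["y"], "rmsd": [1.0],
                "n_aligned": [100], "sas": [1.5], "one_minus_q": [0.3],
            }
        )
        t = table_from_dataframe(df)
        assert t.n_rows == 1
        assert len(t.flags) == 1

    def test_missing_columns(self):
        with pytest.raises(SchemaError):
            table_from_dataframe(pd.DataFrame({"id_a": ["x"], "id_b": ["y"]}))

    def test_self_pair_rejected(self):
        df = pd.DataFrame(
            {
                "id_a": ["x"], "id_b": ["x"], "rmsd": [0.0],
                "n_aligned": [10], "sas": [0.0], "one_minus_q": [0.0],
            }
        )
        with pytest.raises(ValueError):
            table_from_dataframe(df)


class TestSummarize:
    def table(self):
        return table_from_dataframe(
            pd.read_csv(__import__("io").StringIO(TSV_3ROWS), sep="\t")
        )

    def test_scope_all(self):
        s = summarize(self.table(), scope="all")
        assert s["n_pairs"] == 3
        assert s["mean_sas"] == pytest.approx((1.0 + 2.5 + 3.0) / 3)
        assert s["mean_n_aligned"] == pytest.approx((100 + 80 + 50) / 3)

    def test_single_pair_clade(self):
        cmap = {"s1": 1, "s2": 1, "s3": 2}
        s = summarize(self.table(), cmap, 1)
        assert s["n_pairs"] == 1
        assert s["mean_sas"] == pytest.approx(1.0)
        assert s["mean_one_minus_q"] == pytest.approx(0.2)

    def test_empty_scope_raises(self):
        with pytest.raises(EmptyScopeError):
            summarize(self.table(), {"s1": 1, "s2": 2, "s3": 3}, 1)

    def test_means_permutation_invariant(self, twin):
        table, cmap, _ = twin
        t1 = table_from_dataframe(table)
        t2 = table_from_dataframe(table.sample(frac=1.0, random_state=0))
        for scope in ["all", 3]:
            a = summarize(t1, cmap, scope)
            b = summarize(t2, cmap, scope)
            assert a["mean_sas"] == pytest.approx(b["mean_sas"])

    def test_complete_table_pair_count(self, twin):
        table, _, _ = twin
        t = table_from_dataframe(table)
        L = len(t.labels)
        assert summarize(t)["n_pairs"] == L * (L - 1) // 2

    def test_clade_means_cannot_all_exceed_overall(self, twin):
        # weighted-average identity: within+between means average to overall
        table, cmap, _ = twin
        t = table_from_dataframe(table)
        overall = summarize(t)["mean_sas"]
        clade_means = [summarize(t, cmap, c)["mean_sas"] for c in range(1, 8)]
        assert min(clade_means) <= overall


class TestCladesRecovered:
    def test_constructed_clades_all_recovered(self):
        tree, cmap = clade_tree([3, 4, 5], seed=1)
        rec, count = clades_recovered(tree, cmap)
        assert count == 3
        assert all(rec.values())

    def test_paraphyletic_group_not_recovered(self):
        # caterpillar (((a,b),c),d)... with a map splitting it mid-spine
        newick = "(a:1,(b:1,(c:1,(d:1,e:1):1):1):1);"
        tree = PhyloTree.from_newick(newick)
        cmap = {"a": 1, "c": 1, "e": 1, "b": 2, "d": 2}
        rec, count = clades_recovered(tree, cmap)
        assert rec[1] is False and rec[2] is False

    def test_noise_free_matrix_tree_recovers_clades(self):
        tree, cmap = clade_tree([3, 3, 4], seed=5)
        dm = make_distance_fixture(tree, 0.0, 0)
        ft = fitch_tree(dm, n_restarts=2, seed=1)
        rec, count = clades_recovered(ft, cmap)
        assert count == 3


class TestMatrixFromTable:
    def test_incomplete_rejected(self):
        df = pd.DataFrame(
            {
                "id_a": ["x", "x"], "id_b": ["y", "z"], "rmsd": [1.0, 1.0],
                "n_aligned": [100, 100], "sas": [1.0, 1.0],
                "one_minus_q": [0.1, 0.1],
            }
        )
        with pytest.raises(ValueError):
            matrix_from_table(table_from_dataframe(df))

    def test_matrix_reproduces_columns(self, twin):
        table, _, _ = twin
        t = table_from_dataframe(table)
        dm = matrix_from_table(t, "SAS")
        for a, b, v in zip(table["id_a"].head(40), table["id_b"].head(40), table["sas"].head(40)):
            assert dm.get(a, b) == pytest.approx(v, abs=1e-9)


def test_load_clade_map(tmp_path):
    p = tmp_path / "clades.tsv"
    p.write_text("id\tclade\ttaxon_domain\nx\t1\tBacteria\ny\t2\tArchaea\nz\tunassigned\t\n")
    cm = load_clade_map(p)
    assert cm.clade == {"x": 1, "y": 2, "z": "unassigned"}
    assert cm.members(1) == {"x"}
    assert cm.clade_ids() == [1, 2]
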