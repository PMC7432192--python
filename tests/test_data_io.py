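import numpy as np
import pytest

from lncdbn.data_io import (
    DEFAULT_TISSUES,
    AssemblyError,
    AssociationTable,
    ExpressionTable,
    FormatError,
    TargetGeneTable,
    assemble_dataset,
    read_association_table,
    read_expression_table,
    read_predictions,
    read_target_gene_table,
    write_association_table,
    write_expression_table,
    write_predictions,
    write_target_gene_table,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestAssociationReader:
    def test_duplicates_dropped(self, tmp_path):
        p = _write(
            tmp_path / "a.tsv",
            "lncrna\tdisease\nH19\tbreast cancer\nH19\tBreast Cancer \nX1\tlung cancer\n",
        )
        table = read_association_table(p)
        assert len(table.records) == 2  # case-fold + trim makes rows 1-2 equal

    def test_header_only_gives_empty_table(self, tmp_path):
        p = _write(tmp_path / "a.tsv", "lncrna\tdisease\n")
        assert read_association_table(p).records == []

    def test_missing_column_names_it(self, tmp_path):
        p = _write(tmp_path / "a.tsv", "lncrna\tillness\nH19\tx\n")
        with pytest.raises(FormatError, match="disease"):
            read_association_table(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_association_table(tmp_path / "nope.tsv")

    def test_round_trip(self, tmp_path, rng):
        records = sorted(
            {
                (f"LNC{rng.integers(30):03d}", f"disease {rng.integers(8)}")
                for _ in range(50)
            }
        )
        table = AssociationTable(list(records))
        path = tmp_path / "rt.tsv"
        write_association_table(path, table)
        assert set(read_association_table(path).records) == set(records)


class TestTargetGeneReader:
    def test_round_trip(self, tmp_path, rng):
        records = sorted(
            {(f"L{rng.integers(40)}", f"G{rng.integers(25)}") for _ in range(80)}
        )
        path = tmp_path / "t.tsv"
        write_target_gene_table(path, TargetGeneTable(list(records)))
        assert set(read_target_gene_table(path).records) == set(records)

    def test_distinct_lncrna_count(self, tmp_path):
        rows = "".join(f"L{i:03d}\tG1\n" for i in range(349))
        p = _write(tmp_path / "t.tsv", "lncrna\tgene\n" + rows)
        assert len(read_target_gene_table(p).lncrna_ids) == 349

    def test_empty_body(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "lncrna\tgene\n")
        assert read_target_gene_table(p).records == []


class TestExpressionReader:
    def test_extra_columns_ignored(self, tmp_path):
        cols = list(DEFAULT_TISSUES) + ["placenta"]
        header = "lncrna\t" + "\t".join(cols)
        row = "L1\t" + "\t".join(str(i) for i in range(14))
        p = _write(tmp_path / "e.tsv", header + "\n" + row + "\n")
        table = read_expression_table(p)
        assert table.tissue_names == list(DEFAULT_TISSUES)
        assert table.values.shape == (1, 13)

    def test_missing_value_row_dropped(self, tmp_path):
        header = "lncrna\t" + "\t".join(DEFAULT_TISSUES)
        good = "L1\t" + "\t".join("1" for _ in range(13))
        bad = "L2\t" + "\t".join("2" for _ in range(12)) + "\t"
        p = _write(tmp_path / "e.tsv", f"{header}\n{good}\n{bad}\n")
        table = read_expression_table(p)
        assert table.lncrna_ids == ["L1"]

    def test_wrong_tissue_count_rejected(self, tmp_path):
        p = _write(tmp_path / "e.tsv", "lncrna\tadipose\nL1\t1\n")
        with pytest.raises(FormatError):
            read_expression_table(p, tissue_columns=["adipose", "adrenal"])

    def test_unresolvable_columns_listed(self, tmp_path):
        header = "lncrna\t" + "\t".join(DEFAULT_TISSUES[:-1]) + "\tsomething"
        p = _write(tmp_path / "e.tsv", header + "\n")
        with pytest.raises(FormatError, match="thyroid"):
            read_expression_table(p)

    def test_negative_values_rejected(self, tmp_path):
        header = "lncrna\t" + "\t".join(DEFAULT_TISSUES)
        row = "L1\t-1\t" + "\t".join("1" for _ in range(12))
        p = _write(tmp_path / "e.tsv", header + "\n" + row + "\n")
        with pytest.raises(FormatError, match="non-negative"):
            read_expression_table(p)

    def test_round_trip_bitwise(self, tmp_path, rng):
        values = rng.lognormal(size=(20, 13))
        table = ExpressionTable(
            [f"L{i}" for i in range(20)], list(DEFAULT_TISSUES), values
        )
        path = tmp_path / "e.tsv"
        write_expression_table(path, table)
        back = read_expression_table(path)
        assert back.lncrna_ids == table.lncrna_ids
        assert np.array_equal(back.values, values)


class TestAssembleDataset:
    @staticmethod
    def _fixture(counts):
        records, lncs = [], []
        i = 0
        for c, (cancer, n) in enumerate(counts.items()):
            for _ in range(n):
                lnc = f"L{i:03d}"
                records.append((lnc, cancer))
                lncs.append(lnc)
                i += 1
        assoc = AssociationTable(records)
        targets = TargetGeneTable([(l, "G1") for l in lncs])
        expr = ExpressionTable(
            lncs, list(DEFAULT_TISSUES), np.ones((len(lncs), 13))
        )
        return assoc, targets, expr

    def test_strict_threshold(self):
        assoc, targets, expr = self._fixture({"a": 25, "b": 20, "c": 5})
        ds = assemble_dataset(assoc, targets, expr, min_positives=20)
        assert set(ds.associations) == {"a"}  # 20 is NOT more than 20

    def test_whitelist(self):
        assoc, targets, expr = self._fixture({"a": 25, "b": 30, "c": 40})
        ds = assemble_dataset(assoc, targets, expr, 20, cancer_whitelist=["a", "b"])
        assert set(ds.associations) <= {"a", "b"}

    def test_row_order_invariance(self, tiny_tables):
        assoc, targets, expr = tiny_tables[:3]
        shuffled = AssociationTable(list(reversed(assoc.records)))
        t2 = TargetGeneTable(list(reversed(targets.records)))
        perm = np.random.default_rng(0).permutation(len(expr.lncrna_ids))
        e2 = ExpressionTable(
            [expr.lncrna_ids[i] for i in perm],
            expr.tissue_names,
            expr.values[perm],
        )
        a = assemble_dataset(assoc, targets, expr)
        b = assemble_dataset(shuffled, t2, e2)
        assert a.lncrna_ids == b.lncrna_ids
        assert a.associations == b.associations
        assert np.array_equal(a.expression.values, b.expression.values)

    def test_kept_cancers_match_brute_force(self, tiny_tables):
        assoc, targets, expr = tiny_tables[:3]
        ds = assemble_dataset(assoc, targets, expr, min_positives=20)
        ids = set(expr.lncrna_ids) & targets.lncrna_ids & assoc.lncrna_ids
        expected = set()
        for lnc, disease in assoc.records:
            pass
        by_disease = {}
        for lnc, disease in assoc.records:
            if lnc in ids:
                by_disease.setdefault(disease, set()).add(lnc)
        expected = {d for d, s in by_disease.items() if len(s) > 20}
        assert set(ds.associations) == expected
        for d in expected:
            assert ds.associations[d] == by_disease[d]

    def test_empty_intersection_raises(self):
        assoc, _, expr = self._fixture({"a": 25})
        targets = TargetGeneTable([("OTHER", "G1")])
        with pytest.raises(AssemblyError):
            assemble_dataset(assoc, targets, expr)


class TestPredictionsWriter:
    def test_tie_order_and_round_trip(self, tmp_path):
        ranking = [
            ("ca", "L2", 0.5, False),
            ("ca", "L1", 0.5, True),
            ("ca", "L3", 0.9, False),
        ]
        path = tmp_path / "pred.tsv"
        write_predictions(path, ranking)
        back = read_predictions(path)
        assert [r[1] for r in back] == ["L3", "L1", "L2"]  # score desc, id asc
        assert set(back) == set(ranking)

    def test_empty_ranking_header_only(self, tmp_path):
        path = tmp_path / "pred.tsv"
        write_predictions(path, [])
        assert path.read_text().strip() == "cancer\tlncrna\tscore\tknown"

    def test_score_range_enforced(self, tmp_path):
        with pytest.raises(ValueError):
            write_predictions(tmp_path / "p.tsv", [("c", "L1", 1.5, False)])
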