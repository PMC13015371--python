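"""Contrast-table IO, thresholding, and the direction-concordance partition."""

import numpy as np
import pytest

from oracles import partition_naive

from npcscreen import (
    ContrastTable,
    DegRecord,
    ThresholdSpec,
    apply_thresholds,
    classify_concordance,
    concordance_report,
    filter_by_chromosome,
    read_contrast_table,
    shared_response,
)
from npcscreen.errors import IntegrityError, SchemaError, SignAmbiguityError


def table(name, genes):
    """genes: mapping gene -> (fold_change, p_adj) or fold_change (p=0.01)."""
    records = []
    for g, spec in genes.items():
        fc, p = spec if isinstance(spec, tuple) else (spec, 0.01)
        records.append(DegRecord.from_fold_change(g, fc, p))
    return ContrastTable(name=name, records=records)


class TestReadContrastTable:
    def test_fold_change_derived_from_log2fc(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene_id\tlog2fc\tp_adj\nA\t1.0\t0.01\nB\t-1.0\t0.2\nC\t0.585\t0.04\n")
        tab = read_contrast_table(path)
        rec = tab.by_gene()
        assert rec["A"].fold_change == pytest.approx(2.0)
        assert rec["B"].fold_change == pytest.approx(-2.0)
        assert rec["C"].fold_change == pytest.approx(1.5, rel=1e-3)

    def test_log2fc_derived_from_fold_change(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene_id\tfold_change\tp_adj\nA\t-4.0\t0.01\n")
        tab = read_contrast_table(path)
        assert tab.by_gene()["A"].log2fc == pytest.approx(-2.0)

    def test_duplicate_gene_is_integrity_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene_id\tlog2fc\tp_adj\nG7\t1.0\t0.01\nG7\t2.0\t0.01\n")
        with pytest.raises(IntegrityError, match="G7"):
            read_contrast_table(path)

    def test_missing_columns_is_schema_error_listing_available(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("gene\tlfc\tq\nA\t1.0\t0.01\n")
        with pytest.raises(SchemaError, match="gene"):
            read_contrast_table(path)

    def test_column_map_resolves_nonstandard_headers(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("symbol,logfc,padj\nA,1.0,0.01\n")
        tab = read_contrast_table(
            path, column_map={"gene_id": "symbol", "log2fc": "logfc", "p_adj": "padj"}
        )
        assert tab.by_gene()["A"].fold_change == pytest.approx(2.0)

    def test_round_trip_write_read_is_identity(self, tmp_path):
        from npcscreen import DegSimConfig, simulate_deg_tables

        geno, _, _ = simulate_deg_tables(DegSimConfig(seed=4, n_genes=300))
        path = tmp_path / "geno.tsv"
        geno.write_tsv(path)
        back = read_contrast_table(path, name=geno.name)
        for a, b in zip(geno.records, back.records):
            assert a.gene_id == b.gene_id
            assert a.log2fc == pytest.approx(b.log2fc)
            assert a.fold_change == pytest.approx(b.fold_change)
            assert a.p_adj == pytest.approx(b.p_adj)
            assert a.chromosome == b.chromosome


class TestApplyThresholds:
    def test_boundary_values_are_kept_inclusive(self):
        tab = table("t", {"A": (1.5, 0.05)})
        kept = apply_thresholds(tab, ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.5))
        assert kept.gene_ids() == {"A"}

    def test_fc_floor_sensitivity(self):
        tab = table("t", {"A": (-1.4, 0.04)})
        assert apply_thresholds(tab, ThresholdSpec(abs_fc_min=1.5)).gene_ids() == set()
        assert apply_thresholds(tab, ThresholdSpec(abs_fc_min=1.2)).gene_ids() == {"A"}

    def test_no_fc_cutoff_keeps_tiny_fold_changes(self):
        tab = table("t", {"A": (1.05, 0.01), "B": (1.05, 0.2)})
        kept = apply_thresholds(tab, ThresholdSpec(p_adj_max=0.05, abs_fc_min=None))
        assert kept.gene_ids() == {"A"}

    def test_empty_table_stays_empty(self):
        assert len(apply_thresholds(ContrastTable(name="e"), ThresholdSpec())) == 0


class TestClassifyConcordance:
    def test_worked_four_gene_example(self):
        geno = table("g", {"A": 2.0, "B": -1.8, "C": 1.6})
        treat = table("t", {"A": -1.7, "B": 1.5, "C": 1.9, "D": -1.6})
        part = classify_concordance(treat, geno)
        assert part.corrected_down == {"A"}
        assert part.corrected_up == {"B"}
        assert part.worsened == {"C"}
        assert part.novel == {"D"}
        assert part.frac_corrected == pytest.approx(2 / 3)

    def test_empty_treatment_table(self):
        part = classify_concordance(ContrastTable(name="t"), table("g", {"A": 2.0}))
        assert part.n_overlap == 0 and part.n_treatment_degs == 0
        assert part.frac_corrected is None

    def test_zero_fold_change_is_sign_ambiguity_error(self):
        geno = table("g", {"A": 2.0})
        treat = ContrastTable(name="t", records=[DegRecord("A", 0.0, 0.0, 0.01)])
        with pytest.raises(SignAmbiguityError, match="A"):
            classify_concordance(treat, geno)

    def test_partition_conserves_and_is_disjoint(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            genes = [f"g{i}" for i in range(60)]
            treat = table(
                "t", {g: float(rng.choice([-1, 1]) * rng.uniform(1.5, 4)) for g in rng.choice(genes, n, replace=False)}
            )
            geno = table(
                "g", {g: float(rng.choice([-1, 1]) * rng.uniform(1.5, 4)) for g in rng.choice(genes, 30, replace=False)}
            )
            part = classify_concordance(treat, geno)
            sets = [part.corrected_down, part.corrected_up, part.worsened, part.novel]
            union = set().union(*sets)
            assert union == treat.gene_ids()
            assert sum(len(s) for s in sets) == len(union)

    def test_record_order_invariance(self):
        geno = table("g", {"A": 2.0, "B": -2.0})
        treat = table("t", {"A": -1.7, "B": 1.5, "C": 1.9})
        part1 = classify_concordance(treat, geno)
        treat_rev = ContrastTable(name="t", records=list(reversed(treat.records)))
        geno_rev = ContrastTable(name="g", records=list(reversed(geno.records)))
        part2 = classify_concordance(treat_rev, geno_rev)
        assert part1.category_of() == part2.category_of()

    def test_simultaneous_sign_flip_swaps_down_up_buckets(self):
        geno = table("g", {"A": 2.0, "B": -1.8, "C": 1.6})
        treat = table("t", {"A": -1.7, "B": 1.5, "C": 1.9, "D": -1.6})
        part = classify_concordance(treat, geno)
        flip = lambda tab: ContrastTable(
            name=tab.name,
            records=[
                DegRecord(r.gene_id, -r.log2fc, -r.fold_change, r.p_adj, r.chromosome)
                for r in tab.records
            ],
        )
        flipped = classify_concordance(flip(treat), flip(geno))
        assert flipped.corrected_down == part.corrected_up
        assert flipped.corrected_up == part.corrected_down
        assert flipped.worsened == part.worsened
        assert flipped.novel == part.novel

    def test_matches_naive_double_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(1000):
            t_genes = rng.choice(genes, int(rng.integers(0, 20)), replace=False)
            g_genes = rng.choice(genes, int(rng.integers(0, 20)), replace=False)
            t_map = {g: float(rng.choice([-1, 1]) * rng.uniform(1.5, 5)) for g in t_genes}
            g_map = {g: float(rng.choice([-1, 1]) * rng.uniform(1.5, 5)) for g in g_genes}
            part = classify_concordance(
                table("t", t_map), table("g", g_map)
            )
            expected = partition_naive(t_map, g_map)
            assert part.corrected_down == expected["corrected_down"]
            assert part.corrected_up == expected["corrected_up"]
            assert part.worsened == expected["worsened"]
            assert part.novel == expected["novel"]


class TestSharedResponse:
    def test_disjoint_tables_share_nothing(self):
        res = shared_response(table("a", {"X": 2.0}), table("b", {"Y": 2.0}))
        assert res.shared == frozenset()

    def test_worked_example_with_fc_dominance(self):
        a = table("a", {"X": 2.0, "Y": -2.0})
        b = table("b", {"X": 3.0, "Y": 2.0})
        res = shared_response(a, b)
        assert res.shared == {"X", "Y"}
        assert res.same_direction == {"X"}
        assert res.larger_in_a == frozenset()  # |3.0| > |2.0| so b dominates X

    def test_symmetry_of_shared_and_same_direction(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(25)]
        a = table("a", {g: float(rng.choice([-1, 1]) * rng.uniform(1.5, 4)) for g in genes[:15]})
        b = table("b", {g: float(rng.choice([-1, 1]) * rng.uniform(1.5, 4)) for g in genes[8:]})
        ab, ba = shared_response(a, b), shared_response(b, a)
        assert ab.shared == ba.shared
        assert ab.same_direction == ba.same_direction

    def test_zero_fold_change_is_sign_ambiguity_error(self):
        a = ContrastTable(name="a", records=[DegRecord("X", 0.0, 0.0, 0.01)])
        b = table("b", {"X": 2.0})
        with pytest.raises(SignAmbiguityError):
            shared_response(a, b)


class TestFilterByChromosome:
    def make_table(self):
        records = [
            DegRecord.from_fold_change(f"G{i}", 2.0, 0.01, chromosome="21" if i < 13 else "1")
            for i in range(20)
        ]
        return ContrastTable(name="t", records=records)

    def test_returns_exactly_the_tagged_genes(self):
        tab = self.make_table()
        kept, gaps = filter_by_chromosome({f"G{i}" for i in range(20)}, tab, "21")
        assert kept == {f"G{i}" for i in range(13)}
        assert gaps == 0

    def test_no_gene_on_query_chromosome(self):
        tab = self.make_table()
        kept, gaps = filter_by_chromosome({"G15", "G16"}, tab, "X")
        assert kept == set() and gaps == 0

    def test_missing_annotation_warns_and_counts_gaps(self):
        tab = ContrastTable(
            name="t",
            records=[DegRecord.from_fold_change("A", 2.0, 0.01, chromosome="21")],
        )
        with pytest.warns(UserWarning, match="lack a chromosome annotation"):
            kept, gaps = filter_by_chromosome({"A", "B"}, tab, "21")
        assert kept == {"A"} and gaps == 1


class TestConcordanceReport:
    def test_published_scale_percentages(self):
        """Partition sized 770/362/224/293 reports 83.5 / 16.5 / 17.8 percent."""
        from npcscreen.concordance import ConcordancePartition

        part = ConcordancePartition(
            treatment_name="t", genotype_name="g",
            corrected_down={f"d{i}" for i in range(770)},
            corrected_up={f"u{i}" for i in range(362)},
            worsened={f"w{i}" for i in range(224)},
            novel={f"n{i}" for i in range(293)},
        )
        rep = concordance_report(part)
        assert rep["n_overlap"] == 1356
        assert rep["n_corrected"] == 1132
        assert rep["pct_corrected"] == 83.5
        assert rep["pct_worsened"] == 16.5
        assert rep["n_treatment_degs"] == 1649
        assert rep["pct_novel"] == 17.8

    def test_empty_partition_reports_undefined_percentages(self):
        from npcscreen.concordance import ConcordancePartition

        part = ConcordancePartition("t", "g", set(), set(), set(), set())
        rep = concordance_report(part)
        assert rep["pct_corrected"] is None
        assert rep["pct_novel"] is None

    def test_corrected_and_worsened_percentages_conserve(self):
        from npcscreen.concordance import ConcordancePartition

        rng = np.random.default_rng(3)
        for _ in range(20):
            part = ConcordancePartition(
                "t", "g",
                corrected_down={f"d{i}" for i in range(int(rng.integers(1, 50)))},
                corrected_up={f"u{i}" for i in range(int(rng.integers(1, 50)))},
                worsened={f"w{i}" for i in range(int(rng.integers(1, 50)))},
                novel=set(),
            )
            rep = concordance_report(part)
            assert rep["pct_corrected"] + rep["pct_worsened"] == pytest.approx(100.0, abs=0.11)
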