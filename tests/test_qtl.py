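"""Interval co-localization, best-hit selection, trait rollups."""

import io

import numpy as np
import pandas as pd
import pytest

from stressprio.fixtures import load_table3_fixture
from stressprio.qtl import (
    GeneLocus, IntervalError, QTLRegion, best_hits, colocalize,
    normalize_chrom, read_blast6, read_gene_loci, summarize_by_trait,
)


class TestColocalize:
    def test_published_representative_assignment(self):
        gene = GeneLocus("Sb01g012195", "Chr 1", 11188494, 11188718)
        qtl = QTLRegion("QYLD1.2", "grain yield", "chr1", 11145830, 12704841)
        res = colocalize([gene], [qtl])
        assert list(res.assignments.gene_id) == ["Sb01g012195"]

    def test_chromosome_mismatch_not_assigned(self):
        gene = GeneLocus("g", "chr2", 100, 200)
        qtl = QTLRegion("q", "t", "chr1", 1, 1000)
        assert colocalize([gene], [qtl]).grand_total == 0

    def test_boundary_straddler_overlap_only(self):
        gene = GeneLocus("g", "chr1", 900, 1100)
        qtl = QTLRegion("q", "t", "chr1", 1, 1000)
        assert colocalize([gene], [qtl], mode="containment").grand_total == 0
        assert colocalize([gene], [qtl], mode="overlap").grand_total == 1

    def test_random_against_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        genes = []
        for i in range(200):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 10000))
            genes.append(GeneLocus(f"g{i}", chrom, start,
                                   start + int(rng.integers(0, 500))))
        qtls = []
        for i in range(20):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 9000))
            qtls.append(QTLRegion(f"q{i}", "t", chrom, start,
                                  start + int(rng.integers(100, 3000))))
        for mode in ("containment", "overlap"):
            res = colocalize(genes, qtls, mode=mode)
            got = set(zip(res.assignments.qtl_id, res.assignments.gene_id))
            brute = set()
            for q in qtls:
                for g in genes:
                    if g.chrom != q.chrom:
                        continue
                    if mode == "containment":
                        hit = q.start <= g.start and g.end <= q.end
                    else:
                        hit = g.end >= q.start and g.start <= q.end
                    if hit:
                        brute.add((q.qtl_id, g.gene_id))
            assert got == brute

    def test_containment_subset_of_overlap(self):
        rng = np.random.default_rng(7)
        genes = [GeneLocus(f"g{i}", "chr1", int(s), int(s) + 50)
                 for i, s in enumerate(rng.integers(1, 5000, size=50))]
        qtls = [QTLRegion(f"q{i}", "t", "chr1", int(s), int(s) + 400)
                for i, s in enumerate(rng.integers(1, 4500, size=10))]
        cont = colocalize(genes, qtls, mode="containment")
        over = colocalize(genes, qtls, mode="overlap")
        c = set(zip(cont.assignments.qtl_id, cont.assignments.gene_id))
        o = set(zip(over.assignments.qtl_id, over.assignments.gene_id))
        assert c <= o

    def test_invalid_interval_rejected(self):
        with pytest.raises(IntervalError):
            GeneLocus("g", "chr1", 10, 5)

    def test_chrom_normalization(self):
        assert normalize_chrom("Chr 1") == "chr1"
        assert normalize_chrom("chr01") == "chr1"
        assert normalize_chrom("3") == "chr3"

    def test_bed_coordinates_converted(self):
        bed = io.StringIO("chr1\t99\t200\tg1\n")
        (locus,) = read_gene_loci(bed, fmt="bed")
        assert (locus.start, locus.end) == (100, 200)


class TestBestHits:
    def hits(self, rows):
        cols = ["query_id", "subject_id", "pct_identity", "aln_length",
                "mismatches", "gap_opens", "q_start", "q_end", "s_start",
                "s_end", "evalue", "bit_score"]
        return pd.DataFrame(rows, columns=cols)

    def test_single_surviving_hit_selected(self):
        df = self.hits([("q1", "s1", 90.0, 100, 1, 0, 1, 100, 1, 100,
                         1e-30, 200.0)])
        out = best_hits(df)
        assert list(out.subject_id) == ["s1"]

    def test_evalue_threshold_excludes_query(self):
        df = self.hits([("q1", "s1", 90.0, 100, 1, 0, 1, 100, 1, 100,
                         1e-5, 200.0)])
        assert best_hits(df, evalue_max=1e-10).empty

    def test_tie_break_key_order(self):
        # equal bit score: lower e-value wins; then identity, length, subject
        rows = [
            ("q1", "sA", 80.0, 100, 0, 0, 1, 1, 1, 1, 1e-20, 300.0),
            ("q1", "sB", 95.0, 200, 0, 0, 1, 1, 1, 1, 1e-30, 300.0),
        ]
        out = best_hits(self.hits(rows))
        assert list(out.subject_id) == ["sB"]

    def test_total_order_matches_sort_oracle(self):
        keys = [
            (300.0, 1e-30, 90.0, 100, "sA"),
            (300.0, 1e-30, 90.0, 100, "sB"),
            (300.0, 1e-30, 95.0, 100, "sC"),
            (300.0, 1e-20, 99.0, 300, "sD"),
            (400.0, 1e-10, 50.0, 50, "sE"),
        ]
        rows = [("q1", s, ident, ln, 0, 0, 1, 1, 1, 1, ev, bs)
                for bs, ev, ident, ln, s in keys]
        best = max(keys, key=lambda k: (k[0], -k[1], k[2], k[3],
                                        [-ord(c) for c in k[4]]))
        out = best_hits(self.hits(rows))
        assert out.subject_id.iloc[0] == best[4]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"q{i % 5}", f"s{j}", float(rng.integers(50, 100)),
             int(rng.integers(50, 500)), 0, 0, 1, 1, 1, 1,
             float(10.0 ** -rng.integers(11, 40)),
             float(rng.integers(100, 500)))
            for i, j in enumerate(rng.integers(0, 50, size=40))
        ]
        df = self.hits(rows)
        base = best_hits(df)
        for seed in range(10):
            shuffled = df.sample(frac=1, random_state=seed).reset_index(drop=True)
            assert best_hits(shuffled).equals(base)

    def test_blast6_round_trip(self):
        text = "q1\ts1\t98.5\t120\t2\t0\t1\t120\t5\t124\t1e-50\t222.0\n"
        df = read_blast6(io.StringIO(text))
        assert df.bit_score.iloc[0] == 222.0
        assert len(best_hits(df)) == 1


class TestSummarizeByTrait:
    def test_reference_table_rollup(self):
        fx = load_table3_fixture()
        res = fx.colocalize_representatives()
        table = summarize_by_trait(
            res, fx.trait_categories, per_qtl_totals=fx.expected_totals,
            qtls=fx.qtls,
        )
        by_cat = table.set_index("category")
        assert by_cat.loc["seed dormancy", "count"] == 48
        assert by_cat.loc["yield-related", "count"] == 84
        assert by_cat.loc["drought adaptation", "count"] == 37

    def test_single_category_full_share(self):
        gene = GeneLocus("g", "chr1", 10, 20)
        qtl = QTLRegion("q", "yield", "chr1", 1, 100)
        res = colocalize([gene], [qtl])
        table = summarize_by_trait(res, {"yield": "yield-related"})
        assert list(table.percent) == [100.0]

    def test_counts_conserved(self):
        rng = np.random.default_rng(11)
        qtls = [QTLRegion(f"q{i}", f"trait{i % 4}", "chr1",
                          int(s), int(s) + 500)
                for i, s in enumerate(rng.integers(1, 5000, size=8))]
        genes = [GeneLocus(f"g{i}", "chr1", int(s), int(s) + 20)
                 for i, s in enumerate(rng.integers(1, 6000, size=60))]
        res = colocalize(genes, qtls)
        cats = {f"trait{i}": f"cat{i % 2}" for i in range(4)}
        table = summarize_by_trait(res, cats)
        assert table["count"].sum() == res.grand_total
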