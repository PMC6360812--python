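"""Selection screens, empirical p-values, FDR and shuffles."""

import numpy as np
import pandas as pd
import pytest

from ridlmap.annotation import classify_exonic_tes, intersect_tes, merge_exons, derive_introns
from ridlmap.io_formats import GenomicInterval
from ridlmap.selection import (
    ConservationCounts,
    adjust_fdr,
    compute_reic,
    conservation_screen,
    element_level_fdr,
    empirical_pvalue,
    enrichment_screen,
    shuffle_gene_structures,
    shuffle_intervals,
    strand_bias_screen,
)

from conftest import mk_gene, mk_te


class TestEmpiricalPvalue:
    def test_floor_when_observed_beats_all_1000_nulls(self):
        r = empirical_pvalue(10.0, np.linspace(0, 5, 1000), "greater")
        assert r.p_empirical == pytest.approx(0.001)
        assert r.rank == 1

    def test_rank_counting_direction_greater(self):
        null = np.concatenate([np.full(49, 2.0), np.full(950, 0.5)])
        r = empirical_pvalue(1.0, null, "greater")
        assert r.rank == 50
        assert r.p_empirical == pytest.approx(0.05)

    def test_least_extreme_observed_gives_p_one(self):
        r = empirical_pvalue(-1.0, np.arange(9) + 1.0, "greater")
        assert r.p_empirical == pytest.approx(1.0)

    def test_direction_less_mirrors_greater(self):
        r = empirical_pvalue(-5.0, np.arange(100) + 1.0, "less")
        assert r.p_empirical == pytest.approx(0.01)  # conservative floor 1/n

    def test_ties_counted_conservatively(self):
        r = empirical_pvalue(1.0, np.ones(9), "greater")
        assert r.p_empirical == pytest.approx(1.0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [], "greater")

    def test_super_uniform_under_exchangeable_null(self, rng):
        # draws exchangeable with the null => Pr(p <= a) <= a (+ MC slack)
        hits = {0.001: 0, 0.01: 0, 0.05: 0}
        n_rep = 400
        for _ in range(n_rep):
            vals = rng.normal(size=201)
            p = empirical_pvalue(vals[0], vals[1:], "greater").p_empirical
            for a in hits:
                hits[a] += p <= a
        assert hits[0.05] / n_rep <= 0.05 + 0.03
        assert hits[0.01] / n_rep <= 0.01 + 0.02
        assert hits[0.001] / n_rep <= 0.001 + 0.01


class TestFdr:
    def test_bh_hand_computation_three_values(self):
        assert adjust_fdr([0.001, 0.002, 0.003]) == pytest.approx([0.003, 0.003, 0.003])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])

    def test_order_preserved(self):
        assert adjust_fdr([0.02, 0.01]) == pytest.approx([0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


class TestReic:
    def test_hand_evaluated_example(self):
        assert compute_reic(ConservationCounts(50, 50, 25, 75)) == pytest.approx(2.0)

    def test_equal_fractions_give_one(self):
        assert compute_reic(ConservationCounts(10, 30, 5, 15)) == pytest.approx(1.0)

    def test_zero_conserved_exonic_gives_zero(self):
        assert compute_reic(ConservationCounts(0, 100, 10, 90)) == pytest.approx(0.0)

    def test_zero_conserved_intronic_undefined(self):
        with pytest.raises(ValueError):
            compute_reic(ConservationCounts(10, 90, 0, 100))


class TestEnrichmentScreen:
    @staticmethod
    def cov(d):
        return pd.DataFrame(
            {"fraction": pd.Series(d), "covered_nt": 0, "total_nt": 1}
        ).rename_axis("te_type")

    def test_fourfold_type_is_candidate(self):
        df = enrichment_screen(self.cov({"A": 0.04}), self.cov({"A": 0.01}))
        assert df.loc["A", "ratio"] == pytest.approx(4.0)
        assert bool(df.loc["A", "candidate"])

    def test_exactly_twofold_is_not_candidate(self):
        df = enrichment_screen(self.cov({"A": 0.02}), self.cov({"A": 0.01}))
        assert df.loc["A", "ratio"] == pytest.approx(2.0)
        assert not df.loc["A", "candidate"]

    def test_zero_exonic_coverage_not_candidate(self):
        df = enrichment_screen(self.cov({"A": 0.0}), self.cov({"A": 0.02}))
        assert df.loc["A", "ratio"] == 0.0
        assert not df.loc["A", "candidate"]

    def test_zero_intronic_coverage_flagged_undefined(self):
        df = enrichment_screen(self.cov({"A": 0.02}), self.cov({"A": 0.0}))
        assert np.isnan(df.loc["A", "ratio"])
        assert df.loc["A", "flag"] == "undefined"
        assert not df.loc["A", "candidate"]


class TestShuffles:
    sizes = {"chr1": 10_000, "chr2": 5_000}

    def genes(self):
        return [
            mk_gene("A", "chr1", "+", [(100, 200), (500, 600)]),
            mk_gene("B", "chr1", "-", [(1000, 1100), (1200, 1300), (1400, 1600)]),
            mk_gene("C", "chr2", "+", [(10, 60)]),
        ]

    def test_structure_preserved_rigidly(self):
        shuffled = shuffle_gene_structures(self.genes(), self.sizes, seed=3)
        for orig, new in zip(self.genes(), shuffled):
            o_ex = [e for t in orig.transcripts for e in t.exons]
            n_ex = [e for t in new.transcripts for e in t.exons]
            assert [e.length for e in o_ex] == [e.length for e in n_ex]
            assert [e.strand for e in o_ex] == [e.strand for e in n_ex]
            o_gaps = [b.start - a.end for a, b in zip(o_ex, o_ex[1:])]
            n_gaps = [b.start - a.end for a, b in zip(n_ex, n_ex[1:])]
            assert o_gaps == n_gaps

    def test_same_seed_identical_placement(self):
        a = shuffle_gene_structures(self.genes(), self.sizes, seed=9)
        b = shuffle_gene_structures(self.genes(), self.sizes, seed=9)
        assert [g.span for g in a] == [g.span for g in b]

    def test_placements_within_chromosome_bounds(self):
        for seed in range(20):
            for g in shuffle_gene_structures(self.genes(), self.sizes, seed=seed):
                span = g.span
                assert span.start >= 0
                assert span.end <= self.sizes[span.chrom]

    def test_gene_longer_than_every_chromosome_rejected(self):
        g = mk_gene("X", "chr1", "+", [(0, 9_999)])
        with pytest.raises(ValueError, match="longer"):
            shuffle_gene_structures([g], {"chr1": 5_000}, seed=0)

    def test_interval_shuffle_preserves_count_and_lengths(self, rng):
        lengths = np.array([10, 50, 200, 7])
        ci, starts = shuffle_intervals(lengths, self.sizes, rng)
        assert ci.size == starts.size == 4
        chroms = sorted(self.sizes)
        for k in range(4):
            assert 0 <= starts[k] <= self.sizes[chroms[ci[k]]] - 1


class TestStrandBiasScreen:
    def test_observed_ratio_and_floor_candidate(self):
        # one gene, sense TE 300 nt and antisense TE 100 nt, both inside
        gene = mk_gene("G", "chr1", "+", [(1000, 2000)])
        tes = [
            mk_te("chr1", 1100, 1400, strand="+", te_type="A"),
            mk_te("chr1", 1500, 1600, strand="-", te_type="A"),
        ]
        records = classify_exonic_tes([merge_exons(gene)], tes)
        df = strand_bias_screen(
            records, [gene], tes, {"chr1": 1_000_000}, n_sim=99, seed=4
        )
        assert df.loc["A", "observed"] == pytest.approx(3.0)
        # shuffled gene almost never lands on the two TEs -> null ratios nan,
        # so the observed ratio beats every null and takes the floor p = 1/n
        assert bool(df.loc["A", "candidate"]) == (
            df.loc["A", "p_greater"] == pytest.approx(1 / 99)
        )

    def test_boundary_crossing_tes_excluded_from_statistic(self):
        gene = mk_gene("G", "chr1", "+", [(1000, 2000), (3000, 4000)])
        tes = [
            mk_te("chr1", 1100, 1200, strand="+", te_type="A"),  # inside
            mk_te("chr1", 950, 1100, strand="+", te_type="A"),   # TSS -> excluded
            mk_te("chr1", 1900, 2100, strand="+", te_type="A"),  # donor -> excluded
        ]
        records = classify_exonic_tes([merge_exons(gene)], tes)
        df = strand_bias_screen(records, [gene], tes, {"chr1": 100_000}, n_sim=5, seed=0)
        assert df.loc["A", "sense"] == 100.0
        assert df.loc["A", "antisense"] == 0.0
        assert np.isinf(df.loc["A", "observed"])

    def test_instance_statistic_option(self):
        gene = mk_gene("G", "chr1", "+", [(1000, 2000)])
        tes = [
            mk_te("chr1", 1100, 1400, strand="+", te_type="A"),
            mk_te("chr1", 1500, 1600, strand="-", te_type="A"),
            mk_te("chr1", 1700, 1800, strand="-", te_type="A"),
        ]
        records = classify_exonic_tes([merge_exons(gene)], tes)
        df = strand_bias_screen(
            records, [gene], tes, {"chr1": 100_000}, n_sim=5, seed=0,
            statistic="instances",
        )
        assert df.loc["A", "observed"] == pytest.approx(0.5)


class TestConservationScreen:
    def build(self, rng, n_genes=25, n_tes=150, n_cons=120):
        genes = []
        pos = 1000
        for i in range(n_genes):
            coords = []
            for _ in range(3):
                coords.append((pos, pos + 120))
                pos += 120 + 300
            pos += 800
            genes.append(mk_gene(f"G{i}", "chr1", "+", coords))
        merged = [merge_exons(g) for g in genes]
        introns = derive_introns(genes, merged)
        tes = [
            mk_te("chr1", int(s), int(s) + int(rng.integers(20, 90)),
                  te_type=str(rng.choice(["A", "B", "C"])))
            for s in rng.integers(0, pos, size=n_tes)
        ]
        cons = [
            (GenomicInterval("chr1", int(s), int(s) + int(rng.integers(10, 40)), "."), "el")
            for s in rng.integers(0, pos, size=n_cons)
        ]
        sizes = {"chr1": pos + 1000}
        return genes, merged, introns, tes, cons, sizes

    def test_observed_reic_matches_per_nucleotide_oracle(self, rng):
        genes, merged, introns, tes, cons, sizes = self.build(rng)
        ex_f = intersect_tes(merged, tes)
        in_f = intersect_tes(introns, tes)
        df = conservation_screen(ex_f, in_f, cons, sizes, n_sim=3, seed=0)

        cons_nts = set()
        for c, _ in cons:
            cons_nts.update(range(c.start, c.end))

        def frag_counts(frags):
            per_type = {}
            for _, row in frags.iterrows():
                c, n = per_type.setdefault(row.te_type, [0, 0])
                nts = set(range(row.frag_start, row.frag_end))
                hit = len(nts & cons_nts)
                per_type[row.te_type] = [c + hit, n + len(nts) - hit]
            return per_type

        ex_counts = frag_counts(ex_f)
        in_counts = frag_counts(in_f)
        for t in df.index:
            if t not in ex_counts or t not in in_counts:
                continue
            Ce, Ne = ex_counts[t]
            Ci, Ni = in_counts[t]
            if Ci == 0:
                assert df.loc[t, "flag"] == "undefined"
                continue
            expected = compute_reic(ConservationCounts(Ce, Ne, Ci, Ni))
            assert df.loc[t, "observed"] == pytest.approx(expected)

    def test_type_absent_from_introns_skipped_with_flag(self, rng):
        genes, merged, introns, tes, cons, sizes = self.build(rng)
        # a type placed only inside one exon
        tes = tes + [mk_te("chr1", 1010, 1060, te_type="ONLYEX")]
        ex_f = intersect_tes(merged, tes)
        in_f = intersect_tes(introns, tes)
        df = conservation_screen(ex_f, in_f, cons, sizes, n_sim=3, seed=0)
        if "ONLYEX" in df.index:
            assert "skipped" in str(df.loc["ONLYEX", "flag"])

    def test_shuffle_preserves_element_count_and_lengths(self, rng):
        lengths = np.array([15, 30, 60])
        ci, starts = shuffle_intervals(lengths, {"chr1": 1000, "chr2": 2000}, rng)
        assert starts.size == 3  # count conserved; lengths are carried unchanged


class TestElementLevelFdr:
    def test_hand_arithmetic(self):
        ex = [True] * 50 + [False] * 50
        intr = [True] * 30 + [False] * 70
        assert element_level_fdr(ex, intr) == pytest.approx(0.4)

    def test_equal_frequencies_give_zero(self):
        assert element_level_fdr([True, False], [True, False]) == 0.0

    def test_zero_intronic_gives_upper_bound_one(self):
        assert element_level_fdr([True, False], [False, False]) == 1.0

    def test_zero_exonic_frequency_undefined(self):
        with pytest.raises(ValueError):
            element_level_fdr([False], [True])
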