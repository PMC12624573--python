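import random

import numpy as np
import pytest
from scipy.stats import kstest

from isletpep import (
    ElutionClass,
    GeneSetTable,
    gene_set_overlap_test,
    rank_abundance,
    tag_candidates,
    venn_counts,
)
from conftest import make_record, random_peptide
from oracles import hypergeom_tail

GENE_SETS = GeneSetTable.from_dict(
    {
        "pancreas_enriched": ["INS", "GCG", "CHGA"],
        "cytokine_up": ["CHGA", "HLA-A", "B2M"],
        "t1d_up": ["INS", "B2M", "SCG1"],
    }
)


class TestTagCandidates:
    def test_gene_in_no_set_is_not_a_candidate(self):
        rec = make_record("ACDEFGHIKLMN", gene_symbol="GAPDH")
        (label,) = tag_candidates([rec], GENE_SETS)
        assert label.venn_cell == "none"
        assert not label.is_candidate

    def test_multi_set_gene_lands_in_intersection_cell(self):
        rec = make_record("ACDEFGHIKLMN", gene_symbol="INS")
        (label,) = tag_candidates([rec], GENE_SETS)
        assert label.pancreas_enriched and label.t1d_up and not label.cytokine_up
        assert label.venn_cell == "pancreas_enriched+t1d_up"

    def test_multi_mapped_peptide_uses_union_of_parent_genes(self):
        rec = make_record("ACDEFGHIKLMN", gene_symbol="GAPDH;GCG")
        (label,) = tag_candidates([rec], GENE_SETS)
        assert label.pancreas_enriched

    def test_known_epitope_bidirectional_containment(self):
        exact = make_record("HLVEALYLV", elution=ElutionClass.ABC)
        nested = make_record("SHLVEALYLVC", elution=ElutionClass.ABC)
        inner = make_record("HLVEALYL", elution=ElutionClass.ABC)
        other = make_record("SIINFEKLM", elution=ElutionClass.ABC)
        labels = tag_candidates(
            [exact, nested, inner, other], GENE_SETS, known_epitopes=["HLVEALYLV"]
        )
        assert [l.known_epitope_exact for l in labels] == [True, True, True, False]

    def test_venn_cells_partition_planted_table(self):
        rng = random.Random(15)
        genes = [f"G{i}" for i in range(30)]
        sets = {
            name: set(rng.sample(genes, 8))
            for name in ("pancreas_enriched", "cytokine_up", "t1d_up")
        }
        table = GeneSetTable.from_dict(sets)
        records = [
            make_record(random_peptide(rng), gene_symbol=rng.choice(genes))
            for _ in range(200)
        ]
        labels = tag_candidates(records, table)
        counts = venn_counts(labels)
        assert sum(counts.values()) == 200
        # brute-force set arithmetic per cell
        for label in labels:
            g = label.peptide.genes[0].upper()
            expected = tuple(
                g in {x.upper() for x in sets[name]}
                for name in ("pancreas_enriched", "cytokine_up", "t1d_up")
            )
            assert (label.pancreas_enriched, label.cytokine_up, label.t1d_up) == expected

    def test_monotone_adding_gene_never_removes_candidates(self):
        rng = random.Random(8)
        records = [
            make_record(random_peptide(rng), gene_symbol=f"G{rng.randint(0, 20)}")
            for _ in range(100)
        ]
        small = GeneSetTable.from_dict({"pancreas_enriched": ["G1", "G2"]})
        big = GeneSetTable.from_dict({"pancreas_enriched": ["G1", "G2", "G3"]})
        before = {id(l.peptide) for l in tag_candidates(records, small) if l.is_candidate}
        after = {id(l.peptide) for l in tag_candidates(records, big) if l.is_candidate}
        assert before <= after


class TestRankAbundance:
    def test_single_protein_gets_rank_one(self):
        rec = make_record("ACDEFGHIKLMN", source_accession="P1", precursor_intensity=5.0)
        (row,) = rank_abundance([rec])
        assert row.rank == 1 and row.total_intensity == 5.0

    def test_summing_and_ordering(self):
        recs = [
            make_record("ACDEFGHIKLMN", source_accession="P1", precursor_intensity=10.0),
            make_record("DEFGHIKLMNPQ", source_accession="P1", precursor_intensity=5.0),
            make_record("GHIKLMNPQRST", source_accession="P2", precursor_intensity=12.0),
        ]
        rows = {r.accession: r for r in rank_abundance(recs)}
        assert rows["P1"].total_intensity == 15.0 and rows["P1"].rank == 1
        assert rows["P2"].rank == 2

    def test_ranks_are_permutation_within_class_and_order_invariant(self):
        rng = random.Random(44)
        recs = []
        for _ in range(150):
            recs.append(
                make_record(
                    random_peptide(rng),
                    elution=rng.choice([ElutionClass.ABC, ElutionClass.DR]),
                    source_accession=f"P{rng.randint(0, 25)}",
                    precursor_intensity=rng.uniform(1, 100),
                )
            )
        rows = rank_abundance(recs)
        by_class = {}
        for r in rows:
            by_class.setdefault(r.elution_class, []).append(r.rank)
        for ranks in by_class.values():
            assert sorted(ranks) == list(range(1, len(ranks) + 1))
        shuffled = recs[:]
        rng.shuffle(shuffled)
        assert rank_abundance(shuffled) == rows

    def test_invariant_to_splitting_intensity_across_rows(self):
        one = [make_record("ACDEFGHIKLMN", source_accession="P1", precursor_intensity=10.0)]
        split = [
            make_record("ACDEFGHIKLMN", source_accession="P1", precursor_intensity=4.0),
            make_record("ACDEFGHIKLMN", source_accession="P1", precursor_intensity=6.0),
        ]
        assert rank_abundance(one) == rank_abundance(split)


class TestOverlapTest:
    def test_identical_sets_are_overwhelmingly_enriched(self):
        genes = [f"G{i}" for i in range(50)]
        _, p = gene_set_overlap_test(genes, genes, universe_size=10_000)
        assert p < 1e-10

    def test_zero_size_set_is_an_error(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test([], ["G1"], universe_size=100)

    def test_p_equals_exhaustive_hypergeometric_tail(self):
        # 2x2 table (10, 10, 10, 970)
        set_a = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
        set_b = [f"A{i}" for i in range(10)] + [f"C{i}" for i in range(10)]
        _, p = gene_set_overlap_test(set_a, set_b, universe_size=1000)
        assert p == pytest.approx(hypergeom_tail(10, 20, 20, 1000), rel=1e-9)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i:05d}" for i in range(20_000)]
        ps = []
        for _ in range(300):
            a = rng.choice(universe, size=2000, replace=False)
            b = rng.choice(universe, size=2000, replace=False)
            _, p = gene_set_overlap_test(list(a), list(b), universe_size=20_000)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01
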