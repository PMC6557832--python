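import numpy as np
import pytest

from smoc.io import SeqRecord, revcomp, translate
from smoc.synthetic import (FAMILY_RECIPES, GeneParams, MotifGrammar,
                            ReadSimParams, make_family_panel, make_gene,
                            make_homolog_queries, make_repeat_unit,
                            make_tandem_locus, masp_like_params,
                            simulate_long_reads, simulate_short_reads)


class TestGeneConstruction:
    def test_single_repeat_no_divergence_is_exact_concatenation(self):
        g = make_gene(MotifGrammar(), GeneParams(
            n_repeats=1, per_copy_divergence=0.0, codon_noise=0.0, seed=3))
        assert g.protein == g.n_terminal + g.repeat_unit_template + g.c_terminal
        assert translate(g.dna) == g.protein

    def test_deterministic_for_fixed_seed(self):
        a = make_gene(MotifGrammar(), masp_like_params(seed=11))
        b = make_gene(MotifGrammar(), masp_like_params(seed=11))
        assert a.dna == b.dna and a.truth == b.truth

    def test_coding_length_arithmetic(self):
        # 3 * (150 + 20*60 + 100) = 4350 nt
        g = make_gene(MotifGrammar(), masp_like_params(seed=7))
        assert len(g.dna) == 3 * (150 + 20 * 60 + 100) == 4350

    def test_truth_annotations_tile_coding_sequence(self):
        g = make_gene(MotifGrammar(), GeneParams(
            n_repeats=6, intron_after=(2, 4), seed=5))
        spans = sorted((a.start, a.end) for a in g.truth
                       if a.feature_type not in ("exon", "gene"))
        assert spans[0][0] == 0 and spans[-1][1] == len(g.dna)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2
        assert translate(g.transcript) == g.protein

    def test_repeat_copies_diverge_at_requested_rate(self):
        g = make_gene(MotifGrammar(), GeneParams(
            n_repeats=50, unit_length=100, per_copy_divergence=0.05, seed=2))
        diffs = [sum(a != b for a, b in zip(copy, g.repeat_unit_template))
                 for copy in g.repeat_units]
        rate = np.mean(diffs) / 100
        assert 0.03 < rate < 0.07

    def test_identical_codons_toggle_makes_dna_copies_identical(self):
        g = make_gene(MotifGrammar(), GeneParams(
            n_repeats=5, identical_codons=True, seed=9))
        units = [a for a in g.truth if a.feature_type == "repeat_unit"]
        seqs = {g.dna[a.start:a.end] for a in units}
        assert len(seqs) == 1

    def test_unit_shorter_than_longest_motif_rejected(self):
        with pytest.raises(ValueError):
            make_repeat_unit(MotifGrammar(), 4, np.random.default_rng(0))

    def test_homolog_queries_are_diverged_termini(self):
        g = make_gene(MotifGrammar(), masp_like_params(seed=7))
        nq, cq = make_homolog_queries(g, divergence=0.1, seed=1)
        ident = np.mean([a == b for a, b in zip(nq.sequence, g.protein[:170])])
        assert 0.8 < ident < 0.97


class TestTandemLocus:
    def test_single_gene_zero_spacer_is_identity(self):
        g = make_gene(MotifGrammar(), GeneParams(n_repeats=2, seed=1))
        locus, anns = make_tandem_locus([g], spacer_bp=0)
        assert locus.sequence == g.dna

    def test_second_gene_annotations_offset(self):
        g1 = make_gene(MotifGrammar(), GeneParams(n_repeats=2, seed=1, gene_id="a"))
        g2 = make_gene(MotifGrammar(), GeneParams(n_repeats=2, seed=2, gene_id="b"))
        locus, anns = make_tandem_locus([g1, g2], spacer_bp=100)
        offset = len(g1.dna) + 100
        b_gene = next(a for a in anns if a.feature_type == "gene"
                      and a.label.endswith("b"))
        assert (b_gene.start, b_gene.end) == (offset, offset + len(g2.dna))

    def test_annotated_spans_reproduce_each_gene(self):
        genes = [make_gene(MotifGrammar(), GeneParams(n_repeats=3, seed=s,
                                                      gene_id=f"g{s}"))
                 for s in (1, 2)]
        locus, anns = make_tandem_locus(genes, spacer_bp=50, flank_bp=20)
        for g in genes:
            span = next(a for a in anns if a.feature_type == "gene"
                        and a.label.endswith(g.gene_id))
            assert locus.sequence[span.start:span.end] == g.dna


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(0)
    return SeqRecord("t", "".join("ACGT"[i] for i in rng.integers(4, size=10_000)))


class TestShortReadSimulation:

    def test_error_free_reads_are_substrings(self, template):
        reads = simulate_short_reads(template, ReadSimParams(
            coverage=5, error_rate_subs=0.0, seed=1))
        for r in reads[:200]:
            assert r.sequence in template.sequence or \
                revcomp(r.sequence) in template.sequence

    def test_realized_coverage_within_5_percent(self, template):
        reads = simulate_short_reads(template, ReadSimParams(coverage=50, seed=2))
        total = sum(len(r.sequence) for r in reads)
        assert abs(total / len(template.sequence) - 50) / 50 < 0.05

    def test_zero_reads_rejected(self):
        t = SeqRecord("t", "ACGT" * 100)
        with pytest.raises(ValueError):
            simulate_short_reads(t, ReadSimParams(coverage=0.0001, seed=1))

    def test_both_strands_sampled(self, template):
        reads = simulate_short_reads(template, ReadSimParams(
            coverage=10, paired=False, seed=3))
        fwd = sum(r.sequence in template.sequence for r in reads)
        assert 0.3 < fwd / len(reads) < 0.7


class TestLongReadSimulation:
    def test_error_free_spanning_read_equals_template(self):
        rng = np.random.default_rng(1)
        t = SeqRecord("t", "".join("ACGT"[i] for i in rng.integers(4, size=2000)))
        p = ReadSimParams(coverage=3, long_read_mean=5000, long_error_subs=0,
                          long_error_ins=0, long_error_del=0, seed=4)
        reads = simulate_long_reads(t, p)
        spanning = [r for r in reads if len(r.sequence) == 2000]
        assert spanning
        for r in spanning:
            assert r.sequence in (t.sequence, revcomp(t.sequence))

    def test_mean_length_honored_within_10_percent(self):
        rng = np.random.default_rng(2)
        t = SeqRecord("t", "".join("ACGT"[i] for i in rng.integers(4, size=60_000)))
        p = ReadSimParams(coverage=100, long_read_mean=5000, seed=5)
        reads = simulate_long_reads(t, p)
        assert len(reads) >= 1000
        mean = np.mean([len(r.sequence) for r in reads])
        assert abs(mean - 5000) / 5000 < 0.10

    def test_substitution_only_reads_align_without_indels(self):
        rng = np.random.default_rng(3)
        t = SeqRecord("t", "".join("ACGT"[i] for i in rng.integers(4, size=3000)))
        p = ReadSimParams(coverage=5, long_error_subs=0.02, long_error_ins=0,
                          long_error_del=0, seed=6)
        for r in simulate_long_reads(t, p):
            # length preserved under a substitution-only model
            assert len(r.sequence) <= 3000


class TestFamilyPanel:
    def test_panel_shape_and_labels(self):
        recs, labels = make_family_panel(seed=0)
        assert len(recs) == 35 and len(set(labels)) == 7
        assert sorted(set(labels)) == list(range(7))

    def test_members_of_a_family_are_similar(self):
        recs, labels = make_family_panel(seed=1)
        a, b = recs[0].sequence, recs[1].sequence
        ident = np.mean([x == y for x, y in zip(a, b)])
        assert ident > 0.9

    def test_recipes_cover_seven_orthologue_groups(self):
        assert set(FAMILY_RECIPES) == {"MaSp1", "MaSp2", "MaSp3", "MiSp",
                                       "Flag", "CySp", "AcSp"}
        assert FAMILY_RECIPES["MaSp3"]["GGR"] > 0   # the arginine motif
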