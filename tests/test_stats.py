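import numpy as np
import pytest

from twinmito.io import AnnotatedGenome, GeneFeature
from twinmito.simulate import simulate_genome
from twinmito.stats import (EmptySelectionError, _coverage_mask,
                            codon_stats, coding_fraction, gc_content,
                            gene_length_summary, intergenic_spacers,
                            summarize)


def genome_with(seq, feats, topology="linear"):
    return AnnotatedGenome("t", topology, seq, feats)


class TestGcContent:
    def test_all_at(self):
        assert gc_content(genome_with("ATAT", []), "total") == 0.0

    def test_all_gc(self):
        assert gc_content(genome_with("GCGC", []), "total") == 100.0

    def test_ambiguity_codes_excluded_from_both_sides(self):
        # 2 GC over 4 unambiguous bases; the two Ns do not dilute
        genome = genome_with("GCATNN", [])
        assert gc_content(genome, "total") == 50.0

    def test_class_selector_counts_positions_once(self):
        feats = [GeneFeature("a", "tRNA", "+", [(1, 4)]),
                 GeneFeature("b", "tRNA", "+", [(1, 4)])]
        genome = genome_with("GGCCAATT", feats)
        assert gc_content(genome, "tRNA") == 100.0

    def test_empty_selection_is_an_error_not_zero(self):
        with pytest.raises(EmptySelectionError):
            gc_content(genome_with("ACGT", []), "tRNA")

    def test_intergenic_complement(self):
        feats = [GeneFeature("a", "protein", "+", [(1, 4)], complete=False)]
        genome = genome_with("GGCCAATT", feats)
        assert gc_content(genome, "intergenic") == 0.0


class TestCodingFraction:
    def test_single_gene(self):
        feats = [GeneFeature("a", "protein", "+", [(1, 90)], complete=False)]
        assert coding_fraction(genome_with("A" * 100, feats)) == 90.0

    def test_full_overlap_counted_once(self):
        feats = [GeneFeature("a", "protein", "+", [(1, 50)], complete=False),
                 GeneFeature("b", "protein", "+", [(1, 50)], complete=False)]
        assert coding_fraction(genome_with("A" * 100, feats)) == 50.0


class TestSpacers:
    def test_adjacent_genes_spacer_zero(self):
        feats = [GeneFeature("a", "tRNA", "+", [(1, 10)]),
                 GeneFeature("b", "tRNA", "+", [(11, 20)])]
        out = intergenic_spacers(genome_with("A" * 20, feats))
        assert out["spacers"] == [("a", "b", 0)]

    def test_five_bp_spacer(self):
        feats = [GeneFeature("a", "tRNA", "+", [(1, 10)]),
                 GeneFeature("b", "tRNA", "+", [(16, 20)])]
        out = intergenic_spacers(genome_with("A" * 20, feats))
        assert out["spacers"] == [("a", "b", 5)]

    def test_overlap_reported_separately_and_excluded_from_mean(self):
        feats = [GeneFeature("a", "tRNA", "+", [(1, 12)]),
                 GeneFeature("b", "tRNA", "+", [(10, 20)]),
                 GeneFeature("c", "tRNA", "+", [(25, 30)])]
        out = intergenic_spacers(genome_with("A" * 30, feats))
        assert out["overlaps"] == [("a", "b", 3)]
        assert out["spacers"] == [("b", "c", 4)]
        assert out["mean"] == 4.0

    def test_circular_closes_the_ring(self):
        feats = [GeneFeature("a", "tRNA", "+", [(3, 10)]),
                 GeneFeature("b", "tRNA", "+", [(13, 18)])]
        out = intergenic_spacers(genome_with("A" * 20, feats,
                                             topology="circular"))
        # a->b spacer 2, b->a wraps: 20-18 + 3-1 = 4
        assert sorted(g for *_, g in out["spacers"]) == [2, 4]


class TestCodonStats:
    def test_single_gene_third_position(self):
        feats = [GeneFeature("g", "protein", "+", [(1, 9)])]
        out = codon_stats(genome_with("ATGAAATAA", feats))
        assert out["start_codons"]["g"] == "ATG"
        assert out["third_position_AT_pct"] == pytest.approx(200 / 3, abs=0.01)

    def test_alternative_start_flagged(self):
        feats = [GeneFeature("g", "protein", "+", [(1, 9)])]
        out = codon_stats(genome_with("ATAAAATAA", feats))
        assert out["alternative_starts"] == {"g": "ATA"}

    def test_incomplete_length_excluded_with_warning(self):
        feats = [GeneFeature("g", "protein", "+", [(1, 8)]),
                 GeneFeature("h", "protein", "+", [(9, 17)])]
        genome = genome_with("ATGAAATAATGAAATAA", feats)
        with pytest.warns(UserWarning, match="not divisible"):
            out = codon_stats(genome)
        assert "g" not in out["start_codons"]
        assert "h" in out["start_codons"]


def test_gene_length_summary_means():
    feats = [GeneFeature("a", "protein", "+", [(1, 100)], complete=False),
             GeneFeature("b", "protein", "+", [(101, 300)], complete=False)]
    mean_prot, mean_all = gene_length_summary(genome_with("A" * 300, feats))
    assert mean_prot == 150.0
    assert mean_all == 150.0


class TestGeneratorRecovery:
    """The stats module must recover the generator's parameters."""

    def test_summary_matches_truth(self, sim_genome):
        genome, truth = sim_genome
        s = summarize(genome)
        prot_lengths = [L for name, L in truth.gene_lengths.items()
                        if dict((n, c) for n, c, _ in
                                truth.params["plan"])[name] == "protein"]
        assert s.mean_protein_gene_bp == pytest.approx(np.mean(prot_lengths))
        assert s.gene_counts["total_genes"] == truth.params["n_genes"]
        assert s.gc_total_pct == pytest.approx(100 * truth.params["gc"], abs=2.0)
        assert s.third_position_AT_pct == pytest.approx(
            100 * truth.params["third_position_at"], abs=3.0)
        assert s.mean_spacer_bp == pytest.approx(np.mean(truth.spacer_lengths))

    @pytest.mark.parametrize("seed", [0, 1, 2, 11])
    def test_accounting_identity(self, seed):
        """coverage + spacers (+ overlap-corrected bp) tile the genome."""
        genome, _ = simulate_genome(seed=seed)
        cov = int(_coverage_mask(genome).sum())
        sp = intergenic_spacers(genome)
        spacer_bp = sum(g for *_, g in sp["spacers"])
        overlap_bp = sum(g for *_, g in sp["overlaps"])
        assert cov + spacer_bp + overlap_bp == len(genome)

    def test_rotation_invariance(self):
        genome, _ = simulate_genome(seed=5, topology="circular")
        shift = 1234
        n = len(genome)
        rotated_seq = genome.sequence[shift:] + genome.sequence[:shift]

        def rot(pos):
            return (pos - 1 - shift) % n + 1

        feats = [GeneFeature(f.name, f.cls, f.strand,
                             [(rot(s), rot(e)) for s, e in f.segments],
                             f.complete)
                 for f in genome.features]
        rotated = AnnotatedGenome("rot", "circular", rotated_seq, feats)
        a, b = summarize(genome), summarize(rotated)
        assert a.gc_total_pct == pytest.approx(b.gc_total_pct)
        assert a.coding_fraction_pct == pytest.approx(b.coding_fraction_pct)
        assert sorted(a.spacer_lengths) == sorted(b.spacer_lengths)
        assert a.third_position_AT_pct == pytest.approx(b.third_position_AT_pct)
        assert a.mean_protein_gene_bp == b.mean_protein_gene_bp


def test_gc_total_is_length_weighted_mean_of_parts(sim_genome):
    genome, _ = sim_genome
    masks = {}
    classes = ["protein", "rRNA", "tRNA"]
    total_gc = gc_content(genome, "total")
    weighted = 0.0
    weight = 0.0
    seq = genome.sequence
    for cls in classes + ["intergenic"]:
        gc = gc_content(genome, cls)
        if cls == "intergenic":
            mask = ~_coverage_mask(genome)
            n_bases = int(mask.sum())
        else:
            from twinmito.stats import _segment_positions
            pos = set()
            for f in genome.features_of_class(cls):
                pos.update(_segment_positions(genome, f).tolist())
            n_bases = len(pos)
        weighted += gc * n_bases
        weight += n_bases
    assert weighted / weight == pytest.approx(total_gc, abs=0.2)
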