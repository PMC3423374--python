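import numpy as np
import pytest

from twinmito.events import (IntronDecompositionError, detect_fission,
                             detect_fusions, detect_inframe_insert,
                             detect_intron_interruption,
                             locate_trans_splice_junction)
from twinmito.io import spliced_sequence, translate
from twinmito.simulate import (_mutate, simulate_genome,
                               simulate_structural_events,
                               simulate_trans_splice, stream)


def protein(genome, name):
    return translate(spliced_sequence(genome, genome.feature(name)),
                     mode="open_frame").rstrip("*")


class TestFission:
    def test_exact_halves_recover_breakpoint_exactly(self):
        rng = stream(0, "test")
        aas = "ACDEFGHIKLMNPQRSTVWY"
        parent = "".join(np.array(list(aas))[rng.integers(0, 20, 300)])
        cut = 150
        event = detect_fission(parent, {"pa": parent[:cut], "pb": parent[cut:]},
                               parent_name="p")
        assert event is not None
        assert event.part_ids == ("pa", "pb")
        assert event.part_spans == ((1, 150), (151, 300))
        assert event.breakpoint == (150, 151)

    def test_unrelated_candidates_give_none(self):
        parent = "MKLV" * 60
        assert detect_fission(parent, {"x": "WYWYHHH" * 20}) is None

    def test_single_candidate_gives_none(self):
        parent = "MKLVACDE" * 40
        assert detect_fission(parent, {"x": parent[:120]}) is None

    @pytest.mark.parametrize("seed", [4, 14])
    def test_generator_fission_with_mutations(self, seed):
        genome, _ = simulate_genome(seed=3)
        mod, truth = simulate_structural_events(
            genome, {"fission": "nad11", "mutate": 0.05}, seed=seed)
        parent = protein(genome, "nad11")
        cands = {n: protein(mod, n) for n in ("nad11a", "nad11b")}
        event = detect_fission(parent, cands, parent_name="nad11")
        assert event is not None
        planted = truth.events["fission"]["breakpoint_aa"]
        assert abs(event.breakpoint[0] - planted) <= 5


class TestFusion:
    @pytest.fixture(scope="class")
    def fusion_pair(self):
        genome, _ = simulate_genome(seed=3)
        split_g, _ = simulate_structural_events(
            genome, {"colocate": ("rps3", "rpl16")}, seed=5)
        fused_g, truth = simulate_structural_events(
            split_g, {"fusion": ("rps3", "rpl16")}, seed=5)
        return split_g, fused_g, truth

    def test_generator_fusion_detected(self, fusion_pair):
        split_g, fused_g, truth = fusion_pair
        events = detect_fusions(fused_g, split_g)
        pairs = {(e.upstream, e.downstream) for e in events}
        assert ("rps3", "rpl16") in pairs
        event = next(e for e in events if e.upstream == "rps3")
        assert event.fused_feature == "rps3-rpl16"
        assert event.no_internal_stop
        assert event.initiator_retained

    def test_identical_genomes_give_no_fusions(self):
        genome, _ = simulate_genome(seed=6)
        assert detect_fusions(genome, genome) == []


class TestInframeInsert:
    @pytest.fixture(scope="class")
    def insert_case(self):
        genome, _ = simulate_genome(seed=3)
        mod, truth = simulate_structural_events(
            genome, {"insert": {"gene": "nad2", "aa_start": 213,
                                "aa_len": 165}}, seed=6)
        mod2, _ = simulate_structural_events(mod, {"mutate": 0.03}, seed=7)
        return genome, mod, mod2, truth

    def test_planted_insert_boundaries_recovered_exactly(self, insert_case):
        genome, mod, mod2, truth = insert_case
        event = detect_inframe_insert(
            {"in1": protein(mod, "nad2"), "in2": protein(mod2, "nad2")},
            {"out": protein(genome, "nad2")}, gene="nad2")
        assert event is not None
        planted = (truth.events["insert"]["aa_start"],
                   truth.events["insert"]["aa_end"])
        assert event.boundaries["in1"] == planted
        assert event.boundaries["in2"] == planted
        assert event.insert_length_nt["in1"] % 3 == 0
        assert event.insert_length_nt["in1"] == truth.events["insert"]["insert_nt"]

    def test_flank_identity_exceeds_insert_identity_at_divergence(self):
        # in-group pair shares the insert; a diverged insert drops identity
        genome, _ = simulate_genome(seed=8)
        mod, _ = simulate_structural_events(
            genome, {"insert": {"gene": "cob", "aa_start": 100,
                                "aa_len": 50}}, seed=9)
        mod2, _ = simulate_structural_events(
            genome, {"insert": {"gene": "cob", "aa_start": 100,
                                "aa_len": 50}}, seed=10)  # different insert
        event = detect_inframe_insert(
            {"a": protein(mod, "cob"), "b": protein(mod2, "cob")},
            {"out": protein(genome, "cob")}, gene="cob")
        assert event is not None
        assert event.flank_identity_pct[0] > event.insert_identity_pct
        assert event.flank_identity_pct[1] > event.insert_identity_pct

    def test_identical_homologs_give_none(self, insert_case):
        genome, *_ = insert_case
        p = protein(genome, "nad2")
        assert detect_inframe_insert({"a": p, "b": p}, {"c": p}) is None

    def test_no_outgroup_is_an_error(self, insert_case):
        genome, mod, mod2, _ = insert_case
        with pytest.raises(ValueError, match="outgroup"):
            detect_inframe_insert({"a": protein(mod, "nad2"),
                                   "b": protein(mod2, "nad2")}, {})


class TestIntronInterruption:
    @pytest.fixture(scope="class")
    def cds(self):
        genome, _ = simulate_genome(seed=3)
        feat = max((f for f in genome.features if f.cls == "protein"),
                   key=lambda f: f.length(len(genome)))
        return spliced_sequence(genome, feat)

    def rnd(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_single_planted_intron(self, cds):
        locus = cds[:300] + self.rnd(150) + cds[300:]
        assert detect_intron_interruption(locus, cds) == [(301, 450)]

    def test_intronless_locus_empty(self, cds):
        assert detect_intron_interruption(cds, cds) == []

    def test_three_introns_with_divergent_exons(self, cds):
        locus = (cds[:200] + self.rnd(100, 1) + cds[200:500]
                 + self.rnd(180, 2) + cds[500:800] + self.rnd(90, 3)
                 + cds[800:])
        diverged = _mutate(np.random.default_rng(5), cds, 0.02)
        found = detect_intron_interruption(locus, diverged)
        expected = [(201, 300), (601, 780), (1081, 1170)]
        assert len(found) == 3
        for (fs, fe), (es, ee) in zip(found, expected):
            assert abs(fs - es) <= 3 and abs(fe - ee) <= 3

    def test_undecomposable_cdna_raises(self, cds):
        with pytest.raises(IntronDecompositionError):
            detect_intron_interruption(cds, self.rnd(len(cds) // 2, 9))


class TestTransSplice:
    @pytest.fixture(scope="class")
    def cds(self):
        genome, _ = simulate_genome(seed=3)
        return spliced_sequence(genome, genome.feature("cox3"))

    def test_exact_concatenation_empty_insert(self, cds):
        cut = 3 * 100
        junction = locate_trans_splice_junction(cds[:cut], cds[cut:],
                                                cds, gene="cox3")
        assert junction.junction_aa == (100, 101)
        assert junction.insert == ""
        assert junction.ambiguous_overlap == 0

    def test_penta_a_insert_recovered(self, cds):
        cut = 3 * 100
        transcript = cds[:cut] + "AAAAA" + cds[cut:]
        junction = locate_trans_splice_junction(cds[:cut], cds[cut:],
                                                transcript)
        assert junction.insert == "AAAAA"

    def test_upstream_editing_does_not_move_junction(self, cds):
        n_codons = len(cds) // 3
        cut_aa = n_codons // 2
        part1, part2, transcript, truth = simulate_trans_splice(
            cds, aa_cut=cut_aa, n_upstream_edits=10, seed=8)
        junction = locate_trans_splice_junction(part1, part2, transcript)
        assert junction.junction_aa == truth.events["junction_aa"]
        assert junction.insert == truth.events["insert"]


class TestSelfComparisonNegativeControls:
    def test_all_detectors_silent_on_self(self):
        genome, _ = simulate_genome(seed=12)
        assert detect_fusions(genome, genome) == []
        p = protein(genome, "cox1")
        assert detect_fission(p, {"cox1": p}) is None
        cds = spliced_sequence(genome, genome.feature("cox1"))
        assert detect_intron_interruption(cds, cds) == []
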