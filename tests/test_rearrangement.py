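import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinmito.rearrangement import (InsufficientOverlapError,
                                    SignedGeneOrder, SignedPermutation,
                                    apply_reversal, bfs_reversal_distance,
                                    build_joint_permutation,
                                    find_conserved_blocks, gene_order,
                                    reversal_distance)
from twinmito.simulate import apply_random_reversals, simulate_genome


def random_signed(rng, n):
    vals = rng.sample(range(1, n + 1), n)
    return [v * rng.choice([1, -1]) for v in vals]


class TestJointPermutation:
    def order(self, gid, entries, topology="linear"):
        return SignedGeneOrder(gid, entries, topology)

    def test_identical_orders_give_identity(self):
        entries = [("a", "+"), ("b", "-"), ("c", "+")]
        perm = build_joint_permutation(self.order("r", entries),
                                       self.order("q", entries))
        assert perm.is_identity()

    def test_constructed_inversion(self):
        ref = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+"), ("e", "+")]
        qry = [("a", "+"), ("d", "-"), ("c", "-"), ("b", "-"), ("e", "+")]
        perm = build_joint_permutation(self.order("r", ref),
                                       self.order("q", qry))
        assert perm.values == [1, -4, -3, -2, 5]

    def test_reference_minus_strand_defines_plus(self):
        ref = [("a", "-"), ("b", "+")]
        qry = [("a", "-"), ("b", "+"), ("c", "+")]
        perm = build_joint_permutation(self.order("r", ref + [("c", "+")]),
                                       self.order("q", qry))
        assert perm.is_identity()

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            build_joint_permutation(
                self.order("r", [("a", "+"), ("b", "+"), ("c", "+")]),
                self.order("q", [("a", "+"), ("x", "+"), ("y", "+")]))

    def test_duplicates_dropped_with_warning(self):
        ref = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")]
        qry = [("a", "+"), ("b", "+"), ("b", "-"), ("c", "+"), ("d", "+")]
        with pytest.warns(UserWarning, match="duplicated"):
            perm = build_joint_permutation(self.order("r", ref),
                                           self.order("q", qry))
        assert len(perm) == 3  # b dropped


class TestReversalDistance:
    def test_identity_zero(self):
        assert reversal_distance(SignedPermutation([1, 2, 3, 4])) == 0

    def test_whole_block_flip_is_one(self):
        assert reversal_distance(SignedPermutation([-3, -2, -1])) == 1

    def test_transposed_pair_needs_three(self):
        # frozen from the exhaustive BFS oracle: (+2,+1) is a hurdle
        assert reversal_distance(SignedPermutation([2, 1])) == 3
        assert bfs_reversal_distance(SignedPermutation([2, 1])) == 3

    def test_exhaustive_equivalence_small_n(self):
        for n in range(1, 5):
            for perm in itertools.permutations(range(1, n + 1)):
                for signs in itertools.product([1, -1], repeat=n):
                    vals = [p * s for p, s in zip(perm, signs)]
                    sp = SignedPermutation(vals)
                    assert reversal_distance(sp) == bfs_reversal_distance(sp), vals

    def test_random_equivalence_n_to_7(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randint(2, 7)
            sp = SignedPermutation(random_signed(rng, n))
            assert reversal_distance(sp) == bfs_reversal_distance(sp), sp.values

    def test_symmetric_under_inversion(self):
        rng = random.Random(7)
        for _ in range(50):
            n = rng.randint(2, 7)
            vals = random_signed(rng, n)
            inv = [0] * n
            for i, v in enumerate(vals, start=1):
                if v > 0:
                    inv[v - 1] = i
                else:
                    inv[-v - 1] = -i
            assert (reversal_distance(SignedPermutation(vals))
                    == reversal_distance(SignedPermutation(inv)))

    def test_one_extra_reversal_changes_distance_by_at_most_one(self):
        rng = random.Random(13)
        for _ in range(40):
            n = rng.randint(3, 7)
            vals = random_signed(rng, n)
            d0 = reversal_distance(SignedPermutation(vals))
            i, j = sorted(rng.sample(range(n), 2))
            d1 = reversal_distance(SignedPermutation(apply_reversal(vals, i, j)))
            assert abs(d1 - d0) <= 1

    def test_circular_rotation_and_reflection_invariance(self):
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randint(3, 7)
            vals = random_signed(rng, n)
            d0 = reversal_distance(SignedPermutation(vals, "circular"))
            for r in range(1, n):
                rot = vals[r:] + vals[:r]
                assert reversal_distance(
                    SignedPermutation(rot, "circular")) == d0
            refl = [-v for v in vals[::-1]]
            assert reversal_distance(SignedPermutation(refl, "circular")) == d0

    def test_k_reversals_bound(self):
        genome, _ = simulate_genome(seed=2)
        base = gene_order(genome)
        for k in (0, 1, 3, 6):
            shuffled, _ = apply_random_reversals(base, k, seed=k + 10)
            d = reversal_distance(build_joint_permutation(base, shuffled))
            assert d <= k
            if k == 0:
                assert d == 0

    def test_bfs_guard(self):
        with pytest.raises(ValueError, match="n <= 9"):
            bfs_reversal_distance(SignedPermutation(list(range(1, 12))))


class TestSyntenyBlocks:
    def orders(self, *entry_lists, topology="linear"):
        return [SignedGeneOrder(f"g{i}", e, topology)
                for i, e in enumerate(entry_lists)]

    def test_identical_orders_single_block(self):
        entries = [("a", "+"), ("b", "-"), ("c", "+"), ("d", "+")]
        blocks = find_conserved_blocks(self.orders(entries, list(entries)))
        assert len(blocks) == 1
        assert blocks[0].genes == ["a", "b", "c", "d"]

    def test_identical_circular_orders_single_wrapping_block(self):
        entries = [("a", "+"), ("b", "-"), ("c", "+")]
        blocks = find_conserved_blocks(
            self.orders(entries, list(entries), topology="circular"))
        assert len(blocks) == 1
        assert len(blocks[0]) == 3

    def test_internal_inversion_splits_runs_at_boundaries(self):
        ref = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+"), ("e", "+"),
               ("f", "+")]
        # invert c..d in the second genome
        qry = [("a", "+"), ("b", "+"), ("d", "-"), ("c", "-"), ("e", "+"),
               ("f", "+")]
        blocks = find_conserved_blocks(self.orders(ref, qry), min_len=2)
        assert sorted(tuple(b.genes) for b in blocks) == [
            ("a", "b"), ("c", "d"), ("e", "f")]

    def test_whole_block_strand_flip_preserved(self):
        ref = [("a", "+"), ("b", "-"), ("x", "+"), ("y", "+")]
        qry = [("b", "+"), ("a", "-"), ("x", "+"), ("y", "+")]
        blocks = find_conserved_blocks(self.orders(ref, qry), min_len=2)
        assert any(b.genes == ["a", "b"] for b in blocks)

    def test_shuffled_orders_yield_no_blocks(self):
        rng = random.Random(17)
        names = [f"g{i}" for i in range(30)]
        ref = [(n, "+") for n in names]
        shuffled = [(n, rng.choice("+-")) for n in rng.sample(names, 30)]
        blocks = find_conserved_blocks(self.orders(ref, shuffled), min_len=2)
        assert blocks == []

    def test_three_genomes_restrict_to_common(self):
        a = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")]
        b = [("a", "+"), ("b", "+"), ("z", "+"), ("c", "+"), ("d", "+")]
        c = [("a", "+"), ("b", "+"), ("d", "-"), ("c", "-")]
        blocks = find_conserved_blocks(self.orders(a, b, c), min_len=2)
        # only a-b is conserved in all three once z is ignored;
        # c-d flips relative order in the third genome but stays adjacent
        names = sorted(tuple(blk.genes) for blk in blocks)
        assert ("a", "b") in names


@st.composite
def signed_permutations(draw, max_n=6):
    n = draw(st.integers(min_value=2, max_value=max_n))
    order = draw(st.permutations(list(range(1, n + 1))))
    signs = draw(st.lists(st.sampled_from([1, -1]), min_size=n, max_size=n))
    return [v * s for v, s in zip(order, signs)]


@settings(max_examples=75, deadline=None, derandomize=True)
@given(signed_permutations())
def test_distance_equals_oracle_for_arbitrary_permutations(vals):
    """Hannenhalli–Pevzner distance agrees with exhaustive BFS everywhere."""
    sp = SignedPermutation(vals)
    assert reversal_distance(sp) == bfs_reversal_distance(sp)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(signed_permutations(), st.integers(min_value=0, max_value=5))
def test_applying_reversals_never_exceeds_count(vals, k):
    """Distance after k extra reversals grows by at most k."""
    rng = random.Random(k * 1000 + len(vals))
    d0 = reversal_distance(SignedPermutation(vals))
    cur = list(vals)
    for _ in range(k):
        i, j = sorted(rng.sample(range(len(cur)), 2)) if len(cur) > 1 else (0, 0)
        cur = apply_reversal(cur, i, j)
    assert reversal_distance(SignedPermutation(cur)) <= d0 + k


def test_gene_order_collapses_reader_suffixes():
    genome, _ = simulate_genome(seed=4)
    order = gene_order(genome)
    assert len(order.entries) == len(genome.features)
    assert all(s in "+-" for _, s in order.entries)
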