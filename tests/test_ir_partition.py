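"""Inverted-repeat detection and quadripartite partitioning, checked against
an exhaustive O(n^2) dynamic-programming oracle on small circles."""

import numpy as np
import pytest

import plastcomp as pc
from plastcomp.ir_partition import interval_contains, interval_length


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def oracle_inverted_repeat(seq, min_len):
    """All-cells DP for the longest disjoint reverse-complement interval pair.

    Builds the full common-substring run-length matrix between the doubled
    sequence and its reverse complement, then for every cell admits the
    longest sub-match whose two intervals are disjoint on the circle.
    Independent of the seed-and-extend path it checks.
    """
    n = len(seq)
    A = seq + seq
    B = pc.revcomp(A)
    m = len(A)
    a = np.frombuffer(A.encode(), np.uint8)
    b = np.frombuffer(B.encode(), np.uint8)

    def circle_pair(a_start, b_start, L):
        # b_start indexes B; map the B interval back onto the forward strand
        p = 2 * n - b_start - L  # forward start (0-based) of the B interval
        if L > n // 2:
            return None
        iv_a = (a_start % n + 1, (a_start + L - 1) % n + 1)
        iv_b = (p % n + 1, (p + L - 1) % n + 1)
        from plastcomp.ir_partition import _disjoint

        if not _disjoint(iv_a, iv_b, n):
            return None
        return tuple(sorted([iv_a, iv_b]))

    best = None  # (length, first, second)
    prev = np.zeros(m + 1, np.int32)
    for i in range(1, m + 1):
        cur = np.zeros(m + 1, np.int32)
        match = a[i - 1] == b
        cur[1:][match] = prev[:-1][match] + 1
        for j in np.nonzero(cur >= min_len)[0]:
            R = int(cur[j])
            # ends fixed at (i, j); feasibility is monotone in the length
            lo, hi, found = min_len, R, None
            while lo <= hi:
                mid = (lo + hi) // 2
                pair = circle_pair(i - mid, j - mid, mid)
                if pair is not None:
                    found = (mid, pair)
                    lo = mid + 1
                else:
                    hi = mid - 1
            if found is not None:
                L, (first, second) = found
                cand = (L, first, second)
                if (
                    best is None
                    or L > best[0]
                    or (L == best[0] and (first, second) < (best[1], best[2]))
                ):
                    best = cand
        prev = cur
    return best


def planted_genome(rng, r1=1000, x=300, r2=200):
    """R1 + X + R2 + revcomp(X): IR copies of length x at known positions."""
    part1 = random_seq(rng, r1)
    ir = random_seq(rng, x)
    part2 = random_seq(rng, r2)
    seq = part1 + ir + part2 + pc.revcomp(ir)
    return pc.GenomeRecord(id="planted", sequence=seq), (r1 + 1, r1 + x), (
        r1 + x + r2 + 1,
        r1 + 2 * x + r2,
    )


class TestFindInvertedRepeat:
    def test_planted_ir_recovered(self):
        rng = np.random.default_rng(0)
        genome, iv1, iv2 = planted_genome(rng)
        found = pc.find_inverted_repeat(genome, min_len=100)
        assert found is not None
        assert found.length >= 300
        # the planted copies are contained in what is found
        assert interval_contains(found.first, iv1[0], len(genome)) or found.first == iv1
        assert found.second[1] == iv2[1] or found.length > 300

    def test_ir_copies_are_exact_revcomp(self):
        rng = np.random.default_rng(1)
        genome, _, _ = planted_genome(rng)
        found = pc.find_inverted_repeat(genome, min_len=100)
        s1 = genome.slice(*found.first)
        s2 = genome.slice(*found.second)
        assert s2 == pc.revcomp(s1)

    def test_no_ir_is_a_result_not_an_error(self):
        rng = np.random.default_rng(2)
        genome = pc.GenomeRecord(id="r", sequence=random_seq(rng, 5000))
        assert pc.find_inverted_repeat(genome, min_len=1000) is None
        assert oracle_inverted_repeat(genome.sequence, 1000) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_dp_oracle_on_random_circles(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(200, 450))
        seq = random_seq(rng, length, alphabet="ACGT")
        if seed % 2:  # plant a small IR in half the cases
            ir = random_seq(rng, int(rng.integers(20, 50)))
            pos = int(rng.integers(0, length // 2))
            pos2 = int(rng.integers(length // 2, length - len(ir)))
            seq = seq[:pos] + ir + seq[pos + len(ir):pos2] + pc.revcomp(ir) + seq[pos2 + len(ir):]
        genome = pc.GenomeRecord(id="r", sequence=seq)
        expected = oracle_inverted_repeat(seq, min_len=12)
        found = pc.find_inverted_repeat(genome, min_len=12, seed_len=8)
        if expected is None:
            assert found is None
        else:
            assert found is not None
            assert found.length == expected[0]
            assert (found.first, found.second) == (expected[1], expected[2])


class TestPartition:
    def test_planted_lengths(self):
        rng = np.random.default_rng(0)
        genome, _, _ = planted_genome(rng, r1=1000, x=300, r2=200)
        found = pc.find_inverted_repeat(genome, min_len=100)
        struct = pc.partition_regions(genome, found)
        assert struct.lengths == {"LSC": 1000, "IRb": 300, "SSC": 200, "IRa": 300}
        assert sum(struct.lengths.values()) == len(genome)

    def test_region_lengths_sum_under_rotation(self, truth):
        genome = truth.genome
        n = len(genome)
        base = pc.partition_regions(genome, pc.find_inverted_repeat(genome, min_len=500))
        for offset in (1, 137, n // 2, n - 3):
            rotated = pc.GenomeRecord(
                id="rot", sequence=genome.sequence[offset:] + genome.sequence[:offset]
            )
            found = pc.find_inverted_repeat(rotated, min_len=500)
            struct = pc.partition_regions(rotated, found)
            assert struct.lengths == base.lengths

    def test_single_copy_tie_flagged(self):
        rng = np.random.default_rng(5)
        sc = random_seq(rng, 150)
        sc2 = random_seq(rng, 150)
        ir = random_seq(rng, 60)
        genome = pc.GenomeRecord(id="tie", sequence=sc + ir + sc2 + pc.revcomp(ir))
        pair = pc.InvertedRepeatPair(first=(151, 210), second=(361, 420), length=60)
        struct = pc.partition_regions(genome, pair)
        assert struct.sc_tie
        assert struct.lsc[0] < struct.ssc[0]  # first segment in linear order wins


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0), ("ATGCNNNN", 0.5)],
    )
    def test_fraction(self, seq, expected):
        assert pc.gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_missing(self):
        assert pc.gc_content("NNNN") is None

    def test_region_gc_populated(self, truth):
        assert set(truth.structure.gc) == {"whole", "LSC", "IRb", "SSC", "IRa"}
        assert all(0 <= v <= 1 for v in truth.structure.gc.values())


class TestJunctions:
    def test_spanning_gene_reported(self):
        struct = pc.QuadripartiteStructure(
            lsc=(1, 1000), irb=(1001, 1300), ssc=(1301, 1500), ira=(1501, 1800),
            genome_length=1800,
        )
        feats = [pc.FeatureAnnotation(gene="span", kind="CDS", intervals=[(990, 1010)])]
        rep = pc.junction_report(struct, feats)
        assert rep.junctions["LSC/IRb"].coordinate == 1000
        assert rep.junctions["LSC/IRb"].spanning == ["span"]

    def test_distances_nonnegative_and_identity(self, truth):
        rep = pc.junction_report(truth.structure, truth.features)
        for info in rep.junctions.values():
            if info.upstream:
                assert info.upstream.distance >= 0
            if info.downstream:
                assert info.downstream.distance >= 0
        # identical structures are pairwise junction-identical
        rep2 = pc.junction_report(truth.structure, truth.features)
        assert pc.junction_identical(rep, rep2)

    def test_empty_features_empty_report(self, truth):
        rep = pc.junction_report(truth.structure, [])
        for info in rep.junctions.values():
            assert info.spanning == []
            assert info.upstream is None and info.downstream is None
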