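"""Flank extraction, Karlin-Altschul similarity, and cross-genome grouping."""

from math import exp, inf

import numpy as np
import pytest

import plastcomp as pc
from plastcomp.ssr_compare import (
    best_gapless_scores,
    e_value,
    karlin_altschul_lambda,
)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="module")
def six_genomes(truth):
    """Ancestor plus five derived genomes (point mutations and tiny indels)."""
    genomes = [truth.genome]
    for i in range(5):
        pair = pc.mutate_genome(
            truth, n_snp=30, indel_events=[(1, False)] * 3,
            seed=100 + i, derived_id=f"iso{i}",
        )
        genomes.append(pair.derived)
    return genomes


@pytest.fixture(scope="module")
def six_genome_flanks(six_genomes):
    flanked = []
    for g in six_genomes:
        ir = pc.find_inverted_repeat(g, min_len=500)
        struct = pc.partition_regions(g, ir)
        for locus in pc.detect_ssrs(g, struct):
            flanked.append(pc.extract_flanks(locus, g))
    return flanked


class TestExtractFlanks:
    def test_full_flanks_on_large_genome(self, truth):
        locus = pc.detect_ssrs(truth.genome)[2]
        fl = pc.extract_flanks(locus, truth.genome, max_flank=60)
        assert len(fl.left_flank) == 60 and len(fl.right_flank) == 60
        assert fl.left_flank == truth.genome.slice(locus.start - 60, locus.start - 1)
        assert fl.right_flank == truth.genome.slice(locus.end + 1, locus.end + 60)

    def test_truncation_on_linear_sequence(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 200)
        genome = pc.GenomeRecord(id="lin", sequence=seq, circular=False)
        locus = pc.SSRLocus(genome_id="lin", start=20, end=30, unit="A",
                            copies=11, category="normal")
        fl = pc.extract_flanks(locus, genome)
        assert len(fl.left_flank) == 19
        assert fl.left_flank == seq[:19]

    def test_wrap_on_circular_genome(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 300)
        genome = pc.GenomeRecord(id="circ", sequence=seq, circular=True)
        locus = pc.SSRLocus(genome_id="circ", start=290, end=300, unit="A",
                            copies=11, category="normal")
        fl = pc.extract_flanks(locus, genome)
        assert fl.right_flank == seq[:60]
        assert len(fl.left_flank) == 60


class TestSimilarity:
    def test_lambda_solves_the_score_equation(self):
        lam = karlin_altschul_lambda(1, -2)
        assert 0.25 * exp(lam) + 0.75 * exp(-2 * lam) == pytest.approx(1.0, abs=1e-12)

    def test_identical_flanks_are_similar(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 120)
        locus = pc.SSRLocus(genome_id="a", start=1, end=10, unit="A",
                            copies=10, category="normal")
        fa = pc.FlankedSSR(ssr=locus, left_flank=seq[:60], right_flank=seq[60:])
        score, e = pc.flank_similarity(fa, fa)
        assert score == 120
        assert e < 1e-10

    def test_empty_flanks_never_similar(self):
        locus = pc.SSRLocus(genome_id="a", start=1, end=10, unit="A",
                            copies=10, category="normal")
        fa = pc.FlankedSSR(ssr=locus, left_flank="", right_flank="")
        fb = pc.FlankedSSR(ssr=locus, left_flank="ACGT" * 30, right_flank="")
        assert pc.flank_similarity(fa, fb)[1] == inf

    def test_similarity_is_symmetric(self):
        rng = np.random.default_rng(3)
        locus = pc.SSRLocus(genome_id="a", start=1, end=10, unit="A",
                            copies=10, category="normal")
        fa = pc.FlankedSSR(ssr=locus, left_flank=random_seq(rng, 60),
                           right_flank=random_seq(rng, 60))
        fb = pc.FlankedSSR(ssr=locus, left_flank=random_seq(rng, 60),
                           right_flank=random_seq(rng, 60))
        assert pc.flank_similarity(fa, fb) == pc.flank_similarity(fb, fa)

    def test_random_flanks_not_similar_monte_carlo(self):
        """Null calibration: over 10^4 independent random 120 bp pairs the
        empirical probability of e <= 1e-10 is below 1e-3."""
        rng = np.random.default_rng(4)
        n_pairs = 10_000
        codes = rng.integers(0, 4, size=(2 * n_pairs, 120))
        seqs = ["".join("ACGT"[c] for c in row) for row in codes]
        xs, ys = seqs[:n_pairs], seqs[n_pairs:]
        scores = best_gapless_scores(xs, ys)
        hits = sum(
            1 for s in scores if e_value(int(s), 120, 120) <= 1e-10
        )
        assert hits / n_pairs < 1e-3

    def test_gapless_score_matches_tiny_dp(self):
        # independent quadratic-time reference on short strings
        def ref(x, y):
            best = 0
            for i in range(len(x)):
                for j in range(len(y)):
                    run = 0
                    cur = 0
                    k = 0
                    while i + k < len(x) and j + k < len(y):
                        cur += 1 if x[i + k] == y[j + k] else -2
                        if cur < 0:
                            break
                        run = max(run, cur)
                        k += 1
                    best = max(best, run)
            return best

        rng = np.random.default_rng(5)
        for _ in range(20):
            x = random_seq(rng, int(rng.integers(0, 30)))
            y = random_seq(rng, int(rng.integers(1, 30)))
            got = int(best_gapless_scores([x], [y])[0])
            assert got == ref(x, y)


class TestClustering:
    def test_orthologous_ssrs_form_complete_groups(self, six_genome_flanks, six_genomes):
        groups = pc.cluster_ssrs(six_genome_flanks)
        spectrum = pc.group_spectrum(groups)
        # point mutations only: every planted locus set stays one type-6 group
        assert set(spectrum) == {6}
        assert spectrum[6][1] == len(six_genome_flanks)

    def test_conservation_identity(self, six_genome_flanks):
        groups = pc.cluster_ssrs(six_genome_flanks)
        spectrum = pc.group_spectrum(groups)
        assert sum(nm for _, nm in spectrum.values()) == len(six_genome_flanks)

    def test_order_invariance(self, six_genome_flanks):
        groups_fwd = pc.cluster_ssrs(six_genome_flanks)
        groups_rev = pc.cluster_ssrs(list(reversed(six_genome_flanks)))
        key = lambda gs: sorted(
            tuple(sorted((m.ssr.genome_id, m.ssr.start) for m in g.members))
            for g in gs
        )
        assert key(groups_fwd) == key(groups_rev)

    def test_shuffled_flanks_become_singleton(self, six_genome_flanks):
        rng = np.random.default_rng(6)
        flanked = [
            pc.FlankedSSR(
                ssr=f.ssr,
                left_flank="".join(rng.permutation(list(f.left_flank))),
                right_flank="".join(rng.permutation(list(f.right_flank))),
            )
            if i == 0 else f
            for i, f in enumerate(six_genome_flanks)
        ]
        groups = pc.cluster_ssrs(flanked)
        by_locus = {
            (m.ssr.genome_id, m.ssr.start): g for g in groups for m in g.members
        }
        shuffled = flanked[0].ssr
        assert len(by_locus[(shuffled.genome_id, shuffled.start)].members) == 1

    def test_within_genome_edges_ignored(self, truth):
        # both IR copies of one genome alone never merge into one group
        flanked = []
        ir = pc.find_inverted_repeat(truth.genome, min_len=500)
        struct = pc.partition_regions(truth.genome, ir)
        for locus in pc.detect_ssrs(truth.genome, struct):
            flanked.append(pc.extract_flanks(locus, truth.genome))
        groups = pc.cluster_ssrs(flanked)
        assert all(len(g.members) == 1 for g in groups)


class TestGroupSpectrum:
    def test_simple_spectrum(self, truth):
        locus = pc.detect_ssrs(truth.genome)[0]
        mk = lambda gid: pc.FlankedSSR(
            ssr=pc.SSRLocus(genome_id=gid, start=locus.start, end=locus.end,
                            unit=locus.unit, copies=locus.copies,
                            category=locus.category),
            left_flank="", right_flank="")
        groups = [
            pc.SSRGroup(members=[mk(f"g{i}") for i in range(6)]),
            pc.SSRGroup(members=[mk("g0")]),
            pc.SSRGroup(members=[mk("g1")]),
        ]
        assert pc.group_spectrum(groups) == {6: (1, 6), 1: (2, 2)}

    def test_reported_spectrum_arithmetic_is_conservative(self):
        # a six-genome study spectrum must account for every input locus:
        # 117 complete groups of 6 + 21x5 + 5x4 + 3x3 + 4x2 + 20 singletons
        spectrum = {6: (117, 702), 5: (21, 105), 4: (5, 20), 3: (3, 9),
                    2: (4, 8), 1: (20, 20)}
        members = sum(nm for _, nm in spectrum.values())
        assert members == sum(t * ng for t, (ng, _) in spectrum.items())
        assert members == 864 == 143 + 144 + 145 + 144 + 144 + 144

    def test_empty_input(self):
        assert pc.group_spectrum([]) == {}
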