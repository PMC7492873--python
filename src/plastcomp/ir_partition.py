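"""Quadripartite structure of a plastome: IR detection, region partition, GC,
and IR-junction gene context.

A typical plastome is a circle of four regions in the order
LSC - IRb - SSC - IRa, where the two inverted-repeat copies are exact reverse
complements of each other and the large single-copy region is longer than the
small one. Intervals here are 1-based inclusive on the linearised circle; an
interval whose end is smaller than its start wraps across the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_io import FeatureAnnotation, GenomeRecord, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def interval_length(iv: tuple[int, int], n: int) -> int:
    s, e = iv
    return (e - s) % n + 1


def interval_contains(iv: tuple[int, int], pos: int, n: int) -> bool:
    s, e = iv
    return (pos - s) % n <= (e - s) % n


def _disjoint(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    return not (
        interval_contains(a, b[0], n)
        or interval_contains(a, b[1], n)
        or interval_contains(b, a[0], n)
        or interval_contains(b, a[1], n)
    )


@dataclass(frozen=True)
class InvertedRepeatPair:
    """Two disjoint intervals, the second the reverse complement of the first."""

    first: tuple[int, int]
    second: tuple[int, int]
    length: int
    mismatches: int = 0


@dataclass
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals with lengths and per-region GC fractions."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    gc: dict[str, float | None] = field(default_factory=dict)
    sc_tie: bool = False  # equal single-copy lengths; LSC chosen by linear order

    @property
    def lengths(self) -> dict[str, int]:
        n = self.genome_length
        return {
            "LSC": interval_length(self.lsc, n),
            "IRb": interval_length(self.irb, n),
            "SSC": interval_length(self.ssc, n),
            "IRa": interval_length(self.ira, n),
        }

    @property
    def ir_length(self) -> int:
        return interval_length(self.irb, self.genome_length)

    def region_of(self, pos: int) -> str:
        n = self.genome_length
        for name, iv in (("LSC", self.lsc), ("IRb", self.irb),
                         ("SSC", self.ssc), ("IRa", self.ira)):
            if interval_contains(iv, pos, n):
                return name
        return "none"


def find_inverted_repeat(
    genome: GenomeRecord,
    min_len: int = 1000,
    max_mismatch: int = 0,
    seed_len: int = 12,
) -> InvertedRepeatPair | None:
    """Locate the longest pair of disjoint intervals where one is the reverse
    complement of the other (the plastome IR pair).

    Seed-and-extend over the doubled sequence so repeats wrapping the circular
    origin are found. With ``max_mismatch`` 0 (the default) the reported copies
    are exact reverse complements; a small mismatch budget is spent greedily
    during extension. Ties on length are broken by the smaller start coordinate
    of the first interval. Returns ``None`` when no repeat of at least
    ``min_len`` exists (a single-copy genome), which is a result, not an error.
    """
    n = len(genome)
    if n < 2 * min_len:
        return None
    k = max(1, min(seed_len, min_len))
    s2 = genome.sequence + genome.sequence if genome.circular else genome.sequence
    m2 = len(s2)

    index: dict[str, list[int]] = {}
    for i in range(m2 - k + 1):
        index.setdefault(s2[i : i + k], []).append(i)

    # anti-diagonal (a+b at seed scale) -> list of covered seed-a ranges
    covered: dict[int, list[tuple[int, int]]] = {}
    candidates: set[tuple[int, int, int, int]] = set()

    for a in range(n):  # seeds only from the first copy
        kmer = s2[a : a + k]
        rc = revcomp(kmer)
        for b in index.get(rc, ()):  # S2[b:b+k] == revcomp(S2[a:a+k])
            diag = a + b
            done = False
            for lo, hi in covered.get(diag, ()):
                if lo <= a <= hi:
                    done = True
                    break
            if done:
                continue
            a0, b0, L = a, b, k
            budget = max_mismatch
            mism = 0
            # extend left of A / right of B
            while a0 > 0 and b0 + L < m2:
                if s2[b0 + L] == _COMP[s2[a0 - 1]]:
                    a0 -= 1
                    L += 1
                elif mism < budget:
                    a0 -= 1
                    L += 1
                    mism += 1
                else:
                    break
            # extend right of A / left of B
            while a0 + L < m2 and b0 > 0:
                if s2[b0 - 1] == _COMP[s2[a0 + L]]:
                    b0 -= 1
                    L += 1
                elif mism < budget:
                    b0 -= 1
                    L += 1
                    mism += 1
                else:
                    break
            # trim mismatched ends so maximal matches end on a match
            while L > 0 and s2[b0 + L - 1] != _COMP[s2[a0]]:
                a0 += 1
                L -= 1
                mism -= 1
            while L > 0 and s2[b0] != _COMP[s2[a0 + L - 1]]:
                b0 += 1
                L -= 1
                mism -= 1
            if L >= min_len:
                candidates.add((a0, b0, L, max(mism, 0)))
            seed_diag = a0 + b0 + L - k
            covered.setdefault(seed_diag, []).append((a0, a0 + L - k))

    def circle_pair(a0: int, b0: int, L: int) -> tuple[tuple[int, int], tuple[int, int]] | None:
        if L > n // 2:
            return None  # the two copies cannot both fit on the circle
        iv_a = (a0 % n + 1, (a0 + L - 1) % n + 1)
        iv_b = (b0 % n + 1, (b0 + L - 1) % n + 1)
        if not _disjoint(iv_a, iv_b, n):
            return None
        return iv_a, iv_b

    # a self-overlapping maximal match (palindrome-like) may still contain a
    # valid disjoint sub-match: shrink from either end, largest L' first
    trimmed: set[tuple[int, int, int, int]] = set()
    for a0, b0, L, mism in candidates:
        if circle_pair(a0, b0, L) is not None:
            continue
        for keep_left in (True, False):
            lo, hi, bestL = min_len, min(L, n // 2), None
            while lo <= hi:
                mid = (lo + hi) // 2
                if keep_left:
                    ok = circle_pair(a0, b0 + L - mid, mid)
                else:
                    ok = circle_pair(a0 + L - mid, b0, mid)
                if ok is not None:
                    bestL = mid
                    lo = mid + 1
                else:
                    hi = mid - 1
            if bestL is not None:
                if keep_left:
                    trimmed.add((a0, b0 + L - bestL, bestL, mism))
                else:
                    trimmed.add((a0 + L - bestL, b0, bestL, mism))
    candidates |= trimmed

    best: InvertedRepeatPair | None = None
    seen_pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for a0, b0, L, mism in candidates:
        pair = circle_pair(a0, b0, L)
        if pair is None:
            continue
        iv_a, iv_b = pair
        first, second = sorted([iv_a, iv_b])
        if (first, second) in seen_pairs:
            continue
        seen_pairs.add((first, second))
        cand = InvertedRepeatPair(first=first, second=second, length=L, mismatches=mism)
        if (
            best is None
            or cand.length > best.length
            or (cand.length == best.length and cand.first[0] < best.first[0])
        ):
            best = cand
    return best


def gc_content(sequence: str) -> float | None:
    """(G+C)/(A+C+G+T); N is excluded from the denominator. ``None`` when the
    sequence has no unambiguous base (e.g. all-N)."""
    gc = sequence.count("G") + sequence.count("C")
    acgt = gc + sequence.count("A") + sequence.count("T")
    if acgt == 0:
        return None
    return gc / acgt


def partition_regions(
    genome: GenomeRecord, ir_pair: InvertedRepeatPair
) -> QuadripartiteStructure:
    """Partition the circle into LSC / IRb / SSC / IRa around the IR pair.

    The two single-copy segments between the IR copies are labelled LSC
    (longer) and SSC (shorter); IRb is the IR copy that immediately follows the
    LSC in circular order, IRa the other. On a single-copy length tie the
    segment earlier in linear order becomes the LSC and the structure is
    flagged. Region lengths always sum exactly to the genome length.
    """
    n = len(genome)
    ir1, ir2 = ir_pair.first, ir_pair.second
    if not _disjoint(ir1, ir2, n):
        raise ValueError("IR copies overlap; cannot partition")

    def gap_after(iv_from: tuple[int, int], iv_to: tuple[int, int]) -> tuple[tuple[int, int], int]:
        start = iv_from[1] % n + 1
        end = (iv_to[0] - 2) % n + 1
        length = (iv_to[0] - iv_from[1] - 1) % n
        return (start, end), length

    gap_a, len_a = gap_after(ir1, ir2)  # between end of first IR and start of second
    gap_b, len_b = gap_after(ir2, ir1)
    if len_a == 0 or len_b == 0:
        raise ValueError("adjacent IR copies leave no single-copy region")

    sc_tie = len_a == len_b
    if len_a > len_b or (sc_tie and (gap_a[0] < gap_b[0])):
        lsc, ssc = gap_a, gap_b
        irb, ira = ir2, ir1  # IRb follows the LSC
    else:
        lsc, ssc = gap_b, gap_a
        irb, ira = ir1, ir2

    struct = QuadripartiteStructure(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n, sc_tie=sc_tie
    )
    lengths = struct.lengths
    assert sum(lengths.values()) == n, "region lengths must sum to genome length"
    assert lengths["IRb"] == lengths["IRa"]

    struct.gc = {
        "whole": gc_content(genome.sequence),
        "LSC": gc_content(genome.slice(*lsc)),
        "IRb": gc_content(genome.slice(*irb)),
        "SSC": gc_content(genome.slice(*ssc)),
        "IRa": gc_content(genome.slice(*ira)),
    }
    return struct


@dataclass
class JunctionSide:
    gene: str
    distance: int


@dataclass
class JunctionInfo:
    coordinate: int
    spanning: list[str]
    upstream: JunctionSide | None
    downstream: JunctionSide | None


@dataclass
class JunctionReport:
    """Gene context of the four region boundaries.

    The junction coordinate is defined as the last base of the upstream region,
    so the LSC/IRb junction is the LSC end. A feature spans a junction when its
    interval contains both the junction base and the following one.
    """

    junctions: dict[str, JunctionInfo]

    def signature(self) -> tuple:
        sig = []
        for name in ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC"):
            j = self.junctions[name]
            sig.append((
                name,
                tuple(sorted(j.spanning)),
                j.upstream.gene if j.upstream else "",
                j.downstream.gene if j.downstream else "",
            ))
        return tuple(sig)


def junction_report(
    structure: QuadripartiteStructure, features: Sequence[FeatureAnnotation]
) -> JunctionReport:
    """Report, for each of the four junctions, the genes spanning it and the
    nearest gene on each side with its distance (0 when abutting)."""
    n = structure.genome_length
    coords = {
        "LSC/IRb": structure.lsc[1],
        "IRb/SSC": structure.irb[1],
        "SSC/IRa": structure.ssc[1],
        "IRa/LSC": structure.ira[1],
    }
    out: dict[str, JunctionInfo] = {}
    for name, j in coords.items():
        j_next = j % n + 1
        spanning = []
        up_best: JunctionSide | None = None
        down_best: JunctionSide | None = None
        for feat in features:
            s, e = feat.span
            if interval_contains((s, e), j, n) and interval_contains((s, e), j_next, n):
                spanning.append(feat.gene)
                continue
            d_up = (j - e) % n
            if interval_contains((s, e), j, n):
                d_up = 0
            if up_best is None or d_up < up_best.distance:
                up_best = JunctionSide(gene=feat.gene, distance=d_up)
            d_down = (s - j_next) % n
            if interval_contains((s, e), j_next, n):
                d_down = 0
            if down_best is None or d_down < down_best.distance:
                down_best = JunctionSide(gene=feat.gene, distance=d_down)
        out[name] = JunctionInfo(
            coordinate=j, spanning=sorted(spanning), upstream=up_best, downstream=down_best
        )
    return JunctionReport(junctions=out)


def junction_identical(a: JunctionReport, b: JunctionReport) -> bool:
    """True when the same genes span/flank all four junctions in both genomes."""
    return a.signature() == b.signature()
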