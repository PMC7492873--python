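"""Cross-genome grouping of SSR loci by flanking-sequence similarity.

Orthologous microsatellites in different genomes sit in homologous sequence
neighbourhoods even when the repeat motif itself has mutated, so loci are
linked by comparing up to 60 bp of flanking sequence on each side. Similarity
is the best gapless local alignment score between the concatenated flanks
(match +1 / mismatch -2), converted to a Karlin-Altschul e-value
``E = K * m * n * exp(-lambda * S)``; two loci are similar when E is at or
below the cutoff (default 1e-10). Groups are single-linkage connected
components of the similarity graph, with edges drawn only between loci from
different genomes so that IR-duplicated copies within one genome cannot merge
unrelated groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import exp, inf, log
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .genome_io import GenomeRecord
from .ssr_detect import SSRLocus

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_CUTOFF = 1e-10
DEFAULT_MAX_FLANK = 60

#: K for ungapped +1/-2 nucleotide comparison under uniform base composition,
#: the published parameter for this scheme; configurable in the e-value call.
DEFAULT_K = 0.621


@dataclass
class FlankedSSR:
    """An SSR locus with up to ``max_flank`` bp of sequence on each side.

    Flanks exclude the repeat span itself, wrap across the origin on circular
    genomes and truncate at the ends of linear ones.
    """

    ssr: SSRLocus
    left_flank: str
    right_flank: str

    @property
    def concat(self) -> str:
        return self.left_flank + self.right_flank


@dataclass
class SSRGroup:
    members: list[FlankedSSR]
    label: str = ""

    @property
    def genomes(self) -> set[str]:
        return {m.ssr.genome_id for m in self.members}

    @property
    def group_type(self) -> int:
        return len(self.genomes)


def extract_flanks(
    ssr: SSRLocus, genome: GenomeRecord, max_flank: int = DEFAULT_MAX_FLANK
) -> FlankedSSR:
    """Take up to ``max_flank`` bases either side of the locus.

    On a circular genome each flank is additionally capped at the number of
    non-repeat bases available, so a flank never wraps into the repeat itself.
    """
    n = len(genome)
    span = ssr.span
    if genome.circular:
        avail = max(0, n - span)
        lf = min(max_flank, avail)
        rf = min(max_flank, avail)
        left = "".join(genome.base(p) for p in range(ssr.start - lf, ssr.start))
        right = "".join(genome.base(p) for p in range(ssr.end + 1, ssr.end + 1 + rf))
    else:
        left = genome.sequence[max(0, ssr.start - 1 - max_flank) : ssr.start - 1]
        right = genome.sequence[ssr.end : ssr.end + max_flank]
    return FlankedSSR(ssr=ssr, left_flank=left, right_flank=right)


@lru_cache(maxsize=None)
def karlin_altschul_lambda(match: int = DEFAULT_MATCH, mismatch: int = DEFAULT_MISMATCH) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies.

    With four equifrequent bases the equation reduces to
    ``(1/4) e^(lambda*match) + (3/4) e^(lambda*mismatch) = 1``.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 > mismatch")

    def f(lam: float) -> float:
        return 0.25 * exp(lam * match) + 0.75 * exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


def e_value(
    score: float, m: int, n: int,
    match: int = DEFAULT_MATCH, mismatch: int = DEFAULT_MISMATCH, K: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expected number of chance local alignments >= score."""
    if m == 0 or n == 0:
        return inf
    lam = karlin_altschul_lambda(match, mismatch)
    return K * m * n * exp(-lam * score)


_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str, pad_to: int, pad_code: int) -> np.ndarray:
    arr = np.full(pad_to, pad_code, dtype=np.int8)
    for i, ch in enumerate(seq):
        arr[i] = _CODES.get(ch, 6)  # N and pads never match anything
    return arr


def best_gapless_scores(
    xs: Sequence[str], ys: Sequence[str],
    match: int = DEFAULT_MATCH, mismatch: int = DEFAULT_MISMATCH,
) -> np.ndarray:
    """Best gapless (Smith-Waterman without gaps) local score for each pair.

    Vectorised over pairs: a diagonal-wise maximum-subarray recurrence run in
    lockstep across the whole batch. Empty-vs-anything pairs score 0.
    """
    if len(xs) != len(ys):
        raise ValueError("xs and ys must pair up")
    P = len(xs)
    if P == 0:
        return np.zeros(0, dtype=np.int32)
    mx = max(1, max(len(x) for x in xs))
    my = max(1, max(len(y) for y in ys))
    Xb = np.stack([_encode(x, mx, 4) for x in xs])
    Yb = np.stack([_encode(y, my, 5) for y in ys])
    running = np.zeros((P, my), dtype=np.int32)
    best = np.zeros(P, dtype=np.int32)
    shifted = np.zeros_like(running)
    for i in range(mx):
        s_i = np.where(Xb[:, i : i + 1] == Yb, match, mismatch).astype(np.int32)
        shifted[:, 0] = 0
        shifted[:, 1:] = running[:, :-1]
        running = np.maximum(shifted + s_i, 0)
        np.maximum(best, running.max(axis=1), out=best)
    return best


def flank_similarity(
    a: FlankedSSR, b: FlankedSSR,
    match: int = DEFAULT_MATCH, mismatch: int = DEFAULT_MISMATCH,
    K: float = DEFAULT_K,
) -> tuple[int, float]:
    """Score and e-value of the best gapless local alignment between the
    concatenated (left + right) flanks of two loci."""
    x, y = a.concat, b.concat
    if not x or not y:
        return 0, inf
    score = int(best_gapless_scores([x], [y], match, mismatch)[0])
    return score, e_value(score, len(x), len(y), match, mismatch, K)


def cluster_ssrs(
    flanked: Sequence[FlankedSSR],
    cutoff: float = DEFAULT_CUTOFF,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    K: float = DEFAULT_K,
    batch_size: int = 20000,
) -> list[SSRGroup]:
    """Single-linkage groups over the cross-genome flank-similarity graph.

    Only pairs from different genomes are scored; components of size one are
    singleton groups. The result is invariant to input order (members are
    sorted canonically and groups by their first member).
    """
    items = list(flanked)
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if items[i].ssr.genome_id != items[j].ssr.genome_id
        and items[i].concat and items[j].concat
    ]
    lam = karlin_altschul_lambda(match, mismatch)
    for lo in range(0, len(pairs), batch_size):
        chunk = pairs[lo : lo + batch_size]
        xs = [items[i].concat for i, _ in chunk]
        ys = [items[j].concat for _, j in chunk]
        scores = best_gapless_scores(xs, ys, match, mismatch)
        for (i, j), s, x, y in zip(chunk, scores, xs, ys):
            # e <= cutoff  <=>  S >= (ln(K m n) - ln cutoff) / lambda
            thresh = (log(K * len(x) * len(y)) - log(cutoff)) / lam
            if s >= thresh:
                union(i, j)

    comps: dict[int, list[FlankedSSR]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i])
    groups = [
        SSRGroup(members=sorted(ms, key=lambda f: (f.ssr.genome_id, f.ssr.start)))
        for ms in comps.values()
    ]
    groups.sort(key=lambda g: (g.members[0].ssr.genome_id, g.members[0].ssr.start))
    for idx, g in enumerate(groups, 1):
        g.label = f"group_{idx}"
    return groups


def group_spectrum(groups: Sequence[SSRGroup]) -> dict[int, tuple[int, int]]:
    """``{group_type: (n_groups, n_member_SSRs)}``.

    Conservation identity: the member counts summed over all types equal the
    total number of input loci; this is asserted on every call.
    """
    spectrum: dict[int, tuple[int, int]] = {}
    for g in groups:
        t = g.group_type
        ng, nm = spectrum.get(t, (0, 0))
        spectrum[t] = (ng + 1, nm + len(g.members))
    total_members = sum(nm for _, nm in spectrum.values())
    assert total_members == sum(len(g.members) for g in groups)
    return dict(sorted(spectrum.items(), reverse=True))
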