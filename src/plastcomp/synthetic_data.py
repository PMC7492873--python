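"""Synthetic plastome-like inputs with full ground truth.

The generator emulates the statistical shape of a plastome comparison study:
a circular genome with LSC/IRb/SSC/IRa structure (IR copies exact reverse
complements), planted SSR loci of every class, planted gene features, derived
genomes carrying known substitutions and deletions together with their true
alignments, and multiple alignments with controllable per-window difference
density.

Background sequence is kept repeat-free by rejection against the SSR
classifier itself: after assembly the genome is rescanned and any background
stretch that produced an unplanned passing locus is redrawn (mirrored into
both IR copies when needed) until the detected set equals the planted set.
All randomness flows from an explicit integer seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import AlignedSet, FeatureAnnotation, GenomeRecord, revcomp
from .ir_partition import QuadripartiteStructure, gc_content
from .ssr_detect import SSRLocus, classify_run, detect_ssrs
from .variant_calls import Variant

_BASES = "ACGT"


@dataclass
class SSRPlanItem:
    unit_len: int
    copies: int
    region: str  # LSC | IRb | SSC


#: one planted locus per SSR class, spread over the three plantable regions
DEFAULT_SSR_PLAN = [
    SSRPlanItem(1, 12, "LSC"),
    SSRPlanItem(2, 5, "LSC"),
    SSRPlanItem(3, 4, "LSC"),
    SSRPlanItem(4, 3, "LSC"),
    SSRPlanItem(7, 2, "LSC"),
    SSRPlanItem(9, 2, "LSC"),
    SSRPlanItem(5, 3, "IRb"),
    SSRPlanItem(8, 2, "IRb"),
    SSRPlanItem(6, 3, "SSC"),
    SSRPlanItem(10, 2, "SSC"),
    SSRPlanItem(5, 2, "SSC"),  # potentialSSR
    SSRPlanItem(6, 2, "SSC"),  # potentialSSR
]


@dataclass
class SyntheticTruth:
    genome: GenomeRecord
    structure: QuadripartiteStructure
    planted_ssrs: list[SSRLocus]
    features: list[FeatureAnnotation]
    seed: int


@dataclass
class MutatedPair:
    ancestor: GenomeRecord
    derived: GenomeRecord
    alignment: AlignedSet  # the true alignment (deletions as gaps in the derived row)
    variants: list[Variant]
    seed: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _random_primitive_unit(rng: np.random.Generator, unit_len: int) -> str:
    from .ssr_detect import is_primitive

    while True:
        unit = _random_seq(rng, unit_len)
        if unit_len == 1 or is_primitive(unit):
            return unit


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def generate_plastome(
    seed: int,
    lsc_len: int = 6000,
    ir_len: int = 2000,
    ssc_len: int = 1200,
    n_genes: int = 6,
    ssr_plan: Sequence[SSRPlanItem] | None = None,
    max_fix_rounds: int = 60,
) -> SyntheticTruth:
    """Build a circular synthetic plastome with known structure, SSRs and genes.

    The genome is LSC + IRb + SSC + IRa with IRa the exact reverse complement
    of IRb; SSRs planted in the IRb appear (reverse-complemented) in both IR
    copies and are recorded twice in the truth. Fully deterministic given
    ``seed``. Raises ``ValueError`` when the plan does not fit the regions.
    """
    if min(lsc_len, ir_len, ssc_len) <= 0:
        raise ValueError("region lengths must be positive")
    plan = list(DEFAULT_SSR_PLAN if ssr_plan is None else ssr_plan)
    for item in plan:
        if classify_run(item.unit_len, item.copies) is None:
            raise ValueError(
                f"plan item {item} does not satisfy the SSR classification thresholds"
            )
        if item.region not in {"LSC", "IRb", "SSC"}:
            raise ValueError(f"plantable regions are LSC, IRb, SSC; got {item.region}")

    rng = np.random.default_rng(seed)
    n = lsc_len + 2 * ir_len + ssc_len
    region_offsets = {"LSC": 0, "IRb": lsc_len, "SSC": lsc_len + ir_len}
    region_lens = {"LSC": lsc_len, "IRb": ir_len, "SSC": ssc_len}

    # background for the three independent regions (IRa is derived)
    body = list(_random_seq(rng, lsc_len + ir_len + ssc_len))

    # --- plant SSRs, evenly spaced inside their region, margin from junctions
    margin = 25
    planted: list[tuple[int, str, int]] = []  # (0-based body start, unit, copies)
    protected: set[int] = set()
    for region in ("LSC", "IRb", "SSC"):
        items = [it for it in plan if it.region == region]
        if not items:
            continue
        rlen, roff = region_lens[region], region_offsets[region]
        spans = [it.unit_len * it.copies for it in items]
        if sum(spans) + 2 * margin + (len(items) - 1) * 2 * margin > rlen:
            raise ValueError(f"SSR plan overflows region {region}")
        free = rlen - 2 * margin - sum(spans)
        gap = free // (len(items) + 1)
        cursor = roff + margin + gap
        for item in items:
            unit = _random_primitive_unit(rng, item.unit_len)
            text = unit * item.copies
            body[cursor : cursor + len(text)] = list(text)
            planted.append((cursor, unit, item.copies))
            protected.update(range(cursor, cursor + len(text)))
            cursor += len(text) + gap

    def set_base(idx: int, ch: str) -> None:
        body[idx] = ch

    # guard bases: the run must not extend by even one periodic base
    for start, unit, copies in planted:
        k, end = len(unit), None
        end = start + k * copies  # exclusive
        if start > 0 and body[start - 1] == unit[-1] and (start - 1) not in protected:
            set_base(start - 1, _other_base(rng, unit[-1]))
        if end < len(body) and body[end] == unit[0] and end not in protected:
            set_base(end, _other_base(rng, unit[0]))

    # --- gene features ------------------------------------------------------
    features: list[FeatureAnnotation] = []
    occupied = sorted((s, s + len(u) * c - 1) for s, u, c in planted)

    def free_slot(lo: int, hi: int, length: int) -> int | None:
        """Leftmost 0-based start in [lo, hi] such that [start, start+length)
        avoids planted SSR spans (with a small buffer)."""
        start = lo
        while start + length - 1 <= hi:
            clash = None
            for s, e in occupied:
                if not (start + length - 1 < s - 12 or start > e + 12):
                    clash = e + 13
                    break
            if clash is None:
                return start
            start = clash
        return None

    gene_len = 300  # single-exon CDS length (a whole number of codons)
    placed = 0
    cursor = margin
    while placed < max(0, n_genes - 2) and cursor < lsc_len - gene_len - margin:
        start = free_slot(cursor, lsc_len - margin - gene_len, gene_len)
        if start is None:
            break
        features.append(FeatureAnnotation(
            gene=f"geneL{placed + 1}", kind="CDS",
            intervals=[(start + 1, start + gene_len)], strand="+",
        ))
        placed += 1
        cursor = start + gene_len + 60
    # one two-exon CDS (intron between the exons), placed after the others
    start = free_slot(cursor, lsc_len - margin - 400, 400)
    if start is not None:
        features.append(FeatureAnnotation(
            gene="geneJoin", kind="CDS",
            intervals=[(start + 1, start + 150), (start + 241, start + 390)],
            strand="+",
        ))
    # one CDS in the IRb, mirrored into the IRa on the opposite strand
    irb_off = region_offsets["IRb"]
    start = free_slot(irb_off + margin, irb_off + ir_len - margin - gene_len, gene_len)
    if start is not None:
        s1, e1 = start + 1, start + gene_len
        features.append(FeatureAnnotation(
            gene="geneIR", kind="CDS", intervals=[(s1, e1)], strand="+",
        ))
        rel_s, rel_e = s1 - 1 - irb_off, e1 - 1 - irb_off
        ira_off = lsc_len + ir_len + ssc_len
        features.append(FeatureAnnotation(
            gene="geneIR", kind="CDS",
            intervals=[(ira_off + ir_len - rel_e, ira_off + ir_len - rel_s)],
            strand="-",
        ))
    # one minus-strand CDS in the SSC
    ssc_off = region_offsets["SSC"]
    start = free_slot(ssc_off + margin, ssc_off + ssc_len - margin - gene_len, gene_len)
    if start is not None:
        features.append(FeatureAnnotation(
            gene="geneS1", kind="CDS",
            intervals=[(start + 1, start + gene_len)], strand="-",
        ))

    # --- expected truth loci (including IRa mirrors) ------------------------
    def expected_loci() -> set[tuple[int, int, str, int]]:
        out = set()
        for s, u, c in planted:
            k = len(u)
            out.add((s + 1, s + k * c, u, c))
            if region_offsets["IRb"] <= s < region_offsets["IRb"] + ir_len:
                rel_end = s + k * c - 1 - irb_off  # 0-based, IRb-relative
                ira_start0 = (lsc_len + ir_len + ssc_len) + (ir_len - 1 - rel_end)
                out.add((ira_start0 + 1, ira_start0 + k * c, revcomp(u), c))
        return out

    def assemble() -> str:
        s = "".join(body)
        return s + revcomp(s[irb_off : irb_off + ir_len])

    _comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def enforce_junction_guards() -> None:
        """Keep the planted IR maximal: the bases just outside each IR copy
        must not extend the reverse-complement match by chance."""
        lsc_last, lsc_first = lsc_len - 1, 0
        ssc_first = lsc_len + ir_len
        ssc_last = lsc_len + ir_len + ssc_len - 1
        if body[lsc_last] == _comp[body[lsc_first]] and lsc_last not in protected:
            set_base(lsc_last, _other_base(rng, _comp[body[lsc_first]]))
        if body[ssc_first] == _comp[body[ssc_last]] and ssc_first not in protected:
            set_base(ssc_first, _other_base(rng, _comp[body[ssc_last]]))

    # --- rejection loop: background must add no passing locus ---------------
    for _ in range(max_fix_rounds):
        enforce_junction_guards()
        genome = GenomeRecord(id=f"synthetic_{seed}", sequence=assemble(), circular=True)
        detected = {(l.start, l.end, l.unit, l.copies) for l in detect_ssrs(genome)}
        want = expected_loci()
        if detected == want:
            break
        offending = detected - want
        missing = want - detected
        redraw: set[int] = set()
        for s1, e1, _, _ in offending | missing:
            for pos in range(s1 - 2, e1 + 2):  # 1-based, slight margin
                idx = (pos - 1) % n
                if idx >= lsc_len + ir_len + ssc_len:  # inside IRa: map to IRb
                    rel = idx - (lsc_len + ir_len + ssc_len)
                    idx = irb_off + (ir_len - 1 - rel)
                if idx in protected or not 0 <= idx < len(body):
                    continue
                redraw.add(idx)
        if not redraw:
            raise ValueError("SSR plan conflicts with itself; cannot de-repeat background")
        for idx in redraw:
            set_base(idx, _other_base(rng, body[idx]))
    else:
        raise ValueError("could not build a repeat-free background for this plan")

    structure = QuadripartiteStructure(
        lsc=(1, lsc_len),
        irb=(lsc_len + 1, lsc_len + ir_len),
        ssc=(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len + 1, n),
        genome_length=n,
    )
    structure.gc = {
        "whole": gc_content(genome.sequence),
        "LSC": gc_content(genome.slice(*structure.lsc)),
        "IRb": gc_content(genome.slice(*structure.irb)),
        "SSC": gc_content(genome.slice(*structure.ssc)),
        "IRa": gc_content(genome.slice(*structure.ira)),
    }
    genome.features = features
    truth_ssrs = []
    for s1, e1, u, c in sorted(expected_loci()):
        locus = SSRLocus(
            genome_id=genome.id, start=s1, end=e1, unit=u, copies=c,
            category=classify_run(len(u), c),
        )
        from .ssr_detect import assign_context

        assign_context(locus, structure, features)
        truth_ssrs.append(locus)
    return SyntheticTruth(
        genome=genome, structure=structure, planted_ssrs=truth_ssrs,
        features=features, seed=seed,
    )


def mutate_genome(
    truth: SyntheticTruth,
    n_snp: int,
    indel_events: Sequence[tuple[int, bool]] = (),
    seed: int = 0,
    derived_id: str | None = None,
    max_rounds: int = 40,
) -> MutatedPair:
    """Derive a genome by planting substitutions and deletions, with truth.

    ``indel_events`` is a list of ``(length, in_cds)`` deletion events removed
    from the ancestor; an in-CDS event of length divisible by 3 is placed on a
    codon boundary of a plus-strand single-exon CDS (an in-frame deletion),
    any other length causes a frameshift. Mutation sites are drawn from the
    single-copy regions only (so the derived IR copies stay identical) and are
    rejected when they would create or destroy a planted SSR locus. The true
    alignment pairs the ancestor with the derived sequence, deleted bases as
    gap columns. Each event of length L contributes L INDEL records.
    """
    rng = np.random.default_rng(seed)
    anc = truth.genome
    n = len(anc)
    structure = truth.structure
    derived_id = derived_id or f"{anc.id}_derived"

    ssr_spans: set[int] = set()
    for l in truth.planted_ssrs:
        ssr_spans.update(range(l.start - 12, l.end + 13))
    feature_spans: set[int] = set()
    for f in truth.features:
        s, e = f.span
        feature_spans.update(range(s, e + 1))

    def in_single_copy(pos: int) -> bool:
        return structure.region_of(pos) in {"LSC", "SSC"}

    plus_cds = [
        f for f in truth.features
        if f.kind == "CDS" and f.strand == "+" and len(f.intervals) == 1
        and structure.region_of(f.span[0]) == "LSC"
    ]

    want = Counter((l.unit, l.copies) for l in truth.planted_ssrs)

    def place_deletions(attempt: int) -> tuple[set[int], list[tuple[int, int, bool]]]:
        deleted: set[int] = set()
        events: list[tuple[int, int, bool]] = []  # (start_pos, length, in_cds)
        cds_cursor = 0
        for length, in_cds in indel_events:
            if length < 1:
                raise ValueError("deletion length must be >= 1")
            if in_cds:
                if not plus_cds:
                    raise ValueError("no plus-strand single-exon CDS available")
                feat = plus_cds[cds_cursor % len(plus_cds)]
                cds_cursor += 1
                s, e = feat.span
                # codon-aligned start near the middle, nudged on each attempt
                max_m = (e - s + 1 - length) // 3
                if max_m < 0:
                    raise ValueError("deletion longer than the CDS")
                m = (((e - s + 1) // 2 // 3) + attempt) % (max_m + 1)
                start = s + 3 * m
            else:
                for _ in range(2000):
                    cand = int(rng.integers(2, n - length))
                    span = set(range(cand, cand + length))
                    if (
                        in_single_copy(cand) and in_single_copy(cand + length - 1)
                        and not span & ssr_spans and not span & feature_spans
                        and not span & deleted
                    ):
                        start = cand
                        break
                else:
                    raise ValueError("could not place an intergenic deletion")
            span = set(range(start, start + length))
            if span & deleted:
                raise ValueError("deletion events overlap")
            deleted |= span
            events.append((start, length, in_cds))
        return deleted, events

    def place_snps(deleted: set[int]) -> dict[int, str]:
        snps: dict[int, str] = {}
        for _ in range(n_snp):
            for _ in range(5000):
                cand = int(rng.integers(1, n + 1))
                if (
                    in_single_copy(cand) and cand not in ssr_spans
                    and cand not in deleted and cand not in snps
                ):
                    snps[cand] = _other_base(rng, anc.base(cand))
                    break
            else:
                raise ValueError("n_snp exceeds the number of available sites")
        return snps

    # rejection loop: a substitution or a deletion-induced juxtaposition may
    # seed a new passing repeat; redraw the whole placement until the derived
    # genome's SSR content equals the planted truth
    for attempt in range(max_rounds):
        deleted, events = place_deletions(attempt)
        snps = place_snps(deleted)
        chars = list(anc.sequence)
        for pos, base in snps.items():
            chars[pos - 1] = base
        derived_seq = "".join(
            ch for i, ch in enumerate(chars, 1) if i not in deleted
        )
        derived = GenomeRecord(id=derived_id, sequence=derived_seq, circular=True)
        detected = Counter((l.unit, l.copies) for l in detect_ssrs(derived))
        if detected == want:
            break
    else:
        raise ValueError("could not place mutations without disturbing the SSR truth")

    # --- true alignment and variant truth -----------------------------------
    row_a = anc.sequence
    row_b = "".join(
        "-" if i in deleted else (snps.get(i) or ch)
        for i, ch in enumerate(anc.sequence, 1)
    )
    alignment = AlignedSet(ids=[anc.id, derived.id], rows=[row_a, row_b])

    def context_at(pos: int) -> tuple[str, str]:
        for f in truth.features:
            if f.in_exon(pos):
                return "exon", f.gene
            if f.contains(pos):
                return "intron", f.gene
        return "intergenic", ""

    variants: list[Variant] = []
    for pos in sorted(snps):
        ctx, gene = context_at(pos)
        variants.append(Variant(
            kind="SNP", aln_col=pos, coord_a=pos,
            coord_b=alignment.pos_in_row(1, pos),
            base_a=anc.base(pos), base_b=snps[pos],
            context=ctx, gene=gene,
        ))
    for start, length, in_cds in events:
        effect = "none"
        if in_cds:
            effect = "in_frame_indel" if length % 3 == 0 else "frameshift"
        for pos in range(start, start + length):
            ctx, gene = context_at(pos)
            variants.append(Variant(
                kind="INDEL", aln_col=pos, coord_a=pos, coord_b=None,
                base_a=anc.base(pos), base_b="-",
                context=ctx, gene=gene, effect=effect,
            ))
    variants.sort(key=lambda v: v.aln_col)
    return MutatedPair(
        ancestor=anc, derived=derived, alignment=alignment,
        variants=variants, seed=seed,
    )


def generate_msa(
    n_rows: int,
    n_cols: int,
    window_plan: Sequence[float] | dict[int, float] | None = None,
    seed: int = 0,
    window: int = 500,
    step: int = 200,
) -> tuple[AlignedSet, list[float]]:
    """A gap-free multiple alignment with planted per-window diversity.

    ``window_plan`` gives a target pi per window (list aligned with the window
    layout, or a sparse ``{window_index: pi}`` map; unlisted windows stay 0).
    Differences are planted as single-column substitutions in one row each, so
    a window with target ``t`` receives ``round(t * n_rows * width / 2)``
    mutated columns. The returned truth is the exact realised pi per window,
    recomputed directly from the rows.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, n_cols)
    rows = [list(base) for _ in range(n_rows)]

    from .nuc_diversity import _window_starts

    layout = _window_starts(n_cols, window, step)
    targets = [0.0] * len(layout)
    if isinstance(window_plan, dict):
        for i, t in window_plan.items():
            targets[i] = t
    elif window_plan is not None:
        for i, t in enumerate(window_plan):
            targets[i] = t

    used_cols: set[int] = set()
    for (start, end, _), target in zip(layout, targets):
        if target <= 0:
            continue
        width = end - start + 1
        k = int(round(target * n_rows * width / 2.0))
        if k > width:
            raise ValueError(f"window target pi {target} infeasible for width {width}")
        # prefer columns not shared with the preceding overlapping window
        candidates = [c for c in range(start, end + 1) if c not in used_cols]
        if len(candidates) < k:
            raise ValueError("window plan overlaps too densely to realise")
        cols = rng.choice(len(candidates), size=k, replace=False)
        for idx, col in enumerate(sorted(candidates[i] for i in cols)):
            row = 1 + (idx % (n_rows - 1))
            rows[row][col - 1] = _other_base(rng, rows[row][col - 1])
            used_cols.add(col)

    aln = AlignedSet(
        ids=[f"msa_row_{i}" for i in range(n_rows)],
        rows=["".join(r) for r in rows],
    )

    # realised truth, computed directly (all columns comparable: no gaps/N)
    mats = np.array([np.frombuffer(r.encode(), np.uint8) for r in aln.rows])
    truth: list[float] = []
    for start, end, _ in layout:
        sub = mats[:, start - 1 : end]
        diffs = 0
        pairs = 0
        for i in range(n_rows):
            for j in range(i + 1, n_rows):
                diffs += int((sub[i] != sub[j]).sum())
                pairs += 1
        truth.append(diffs / (pairs * (end - start + 1)))
    return aln, truth
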