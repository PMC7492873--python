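"""SNP/INDEL extraction from pairwise alignments with coding-effect annotation.

Variants are read column-by-column from a two-row alignment: a SNP is a
column where both bases are unambiguous and differ; an INDEL is a column
where exactly one row has a gap, counted per column (a 6 bp deletion is six
INDEL records). Columns containing N on either row are skipped and tallied in
a QC counter; both-gap columns (artifacts of projecting a multiple alignment
onto a pair) are skipped silently.

Coding effects are evaluated per affected codon under the bacterial/plastid
genetic code (translation table 11): a coding SNP is synonymous when the
encoded amino acid is unchanged; a contiguous run of INDEL columns inside a
CDS is an in-frame indel when its length is a multiple of 3 and a frameshift
otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .genome_io import AlignedSet, FeatureAnnotation, GenomeRecord

PLASTID_TABLE = 11
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class Variant:
    kind: str  # SNP | INDEL
    aln_col: int  # 1-based alignment column
    coord_a: int | None
    coord_b: int | None
    base_a: str
    base_b: str
    context: str = ""  # exon | intron | intergenic
    gene: str = ""
    effect: str = "none"  # synonymous | nonsynonymous | in_frame_indel | frameshift | none | unresolved
    aa_change: str = ""


@dataclass
class VariantCallResult:
    variants: list[Variant]
    n_skipped_n: int = 0  # columns excluded because either base was N
    n_both_gap: int = 0

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def call_pairwise_variants(alignment: AlignedSet) -> VariantCallResult:
    """Extract one SNP per mismatching column and one INDEL per gap column."""
    if alignment.n_rows != 2:
        raise ValueError("pairwise calling needs exactly 2 rows")
    row_a, row_b = alignment.rows
    map_a, map_b = alignment.col_to_pos
    variants: list[Variant] = []
    n_skip = 0
    n_both_gap = 0
    for c in range(alignment.n_columns):
        a, b = row_a[c], row_b[c]
        if a == b == "-":
            n_both_gap += 1
            continue
        if a == b:
            continue
        if "N" in (a, b):
            n_skip += 1
            continue
        coord_a = int(map_a[c]) or None
        coord_b = int(map_b[c]) or None
        kind = "INDEL" if "-" in (a, b) else "SNP"
        variants.append(Variant(
            kind=kind, aln_col=c + 1,
            coord_a=coord_a, coord_b=coord_b, base_a=a, base_b=b,
        ))
    return VariantCallResult(variants=variants, n_skipped_n=n_skip, n_both_gap=n_both_gap)


def _cds_positions(feat: FeatureAnnotation) -> list[int]:
    """Genomic positions of the CDS in translation order, codon_start applied."""
    pos: list[int] = []
    if feat.strand == "+":
        for s, e in feat.intervals:
            pos.extend(range(s, e + 1))
    else:
        for s, e in reversed(feat.intervals):
            pos.extend(range(e, s - 1, -1))
    return pos[feat.codon_start - 1 :]


def _read_base(genome: GenomeRecord, pos: int, strand: str) -> str:
    b = genome.base(pos)
    return _COMP[b] if strand == "-" else b


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=PLASTID_TABLE))


def _context_of(
    pos: int, features: Sequence[FeatureAnnotation]
) -> tuple[str, str, FeatureAnnotation | None]:
    context, gene, hit = "intergenic", "", None
    for feat in features:
        if feat.in_exon(pos):
            return "exon", feat.gene, feat
        if feat.contains(pos) and context == "intergenic":
            context, gene, hit = "intron", feat.gene, feat
    return context, gene, hit


def annotate_effects(
    result: VariantCallResult | Sequence[Variant],
    features: Sequence[FeatureAnnotation],
    genome_a: GenomeRecord,
) -> list[Variant]:
    """Fill in genic context and coding effect for every variant, in place.

    Context is looked up on genome A's coordinates (the reference row of the
    alignment); an insertion column with no A coordinate is anchored at the
    last preceding A position. SNP effects are computed by substituting the
    alternate base into the reference codon; INDEL effects are computed per
    contiguous run of gap columns within one CDS.
    """
    variants = list(result.variants if isinstance(result, VariantCallResult) else result)
    anchor_map: dict[int, int] = {}
    last = 0
    for v in variants:
        if v.coord_a is not None:
            last = v.coord_a
        anchor_map[id(v)] = last if last else 1

    for v in variants:
        pos = v.coord_a if v.coord_a is not None else anchor_map[id(v)]
        v.context, v.gene, feat = _context_of(pos, features)
        if v.kind == "SNP" and v.context == "exon" and feat is not None and feat.kind == "CDS":
            _annotate_snp(v, feat, genome_a)

    # contiguous INDEL runs: consecutive alignment columns, same gapped side
    runs: list[list[Variant]] = []
    for v in variants:
        if v.kind != "INDEL":
            continue
        side = "a" if v.base_a == "-" else "b"
        if (
            runs
            and runs[-1][-1].aln_col == v.aln_col - 1
            and ("a" if runs[-1][-1].base_a == "-" else "b") == side
        ):
            runs[-1].append(v)
        else:
            runs.append([v])
    for run in runs:
        head = run[0]
        if head.context != "exon":
            continue
        pos = head.coord_a if head.coord_a is not None else anchor_map[id(head)]
        _, _, feat = _context_of(pos, features)
        if feat is None or feat.kind != "CDS":
            continue
        effect = "in_frame_indel" if len(run) % 3 == 0 else "frameshift"
        for v in run:
            v.effect = effect
        if effect == "in_frame_indel" and head.base_b == "-":
            head.aa_change = _deletion_aa_change(run, feat, genome_a)
    return variants


def _annotate_snp(v: Variant, feat: FeatureAnnotation, genome: GenomeRecord) -> None:
    cds = _cds_positions(feat)
    try:
        idx = cds.index(v.coord_a)
    except ValueError:
        v.effect = "unresolved"
        return
    codon_i = idx // 3
    codon_pos = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon_pos) < 3:
        v.effect = "unresolved"
        return
    ref = "".join(_read_base(genome, p, feat.strand) for p in codon_pos)
    alt_base = _COMP[v.base_b] if feat.strand == "-" else v.base_b
    alt = "".join(
        alt_base if p == v.coord_a else _read_base(genome, p, feat.strand)
        for p in codon_pos
    )
    aa_ref, aa_alt = _translate(ref), _translate(alt)
    if aa_ref == aa_alt:
        v.effect = "synonymous"
        v.aa_change = ""
    else:
        v.effect = "nonsynonymous"
        v.aa_change = f"{aa_ref} to {aa_alt}"


def _deletion_aa_change(run: list[Variant], feat: FeatureAnnotation, genome: GenomeRecord) -> str:
    """Amino acids removed by a codon-aligned in-frame deletion, e.g. 'DN to -'.

    When the deleted bases do not line up with codon boundaries the amino-acid
    rendering is ambiguous and an empty string is returned.
    """
    cds = _cds_positions(feat)
    try:
        idxs = sorted(cds.index(v.coord_a) for v in run)
    except ValueError:
        return ""
    if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
        return ""
    if idxs[0] % 3 != 0 or len(idxs) % 3 != 0:
        return ""
    removed = "".join(
        _read_base(genome, cds[i], feat.strand) for i in range(idxs[0], idxs[0] + len(idxs))
    )
    return f"{_translate(removed)} to -"


@dataclass
class VariantCounts:
    n_snp: int
    n_indel: int
    by_context: Counter = field(default_factory=Counter)

    def as_tuple(self) -> tuple[int, int]:
        return (self.n_snp, self.n_indel)


def count_variants(variants: VariantCallResult | Sequence[Variant]) -> VariantCounts:
    vs = list(variants.variants if isinstance(variants, VariantCallResult) else variants)
    by_context = Counter(v.context or "unannotated" for v in vs)
    return VariantCounts(
        n_snp=sum(v.kind == "SNP" for v in vs),
        n_indel=sum(v.kind == "INDEL" for v in vs),
        by_context=by_context,
    )


def classify_variation_level(n_snp: int, n_indel: int) -> str:
    """Bin a genome pair by its variant counts.

    ``low``: fewer than 80 SNPs and fewer than 100 INDELs; ``medium``: fewer
    than 80 SNPs with 100-200 INDELs; ``high``: at least 80 SNPs or more than
    200 INDELs.
    """
    if n_snp < 0 or n_indel < 0:
        raise ValueError("counts must be non-negative")
    if n_snp >= 80 or n_indel > 200:
        return "high"
    if n_indel >= 100:
        return "medium"
    return "low"


def merge_indel_events(variants: Sequence[Variant]) -> list[dict]:
    """Human-readable view merging consecutive INDEL columns into events."""
    events: list[dict] = []
    for v in variants:
        if v.kind != "INDEL":
            continue
        side = "deletion" if v.base_b == "-" else "insertion"
        if events and events[-1]["end_col"] == v.aln_col - 1 and events[-1]["side"] == side:
            events[-1]["end_col"] = v.aln_col
            events[-1]["length"] += 1
        else:
            events.append({
                "start_col": v.aln_col, "end_col": v.aln_col,
                "length": 1, "side": side, "gene": v.gene, "context": v.context,
            })
    return events
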