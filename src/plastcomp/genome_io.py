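"""Shared sequence/coordinate model and readers for the formats the pipeline touches.

All coordinates are 1-based inclusive, the convention of GenBank feature
tables; alignment columns are also 1-based. Plastomes are treated as circular
molecules but stored linearised exactly as read from the input file — no
rotation to a canonical start is applied (deposited plastome records
conventionally begin at the LSC origin already).

`N` is a legal sequence character; every downstream statistic defines its own
N handling explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

ALPHABET = frozenset("ACGTN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class FeatureAnnotation:
    """One annotated feature: a gene symbol, feature kind, and its intervals.

    ``intervals`` are ordered (exon order for a joined CDS), each 1-based
    inclusive. ``codon_start`` is the GenBank phase offset (1, 2 or 3) for CDS
    features. ``flagged`` marks a soft validation problem (e.g. a CDS whose
    exonic length is not divisible by 3); flagged features are kept, not
    dropped.
    """

    gene: str
    kind: str  # CDS | tRNA | rRNA | intron | exon | gene
    intervals: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    codon_start: int = 1
    flagged: bool = False

    @property
    def span(self) -> tuple[int, int]:
        """Smallest single interval covering the whole feature."""
        return (min(s for s, _ in self.intervals), max(e for _, e in self.intervals))

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return list(self.intervals)

    @property
    def intron_intervals(self) -> list[tuple[int, int]]:
        """Gaps between consecutive intervals within the gene span."""
        ivs = sorted(self.intervals)
        out = []
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)


@dataclass
class GenomeRecord:
    """A named nucleotide sequence, optionally circular and annotated."""

    id: str
    sequence: str
    circular: bool = True
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be nonempty")
        if not self.sequence:
            raise ValueError(f"GenomeRecord {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"GenomeRecord {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """1-based access with circular wrap-around."""
        n = len(self.sequence)
        if self.circular:
            return self.sequence[(pos - 1) % n]
        if not 1 <= pos <= n:
            raise IndexError(pos)
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps across the origin when circular.

        A wrapping interval is expressed with ``end < start`` (e.g. on a
        100 bp circle, ``slice(95, 5)`` returns 11 bases).
        """
        n = len(self.sequence)
        if start <= end:
            if start < 1 or end > n:
                if not self.circular:
                    raise IndexError((start, end))
                return "".join(self.base(p) for p in range(start, end + 1))
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError(f"wrapping interval {start}..{end} on linear sequence")
        return self.sequence[start - 1 :] + self.sequence[:end]


def _normalise(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET - {GAP}
    if bad:
        raise ParseError(f"{where}: illegal characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path, circular: bool = True) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T. Circularity defaults to
    true (plastomes); a ``circular`` or ``linear`` token in the description
    overrides the flag per record. Duplicate ids and illegal characters raise
    :class:`ParseError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        tokens = rec.description.lower().split()
        circ = circular
        if "linear" in tokens:
            circ = False
        elif "circular" in tokens:
            circ = True
        seq = _normalise(str(rec.seq), f"{path}:{rec.id}")
        if GAP in seq:
            raise ParseError(f"{path}:{rec.id}: gap character in unaligned FASTA")
        out.append(GenomeRecord(id=rec.id, sequence=seq, circular=circ))
    return out


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (uppercase, fixed line wrap)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            topo = "circular" if rec.circular else "linear"
            fh.write(f">{rec.id} {topo}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# --- feature tables ---------------------------------------------------------

_KINDS = {"CDS", "tRNA", "rRNA", "intron", "exon", "gene"}


def _gene_from_gff_attrs(attrs: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in ("gene", "Name", "ID", "Parent"):
        if key in fields:
            return fields[key]
    return ""


def read_features(path: str | Path, genome: GenomeRecord | None = None) -> list[FeatureAnnotation]:
    """Read gene annotations from a GFF3-like TSV file.

    Two layouts are accepted and distinguished per line:

    * 9-column GFF3 (``seqid source type start end score strand frame attrs``);
      rows of the same type sharing a gene symbol are joined, in file order,
      into one multi-interval feature (a joined CDS).
    * a minimal 6-column TSV with header
      ``gene  kind  start  end  strand  codon_start``; multi-exon features
      repeat the gene/kind on consecutive rows.

    Features are validated against ``genome`` when given: out-of-range
    intervals raise :class:`ParseError` (wrap across the origin is allowed on
    circular genomes); a CDS whose exonic length (after the codon_start
    offset) is not divisible by 3 is flagged with a warning, not dropped.
    """
    path = Path(path)
    grouped: dict[tuple[str, str], FeatureAnnotation] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 9:
                _, _, kind, start, end, _, strand, frame, attrs = parts
                gene = _gene_from_gff_attrs(attrs)
                codon_start = int(frame) + 1 if frame in {"0", "1", "2"} else 1
            elif len(parts) == 6:
                gene, kind, start, end, strand, cs = parts
                if gene == "gene" and kind == "kind":  # header row
                    continue
                codon_start = int(cs) if cs else 1
            else:
                raise ParseError(f"{path}:{lineno}: expected 6 or 9 tab-separated fields")
            if kind not in _KINDS:
                continue
            try:
                iv = (int(start.replace(",", "")), int(end.replace(",", "")))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            key = (gene, kind)
            if key not in grouped:
                grouped[key] = FeatureAnnotation(
                    gene=gene, kind=kind, intervals=[], strand=strand,
                    codon_start=codon_start,
                )
                order.append(key)
            grouped[key].intervals.append(iv)

    features = [grouped[k] for k in order]
    for feat in features:
        for s, e in feat.intervals:
            if s > e:
                if genome is None or not genome.circular:
                    raise ParseError(
                        f"{path}: feature {feat.gene}: interval {s}..{e} start > end"
                    )
            if genome is not None and (s < 1 or max(s, e) > len(genome)):
                raise ParseError(
                    f"{path}: feature {feat.gene}: interval {s}..{e} outside "
                    f"genome of length {len(genome)}"
                )
        if feat.kind == "CDS":
            effective = feat.exonic_length - (feat.codon_start - 1)
            if effective % 3 != 0:
                feat.flagged = True
                warnings.warn(
                    f"CDS {feat.gene}: exonic length {feat.exonic_length} with "
                    f"codon_start {feat.codon_start} is not a whole number of codons"
                )
    return features


def write_features(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    """Write features in the minimal 6-column TSV layout read_features accepts."""
    with open(path, "w") as fh:
        fh.write("gene\tkind\tstart\tend\tstrand\tcodon_start\n")
        for feat in features:
            for s, e in feat.intervals:
                fh.write(f"{feat.gene}\t{feat.kind}\t{s}\t{e}\t{feat.strand}\t{feat.codon_start}\n")


# --- alignments -------------------------------------------------------------


@dataclass
class AlignedSet:
    """A gapped multiple alignment with per-row column/coordinate maps.

    ``col_to_pos[i][c]`` gives the 1-based ungapped coordinate in row ``i`` of
    0-based alignment column ``c``, or 0 at gap columns. The maps are strictly
    increasing over non-gap columns and therefore invertible.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ParseError(
                "ragged alignment rows: lengths "
                + ", ".join(f"{i}={len(r)}" for i, r in zip(self.ids, self.rows))
            )
        self.col_to_pos = []
        for row in self.rows:
            arr = np.asarray(bytearray(row.encode()), dtype=np.uint8)
            nongap = arr != ord(GAP)
            self.col_to_pos.append(np.where(nongap, np.cumsum(nongap), 0))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def pos_in_row(self, i: int, col: int) -> int | None:
        """1-based coordinate in row i of 1-based alignment column col."""
        p = int(self.col_to_pos[i][col - 1])
        return p if p else None


def read_alignment(path: str | Path) -> AlignedSet:
    """Read an aligned FASTA file into an :class:`AlignedSet`."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ParseError(f"{path}: an alignment needs at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate ids in alignment")
    rows = [_normalise(str(r.seq), f"{path}:{r.id}") for r in records]
    return AlignedSet(ids=ids, rows=rows)


def write_alignment(aln: AlignedSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
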