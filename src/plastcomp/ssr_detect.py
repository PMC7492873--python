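"""Detection and classification of simple sequence repeats (microsatellites).

A locus is a maximal tandem run of at least two complete copies of a primitive
unit of 1-10 bp. Classification follows the chloroplast-genome convention:

* normal SSRs: units of 1-6 bp (mono- to hexanucleotide) whose total span is
  at least 10 bp — minimum copy numbers mono >= 10, di >= 5, tri >= 4,
  tetra >= 3, penta/hexa >= 3;
* potential SSRs: penta- or hexanucleotide runs of exactly two copies;
* extended SSRs: units of 7-10 bp (hepta- to decanucleotide), >= 2 copies.

Runs are maximal (not extendable by a full unit on either side); partial
trailing units are not counted; the unit is reported in the phase at which the
run starts (leftmost phase) and is always primitive (not itself a repetition
of a shorter unit).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import FeatureAnnotation, GenomeRecord
from .ir_partition import QuadripartiteStructure, interval_contains

TYPE_NAMES = {
    1: "monoSSR", 2: "diSSR", 3: "triSSR", 4: "tetraSSR", 5: "pentaSSR",
    6: "hexaSSR", 7: "heptaSSR", 8: "octaSSR", 9: "nonaSSR", 10: "decaSSR",
}

#: minimum copy number for a normal SSR at each unit length 1..6
_MIN_COPIES_NORMAL = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
MIN_SPAN = 10


@dataclass
class SSRLocus:
    genome_id: str
    start: int
    end: int
    unit: str
    copies: int
    category: str  # normal | potential | extended
    region: str = "none"  # LSC | IRb | SSC | IRa | none
    context: str = ""  # exon | intron | intergenic
    gene: str = ""
    junction_flag: bool = False  # locus spans a region boundary

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def type_name(self) -> str:
        return TYPE_NAMES[self.unit_len]

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def is_primitive(unit: str) -> bool:
    """True when the unit is not a whole-number repetition of a shorter string."""
    return (unit + unit).find(unit, 1) == len(unit)


def classify_run(unit_len: int, copies: int) -> str | None:
    """Classify a tandem run; ``None`` means below threshold (not an SSR).

    Returns one of ``normal``, ``potential``, ``extended``. All accepted loci
    have span (unit_len * copies) of at least 10 bp.
    """
    if not 1 <= unit_len <= 10:
        raise ValueError(f"unit length {unit_len} outside 1..10")
    if copies < 2:
        return None
    if unit_len >= 7:
        return "extended"
    if unit_len in (5, 6) and copies == 2:
        return "potential"
    if copies >= _MIN_COPIES_NORMAL[unit_len] and unit_len * copies >= MIN_SPAN:
        return "normal"
    return None


def find_tandem_runs(sequence: str, unit_len: int) -> list[tuple[int, str, int]]:
    """All maximal runs of >= 2 complete copies of a primitive ``unit_len``-mer.

    Returns (start, unit, copies) with 1-based starts. A run is maximal when it
    cannot be extended by a full unit on either side; partial trailing copies
    do not count. The unit is taken in the phase of the leftmost start.
    """
    if not 1 <= unit_len <= 10:
        raise ValueError(f"unit length {unit_len} outside 1..10")
    n = len(sequence)
    if n < 2 * unit_len:
        return []
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    eq = arr[unit_len:] == arr[:-unit_len]  # eq[j]: s[j] == s[j+unit_len]
    runs: list[tuple[int, str, int]] = []
    # maximal stretches of True in eq
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]  # exclusive
    for a, b in zip(starts, ends):
        total = (b - a) + unit_len  # length of the periodic stretch s[a : b+unit_len]
        copies = total // unit_len
        if copies < 2:
            continue
        unit = sequence[a : a + unit_len]
        if "N" in unit or not is_primitive(unit):
            continue
        runs.append((int(a) + 1, unit, int(copies)))
    return runs


def detect_ssrs(
    genome: GenomeRecord,
    structure: QuadripartiteStructure | None = None,
    features: Sequence[FeatureAnnotation] | None = None,
) -> list[SSRLocus]:
    """Scan all unit lengths 1-10, classify, de-overlap and annotate.

    When two accepted loci cover the identical interval, the one with the
    shorter primitive unit is kept. Loci falling inside both IR copies are
    reported once per copy (each copy contains a genuine run). Region and
    genic context are filled in when ``structure``/``features`` are supplied.
    """
    by_interval: dict[tuple[int, int], SSRLocus] = {}
    for unit_len in range(1, 11):
        for start, unit, copies in find_tandem_runs(genome.sequence, unit_len):
            category = classify_run(unit_len, copies)
            if category is None:
                continue
            end = start + unit_len * copies - 1
            locus = SSRLocus(
                genome_id=genome.id, start=start, end=end,
                unit=unit, copies=copies, category=category,
            )
            key = (start, end)
            prev = by_interval.get(key)
            if prev is None or locus.unit_len < prev.unit_len:
                by_interval[key] = locus
    loci = sorted(by_interval.values(), key=lambda l: (l.start, l.unit_len))
    if structure is not None or features is not None:
        for locus in loci:
            assign_context(locus, structure, features or [])
    return loci


def assign_context(
    ssr: SSRLocus,
    structure: QuadripartiteStructure | None,
    features: Sequence[FeatureAnnotation],
) -> tuple[str, str, str]:
    """Assign quadripartite region and genic context by locus midpoint.

    Region is the region containing the midpoint; a locus straddling a region
    boundary is flagged. Context is ``exon`` when the midpoint falls in an
    exon interval of any feature, ``intron`` when inside a gene span but not an
    exon, else ``intergenic``.
    """
    mid = ssr.midpoint
    if structure is not None:
        ssr.region = structure.region_of(mid)
        n = structure.genome_length
        start_region = structure.region_of(ssr.start)
        end_region = structure.region_of(ssr.end)
        ssr.junction_flag = not (start_region == end_region == ssr.region)
    context, gene = "intergenic", ""
    for feat in features:
        if feat.in_exon(mid):
            context, gene = "exon", feat.gene
            break
        if feat.contains(mid):
            context, gene = "intron", feat.gene
            # keep scanning: an exon of another feature wins over an intron
    ssr.context, ssr.gene = context, gene
    return ssr.region, context, gene


def summarize_types(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Counts by SSR type with a total row; potential SSRs are counted inside
    their unit-length row and also reported in their own column."""
    counts = Counter(l.type_name for l in loci)
    potential = Counter(l.type_name for l in loci if l.category == "potential")
    rows = []
    for unit_len in range(1, 11):
        name = TYPE_NAMES[unit_len]
        rows.append({
            "type": name,
            "count": counts.get(name, 0),
            "potential": potential.get(name, 0),
        })
    rows.append({
        "type": "total",
        "count": sum(counts.values()),
        "potential": sum(potential.values()),
    })
    return pd.DataFrame(rows)


def loci_to_frame(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Flat table of loci (the shape written by the ``ssr`` CLI subcommand)."""
    return pd.DataFrame([
        {
            "genome_id": l.genome_id, "start": l.start, "end": l.end,
            "unit": l.unit, "unit_len": l.unit_len, "copies": l.copies,
            "span": l.span, "type_name": l.type_name, "category": l.category,
            "region": l.region, "context": l.context, "gene": l.gene,
        }
        for l in loci
    ])
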