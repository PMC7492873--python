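"""End-to-end orchestration: run every stage on a set of genomes and emit the
summary artifacts (region table, SSR tables and type summary, cross-genome
SSR groups and spectrum, all-pairs variant matrix, diversity windows and
peaks, junction report, and a manifest with checksums).

Alignment construction is delegated: the runner consumes precomputed aligned
FASTA files and never invokes an external aligner itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_io import read_alignment, read_fasta, read_features
from .ir_partition import find_inverted_repeat, junction_report, partition_regions
from .nuc_diversity import find_peaks, sliding_pi
from .ssr_compare import cluster_ssrs, extract_flanks, group_spectrum
from .ssr_detect import detect_ssrs, loci_to_frame, summarize_types
from .variant_calls import (
    annotate_effects,
    call_pairwise_variants,
    classify_variation_level,
    count_variants,
)

log = logging.getLogger("plastcomp")


@dataclass
class RunConfig:
    """Configuration of a full comparison run; round-trips through YAML."""

    fastas: list[str] = field(default_factory=list)
    features: dict[str, str] = field(default_factory=dict)  # genome id -> path
    alignments: list[str] = field(default_factory=list)  # pairwise aligned FASTA
    msa: str | None = None
    out_dir: str = "plastcomp_out"
    min_ir_len: int = 1000
    max_mismatch: int = 0
    max_flank: int = 60
    cutoff: float = 1e-10
    window: int = 500
    step: int = 200
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if min(self.min_ir_len, self.max_flank, self.window, self.step) <= 0:
            raise ValueError("thresholds must be positive")
        if self.cutoff <= 0:
            raise ValueError("e-value cutoff must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(path, df.to_csv(sep="\t", index=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_comparison(config: RunConfig) -> dict:
    """Run the whole comparison and write its artifact bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Pairwise stages are skipped with a warning when fewer than two genomes or
    no alignments are given; a stage failure leaves earlier outputs in place
    and marks the manifest incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "outputs": {},
        "complete": False,
        "warnings": [],
    }

    genomes = []
    for path in config.fastas:
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input: {path}")
        genomes.extend(read_fasta(path))
    features = {}
    for gid, path in config.features.items():
        genome = next((g for g in genomes if g.id == gid), None)
        if genome is None:
            raise FileNotFoundError(f"feature table for unknown genome id {gid!r}")
        features[gid] = read_features(path, genome)

    # --- per-genome partition + GC + SSRs ----------------------------------
    region_rows = []
    structures = {}
    all_flanked = []
    ssr_frames = []
    type_frames = []
    junctions = {}
    for genome in genomes:
        ir = find_inverted_repeat(genome, config.min_ir_len, config.max_mismatch)
        struct = None
        if ir is None:
            manifest["warnings"].append(f"{genome.id}: no inverted repeat >= {config.min_ir_len} bp")
        else:
            struct = partition_regions(genome, ir)
            structures[genome.id] = struct
            row = {"genome_id": genome.id, "length": len(genome)}
            for name in ("LSC", "IRb", "SSC", "IRa"):
                row[f"{name}_len"] = struct.lengths[name]
            for name, val in struct.gc.items():
                row[f"GC_{name}"] = round(val * 100, 1) if val is not None else None
            region_rows.append(row)
            junctions[genome.id] = junction_report(struct, features.get(genome.id, []))
        loci = detect_ssrs(genome, struct, features.get(genome.id, []))
        ssr_frames.append(loci_to_frame(loci))
        summary = summarize_types(loci)
        summary.insert(0, "genome_id", genome.id)
        type_frames.append(summary)
        for locus in loci:
            all_flanked.append(extract_flanks(locus, genome, config.max_flank))

    if region_rows:
        _write_tsv(pd.DataFrame(region_rows), out / "regions.tsv")
        manifest["outputs"]["regions.tsv"] = None
    if ssr_frames:
        _write_tsv(pd.concat(ssr_frames, ignore_index=True), out / "ssr.tsv")
        _write_tsv(pd.concat(type_frames, ignore_index=True), out / "ssr_types.tsv")
        manifest["outputs"]["ssr.tsv"] = None
        manifest["outputs"]["ssr_types.tsv"] = None
    if junctions:
        payload = {
            gid: {
                name: {
                    "coordinate": info.coordinate,
                    "spanning": info.spanning,
                    "upstream": dataclasses.asdict(info.upstream) if info.upstream else None,
                    "downstream": dataclasses.asdict(info.downstream) if info.downstream else None,
                }
                for name, info in rep.junctions.items()
            }
            for gid, rep in junctions.items()
        }
        ids = sorted(junctions)
        payload["identical_pairs"] = [
            [a, b]
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if junctions[a].signature() == junctions[b].signature()
        ]
        _atomic_write(out / "junctions.json", json.dumps(payload, indent=2))
        manifest["outputs"]["junctions.json"] = None

    # --- cross-genome SSR groups -------------------------------------------
    if len(genomes) >= 2:
        groups = cluster_ssrs(all_flanked, cutoff=config.cutoff)
        rows = []
        for g in groups:
            for m in g.members:
                rows.append({
                    "group_id": g.label, "group_type": g.group_type,
                    "genome_id": m.ssr.genome_id, "start": m.ssr.start,
                    "end": m.ssr.end, "unit": m.ssr.unit, "copies": m.ssr.copies,
                })
        _write_tsv(pd.DataFrame(rows), out / "groups.tsv")
        spectrum = group_spectrum(groups)
        _write_tsv(
            pd.DataFrame(
                [{"group_type": t, "n_groups": ng, "n_members": nm}
                 for t, (ng, nm) in spectrum.items()]
            ),
            out / "spectrum.tsv",
        )
        manifest["outputs"]["groups.tsv"] = None
        manifest["outputs"]["spectrum.tsv"] = None
    else:
        manifest["warnings"].append("single genome input: pairwise stages skipped")

    # --- pairwise variants --------------------------------------------------
    pair_rows = []
    for path in config.alignments:
        aln = read_alignment(path)
        result = call_pairwise_variants(aln)
        id_a = aln.ids[0]
        annotate_effects(result, features.get(id_a, []), _genome_by_id(genomes, id_a, aln))
        counts = count_variants(result)
        frame = pd.DataFrame([
            {
                "no": i + 1, "type": v.kind, "coordinate": v.coord_a,
                "aln_col": v.aln_col, "gene": v.gene or v.context,
                "context": v.context,
                "base_change": f"{v.base_a} to {v.base_b}",
                "effect": v.effect, "aa_change": v.aa_change,
            }
            for i, v in enumerate(result.variants)
        ])
        name = f"variants_{id_a}_vs_{aln.ids[1]}.tsv"
        _write_tsv(frame, out / name)
        manifest["outputs"][name] = None
        pair_rows.append({
            "genome_a": id_a, "genome_b": aln.ids[1],
            "n_snp": counts.n_snp, "n_indel": counts.n_indel,
            "variation_level": classify_variation_level(counts.n_snp, counts.n_indel),
            "n_skipped_N": result.n_skipped_n,
        })
    if pair_rows:
        _write_tsv(pd.DataFrame(pair_rows), out / "pair_matrix.tsv")
        manifest["outputs"]["pair_matrix.tsv"] = None

    # --- diversity ----------------------------------------------------------
    if config.msa:
        msa = read_alignment(config.msa)
        profile = sliding_pi(msa, config.window, config.step)
        _write_tsv(
            pd.DataFrame([
                {"aln_start": w.aln_start, "aln_end": w.aln_end,
                 "pi": w.pi, "valid_pairs": w.valid_pairs}
                for w in profile.windows
            ]),
            out / "diversity.tsv",
        )
        peaks = find_peaks(profile.windows)
        _atomic_write(out / "diversity_summary.json", json.dumps({
            "mean_window_pi": profile.mean_pi,
            "site_pi": profile.site_pi,
            "peaks": [
                {"aln_start": p.aln_start, "aln_end": p.aln_end, "pi": p.pi}
                for p in peaks
            ],
        }, indent=2))
        manifest["outputs"]["diversity.tsv"] = None
        manifest["outputs"]["diversity_summary.json"] = None

    for name in manifest["outputs"]:
        manifest["outputs"][name] = _sha256(out / name)
    manifest["complete"] = True
    _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2))
    return manifest


def _genome_by_id(genomes, gid, aln):
    from .genome_io import GenomeRecord

    for g in genomes:
        if g.id == gid:
            return g
    # fall back to the ungapped alignment row (sufficient for annotation)
    return GenomeRecord(id=gid, sequence=aln.ungapped(0), circular=True)
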