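"""Readers and writers for the pipeline's file formats.

FASTA goes through Bio.SeqIO, MAF through Bio.AlignIO, trees through
dendropy; BED/BedGraph/TSV are plain tab-separated tables via pandas.
All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import CandidateInterval, LibraryEntry, LTRHit, LTRLibrary
from .classify import LTRPair, SoloLTR, TSDReport
from .simulate import Element, SimTruth
from .trace import AlignmentBlock, AlignmentBlockSet, BlockRow

# ---------------------------------------------------------------- FASTA

def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_library_fasta(library: LTRLibrary, path: str | Path) -> None:
    """Library dialect: ``>id#FAMILY``."""
    records = [SeqRecord(Seq(e.sequence), id=f"{e.id}#{e.family}", description="")
               for e in library]
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(path: str | Path, clustering_identity: float = 0.95
                       ) -> LTRLibrary:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, _, family = rec.id.partition("#")
        entries.append(LibraryEntry(seq_id, family or "LTR", str(rec.seq)))
    return LTRLibrary(entries=entries, clustering_identity=clustering_identity)


# ------------------------------------------------------------------ BED

def write_candidates_bed(intervals: Sequence[CandidateInterval],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.source}\n")


def read_candidates_bed(path: str | Path, source: str = "A"
                        ) -> list[CandidateInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [CandidateInterval(str(r[0]), int(r[1]), int(r[2]), source)
            for r in df.itertuples(index=False)]


def write_truth_bed(truth: SimTruth, path: str | Path) -> None:
    """One BED6 row per planted LTR interval; name=element_id|kind|family."""
    with open(path, "w") as fh:
        for element in truth.elements:
            name = f"{element.element_id}|{element.kind}|{element.family}"
            for start, end in element.ltr_intervals:
                fh.write(f"{element.scaffold}\t{start}\t{end}\t{name}\t0\t"
                         f"{element.strand}\n")


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "scaffold_lengths": truth.scaffold_lengths,
        "library": truth.library,
        "elements": [{
            "element_id": e.element_id, "kind": e.kind, "scaffold": e.scaffold,
            "strand": e.strand, "family": e.family, "source_id": e.source_id,
            "ltr_intervals": e.ltr_intervals,
            "internal_interval": e.internal_interval,
            "tsd": e.tsd, "tsd_intervals": e.tsd_intervals,
            "allele": e.allele, "origin_branch": e.origin_branch,
        } for e in truth.elements],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    elements = [Element(
        element_id=d["element_id"], kind=d["kind"], scaffold=d["scaffold"],
        strand=d["strand"], family=d["family"], source_id=d["source_id"],
        ltr_intervals=[tuple(iv) for iv in d["ltr_intervals"]],
        internal_interval=(tuple(d["internal_interval"])
                           if d["internal_interval"] else None),
        tsd=d["tsd"],
        tsd_intervals=tuple(tuple(iv) for iv in d["tsd_intervals"]),
        allele=d["allele"], origin_branch=d["origin_branch"],
    ) for d in payload["elements"]]
    return SimTruth(elements=elements,
                    scaffold_lengths=payload["scaffold_lengths"],
                    library=[tuple(e) for e in payload["library"]])


# ------------------------------------------------------------------ hits

HIT_COLUMNS = ["scaffold", "start", "end", "strand", "library_id", "family",
               "identity", "query_coverage", "score"]


def write_hits_tsv(hits: Sequence[LTRHit], path: str | Path) -> None:
    pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[LTRHit]:
    df = pd.read_csv(path, sep="\t")
    return [LTRHit(str(r.scaffold), int(r.start), int(r.end), str(r.strand),
                   str(r.library_id), str(r.family), float(r.identity),
                   float(r.query_coverage), float(r.score))
            for r in df.itertuples(index=False)]


def write_pairs_tsv(pairs: Sequence[LTRPair], path: str | Path) -> None:
    """BEDPE-style: both LTR intervals plus gap and identity."""
    rows = [{
        "scaffold": p.hit_left.scaffold,
        "left_start": p.hit_left.start, "left_end": p.hit_left.end,
        "right_start": p.hit_right.start, "right_end": p.hit_right.end,
        "strand": p.hit_left.strand, "family": p.hit_left.family,
        "inner_gap": p.inner_gap, "pair_identity": p.pair_identity,
    } for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_solos_bed(solos: Sequence[SoloLTR], path: str | Path) -> None:
    with open(path, "w") as fh:
        for solo in solos:
            hit = solo.hit
            fh.write(f"{hit.scaffold}\t{hit.start}\t{hit.end}\t"
                     f"{solo.id}|{solo.family}\t0\t{hit.strand}\n")


def read_solos_bed(path: str | Path) -> list[SoloLTR]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    solos = []
    for r in df.itertuples(index=False):
        name = str(r[3]) if len(r) > 3 else "solo"
        family = name.rsplit("|", 1)[-1] if "|" in name else "LTR"
        strand = str(r[5]) if len(r) > 5 else "+"
        hit = LTRHit(str(r[0]), int(r[1]), int(r[2]), strand, "bed", family,
                     100.0, 100.0, 0.0)
        solos.append(SoloLTR(hit=hit, family=family))
    return solos


def write_tsd_tsv(reports: Sequence[tuple[str, TSDReport]],
                  path: str | Path) -> None:
    rows = [{"element": name, **report.__dict__} for name, report in reports]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ MAF

def write_maf(blocks: AlignmentBlockSet, genomes: dict[str, dict[str, str]],
              path: str | Path) -> None:
    """Blocks to MAF; sequence text is looked up in the per-species genomes.
    Rows in one block must have equal lengths (substitution-only alignment)."""
    alignments = []
    for block in blocks.blocks:
        records = []
        for row in block.rows:
            seq = genomes[row.species][row.scaffold][row.start:row.end]
            rec = SeqRecord(Seq(seq), id=f"{row.species}.{row.scaffold}")
            rec.annotations.update({
                "start": row.start, "size": row.end - row.start,
                "strand": 1 if row.strand == "+" else -1,
                "srcSize": len(genomes[row.species][row.scaffold]),
            })
            records.append(rec)
        alignments.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(alignments, fh, "maf")


def read_maf(path: str | Path, reference: str | None = None) -> AlignmentBlockSet:
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in aln:
            species, _, scaffold = rec.id.partition(".")
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            strand = "+" if rec.annotations.get("strand", 1) == 1 else "-"
            rows.append(BlockRow(species, scaffold, start, start + size, strand))
        blocks.append(AlignmentBlock(rows))
    return AlignmentBlockSet(blocks=blocks, reference=reference)


# ------------------------------------------------------------- coverage

def write_bedgraph(track: dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded 4-column BedGraph dialect (scaffold start end depth)."""
    with open(path, "w") as fh:
        for scaffold in sorted(track):
            depths = np.asarray(track[scaffold])
            if depths.size == 0:
                continue
            change = np.flatnonzero(np.diff(depths)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depths.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{scaffold}\t{s}\t{e}\t{int(depths[s])}\n")


def read_bedgraph(path: str | Path,
                  scaffold_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    track = {name: np.zeros(length, dtype=np.int32)
             for name, length in scaffold_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["scaffold", "start", "end", "depth"])
    for r in df.itertuples(index=False):
        track[str(r.scaffold)][int(r.start):int(r.end)] = int(r.depth)
    return track


# -------------------------------------------------------------- config

def write_config(config, path: str | Path) -> None:
    """Flat key=value file for SimConfig."""
    lines = []
    for key, value in config.__dict__.items():
        if isinstance(value, (tuple, list)):
            value = ",".join(map(str, value))
        lines.append(f"{key}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path):
    from .simulate import SimConfig

    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key == "family_labels":
            kwargs[key] = tuple(raw.split(","))
        elif key in ("divergence", "insertion_divergence"):
            kwargs[key] = float(raw)
        elif key == "tsd_length":
            kwargs[key] = None if raw == "None" else int(raw)
        else:
            kwargs[key] = int(raw)
    return SimConfig(**kwargs)
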