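"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are normalised to a single internal convention — 0-based,
half-open — at the I/O boundary: GFF3 (1-based closed) is converted on read
and write, BED and the tabular alignment dialect are already half-open, and
GFA A-line offsets are 0-based. Strand/orientation is carried through but
never flips coordinates; the downstream contamination arithmetic is purely
positional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .taxonomy import ClassificationCall, HitRecord, UNCLASSIFIED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (a HiFi read, contig or reference)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start in {self}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def pair(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig mapping."""

    read_id: str
    target: Interval
    mapq: int
    is_primary: bool = True
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq {self.mapq} out of range for read {self.read_id!r}")


@dataclass(frozen=True)
class ReadPlacement:
    """A read's position inside a contig as recorded by the assembler (GFA A-line)."""

    read_id: str
    target: Interval
    orientation: str = "+"


@dataclass(frozen=True)
class MRNA:
    mrna_id: str
    exons: Tuple[Interval, ...]
    cds: Tuple[Interval, ...] = ()

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].contig, self.exons[0].start, self.exons[-1].end)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its mRNAs, exons, CDS and derived introns."""

    gene_id: str
    contig: str
    span: Interval
    mrnas: Tuple[MRNA, ...] = field(default_factory=tuple)

    def introns(self) -> List[Interval]:
        """Union of introns across all mRNAs (gaps between consecutive exons)."""
        out: List[Interval] = []
        for m in self.mrnas:
            out.extend(derive_introns(list(m.exons)))
        return out


def derive_introns(exons: Sequence[Interval]) -> List[Interval]:
    """Gaps between consecutive exons of one mRNA.

    Requires exons sorted by start and non-overlapping; returns
    max(0, n_exons - 1) intervals whose union with the exons tiles the mRNA
    span contiguously.
    """
    for a, b in zip(exons, exons[1:]):
        if b.start < a.start:
            raise ValueError("exons must be sorted by start")
        if b.start < a.end:
            raise ValueError(f"exons overlap: {a} and {b}")
    return [
        Interval(a.contig, a.end, b.start)
        for a, b in zip(exons, exons[1:])
        if b.start > a.end
    ]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> List[SeqRecord]:
    records: List[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    bio = (_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 gene models (1-based closed on disk, half-open in memory)
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> List[GeneModel]:
    """Parse gene/mRNA/exon/CDS features linked by ID/Parent into GeneModels."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    # orphan Parent references are a hard error
    for ftype in ("mRNA", "exon", "CDS"):
        for feat in db.features_of_type(ftype):
            for pid in feat.attributes.get("Parent", []):
                try:
                    db[pid]
                except gffutils.FeatureNotFoundError:
                    raise ValueError(
                        f"{path}: {ftype} {feat.id or '?'} references missing Parent {pid!r}"
                    ) from None

    models: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        span = Interval(gene.seqid, gene.start - 1, gene.end)
        mrnas: List[MRNA] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = tuple(
                Interval(f.seqid, f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            )
            cds = tuple(
                Interval(f.seqid, f.start - 1, f.end)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            )
            for ex in exons:
                if ex.start < span.start or ex.end > span.end:
                    raise ValueError(
                        f"{path}: exon {ex} of mRNA {mrna.id} outside gene span {span}"
                    )
            derive_introns(list(exons))  # validates sorted / non-overlapping
            mrnas.append(MRNA(mrna.id, exons, cds))
        models.append(GeneModel(gene.id, gene.seqid, span, tuple(mrnas)))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.contig}\tbinaudit\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )
            for m in g.mrnas:
                fh.write(
                    f"{g.contig}\tbinaudit\tmRNA\t{m.span.start + 1}\t{m.span.end}\t.\t+\t.\t"
                    f"ID={m.mrna_id};Parent={g.gene_id}\n"
                )
                for i, ex in enumerate(m.exons, 1):
                    fh.write(
                        f"{g.contig}\tbinaudit\texon\t{ex.start + 1}\t{ex.end}\t.\t+\t.\t"
                        f"ID={m.mrna_id}.exon{i};Parent={m.mrna_id}\n"
                    )
                for i, c in enumerate(m.cds, 1):
                    fh.write(
                        f"{g.contig}\tbinaudit\tCDS\t{c.start + 1}\t{c.end}\t.\t+\t0\t"
                        f"ID={m.mrna_id}.cds{i};Parent={m.mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# GFA read placements (hifiasm A-lines)
# ---------------------------------------------------------------------------

def read_gfa_placements(path: str | Path) -> List[ReadPlacement]:
    """Extract read-to-contig placements from a GFA assembly graph.

    Any line whose first token is ``A`` is treated as a placement
    (contig, contigStart, orientation, readName, readStart, readEnd); S/L and
    other record types are skipped (unknown types with a logged warning).
    """
    placements: List[ReadPlacement] = []
    known = {"S", "L", "A", "H", "C", "P", "W", "J"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag != "A":
                if tag not in known:
                    logger.warning("%s:%d: skipping unknown GFA record type %r", path, lineno, tag)
                continue
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: A-line has {len(fields)} fields, expected >= 7")
            contig, offset, orient, read_id, rstart, rend = fields[1:7]
            offset_i, rstart_i, rend_i = int(offset), int(rstart), int(rend)
            if offset_i < 0:
                raise ValueError(f"{path}:{lineno}: negative contig offset {offset_i}")
            length = rend_i - rstart_i
            placements.append(
                ReadPlacement(read_id, Interval(contig, offset_i, offset_i + length), orient)
            )
    return placements


def write_gfa(
    placements: Iterable[ReadPlacement],
    path: str | Path,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write a minimal GFA: optional S-lines plus one A-line per placement."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        if contig_lengths:
            for contig, length in sorted(contig_lengths.items()):
                fh.write(f"S\t{contig}\t*\tLN:i:{length}\n")
        for p in placements:
            fh.write(
                f"A\t{p.target.contig}\t{p.target.start}\t{p.orientation}\t{p.read_id}\t"
                f"0\t{len(p.target)}\tid:i:0\n"
            )


# ---------------------------------------------------------------------------
# Tabular alignments (6-column dialect), Kraken tables, hit tables, BED
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> List[AlignmentRecord]:
    """Read the 6-column alignment dialect:
    read_id, contig, start, end, mapq, flags — flags a comma-joined subset of
    {primary, secondary, duplicate}; an empty or ``.`` flags field means a
    primary, non-duplicate record."""
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            read_id, contig, start, end, mapq, flags = fields
            try:
                iv = Interval(contig, int(start), int(end))
                mapq_i = int(mapq)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            tokens = set() if flags in ("", ".") else set(flags.split(","))
            unknown = tokens - {"primary", "secondary", "duplicate"}
            if unknown:
                raise ValueError(f"{path}:{lineno}: unknown flag(s) {sorted(unknown)}")
            records.append(
                AlignmentRecord(
                    read_id,
                    iv,
                    mapq_i,
                    is_primary="secondary" not in tokens,
                    is_duplicate="duplicate" in tokens,
                )
            )
    return records


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            tokens = []
            if not r.is_primary:
                tokens.append("secondary")
            if r.is_duplicate:
                tokens.append("duplicate")
            flags = ",".join(tokens) if tokens else "primary"
            fh.write(
                f"{r.read_id}\t{r.target.contig}\t{r.target.start}\t{r.target.end}\t"
                f"{r.mapq}\t{flags}\n"
            )


def read_kraken_table(path: str | Path) -> List[ClassificationCall]:
    """Read Kraken2-style 5-column output (C/U, seq id, taxon, length, LCA map)."""
    calls: List[ClassificationCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            status, seq_id, taxon = fields[0], fields[1], fields[2]
            if status == "U" or taxon in ("0", UNCLASSIFIED):
                calls.append(ClassificationCall(seq_id, UNCLASSIFIED, "kmer", 0.0))
            elif status == "C":
                calls.append(ClassificationCall(seq_id, taxon, "kmer", 0.0))
            else:
                raise ValueError(f"{path}:{lineno}: unknown status {status!r}")
    return calls


def write_kraken_table(
    calls: Iterable[ClassificationCall],
    path: str | Path,
    lengths: Optional[Dict[str, int]] = None,
) -> None:
    with open(path, "w") as fh:
        for c in calls:
            length = lengths.get(c.seq_id, 0) if lengths else 0
            if c.taxon == UNCLASSIFIED:
                fh.write(f"U\t{c.seq_id}\t0\t{length}\t0:0\n")
            else:
                fh.write(f"C\t{c.seq_id}\t{c.taxon}\t{length}\t{c.taxon}:1\n")


def read_hit_table(path: str | Path) -> List[HitRecord]:
    """Read a BLAST outfmt-6-like 12-column table.

    The subject field carries the taxon id directly (the custom reference
    database names subjects by taxon); qstart/qend (1-based closed) become a
    half-open query interval.
    """
    hits: List[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_taxon=fields[1],
                    bitscore=bitscore,
                    evalue=evalue,
                    query_interval=(qstart - 1, qend),
                )
            )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_interval if h.query_interval else (0, 1)
            fh.write(
                f"{h.query_id}\t{h.subject_taxon}\t100.000\t{qe - qs}\t0\t0\t"
                f"{qs + 1}\t{qe}\t1\t{qe - qs}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as 3-column BED (0-based half-open, as stored)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
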