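"""Genome sequences, gene models, and intron extraction.

Reads FASTA genomes and GFF3 gene annotations, builds per-gene transcript
models, and extracts introns together with their flanking exon sequences —
the raw material for intron-length-polymorphism (ILP) primer design.

Coordinate convention: everything in memory is 0-based half-open on the
plus strand. GFF3 (1-based inclusive) is converted at the I/O boundary.
Intron and exon sequences are always reported on the forward strand
regardless of gene orientation: PCR amplification is strand-symmetric, so
primer design downstream never needs the transcribed strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import gffutils

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised on malformed FASTA/GFF3 input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence (chromosome, scaffold, or contig)."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{self.seq_id}: unexpected characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    """Ordered exon intervals (0-based half-open) of one mRNA."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seq_id: str
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass(frozen=True)
class IntronRecord:
    """An intron between two consecutive exons of one transcript.

    ``sequence`` is the plus-strand genome slice [start, end);
    ``left_exon_seq``/``right_exon_seq`` are the plus-strand sequences of
    the exons immediately upstream/downstream in genome coordinates.
    ``intron_index`` is 1-based in genomic order along the transcript.
    """

    gene_id: str
    transcript_id: str
    intron_index: int
    seq_id: str
    start: int
    end: int
    sequence: str
    left_exon_seq: str
    right_exon_seq: str
    left_exon_interval: tuple[int, int] = field(default=(0, 0))
    right_exon_interval: tuple[int, int] = field(default=(0, 0))

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> list[SequenceRecord]:
    """Read a multi-record FASTA file; sequences are uppercased.

    Raises :class:`FormatError` on an empty file, duplicate ids, or
    characters outside {A,C,G,T,N}.
    """
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sequence ids")
    return records


def write_fasta(records: list[SequenceRecord], path: str, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.seq_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def genome_dict(records: list[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {r.seq_id: r for r in records}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str, genome: list[SequenceRecord]) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates become 0-based half-open. Models
    whose exons fall outside the named sequence are dropped with a warning,
    as are transcripts with no exons and exons whose Parent cannot be
    resolved.
    """
    lengths = {r.seq_id: r.length for r in genome}
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(mrna, featuretype="exon", order_by="start")
            )
            if not exons:
                logger.warning("transcript %s has no exons; skipped", mrna.id)
                continue
            transcripts.append(Transcript(mrna.id, tuple(exons)))
        if not transcripts:
            logger.warning("gene %s has no transcripts with exons; excluded", gene.id)
            continue
        if gene.seqid not in lengths:
            logger.warning("gene %s on unknown sequence %s; excluded", gene.id, gene.seqid)
            continue
        limit = lengths[gene.seqid]
        if any(s < 0 or e > limit for t in transcripts for s, e in t.exons):
            logger.warning("gene %s has exons beyond %s length %d; excluded",
                           gene.id, gene.seqid, limit)
            continue
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(transcripts)))
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g_start = min(t.span[0] for t in m.transcripts)
            g_end = max(t.span[1] for t in m.transcripts)
            fh.write(
                f"{m.seq_id}\tilpkit\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for t in m.transcripts:
                s, e = t.span
                fh.write(
                    f"{m.seq_id}\tilpkit\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={m.gene_id}\n"
                )
                for i, (es, ee) in enumerate(t.exons, 1):
                    fh.write(
                        f"{m.seq_id}\tilpkit\texon\t{es + 1}\t{ee}\t.\t{m.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Intron extraction
# ---------------------------------------------------------------------------

def select_primary_transcript(model: GeneModel) -> str:
    """Transcript with the greatest summed exon length; ties go to the
    lexicographically smallest transcript_id."""
    best = min(model.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))
    return best.transcript_id


def extract_introns(
    genome: list[SequenceRecord],
    models: list[GeneModel],
    min_intron_len: int = 80,
    max_intron_len: int = 300,
) -> list[IntronRecord]:
    """One IntronRecord per exon-exon gap of each gene's primary transcript
    with length inside [min_intron_len, max_intron_len].

    Transcripts with overlapping exons are skipped with a warning.
    """
    if not (0 < min_intron_len <= max_intron_len):
        raise ValueError("require 0 < min_intron_len <= max_intron_len")
    seqs = genome_dict(genome)
    introns: list[IntronRecord] = []
    for model in models:
        tid = select_primary_transcript(model)
        tx = next(t for t in model.transcripts if t.transcript_id == tid)
        if any(tx.exons[i][1] > tx.exons[i + 1][0] for i in range(len(tx.exons) - 1)):
            logger.warning("transcript %s has overlapping exons; skipped", tid)
            continue
        chrom = seqs[model.seq_id].sequence
        for idx in range(len(tx.exons) - 1):
            (ls, le), (rs, re) = tx.exons[idx], tx.exons[idx + 1]
            start, end = le, rs
            length = end - start
            if not (min_intron_len <= length <= max_intron_len):
                continue
            introns.append(
                IntronRecord(
                    gene_id=model.gene_id,
                    transcript_id=tid,
                    intron_index=idx + 1,
                    seq_id=model.seq_id,
                    start=start,
                    end=end,
                    sequence=chrom[start:end],
                    left_exon_seq=chrom[ls:le],
                    right_exon_seq=chrom[rs:re],
                    left_exon_interval=(ls, le),
                    right_exon_interval=(rs, re),
                )
            )
    return introns


def write_intron_table(introns: list[IntronRecord], path: str) -> None:
    """Human-readable TSV; start/end are 1-based inclusive (flagged in header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("gene_id\ttranscript_id\tintron_index\tseq_id\tstart\tend\tlength\n")
        for r in introns:
            fh.write(
                f"{r.gene_id}\t{r.transcript_id}\t{r.intron_index}\t{r.seq_id}\t"
                f"{r.start + 1}\t{r.end}\t{r.length}\n"
            )
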