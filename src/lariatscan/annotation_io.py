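"""Genome and annotation input: transcript models and intron derivation.

Transcripts are represented with their exons ordered 5'->3' along the
transcript (for minus-strand genes the genomic start coordinates therefore
descend).  Introns are the gaps between consecutive exons and carry their
sequence in transcript orientation.  All coordinates are 1-based inclusive
internally; BED export is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")


class AnnotationError(ValueError):
    """Fatal inconsistency between annotation and genome."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered list of exon intervals.

    ``exons`` are 1-based inclusive genomic intervals sorted 5'->3' in
    transcript orientation: ascending genomic starts on "+", descending
    on "-".
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        for start, end in self.exons:
            if start > end or start < 1:
                raise AnnotationError(
                    f"{self.transcript_id}: bad exon interval ({start}, {end})"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class Intron:
    """Gap between two consecutive exons, sequence in transcript orientation."""

    intron_id: str
    transcript_id: str
    index: int  # 1-based position along the transcript, 5'->3'
    chromosome: str
    genomic_interval: tuple[int, int]  # 1-based inclusive
    strand: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the ACGTN alphabet (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def extract_sequence(sequence: str, interval: tuple[int, int], strand: str = "+") -> str:
    """Slice ``interval`` (1-based inclusive) out of ``sequence``.

    Minus strand returns the reverse complement.  Input is normalized to
    uppercase; characters outside ACGTN raise ``AnnotationError`` naming
    the first offending (1-based) position.
    """
    start, end = interval
    if start < 1 or end > len(sequence) or start > end:
        raise AnnotationError(
            f"interval ({start}, {end}) out of bounds for sequence of length {len(sequence)}"
        )
    region = sequence[start - 1 : end].upper()
    for i, base in enumerate(region):
        if base not in _VALID_BASES:
            raise AnnotationError(
                f"non-ACGTN character {base!r} at position {start + i}"
            )
    if strand == "-":
        return reverse_complement(region)
    return region


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a {chromosome: uppercase sequence} map."""
    genome = {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise AnnotationError(f"no FASTA records found in {path}")
    return genome


# ---------------------------------------------------------------------------
# Annotation parsing (GFF3 / GTF)
# ---------------------------------------------------------------------------

def _transcript_key(attrs: Mapping[str, list[str]]) -> str:
    for key in ("transcript_id", "Parent"):
        if key in attrs:
            # GFF3 Parent may be prefixed ("transcript:xyz") or multi-valued.
            return attrs[key][0].split(":")[-1]
    raise AnnotationError(
        "exon record lacks transcript grouping (no transcript_id/Parent attribute)"
    )


def load_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse transcript models from a GFF3 or GTF file.

    Only ``exon`` features are used; they are grouped by transcript_id
    (GTF) or Parent (GFF3).  Transcripts whose exons overlap each other
    are rejected with a warning rather than failing the whole parse.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    for exon in db.features_of_type("exon"):
        tx_id = _transcript_key(exon.attributes)
        gene_attr = exon.attributes.get("gene_id", [tx_id])
        gene_id = gene_attr[0].split(":")[-1]
        exons_by_tx.setdefault(tx_id, []).append((exon.start, exon.end))
        meta.setdefault(tx_id, (gene_id, exon.seqid, exon.strand))

    transcripts: list[TranscriptModel] = []
    for tx_id, exons in exons_by_tx.items():
        gene_id, chrom, strand = meta[tx_id]
        exons.sort()
        if any(a[1] >= b[0] for a, b in zip(exons, exons[1:])):
            logger.warning("transcript %s has overlapping exons; record rejected", tx_id)
            continue
        if strand == "-":
            exons = exons[::-1]
        transcripts.append(
            TranscriptModel(tx_id, gene_id, chrom, strand, tuple(exons))
        )
    return transcripts


# ---------------------------------------------------------------------------
# Intron derivation
# ---------------------------------------------------------------------------

def intron_id_for(transcript_id: str, index: int) -> str:
    return f"{transcript_id}.i{index}"


def derive_introns(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
) -> list[Intron]:
    """Derive one intron per consecutive exon pair of each transcript.

    The gap between two consecutive exons (in transcript order) is taken
    as a putative intron; its sequence is extracted in transcript
    orientation (reverse-complemented on "-").  Single-exon transcripts
    yield nothing.
    """
    introns: list[Intron] = []
    for tx in transcripts:
        if tx.chromosome not in genome:
            raise AnnotationError(
                f"{tx.transcript_id}: chromosome {tx.chromosome!r} absent from genome"
            )
        chrom_seq = genome[tx.chromosome]
        for exon in tx.exons:
            if exon[1] > len(chrom_seq):
                raise AnnotationError(
                    f"{tx.transcript_id}: exon {exon} outside chromosome bounds"
                )
        skip = False
        intervals: list[tuple[int, int]] = []
        for up, down in zip(tx.exons, tx.exons[1:]):
            if tx.strand == "+":
                interval = (up[1] + 1, down[0] - 1)
            else:
                interval = (down[1] + 1, up[0] - 1)
            if interval[0] > interval[1]:
                logger.warning(
                    "transcript %s: exons %s and %s leave no intron gap; record rejected",
                    tx.transcript_id, up, down,
                )
                skip = True
                break
            intervals.append(interval)
        if skip:
            continue
        for index, interval in enumerate(intervals, start=1):
            introns.append(
                Intron(
                    intron_id=intron_id_for(tx.transcript_id, index),
                    transcript_id=tx.transcript_id,
                    index=index,
                    chromosome=tx.chromosome,
                    genomic_interval=interval,
                    strand=tx.strand,
                    sequence=extract_sequence(chrom_seq, interval, tx.strand),
                )
            )
    return introns


def introns_to_bed(introns: Iterable[Intron]) -> str:
    """BED6 text for a set of introns (0-based half-open)."""
    lines = []
    for intron in introns:
        start, end = intron.genomic_interval
        lines.append(
            "\t".join(
                [
                    intron.chromosome,
                    str(start - 1),
                    str(end),
                    intron.intron_id,
                    "0",
                    intron.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def exon_sequence(tx: TranscriptModel, genome: Mapping[str, str], exon_index: int) -> str:
    """Transcript-oriented sequence of the ``exon_index``-th exon (1-based)."""
    exon = tx.exons[exon_index - 1]
    return extract_sequence(genome[tx.chromosome], exon, tx.strand)


def mature_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced (exon-concatenated) transcript sequence."""
    return "".join(exon_sequence(tx, genome, i) for i in range(1, tx.n_exons + 1))


def premrna_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Unspliced transcript sequence (first exon start to last exon end)."""
    positions = [p for exon in tx.exons for p in exon]
    interval = (min(positions), max(positions))
    return extract_sequence(genome[tx.chromosome], interval, tx.strand)
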