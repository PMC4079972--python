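"""Exon-exon junction database.

Junction records let reads diagnostic for spliced mRNA be mapped without
a spliced aligner: each record is the last ``window`` bases of an
upstream exon joined to the first ``window`` bases of a downstream exon,
with ``window = read_length - min_overlap``.  A fully contained read of
``read_length`` bases therefore overlaps the exon-exon boundary by at
least ``min_overlap`` bases on each side.  The default configuration
(read length 49, minimum overlap 6) gives 43-base windows.

Records for non-adjacent exon pairs (exon skipping) can be generated
behind a flag; they are off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_io import TranscriptModel, exon_sequence


@dataclass(frozen=True)
class JunctionRecord:
    """Sequence window around one exon-exon boundary.

    ``boundary_index`` is the 0-based index of the first downstream-exon
    base within ``sequence`` (equal to the length of the upstream window).
    """

    junction_id: str
    transcript_id: str
    upstream_exon_index: int
    downstream_exon_index: int
    sequence: str
    boundary_index: int
    kind: str  # "adjacent" | "skipping"

    @property
    def intron_index(self) -> int:
        """Index of the intron this junction's splicing removes (adjacent only)."""
        return self.upstream_exon_index


def build_junction_db(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    read_length: int = 49,
    min_overlap: int = 6,
    include_skipping: bool = False,
) -> list[JunctionRecord]:
    """Junction records for every consecutive exon pair of each transcript.

    When ``include_skipping`` is set, records bridging non-neighboring
    exons are generated as well (kind ``skipping``).
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if min_overlap >= read_length:
        raise ValueError(
            f"min_overlap ({min_overlap}) must be smaller than read_length ({read_length})"
        )
    window = read_length - min_overlap
    records: list[JunctionRecord] = []
    for tx in transcripts:
        exon_seqs = [exon_sequence(tx, genome, i) for i in range(1, tx.n_exons + 1)]
        for up in range(1, tx.n_exons + 1):
            for down in range(up + 1, tx.n_exons + 1):
                adjacent = down == up + 1
                if not adjacent and not include_skipping:
                    continue
                up_part = exon_seqs[up - 1][-min(window, len(exon_seqs[up - 1])) :]
                down_part = exon_seqs[down - 1][: min(window, len(exon_seqs[down - 1]))]
                records.append(
                    JunctionRecord(
                        junction_id=f"{tx.transcript_id}.j{up}-{down}",
                        transcript_id=tx.transcript_id,
                        upstream_exon_index=up,
                        downstream_exon_index=down,
                        sequence=up_part + down_part,
                        boundary_index=len(up_part),
                        kind="adjacent" if adjacent else "skipping",
                    )
                )
    return records


def write_junction_fasta(records: Sequence[JunctionRecord], path: str | Path) -> Path:
    """FASTA with headers ``junction_id|transcript_id|up|down|boundary_index|kind``."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = "|".join(
                [
                    rec.junction_id,
                    rec.transcript_id,
                    str(rec.upstream_exon_index),
                    str(rec.downstream_exon_index),
                    str(rec.boundary_index),
                    rec.kind,
                ]
            )
            out.write(f">{header}\n{rec.sequence}\n")
    return path


def read_junction_fasta(path: str | Path) -> list[JunctionRecord]:
    records: list[JunctionRecord] = []
    header: str | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        jid, tx, up, down, boundary, kind = header.split("|")
        records.append(
            JunctionRecord(jid, tx, int(up), int(down), "".join(seq_parts), int(boundary), kind)
        )

    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        flush()
    return records
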