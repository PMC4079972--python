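"""Lariat signature database construction.

A lariat signature is the diagnostic sequence a reverse transcriptase
produces when it reads through the 2'-5' bond of an intron lariat: the
intronic sequence immediately upstream of the branch point (ending at the
branch-point base) followed by the 5' end of the intron.  For a read
length ``k`` only the last ``k-1`` bases of the 5' segment and the first
``k-1`` bases of the 3' segment can ever be covered by a single read, so
signatures are at most ``2k-1`` bases long.

Canonical signatures treat every base of an intron (or every adenine, in
adenine-only mode) as a candidate branch point.  Exon-skipping signatures
do the same for the downstream intron of every ordered intron pair of a
transcript, with the 3' segment taken from the upstream intron's 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_io import Intron, intron_id_for

logger = logging.getLogger(__name__)

MODES = ("all_bases", "adenine_only")


@dataclass(frozen=True)
class LariatSignature:
    """One diagnostic lariat sequence with its provenance.

    ``bp_offset`` is the 1-based position of the branch-point base within
    the branch-point-donor intron (the downstream intron for skipping
    events), in transcript orientation.  ``bp_index_in_sequence`` is the
    0-based index of that base within ``sequence``.
    """

    signature_id: str
    transcript_id: str
    upstream_intron_index: int
    downstream_intron_index: int
    bp_offset: int
    bp_base: str
    sequence: str
    bp_index_in_sequence: int
    kind: str  # "canonical" | "skipping"
    degenerate: bool = False  # branch point at intron position 1 (empty 5' segment)

    @property
    def source_id(self) -> str:
        """Identifier of the intron (canonical) or intron pair (skipping)."""
        if self.kind == "canonical":
            return intron_id_for(self.transcript_id, self.downstream_intron_index)
        return (
            f"{self.transcript_id}.i{self.upstream_intron_index}"
            f"-i{self.downstream_intron_index}"
        )

    @property
    def contains_n(self) -> bool:
        return "N" in self.sequence


def _candidate_positions(sequence: str, mode: str) -> Iterable[int]:
    """Candidate branch-point positions, iterated 3' end -> position 1."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    for p in range(len(sequence), 0, -1):
        if mode == "all_bases" or sequence[p - 1] == "A":
            yield p


def build_canonical_signatures(
    intron: Intron, read_length: int, mode: str = "all_bases"
) -> list[LariatSignature]:
    """All lariat signatures of one intron.

    The 3' segment is the first ``min(read_length-1, L)`` bases of the
    intron; for each candidate branch-point position ``p`` the 5' segment
    is the last ``min(read_length-1, p-1)`` bases upstream of ``p``.
    In ``all_bases`` mode every position is a candidate (L signatures),
    in ``adenine_only`` mode only adenines are.
    """
    if read_length < 2:
        raise ValueError(f"read_length must be >= 2, got {read_length}")
    seq = intron.sequence
    if not seq:
        raise ValueError(f"intron {intron.intron_id} has an empty sequence")
    window = read_length - 1
    three = seq[: min(window, len(seq))]
    signatures = []
    for p in _candidate_positions(seq, mode):
        five = seq[max(0, p - 1 - window) : p - 1]
        signatures.append(
            LariatSignature(
                signature_id=f"{intron.intron_id}:bp{p}",
                transcript_id=intron.transcript_id,
                upstream_intron_index=intron.index,
                downstream_intron_index=intron.index,
                bp_offset=p,
                bp_base=seq[p - 1],
                sequence=five + seq[p - 1] + three,
                bp_index_in_sequence=len(five),
                kind="canonical",
                degenerate=(p == 1),
            )
        )
    return signatures


def build_skipping_signatures(
    introns_of_transcript: Sequence[Intron],
    read_length: int,
    mode: str = "all_bases",
    intervening: Mapping[tuple[int, int], str] | None = None,
) -> list[LariatSignature]:
    """Signatures for every exon-skipping event of one transcript.

    For each ordered intron pair (i, j) with i < j the input sequence is
    the upstream intron with the downstream intron attached to its 3' end;
    branch-point candidates iterate over the downstream intron only, and
    the 3' segment is always the 5' end of the upstream intron.  When the
    branch point sits near the downstream intron's 5' end the 5' segment
    extends into the attached upstream sequence.

    ``intervening`` optionally maps an intron-index pair to the genuine
    transcript sequence between the two introns (the skipped exons); when
    given it is inserted between the concatenated introns so that 5'
    segments crossing the intron boundary use real exonic context instead
    of the intron-concatenation construction.
    """
    if read_length < 2:
        raise ValueError(f"read_length must be >= 2, got {read_length}")
    introns = sorted(introns_of_transcript, key=lambda i: i.index)
    if len(introns) < 2:
        return []
    tx_ids = {i.transcript_id for i in introns}
    if len(tx_ids) != 1:
        raise ValueError(f"introns span multiple transcripts: {sorted(tx_ids)}")
    window = read_length - 1
    signatures = []
    for a, up in enumerate(introns):
        for down in introns[a + 1 :]:
            pair = (up.index, down.index)
            between = intervening.get(pair, "") if intervening else ""
            concat = up.sequence + between + down.sequence
            head = len(up.sequence) + len(between)
            three = up.sequence[: min(window, len(up.sequence))]
            for p in _candidate_positions(down.sequence, mode):
                g = head + p  # 1-based position of the BP in the concatenation
                five = concat[max(0, g - 1 - window) : g - 1]
                signatures.append(
                    LariatSignature(
                        signature_id=(
                            f"{up.transcript_id}.i{up.index}-i{down.index}:bp{p}"
                        ),
                        transcript_id=up.transcript_id,
                        upstream_intron_index=up.index,
                        downstream_intron_index=down.index,
                        bp_offset=p,
                        bp_base=down.sequence[p - 1],
                        sequence=five + down.sequence[p - 1] + three,
                        bp_index_in_sequence=len(five),
                        kind="skipping",
                        degenerate=False,
                    )
                )
    return signatures


def enumerate_skipping_pairs(n_introns: int) -> int:
    """Number of distinct exon-skipping events for ``n_introns`` introns.

    Equals the number of ordered intron pairs i < j: (I-1) * I / 2.
    """
    if n_introns < 0:
        raise ValueError(f"intron count must be >= 0, got {n_introns}")
    return (n_introns - 1) * n_introns // 2


def build_signature_db(
    introns: Sequence[Intron],
    read_length: int,
    mode: str = "all_bases",
    include_skipping: bool = True,
) -> list[LariatSignature]:
    """Canonical (+ optionally skipping) signatures for a whole annotation."""
    by_tx: dict[str, list[Intron]] = {}
    for intron in introns:
        by_tx.setdefault(intron.transcript_id, []).append(intron)
    signatures: list[LariatSignature] = []
    for tx_introns in by_tx.values():
        for intron in sorted(tx_introns, key=lambda i: i.index):
            signatures.extend(build_canonical_signatures(intron, read_length, mode))
        if include_skipping:
            signatures.extend(build_skipping_signatures(tx_introns, read_length, mode))
    n_flagged = sum(1 for s in signatures if s.contains_n)
    if n_flagged:
        logger.warning("%d signatures contain N bases", n_flagged)
    return signatures


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _provenance_block(sig: LariatSignature) -> str:
    return "|".join(
        [
            sig.signature_id,
            sig.transcript_id,
            str(sig.upstream_intron_index),
            str(sig.downstream_intron_index),
            str(sig.bp_offset),
            sig.bp_base,
            str(sig.bp_index_in_sequence),
            sig.kind,
        ]
    )


def _sort_key(sig: LariatSignature):
    return (
        sig.transcript_id,
        sig.kind,
        sig.upstream_intron_index,
        sig.downstream_intron_index,
        -sig.bp_offset,
    )


def write_lariat_fasta(
    signatures: Sequence[LariatSignature],
    path: str | Path,
    chunk_size: int | None = None,
) -> list[Path]:
    """Write signatures as FASTA, optionally chunked into several files.

    Headers carry one or more pipe-delimited provenance blocks
    (``signature_id|transcript_id|up|down|bp_offset|bp_base|bp_index|kind``)
    separated by ``;``.  Exact duplicate sequences within one transcript
    are collapsed into a single record that retains every provenance.
    Ordering is deterministic: transcript, kind, intron pair, descending
    branch-point offset.
    """
    if not signatures:
        raise ValueError("no signatures to write")
    ordered = sorted(signatures, key=_sort_key)
    grouped: dict[tuple[str, str], list[LariatSignature]] = {}
    for sig in ordered:
        grouped.setdefault((sig.transcript_id, sig.sequence), []).append(sig)
    records: list[tuple[str, str]] = []  # (header, sequence)
    seen: set[tuple[str, str]] = set()
    for sig in ordered:
        key = (sig.transcript_id, sig.sequence)
        if key in seen:
            continue
        seen.add(key)
        header = ";".join(_provenance_block(s) for s in grouped[key])
        records.append((header, sig.sequence))

    path = Path(path)
    if chunk_size is None or chunk_size >= len(records):
        chunks = [records]
        paths = [path]
    else:
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        chunks = [
            records[i : i + chunk_size] for i in range(0, len(records), chunk_size)
        ]
        paths = [
            path.with_name(f"{path.stem}.{i:04d}{path.suffix}")
            for i in range(len(chunks))
        ]
    for chunk_path, chunk in zip(paths, chunks):
        with open(chunk_path, "w") as out:
            for header, seq in chunk:
                out.write(f">{header}\n{seq}\n")
    return paths


def read_lariat_fasta(paths: Iterable[str | Path]) -> list[LariatSignature]:
    """Round-trip reader for :func:`write_lariat_fasta` output.

    Collapsed duplicates are re-expanded: one ``LariatSignature`` per
    provenance block.
    """
    signatures: list[LariatSignature] = []
    for path in paths:
        with open(path) as handle:
            header: str | None = None
            seq_parts: list[str] = []
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if header is not None:
                        signatures.extend(_expand_record(header, "".join(seq_parts)))
                    header = line[1:]
                    seq_parts = []
                else:
                    seq_parts.append(line)
            if header is not None:
                signatures.extend(_expand_record(header, "".join(seq_parts)))
    return signatures


def _expand_record(header: str, sequence: str) -> list[LariatSignature]:
    out = []
    for block in header.split(";"):
        (sig_id, tx, up, down, bp_offset, bp_base, bp_index, kind) = block.split("|")
        out.append(
            LariatSignature(
                signature_id=sig_id,
                transcript_id=tx,
                upstream_intron_index=int(up),
                downstream_intron_index=int(down),
                bp_offset=int(bp_offset),
                bp_base=bp_base,
                sequence=sequence,
                bp_index_in_sequence=int(bp_index),
                kind=kind,
                degenerate=(kind == "canonical" and int(bp_offset) == 1),
            )
        )
    return out


def signature_manifest_tsv(signatures: Sequence[LariatSignature]) -> str:
    """TSV manifest (one row per signature) for bookkeeping and audits."""
    header = (
        "signature_id\ttranscript_id\tupstream_intron_index\t"
        "downstream_intron_index\tbp_offset\tbp_base\tbp_index_in_sequence\t"
        "kind\tdegenerate\tlength"
    )
    rows = [header]
    for sig in sorted(signatures, key=_sort_key):
        rows.append(
            "\t".join(
                [
                    sig.signature_id,
                    sig.transcript_id,
                    str(sig.upstream_intron_index),
                    str(sig.downstream_intron_index),
                    str(sig.bp_offset),
                    sig.bp_base,
                    str(sig.bp_index_in_sequence),
                    sig.kind,
                    str(int(sig.degenerate)),
                    str(len(sig.sequence)),
                ]
            )
        )
    return "\n".join(rows) + "\n"
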