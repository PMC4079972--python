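"""Ungapped, mismatch-tolerant read matching and staged classification.

The matcher's contract is brute force: a hit is every placement of the
whole read inside a reference with Hamming distance at most
``max_mismatches`` (N counts as a mismatch on either side).  For speed a
pigeonhole seed index is used: a placement with at most ``m`` mismatches
must contain at least one exact ``len(read) // (m + 1)``-mer among
``m + 1`` disjoint seeds, so exact seed lookup followed by verification
finds every valid placement.  Depending on which side is larger, either
the references or the read seeds are indexed; both paths produce
identical hit sets.

Classification follows the lariat detection workflow: reads are matched
against the genome first (3 mismatches by default, both orientations),
then against exon-exon junction/transcriptome references, and only reads
unmapped after those stages are matched against the lariat signature
database (1 mismatch by default, to absorb the reverse-transcriptase
mutation at the branch point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .annotation_io import reverse_complement

logger = logging.getLogger(__name__)

# Above this many total reference bases the matcher indexes read seeds and
# scans the references instead of indexing the references.
_REF_INDEX_MAX_BASES = 2_000_000

STAGES = ("genome", "junction", "lariat", "unmapped")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id} has an empty sequence")


@dataclass(frozen=True)
class LariatHit:
    """One ungapped placement of a read inside a reference sequence.

    ``offset`` is the 0-based start of the read within the reference;
    ``mismatch_positions`` are 0-based indices into the read in its
    original orientation.  The branch-point annotations
    (``overlap_5prime``/``overlap_3prime``/``mismatch_at_bp``) are only
    set for hits against lariat signatures, where the lariat junction is
    the boundary between the branch-point base and the 3' segment.
    """

    read_id: str
    ref_id: str
    offset: int
    orientation: str  # "sense" | "antisense"
    mismatch_positions: tuple[int, ...]
    read_length: int
    overlap_5prime: int | None = None
    overlap_3prime: int | None = None
    mismatch_at_bp: bool | None = None
    mismatch_count_unknown: bool = False  # external alignments lacking NM

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def signature_id(self) -> str:
        return self.ref_id


def annotate_bp(hit: LariatHit, bp_index_in_sequence: int) -> LariatHit:
    """Fill branch-point junction annotations for a lariat-signature hit.

    The 5' side of the lariat junction includes the branch-point base
    itself (reference indices <= ``bp_index_in_sequence``).
    """
    ov5 = min(max(bp_index_in_sequence + 1 - hit.offset, 0), hit.read_length)
    ov3 = hit.read_length - ov5
    if hit.orientation == "sense":
        at_bp = any(hit.offset + i == bp_index_in_sequence for i in hit.mismatch_positions)
    else:
        at_bp = any(
            hit.offset + (hit.read_length - 1 - i) == bp_index_in_sequence
            for i in hit.mismatch_positions
        )
    return replace(hit, overlap_5prime=ov5, overlap_3prime=ov3, mismatch_at_bp=at_bp)


# ---------------------------------------------------------------------------
# Core matching
# ---------------------------------------------------------------------------

def _mismatch_positions(query: str, ref: str, start: int, max_mm: int) -> list[int] | None:
    """Mismatch indices of ``query`` placed at ``ref[start:]``, or None if > max_mm."""
    positions: list[int] = []
    for i, base in enumerate(query):
        r = ref[start + i]
        if base != r or base == "N" or r == "N":
            positions.append(i)
            if len(positions) > max_mm:
                return None
    return positions


def brute_force_hits(query: str, ref: str, max_mm: int) -> list[tuple[int, tuple[int, ...]]]:
    """Exhaustive scan over all placements; the matcher's reference semantics."""
    hits = []
    for start in range(len(ref) - len(query) + 1):
        positions = _mismatch_positions(query, ref, start, max_mm)
        if positions is not None:
            hits.append((start, tuple(positions)))
    return hits


def _normalize_refs(references) -> list[tuple[str, str, int | None]]:
    """Coerce reference entries to (ref_id, sequence, bp_index or None)."""
    norm = []
    for ref in references:
        if hasattr(ref, "signature_id") and hasattr(ref, "bp_index_in_sequence"):
            norm.append((ref.signature_id, ref.sequence, ref.bp_index_in_sequence))
        elif hasattr(ref, "junction_id"):
            norm.append((ref.junction_id, ref.sequence, None))
        elif len(ref) == 3:  # already normalized
            norm.append(tuple(ref))
        else:
            ref_id, seq = ref
            norm.append((ref_id, seq, None))
    return norm


def _oriented_queries(
    reads: Sequence[ReadRecord], orientation_policy: str
) -> list[tuple[int, str, str]]:
    """(read index, oriented sequence, orientation) for each query to run."""
    if orientation_policy not in ("sense_only", "both"):
        raise ValueError(f"unknown orientation policy {orientation_policy!r}")
    queries = []
    for idx, read in enumerate(reads):
        seq = read.sequence.upper()
        queries.append((idx, seq, "sense"))
        if orientation_policy == "both":
            queries.append((idx, reverse_complement(seq), "antisense"))
    return queries


def _verify(
    queries: list[tuple[int, str, str]],
    refs: list[tuple[str, str, int | None]],
    candidates: dict[int, set[tuple[int, int]]],
    reads: Sequence[ReadRecord],
    max_mm: int,
) -> dict[str, list[LariatHit]]:
    hits_by_read: dict[str, list[LariatHit]] = {}
    for q_idx, placements in candidates.items():
        read_idx, qseq, orientation = queries[q_idx]
        read = reads[read_idx]
        for ref_idx, start in sorted(placements):
            ref_id, ref_seq, bp_index = refs[ref_idx]
            positions = _mismatch_positions(qseq, ref_seq, start, max_mm)
            if positions is None:
                continue
            if orientation == "antisense":
                mm = tuple(sorted(len(qseq) - 1 - i for i in positions))
            else:
                mm = tuple(positions)
            hit = LariatHit(
                read_id=read.read_id,
                ref_id=ref_id,
                offset=start,
                orientation=orientation,
                mismatch_positions=mm,
                read_length=len(qseq),
            )
            if bp_index is not None:
                hit = annotate_bp(hit, bp_index)
            hits_by_read.setdefault(read.read_id, []).append(hit)
    return hits_by_read


def match_reads(
    reads: Sequence[ReadRecord],
    references,
    max_mismatches: int,
    orientation_policy: str = "sense_only",
) -> dict[str, list[LariatHit]]:
    """Match many reads against a reference set; {read_id: hits}.

    Reads without any acceptable placement are absent from the result.
    """
    if max_mismatches not in (0, 1, 2, 3):
        raise ValueError(f"max_mismatches must be in 0..3, got {max_mismatches}")
    refs = _normalize_refs(references)
    queries = _oriented_queries(reads, orientation_policy)
    total_ref_bases = sum(len(seq) for _, seq, _ in refs)

    # Group queries by seed length; k = 0 (read shorter than m+1) -> brute force.
    by_k: dict[int, list[int]] = {}
    for q_idx, (_, qseq, _) in enumerate(queries):
        k = len(qseq) // (max_mismatches + 1)
        by_k.setdefault(k, []).append(q_idx)

    candidates: dict[int, set[tuple[int, int]]] = {}

    def add(q_idx: int, ref_idx: int, start: int, qlen: int) -> None:
        if 0 <= start <= len(refs[ref_idx][1]) - qlen:
            candidates.setdefault(q_idx, set()).add((ref_idx, start))

    brute_queries = by_k.pop(0, [])
    for q_idx in brute_queries:
        _, qseq, _ = queries[q_idx]
        for ref_idx, (_, ref_seq, _) in enumerate(refs):
            for start in range(len(ref_seq) - len(qseq) + 1):
                add(q_idx, ref_idx, start, len(qseq))

    if by_k and total_ref_bases <= _REF_INDEX_MAX_BASES:
        for k, q_indices in by_k.items():
            index: dict[str, list[tuple[int, int]]] = {}
            for ref_idx, (_, ref_seq, _) in enumerate(refs):
                for pos in range(len(ref_seq) - k + 1):
                    index.setdefault(ref_seq[pos : pos + k], []).append((ref_idx, pos))
            for q_idx in q_indices:
                _, qseq, _ = queries[q_idx]
                for seed_no in range(max_mismatches + 1):
                    off = seed_no * k
                    for ref_idx, pos in index.get(qseq[off : off + k], ()):
                        add(q_idx, ref_idx, pos - off, len(qseq))
    elif by_k:
        for k, q_indices in by_k.items():
            seed_map: dict[str, list[tuple[int, int]]] = {}
            for q_idx in q_indices:
                _, qseq, _ = queries[q_idx]
                for seed_no in range(max_mismatches + 1):
                    off = seed_no * k
                    seed_map.setdefault(qseq[off : off + k], []).append((q_idx, off))
            get = seed_map.get
            for ref_idx, (_, ref_seq, _) in enumerate(refs):
                for pos in range(len(ref_seq) - k + 1):
                    entry = get(ref_seq[pos : pos + k])
                    if entry is not None:
                        for q_idx, off in entry:
                            qlen = len(queries[q_idx][1])
                            add(q_idx, ref_idx, pos - off, qlen)

    return _verify(queries, refs, candidates, reads, max_mismatches)


def match_read(
    read: ReadRecord,
    references,
    max_mismatches: int,
    orientation_policy: str = "sense_only",
) -> list[LariatHit]:
    """Every ungapped, fully contained placement of one read (see module doc)."""
    return match_reads([read], references, max_mismatches, orientation_policy).get(
        read.read_id, []
    )


# ---------------------------------------------------------------------------
# Staged classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifyParams:
    genome_mm: int = 3
    lariat_mm: int = 1
    unique_only: bool = True
    stranded: bool = True  # strand-specific library: junction/lariat stages sense-only
    pretrim: int = 0  # trim a fixed prefix off every read before classification


@dataclass
class ClassificationResult:
    """Disjoint partition of the input reads over the workflow stages."""

    assignments: dict[str, str]  # read_id -> stage
    ambiguous: set[str]  # multi-placed reads, flagged within their stage
    genome_hits: dict[str, LariatHit]
    junction_hits: dict[str, LariatHit]
    lariat_hits: dict[str, list[LariatHit]]
    counts: dict[str, dict[str, int]]

    def counts_tsv(self) -> str:
        lines = ["stage\tunique\tambiguous\ttotal"]
        for stage in STAGES:
            row = self.counts.get(stage, {"unique": 0, "ambiguous": 0})
            lines.append(
                f"{stage}\t{row['unique']}\t{row['ambiguous']}\t{row['unique'] + row['ambiguous']}"
            )
        return "\n".join(lines) + "\n"


def _best_placement(hits: list[LariatHit]) -> LariatHit:
    """Fewest mismatches, then smallest offset (tie-break within one reference)."""
    return min(hits, key=lambda h: (h.n_mismatches, h.offset))


def classify_reads(
    reads: Sequence[ReadRecord],
    genome_refs,
    transcriptome_and_junction_refs,
    lariat_refs,
    params: ClassifyParams = ClassifyParams(),
) -> ClassificationResult:
    """Run reads through the staged workflow and partition them.

    A read is assigned to the first stage with at least one acceptable
    placement.  Under ``unique_only``, multi-placed reads (multiple loci
    on the genome; multiple distinct reference sequences in the junction
    or lariat stage) are flagged ambiguous: they stay in that stage's
    partition but are excluded from the per-read hit tables.  Only reads
    surviving the genome and junction stages unmapped are matched against
    the lariat database.
    """
    if params.pretrim:
        reads = [
            ReadRecord(r.read_id, r.sequence[params.pretrim :], r.qualities)
            for r in reads
        ]
    assignments: dict[str, str] = {}
    ambiguous: set[str] = set()
    counts = {stage: {"unique": 0, "ambiguous": 0} for stage in STAGES}

    genome_norm = _normalize_refs(genome_refs)
    junction_norm = _normalize_refs(transcriptome_and_junction_refs)
    lariat_norm = _normalize_refs(lariat_refs)
    junction_seq = {ref_id: seq for ref_id, seq, _ in junction_norm}
    lariat_seq = {ref_id: seq for ref_id, seq, _ in lariat_norm}
    sense_policy = "sense_only" if params.stranded else "both"

    # Stage 1: genome (double-stranded, so always both orientations).
    genome_hits: dict[str, LariatHit] = {}
    stage1 = match_reads(reads, genome_norm, params.genome_mm, "both")
    remaining: list[ReadRecord] = []
    for read in reads:
        hits = stage1.get(read.read_id)
        if not hits:
            remaining.append(read)
            continue
        assignments[read.read_id] = "genome"
        placements = {(h.ref_id, h.offset, h.orientation) for h in hits}
        if params.unique_only and len(placements) > 1:
            ambiguous.add(read.read_id)
            counts["genome"]["ambiguous"] += 1
        else:
            genome_hits[read.read_id] = _best_placement(hits)
            counts["genome"]["unique"] += 1

    # Stage 2: transcriptome / exon-exon junctions.
    junction_hits: dict[str, LariatHit] = {}
    stage2 = match_reads(remaining, junction_norm, params.genome_mm, sense_policy)
    still: list[ReadRecord] = []
    for read in remaining:
        hits = stage2.get(read.read_id)
        if not hits:
            still.append(read)
            continue
        assignments[read.read_id] = "junction"
        distinct = {junction_seq[h.ref_id] for h in hits}
        if params.unique_only and len(distinct) > 1:
            ambiguous.add(read.read_id)
            counts["junction"]["ambiguous"] += 1
        else:
            junction_hits[read.read_id] = _best_placement(hits)
            counts["junction"]["unique"] += 1

    # Stage 3: lariat signatures (only reads unmapped so far).
    lariat_hits: dict[str, list[LariatHit]] = {}
    stage3 = match_reads(still, lariat_norm, params.lariat_mm, sense_policy)
    for read in still:
        hits = stage3.get(read.read_id)
        if not hits:
            assignments[read.read_id] = "unmapped"
            counts["unmapped"]["unique"] += 1
            continue
        assignments[read.read_id] = "lariat"
        distinct = {lariat_seq[h.ref_id] for h in hits}
        if params.unique_only and len(distinct) > 1:
            ambiguous.add(read.read_id)
            counts["lariat"]["ambiguous"] += 1
        else:
            # Best placement per reference; several references may share the
            # one winning sequence (collapsed provenance) - keep them all.
            by_ref: dict[str, list[LariatHit]] = {}
            for h in hits:
                by_ref.setdefault(h.ref_id, []).append(h)
            lariat_hits[read.read_id] = [_best_placement(v) for v in by_ref.values()]
            counts["lariat"]["unique"] += 1

    logger.info(
        "classified %d reads: %s",
        len(reads),
        {s: counts[s]["unique"] + counts[s]["ambiguous"] for s in STAGES},
    )
    return ClassificationResult(
        assignments=assignments,
        ambiguous=ambiguous,
        genome_hits=genome_hits,
        junction_hits=junction_hits,
        lariat_hits=lariat_hits,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# External alignments (SAM)
# ---------------------------------------------------------------------------

@dataclass
class ExternalPartition:
    """Mapped/unmapped split recovered from an external aligner's SAM."""

    stage: str
    mapped: dict[str, LariatHit]
    unmapped: set[str]
    ambiguous: set[str]


def ingest_external_alignments(
    sam_path: str, stage: str = "genome", unique_only: bool = True
) -> ExternalPartition:
    """Convert a SAM file into the same partition structure as the matcher.

    Mismatch counts come from the NM tag; records lacking it are kept
    with the count unknown and flagged.  Under ``unique_only``, reads
    with several mapped records are dropped as ambiguous.
    """
    import pysam

    records: dict[str, list] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam:
            records.setdefault(aln.query_name, []).append(aln)

    mapped: dict[str, LariatHit] = {}
    unmapped: set[str] = set()
    ambiguous: set[str] = set()
    for name, alns in records.items():
        placed = [a for a in alns if not a.is_unmapped]
        if not placed:
            unmapped.add(name)
            continue
        if unique_only and len(placed) > 1:
            ambiguous.add(name)
            continue
        aln = placed[0]
        nm_known = aln.has_tag("NM")
        nm = int(aln.get_tag("NM")) if nm_known else 0
        if not nm_known:
            logger.warning("read %s: NM tag missing, mismatch count unknown", name)
        mapped[name] = LariatHit(
            read_id=name,
            ref_id=aln.reference_name or "",
            offset=aln.reference_start,
            orientation="antisense" if aln.is_reverse else "sense",
            mismatch_positions=tuple(range(nm)),  # positions unknown from NM alone
            read_length=aln.query_length or len(aln.query_sequence or ""),
            mismatch_count_unknown=not nm_known,
        )
    return ExternalPartition(stage=stage, mapped=mapped, unmapped=unmapped, ambiguous=ambiguous)
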