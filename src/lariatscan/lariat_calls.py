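"""From lariat hits to branch-point calls.

Reads matched to lariat signatures become per-position branch-point
observations.  Reverse transcription scatters observations over the one
or two bases next to the real branch point (base skipping and mutation at
the 2'-5' bond), so observations within ``cluster_gap`` bases of each
other are chained into clusters.  Within a cluster the representative is
the member with the most reads, except that when the top members differ
by fewer than ``tie_delta`` reads the one closer to the intron's 3' end
wins.  Clusters below ``min_reads`` total support are discarded; the
best-supported surviving cluster yields the primary branch point and the
rest become alternates.

A stringent filter set (used for noisy, debranching-proficient data such
as human tissue libraries) additionally requires uniquely placed sense
hits whose single mismatch, if any, falls exactly on the branch-point
base, overlapping the lariat junction by at least 10 bases on each side.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import LariatHit
from .lariat_db import LariatSignature

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_BINS = (0, 50, 75, 100, 150, 250, 10_000_000)


@dataclass(frozen=True)
class BranchPointObservation:
    """Read support for one candidate branch-point position."""

    source_id: str  # intron id (canonical) or intron pair id (skipping)
    bp_offset: int
    bp_base: str
    read_count: int
    kind: str  # "canonical" | "skipping"


@dataclass(frozen=True)
class BranchPointCall:
    """Clustered primary (and alternate) branch points of one intron."""

    source_id: str
    kind: str
    primary_offset: int
    primary_base: str
    primary_reads: int  # total support of the primary cluster
    cluster_members: tuple[int, ...]  # offsets absorbed into the primary
    alternates: tuple[tuple[int, int], ...]  # (offset, cluster support)
    distance_to_3prime: int | None = None  # L - primary_offset
    distance_to_5prime: int | None = None  # primary_offset - 1
    bp_shared_with_canonical: bool | None = None  # skipping calls only


@dataclass(frozen=True)
class StringentFilterOptions:
    unique_only: bool = True
    sense_only: bool = True
    require_mismatch_at_bp: bool = True
    min_junction_overlap: int = 10


def filter_hits_stringent(
    hits: Iterable[LariatHit],
    opts: StringentFilterOptions = StringentFilterOptions(),
    ambiguous_reads: frozenset[str] | set[str] = frozenset(),
) -> list[LariatHit]:
    """Apply the stringent hit filters; zero-mismatch hits always satisfy
    the mismatch-at-branch-point criterion."""
    kept = []
    for hit in hits:
        if opts.unique_only and hit.read_id in ambiguous_reads:
            continue
        if opts.sense_only and hit.orientation != "sense":
            continue
        if opts.require_mismatch_at_bp and hit.n_mismatches > 0 and not hit.mismatch_at_bp:
            continue
        if hit.overlap_5prime is None or hit.overlap_3prime is None:
            raise ValueError(f"hit for read {hit.read_id} lacks junction overlap annotation")
        if min(hit.overlap_5prime, hit.overlap_3prime) < opts.min_junction_overlap:
            continue
        kept.append(hit)
    return kept


def filter_hits_min_overlap(
    hits: Iterable[LariatHit], min_junction_overlap: int = 1
) -> list[LariatHit]:
    """Permissive default filter: junction overlap only (degenerate
    signatures with an empty 5' segment become inert for overlap >= 1)."""
    return [
        h
        for h in hits
        if h.overlap_5prime is not None
        and min(h.overlap_5prime, h.overlap_3prime) >= min_junction_overlap
    ]


def hits_to_observations(
    lariat_hits: Mapping[str, Sequence[LariatHit]],
    signatures_by_id: Mapping[str, LariatSignature],
    min_junction_overlap: int = 1,
    stringent: StringentFilterOptions | None = None,
    ambiguous_reads: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[BranchPointObservation], int]:
    """Aggregate per-read lariat hits into per-position observations.

    ``lariat_hits`` maps a read to its hits; a read whose hits point at
    several distinct (source, offset) branch points (identical collapsed
    sequences with diverging provenance) is dropped as ambiguous.
    Returns (observations, number of provenance-ambiguous reads).
    """
    counts: dict[tuple[str, int], list] = {}
    n_ambiguous = 0
    for read_id, hits in lariat_hits.items():
        if stringent is not None:
            hits = filter_hits_stringent(hits, stringent, ambiguous_reads)
        else:
            hits = filter_hits_min_overlap(hits, min_junction_overlap)
        targets = set()
        for hit in hits:
            sig = signatures_by_id[hit.ref_id]
            targets.add((sig.source_id, sig.bp_offset, sig.bp_base, sig.kind))
        if not targets:
            continue
        if len(targets) > 1:
            n_ambiguous += 1
            continue
        source_id, bp_offset, bp_base, kind = next(iter(targets))
        key = (source_id, bp_offset)
        if key in counts:
            counts[key][0] += 1
        else:
            counts[key] = [1, bp_base, kind]
    observations = [
        BranchPointObservation(source, offset, base, n, kind)
        for (source, offset), (n, base, kind) in sorted(counts.items())
    ]
    if n_ambiguous:
        logger.info("%d reads dropped for provenance-ambiguous branch points", n_ambiguous)
    return observations, n_ambiguous


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _cluster_chain(
    observations: Sequence[BranchPointObservation], cluster_gap: int
) -> list[list[BranchPointObservation]]:
    """Chain observations whose consecutive offsets are <= cluster_gap apart."""
    ordered = sorted(observations, key=lambda o: o.bp_offset)
    clusters: list[list[BranchPointObservation]] = []
    for obs in ordered:
        if clusters and obs.bp_offset - clusters[-1][-1].bp_offset <= cluster_gap:
            clusters[-1].append(obs)
        else:
            clusters.append([obs])
    return clusters


def _representative(
    cluster: Sequence[BranchPointObservation], tie_delta: int
) -> BranchPointObservation:
    """Highest-read member; the 3'-most of the top two when they differ by < tie_delta."""
    by_count = sorted(cluster, key=lambda o: (-o.read_count, -o.bp_offset))
    if len(by_count) >= 2 and by_count[0].read_count - by_count[1].read_count < tie_delta:
        return max(by_count[:2], key=lambda o: o.bp_offset)
    return by_count[0]


def cluster_branch_points(
    observations: Sequence[BranchPointObservation],
    min_reads: int = 3,
    tie_delta: int = 10,
    cluster_gap: int = 1,
    per_offset_threshold: bool = False,
) -> BranchPointCall | None:
    """Cluster one intron's observations into a branch-point call.

    ``min_reads`` applies to total cluster support by default (reverse
    transcription scatters reads over adjacent offsets); with
    ``per_offset_threshold`` it applies to the representative's own count.
    Returns None when no cluster survives.
    """
    if not observations:
        return None
    sources = {o.source_id for o in observations}
    if len(sources) != 1:
        raise ValueError(f"observations span several introns: {sorted(sources)}")
    clusters = _cluster_chain(observations, cluster_gap)
    scored = []
    for cluster in clusters:
        support = sum(o.read_count for o in cluster)
        rep = _representative(cluster, tie_delta)
        threshold_value = rep.read_count if per_offset_threshold else support
        if threshold_value >= min_reads:
            scored.append((support, rep, cluster))
    if not scored:
        return None
    scored.sort(key=lambda item: (-item[0], -item[1].bp_offset))
    support, rep, cluster = scored[0]
    return BranchPointCall(
        source_id=rep.source_id,
        kind=rep.kind,
        primary_offset=rep.bp_offset,
        primary_base=rep.bp_base,
        primary_reads=support,
        cluster_members=tuple(o.bp_offset for o in cluster),
        alternates=tuple(
            (alt_rep.bp_offset, alt_support) for alt_support, alt_rep, _ in scored[1:]
        ),
    )


def call_branch_points(
    observations: Iterable[BranchPointObservation],
    intron_lengths: Mapping[str, int],
    min_reads: int = 3,
    tie_delta: int = 10,
    cluster_gap: int = 1,
    per_offset_threshold: bool = False,
) -> list[BranchPointCall]:
    """Cluster observations per intron / skipping event and attach distances.

    Skipping calls are labeled ``bp_shared_with_canonical`` when their
    branch point equals the canonical primary of the downstream intron.
    """
    by_source: dict[str, list[BranchPointObservation]] = {}
    for obs in observations:
        by_source.setdefault(obs.source_id, []).append(obs)
    calls: list[BranchPointCall] = []
    canonical_primary: dict[str, int] = {}
    for source_id in sorted(by_source):
        call = cluster_branch_points(
            by_source[source_id], min_reads, tie_delta, cluster_gap, per_offset_threshold
        )
        if call is None:
            continue
        length = intron_lengths.get(_donor_intron_id(call))
        call = BranchPointCall(
            source_id=call.source_id,
            kind=call.kind,
            primary_offset=call.primary_offset,
            primary_base=call.primary_base,
            primary_reads=call.primary_reads,
            cluster_members=call.cluster_members,
            alternates=call.alternates,
            distance_to_3prime=None if length is None else length - call.primary_offset,
            distance_to_5prime=call.primary_offset - 1,
        )
        if call.kind == "canonical":
            canonical_primary[call.source_id] = call.primary_offset
        calls.append(call)
    # Second pass: label skipping events sharing the downstream canonical BP.
    labeled = []
    for call in calls:
        if call.kind == "skipping":
            shared = canonical_primary.get(_donor_intron_id(call)) == call.primary_offset
            call = BranchPointCall(
                **{**call.__dict__, "bp_shared_with_canonical": shared}
            )
        labeled.append(call)
    return labeled


def _donor_intron_id(call: BranchPointCall) -> str:
    """Intron that donates the branch point (downstream intron for skipping)."""
    if call.kind == "canonical":
        return call.source_id
    base, pair = call.source_id.rsplit(".", 1)
    down = pair.split("-")[1]  # "iK"
    return f"{base}.{down}"


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def bp_distance_stats(
    calls: Sequence[BranchPointCall],
    intron_lengths: Mapping[str, int],
    length_bins: Sequence[int] = DEFAULT_LENGTH_BINS,
) -> dict:
    """Distance of primary branch points to the intron 3' end, plus
    per-intron-length-bin detection counts."""
    canonical = [c for c in calls if c.kind == "canonical"]
    distances = {}
    for call in canonical:
        if call.source_id not in intron_lengths:
            raise KeyError(f"unknown intron {call.source_id}")
        distances[call.source_id] = intron_lengths[call.source_id] - call.primary_offset
    if not distances:
        return {"median_distance_to_3prime": None, "distances": {}, "per_length_bin": pd.DataFrame()}
    edges = list(length_bins)
    labels = [f"[{a},{b})" for a, b in zip(edges, edges[1:])]
    rows = []
    called = set(distances)
    for label, lo, hi in zip(labels, edges, edges[1:]):
        in_bin = [i for i, L in intron_lengths.items() if lo <= L < hi]
        rows.append(
            {
                "length_bin": label,
                "n_introns": len(in_bin),
                "n_detected": sum(1 for i in in_bin if i in called),
            }
        )
    per_bin = pd.DataFrame(rows).set_index("length_bin")
    per_bin["detection_rate"] = per_bin["n_detected"] / per_bin["n_introns"].replace(0, np.nan)
    return {
        "median_distance_to_3prime": statistics.median(distances.values()),
        "distances": distances,
        "per_length_bin": per_bin,
    }


def consensus_matrix(
    calls: Sequence[BranchPointCall],
    intron_sequences: Mapping[str, str],
    flank: int = 5,
    background_gc: float = 0.30,
) -> tuple[pd.DataFrame, pd.Series]:
    """Position frequency matrix around primary branch points.

    Windows run from -flank to +flank around each canonical primary
    branch point in transcript orientation; windows clipped by the intron
    bounds are excluded.  Per-column information content is the relative
    entropy sum_b p_b * log2(p_b / q_b) against a background with the
    given GC content (defaults: A=T=0.35, C=G=0.15).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    positions = list(range(-flank, flank + 1))
    counts = pd.DataFrame(0.0, index=list("ACGT"), columns=positions)
    n_used = 0
    for call in calls:
        if call.kind != "canonical":
            continue
        seq = intron_sequences[call.source_id]
        lo = call.primary_offset - flank
        hi = call.primary_offset + flank
        if lo < 1 or hi > len(seq):
            continue
        window = seq[lo - 1 : hi]
        for pos, base in zip(positions, window):
            if base in "ACGT":
                counts.loc[base, pos] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable (unclipped) branch-point windows")
    pfm = counts / counts.sum(axis=0)
    q = pd.Series(
        {
            "A": (1 - background_gc) / 2,
            "T": (1 - background_gc) / 2,
            "C": background_gc / 2,
            "G": background_gc / 2,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = pfm.mul(np.log2(pfm.div(q, axis=0)))
    ic = contrib.fillna(0.0).sum(axis=0)
    return pfm, ic


def calls_to_tsv(
    calls: Sequence[BranchPointCall], intron_lengths: Mapping[str, int] | None = None
) -> str:
    """Flat TSV call table (one row per primary branch point)."""
    header = (
        "source_id\tkind\tprimary_offset\tprimary_base\tprimary_reads\t"
        "cluster_members\talternates\tdistance_to_3prime\tdistance_to_5prime\t"
        "bp_shared_with_canonical"
    )
    rows = [header]
    for c in calls:
        rows.append(
            "\t".join(
                [
                    c.source_id,
                    c.kind,
                    str(c.primary_offset),
                    c.primary_base,
                    str(c.primary_reads),
                    ",".join(map(str, c.cluster_members)),
                    ",".join(f"{o}:{r}" for o, r in c.alternates) or ".",
                    "." if c.distance_to_3prime is None else str(c.distance_to_3prime),
                    "." if c.distance_to_5prime is None else str(c.distance_to_5prime),
                    "." if c.bp_shared_with_canonical is None else str(int(c.bp_shared_with_canonical)),
                ]
            )
        )
    return "\n".join(rows) + "\n"
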