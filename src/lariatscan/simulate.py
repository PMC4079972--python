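"""Synthetic genomes, reads and ground truth for end-to-end testing.

The generator emulates the data the lariat-detection workflow consumes:
multi-exon genes whose introns start GT, end AG and carry a planted
CTAAC branch site (the YURAY consensus with the branch-point adenine in
fourth position) near the 3' end (distance to the 3' end uniform on
8..16 bases, median 12).  Reads are single-end and strand-specific and
come from three sources: spliced mRNA, unspliced pre-mRNA, and lariat
junctions.  A lariat junction read runs along the lariat loop: up to
``u`` intronic bases ending at the branch point followed by the intron's
5' end.  The reverse transcriptase mutates the branch-point base with
probability ``rt_mutation`` (uniformly to one of the other three bases)
and skips it (1-base deletion) with probability ``rt_bp_skip``; reads
whose loop-side arm exceeds the available loop wrap around the loop,
cross the junction twice, and are therefore unmappable - this is what
biases detection against introns shorter than the read length.

Every emitted read carries exactly one ground-truth row, so each
pipeline stage can be checked for parameter recovery without downloads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import ClassifyParams, ReadRecord, classify_reads
from .annotation_io import (
    Intron,
    TranscriptModel,
    derive_introns,
    exon_sequence,
    mature_sequence,
    premrna_sequence,
    reverse_complement,
)
from .junction_db import build_junction_db
from .lariat_calls import call_branch_points, hits_to_observations
from .lariat_db import build_signature_db

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_BRANCH_SITE = "CTAAC"  # YURAY-like, branch-point adenine at the 4th position
_BP_IN_SITE = 3  # 0-based index of the branch-point base within the site


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data generator."""

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 5)  # uniform, inclusive
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (30, 500)
    bp_distance_to_3prime: tuple[int, int] = (8, 16)  # uniform, median 12
    fraction_mrna: float = 0.4
    fraction_premrna: float = 0.2
    fraction_lariat: float = 0.4
    skipping_rate: float = 0.05
    rt_mutation: float = 0.2
    rt_bp_skip: float = 0.02
    read_length: int = 49
    depth: int = 20_000
    lariat_reads_per_intron: int | None = None  # overrides fraction_lariat when set
    gc_content: float = 0.36
    intergenic: tuple[int, int] = (100, 300)
    stranded: bool = True

    def __post_init__(self) -> None:
        fractions = (self.fraction_mrna, self.fraction_premrna, self.fraction_lariat)
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"read-class fractions must sum to 1, got {fractions}")
        for name in ("skipping_rate", "rt_mutation", "rt_bp_skip", "gc_content"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.intron_length[0] < len(_BRANCH_SITE) + 4:
            raise ValueError("introns too short to hold GT..AG and a branch site")
        if self.bp_distance_to_3prime[0] < 3:
            raise ValueError("branch site would overwrite the 3' splice site")


@dataclass
class SyntheticGenome:
    """Genome, annotation and branch-point ground truth of one simulation."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    introns: list[Intron]
    truth: pd.DataFrame  # per intron: transcript_id, length, bp_offset, distance_to_3prime


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _make_intron(rng: np.random.Generator, config: SimulationConfig) -> tuple[str, int]:
    """One intron sequence (GT..AG, planted branch site) and its BP offset.

    Lengths are log-uniform over the configured span: intron length
    distributions are dominated by short introns (in fission yeast about
    a third are shorter than a 49-base read and >90% shorter than ~200
    bases), which is what drives the short-lariat detection bias.
    """
    lo, hi = config.intron_length
    length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    length = max(lo, min(hi, length))
    d3 = int(
        rng.integers(config.bp_distance_to_3prime[0], config.bp_distance_to_3prime[1] + 1)
    )
    d3 = min(d3, length - len(_BRANCH_SITE) - 2)  # keep the site inside GT..AG
    bp_offset = length - d3
    seq = list(_random_seq(rng, length, config.gc_content))
    seq[0:2] = "GT"
    seq[-2:] = "AG"
    site_start = bp_offset - 1 - _BP_IN_SITE  # 0-based
    seq[site_start : site_start + len(_BRANCH_SITE)] = _BRANCH_SITE
    return "".join(seq), bp_offset


def generate_genome(config: SimulationConfig, seed: int) -> SyntheticGenome:
    """Build a deterministic synthetic genome with annotated multi-exon genes."""
    rng = np.random.default_rng(seed)
    chrom_parts: list[str] = []
    cursor = 0  # 0-based length of chromosome assembled so far
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    for g in range(config.n_genes):
        spacer = int(rng.integers(config.intergenic[0], config.intergenic[1] + 1))
        chrom_parts.append(_random_seq(rng, spacer, config.gc_content))
        cursor += spacer
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tx_id = f"g{g + 1:04d}.1"
        parts: list[tuple[str, str, int]] = []  # (type, sequence, intron index)
        intron_meta: list[tuple[int, int, int]] = []  # (index, bp_offset, length)
        for e in range(n_exons):
            exon_len = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            parts.append(("exon", _random_seq(rng, exon_len, config.gc_content), 0))
            if e < n_exons - 1:
                intron_seq, bp_offset = _make_intron(rng, config)
                parts.append(("intron", intron_seq, e + 1))
                intron_meta.append((e + 1, bp_offset, len(intron_seq)))
        gene_seq_tx = "".join(seq for _, seq, _ in parts)
        gene_len = len(gene_seq_tx)
        gene_start = cursor + 1  # 1-based
        # Genomic intervals of the transcript-oriented parts.
        exon_intervals: list[tuple[int, int]] = []
        offset = 0
        for part_type, seq, _ in parts:
            if part_type == "exon":
                if strand == "+":
                    interval = (gene_start + offset, gene_start + offset + len(seq) - 1)
                else:
                    interval = (
                        gene_start + gene_len - offset - len(seq),
                        gene_start + gene_len - 1 - offset,
                    )
                exon_intervals.append(interval)
            offset += len(seq)
        chrom_parts.append(gene_seq_tx if strand == "+" else reverse_complement(gene_seq_tx))
        cursor += gene_len
        transcripts.append(
            TranscriptModel(tx_id, f"g{g + 1:04d}", "chr1", strand, tuple(exon_intervals))
        )
        for index, bp_offset, length in intron_meta:
            truth_rows.append(
                {
                    "intron_id": f"{tx_id}.i{index}",
                    "transcript_id": tx_id,
                    "intron_index": index,
                    "length": length,
                    "bp_offset": bp_offset,
                    "distance_to_3prime": length - bp_offset,
                }
            )
    genome = {"chr1": "".join(chrom_parts)}
    transcripts_list = transcripts
    introns = derive_introns(transcripts_list, genome)
    truth = pd.DataFrame(truth_rows).set_index("intron_id")
    # Construction check: derived introns must equal the planted ones.
    for intron in introns:
        assert intron.length == truth.loc[intron.intron_id, "length"]
    return SyntheticGenome(genome, transcripts_list, introns, truth)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _lariat_read(
    rng: np.random.Generator,
    loop_context: str,  # sequence upstream of and including the BP (ends at BP)
    loop_len: int,  # bases of the lariat loop available upstream of the BP
    three_src: str,  # intron whose 5' end follows the junction
    config: SimulationConfig,
) -> tuple[str, dict]:
    """One junction-spanning lariat read plus its truth attributes."""
    read_len = config.read_length
    u = int(rng.integers(1, read_len))  # bases on the 5' side of the junction
    v = min(read_len - u, len(three_src))
    u = read_len - v
    wrapped = u > loop_len
    if wrapped:
        loop = loop_context[-loop_len:]
        reps = math.ceil(u / loop_len) + 1
        left = (loop * reps)[-u:]
    else:
        left = loop_context[-u:]
    right = three_src[:v]
    mutated = False
    skipped = False
    if rng.random() < config.rt_bp_skip:
        skipped = True
        read = left[:-1] + right  # 1-base deletion at the branch point
    else:
        if rng.random() < config.rt_mutation:
            mutated = True
            left = left[:-1] + _mutate_base(rng, left[-1])
        read = left + right
    return read, {
        "overlap_5prime": u,
        "overlap_3prime": v,
        "bp_mutated": mutated,
        "bp_skipped": skipped,
        "wrapped": wrapped,
    }


def generate_reads(
    sim: SyntheticGenome, config: SimulationConfig, seed: int
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Sample strand-specific single-end reads with one truth row each.

    With ``lariat_reads_per_intron`` set, every intron receives exactly
    that many canonical lariat reads (plus Binomial(n, skipping_rate)
    reads per skipping pair) and ``depth`` covers the mRNA/pre-mRNA
    background; otherwise read classes are multinomial over the
    configured fractions.
    """
    rng = np.random.default_rng(seed)
    mature = {t.transcript_id: mature_sequence(t, sim.genome) for t in sim.transcripts}
    pre = {t.transcript_id: premrna_sequence(t, sim.genome) for t in sim.transcripts}
    introns_by_tx: dict[str, list[Intron]] = {}
    for intron in sim.introns:
        introns_by_tx.setdefault(intron.transcript_id, []).append(intron)
    for v in introns_by_tx.values():
        v.sort(key=lambda i: i.index)
    intron_by_id = {i.intron_id: i for i in sim.introns}
    exon_cache: dict[tuple[str, int], str] = {}
    tx_by_id = {t.transcript_id: t for t in sim.transcripts}

    def intervening_exons(tx_id: str, up: int, down: int) -> str:
        parts = []
        for e in range(up + 1, down + 1):  # exons between intron up and intron down
            key = (tx_id, e)
            if key not in exon_cache:
                exon_cache[key] = exon_sequence(tx_by_id[tx_id], sim.genome, e)
            parts.append(exon_cache[key])
        return "".join(parts)

    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []

    def emit(seq: str, category: str, tx_id: str, source_id: str, extra: dict) -> None:
        read_id = f"r{len(reads):07d}"
        reads.append(ReadRecord(read_id, seq))
        truth_rows.append(
            {
                "read_id": read_id,
                "category": category,
                "transcript_id": tx_id,
                "source_id": source_id,
                "bp_mutated": extra.get("bp_mutated", False),
                "bp_skipped": extra.get("bp_skipped", False),
                "wrapped": extra.get("wrapped", False),
                "overlap_5prime": extra.get("overlap_5prime", np.nan),
                "overlap_3prime": extra.get("overlap_3prime", np.nan),
            }
        )

    def emit_template_read(templates: Mapping[str, str], category: str) -> None:
        for _ in range(50):
            tx = sim.transcripts[int(rng.integers(0, len(sim.transcripts)))]
            template = templates[tx.transcript_id]
            if len(template) >= config.read_length:
                start = int(rng.integers(0, len(template) - config.read_length + 1))
                emit(
                    template[start : start + config.read_length],
                    category,
                    tx.transcript_id,
                    tx.transcript_id,
                    {},
                )
                return
        raise RuntimeError("no transcript long enough for the configured read length")

    def emit_canonical(intron: Intron) -> None:
        bp = int(sim.truth.loc[intron.intron_id, "bp_offset"])
        read, extra = _lariat_read(
            rng,
            loop_context=intron.sequence[:bp],
            loop_len=bp,
            three_src=intron.sequence,
            config=config,
        )
        emit(read, "lariat_canonical", intron.transcript_id, intron.intron_id, extra)

    def emit_skipping(up: Intron, down: Intron) -> None:
        bp = int(sim.truth.loc[down.intron_id, "bp_offset"])
        # Upstream of the downstream intron's loop lies the skipped exon(s):
        # true transcript context, which the intron-concatenation signature
        # construction does not model (reads reaching into it go unmapped).
        context = (
            intervening_exons(up.transcript_id, up.index, down.index)
            + down.sequence[:bp]
        )
        read, extra = _lariat_read(
            rng,
            loop_context=context,
            loop_len=len(context),
            three_src=up.sequence,
            config=config,
        )
        extra["wrapped"] = extra["wrapped"] or extra["overlap_5prime"] > bp
        source = f"{up.transcript_id}.i{up.index}-i{down.index}"
        emit(read, "lariat_skipping", up.transcript_id, source, extra)

    if config.lariat_reads_per_intron is not None:
        n_per = config.lariat_reads_per_intron
        for intron in sim.introns:
            for _ in range(n_per):
                emit_canonical(intron)
        for tx_introns in introns_by_tx.values():
            for a in range(len(tx_introns)):
                for b in range(a + 1, len(tx_introns)):
                    for _ in range(int(rng.binomial(n_per, config.skipping_rate))):
                        emit_skipping(tx_introns[a], tx_introns[b])
        background = config.fraction_mrna + config.fraction_premrna
        if background > 0 and config.depth > 0:
            n_mrna = int(rng.binomial(config.depth, config.fraction_mrna / background))
            for _ in range(n_mrna):
                emit_template_read(mature, "mRNA")
            for _ in range(config.depth - n_mrna):
                emit_template_read(pre, "preRNA")
    else:
        classes = rng.choice(
            3,
            size=config.depth,
            p=[config.fraction_mrna, config.fraction_premrna, config.fraction_lariat],
        )
        multi_intron_tx = [tx for tx, v in introns_by_tx.items() if len(v) >= 2]
        for cls in classes:
            if cls == 0:
                emit_template_read(mature, "mRNA")
            elif cls == 1:
                emit_template_read(pre, "preRNA")
            else:
                if multi_intron_tx and rng.random() < config.skipping_rate:
                    tx_id = multi_intron_tx[int(rng.integers(0, len(multi_intron_tx)))]
                    tx_introns = introns_by_tx[tx_id]
                    a, b = sorted(
                        rng.choice(len(tx_introns), size=2, replace=False).tolist()
                    )
                    emit_skipping(tx_introns[a], tx_introns[b])
                else:
                    intron = sim.introns[int(rng.integers(0, len(sim.introns)))]
                    emit_canonical(intron)

    columns = [
        "read_id", "category", "transcript_id", "source_id",
        "bp_mutated", "bp_skipped", "wrapped", "overlap_5prime", "overlap_3prime",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns).set_index("read_id")
    return reads, truth


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for name in sorted(genome):
            out.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
    return path


def write_annotation_gff(transcripts: Sequence[TranscriptModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for tx in transcripts:
            span = [p for exon in tx.exons for p in exon]
            out.write(
                "\t".join(
                    [
                        tx.chromosome,
                        "lariatscan_sim",
                        "mRNA",
                        str(min(span)),
                        str(max(span)),
                        ".",
                        tx.strand,
                        ".",
                        f"ID=transcript:{tx.transcript_id};gene_id={tx.gene_id}",
                    ]
                )
                + "\n"
            )
            genomic_order = sorted(tx.exons)
            for start, end in genomic_order:
                out.write(
                    "\t".join(
                        [
                            tx.chromosome,
                            "lariatscan_sim",
                            "exon",
                            str(start),
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            f"Parent=transcript:{tx.transcript_id};gene_id={tx.gene_id}",
                        ]
                    )
                    + "\n"
                )
    return path


def write_reads_fastq(reads: Sequence[ReadRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for read in reads:
            quals = read.qualities or "I" * len(read.sequence)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")
    return path


# ---------------------------------------------------------------------------
# End-to-end recovery harness
# ---------------------------------------------------------------------------

def evaluate_recovery(
    config: SimulationConfig | None = None,
    seed: int = 0,
    mode: str = "all_bases",
    min_reads: int = 3,
) -> dict:
    """Run the full workflow on simulated data and score it against truth.

    Returns a dict with the branch-point recovery rate among eligible
    introns (length >= read length and at least ``min_reads`` error-free
    lariat reads in truth, where error-free means the branch-point base
    was neither mutated nor skipped and the read did not wrap the loop),
    short- versus long-intron detection rates, the median called distance
    to the intron 3' end, and the intermediate objects for reuse.
    """
    if config is None:
        config = SimulationConfig(lariat_reads_per_intron=10)
    sim = generate_genome(config, seed)
    reads, read_truth = generate_reads(sim, config, seed + 1)
    signatures = build_signature_db(
        sim.introns, config.read_length, mode, include_skipping=True
    )
    junctions = build_junction_db(
        sim.transcripts, sim.genome, config.read_length, min_overlap=6
    )
    classification = classify_reads(
        reads,
        list(sim.genome.items()),
        junctions,
        signatures,
        ClassifyParams(stranded=config.stranded),
    )
    sig_by_id = {s.signature_id: s for s in signatures}
    observations, n_ambiguous = hits_to_observations(
        classification.lariat_hits, sig_by_id, min_junction_overlap=1
    )
    intron_lengths = {i.intron_id: i.length for i in sim.introns}
    calls = call_branch_points(observations, intron_lengths, min_reads=min_reads)
    called = {c.source_id: c for c in calls if c.kind == "canonical"}

    lariat_truth = read_truth[read_truth["category"] == "lariat_canonical"]
    clean = lariat_truth[
        ~(lariat_truth["bp_mutated"] | lariat_truth["bp_skipped"] | lariat_truth["wrapped"])
    ]
    clean_per_intron = clean.groupby("source_id").size()

    eligible = [
        intron_id
        for intron_id in sim.truth.index
        if sim.truth.loc[intron_id, "length"] >= config.read_length
        and clean_per_intron.get(intron_id, 0) >= min_reads
    ]
    correct = [
        intron_id
        for intron_id in eligible
        if intron_id in called
        and called[intron_id].primary_offset == int(sim.truth.loc[intron_id, "bp_offset"])
    ]
    short = sim.truth.index[sim.truth["length"] < config.read_length]
    long_ = sim.truth.index[sim.truth["length"] >= config.read_length]
    detection = lambda ids: (
        float(np.mean([i in called for i in ids])) if len(ids) else float("nan")
    )
    distances = [
        c.distance_to_3prime for c in called.values() if c.distance_to_3prime is not None
    ]
    return {
        "config": config,
        "sim": sim,
        "reads": reads,
        "read_truth": read_truth,
        "signatures": signatures,
        "junctions": junctions,
        "classification": classification,
        "observations": observations,
        "n_ambiguous_provenance": n_ambiguous,
        "calls": calls,
        "n_eligible": len(eligible),
        "n_correct": len(correct),
        "recovery_rate": len(correct) / len(eligible) if eligible else float("nan"),
        "detection_rate_short": detection(short),
        "detection_rate_long": detection(long_),
        "n_short": int(len(short)),
        "n_long": int(len(long_)),
        "median_called_distance_to_3prime": (
            float(np.median(distances)) if distances else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# Two-condition splice-count simulation (for the differential-splicing power check)
# ---------------------------------------------------------------------------

def simulate_splice_counts(
    n_introns: int = 300,
    n_affected: int = 30,
    n_replicates: int = 2,
    mean_depth: float = 60.0,
    se_range: tuple[float, float] = (0.7, 0.95),
    effect: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Simulate JR/EI counts for two conditions with paired replicates.

    Condition B multiplies the splicing probability of ``n_affected``
    designated introns by ``effect`` (default: halves it).  Returns
    ({sample: JR/EI frame}, affected intron ids); samples are named
    A1..Ak, B1..Bk.
    """
    rng = np.random.default_rng(seed)
    intron_ids = [f"intron{i:04d}" for i in range(n_introns)]
    base_se = rng.uniform(se_range[0], se_range[1], size=n_introns)
    affected = sorted(rng.choice(n_introns, size=n_affected, replace=False).tolist())
    affected_ids = [intron_ids[i] for i in affected]
    se_b = base_se.copy()
    se_b[affected] *= effect
    counts: dict[str, pd.DataFrame] = {}
    for rep in range(1, n_replicates + 1):
        for label, se in (("A", base_se), ("B", se_b)):
            depth = rng.poisson(mean_depth, size=n_introns)
            jr = rng.binomial(depth, se)
            counts[f"{label}{rep}"] = pd.DataFrame(
                {"JR": jr, "EI": depth - jr}, index=pd.Index(intron_ids, name="intron_id")
            )
    return counts, affected_ids
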