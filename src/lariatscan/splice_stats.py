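"""Splicing efficiency, differential splicing and expression statistics.

Splicing efficiency (SE) of an intron contrasts reads diagnostic for the
spliced mRNA (exon-exon junction reads, JR) with reads diagnostic for the
unspliced pre-mRNA (reads straddling the upstream-exon/intron boundary,
EI): SE = JR / (JR + EI), undefined when both are zero.  Differences in
SE between two conditions with paired replicates are tested per intron
with a Cochran-Mantel-Haenszel chi-square test on the 2x2xK table
(rows JR/EI, columns condition, strata replicates), and the resulting
p values are converted to false-discovery-rate q values (Storey's
lambda-grid estimator by default, Benjamini-Hochberg as an alternative).

Expression is normalized as RPKM: E = R * 1e9 / (T * L) + 1e-5, where R
is the read count in a region of length L and T the sample's total reads.
"""

from __future__ import annotations

import bisect
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aligner import ClassificationResult
from .annotation_io import Intron, TranscriptModel
from .junction_db import JunctionRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Diagnostic read counting
# ---------------------------------------------------------------------------

def _intron_boundaries(
    introns: Iterable[Intron],
) -> dict[str, list[tuple[int, str, str]]]:
    """Per chromosome, sorted (genomic boundary, intron_id, strand).

    The boundary is the last genomic base of the upstream (5') exon:
    intron start - 1 on "+", intron end on "-" (where the upstream exon
    lies genomically to the right).
    """
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for intron in introns:
        start, end = intron.genomic_interval
        boundary = start - 1 if intron.strand == "+" else end
        by_chrom.setdefault(intron.chromosome, []).append(
            (boundary, intron.intron_id, intron.strand)
        )
    for entries in by_chrom.values():
        entries.sort()
    return by_chrom


def count_diagnostic_reads(
    classification: ClassificationResult,
    junctions: Sequence[JunctionRecord],
    introns: Sequence[Intron],
    transcripts: Sequence[TranscriptModel] | None = None,
    min_overlap: int = 6,
    stranded: bool = True,
) -> pd.DataFrame:
    """Count JR and EI reads per intron for one sample.

    JR: uniquely junction-mapped reads overlapping an adjacent exon-exon
    boundary by at least ``min_overlap`` bases on each side.  EI: uniquely
    genome-mapped reads straddling the upstream-exon/intron boundary by at
    least ``min_overlap`` on each side (only the 5' exon side relative to
    the intron is counted).  For stranded libraries a genomic placement
    must match the gene's strand to count.
    """
    junction_by_id = {j.junction_id: j for j in junctions}
    jr = {i.intron_id: 0 for i in introns}
    ei = {i.intron_id: 0 for i in introns}
    intron_ids = set(jr)

    for hit in classification.junction_hits.values():
        rec = junction_by_id.get(hit.ref_id)
        if rec is None or rec.kind != "adjacent":
            continue
        ov_up = rec.boundary_index - hit.offset
        ov_down = (hit.offset + hit.read_length) - rec.boundary_index
        if min(ov_up, ov_down) < min_overlap:
            continue
        intron_id = f"{rec.transcript_id}.i{rec.intron_index}"
        if intron_id in intron_ids:
            jr[intron_id] += 1

    boundaries = _intron_boundaries(introns)
    for hit in classification.genome_hits.values():
        entries = boundaries.get(hit.ref_id)
        if not entries:
            continue
        lo = hit.offset + min_overlap  # smallest boundary the read straddles
        hi = hit.offset + hit.read_length - min_overlap  # largest
        if lo > hi:
            continue
        left = bisect.bisect_left(entries, (lo, "", ""))
        right = bisect.bisect_right(entries, (hi, "\x7f", "\x7f"))
        for boundary, intron_id, strand in entries[left:right]:
            if stranded:
                expected = "sense" if strand == "+" else "antisense"
                if hit.orientation != expected:
                    continue
            ei[intron_id] += 1

    frame = pd.DataFrame(
        {"JR": pd.Series(jr), "EI": pd.Series(ei)}
    ).rename_axis("intron_id")
    return frame.sort_index()


# ---------------------------------------------------------------------------
# Splicing efficiency
# ---------------------------------------------------------------------------

def splicing_efficiency(jr, ei, ratio: bool = False):
    """SE = JR / (JR + EI); NaN when both are zero.

    With ``ratio`` the unbounded raw ratio JR / EI is returned instead
    (infinite when EI is zero and JR positive).  Accepts scalars or
    array-likes.
    """
    jr_arr = np.asarray(jr, dtype=float)
    ei_arr = np.asarray(ei, dtype=float)
    if (jr_arr < 0).any() or (ei_arr < 0).any():
        raise ValueError("read counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        if ratio:
            out = jr_arr / ei_arr
            out = np.where((ei_arr == 0) & (jr_arr == 0), np.nan, out)
        else:
            total = jr_arr + ei_arr
            out = np.where(total > 0, jr_arr / np.where(total > 0, total, 1), np.nan)
    if np.isscalar(jr) and np.isscalar(ei):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Cochran-Mantel-Haenszel test
# ---------------------------------------------------------------------------

def cmh_test(
    tables, continuity_correction: bool = False
) -> tuple[float, float]:
    """Classical CMH chi-square (1 df) over stratified 2x2 tables.

    ``tables`` has shape (K, 2, 2): rows JR/EI, columns condition A/B,
    strata K replicate pairs.  Strata with a zero margin contribute
    nothing.  Returns (statistic, p); (nan, nan) with a warning when
    every stratum is degenerate.
    """
    arr = np.asarray(tables, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[1:] != (2, 2):
        raise ValueError(f"expected (K, 2, 2) tables, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    num = 0.0
    var = 0.0
    for a, b, c, d in arr.reshape(-1, 4):
        n = a + b + c + d
        if n <= 1:
            continue
        row1, col1 = a + b, a + c
        row2, col2 = c + d, b + d
        if 0 in (row1, row2, col1, col2):
            continue
        num += a - row1 * col1 / n
        var += row1 * row2 * col1 * col2 / (n * n * (n - 1))
    if var == 0:
        logger.warning("CMH test undefined: all strata degenerate")
        return float("nan"), float("nan")
    if continuity_correction:
        stat = (abs(num) - 0.5) ** 2 / var if abs(num) > 0.5 else 0.0
    else:
        stat = num * num / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# False discovery rate
# ---------------------------------------------------------------------------

def qvalues(pvals, method: str = "storey_lambda_grid") -> np.ndarray:
    """Convert p values to q values.

    ``storey_lambda_grid`` estimates the null proportion pi0 on a lambda
    grid 0.05..0.95 (step 0.05) with a cubic trend evaluated at the top
    of the grid, then applies the step-up transform; ``bh`` is plain
    Benjamini-Hochberg (pi0 = 1).  Output is monotone in p rank.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    if method == "bh":
        pi0 = 1.0
    elif method == "storey_lambda_grid":
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        if np.allclose(pi0_l, pi0_l[0]):
            pi0 = pi0_l[0]
        else:
            coeffs = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coeffs, lambdas[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def rpkm(reads, total_reads, region_length, constant: float = 1e9, eps: float = 1e-5):
    """RPKM expression: E = R * C / (T * L) + eps (eps avoids log-of-zero)."""
    total = np.asarray(total_reads, dtype=float)
    length = np.asarray(region_length, dtype=float)
    if (total <= 0).any() or (length <= 0).any():
        raise ValueError("total reads and region length must be positive")
    out = np.asarray(reads, dtype=float) * constant / (total * length) + eps
    if np.isscalar(reads):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Differential splicing across samples
# ---------------------------------------------------------------------------

def differential_splicing(
    counts: Mapping[str, pd.DataFrame],
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    fdr_method: str = "storey_lambda_grid",
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-intron SE table with CMH statistic, p and q values.

    ``counts`` maps a sample name to its JR/EI frame (as produced by
    :func:`count_diagnostic_reads`); ``condition_a``/``condition_b`` list
    the paired replicate sample names (stratum k = a_k vs b_k).
    """
    if len(condition_a) != len(condition_b) or not condition_a:
        raise ValueError("conditions must list the same, non-zero number of replicates")
    index = counts[condition_a[0]].index
    table = pd.DataFrame(index=index.copy())
    for sample, frame in counts.items():
        table[f"JR_{sample}"] = frame["JR"]
        table[f"EI_{sample}"] = frame["EI"]
        table[f"SE_{sample}"] = splicing_efficiency(
            frame["JR"].to_numpy(), frame["EI"].to_numpy()
        )
    stats_rows = []
    for intron in index:
        strata = []
        for sa, sb in zip(condition_a, condition_b):
            strata.append(
                [
                    [counts[sa].loc[intron, "JR"], counts[sb].loc[intron, "JR"]],
                    [counts[sa].loc[intron, "EI"], counts[sb].loc[intron, "EI"]],
                ]
            )
        stat, p = cmh_test(np.array(strata), continuity_correction)
        stats_rows.append((stat, p))
    table["cmh_stat"] = [s for s, _ in stats_rows]
    table["p_value"] = [p for _, p in stats_rows]
    tested = table["p_value"].notna()
    table["q_value"] = np.nan
    if tested.any():
        table.loc[tested, "q_value"] = qvalues(
            table.loc[tested, "p_value"].to_numpy(), method=fdr_method
        )
    return table
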