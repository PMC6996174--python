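"""Interval algebra and site characterization.

Overlap-rate matrices across assays, specific-vs-common site
classification, genomic feature categorization, cognate-gene assignment,
chromosomal distribution, peak-level quantification (reads per million)
with rank correlation, and tissue-specificity entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ChromSizes, GeneModel, GenomicInterval, IntervalSet, SignalTrack

__all__ = [
    "overlaps_any",
    "overlap_rate",
    "overlap_matrix",
    "classify_specific",
    "FeatureCategory",
    "categorize",
    "CognateAssignment",
    "assign_cognate_gene",
    "chromosome_distribution",
    "peak_level_rpm",
    "rank_correlation",
    "shannon_entropy",
]


def _chrom_index(subject: IntervalSet) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts sorted, running max of ends) for overlap queries."""
    out = {}
    for chrom, (starts, ends) in subject.by_chrom().items():
        out[chrom] = (starts, np.maximum.accumulate(ends))
    return out


def overlaps_any(query: IntervalSet, subject: IntervalSet, min_overlap: int = 1) -> np.ndarray:
    """Boolean per query interval: does it overlap >= min_overlap bp of any
    subject interval? Order follows query's sorted intervals."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    idx = _chrom_index(subject)
    raw = subject.by_chrom()
    out = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        if iv.chrom not in idx:
            continue
        starts, maxends = idx[iv.chrom]
        # only subjects starting early enough can reach min_overlap
        j = int(np.searchsorted(starts, iv.end - min_overlap, side="right"))
        if j == 0 or maxends[j - 1] < iv.start + min_overlap:
            continue
        if min_overlap == 1:
            # start < iv.end and end > iv.start within the prefix => hit
            out[i] = True
        else:
            s, e = raw[iv.chrom]
            ov = np.minimum(e[:j], iv.end) - np.maximum(s[:j], iv.start)
            out[i] = bool(np.any(ov >= min_overlap))
    return out


def overlap_rate(source: IntervalSet, linked: IntervalSet, min_overlap: int = 1) -> float:
    """Percentage of ``source`` intervals overlapping any ``linked`` interval.

    One-directional by design: rate(A, B) need not equal rate(B, A).
    """
    if len(source) == 0:
        raise ValueError("overlap_rate undefined for an empty source set")
    hits = overlaps_any(source, linked, min_overlap=min_overlap)
    return 100.0 * float(np.count_nonzero(hits)) / len(source)


def overlap_matrix(sets: Dict[str, IntervalSet], min_overlap: int = 1) -> pd.DataFrame:
    """All-pairs overlap-rate matrix: entry (row r, column c) is the
    percentage of set r's intervals overlapping set c. Diagonal is 100."""
    names = list(sets)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for r in names:
        for c in names:
            mat.loc[r, c] = overlap_rate(sets[r], sets[c], min_overlap=min_overlap)
    return mat


def classify_specific(
    mhs: IntervalSet,
    others: Sequence[IntervalSet],
    tracks: Optional[Sequence[SignalTrack]] = None,
    coverage_quantile: float = 0.5,
) -> List[str]:
    """Label each site 'cMHS' (covered by any other assay) or 'sMHS'.

    A site overlapping >= 1 bp of any interval in any other assay's peak
    set is common (cMHS); otherwise specific (sMHS). When signal tracks
    are supplied, a nominal cMHS is demoted to sMHS if its mean coverage
    falls below the genome-wide ``coverage_quantile`` in *every* track —
    i.e. it sits in a peak but carries no appreciable reads. Demotion can
    only move labels cMHS -> sMHS.
    """
    if not others:
        raise ValueError("need at least one comparison peak set")
    covered = np.zeros(len(mhs), dtype=bool)
    for other in others:
        covered |= overlaps_any(mhs, other)
    labels = ["cMHS" if c else "sMHS" for c in covered]
    if tracks:
        cutoffs = [float(np.quantile(t.all_values(), coverage_quantile)) for t in tracks]
        for i, iv in enumerate(mhs):
            if labels[i] != "cMHS":
                continue
            low_everywhere = True
            for track, cut in zip(tracks, cutoffs):
                seg = track.per_bp(iv.chrom, iv.start, min(iv.end, track.genome[iv.chrom]))
                if seg.size and float(seg.mean()) >= cut:
                    low_everywhere = False
                    break
            if low_everywhere:
                labels[i] = "sMHS"
    return labels


class FeatureCategory(str, Enum):
    GENIC = "genic"
    PROXIMAL_TSS = "proximal_TSS"
    PROXIMAL_TTS = "proximal_TTS"
    NEAR_GENE = "near_gene"
    TRANSPOSABLE_ELEMENT = "transposable_element"
    INTERGENIC = "intergenic"


def _point_distance(iv: GenomicInterval, pos: int) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end + 1
    return 0


def categorize(
    intervals: IntervalSet,
    genes: Sequence[GeneModel],
    tes: IntervalSet,
    proximal_bp: int = 1000,
    distal_bp: int = 3000,
) -> List[FeatureCategory]:
    """Assign each interval exactly one genomic-feature category.

    Precedence: overlapping a gene body -> genic; within ``proximal_bp``
    of a TSS/TTS -> proximal_TSS / proximal_TTS (nearer wins, TSS on
    ties); within ``distal_bp`` of a gene -> near_gene; else overlapping
    a transposable element -> transposable_element (so a TE category
    implies >= distal_bp from any gene); else intergenic.
    """
    gene_sets: Dict[str, List[GeneModel]] = {}
    for g in genes:
        gene_sets.setdefault(g.interval.chrom, []).append(g)
    out: List[FeatureCategory] = []
    te_hits = overlaps_any(intervals, tes) if len(tes) else np.zeros(len(intervals), dtype=bool)
    for i, iv in enumerate(intervals):
        cat = FeatureCategory.INTERGENIC
        chrom_genes = gene_sets.get(iv.chrom, [])
        best_tss = best_tts = best_gap = np.inf
        overlapping = False
        for g in chrom_genes:
            gi = g.interval
            gap = max(gi.start - iv.end + 1, iv.start - gi.end + 1, 0) if not iv.overlaps(gi) else 0
            if gap == 0:
                overlapping = True
                break
            best_gap = min(best_gap, gap)
            best_tss = min(best_tss, _point_distance(iv, g.tss))
            best_tts = min(best_tts, _point_distance(iv, g.tts))
        if overlapping:
            cat = FeatureCategory.GENIC
        elif min(best_tss, best_tts) <= proximal_bp:
            cat = (
                FeatureCategory.PROXIMAL_TSS
                if best_tss <= best_tts
                else FeatureCategory.PROXIMAL_TTS
            )
        elif best_gap <= distal_bp:
            cat = FeatureCategory.NEAR_GENE
        elif te_hits[i]:
            cat = FeatureCategory.TRANSPOSABLE_ELEMENT
        out.append(cat)
    return out


@dataclass(frozen=True)
class CognateAssignment:
    mhs_index: int
    gene_id: Optional[str]
    distance: Optional[int]


def assign_cognate_gene(
    mhs: GenomicInterval,
    genes: Sequence[GeneModel],
    max_dist: int = 1000,
    mhs_index: int = 0,
) -> CognateAssignment:
    """Nearest gene within ``max_dist`` bp up- or downstream (0 if
    overlapping); ties broken by smaller gene start. No directionality
    requirement — regulatory elements act in both orientations."""
    best: Optional[Tuple[int, int, str]] = None  # (distance, start, gene_id)
    for g in genes:
        if g.interval.chrom != mhs.chrom:
            continue
        d = mhs.distance_to(g.interval)
        if d is None or d > max_dist:
            continue
        key = (d, g.interval.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return CognateAssignment(mhs_index, None, None)
    return CognateAssignment(mhs_index, best[2], best[0])


def chromosome_distribution(
    intervals: IntervalSet, genome: ChromSizes, window: int = 10_000
) -> Dict[str, np.ndarray]:
    """Counts of interval midpoints per non-overlapping genomic window."""
    out = {}
    mids = intervals.midpoints()
    for chrom in genome:
        n = -(-genome[chrom] // window)
        vec = np.zeros(n, dtype=np.int64)
        if chrom in mids:
            np.add.at(vec, mids[chrom] // window, 1)
        out[chrom] = vec
    return out


def peak_level_rpm(peaks: IntervalSet, fragments: IntervalSet) -> np.ndarray:
    """Reads-per-million peak quantification.

    level = 1e6 x (fragments overlapping the peak) / (total fragments).
    A fragment overlaps when its extent intersects the peak by >= 1 bp.
    """
    total = len(fragments)
    if total == 0:
        raise ValueError("peak_level_rpm needs a nonempty fragment set")
    by_chrom = fragments.by_chrom()
    levels = np.zeros(len(peaks))
    sorted_frags = {
        c: (np.sort(starts), np.sort(ends)) for c, (starts, ends) in by_chrom.items()
    }
    for i, iv in enumerate(peaks):
        if iv.chrom not in sorted_frags:
            continue
        starts_sorted, ends_sorted = sorted_frags[iv.chrom]
        n_left = np.searchsorted(ends_sorted, iv.start, side="right")  # end <= start
        n_not_right = np.searchsorted(starts_sorted, iv.end, side="left")  # start < end
        levels[i] = n_not_right - n_left
    return 1e6 * levels / total


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman's rho with its large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def shannon_entropy(expression: Sequence[float]) -> float:
    """Shannon entropy (bits) of an expression profile across tissues.

    p_i = x_i / sum(x); H = -sum p_i log2 p_i with 0 log 0 := 0. A gene
    expressed in a single tissue scores 0; uniform expression across T
    tissues scores log2 T.
    """
    x = np.asarray(expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression values must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero vector")
    p = x / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())
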