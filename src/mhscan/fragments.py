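"""Fragment-level preprocessing: quality filtering and coverage tracks.

The retention contract for MNase-released fragments is mapping quality
strictly greater than the threshold (default 10) and, optionally, a
full-length alignment (no soft/hard clipping).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .intervals import ChromSizes, FragmentRecord, IntervalSet, SignalTrack

__all__ = ["filter_fragments", "filter_fragment_table", "coverage_from_fragments"]


def filter_fragments(
    records: Iterable[FragmentRecord],
    min_mapq: int = 10,
    require_full_length: bool = True,
) -> Iterator[FragmentRecord]:
    """Keep fragments with mapq > min_mapq (strict) and, if required, a
    full-length alignment (aligned_fraction == 1). Idempotent."""
    for rec in records:
        if rec.mapq <= min_mapq:
            continue
        if require_full_length and rec.aligned_fraction < 1.0:
            continue
        yield rec


def filter_fragment_table(
    table,
    min_mapq: int = 10,
    require_full_length: bool = True,
):
    """Vectorised counterpart of :func:`filter_fragments` for a DataFrame
    with mapq / aligned_fraction columns; identical retention predicate."""
    keep = table["mapq"] > min_mapq
    if require_full_length:
        keep &= table["aligned_fraction"] >= 1.0
    return table[keep].reset_index(drop=True)


def coverage_from_fragments(
    fragments: IntervalSet,
    genome: ChromSizes,
    resolution: int = 1,
    name: str = "coverage",
) -> SignalTrack:
    """Number of fragments overlapping each bp (or fixed-size bin).

    At resolution 1 the track conserves mass: its sum equals the summed
    fragment lengths. Fragments running off a chromosome end are clipped.
    At coarser resolutions a fragment increments every bin it touches.
    """
    import warnings

    values = {}
    by_chrom = fragments.by_chrom()
    for chrom in genome:
        L = genome[chrom]
        n = -(-L // resolution)
        diff = np.zeros(n + 1)
        if chrom in by_chrom:
            starts, ends = by_chrom[chrom]
            if np.any(ends > L) or np.any(starts < 0):
                warnings.warn(f"{chrom}: fragments beyond chromosome end clipped")
                starts = np.clip(starts, 0, L)
                ends = np.clip(ends, 0, L)
            keep = ends > starts
            starts, ends = starts[keep], ends[keep]
            lo = starts // resolution
            hi = (ends - 1) // resolution + 1  # last bin touched, exclusive
            np.add.at(diff, lo, 1)
            np.add.at(diff, hi, -1)
        values[chrom] = np.cumsum(diff[:-1])
    return SignalTrack(genome, values, resolution=resolution, name=name)
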