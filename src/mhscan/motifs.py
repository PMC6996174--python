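"""Positional bias of TF-binding motif occurrences around site centers.

Motif occurrences (from an external scanner) are mapped to offsets from
the midpoints of site regions; the positional profile at offset d is the
fraction of regions with at least one occurrence midpoint at d, within a
+-halfwidth (default 150 bp) window. A per-TF-family percentage-change
table contrasts common and specific site classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "MotifOccurrence",
    "PositionalProfile",
    "positional_profile",
    "smooth_profile",
    "family_percentage",
    "percentage_change_table",
]


@dataclass(frozen=True)
class MotifOccurrence:
    interval: GenomicInterval
    motif_id: str
    family: str = ""

    def __post_init__(self):
        if len(self.interval) < 1:
            raise ValueError("occurrence must span >= 1 bp")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class PositionalProfile:
    motif_id: str
    halfwidth: int
    probabilities: np.ndarray  # offsets -halfwidth..+halfwidth

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != 2 * self.halfwidth + 1:
            raise ValueError("profile length must be 2*halfwidth + 1")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "probability": self.probabilities})


def positional_profile(
    occurrences: Sequence[MotifOccurrence],
    centers: IntervalSet,
    halfwidth: int = 150,
    motif_id: str = "",
) -> PositionalProfile:
    """Per-bp probability of a motif at each offset from region midpoints.

    probability(d) = (#regions with >= 1 occurrence whose midpoint sits at
    offset d from the region midpoint) / (#regions). Each region counts at
    most once per offset, so values are proportions in [0, 1].
    """
    if len(centers) == 0:
        raise ValueError("need a nonempty center set")
    mids_by_chrom: Dict[str, np.ndarray] = centers.midpoints()
    order: Dict[str, np.ndarray] = {}
    region_index: Dict[str, np.ndarray] = {}
    offset0 = 0
    for chrom in sorted(mids_by_chrom):
        m = mids_by_chrom[chrom]
        region_index[chrom] = np.arange(offset0, offset0 + len(m))
        offset0 += len(m)

    hits = set()  # (region global index, offset)
    for occ in occurrences:
        chrom = occ.interval.chrom
        if chrom not in mids_by_chrom:
            continue
        cmids = mids_by_chrom[chrom]
        om = occ.midpoint
        lo = np.searchsorted(cmids, om - halfwidth, side="left")
        hi = np.searchsorted(cmids, om + halfwidth, side="right")
        for j in range(lo, hi):
            hits.add((int(region_index[chrom][j]), int(om - cmids[j])))
    probs = np.zeros(2 * halfwidth + 1)
    for _, d in hits:
        probs[d + halfwidth] += 1
    probs /= len(centers)
    return PositionalProfile(motif_id=motif_id, halfwidth=halfwidth, probabilities=probs)


def smooth_profile(profile: PositionalProfile, window: int = 11) -> np.ndarray:
    """Moving-average smoothing for display; stored profiles stay raw."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    kernel = np.ones(window) / window
    padded = np.pad(profile.probabilities, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def family_percentage(
    regions: IntervalSet,
    occurrences: Sequence[MotifOccurrence],
) -> Dict[str, float]:
    """Percentage of regions containing >= 1 occurrence of each TF family.

    Membership is by occurrence-midpoint containment in the region.
    """
    if len(regions) == 0:
        raise ValueError("need a nonempty region set")
    by_chrom = regions.by_chrom()
    fam_hits: Dict[str, set] = {}
    idx_base: Dict[str, int] = {}
    max_span: Dict[str, int] = {}
    base = 0
    for chrom in sorted(by_chrom):
        starts, ends = by_chrom[chrom]
        idx_base[chrom] = base
        max_span[chrom] = int((ends - starts).max())
        base += len(starts)
    for occ in occurrences:
        chrom = occ.interval.chrom
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        om = occ.midpoint
        # candidates: start in (om - max_span, om]; check end > om for each
        k = int(np.searchsorted(starts, om, side="right")) - 1
        while k >= 0 and starts[k] > om - max_span[chrom]:
            if ends[k] > om:
                fam_hits.setdefault(occ.family, set()).add(idx_base[chrom] + k)
            k -= 1
    return {
        fam: 100.0 * len(members) / len(regions) for fam, members in sorted(fam_hits.items())
    }


def percentage_change_table(
    common: IntervalSet,
    specific: IntervalSet,
    occurrences: Sequence[MotifOccurrence],
) -> pd.DataFrame:
    """Per-family percentages in each class and their difference.

    percentage_change = pct(common) - pct(specific); positive values mark
    families enriched in common sites. Families with no occurrences are
    omitted with a warning. Antisymmetric under swapping the two classes.
    """
    families = sorted({o.family for o in occurrences})
    if not families:
        warnings.warn("no motif occurrences supplied; empty table")
    pc = family_percentage(common, occurrences) if occurrences else {}
    ps = family_percentage(specific, occurrences) if occurrences else {}
    rows = []
    for fam in families:
        in_c, in_s = pc.get(fam, 0.0), ps.get(fam, 0.0)
        rows.append(
            {
                "family": fam,
                "pct_common": in_c,
                "pct_specific": in_s,
                "percentage_change": in_c - in_s,
            }
        )
    df = pd.DataFrame(rows, columns=["family", "pct_common", "pct_specific", "percentage_change"])
    return df.sort_values("percentage_change", ascending=False).reset_index(drop=True)
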