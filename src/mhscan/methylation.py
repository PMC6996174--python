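"""Per-cytosine methylation calls and sliding-window methylated regions.

A cytosine is called methylated when its level strictly exceeds the
context threshold (CG > 0.60, CHG > 0.20, CHH > 0.05) at sufficient
depth. Methylated regions come from a window of five consecutive
same-context cytosines slid one cytosine at a time: windows with fewer
than four methylated cytosines are discarded, retained windows are
merged per context, and the three contexts are unioned into the final
region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "CONTEXTS",
    "MethThresholds",
    "CytosineCall",
    "call_cytosine",
    "call_cytosines",
    "MethWindow",
    "window_regions",
    "MethylatedRegion",
    "merge_windows",
    "merge_and_union",
    "call_methylated_regions",
    "region_level",
    "collapse_cg_strands",
]

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class MethThresholds:
    """Strict lower bounds on per-context methylation level."""

    cg: float = 0.60
    chg: float = 0.20
    chh: float = 0.05
    strict: bool = True  # level must exceed (not just reach) the bound

    def __post_init__(self):
        for v in (self.cg, self.chg, self.chh):
            if not (0.0 < v < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")

    def for_context(self, context: str) -> float:
        return {"CG": self.cg, "CHG": self.chg, "CHH": self.chh}[context]


class CytosineCall(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    NO_CALL = "no_call"


def call_cytosine(
    count_methylated: int,
    count_total: int,
    context: str,
    thresholds: MethThresholds = MethThresholds(),
    min_depth: int = 4,
) -> CytosineCall:
    """Call one cytosine from its read counts."""
    if not (0 <= count_methylated <= count_total):
        raise ValueError("need 0 <= count_methylated <= count_total")
    if count_total < min_depth or count_total == 0:
        return CytosineCall.NO_CALL
    level = count_methylated / count_total
    bound = thresholds.for_context(context)
    hit = level > bound if thresholds.strict else level >= bound
    return CytosineCall.METHYLATED if hit else CytosineCall.UNMETHYLATED


def call_cytosines(
    df: pd.DataFrame,
    thresholds: MethThresholds = MethThresholds(),
    min_depth: int = 4,
) -> pd.DataFrame:
    """Vectorised per-cytosine calls over a CX table.

    Adds ``level`` and ``call`` columns; rows below ``min_depth`` are
    no_call and excluded from window calling downstream.
    """
    out = df.copy()
    total = out["count_total"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(total > 0, out["count_methylated"].to_numpy() / np.maximum(total, 1), np.nan)
    out["level"] = level
    bounds = out["context"].map(thresholds.for_context).to_numpy()
    if thresholds.strict:
        meth = level > bounds
    else:
        meth = level >= bounds
    call = np.where(
        (total < min_depth) | (total == 0),
        CytosineCall.NO_CALL.value,
        np.where(meth, CytosineCall.METHYLATED.value, CytosineCall.UNMETHYLATED.value),
    )
    out["call"] = call
    return out


@dataclass(frozen=True)
class MethWindow:
    chrom: str
    start: int  # first cytosine position
    end: int  # last cytosine position + 1 (half-open)
    context: str
    n_methylated: int
    mean_level: float
    n_cytosines: int


def window_regions(
    called: pd.DataFrame,
    window_n: int = 5,
    min_methylated: int = 4,
) -> List[MethWindow]:
    """Slide a ``window_n``-cytosine window (step: one cytosine) per
    chromosome and context over callable sites; retain windows with at
    least ``min_methylated`` methylated cytosines.

    ``called`` must carry the columns added by :func:`call_cytosines`;
    no_call sites are excluded before sliding. The window's genomic
    extent runs from its first to one past its last cytosine. The mean
    methylation level is recorded as an annotation, not a filter.
    """
    usable = called[called["call"] != CytosineCall.NO_CALL.value]
    windows: List[MethWindow] = []
    for (chrom, context), grp in usable.groupby(["chrom", "context"], sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        meth = (grp["call"] == CytosineCall.METHYLATED.value).to_numpy().astype(int)
        lvl = grp["level"].to_numpy()
        n = len(pos)
        if n < window_n:
            continue
        meth_run = np.convolve(meth, np.ones(window_n, dtype=int), mode="valid")
        lvl_run = np.convolve(lvl, np.ones(window_n), mode="valid") / window_n
        for i in np.nonzero(meth_run >= min_methylated)[0]:
            windows.append(
                MethWindow(
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[i + window_n - 1]) + 1,
                    context=context,
                    n_methylated=int(meth_run[i]),
                    mean_level=float(lvl_run[i]),
                    n_cytosines=window_n,
                )
            )
    return windows


@dataclass(frozen=True)
class MethylatedRegion:
    interval: GenomicInterval
    context: str  # "CG", "CHG", "CHH", or a '+'-joined union label
    mean_level: float
    n_cytosines: int


def merge_windows(windows: Sequence[MethWindow]) -> List[MethylatedRegion]:
    """Merge overlapping/adjacent retained windows within each context.

    The merged region's mean level is the cytosine-count-weighted mean of
    its windows (each window weighted by its cytosine count).
    """
    regions: List[MethylatedRegion] = []
    by_key: Dict[Tuple[str, str], List[MethWindow]] = {}
    for w in windows:
        by_key.setdefault((w.chrom, w.context), []).append(w)
    for (chrom, context), ws in sorted(by_key.items()):
        ws = sorted(ws, key=lambda w: (w.start, w.end))
        cur_start, cur_end = ws[0].start, ws[0].end
        cur_w, cur_lvl = ws[0].n_cytosines, ws[0].mean_level * ws[0].n_cytosines
        for w in ws[1:]:
            if w.start <= cur_end:  # overlapping or touching
                cur_end = max(cur_end, w.end)
                cur_w += w.n_cytosines
                cur_lvl += w.mean_level * w.n_cytosines
            else:
                regions.append(
                    MethylatedRegion(
                        GenomicInterval(chrom, cur_start, cur_end), context,
                        cur_lvl / cur_w, cur_w,
                    )
                )
                cur_start, cur_end = w.start, w.end
                cur_w, cur_lvl = w.n_cytosines, w.mean_level * w.n_cytosines
        regions.append(
            MethylatedRegion(
                GenomicInterval(chrom, cur_start, cur_end), context, cur_lvl / cur_w, cur_w
            )
        )
    return regions


def merge_and_union(windows: Sequence[MethWindow]) -> List[MethylatedRegion]:
    """Per-context merging followed by interval union across contexts.

    Union regions are labelled with the '+'-joined contexts that
    contributed (e.g. "CG+CHH"); levels are cytosine-count-weighted.
    """
    per_context = merge_windows(windows)
    by_chrom: Dict[str, List[MethylatedRegion]] = {}
    for r in per_context:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    out: List[MethylatedRegion] = []
    for chrom in sorted(by_chrom):
        regs = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cur = [regs[0]]
        cur_start, cur_end = regs[0].interval.start, regs[0].interval.end
        for r in regs[1:]:
            if r.interval.start <= cur_end:
                cur_end = max(cur_end, r.interval.end)
                cur.append(r)
            else:
                out.append(_union_region(chrom, cur_start, cur_end, cur))
                cur = [r]
                cur_start, cur_end = r.interval.start, r.interval.end
        out.append(_union_region(chrom, cur_start, cur_end, cur))
    return out


def _union_region(chrom, start, end, members: List[MethylatedRegion]) -> MethylatedRegion:
    contexts = sorted({m.context for m in members}, key=CONTEXTS.index)
    n = sum(m.n_cytosines for m in members)
    lvl = sum(m.mean_level * m.n_cytosines for m in members) / n
    return MethylatedRegion(GenomicInterval(chrom, start, end), "+".join(contexts), lvl, n)


def call_methylated_regions(
    cx: pd.DataFrame,
    thresholds: MethThresholds = MethThresholds(),
    min_depth: int = 4,
    window_n: int = 5,
    min_methylated: int = 4,
) -> List[MethylatedRegion]:
    """End-to-end: per-cytosine calls -> sliding windows -> merged union set."""
    called = call_cytosines(cx, thresholds=thresholds, min_depth=min_depth)
    windows = window_regions(called, window_n=window_n, min_methylated=min_methylated)
    return merge_and_union(windows)


def region_level(
    region: GenomicInterval,
    cx: pd.DataFrame,
    context: Optional[str] = None,
) -> Optional[float]:
    """Read-count-weighted mean methylation of cytosines inside a region.

    Returns None when no covered cytosine (of the requested context)
    falls inside the region.
    """
    sel = (
        (cx["chrom"] == region.chrom)
        & (cx["pos"] >= region.start)
        & (cx["pos"] < region.end)
        & (cx["count_total"] > 0)
    )
    if context is not None:
        sel &= cx["context"] == context
    sub = cx[sel]
    if sub.empty:
        return None
    return float(sub["count_methylated"].sum() / sub["count_total"].sum())


def methylation_level_track(
    cx: pd.DataFrame,
    genome,
    resolution: int = 50,
    context: Optional[str] = None,
):
    """Binned methylation-level signal track (read-count-weighted per bin).

    Bins without covered cytosines carry 0. Feeds the same profile and
    clustering machinery as any other epigenomic track.
    """
    import numpy as np

    from .intervals import SignalTrack

    sub = cx if context is None else cx[cx["context"] == context]
    values = {}
    for chrom in genome:
        n = -(-genome[chrom] // resolution)
        meth = np.zeros(n)
        total = np.zeros(n)
        g = sub[sub["chrom"] == chrom]
        if len(g):
            bins = g["pos"].to_numpy() // resolution
            np.add.at(meth, bins, g["count_methylated"].to_numpy())
            np.add.at(total, bins, g["count_total"].to_numpy())
        with np.errstate(invalid="ignore"):
            values[chrom] = np.where(total > 0, meth / np.maximum(total, 1), 0.0)
    return SignalTrack(genome, values, resolution=resolution,
                       name=f"meth_{context or 'all'}")


def collapse_cg_strands(cx: pd.DataFrame) -> pd.DataFrame:
    """Optionally pool symmetric CG counts from the two strands.

    A minus-strand CG at position p is pooled onto the plus-strand CG at
    p-1; other contexts pass through unchanged. Makes calls strand
    invariant for the symmetric CG context.
    """
    cg = cx[cx["context"] == "CG"].copy()
    rest = cx[cx["context"] != "CG"]
    minus = cg["strand"] == "-"
    cg.loc[minus, "pos"] = cg.loc[minus, "pos"] - 1
    cg["strand"] = "+"
    pooled = (
        cg.groupby(["chrom", "pos", "strand", "context"], as_index=False)[
            ["count_methylated", "count_unmethylated"]
        ].sum()
    )
    pooled["count_total"] = pooled["count_methylated"] + pooled["count_unmethylated"]
    out = pd.concat([pooled, rest], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
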