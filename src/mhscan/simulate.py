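"""Seeded synthetic data emulating every input of the pipeline.

The generator plants two classes of open-chromatin sites on a small
genome — wide "common" sites (mean 262 bp, two fragment summits, phased
flanking nucleosomes) and narrow "specific" sites (mean 85 bp, one
central summit) — and draws 20–100 bp sub-nucleosomal fragments whose
midpoint density inside sites is ``enrichment_fold`` times the mappable
background. A fraction ``zip_pi`` of the genome is unmappable in 1-kb
blocks, producing the window-level zero inflation the caller models.
Histone-mark tracks follow five chromatin-class templates (repressive
H3K27me3; methylated flanks; two asymmetric active classes; quiescent),
with class frequencies differing between site classes so that specific
sites are biased toward the repressive classes. The methylome plants
per-context methylated blocks above the calling thresholds on a
sub-threshold background, with binomial read counts at fixed depth.

Everything is deterministic per seed (NumPy PCG64 generator).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet, SignalTrack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_sites",
    "simulate_fragments",
    "simulate_marks",
    "simulate_methylome",
    "simulate_all",
    "SimResult",
]

MARK_NAMES = ("H3K27me3", "H3K27ac", "H2A.Z", "nucleosome")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the biology the toolkit targets: mean site widths of
    262 bp (common) and 85 bp (specific); fragments of 20–100 bp; an
    enrichment fold chosen so that roughly 60% of fragments fall inside
    planted sites, the fraction-of-reads-in-peaks of a good library;
    chromatin-class frequencies of 26/18/9/9/38% for specific sites and
    6/5/30/29/30% for common ones.
    """

    seed: int = 0
    genome: Tuple[Tuple[str, int], ...] = (("chr1", 5_000_000),)
    n_common_sites: int = 250
    n_specific_sites: int = 250
    common_width_mean: float = 262.0
    common_width_sd: float = 40.0
    specific_width_mean: float = 85.0
    specific_width_sd: float = 12.0
    min_width: int = 40
    min_gap: int = 2000
    n_fragments: int = 1_000_000
    frag_len_range: Tuple[int, int] = (20, 100)
    enrichment_fold: float = 80.0
    zip_pi: float = 0.30
    unmappable_block: int = 1000
    common_summits: int = 2
    specific_summits: int = 1
    low_mapq_fraction: float = 0.05
    clipped_fraction: float = 0.02
    # histone-mark tracks
    mark_resolution: int = 10
    mark_background: float = 0.10
    mark_noise_sd: float = 0.05
    mark_amplitude: float = 1.0
    specific_class_probs: Tuple[float, ...] = (0.26, 0.18, 0.09, 0.09, 0.38)
    common_class_probs: Tuple[float, ...] = (0.06, 0.05, 0.30, 0.29, 0.30)
    nucleosome_period: int = 180
    # methylome
    cytosine_spacing: float = 8.0
    context_probs: Tuple[float, float, float] = (0.35, 0.25, 0.40)  # CG, CHG, CHH
    meth_depth: int = 20
    block_levels: Tuple[float, float, float] = (0.90, 0.60, 0.30)
    background_levels: Tuple[float, float, float] = (0.05, 0.04, 0.01)
    n_meth_blocks: int = 100
    meth_block_len_mean: float = 300.0

    def __post_init__(self):
        lo, hi = self.frag_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid frag_len_range")
        if min(dict(self.genome).values()) < hi:
            raise ValueError("fragments longer than the shortest chromosome")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must be > 1")
        for probs in (self.specific_class_probs, self.common_class_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("class probabilities must sum to 1")

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(dict(self.genome))

    def rng(self, stream: int = 0) -> np.random.Generator:
        # independent deterministic streams per simulation stage
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream module."""

    sites: pd.DataFrame  # chrom,start,end,site_class,mark_class,summits(json list)
    mappable: Dict[str, List[Tuple[int, int]]]  # per-chrom mappable intervals
    meth_blocks: pd.DataFrame  # chrom,start,end

    def site_interval_set(self, genome: ChromSizes, which: Optional[str] = None) -> IntervalSet:
        df = self.sites if which is None else self.sites[self.sites["site_class"] == which]
        return IntervalSet.from_arrays(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            label=np.array(
                [f"{c}_{i}" for i, c in zip(df.index, df["site_class"])], dtype=object
            ),
            name=which or "planted_sites",
            genome=genome,
        )

    def mappable_bp(self) -> int:
        return sum(e - s for ivs in self.mappable.values() for s, e in ivs)

    def write(self, prefix: Path) -> None:
        prefix = Path(prefix)
        df = self.sites.copy()
        df["name"] = [
            f"{c}.mark{m}" for c, m in zip(df["site_class"], df["mark_class"])
        ]
        df[["chrom", "start", "end", "name"]].to_csv(
            prefix.with_suffix(".sites.bed"), sep="\t", header=False, index=False
        )
        self.meth_blocks.to_csv(
            prefix.with_suffix(".meth_blocks.tsv"), sep="\t", index=False
        )


def simulate_sites(cfg: SimConfig) -> GroundTruth:
    """Plant non-overlapping open sites with >= min_gap bp between them."""
    rng = cfg.rng(1)
    genome = dict(cfg.genome)
    total_bp = sum(genome.values())
    n_total = cfg.n_common_sites + cfg.n_specific_sites

    # allocate sites to chromosomes proportional to length
    chroms = list(genome)
    alloc = rng.multinomial(n_total, [genome[c] / total_bp for c in chroms]) if n_total else []
    classes = np.array(
        ["common"] * cfg.n_common_sites + ["specific"] * cfg.n_specific_sites, dtype=object
    )
    classes = classes[rng.permutation(n_total)] if n_total else classes

    rows = []
    ci = 0
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        sub_classes = classes[ci : ci + n]
        ci += n
        widths = np.empty(n, dtype=np.int64)
        for j, cl in enumerate(sub_classes):
            mu, sd = (
                (cfg.common_width_mean, cfg.common_width_sd)
                if cl == "common"
                else (cfg.specific_width_mean, cfg.specific_width_sd)
            )
            widths[j] = max(cfg.min_width, int(round(rng.normal(mu, sd))))
        L = genome[chrom]
        slack = L - int(widths.sum()) - (n + 1) * cfg.min_gap
        if slack < 0:
            raise ValueError(f"{chrom}: too many/too wide sites for chromosome length")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = cfg.min_gap + extra[0]
        for j in range(n):
            start, end = pos, pos + int(widths[j])
            cl = sub_classes[j]
            n_summits = cfg.common_summits if cl == "common" else cfg.specific_summits
            w = end - start
            if n_summits == 1:
                summits = [int(start + w // 2)]
            else:
                offs = np.linspace(0.25, 0.75, n_summits)
                summits = [int(start + round(o * w)) for o in offs]
            probs = (
                cfg.common_class_probs if cl == "common" else cfg.specific_class_probs
            )
            mark_class = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "site_class": cl,
                    "mark_class": mark_class,
                    "summits": json.dumps(summits),
                }
            )
            pos = end + cfg.min_gap + int(extra[j + 1])
    sites = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "site_class", "mark_class", "summits"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    mappable = _draw_mappability(cfg, sites, rng)
    meth_blocks = _draw_meth_blocks(cfg, sites, mappable, rng)
    return GroundTruth(sites=sites, mappable=mappable, meth_blocks=meth_blocks)


def _draw_mappability(cfg, sites, rng) -> Dict[str, List[Tuple[int, int]]]:
    """Remove zip_pi of each chromosome in fixed-size blocks that avoid
    planted sites (open sites are mappable by construction)."""
    genome = dict(cfg.genome)
    out: Dict[str, List[Tuple[int, int]]] = {}
    B = cfg.unmappable_block
    margin = 500
    for chrom, L in genome.items():
        n_blocks = L // B
        block_ok = np.ones(n_blocks, dtype=bool)
        for _, row in sites[sites["chrom"] == chrom].iterrows():
            lo = max(0, (row["start"] - margin) // B)
            hi = min(n_blocks - 1, (row["end"] + margin) // B)
            block_ok[lo : hi + 1] = False
        candidates = np.nonzero(block_ok)[0]
        n_drop = min(len(candidates), int(round(cfg.zip_pi * n_blocks)))
        drop = set(rng.choice(candidates, size=n_drop, replace=False).tolist())
        # complement of dropped blocks, merged into mappable intervals
        ivs: List[Tuple[int, int]] = []
        pos = 0
        for b in sorted(drop):
            if b * B > pos:
                ivs.append((pos, b * B))
            pos = (b + 1) * B
        if pos < L:
            ivs.append((pos, L))
        out[chrom] = ivs
    return out


def _draw_meth_blocks(cfg, sites, mappable, rng) -> pd.DataFrame:
    """Methylated blocks: flanks of mark-class-2 sites plus random
    intergenic blocks well away from any planted site."""
    rows = []
    genome = dict(cfg.genome)
    flank = 400
    for _, row in sites[sites["mark_class"] == 2].iterrows():
        L = genome[row["chrom"]]
        rows.append(
            {"chrom": row["chrom"], "start": max(0, row["start"] - flank), "end": row["start"]}
        )
        rows.append(
            {"chrom": row["chrom"], "start": row["end"], "end": min(L, row["end"] + flank)}
        )
    # random background blocks, placed in the middle of inter-site gaps
    for chrom, L in genome.items():
        chrom_sites = sites[sites["chrom"] == chrom]
        edges = [0] + list(chrom_sites["end"]) + [L]
        starts = [0] + list(chrom_sites["start"]) + [L]
        n_extra = cfg.n_meth_blocks // max(len(genome), 1)
        gaps = [
            (e, s) for e, s in zip(edges[:-1], starts[1:]) if s - e > 3 * cfg.min_gap
        ]
        if not gaps:
            continue
        for _ in range(n_extra):
            g = gaps[rng.integers(len(gaps))]
            blen = max(50, int(rng.exponential(cfg.meth_block_len_mean)))
            lo = g[0] + cfg.min_gap
            hi = g[1] - cfg.min_gap - blen
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            rows.append({"chrom": chrom, "start": start, "end": start + blen})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_fragments(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Draw fragments as a table (chrom, start, end, mapq, aligned_fraction).

    Midpoints are a mixture of uniform placement over the mappable genome
    and within-site placement at ``enrichment_fold`` times the background
    density; within a site the density is triangular around each summit.
    Lengths are uniform over ``frag_len_range``.
    """
    rng = cfg.rng(2)
    if cfg.n_fragments == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mapq", "aligned_fraction"]
        )
    sites = truth.sites
    site_w = (sites["end"] - sites["start"]).to_numpy()
    weights = np.concatenate(([float(truth.mappable_bp())], cfg.enrichment_fold * site_w))
    weights /= weights.sum()
    alloc = rng.multinomial(cfg.n_fragments, weights)

    mids_parts: List[np.ndarray] = []
    chrom_parts: List[np.ndarray] = []

    # background: uniform over mappable intervals
    n_bg = alloc[0]
    flat: List[Tuple[str, int, int]] = [
        (chrom, s, e) for chrom, ivs in truth.mappable.items() for s, e in ivs
    ]
    lens = np.array([e - s for _, s, e in flat], dtype=float)
    cum = np.cumsum(lens / lens.sum())
    u = rng.random(n_bg)
    which = np.searchsorted(cum, u, side="right")
    offs = rng.random(n_bg)
    for i, (chrom, s, e) in enumerate(flat):
        sel = which == i
        k = int(sel.sum())
        if k == 0:
            continue
        mids_parts.append((s + offs[sel] * (e - s)).astype(np.int64))
        chrom_parts.append(np.full(k, chrom, dtype=object))

    # sites: triangular humps around summits
    for i, (_, row) in enumerate(sites.iterrows()):
        k = int(alloc[i + 1])
        if k == 0:
            continue
        summits = json.loads(row["summits"])
        w = row["end"] - row["start"]
        half = max(8, w // (2 * len(summits)))
        pick = rng.integers(len(summits), size=k)
        m = np.empty(k)
        for j, smt in enumerate(summits):
            sel = pick == j
            kk = int(sel.sum())
            if kk == 0:
                continue
            m[sel] = rng.triangular(smt - half, smt, smt + half, size=kk)
        mids_parts.append(np.clip(np.round(m), row["start"], row["end"] - 1).astype(np.int64))
        chrom_parts.append(np.full(k, row["chrom"], dtype=object))

    mids = np.concatenate(mids_parts)
    chroms = np.concatenate(chrom_parts)
    n = len(mids)
    lo, hi = cfg.frag_len_range
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = mids - lengths // 2
    ends = starts + lengths
    # clip to chromosome bounds, preserving length where possible
    genome = dict(cfg.genome)
    chrom_len = np.array([genome[c] for c in chroms], dtype=np.int64)
    shift = np.maximum(0, -starts) - np.maximum(0, ends - chrom_len)
    starts = starts + shift
    ends = ends + shift

    mapq = rng.integers(20, 43, size=n)
    low = rng.random(n) < cfg.low_mapq_fraction
    mapq[low] = rng.integers(0, 11, size=int(low.sum()))
    aligned = np.ones(n)
    clipped = rng.random(n) < cfg.clipped_fraction
    aligned[clipped] = rng.uniform(0.5, 0.99, size=int(clipped.sum()))

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "mapq": mapq,
            "aligned_fraction": aligned,
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def fragments_to_interval_set(df: pd.DataFrame, genome: ChromSizes, name: str = "fragments") -> IntervalSet:
    return IntervalSet.from_arrays(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        name=name,
        genome=genome,
    )


# chromatin-class templates: amplitude multipliers per mark, plus shape flags
# classes: 1 repressive (H3K27me3), 2 methylated flanks, 3/4 asymmetric active
# (H3K27ac + H2A.Z, left/right), 5 quiescent
_CLASS_TEMPLATES = {
    1: {"H3K27me3": 1.0, "H3K27ac": 0.05, "H2A.Z": 0.15, "shape": "broad"},
    2: {"H3K27me3": 0.25, "H3K27ac": 0.05, "H2A.Z": 0.10, "shape": "flanks"},
    3: {"H3K27me3": 0.03, "H3K27ac": 1.0, "H2A.Z": 0.9, "shape": "left"},
    4: {"H3K27me3": 0.03, "H3K27ac": 1.0, "H2A.Z": 0.9, "shape": "right"},
    5: {"H3K27me3": 0.05, "H3K27ac": 0.15, "H2A.Z": 0.25, "shape": "broad"},
}


def simulate_marks(
    cfg: SimConfig, truth: GroundTruth, noise: Optional[float] = None
) -> Dict[str, SignalTrack]:
    """Histone-mark and nucleosome-occupancy tracks from class templates.

    With ``noise=0`` the tracks are the exact deterministic templates.
    Common-site flanks get phased nucleosome peaks (cosine, period
    ``nucleosome_period``); specific-site flanks get unphased noise.
    """
    rng = cfg.rng(3)
    noise_sd = cfg.mark_noise_sd if noise is None else noise
    genome = cfg.chrom_sizes()
    r = cfg.mark_resolution
    amp = cfg.mark_amplitude
    vals = {
        name: {c: np.full(-(-genome[c] // r), cfg.mark_background) for c in genome}
        for name in MARK_NAMES
    }
    flank = 1000
    for _, row in truth.sites.iterrows():
        chrom, start, end = row["chrom"], row["start"], row["end"]
        mid = (start + end) // 2
        cls = _CLASS_TEMPLATES[int(row["mark_class"])]
        L = genome[chrom]
        lo, hi = max(0, mid - flank), min(L, mid + flank)
        blo, bhi = lo // r, -(-hi // r)
        x = (np.arange(blo, bhi) * r + r / 2 - mid) / flank  # -1..1 across window
        gauss = np.exp(-0.5 * (x / 0.45) ** 2)
        if cls["shape"] == "flanks":
            profile = np.exp(-0.5 * ((np.abs(x) - 0.45) / 0.18) ** 2)
        elif cls["shape"] == "left":
            profile = gauss * (1.0 + np.clip(-x, 0, None))
        elif cls["shape"] == "right":
            profile = gauss * (1.0 + np.clip(x, 0, None))
        else:
            profile = gauss
        for mark in ("H3K27me3", "H3K27ac", "H2A.Z"):
            weight = cls[mark]
            if cls["shape"] == "flanks" and mark == "H3K27me3":
                vals[mark][chrom][blo:bhi] += amp * weight * gauss
            else:
                vals[mark][chrom][blo:bhi] += amp * weight * profile
        # nucleosome occupancy: depleted over the site; phased flanks for
        # common sites only
        bp = np.arange(blo, bhi) * r + r / 2
        occ = np.full(len(bp), 0.5 * amp)
        inside = (bp >= start) & (bp < end)
        occ[inside] *= 0.1
        if row["site_class"] == "common":
            dist = np.where(bp < start, start - bp, bp - (end - 1))
            in_flank = ~inside & (dist > 0)
            phase = np.cos(2 * np.pi * dist / cfg.nucleosome_period)
            occ[in_flank] += 0.4 * amp * np.clip(phase[in_flank], 0, None) * np.exp(
                -dist[in_flank] / 900.0
            )
        vals["nucleosome"][chrom][blo:bhi] += occ
    if noise_sd > 0:
        for name in MARK_NAMES:
            for c in genome:
                v = vals[name][c]
                vals[name][c] = np.clip(v + rng.normal(0, noise_sd, size=len(v)), 0, None)
    return {
        name: SignalTrack(genome, vals[name], resolution=r, name=name) for name in MARK_NAMES
    }


def simulate_methylome(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-cytosine CX table with planted methylated blocks.

    Returns the same column layout as :func:`mhscan.io.read_cx_table`
    (0-based positions).
    """
    rng = cfg.rng(4)
    genome = dict(cfg.genome)
    rows = []
    blocks = truth.meth_blocks
    block_by_chrom = {
        c: list(zip(g["start"], g["end"])) for c, g in blocks.groupby("chrom")
    }
    ctx_levels_block = dict(zip(("CG", "CHG", "CHH"), cfg.block_levels))
    ctx_levels_bg = dict(zip(("CG", "CHG", "CHH"), cfg.background_levels))
    p_spacing = min(1.0, 1.0 / cfg.cytosine_spacing)
    for chrom, L in genome.items():
        # geometric inter-cytosine gaps give ~1 cytosine per `spacing` bp
        n_approx = int(L * p_spacing * 1.2) + 10
        gaps = rng.geometric(p_spacing, size=n_approx)
        pos = np.cumsum(gaps) - 1
        pos = pos[pos < L]
        contexts = rng.choice(np.array(["CG", "CHG", "CHH"]), size=len(pos), p=cfg.context_probs)
        strands = rng.choice(np.array(["+", "-"]), size=len(pos))
        in_block = np.zeros(len(pos), dtype=bool)
        for s, e in block_by_chrom.get(chrom, []):
            in_block |= (pos >= s) & (pos < e)
        levels = np.where(
            in_block,
            np.array([ctx_levels_block[c] for c in contexts]),
            np.array([ctx_levels_bg[c] for c in contexts]),
        )
        depth = np.full(len(pos), cfg.meth_depth)
        meth = rng.binomial(depth, levels) if cfg.meth_depth > 0 else np.zeros(len(pos), dtype=int)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strands,
                    "count_methylated": meth,
                    "count_unmethylated": depth - meth,
                    "context": contexts,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    df["count_total"] = df["count_methylated"] + df["count_unmethylated"]
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_other_assay_peaks(
    cfg: SimConfig, truth: GroundTruth, assay: str = "DHS", width_scale: float = 1.6
) -> IntervalSet:
    """Peak set of a nuclease-based assay that sees only the common sites.

    Common planted sites are recovered as wider peaks (open-chromatin
    peaks from DNase-seq are broader than MNase-fragment sites) with
    small positional jitter; specific sites are invisible to the assay —
    that is precisely what makes them specific.
    """
    rng = cfg.rng(10 + sum(ord(ch) for ch in assay) % 97)  # stable per assay name
    genome = cfg.chrom_sizes()
    rows = truth.sites[truth.sites["site_class"] == "common"]
    chroms, starts, ends = [], [], []
    for _, row in rows.iterrows():
        w = row["end"] - row["start"]
        extra = int(round((width_scale - 1.0) * w / 2))
        jitter = int(rng.integers(-20, 21))
        s = max(0, row["start"] - extra + jitter)
        e = min(genome[row["chrom"]], row["end"] + extra + jitter)
        chroms.append(row["chrom"]); starts.append(s); ends.append(e)
    return IntervalSet.from_arrays(
        np.array(chroms, dtype=object), np.array(starts), np.array(ends),
        name=assay, genome=genome,
    )


def simulate_genes(cfg: SimConfig, truth: GroundTruth, cognate_fraction: float = 0.7):
    """Gene models placed so a fraction of planted sites has a cognate
    gene starting within 1 kb; remaining genes fall in site-free gaps."""
    from .intervals import GeneModel

    rng = cfg.rng(20)
    genome = dict(cfg.genome)
    genes: List[GeneModel] = []
    gid = 0
    for _, row in truth.sites.iterrows():
        if rng.random() > cognate_fraction:
            continue
        L = genome[row["chrom"]]
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(800, 2500))
        gap = int(rng.integers(100, 900))
        if strand == "+":
            start = row["end"] + gap
            end = start + glen
        else:
            end = row["start"] - gap
            start = end - glen
        if start < 0 or end > L or end <= start:
            continue
        gid += 1
        genes.append(
            GeneModel(GenomicInterval(row["chrom"], start, end, strand), f"GENE{gid:05d}")
        )
    return genes


def simulate_tes(cfg: SimConfig, truth: GroundTruth, n_tes: int = 60) -> IntervalSet:
    """Transposable elements in the deserts between planted sites."""
    rng = cfg.rng(21)
    genome = dict(cfg.genome)
    chroms, starts, ends = [], [], []
    for chrom, L in genome.items():
        site_iv = truth.sites[truth.sites["chrom"] == chrom]
        occupied = list(zip(site_iv["start"], site_iv["end"]))
        for _ in range(n_tes // max(len(genome), 1)):
            tlen = int(rng.integers(200, 3000))
            pos = int(rng.integers(0, max(1, L - tlen)))
            if any(pos < e + 500 and pos + tlen > s - 500 for s, e in occupied):
                continue
            chroms.append(chrom); starts.append(pos); ends.append(pos + tlen)
    return IntervalSet.from_arrays(
        np.array(chroms, dtype=object), np.array(starts), np.array(ends),
        name="TE", genome=cfg.chrom_sizes(),
    )


COMMON_FAMILIES = ("WRKY", "bHLH", "NAC", "MYB", "TCP")
SPECIFIC_FAMILIES = ("MYB-related", "ZFHD", "Homeobox", "AP2EREBP")


def simulate_motif_occurrences(
    cfg: SimConfig,
    truth: GroundTruth,
    p_family: float = 0.5,
    specific_sigma: float = 12.0,
):
    """Motif occurrences with class-specific families and positioning.

    Common sites draw occurrences of the common families spread broadly
    across the site; specific sites draw the specific families tightly
    concentrated at the center (narrow sites centre their single
    binding footprint).
    """
    from .motifs import MotifOccurrence

    rng = cfg.rng(22)
    genome = dict(cfg.genome)
    occs = []
    for _, row in truth.sites.iterrows():
        mid = (row["start"] + row["end"]) // 2
        w = row["end"] - row["start"]
        L = genome[row["chrom"]]
        if row["site_class"] == "common":
            fams, spread = COMMON_FAMILIES, max(w / 4.0, 20.0)
        else:
            fams, spread = SPECIFIC_FAMILIES, specific_sigma
        for fam in fams:
            if rng.random() > p_family:
                continue
            pos = int(round(rng.normal(mid, spread)))
            mlen = int(rng.integers(6, 15))
            s = max(0, min(pos - mlen // 2, L - mlen))
            occs.append(
                MotifOccurrence(
                    GenomicInterval(row["chrom"], s, s + mlen),
                    motif_id=f"{fam}_m1", family=fam,
                )
            )
    return occs


def simulate_expression(
    cfg: SimConfig, genes, n_tissues: int = 79, specific_gene_ids: Optional[set] = None
) -> pd.DataFrame:
    """Gene-by-tissue expression: broadly expressed by default, tissue
    restricted for the given gene ids (cognates of repressive sites)."""
    rng = cfg.rng(23)
    specific_gene_ids = specific_gene_ids or set()
    rows = {}
    for g in genes:
        if g.gene_id in specific_gene_ids:
            x = np.zeros(n_tissues)
            on = rng.integers(1, 4)
            x[rng.choice(n_tissues, size=on, replace=False)] = rng.uniform(5, 50, size=on)
        else:
            x = rng.uniform(1, 20, size=n_tissues)
        rows[g.gene_id] = x
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"tissue_{i + 1}" for i in range(n_tissues)]
    )


@dataclass
class SimResult:
    config: SimConfig
    truth: GroundTruth
    fragments: pd.DataFrame
    marks: Dict[str, SignalTrack]
    methylome: pd.DataFrame
    other_assays: Dict[str, IntervalSet] = field(default_factory=dict)
    genes: list = field(default_factory=list)
    tes: Optional[IntervalSet] = None
    motif_occurrences: list = field(default_factory=list)

    def write(self, outdir) -> None:
        """Emit all standard-format files plus a JSON parameter manifest."""
        from . import io as mio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome = self.config.chrom_sizes()
        mio.write_chrom_sizes(genome, outdir / "genome.chrom.sizes")
        frag = self.fragments.copy()
        frag["name"] = "frag"
        frag["score"] = frag["mapq"]
        frag["strand"] = "."
        frag[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            outdir / "fragments.bed", sep="\t", header=False, index=False
        )
        frag[["chrom", "start", "end", "mapq", "aligned_fraction"]].to_csv(
            outdir / "fragments.tsv", sep="\t", index=False
        )
        self.truth.write(outdir / "truth")
        for name, track in self.marks.items():
            safe = name.replace(".", "").replace("/", "_")
            mio.write_bedgraph(track, outdir / f"mark.{safe}.bedgraph")
        mio.write_cx_table(self.methylome, outdir / "methylome.cx.tsv")
        for assay, peaks in self.other_assays.items():
            mio.write_bed(peaks, outdir / f"peaks.{assay.lower()}.bed")
        if self.genes:
            with open(outdir / "genes.gff3", "w") as fh:
                fh.write("##gff-version 3\n")
                for g in self.genes:
                    iv = g.interval
                    fh.write(
                        f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{iv.strand}\t.\tID={g.gene_id}\n"
                    )
        if self.tes is not None and len(self.tes):
            mio.write_bed(self.tes, outdir / "tes.bed")
        if self.motif_occurrences:
            with open(outdir / "motifs.bed", "w") as fh:
                for o in self.motif_occurrences:
                    iv = o.interval
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{o.motif_id}\t.\t.\t{o.family}\n"
                    )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"config": asdict(self.config)}, fh, indent=2, default=list)


def simulate_all(cfg: SimConfig, with_annotations: bool = True) -> SimResult:
    truth = simulate_sites(cfg)
    result = SimResult(
        config=cfg,
        truth=truth,
        fragments=simulate_fragments(cfg, truth),
        marks=simulate_marks(cfg, truth),
        methylome=simulate_methylome(cfg, truth),
    )
    if with_annotations:
        result.other_assays = {
            "DHS": simulate_other_assay_peaks(cfg, truth, "DHS", width_scale=1.6),
            "ATAC": simulate_other_assay_peaks(cfg, truth, "ATAC", width_scale=1.4),
        }
        result.genes = simulate_genes(cfg, truth)
        result.tes = simulate_tes(cfg, truth)
        result.motif_occurrences = simulate_motif_occurrences(cfg, truth)
    return result
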