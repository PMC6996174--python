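"""Per-cytosine calls and the sliding-window methylated-region caller."""

import numpy as np
import pandas as pd
import pytest

from mhscan.intervals import GenomicInterval
from mhscan.methylation import (
    CONTEXTS,
    CytosineCall,
    MethThresholds,
    call_cytosine,
    call_cytosines,
    call_methylated_regions,
    collapse_cg_strands,
    merge_and_union,
    merge_windows,
    region_level,
    window_regions,
)


def _cx(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_methylated",
                                     "count_unmethylated", "context"])
    df["count_total"] = df["count_methylated"] + df["count_unmethylated"]
    return df


def _cg_sites(levels, depth=10, chrom="chr1", spacing=10, context="CG"):
    rows = []
    for i, lvl in enumerate(levels):
        m = int(round(lvl * depth))
        rows.append((chrom, i * spacing, "+", m, depth - m, context))
    return _cx(rows)


class TestCytosineCall:
    def test_strictly_above_threshold_is_methylated(self):
        assert call_cytosine(61, 100, "CG") == CytosineCall.METHYLATED

    def test_exactly_at_threshold_is_unmethylated(self):
        assert call_cytosine(60, 100, "CG") == CytosineCall.UNMETHYLATED

    def test_zero_depth_is_no_call(self):
        assert call_cytosine(0, 0, "CG") == CytosineCall.NO_CALL

    @pytest.mark.parametrize("context,level,expected", [
        ("CHG", 0.21, CytosineCall.METHYLATED),
        ("CHG", 0.20, CytosineCall.UNMETHYLATED),
        ("CHH", 0.06, CytosineCall.METHYLATED),
        ("CHH", 0.05, CytosineCall.UNMETHYLATED),
    ])
    def test_context_thresholds(self, context, level, expected):
        assert call_cytosine(int(level * 100), 100, context) == expected

    def test_min_depth_boundary(self):
        assert call_cytosine(3, 3, "CG", min_depth=4) == CytosineCall.NO_CALL
        assert call_cytosine(4, 4, "CG", min_depth=4) == CytosineCall.METHYLATED

    def test_vectorised_calls_agree_with_scalar(self, rng):
        rows = []
        for i in range(300):
            total = int(rng.integers(0, 30))
            meth = int(rng.integers(0, total + 1)) if total else 0
            ctx = str(rng.choice(CONTEXTS))
            rows.append(("chr1", i * 3, "+", meth, total - meth, ctx))
        df = _cx(rows)
        called = call_cytosines(df)
        for row, got in zip(rows, called["call"]):
            assert got == call_cytosine(row[3], row[3] + row[4], row[5]).value


class TestWindowCaller:
    def test_worked_six_site_example(self):
        """Six CG sites at levels .9/.9/0/.9/.9/.9: both 5-site windows carry
        four methylated cytosines, are retained, and merge across sites 1-6."""
        df = _cg_sites([0.9, 0.9, 0.0, 0.9, 0.9, 0.9])
        called = call_cytosines(df)
        windows = window_regions(called)
        assert len(windows) == 2
        assert [w.n_methylated for w in windows] == [4, 4]
        regions = merge_and_union(windows)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 51)

    def test_three_of_five_discarded(self):
        df = _cg_sites([0.9, 0.9, 0.9, 0.0, 0.0])
        assert window_regions(call_cytosines(df)) == []

    def test_all_unmethylated_no_windows(self):
        df = _cg_sites([0.1] * 10)
        assert window_regions(call_cytosines(df)) == []

    def test_fewer_than_window_n_sites(self):
        df = _cg_sites([0.9] * 4)
        assert window_regions(call_cytosines(df)) == []

    def test_no_call_sites_are_excluded_before_sliding(self):
        # a zero-depth site between methylated sites must not break the run
        df = _cg_sites([0.9, 0.9, 0.9, 0.9, 0.9, 0.9])
        df.loc[2, ["count_methylated", "count_unmethylated", "count_total"]] = [0, 0, 0]
        windows = window_regions(call_cytosines(df))
        assert len(windows) == 1
        assert windows[0].n_methylated == 5

    def test_matches_exhaustive_oracle_random(self, rng):
        for _ in range(25):
            df = _random_methylome(rng, n=int(rng.integers(5, 120)))
            mine = _region_tuples(call_methylated_regions(df))
            assert mine == oracle_regions(df)


class TestMergeUnion:
    def test_overlapping_windows_merge(self):
        df = _cg_sites([0.9] * 8)
        regions = merge_and_union(window_regions(call_cytosines(df)))
        assert len(regions) == 1
        assert regions[0].context == "CG"

    def test_disjoint_contexts_labelled_by_origin(self):
        cg = _cg_sites([0.9] * 5, spacing=10)
        chh = _cg_sites([0.5] * 5, spacing=10, context="CHH")
        chh["pos"] += 10_000
        df = pd.concat([cg, chh], ignore_index=True)
        regions = merge_and_union(window_regions(call_cytosines(df)))
        assert [r.context for r in regions] == ["CG", "CHH"]

    def test_union_equals_bp_set_oracle(self, rng):
        df = _random_methylome(rng, n=150)
        regions = merge_and_union(window_regions(call_cytosines(df)))
        union_bp = set()
        for r in regions:
            union_bp |= set(range(r.interval.start, r.interval.end))
        per_ctx = merge_windows(window_regions(call_cytosines(df)))
        oracle_bp = set()
        for r in per_ctx:
            oracle_bp |= set(range(r.interval.start, r.interval.end))
        assert union_bp == oracle_bp

    def test_merging_idempotent(self, rng):
        df = _random_methylome(rng, n=100)
        windows = window_regions(call_cytosines(df))
        once = merge_windows(windows)
        spans = [(r.interval.chrom, r.interval.start, r.interval.end, r.context) for r in once]
        assert len(spans) == len(set(spans))
        for a, b in zip(spans, spans[1:]):
            if a[0] == b[0] and a[3] == b[3]:
                assert a[2] < b[1]  # non-overlapping after merge


class TestRegionLevel:
    def test_no_cytosines_is_none(self):
        df = _cg_sites([0.5] * 3)
        assert region_level(GenomicInterval("chr1", 500, 600), df) is None

    def test_single_cytosine_level(self):
        df = _cg_sites([0.7], depth=10)
        assert region_level(GenomicInterval("chr1", 0, 5), df) == pytest.approx(0.7)

    def test_weighted_mean_oracle(self, rng):
        df = _random_methylome(rng, n=80)
        region = GenomicInterval("chr1", 0, 10_000)
        lvl = region_level(region, df)
        sub = df[(df["pos"] < 10_000) & (df["count_total"] > 0)]
        if len(sub) == 0:
            assert lvl is None
        else:
            assert lvl == pytest.approx(
                sub["count_methylated"].sum() / sub["count_total"].sum()
            )


def test_cg_strand_collapse_pools_symmetric_sites():
    df = _cx([
        ("chr1", 100, "+", 6, 4, "CG"),
        ("chr1", 101, "-", 5, 5, "CG"),
        ("chr1", 200, "+", 1, 9, "CHH"),
    ])
    pooled = collapse_cg_strands(df)
    cg = pooled[pooled["context"] == "CG"]
    assert len(cg) == 1
    assert int(cg["count_methylated"].iloc[0]) == 11
    assert int(cg["count_total"].iloc[0]) == 20


# ---------------------------------------------------------------------------
# independent exhaustive oracle

def _region_tuples(regions):
    return sorted(
        (r.interval.chrom, r.interval.start, r.interval.end, r.context) for r in regions
    )


def _random_methylome(rng, n=100, chrom="chr1"):
    rows = []
    pos = 0
    for _ in range(n):
        pos += int(rng.integers(1, 60))
        total = int(rng.integers(0, 25))
        meth = int(rng.binomial(total, rng.choice([0.02, 0.3, 0.95]))) if total else 0
        ctx = str(rng.choice(CONTEXTS))
        rows.append((chrom, pos, "+", meth, total - meth, ctx))
    return _cx(rows)


def oracle_regions(df, thresholds=MethThresholds(), min_depth=4, window_n=5, min_meth=4):
    """Brute-force window enumeration, per-context merging and bp-level union."""
    bounds = {"CG": thresholds.cg, "CHG": thresholds.chg, "CHH": thresholds.chh}
    per_context_bp = {}
    for (chrom, ctx), grp in df.groupby(["chrom", "context"]):
        grp = grp.sort_values("pos")
        sites = [
            (int(r["pos"]), r["count_methylated"] / r["count_total"] > bounds[ctx])
            for _, r in grp.iterrows()
            if r["count_total"] >= min_depth
        ]
        for i in range(len(sites) - window_n + 1):
            chunk = sites[i : i + window_n]
            if sum(1 for _, m in chunk if m) >= min_meth:
                per_context_bp.setdefault((chrom, ctx), set()).update(
                    range(chunk[0][0], chunk[-1][0] + 1)
                )
    # union across contexts per chromosome, tracking contributing contexts
    out = []
    chroms = {c for c, _ in per_context_bp}
    for chrom in chroms:
        all_bp = set()
        for (c, ctx), bps in per_context_bp.items():
            if c == chrom:
                all_bp |= bps
        for start, end in _runs_from_bp(all_bp):
            ctxs = sorted(
                {
                    ctx
                    for (c, ctx), bps in per_context_bp.items()
                    if c == chrom and bps & set(range(start, end))
                },
                key=CONTEXTS.index,
            )
            out.append((chrom, start, end, "+".join(ctxs)))
    return sorted(out)


def _runs_from_bp(bps):
    if not bps:
        return []
    srt = sorted(bps)
    runs = []
    start = prev = srt[0]
    for p in srt[1:]:
        if p != prev + 1:
            runs.append((start, prev + 1))
            start = p
        prev = p
    runs.append((start, prev + 1))
    return runs
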