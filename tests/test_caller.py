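"""Window counting, MHS calling and sub-peak resolution."""

import numpy as np
import pytest

from mhscan.caller import (
    CallerConfig,
    EnrichmentPrior,
    MHSCall,
    ZIPModel,
    bayes_factors,
    call_mhs,
    call_peaks,
    call_subpeaks,
    count_windows,
    fit_zip_em,
    null_exceedance_prob,
)
from mhscan.intervals import ChromSizes, GenomicInterval, IntervalSet
from mhscan.caller import WindowGrid


def _frag_set(midpoints, genome, length=30):
    ivs = [
        GenomicInterval("chr1", max(0, m - length // 2), max(0, m - length // 2) + length)
        for m in midpoints
    ]
    return IntervalSet(ivs, genome=genome)


class TestCountWindows:
    genome = ChromSizes({"chr1": 1000})

    def test_empty(self):
        grid = count_windows(IntervalSet([], genome=self.genome), self.genome, 20, 10)
        assert grid.counts["chr1"].sum() == 0

    def test_midpoint_hits_exactly_covering_windows(self):
        grid = count_windows(_frag_set([25], self.genome), self.genome, 20, 10)
        hit = np.nonzero(grid.counts["chr1"])[0]
        # windows [10,30) and [20,40) cover bp 25; [0,20) does not
        np.testing.assert_array_equal(hit, [1, 2])

    def test_nonoverlapping_grid_conserves_and_matches_naive(self, rng):
        mids = rng.integers(0, 1000, size=10_000)
        genome = ChromSizes({"chr1": 1000})
        frags = _frag_set(mids, genome, length=2)
        grid = count_windows(frags, genome, window_size=50, step=50)
        actual_mids = np.concatenate(
            [(s + e) // 2 for s, e in frags.by_chrom().values()]
        )
        naive = np.zeros(len(grid.counts["chr1"]), dtype=int)
        for m in actual_mids:
            w = m // 50
            if w < len(naive):
                naive[w] += 1
        np.testing.assert_array_equal(grid.counts["chr1"], naive)
        assert grid.counts["chr1"].sum() == naive.sum()

    def test_short_chromosome_warns(self):
        tiny = ChromSizes({"chr1": 10})
        with pytest.warns(UserWarning, match="shorter than window"):
            grid = count_windows(IntervalSet([], genome=tiny), tiny, 20, 10)
        assert grid.n_windows("chr1") == 0


class TestCallMhs:
    def test_empty_grid_empty_calls(self):
        genome = ChromSizes({"chr1": 10})
        grid = WindowGrid(20, 10, genome, {"chr1": np.zeros(0, dtype=int)})
        bg = ZIPModel(pi=0.3, lam=2.0)
        prior = EnrichmentPrior.from_background(bg)
        assert call_mhs(grid, bg, prior, CallerConfig()) == []

    def test_single_planted_spike_gives_one_call(self):
        rng = np.random.default_rng(0)
        genome = ChromSizes({"chr1": 100_000})
        counts = rng.poisson(2.0, size=(100_000 - 20) // 10 + 1)
        counts[500:505] = 100  # 5 consecutive windows at 50x the mean
        grid = WindowGrid(20, 10, genome, {"chr1": counts})
        bg = fit_zip_em(counts[counts <= np.quantile(counts, 0.999)])
        prior = EnrichmentPrior.from_background(bg)
        calls = call_mhs(grid, bg, prior, CallerConfig())
        assert len(calls) == 1
        assert calls[0].interval.start == 5000
        assert calls[0].interval.end == 5060
        assert calls[0].max_bf >= CallerConfig().bf_cutoff

    def test_null_calibration_small(self):
        """On background-simulated counts the exceedance fraction matches
        the model tail within Monte-Carlo error."""
        bg = ZIPModel(pi=0.25, lam=1.8)
        prior = EnrichmentPrior.from_background(bg)
        cutoff = 10.0
        rng = np.random.default_rng(9)
        n = 300_000
        counts = np.where(rng.random(n) < bg.pi, 0, rng.poisson(bg.lam, size=n))
        p_hat = float((bayes_factors(counts, bg, prior) >= cutoff).mean())
        p_model = null_exceedance_prob(bg, prior, cutoff)
        se = max(np.sqrt(p_model * (1 - p_model) / n), 1e-12)
        assert abs(p_hat - p_model) <= 3 * se


class TestSubpeaks:
    cfg = CallerConfig()

    def _mhs(self, start, end):
        return MHSCall(GenomicInterval("chr1", start, end), max_bf=1e6, mean_count=50.0)

    def test_unimodal_single_subpeak_contains_summit(self, rng):
        bp = np.zeros(4000, dtype=int)
        center = 2000
        offsets = np.round(rng.triangular(-40, 0, 40, size=3000)).astype(int)
        np.add.at(bp, center + offsets, 1)
        bp += rng.poisson(0.05, size=4000)
        mhs = call_subpeaks(self._mhs(1900, 2100), bp, self.cfg)
        assert len(mhs.subpeaks) == 1
        sp = mhs.subpeaks[0]
        assert sp.interval.start <= center < sp.interval.end

    def test_bimodal_resolved_into_two(self, rng):
        bp = np.zeros(4000, dtype=int)
        # two 40-bp humps separated by a 60-bp valley at background level
        for c in (1950, 2050):
            offsets = np.round(rng.triangular(-20, 0, 20, size=1500)).astype(int)
            np.add.at(bp, c + offsets, 1)
        bp += rng.poisson(0.05, size=4000)
        mhs = call_subpeaks(self._mhs(1900, 2100), bp, self.cfg)
        assert len(mhs.subpeaks) == 2
        summits = sorted(sp.summit for sp in mhs.subpeaks)
        assert abs(summits[0] - 1950) <= 10 and abs(summits[1] - 2050) <= 10

    def test_subpeaks_nested_within_parent(self, rng):
        for trial in range(20):
            bp = rng.poisson(0.5, size=1000) + rng.poisson(
                rng.uniform(0, 8), size=1000
            ) * (rng.random(1000) < 0.1)
            start, end = sorted(rng.integers(100, 900, size=2))
            if end - start < 40:
                end = start + 40
            mhs = call_subpeaks(self._mhs(start, end), bp.astype(int), self.cfg)
            assert len(mhs.subpeaks) >= 1
            for sp in mhs.subpeaks:
                assert start <= sp.interval.start < sp.interval.end <= end

    def test_flat_zero_region_falls_back_to_whole_interval(self):
        bp = np.zeros(1000, dtype=int)
        mhs = call_subpeaks(self._mhs(400, 500), bp, self.cfg)
        assert len(mhs.subpeaks) == 1
        assert mhs.subpeaks[0].height == 0.0


class TestCallPeaksEndToEnd:
    def test_planted_recovery_small(self, small_sim, small_genome, small_fragments):
        from mhscan.annotate import overlaps_any

        res = call_peaks(small_fragments, small_genome)
        calls = res.to_interval_set(small_genome)
        truth = small_sim.truth.site_interval_set(small_genome)
        recall = overlaps_any(truth, calls).mean()
        precision = overlaps_any(calls, truth).mean()
        assert recall >= 0.95
        assert precision >= 0.9
        assert 0.0 < res.frip < 1.0

    def test_invariant_to_chrom_relabeling_and_order(self, rng):
        genome = ChromSizes({"chrA": 200_000})
        mids = np.concatenate(
            [rng.integers(0, 200_000, size=20_000), rng.integers(50_000, 50_200, size=2_000)]
        )
        ivs = [GenomicInterval("chrA", max(0, m - 15), max(0, m - 15) + 30) for m in mids]
        frags1 = IntervalSet(ivs, genome=genome)
        # shuffled input order
        order = rng.permutation(len(ivs))
        frags2 = IntervalSet([ivs[i] for i in order], genome=genome)
        res1 = call_peaks(frags1, genome)
        res2 = call_peaks(frags2, genome)
        spans1 = [(c.interval.start, c.interval.end) for c in res1.calls]
        spans2 = [(c.interval.start, c.interval.end) for c in res2.calls]
        assert spans1 == spans2
        # relabelled chromosome: identical spans under the new name
        genome_b = ChromSizes({"chrB": 200_000})
        ivs_b = [GenomicInterval("chrB", iv.start, iv.end) for iv in ivs]
        res3 = call_peaks(IntervalSet(ivs_b, genome=genome_b), genome_b)
        assert [(c.interval.start, c.interval.end) for c in res3.calls] == spans1

    def test_output_sidecar_and_bed_shapes(self, small_genome, small_fragments, tmp_path):
        res = call_peaks(small_fragments, small_genome)
        bed = res.to_interval_set(small_genome)
        assert all(iv.label.startswith("MHS_") for iv in bed)
        assert all(0 <= iv.score <= 1000 for iv in bed)
        sub = res.subpeak_interval_set(small_genome)
        assert len(sub) >= len(bed)  # every MHS keeps >= 1 sub-peak
        res.write_json_sidecar(tmp_path / "s.json")
        import json

        doc = json.loads((tmp_path / "s.json").read_text())
        assert {"background", "prior", "config", "n_mhs", "frip"} <= set(doc)
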