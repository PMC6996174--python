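"""Interval algebra: overlap rates, site classes, categories, quantification."""

import numpy as np
import pytest

from mhscan.annotate import (
    FeatureCategory,
    assign_cognate_gene,
    categorize,
    chromosome_distribution,
    classify_specific,
    overlap_matrix,
    overlap_rate,
    overlaps_any,
    peak_level_rpm,
    rank_correlation,
    shannon_entropy,
)
from mhscan.intervals import ChromSizes, GeneModel, GenomicInterval, IntervalSet, SignalTrack

GENOME = ChromSizes({"chr1": 100_000})


def _set(spans, chrom="chr1", genome=GENOME):
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in spans], genome=genome)


def _random_set(rng, n, genome=GENOME, max_len=400):
    spans = []
    for _ in range(n):
        s = int(rng.integers(0, genome["chr1"] - max_len))
        spans.append((s, s + int(rng.integers(1, max_len))))
    return _set(spans)


class TestOverlapRate:
    def test_self_overlap_is_100(self, rng):
        a = _random_set(rng, 50)
        assert overlap_rate(a, a) == 100.0

    def test_manual_asymmetric_example(self):
        a = _set([(0, 100), (200, 300)])
        b = _set([(50, 60)])
        assert overlap_rate(a, b) == 50.0
        assert overlap_rate(b, a) == 100.0

    def test_disjoint_is_zero_and_empty_raises(self):
        a = _set([(0, 10)])
        b = _set([(20, 30)])
        assert overlap_rate(a, b) == 0.0
        with pytest.raises(ValueError):
            overlap_rate(_set([]), a)

    def test_matches_bruteforce_on_random_sets(self, rng):
        a = _random_set(rng, 1000)
        b = _random_set(rng, 300)
        hits = overlaps_any(a, b)
        brute = np.array(
            [any(iv.overlaps(other) for other in b) for iv in a]
        )
        np.testing.assert_array_equal(hits, brute)

    def test_translation_invariance(self, rng):
        a = _random_set(rng, 100)
        b = _random_set(rng, 100)
        shift = 1234
        a2 = _set([(iv.start + shift, iv.end + shift) for iv in a])
        b2 = _set([(iv.start + shift, iv.end + shift) for iv in b])
        assert overlap_rate(a, b) == overlap_rate(a2, b2)

    def test_matrix_diagonal_and_shape(self, rng):
        sets = {"A": _random_set(rng, 40), "B": _random_set(rng, 60)}
        mat = overlap_matrix(sets)
        assert mat.loc["A", "A"] == 100.0 and mat.loc["B", "B"] == 100.0
        assert mat.shape == (2, 2)


class TestClassifySpecific:
    def test_definitional_cases(self):
        mhs = _set([(100, 200), (5000, 5100)])
        dhs = _set([(150, 400)])
        labels = classify_specific(mhs, [dhs])
        assert labels == ["cMHS", "sMHS"]

    def test_bruteforce_oracle_random(self, rng):
        mhs = _random_set(rng, 1000)
        others = [_random_set(rng, 200), _random_set(rng, 150)]
        labels = classify_specific(mhs, others)
        for iv, lab in zip(mhs, labels):
            covered = any(
                iv.overlaps(o) for other in others for o in other
            )
            assert lab == ("cMHS" if covered else "sMHS")

    def test_track_demotion_only_removes_common(self, rng):
        mhs = _random_set(rng, 200)
        others = [_random_set(rng, 100)]
        base = classify_specific(mhs, others)
        vals = rng.uniform(0, 1, size=100_000)
        track = SignalTrack(GENOME, {"chr1": vals}, resolution=1)
        with_tracks = classify_specific(mhs, others, tracks=[track], coverage_quantile=0.9)
        for b, t in zip(base, with_tracks):
            if b == "sMHS":
                assert t == "sMHS"  # demotion never creates cMHS
        assert set(base) <= {"sMHS", "cMHS"}


class TestCategorize:
    genes = [
        GeneModel(GenomicInterval("chr1", 10_000, 12_000, "+"), "g1"),
        GeneModel(GenomicInterval("chr1", 50_000, 53_000, "-"), "g2"),
    ]
    tes = _set([(30_000, 30_500), (80_000, 80_300)])

    def test_gene_body_is_genic(self):
        cats = categorize(_set([(10_500, 10_600)]), self.genes, self.tes)
        assert cats == [FeatureCategory.GENIC]

    def test_te_requires_distance_from_genes(self):
        # 18 kb from the nearest gene and on a TE
        cats = categorize(_set([(30_100, 30_200)]), self.genes, self.tes)
        assert cats == [FeatureCategory.TRANSPOSABLE_ELEMENT]

    def test_proximal_and_near_gene_bands(self):
        # note: IntervalSet keeps intervals sorted by coordinate
        cats = categorize(
            _set([(9_500, 9_600), (9_980, 12_100), (14_000, 14_050)]),
            self.genes,
            self.tes,
        )
        assert cats[0] == FeatureCategory.PROXIMAL_TSS  # 400 bp upstream of TSS
        assert cats[1] == FeatureCategory.GENIC  # overlap wins
        assert cats[2] == FeatureCategory.NEAR_GENE  # 2 kb past the TTS band

    def test_partition_and_bruteforce_oracle(self, rng):
        intervals = _random_set(rng, 1000, max_len=300)
        cats = categorize(intervals, self.genes, self.tes)
        assert len(cats) == len(intervals)
        for iv, cat in zip(intervals, cats):
            expected = self._oracle(iv)
            assert cat == expected, f"{iv} -> {cat} != {expected}"

    def _oracle(self, iv, proximal=1000, distal=3000):
        gene_ivs = [g.interval for g in self.genes]
        if any(iv.overlaps(gi) for gi in gene_ivs):
            return FeatureCategory.GENIC
        def pdist(pos):
            if pos < iv.start:
                return iv.start - pos
            if pos >= iv.end:
                return pos - iv.end + 1
            return 0
        d_tss = min(pdist(g.tss) for g in self.genes)
        d_tts = min(pdist(g.tts) for g in self.genes)
        if min(d_tss, d_tts) <= proximal:
            return FeatureCategory.PROXIMAL_TSS if d_tss <= d_tts else FeatureCategory.PROXIMAL_TTS
        gap = min(
            max(gi.start - iv.end + 1, iv.start - gi.end + 1) for gi in gene_ivs
        )
        if gap <= distal:
            return FeatureCategory.NEAR_GENE
        if any(iv.overlaps(t) for t in self.tes):
            return FeatureCategory.TRANSPOSABLE_ELEMENT
        return FeatureCategory.INTERGENIC


class TestCognateGene:
    def test_single_candidate_within_range(self):
        genes = [GeneModel(GenomicInterval("chr1", 1000, 2000, "+"), "g1")]
        a = assign_cognate_gene(GenomicInterval("chr1", 2500, 2600), genes)
        assert a.gene_id == "g1" and a.distance == 500

    def test_nearest_wins(self):
        genes = [
            GeneModel(GenomicInterval("chr1", 500, 700, "+"), "left"),
            GeneModel(GenomicInterval("chr1", 1800, 2000, "+"), "right"),
        ]
        a = assign_cognate_gene(GenomicInterval("chr1", 1000, 1001), genes)
        assert a.gene_id == "left"  # 300 bp beats 799 bp

    def test_beyond_1kb_unassigned(self):
        genes = [GeneModel(GenomicInterval("chr1", 5000, 6000, "+"), "far")]
        a = assign_cognate_gene(GenomicInterval("chr1", 3000, 3100), genes)
        assert a.gene_id is None and a.distance is None

    def test_overlap_distance_zero_and_tiebreak(self):
        genes = [
            GeneModel(GenomicInterval("chr1", 100, 400, "+"), "b"),
            GeneModel(GenomicInterval("chr1", 50, 400, "+"), "a"),
        ]
        a = assign_cognate_gene(GenomicInterval("chr1", 200, 250), genes)
        assert a.distance == 0
        assert a.gene_id == "a"  # smaller start on tie


class TestChromDistribution:
    def test_empty_and_single(self):
        dist = chromosome_distribution(_set([]), GENOME)
        assert dist["chr1"].sum() == 0
        dist = chromosome_distribution(_set([(14_000, 16_000)]), GENOME)
        # midpoint 15,000 falls in the second 10-kb window
        assert dist["chr1"][1] == 1 and dist["chr1"].sum() == 1

    def test_conservation_and_naive_oracle(self, rng):
        s = _random_set(rng, 5000)
        dist = chromosome_distribution(s, GENOME, window=10_000)
        assert sum(v.sum() for v in dist.values()) == len(s)
        naive = np.zeros(10, dtype=int)
        for iv in s:
            naive[iv.midpoint // 10_000] += 1
        np.testing.assert_array_equal(dist["chr1"], naive)


class TestPeakLevels:
    def test_single_peak_contains_everything(self, rng):
        frags = _random_set(rng, 500, max_len=50)
        peaks = _set([(0, 100_000)])
        levels = peak_level_rpm(peaks, frags)
        assert levels[0] == pytest.approx(1e6)

    def test_levels_match_bruteforce(self, rng):
        frags = _random_set(rng, 800, max_len=60)
        peaks = _random_set(rng, 50, max_len=500)
        levels = peak_level_rpm(peaks, frags)
        for iv, lvl in zip(peaks, levels):
            n = sum(1 for f in frags if f.overlaps(iv))
            assert lvl == pytest.approx(1e6 * n / len(frags))

    def test_rank_correlation_properties(self, rng):
        x = rng.uniform(0, 10, size=100)
        rho, _ = rank_correlation(x, np.exp(x))  # strictly increasing transform
        assert rho == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rank_correlation(np.ones(10), x[:10])

    def test_rank_correlation_definitional(self, rng):
        from scipy import stats

        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        rho, _ = rank_correlation(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-12)


class TestEntropy:
    def test_single_tissue_is_zero(self):
        x = np.zeros(79)
        x[7] = 12.5
        assert shannon_entropy(x) == 0.0

    def test_uniform_is_log2_n(self):
        assert shannon_entropy(np.full(79, 3.3)) == pytest.approx(np.log2(79), abs=1e-9)

    def test_matches_direct_sum_and_bounds(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 5, size=79)
            h = shannon_entropy(x)
            p = x / x.sum()
            direct = -sum(pi * np.log2(pi) for pi in p if pi > 0)
            assert h == pytest.approx(direct, abs=1e-12)
            assert 0.0 <= h <= np.log2(79) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.zeros(5))
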