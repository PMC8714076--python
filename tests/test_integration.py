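import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromlink.integration import (
    assign_targets,
    compare_density_classes,
    exact_mw_null,
    mann_whitney,
    open_peaks,
    tad_density,
)
from chromlink.intervals import GenomicInterval, GeneModel, TAD, ValidationError, overlaps
from chromlink.replication import ConfirmedPeak


def cpeak(chrom, start, end, summit=None):
    return ConfirmedPeak(GenomicInterval(chrom, start, end), summit if summit is not None else (start + end) // 2, 1e-8, support=2)


class TestOpenPeaks:
    def test_peak_inside_open_region_retained(self):
        peaks = [cpeak("chr1", 100, 300)]
        assert open_peaks(peaks, [GenomicInterval("chr1", 0, 1000)]) == peaks

    def test_zero_overlap_dropped(self):
        assert open_peaks([cpeak("chr1", 100, 300)], [GenomicInterval("chr1", 300, 500)]) == []

    def test_matches_pairwise_brute_force(self, rng):
        peaks = [cpeak("chr1", int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 50_000, 200), rng.integers(50, 400, 200))]
        atac = [GenomicInterval("chr1", int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 50_000, 100), rng.integers(100, 800, 100))]
        expected = [p for p in peaks if any(overlaps(p.interval, a) for a in atac)]
        assert open_peaks(peaks, atac) == expected


def deg_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "direction"])


class TestAssignTargets:
    def test_beyond_max_dist_no_call(self):
        degs = deg_frame([("gA", "chr1", 2_000_000, "up")])
        assert assign_targets([cpeak("chr1", 899_000, 901_000)], degs) == []

    def test_within_bound_single_supporting_peak(self):
        degs = deg_frame([("gA", "chr1", 100_000, "down")])
        (call,) = assign_targets([cpeak("chr1", 109_000, 111_000)], degs)
        assert call.gene_id == "gA" and call.direction == "down"
        assert call.n_peaks == 1 and call.min_abs_distance == 10_000

    def test_tie_broken_by_smallest_gene_id(self):
        degs = deg_frame([("gB", "chr1", 90_000, "up"), ("gA", "chr1", 110_000, "up")])
        (call,) = assign_targets([cpeak("chr1", 99_000, 101_000)], degs)
        assert call.gene_id == "gA"

    def test_unchanged_genes_never_targeted(self):
        degs = deg_frame([("gA", "chr1", 100_000, "unchanged")])
        assert assign_targets([cpeak("chr1", 99_000, 101_000)], degs) == []

    def test_matches_exhaustive_nearest_search(self, rng):
        degs = deg_frame(
            [(f"g{i:03d}", "chr1", int(t), str(rng.choice(["up", "down"]))) for i, t in enumerate(rng.integers(0, 5_000_000, size=50))]
        )
        peaks = [cpeak("chr1", int(s), int(s) + 200) for s in rng.integers(0, 5_000_000, size=300)]
        calls = {c.gene_id: c for c in assign_targets(peaks, degs)}
        expected = {}
        for p in peaks:
            cand = sorted(
                ((abs(p.summit - t), g) for g, t in zip(degs["gene_id"], degs["tss"])),
            )
            d, g = cand[0]
            if d <= 1_000_000:
                expected.setdefault(g, []).append(p)
        assert set(calls) == set(expected)
        for g, plist in expected.items():
            assert calls[g].n_peaks == len(plist)


class TestTadDensity:
    TADS = [TAD(GenomicInterval("chr1", 0, 1_000_000), "t1"), TAD(GenomicInterval("chr1", 1_000_000, 2_000_000), "t2")]

    def genes(self, positions):
        return [GeneModel(f"g{i}", GenomicInterval("chr1", p, p + 1_000), "+") for i, p in enumerate(positions)]

    def test_density_is_peaks_over_genes(self):
        genes = self.genes([100_000, 200_000, 300_000, 400_000])
        peaks = [cpeak("chr1", 50_000, 50_200), cpeak("chr1", 60_000, 60_200)]
        density, outside = tad_density(peaks, self.TADS, genes)
        assert (density == 0.5).all()
        assert outside == []

    def test_zero_peaks_zero_density(self):
        genes = self.genes([1_100_000, 1_200_000])
        density, _ = tad_density([], self.TADS, genes)
        assert (density == 0.0).all()

    def test_genes_outside_all_tads_reported(self):
        genes = self.genes([100_000, 5_000_000])
        density, outside = tad_density([], self.TADS, genes)
        assert outside == ["g1"]
        assert list(density.index) == ["g0"]

    def test_overlapping_tads_rejected(self):
        bad = [TAD(GenomicInterval("chr1", 0, 1_000_000), "t1"), TAD(GenomicInterval("chr1", 900_000, 2_000_000), "t2")]
        with pytest.raises(ValidationError):
            tad_density([], bad, self.genes([100_000]))

    def test_matches_brute_force_membership_counting(self, rng):
        tads = [TAD(GenomicInterval("chr1", i * 500_000, (i + 1) * 500_000), f"t{i}") for i in range(10)]
        genes = self.genes(sorted(rng.integers(0, 5_000_000, size=40)))
        peaks = [cpeak("chr1", int(s), int(s) + 200) for s in rng.integers(0, 5_000_000, size=100)]
        density, outside = tad_density(peaks, tads, genes)
        for g in genes:
            tid = next((t for t in tads if t.interval.contains(g.tss)), None)
            if tid is None:
                assert g.gene_id in outside
                continue
            n_p = sum(tid.interval.contains(p.summit) for p in peaks)
            n_g = sum(tid.interval.contains(x.tss) for x in genes)
            assert density[g.gene_id] == pytest.approx(n_p / n_g)


class TestMannWhitney:
    def test_two_singletons(self):
        assert mann_whitney([1], [2]) == (0.0, 1.0)

    def test_fully_separated_three_vs_three(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)=2/20

    def test_null_pmf_sums_to_one_and_is_symmetric(self):
        for m, n in [(3, 4), (5, 7), (9, 10)]:
            pmf = exact_mw_null(m, n)
            assert pmf.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-15)

    @pytest.mark.parametrize("m,n", [(3, 3), (4, 5), (6, 6)])
    def test_null_matches_enumeration(self, m, n):
        pmf = exact_mw_null(m, n)
        counts = np.zeros(m * n + 1)
        for comb in itertools.combinations(range(m + n), m):
            counts[sum(comb) - m * (m - 1) // 2] += 1
        np.testing.assert_allclose(pmf, counts / math.comb(m + n, m), atol=1e-12)

    def test_exact_and_asymptotic_agree_for_moderate_n(self, rng):
        x = rng.normal(0.0, 1.0, size=12)
        y = rng.normal(0.8, 1.0, size=12)
        _, p_exact = mann_whitney(list(x), list(y))  # pooled 24 <= 25, tie-free -> exact
        p_approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) / p_exact < 0.10

    def test_exact_branch_matches_scipy_exact(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=9)
        u, p = mann_whitney(list(x), list(y))
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_ties_fall_back_to_corrected_normal(self):
        x = [1, 1, 2, 3, 3, 3]
        y = [2, 2, 3, 4, 4, 5]
        _, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True).pvalue
        assert p == pytest.approx(ref)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestCompareDensityClasses:
    def make(self, up, down, unchanged):
        vals = np.concatenate([up, down, unchanged])
        labels = ["up"] * len(up) + ["down"] * len(down) + ["unchanged"] * len(unchanged)
        idx = [f"g{i}" for i in range(len(vals))]
        return pd.Series(vals, index=idx), pd.Series(labels, index=idx)

    def test_identical_samples_give_p_near_one(self, rng):
        base = rng.uniform(0, 1, size=20)
        density, labels = self.make(base, base, base)
        res = compare_density_classes(density, labels)
        assert res.p_up_vs_unchanged >= 0.5
        assert res.p_down_vs_unchanged >= 0.5

    def test_planted_enrichment_detected(self, rng):
        # DEG-containing TADs carry ~5x more peaks than unchanged TADs
        up = rng.poisson(5.0, size=100) / rng.integers(1, 6, size=100)
        down = rng.poisson(5.0, size=100) / rng.integers(1, 6, size=100)
        unchanged = rng.poisson(1.0, size=100) / rng.integers(1, 6, size=100)
        density, labels = self.make(up, down, unchanged)
        res = compare_density_classes(density, labels)
        assert res.p_up_vs_unchanged < 0.01
        assert res.p_down_vs_unchanged < 0.01

    def test_gene_order_invariance(self, rng):
        density, labels = self.make(rng.uniform(0, 2, 10), rng.uniform(0, 2, 10), rng.uniform(0, 1, 10))
        res1 = compare_density_classes(density, labels)
        perm = rng.permutation(len(density))
        res2 = compare_density_classes(density.iloc[perm], labels.iloc[perm])
        assert res1.p_up_vs_unchanged == res2.p_up_vs_unchanged
        assert res1.p_down_vs_unchanged == res2.p_down_vs_unchanged

    def test_small_class_rejected(self):
        density, labels = self.make([1.0], [1.0, 2.0], [0.5, 0.7])
        with pytest.raises(ValidationError, match="up"):
            compare_density_classes(density, labels)
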