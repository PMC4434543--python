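"""Metagene profiling: strand orientation, averaging, window sums, and
the rank-sum comparison used for the boxplot views."""

import itertools
from math import comb

import numpy as np
import pytest

from conftest import make_gene
from ligsel.errors import ConfigError, DataError
from ligsel.profiles import (
    metagene_profile,
    rank_sum_test,
    region_scores,
    select_dominant_tss,
)
from ligsel.tracks import CoverageTrack


def spike_track(positions_values, length=60_000, total=1e6):
    arr = np.zeros(length)
    for pos, val in positions_values:
        arr[pos] = val
    return CoverageTrack({"chr1": arr}, total)


class TestMetageneProfile:
    def test_uniform_coverage_gives_flat_profile(self, uniform_track, plus_gene):
        prof = metagene_profile(uniform_track, [plus_gene], window=(-2000, 2000))
        assert prof.mean_rpm.shape == (4001,)
        assert np.allclose(prof.mean_rpm, 1.0)

    def test_minus_strand_spike_flips_to_downstream(self, minus_gene):
        # spike 100 bp genomically upstream of a minus-strand TSS is 3'
        # of the TSS, so it must land at offset +100
        track = spike_track([(minus_gene.primary_tss - 100, 5.0)])
        prof = metagene_profile(track, [minus_gene], window=(-200, 200))
        offsets = dict(zip(prof.offsets, prof.mean_rpm))
        assert offsets[100] == pytest.approx(5.0)
        assert offsets[-100] == 0.0

    def test_mean_across_anchors(self):
        g1 = make_gene("a", tss=20_000, strand="+")
        g2 = make_gene("b", tss=40_000, strand="+")
        track = spike_track([(20_050, 4.0), (40_050, 6.0)])
        prof = metagene_profile(track, [g1, g2], window=(-100, 100))
        assert prof.mean_rpm[prof.offsets.tolist().index(50)] == pytest.approx(5.0)
        assert prof.n_anchors == 2

    def test_edge_anchor_skipped_not_padded(self):
        g_edge = make_gene("edge", tss=500, strand="+")
        g_mid = make_gene("mid", tss=30_000, strand="+")
        track = spike_track([])
        prof = metagene_profile(track, [g_edge, g_mid], window=(-2000, 2000))
        assert prof.n_anchors == 1
        assert prof.n_skipped == 1

    def test_empty_gene_set_raises(self, uniform_track):
        with pytest.raises(DataError):
            metagene_profile(uniform_track, [])

    def test_invalid_window_raises(self, uniform_track, plus_gene):
        with pytest.raises(ConfigError):
            metagene_profile(uniform_track, [plus_gene], window=(100, -100))

    def test_strand_flip_symmetry(self, small_dataset):
        """Reverse-complementing the genome (flipping coordinates and
        strands) must reproduce every profile exactly."""
        ds = small_dataset
        track = ds.tracks["polII_BCR"]
        chrom = ds.config.chrom_name
        length = len(track.chroms[chrom])
        flipped_track = CoverageTrack(
            {chrom: track.chroms[chrom][::-1].copy()}, track.total_mapped_reads
        )
        genes = ds.genes[:20]
        flipped_genes = [
            make_flipped(g, length) for g in genes
        ]
        p1 = metagene_profile(track, genes, window=(-1500, 1500))
        p2 = metagene_profile(flipped_track, flipped_genes, window=(-1500, 1500))
        assert np.array_equal(p1.mean_rpm, p2.mean_rpm)

    def test_union_profile_is_weighted_mean(self, small_dataset):
        ds = small_dataset
        track = ds.tracks["h3k4me3_LPS"]
        set_a, set_b = ds.genes[:8], ds.genes[8:20]
        pa = metagene_profile(track, set_a, window=(-500, 500))
        pb = metagene_profile(track, set_b, window=(-500, 500))
        pu = metagene_profile(track, set_a + set_b, window=(-500, 500))
        weighted = (pa.mean_rpm * pa.n_anchors + pb.mean_rpm * pb.n_anchors) / (
            pa.n_anchors + pb.n_anchors
        )
        assert np.allclose(pu.mean_rpm, weighted, rtol=1e-12)


def make_flipped(gene, length):
    from ligsel.genes import GeneModel

    return GeneModel(
        gene.gene_id,
        gene.chrom,
        length - gene.end,
        length - gene.start,
        "-" if gene.strand == "+" else "+",
        tuple(length - 1 - t for t in gene.tss_list),
    )


class TestRegionScores:
    def test_flat_coverage_window_sum(self, uniform_track, plus_gene):
        scores = region_scores(uniform_track, [plus_gene], window=(-1000, 1000))
        assert scores.scores["plus1"] == pytest.approx(2001.0)

    def test_zero_track_zero_scores(self, plus_gene):
        scores = region_scores(spike_track([]), [plus_gene], window=(-1000, 1000))
        assert scores.scores["plus1"] == 0.0

    def test_spike_outside_window_ignored(self, plus_gene):
        track = spike_track([(plus_gene.primary_tss + 1500, 7.0)])
        scores = region_scores(track, [plus_gene], window=(-1000, 1000))
        assert scores.scores["plus1"] == 0.0

    def test_single_anchor_profile_sum_equals_region_score(self, small_dataset):
        """Conservation: summing a one-anchor profile over its offsets
        gives exactly the region score for the same window."""
        ds = small_dataset
        track = ds.tracks["polII_rest"]
        gene = next(g for g in ds.genes if len(g.tss_list) == 1)
        prof = metagene_profile(track, [gene], window=(-800, 800))
        scores = region_scores(track, [gene], window=(-800, 800))
        assert scores.scores[gene.gene_id] == pytest.approx(
            prof.mean_rpm.sum(), rel=1e-12
        )

    def test_multi_tss_gene_scores_mean_of_transcripts(self):
        gene = make_gene("m", tss=30_000, strand="+", extra_tss=(30_100,))
        track = spike_track([(30_000, 4.0), (30_100, 8.0)])
        scores = region_scores(track, [gene], window=(-50, 50))
        # first TSS window catches only its own spike, second likewise
        assert scores.scores["m"] == pytest.approx((4.0 + 8.0) / 2)


class TestDominantTSS:
    def test_selects_highest_occupancy_tss(self, small_dataset):
        """The planted dominant (primary) TSS carries the tallest Pol II
        peak and must be selected for nearly every gene."""
        ds = small_dataset
        track = ds.tracks["polII_rest"]
        chosen = select_dominant_tss(track, ds.genes)
        hits = sum(
            chosen[g.gene_id] == ds.truth.dominant_tss[g.gene_id] for g in ds.genes
        )
        assert hits / len(ds.genes) >= 0.95


def enumerate_rank_sum_p(x, y, alternative="two-sided"):
    """Independent oracle: exact rank-sum p by enumerating all ways to
    assign the pooled values to the two groups (tie-free samples)."""
    pooled = sorted(x) + sorted(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    observed = u_stat(x, y)
    us = []
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        us.append(u_stat(xs, ys))
    total = comb(len(pooled), n)
    p_ge = sum(1 for u in us if u >= observed) / total
    p_le = sum(1 for u in us if u <= observed) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestRankSum:
    def test_textbook_example(self):
        x, y = [1, 2, 3], [4, 5, 6]
        _, p_one = rank_sum_test(x, y, alternative="less")
        assert p_one == pytest.approx(1 / 20)
        _, p_two = rank_sum_test(x, y)
        assert p_two == pytest.approx(2 / 20)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 2), (5, 5)])
    def test_exact_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        vals = rng.permutation(np.arange(1.0, n + m + 1))
        x, y = list(vals[:n]), list(vals[n:])
        for alt in ("two-sided", "greater", "less"):
            _, p = rank_sum_test(x, y, alternative=alt)
            assert p == pytest.approx(enumerate_rank_sum_p(x, y, alt), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(1.0, 13))
        x, y = list(vals[:6]), list(vals[6:])
        _, p_exact = rank_sum_test(x, y)
        _, p_approx = rank_sum_test(x, y, exact_max_n=0)
        assert abs(p_exact - p_approx) < 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(DataError):
            rank_sum_test([], [1.0])
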