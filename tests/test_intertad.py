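"""Inter-TAD interaction scores, fold-change table, selection, LAD classes,
permutation control and size-distribution comparison."""

import numpy as np
import pandas as pd
import pytest

from tadlamina.contact_io import ContactMatrix, GenomicTrack
from tadlamina.tad_calling import TadSegmentation
from tadlamina.intertad_lad import (
    TadPairTable,
    build_pair_table,
    classify_lad_pairs,
    compare_size_distributions,
    inter_tad_interaction,
    permute_boundaries_control,
    permute_segmentation,
    select_extreme_pairs,
)

from conftest import random_symmetric_matrix


def brute_force_x(m, t1, t2):
    total = 0.0
    for i in range(*t1):
        for j in range(*t2):
            if m.valid_mask[i] and m.valid_mask[j]:
                total += m.values[i, j]
    return total / ((t1[1] - t1[0]) * (t2[1] - t2[0]))


def seg_from_bounds(bounds, n_bins, resolution=25_000, chrom="chrT"):
    b = np.asarray(bounds, dtype=np.int64)
    return TadSegmentation(
        chrom=chrom, resolution=resolution, boundaries=b,
        strengths=np.zeros(len(b)), n_bins=n_bins,
    )


def uniform_track(value, n=100, resolution=100_000, chrom="chrT"):
    return GenomicTrack(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * resolution,
                "end": (np.arange(n) + 1) * resolution,
                "value": np.full(n, float(value)),
            }
        ),
        resolution=resolution,
    )


class TestInterTadInteraction:
    def test_constant_rectangle(self):
        m = ContactMatrix("chrT", 25_000, np.full((10, 10), 3.0), np.ones(10, dtype=bool))
        assert inter_tad_interaction(m, (0, 4), (6, 9)) == pytest.approx(3.0)

    def test_worked_two_by_two(self):
        vals = np.zeros((4, 4))
        vals[0:2, 2:4] = [[1, 2], [3, 4]]
        vals += vals.T.copy()
        m = ContactMatrix("chrT", 25_000, vals, np.ones(4, dtype=bool))
        assert inter_tad_interaction(m, (0, 2), (2, 4)) == pytest.approx(2.5)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            m = random_symmetric_matrix(rng, 50)
            m.valid_mask[rng.choice(50, 5, replace=False)] = False
            s1 = int(rng.integers(0, 15))
            e1 = s1 + int(rng.integers(2, 8))
            s2 = e1 + int(rng.integers(1, 10))
            e2 = s2 + int(rng.integers(2, 8))
            got = inter_tad_interaction(m, (s1, e1), (s2, e2))
            assert got == pytest.approx(brute_force_x(m, (s1, e1), (s2, e2)), rel=1e-12)

    def test_masked_bins_zero_numerator_full_denominator(self):
        m = ContactMatrix("chrT", 25_000, np.full((6, 6), 2.0), np.ones(6, dtype=bool))
        m.valid_mask[4] = False
        # rectangle (0,2) x (3,6): 6 pairs, 2 involve the masked bin
        assert inter_tad_interaction(m, (0, 2), (3, 6)) == pytest.approx(2.0 * 4 / 6)

    def test_overlapping_tads_raise(self):
        m = ContactMatrix("chrT", 25_000, np.ones((10, 10)), np.ones(10, dtype=bool))
        with pytest.raises(ValueError):
            inter_tad_interaction(m, (0, 5), (4, 8))


def make_pair_inputs(rng, n=120, bounds=(0, 30, 60, 85, 120)):
    wt = random_symmetric_matrix(rng, n)
    wt.values += 0.5  # keep every rectangle strictly positive
    wt.values = np.triu(wt.values) + np.triu(wt.values, 1).T
    seg = seg_from_bounds(bounds, n)
    return wt, seg


class TestBuildPairTable:
    def test_identical_conditions_zero_logfc(self, rng):
        wt, seg = make_pair_inputs(rng)
        table = build_pair_table(wt, wt.copy(), seg, min_tad_bp=100_000)
        assert len(table) == 6
        assert np.allclose(table.df["logfc"], 0.0, atol=1e-12)

    def test_global_halving_absorbed_by_median_shift(self, rng):
        wt, seg = make_pair_inputs(rng)
        ko = wt.scaled(0.5)
        table = build_pair_table(wt, ko, seg, min_tad_bp=100_000)
        assert np.allclose(table.df["logfc"], 0.0, atol=1e-12)

    def test_median_centering_invariant(self, rng):
        wt, seg = make_pair_inputs(rng)
        ko = random_symmetric_matrix(rng, 120)
        ko.values += 0.5
        table = build_pair_table(wt, ko, seg, min_tad_bp=100_000)
        assert table.df["logfc"].median() == pytest.approx(0.0, abs=1e-12)

    def test_depth_rescaling_leaves_logfc(self, rng):
        wt, seg = make_pair_inputs(rng)
        ko = random_symmetric_matrix(rng, 120)
        ko.values += 0.5
        t1 = build_pair_table(wt, ko, seg, min_tad_bp=100_000)
        t2 = build_pair_table(wt.scaled(3.7), ko.scaled(0.11), seg, min_tad_bp=100_000)
        np.testing.assert_allclose(t1.df["logfc"], t2.df["logfc"], atol=1e-10)

    def test_min_size_filter(self, rng):
        wt, seg = make_pair_inputs(rng)
        # TAD sizes in bins: 30, 30, 25, 35 -> bp: 750k, 750k, 625k, 875k
        table = build_pair_table(wt, wt.copy(), seg, min_tad_bp=700_000)
        # only the three TADs > 700 kb survive -> 3 pairs
        assert len(table) == 3

    def test_grid_mismatch_raises(self, rng):
        wt, seg = make_pair_inputs(rng)
        ko = random_symmetric_matrix(rng, 60)
        with pytest.raises(ValueError):
            build_pair_table(wt, ko, seg)

    def test_tad_distance_counts_intervening(self, rng):
        wt, seg = make_pair_inputs(rng)
        table = build_pair_table(wt, wt.copy(), seg, min_tad_bp=100_000)
        d = table.df.set_index(["tad1_start", "tad2_start"])["tad_distance"]
        assert d[(0, 30 * 25_000)] == 0
        assert d[(0, 85 * 25_000)] == 2


class TestSelectExtremePairs:
    def _table(self, logfcs, distances=None):
        n = len(logfcs)
        df = pd.DataFrame(
            {
                "chrom": "chrT",
                "tad1_start": np.arange(n),
                "tad1_end": np.arange(n) + 1,
                "tad2_start": np.arange(n) + 10,
                "tad2_end": np.arange(n) + 11,
                "x_wt": 1.0,
                "x_ko": 1.0,
                "logfc": logfcs,
                "tad_distance": distances if distances is not None else np.zeros(n, int),
                "damid1": np.nan,
                "damid2": np.nan,
                "lad_class": "",
            }
        )
        return TadPairTable(df=df, resolution=25_000)

    def test_all_zero_nothing_selected(self):
        dec, inc = select_extreme_pairs(self._table([0.0] * 5))
        assert len(dec) == 0 and len(inc) == 0

    def test_threshold_example(self):
        dec, inc = select_extreme_pairs(self._table([-2.0, -0.5, 0.3, 1.7]), logfc_cut=1.0)
        assert list(dec["logfc"]) == [1.7]
        assert list(inc["logfc"]) == [-2.0]

    def test_per_distance_matches_sort_oracle(self, rng):
        logfcs = rng.normal(size=30)
        dists = rng.integers(0, 4, size=30)
        table = self._table(logfcs, dists)
        dec, inc = select_extreme_pairs(table, mode="per_distance", k=2)
        for d in np.unique(dists):
            sub = np.sort(logfcs[dists == d])
            want_top = set(np.round(sub[-2:], 12))
            got_top = set(np.round(dec[dec["tad_distance"] == d]["logfc"], 12))
            assert got_top == want_top
            want_bot = set(np.round(sub[:2], 12))
            got_bot = set(np.round(inc[inc["tad_distance"] == d]["logfc"], 12))
            assert got_bot == want_bot

    def test_sets_grow_as_cut_decreases(self, rng):
        table = self._table(rng.normal(size=200))
        sizes = []
        for cut in (2.5, 1.5, 0.5, 0.1):
            dec, inc = select_extreme_pairs(table, logfc_cut=cut)
            sizes.append(len(dec) + len(inc))
        assert sizes == sorted(sizes)
        dec, inc = select_extreme_pairs(table, logfc_cut=50.0)
        assert len(dec) == 0 and len(inc) == 0

    def test_invalid_parameters(self):
        table = self._table([0.0])
        with pytest.raises(ValueError):
            select_extreme_pairs(table, logfc_cut=-1.0)
        with pytest.raises(ValueError):
            select_extreme_pairs(table, mode="per_distance", k=0)
        with pytest.raises(ValueError):
            select_extreme_pairs(table, mode="bogus")


class TestClassifyLadPairs:
    def _pairs(self, damid1, damid2):
        return pd.DataFrame({"damid1": damid1, "damid2": damid2})

    def test_uniform_positive_track_all_both_lad(self):
        df = self._pairs([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        rep = classify_lad_pairs(df, df.iloc[0:0])
        assert rep.percentages["decreased"]["both_lad"] == 100.0
        assert rep.percentages["decreased"]["mixed"] == 0.0

    def test_opposite_signs_mixed(self):
        rep = classify_lad_pairs(self._pairs([1.0], [-1.0]), self._pairs([], []))
        assert rep.counts["decreased"]["mixed"] == 1

    def test_percentages_sum_and_concordant(self, rng):
        df = self._pairs(rng.normal(size=200), rng.normal(size=200))
        rep = classify_lad_pairs(df, df)
        p = rep.percentages["decreased"]
        assert p["both_lad"] + p["mixed"] + p["neither"] == pytest.approx(100.0)
        assert p["concordant"] == pytest.approx(p["both_lad"] + p["neither"])

    def test_uncovered_pairs_dropped_and_counted(self):
        df = self._pairs([1.0, np.nan], [1.0, 1.0])
        rep = classify_lad_pairs(df, df.iloc[0:0])
        assert rep.n_dropped_no_coverage == 1
        assert sum(rep.counts["decreased"].values()) == 1


class TestPermutation:
    def test_degenerate_segmentations_unchanged(self, rng):
        g = np.random.default_rng(0)
        one_tad = seg_from_bounds([10, 40], n_bins=100)
        assert permute_segmentation(one_tad, g) is one_tad
        empty = seg_from_bounds([10], n_bins=100)
        assert permute_segmentation(empty, g) is empty

    def test_sizes_conserved_up_to_one_dropped(self):
        g = np.random.default_rng(1)
        seg = seg_from_bounds([5, 25, 60, 80, 130, 155, 190], n_bins=200)
        orig = sorted(seg.tads[:, 1] - seg.tads[:, 0])
        for _ in range(25):
            p = permute_segmentation(seg, g)
            got = sorted(p.tads[:, 1] - p.tads[:, 0])
            assert len(got) in (len(orig), len(orig) - 1)
            remaining = list(orig)
            for s in got:
                assert s in remaining
                remaining.remove(s)
            # intervals stay inside the chromosome and disjoint
            t = p.tads[np.argsort(p.tads[:, 0])]
            assert t[0, 0] >= 0 and t[-1, 1] <= 200
            assert np.all(t[1:, 0] >= t[:-1, 1])

    def test_control_runs_and_returns_distribution(self, rng):
        wt, seg = make_pair_inputs(rng)
        ko = random_symmetric_matrix(rng, 120)
        ko.values += 0.5
        control = permute_boundaries_control(
            seg, wt, ko, uniform_track(1.0, n=30, resolution=100_000),
            n_permutations=10, seed=4, min_tad_bp=100_000, logfc_cut=0.01,
        )
        assert control.n_permutations == 10
        assert np.isfinite(control.mixed_pct_decreased).any()


class TestCompareSizeDistributions:
    def test_identical_samples(self):
        d, p = compare_size_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, _ = compare_size_distributions([1, 2, 3], [10, 20, 30])
        assert d == 1.0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            compare_size_distributions([], [1.0])

    def test_null_calibration(self):
        hits = 0
        for s in range(30):
            g = np.random.default_rng(s)
            a = g.lognormal(0, 0.5, 500)
            b = g.lognormal(0, 0.5, 500)
            _, p = compare_size_distributions(a, b)
            hits += p > 0.05
        assert hits >= 27
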