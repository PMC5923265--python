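"""Quadrant pairing, Wilcoxon, Fisher, and mark-loss statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, mannwhitneyu, rankdata

from divatac.genomic import Region
from divatac.integration import (
    expression_shift_test,
    fisher_exact_2x2,
    fisher_overlap,
    mark_enrichment_at,
    pair_dar_dml,
    quadrant_of,
    venn_mark_promoters,
)


class TestQuadrants:
    @pytest.mark.parametrize(
        "dm,da,q",
        [
            (-40, 2, "Q3"),
            (-40, -2, "Q2"),
            (40, 2, "Q1"),
            (40, -2, "Q4"),
            (0, 2, None),
            (-40, 0, None),
        ],
    )
    def test_quadrant_definitions(self, dm, da, q):
        assert quadrant_of(dm, da) == q

    def test_pairing_respects_half_open_containment(self):
        dars = pd.DataFrame({"region_id": ["r"], "log2fc": [2.0]})
        regions = {"r": ("chr1", 100, 200)}
        dmls = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [99, 100, 200],
             "delta_meth": [-40.0, -40.0, -40.0]}
        )
        out = pair_dar_dml(dars, regions, dmls)
        assert out["cpg_pos"].tolist() == [100]  # 99 before, 200 excluded
        assert out["quadrant"].tolist() == ["Q3"]

    def test_zero_deltas_dropped_and_counted(self):
        dars = pd.DataFrame({"region_id": ["r"], "log2fc": [1.0]})
        regions = {"r": ("chr1", 0, 10)}
        dmls = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1, 2],
             "delta_meth": [0.0, -10.0]}
        )
        out = pair_dar_dml(dars, regions, dmls)
        assert len(out) == 1
        assert out.attrs["n_zero_dropped"] == 1


def enumeration_oracle(x, y):
    """Independent exact rank-sum oracle via the U statistic."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2
    count = total = 0
    for combo in combinations(range(n), n1):
        u = sum(ranks[i] for i in combo)
        if abs(u - mean) >= abs(u_obs - mean) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestWilcoxon:
    def test_fully_separated_small_sample(self):
        # only 2 of C(6,3)=20 labelings are as extreme -> p = 0.1
        res = expression_shift_test([1, 2, 3], [4, 5, 6])
        assert res["pvalue"] == pytest.approx(0.1)
        assert res["method"] == "exact"

    def test_identical_samples_give_p_one(self):
        res = expression_shift_test([1, 2, 3], [1, 2, 3])
        assert res["pvalue"] == pytest.approx(1.0)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(1.0, size=7)
            res = expression_shift_test(x, y, force_method="exact")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res["pvalue"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(6):
            x = rng.integers(0, 4, size=5).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            res = expression_shift_test(x, y, force_method="exact")
            assert res["pvalue"] == pytest.approx(
                enumeration_oracle(x, y), abs=1e-12
            )

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, size=8)
        y = rng.normal(2, 1, size=8)
        p_exact = expression_shift_test(x, y, force_method="exact")["pvalue"]
        p_norm = expression_shift_test(x, y, force_method="normal")["pvalue"]
        assert abs(p_exact - p_norm) <= 0.005

    def test_large_samples_use_normal_path(self):
        rng = np.random.default_rng(15)
        res = expression_shift_test(
            rng.normal(size=20), rng.normal(size=20)
        )
        assert res["method"] == "normal"

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            expression_shift_test([1, 2], [1, 2, 3])


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct comb-based enumeration."""
    n, row, col = a + b + c + d, a + b, a + c

    def prob(k):
        return (
            math.comb(row, k)
            * math.comb(n - row, col - k)
            / math.comb(n, col)
        )

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, col - (n - row)), min(row, col) + 1)
        if prob(k) <= p_obs * (1 + 1e-7)
    )


class TestFisher:
    def test_hand_enumerated_table(self):
        odds, p = fisher_exact_2x2(3, 1, 1, 3)
        assert odds == pytest.approx(9.0)
        assert p == pytest.approx(34 / 70)

    def test_balanced_table(self):
        odds, p = fisher_exact_2x2(4, 4, 4, 4)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cells(self):
        odds, p = fisher_exact_2x2(5, 0, 0, 5)
        assert odds == pytest.approx(121.0)
        assert p == pytest.approx(2 / 252)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(16)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_comb_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            _, p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


class TestFisherOverlap:
    def test_counts_and_universe_check(self):
        universe = [Region("chr1", i * 100, i * 100 + 50, f"u{i}") for i in range(8)]
        subset = universe[:4]
        feature = [Region("chr1", 0, 350, "f")]  # overlaps u0..u3
        table = fisher_overlap(subset, feature, universe)
        assert (table.a, table.b, table.c, table.d) == (4, 0, 0, 4)
        extra = [Region("chr2", 0, 10, "x")]
        with pytest.raises(ValueError):
            fisher_overlap(subset + extra, feature, universe)


class TestMarkEnrichment:
    def test_identical_scores(self):
        res = mark_enrichment_at([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["pvalue"] == pytest.approx(1.0)

    def test_planted_loss_highly_significant(self):
        rng = np.random.default_rng(18)
        pb = rng.normal(1.0, 0.01, size=30)
        b = pb * 4 + 3
        res = mark_enrichment_at(b, pb)
        assert res["pvalue"] < 1e-6

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            mark_enrichment_at([1.0], [2.0])


class TestVenn:
    def make_promoters(self, n, prefix):
        return [
            Region("chr1", 10_000 * i, 10_000 * i + 500, f"{prefix}{i}")
            for i in range(n)
        ]

    def test_full_marking_of_primed_set(self):
        primed = self.make_promoters(5, "p")
        induced = [
            Region("chr1", 10_000 * i + 5_000, 10_000 * i + 5_500, f"i{i}")
            for i in range(5)
        ]
        universe = primed + induced
        marks = [Region("chr1", r.start, r.end, f"m{k}") for k, r in enumerate(primed)]
        out = venn_mark_promoters(marks, primed, induced, universe)
        assert out["n_marked_primed"] == len(primed)
        assert out["n_marked_induced"] == 0

    def test_no_overlap_gives_p_one(self):
        primed = self.make_promoters(3, "p")
        induced = [
            Region("chr1", 10_000 * i + 5_000, 10_000 * i + 5_500, f"i{i}")
            for i in range(3)
        ]
        marks = [Region("chr2", 0, 100, "m")]
        out = venn_mark_promoters(marks, primed, induced, primed + induced)
        assert out["fisher_p_primed"] == pytest.approx(1.0)
        assert out["fisher_p_induced"] == pytest.approx(1.0)

    def test_overlapping_classes_rejected(self):
        primed = self.make_promoters(3, "p")
        with pytest.raises(ValueError):
            venn_mark_promoters([], primed, primed, primed)
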