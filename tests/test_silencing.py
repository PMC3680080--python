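"""Quadrant counting, the one-sided hypergeometric test, filters, grouping."""

import numpy as np
import pytest
from scipy import stats

from stepminer2d import (
    InvalidInputError,
    PairedSeries,
    QuadrantCounts,
    StepMiner2D,
    bonferroni_significant,
    direction_filter,
    hypergeom_pvalue,
    quadrant_counts,
)
from stepminer2d import test_pair as run_pair_test  # alias: bare name would be collected

from conftest import oracle_hypergeom_pvalue


def qc(n, ul, ur, ll, lr):
    return QuadrantCounts(n_total=n, upper_left=ul, upper_right=ur, lower_left=ll, lower_right=lr)


class TestQuadrantCounts:
    def test_one_point_per_quadrant(self):
        c = quadrant_counts([0, 0, 1, 1], [0, 1, 0, 1], 0.5, 0.5)
        assert (c.upper_left, c.upper_right, c.lower_left, c.lower_right) == (1, 1, 1, 1)
        assert (c.R, c.U, c.K) == (2, 2, 1)

    def test_all_low(self):
        c = quadrant_counts([0.1] * 5, [0.2] * 5, 0.5, 0.5)
        assert c.lower_left == 5 and c.n_total == 5

    def test_boundary_values_fall_low(self):
        c = quadrant_counts([0.5, 0.6], [0.5, 0.6], 0.5, 0.5)
        assert c.lower_left == 1 and c.upper_right == 1

    def test_invariant_to_joint_monotone_transform(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        a = quadrant_counts(x, y, 0.3, -0.2)
        b = quadrant_counts(np.exp(x), np.exp(y), np.exp(0.3), np.exp(-0.2))
        assert a == b

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            quadrant_counts([], [], 0.0, 0.0)

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(InvalidInputError):
            qc(5, 1, 1, 1, 1)


class TestHypergeomPvalue:
    def test_full_support_is_exactly_one(self):
        # K = min(R, U): UR=2, LR=0 -> R=2; UL=0 -> U=2; K=2=min
        assert hypergeom_pvalue(qc(10, 0, 2, 8, 0)) == 1.0

    def test_small_table_matches_term_enumeration(self):
        # N=10, R=4, U=5, K=1
        c = qc(10, 4, 1, 2, 3)
        assert (c.R, c.U, c.K) == (4, 5, 1)
        assert hypergeom_pvalue(c) == pytest.approx(oracle_hypergeom_pvalue(10, 4, 5, 1), rel=1e-12)

    def test_no_methylated_samples_gives_one(self):
        c = qc(20, 12, 0, 8, 0)
        assert c.R == 0 and hypergeom_pvalue(c) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_margins_match_enumeration(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(50):
            n = int(r.integers(2, 61))
            rr = int(r.integers(0, n + 1))
            u = int(r.integers(0, n + 1))
            lo = max(0, rr + u - n)
            k = int(r.integers(lo, min(rr, u) + 1))
            c = qc(n, u - k, k, n - rr - u + k, rr - k)
            assert hypergeom_pvalue(c) == pytest.approx(
                oracle_hypergeom_pvalue(n, rr, u, k), rel=1e-10, abs=1e-300
            )

    def test_agrees_with_scipy_cdf_at_large_n(self):
        for (n, rr, u, k) in [(1000, 300, 400, 50), (100_000, 30_000, 40_000, 10_000)]:
            c = qc(n, u - k, k, n - rr - u + k, rr - k)
            expected = stats.hypergeom.cdf(k, n, u, rr)
            assert hypergeom_pvalue(c) == pytest.approx(expected, rel=1e-8)

    def test_monotone_in_k_with_margins_fixed(self):
        n, rr, u = 40, 15, 18
        prev = -1.0
        for k in range(max(0, rr + u - n), min(rr, u) + 1):
            c = qc(n, u - k, k, n - rr - u + k, rr - k)
            p = hypergeom_pvalue(c)
            assert p >= prev
            prev = p

    def test_permutation_null_is_calibrated(self, rng):
        """Permuting the x-y pairing at fixed margins keeps type-I error at bay."""
        n = 200
        x = np.concatenate([rng.normal(2, 0.5, 100), rng.normal(6, 0.5, 100)])
        y = np.concatenate([rng.beta(2, 30, 120), rng.beta(15, 4, 80)])
        thr_x, thr_y = 4.0, 0.4
        rejections = 0
        n_perm = 2000
        for _ in range(n_perm):
            p = hypergeom_pvalue(quadrant_counts(x, rng.permutation(y), thr_x, thr_y))
            rejections += p < 0.05
        rate = rejections / n_perm
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_perm)


class TestDirectionFilter:
    def test_ten_percent_rule(self):
        assert direction_filter(qc(100, 30, 25, 10, 35)) is True  # 25-10=15 > 10
        assert direction_filter(qc(100, 30, 20, 20, 30)) is False  # difference 0... equal
        assert direction_filter(qc(100, 35, 20, 10, 35)) is False  # exactly 10, not more

    def test_equal_quadrants_retained(self):
        assert direction_filter(qc(40, 10, 10, 10, 10)) is False

    def test_bad_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            direction_filter(qc(4, 1, 1, 1, 1), fraction=1.5)


class TestBonferroni:
    def test_single_test_uncorrected(self):
        assert bonferroni_significant([0.005], alpha=0.01).tolist() == [True]

    def test_two_tests_halve_the_cutoff(self):
        assert bonferroni_significant([0.006, 0.004], alpha=0.01).tolist() == [False, True]

    def test_large_family_cutoff(self, rng):
        m = 11_189
        p = rng.uniform(size=m)
        p[:5] = 1e-8
        flags = bonferroni_significant(p, alpha=0.01)
        cutoff = 0.01 / m
        np.testing.assert_array_equal(flags, p < cutoff)
        assert cutoff == pytest.approx(8.937e-7, rel=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            bonferroni_significant([])


def silencing_xy(rng, n, frac_meth=0.4):
    methylated = rng.random(n) < frac_meth
    beta = np.where(methylated, rng.beta(15, 4, n), rng.beta(2, 30, n))
    high = ~methylated & (rng.random(n) < 0.5)
    x = np.where(high, rng.normal(6, 0.5, n), rng.normal(2, 0.5, n))
    return x, beta


class TestTestPair:
    def test_no_groups_gives_single_pan_result(self, rng):
        x, y = silencing_xy(rng, 300)
        pairs = PairedSeries(x=x, y=y)
        fit = StepMiner2D.from_pairs(pairs).fit()
        res = run_pair_test(pairs, fit)
        assert len(res) == 1 and res[0].group_label == "pan"
        assert res[0].p_value < 1e-6

    def test_group_without_methylated_samples_has_p_one(self, rng):
        n_a, n_b = 200, 150
        xa, ya = silencing_xy(rng, n_a)
        yb = rng.uniform(0.0, 0.05, n_b)  # group B: nobody methylated, well below any threshold
        xb = np.where(rng.random(n_b) < 0.5, rng.normal(6, 0.5, n_b), rng.normal(2, 0.5, n_b))
        pairs = PairedSeries(x=np.concatenate([xa, xb]), y=np.concatenate([ya, yb]))
        fit = StepMiner2D.from_pairs(pairs).fit()
        groups = np.array(["A"] * n_a + ["B"] * n_b)
        res = {r.group_label: r for r in run_pair_test(pairs, fit, groups)}
        assert res["A"].p_value < 1e-6
        assert res["B"].counts.R == 0 and res["B"].p_value == 1.0
        assert res["pan"].p_value < 1e-6

    def test_composition_pattern_pan_only(self, rng):
        """Groups differing jointly in level: pan significant, groups not."""
        n_g = 150
        xs, ys, labels = [], [], []
        for g, meth in [("T1", False), ("T2", True), ("T3", False)]:
            if meth:
                ys.append(rng.beta(15, 4, n_g))
                xs.append(rng.normal(2, 0.5, n_g))
            else:
                ys.append(rng.beta(2, 30, n_g))
                xs.append(rng.normal(6, 0.5, n_g))
            labels += [g] * n_g
        pairs = PairedSeries(x=np.concatenate(xs), y=np.concatenate(ys))
        fit = StepMiner2D.from_pairs(pairs).fit()
        res = {r.group_label: r for r in run_pair_test(pairs, fit, np.array(labels))}
        assert res["pan"].p_value < 1e-10
        for g in ("T1", "T2", "T3"):
            assert res[g].p_value > 0.5

    def test_tiny_group_marked_untestable(self, rng):
        x, y = silencing_xy(rng, 101)
        pairs = PairedSeries(x=x, y=y)
        fit = StepMiner2D.from_pairs(pairs).fit()
        groups = np.array(["A"] * 100 + ["B"])
        res = {r.group_label: r for r in run_pair_test(pairs, fit, groups)}
        assert res["B"].testable is False and np.isnan(res["B"].p_value)

    def test_missing_thresholds_rejected(self, rng):
        x, y = silencing_xy(rng, 50)
        pairs = PairedSeries(x=x, y=y)
        from stepminer2d import build_surface, fit_step_2d

        bare = fit_step_2d(build_surface(pairs, grid_size=5))
        with pytest.raises(InvalidInputError):
            run_pair_test(pairs, bare)

    def test_significance_flag_requires_direction_and_cutoff(self):
        from stepminer2d.silencing import AssociationResult

        r = AssociationResult(
            cpg_id="c", gene_id="g", group_label="pan", threshold_x=0.0, threshold_y=0.0,
            counts=qc(10, 2, 0, 5, 3), p_value=0.001, direction_excluded=False,
        )
        assert r.with_significance(0.01).significant is True
        assert r.with_significance(0.0001).significant is False
        r2 = r.__class__(**{**r.__dict__, "direction_excluded": True})
        assert r2.with_significance(0.01).significant is False
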