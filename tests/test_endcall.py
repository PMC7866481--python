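import numpy as np
import pytest
from scipy import stats

from termini.coverage import CoverageTrack, EndCountMatrix
from termini.endcall import (
    DifferentialEnd,
    FilterConfig,
    PositionTestResult,
    adjust_bh,
    estimate_size_factors,
    filter_positions,
    merge_ends,
    select_and_merge,
    test_positions,
)
from termini.errors import ConfigError, DesignError, InputError
from termini.formats import SampleDesign

test_positions.__test__ = False  # imported callable, not a test case


def make_matrix(counts, positions=None, libs=None):
    counts = np.asarray(counts)
    if positions is None:
        positions = [("chr1", 100 + i, "+") for i in range(counts.shape[0])]
    if libs is None:
        libs = [f"l{j}" for j in range(counts.shape[1])]
    return EndCountMatrix(positions, counts, libs)


def full_tracks_for(matrix, full_value):
    """Constant full coverage at every matrix position, per library."""
    tracks = {}
    maxpos = max(p for _, p, _ in matrix.positions) + 1
    for j, lib in enumerate(matrix.library_ids):
        arr_plus = np.zeros(maxpos + 1, int)
        arr_minus = np.zeros(maxpos + 1, int)
        for i, (_, pos, strand) in enumerate(matrix.positions):
            value = full_value[i][j] if np.ndim(full_value) else full_value
            (arr_plus if strand == "+" else arr_minus)[pos] = value
        tracks[lib] = [
            CoverageTrack("chr1", "+", "full", arr_plus),
            CoverageTrack("chr1", "-", "full", arr_minus),
        ]
    return tracks


class TestFilterPositions:
    def test_end_count_9_everywhere_rejected(self):
        mat = make_matrix([[9, 9, 9]])
        out = filter_positions(mat, full_tracks_for(mat, 20), FilterConfig())
        assert out.n_positions == 0

    def test_ratio_004_rejected(self):
        # only library passing the count filter has end/full = 12/300 = 0.04
        mat = make_matrix([[12, 2, 2]])
        full = [[300, 300, 300]]
        out = filter_positions(mat, full_tracks_for(mat, full), FilterConfig())
        assert out.n_positions == 0

    def test_ratio_012_retained_regardless_of_others(self):
        mat = make_matrix([[12, 0, 0]])
        full = [[100, 1000, 1000]]
        out = filter_positions(mat, full_tracks_for(mat, full), FilterConfig())
        assert out.n_positions == 1

    def test_count_and_ratio_must_pass_in_same_library(self):
        # lib0 passes count (ratio fails), lib1 passes ratio (count fails)
        mat = make_matrix([[12, 9]])
        full = [[1000, 10]]
        out = filter_positions(mat, full_tracks_for(mat, full), FilterConfig())
        assert out.n_positions == 0

    def test_zero_full_coverage_fails_that_library(self):
        mat = make_matrix([[12, 0]])
        full = [[0, 0]]
        out = filter_positions(mat, full_tracks_for(mat, full), FilterConfig())
        assert out.n_positions == 0

    def test_missing_full_track_is_config_error(self):
        mat = make_matrix([[12, 12]])
        tracks = full_tracks_for(mat, 100)
        del tracks["l1"]
        with pytest.raises(ConfigError):
            filter_positions(mat, tracks, FilterConfig())

    def test_monotone_in_thresholds(self, rng):
        mat = make_matrix(rng.integers(0, 40, size=(200, 4)))
        full = rng.integers(1, 400, size=(200, 4))
        tracks = full_tracks_for(mat, full)
        base = filter_positions(mat, tracks, FilterConfig(min_end_count=5, min_ratio=0.02))
        kept_base = set(base.positions)
        for cfg in (
            FilterConfig(min_end_count=10, min_ratio=0.02),
            FilterConfig(min_end_count=5, min_ratio=0.1),
            FilterConfig(min_end_count=12, min_ratio=0.2),
        ):
            kept = set(filter_positions(mat, tracks, cfg).positions)
            assert kept <= kept_base

    def test_row_order_preserved(self, rng):
        mat = make_matrix(rng.integers(0, 40, size=(50, 3)))
        out = filter_positions(mat, full_tracks_for(mat, 50), FilterConfig())
        order = [mat.positions.index(p) for p in out.positions]
        assert order == sorted(order)


class TestSizeFactors:
    def test_two_libraries_a_2a(self):
        mat = make_matrix(np.array([[3, 6], [10, 20], [7, 14], [4, 8]]))
        np.testing.assert_allclose(
            estimate_size_factors(mat), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_identical_libraries_all_one(self, rng):
        col = rng.integers(1, 100, 50)
        mat = make_matrix(np.stack([col] * 4, axis=1))
        np.testing.assert_allclose(estimate_size_factors(mat), np.ones(4), rtol=1e-12)

    def test_random_nb_matrix_matches_direct_formula(self, rng):
        counts = rng.negative_binomial(10, 0.1, size=(300, 6)) + 1
        mat = make_matrix(counts)
        factors = estimate_size_factors(mat)
        # brute-force oracle: row-by-row ratios to the geometric mean
        ratios = []
        for row in counts:
            g = np.exp(np.mean(np.log(row)))
            ratios.append(row / g)
        oracle = np.median(np.array(ratios), axis=0)
        np.testing.assert_allclose(factors, oracle, rtol=1e-12)

    def test_fallback_warns_when_no_positive_row(self):
        counts = np.array([[0, 5], [5, 0], [0, 3]])
        mat = make_matrix(counts)
        with pytest.warns(RuntimeWarning):
            factors = estimate_size_factors(mat)
        totals = counts.sum(axis=0)
        np.testing.assert_allclose(factors, totals / np.exp(np.mean(np.log(totals))))


class TestTestPositions:
    def test_identical_conditions_null(self, design_3v3):
        mat = make_matrix(
            np.array([[30, 30, 30, 30, 30, 30], [7, 7, 7, 7, 7, 7]]),
            libs=[d.library_id for d in design_3v3],
        )
        res = test_positions(mat, design_3v3, size_factors=np.ones(6))
        for r in res:
            assert r.log2fc == 0.0
            assert r.p == 1.0

    def test_poisson_limit_matches_poisson_wald_oracle(self, design_3v3):
        # constant counts within conditions -> pooled variance 0 -> dispersion floored
        mu_a, mu_b = 1000, 1600
        counts = np.array([[mu_a] * 3 + [mu_b] * 3] * 5)
        mat = make_matrix(counts, libs=[d.library_id for d in design_3v3])
        res = test_positions(mat, design_3v3, size_factors=np.ones(6))

        c = 0.5
        lfc = np.log2(mu_b + c) - np.log2(mu_a + c)
        var = (mu_a / 3) / ((mu_a + c) ** 2 * np.log(2) ** 2) + (mu_b / 3) / (
            (mu_b + c) ** 2 * np.log(2) ** 2
        )
        p_oracle = 2 * stats.norm.sf(abs(lfc) / np.sqrt(var))
        for r in res:
            assert r.log2fc == pytest.approx(lfc, abs=1e-12)
            assert r.p == pytest.approx(p_oracle, abs=1e-6)

    def test_null_calibration_and_no_joint_calls(self, design_3v3):
        rng = np.random.default_rng(42)
        lam = rng.gamma(1 / 0.1, 100 * 0.1, size=(2000, 6))
        counts = rng.poisson(lam)
        mat = make_matrix(counts, libs=[d.library_id for d in design_3v3])
        res = test_positions(mat, design_3v3, size_factors=np.ones(6))
        p = np.array([r.p for r in res])
        frac = (p <= 0.05).mean()
        assert 0.03 <= frac <= 0.07
        joint = [
            r for r in res if abs(r.log2fc) >= 1.0 and r.padj <= 0.05
        ]
        assert joint == []

    def test_label_swap_negates_lfc_keeps_p(self, design_3v3, rng):
        counts = rng.poisson(80, size=(100, 6)) + rng.integers(0, 30, size=(100, 6))
        libs = [d.library_id for d in design_3v3]
        mat = make_matrix(counts, libs=libs)
        swapped = [
            SampleDesign(d.library_id,
                         "test" if d.condition == "reference" else "reference",
                         d.replicate_index)
            for d in design_3v3
        ]
        res_a = test_positions(mat, design_3v3, size_factors=np.ones(6))
        res_b = test_positions(mat, swapped, size_factors=np.ones(6))
        for ra, rb in zip(res_a, res_b):
            assert ra.log2fc == pytest.approx(-rb.log2fc, abs=1e-12)
            assert ra.p == pytest.approx(rb.p, abs=1e-12)

    def test_scale_equivariance(self, design_3v3, rng):
        """Scaling one library's counts by lambda scales its factor by lambda
        relative to the others and leaves log2fc invariant up to the
        continuity constant's second-order effect at large means."""
        counts = rng.poisson(500, size=(80, 6)) + 1
        libs = [d.library_id for d in design_3v3]
        mat = make_matrix(counts, libs=libs)
        lam = 4
        scaled = counts.copy()
        scaled[:, 0] *= lam
        mat_scaled = make_matrix(scaled, libs=libs)
        f = estimate_size_factors(mat)
        f_scaled = estimate_size_factors(mat_scaled)
        # relative to an unscaled library the factor moves by exactly lambda
        assert f_scaled[0] / f_scaled[1] == pytest.approx(lam * f[0] / f[1], rel=1e-9)
        res = test_positions(mat, design_3v3, size_factors=f)
        res_scaled = test_positions(mat_scaled, design_3v3, size_factors=f_scaled)
        for ra, rb in zip(res, res_scaled):
            assert ra.log2fc == pytest.approx(rb.log2fc, abs=2e-3)

    def test_single_replicate_condition_rejected(self):
        design = [
            SampleDesign("a", "reference", 1),
            SampleDesign("b", "reference", 2),
            SampleDesign("c", "test", 1),
        ]
        mat = make_matrix(np.array([[5, 5, 5]]), libs=["a", "b", "c"])
        with pytest.raises(DesignError):
            test_positions(mat, design, size_factors=np.ones(3))

    def test_non_integer_counts_rejected(self, design_3v3):
        with pytest.raises(InputError):
            make_matrix(np.full((2, 6), 3.5), libs=[d.library_id for d in design_3v3])


class TestAdjustBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            adjust_bh([0.5, 1.2])

    def test_500_random_match_textbook_oracle(self, rng):
        p = rng.uniform(0, 1, 500)
        adjusted = adjust_bh(p)

        # brute-force textbook oracle (O(n^2) min-scan, no sorting machinery):
        # padj_k = min(1, min over {j : p_j >= p_k} of p_j * m / rank_j)
        m = len(p)
        ranks = np.array([1 + np.sum(p < pk) for pk in p])
        q = p * m / ranks
        oracle = np.array([min(1.0, q[p >= pk].min()) for pk in p])
        np.testing.assert_allclose(adjusted, oracle, rtol=0, atol=0)

    def test_padj_at_least_p(self, rng):
        p = rng.uniform(0, 1, 200)
        assert (adjust_bh(p) >= p).all()


def result(pos, lfc, padj=0.01, strand="+", rep="chr1"):
    return PositionTestResult(rep, pos, strand, basemean=100.0, log2fc=lfc,
                              p=padj, padj=padj)


class TestSelectAndMerge:
    def test_gap_rule_merges_into_one_end(self):
        res = [result(100, 6.0), result(102, 4.0), result(106, 5.0)]
        (end,) = select_and_merge(res, FilterConfig())
        assert (end.start, end.end) == (100, 107)
        assert end.distribution_size == 7
        assert end.n_positions == 3
        assert end.mean_log2fc == pytest.approx(5.0)
        assert end.direction == "enriched"

    def test_gap_4_stays_separate(self):
        res = [result(100, 2.0), result(105, 2.0)]
        ends = select_and_merge(res, FilterConfig())
        assert len(ends) == 2
        assert all(e.distribution_size == 1 for e in ends)

    def test_thresholds_applied(self):
        res = [
            result(10, 0.9),            # |lfc| below cutoff
            result(20, 1.0, padj=0.05),  # inclusive boundaries: kept
            result(30, -3.0, padj=0.06),  # padj above alpha
        ]
        ends = select_and_merge(res, FilterConfig())
        assert [(e.start, e.end) for e in ends] == [(20, 21)]

    def test_strands_never_merge(self):
        res = [result(100, 5.0, strand="+"), result(101, 5.0, strand="-")]
        ends = select_and_merge(res, FilterConfig())
        assert len(ends) == 2

    def test_mixed_sign_flagged(self):
        res = [result(100, 5.0), result(101, -5.0)]
        (end,) = select_and_merge(res, FilterConfig())
        assert end.mixed_sign
        assert end.mean_log2fc == pytest.approx(0.0)

    def test_1000_random_positions_match_union_find_oracle(self, rng):
        positions = sorted(set(rng.integers(0, 5000, 1000).tolist()))
        res = [result(int(p), 3.0) for p in positions]
        ends = select_and_merge(res, FilterConfig())

        # union-find oracle
        parent = list(range(len(positions)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(positions) - 1):
            if positions[i + 1] - positions[i] - 1 <= 3:
                parent[find(i + 1)] = find(i)
        groups = {}
        for i, p in enumerate(positions):
            groups.setdefault(find(i), []).append(p)
        oracle = sorted((min(g), max(g) + 1) for g in groups.values())
        assert [(e.start, e.end) for e in ends] == oracle
        # resulting ends pairwise separated by gap > 3
        for a, b in zip(ends, ends[1:]):
            assert b.start - a.end > 3

    def test_merge_idempotent(self, rng):
        positions = sorted(set(rng.integers(0, 3000, 400).tolist()))
        ends = select_and_merge([result(int(p), 2.0) for p in positions], FilterConfig())
        again = merge_ends(ends, merge_distance=3)
        assert [(e.start, e.end, e.n_positions) for e in again] == [
            (e.start, e.end, e.n_positions) for e in ends
        ]

    def test_nan_padj_dropped_with_warning(self):
        res = [result(10, 5.0), result(50, 5.0, padj=float("nan"))]
        with pytest.warns(RuntimeWarning):
            ends = select_and_merge(res, FilterConfig())
        assert [(e.start, e.end) for e in ends] == [(10, 11)]


class TestFilterConfig:
    def test_alpha_bounds(self):
        with pytest.raises(ConfigError):
            FilterConfig(alpha=0.0)
        with pytest.raises(ConfigError):
            FilterConfig(alpha=1.5)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigError):
            FilterConfig(min_ratio=-0.1)
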