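"""Correlation maps: textbook-formula oracles, invariances, significance."""

import numpy as np
import pytest
from scipy import stats

from ecomics.fixtures import gen_correlated_matrices
from ecomics.hetmap import (
    CorrelationMap,
    build_hetmap,
    correlate,
    critical_r,
    r_distribution,
    top_pairs,
)
from ecomics.io_formats import SampleMatrix


def textbook_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _mat(label, rows, n=5, seed=0):
    rng = np.random.default_rng(seed)
    return SampleMatrix(
        [f"{label}{i + 1}" for i in range(rows)],
        [f"S{j + 1}" for j in range(n)],
        rng.normal(size=(rows, n)),
        block_label=label,
    )


class TestCorrelate:
    def test_perfect_linear(self):
        assert correlate([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert correlate([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_spearman_monotone_nonlinear(self):
        assert correlate([1, 2, 3], [1, 8, 27], "spearman") == pytest.approx(1.0)

    def test_cosine_orthogonal_and_identity(self):
        assert correlate([1, 0], [0, 1], "cosine") == pytest.approx(0.0)
        x = [3.0, 1.0, 2.0]
        assert correlate(x, x, "cosine") == pytest.approx(1.0)

    def test_undefined_inputs_give_nan_not_exception(self):
        assert np.isnan(correlate([1, 1, 1], [1, 2, 3]))
        assert np.isnan(correlate([1, 1, 1], [1, 2, 3], "spearman"))
        assert np.isnan(correlate([0, 0, 0], [1, 2, 3], "cosine"))

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            correlate([1], [2])

    @pytest.mark.parametrize("seed", range(10))
    def test_against_textbook_formulas(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=9), rng.normal(size=9)
        assert correlate(x, y) == pytest.approx(textbook_pearson(x, y), abs=1e-12)
        assert correlate(x, y, "spearman") == pytest.approx(
            textbook_pearson(stats.rankdata(x), stats.rankdata(y)), abs=1e-12
        )
        assert correlate(x, y, "cosine") == pytest.approx(
            float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y))), abs=1e-12
        )

    def test_invariances(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = correlate(x, y)
        # pearson: affine with positive scale invariant; sign flips under negative
        assert correlate(3.2 * x + 5, y) == pytest.approx(r, abs=1e-12)
        assert correlate(-2.0 * x + 1, y) == pytest.approx(-r, abs=1e-12)
        # spearman: invariant under strictly monotone transforms
        rs = correlate(x, y, "spearman")
        assert correlate(np.exp(x), y, "spearman") == pytest.approx(rs, abs=1e-12)
        # cosine: invariant under positive scaling
        rc = correlate(x, y, "cosine")
        assert correlate(7.0 * x, 0.1 * y, "cosine") == pytest.approx(rc, abs=1e-12)


class TestBuildHetmap:
    def test_four_block_size_arithmetic(self):
        mats = [_mat(l, r, seed=i) for i, (l, r) in enumerate([("A", 3), ("B", 2), ("C", 4), ("D", 1)])]
        cmap = build_hetmap(mats)
        assert cmap.size == 10
        assert cmap.labels[0] == "A:A1" and cmap.labels[-1] == "D:D1"
        assert [b[0] for b in cmap.blocks] == ["A", "B", "C", "D"]
        np.testing.assert_allclose(cmap.values, cmap.values.T)

    def test_duplicated_row_has_unit_offdiagonal(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=6)
        m = SampleMatrix(["a", "b"], [f"S{i}" for i in range(6)], np.vstack([row, row]))
        cmap = build_hetmap(m)
        assert cmap.values[0, 1] == pytest.approx(1.0)

    def test_stocsy_self_correlation_23_rows(self):
        """Single 23-row ROI matrix -> 23x23 self-correlation map."""
        m = _mat("roi", 23, n=11, seed=5)
        cmap = build_hetmap(m, method="pearson")
        assert cmap.size == 23
        assert np.allclose(np.diag(cmap.values), 1.0)

    def test_column_count_rule_enforced(self):
        with pytest.raises(ValueError, match="same for all"):
            build_hetmap([_mat("A", 2, n=5), _mat("B", 2, n=6)])

    def test_too_many_matrices_rejected(self):
        mats = [_mat(f"B{i}", 1, seed=i) for i in range(5)]
        with pytest.raises(ValueError, match="1 and 4"):
            build_hetmap(mats)

    def test_duplicate_prefixed_labels_rejected(self):
        a1 = _mat("A", 2, seed=0)
        a2 = _mat("A", 2, seed=1)
        with pytest.raises(ValueError, match="duplicate"):
            build_hetmap([a1, a2])

    def test_strict_header_match_flag(self):
        a = _mat("A", 2, seed=0)
        b = _mat("B", 2, seed=1)
        b.sample_labels = [f"T{j}" for j in range(5)]
        build_hetmap([a, b])  # positional alignment: fine
        with pytest.raises(ValueError, match="labels differ"):
            build_hetmap([a, b], require_matching_columns=True)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "cosine"])
    def test_blocks_equal_preconcatenation(self, method):
        """Block structure affects labels only, never the r values."""
        mats = [_mat("A", 3, seed=1), _mat("B", 4, seed=2)]
        stacked = SampleMatrix(
            [f"x{i}" for i in range(7)],
            mats[0].sample_labels,
            np.vstack([m.values for m in mats]),
            block_label="all",
        )
        np.testing.assert_allclose(
            build_hetmap(mats, method).values,
            build_hetmap(stacked, method).values,
            atol=1e-12,
        )

    @pytest.mark.parametrize("method", ["pearson", "spearman", "cosine"])
    def test_matrix_entries_match_pairwise_correlate(self, method):
        mats = [_mat("A", 3, seed=3), _mat("B", 3, seed=4)]
        cmap = build_hetmap(mats, method)
        rows = np.vstack([m.values for m in mats])
        for i in range(6):
            for j in range(6):
                assert cmap.values[i, j] == pytest.approx(
                    correlate(rows[i], rows[j], method), abs=1e-10
                )

    def test_constant_row_marked_undefined(self):
        m = SampleMatrix(
            ["flat", "x"], ["S1", "S2", "S3"], np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        )
        cmap = build_hetmap(m)
        assert np.isnan(cmap.values[0, 1]) and np.isnan(cmap.values[0, 0])
        assert cmap.values[1, 1] == 1.0


class TestCriticalR:
    def test_n7_alpha05_is_075_to_two_decimals(self):
        assert round(critical_r(7, 0.05), 2) == 0.75

    def test_closed_form_t_relation(self):
        for n, alpha in [(5, 0.05), (7, 0.05), (12, 0.01), (100, 0.1)]:
            t_star = stats.t.ppf(1 - alpha / 2, n - 2)
            expect = t_star / np.sqrt(n - 2 + t_star**2)
            assert critical_r(n, alpha) == pytest.approx(expect, abs=1e-10)

    def test_monotone_in_n(self):
        assert critical_r(100, 0.05) < critical_r(10, 0.05)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2, 0.05)

    def test_bonferroni_flag_tightens(self):
        assert critical_r(7, 0.05, n_tests=10) > critical_r(7, 0.05)

    def test_monte_carlo_null_calibration(self):
        """Fraction of independent Gaussian pairs at n=7 with |r| above the
        critical value matches alpha = 0.05 within +-0.005."""
        rng = np.random.default_rng(2024)
        n_rep, n = 100_000, 7
        x = rng.standard_normal((n_rep, n))
        y = rng.standard_normal((n_rep, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        frac = np.mean(np.abs(r) > critical_r(n, 0.05))
        assert frac == pytest.approx(0.05, abs=0.005)


class TestTopPairs:
    def _map(self, values, labels=None):
        values = np.asarray(values, float)
        labels = labels or [f"b:r{i}" for i in range(values.shape[0])]
        return CorrelationMap(labels, values, "pearson", 7, [("b", 0, values.shape[0])])

    def test_single_qualifying_pair(self):
        cmap = self._map([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        pairs = top_pairs(cmap, 0.75)
        assert len(pairs) == 1
        assert (pairs[0].label_a, pairs[0].label_b, pairs[0].r) == ("b:r0", "b:r1", 0.9)

    def test_cutoff_is_strict(self):
        cmap = self._map([[1.0, 0.75], [0.75, 1.0]])
        assert top_pairs(cmap, 0.75) == []
        assert top_pairs(cmap, 1.0) == []  # even perfect self-correlation is diagonal-only

    def test_sorted_by_abs_r_with_negatives(self):
        cmap = self._map(
            [[1.0, -0.95, 0.8], [-0.95, 1.0, 0.1], [0.8, 0.1, 1.0]]
        )
        pairs = top_pairs(cmap, 0.75)
        assert [p.r for p in pairs] == [-0.95, 0.8]

    def test_k_truncation_and_nan_exclusion(self):
        vals = np.array([[1.0, 0.9, np.nan], [0.9, 1.0, 0.85], [np.nan, 0.85, 1.0]])
        pairs = top_pairs(self._map(vals), 0.5, k=1)
        assert len(pairs) == 1 and pairs[0].abs_r == 0.9

    def test_planted_pair_ranks_first(self):
        mats, truth = gen_correlated_matrices(
            [("A", 4), ("B", 4)], [("A1", "B1", 1)], n_samples=7, noise_sd=0.05, seed=42
        )
        cmap = build_hetmap(mats)
        pairs = top_pairs(cmap, critical_r(7, 0.05))
        assert (pairs[0].label_a, pairs[0].label_b) == ("A:A1", "B:B1")


class TestRDistribution:
    def test_identical_rows_mass_at_one(self):
        row = np.array([1.0, 2.0, 3.0, 2.5])
        m = SampleMatrix(["a", "b"], list("wxyz"), np.vstack([row, row]))
        fracs, empty = r_distribution(build_hetmap(m), n_bins=10)
        assert not empty
        assert fracs[-1] == 1.0  # bin containing r = 1 (last bin closed)

    def test_empty_map_flagged(self):
        m = SampleMatrix(["a", "b"], list("xyz"), np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]))
        fracs, empty = r_distribution(build_hetmap(m))
        assert empty and fracs.sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_histogram_oracle_and_normalizes(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        m = SampleMatrix(
            [f"r{i}" for i in range(k)], [f"s{j}" for j in range(9)], rng.normal(size=(k, 9))
        )
        cmap = build_hetmap(m)
        n_bins = int(rng.integers(2, 25))
        fracs, empty = r_distribution(cmap, n_bins)
        assert not empty
        assert fracs.sum() == pytest.approx(1.0, abs=1e-12)
        # brute-force histogram over the upper triangle
        vals = [cmap.values[i, j] for i in range(k) for j in range(i + 1, k)]
        edges = np.linspace(-1, 1, n_bins + 1)
        expect = np.zeros(n_bins)
        for v in vals:
            for b in range(n_bins):
                if (edges[b] <= v < edges[b + 1]) or (b == n_bins - 1 and v <= edges[b + 1]):
                    expect[b] += 1
                    break
        np.testing.assert_allclose(fracs, expect / expect.sum(), atol=1e-12)
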