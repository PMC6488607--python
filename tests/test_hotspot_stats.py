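import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from phosfam.errors import ValidationError
from phosfam.hotspot_stats import (
    HotspotParams,
    bonferroni_threshold,
    call_hotspots,
    family_profile,
    merge_significant_columns,
    null_stats,
    null_window_profiles,
    permute_sites,
    position_pvalues,
    sliding_window_mean,
    window_profile,
)
from conftest import build_alignment
from _oracles import enumerate_null_profiles


class TestWindowProfile:
    def test_center_column_hand_sum(self):
        n = np.array([0, 0, 3, 1, 0, 0, 0])
        W = sliding_window_mean(n, 5)
        assert W[2] == pytest.approx(4 / 5)

    def test_truncated_edge_window(self):
        n = np.array([0, 0, 3, 1, 0, 0, 0])
        W = sliding_window_mean(n, 5)
        assert W[0] == pytest.approx(3 / 3)  # columns 1..3 only
        assert W[-1] == pytest.approx(0.0)

    def test_all_zero(self):
        assert sliding_window_mean(np.zeros(9), 5).tolist() == [0.0] * 9

    def test_matches_naive_loop(self, rng):
        x = rng.poisson(2.0, size=37).astype(float)
        for w in (1, 3, 5, 7):
            W = sliding_window_mean(x, w)
            half = w // 2
            naive = [
                x[max(0, i - half) : min(len(x), i + half + 1)].mean()
                for i in range(len(x))
            ]
            np.testing.assert_allclose(W, naive)

    def test_empty_alignment_rejected(self):
        aln = build_alignment({"a": "MKS"}, {})
        aln.row_ids = ()
        with pytest.raises(ValidationError):
            window_profile(aln, 5)


class TestPermuteSites:
    def test_forced_placement(self, rng):
        aln = build_alignment({"a": "MKS", "b": "MKS"}, {"a": [3]})
        params = HotspotParams()
        for _ in range(5):
            placed = permute_sites(aln, params, rng)
            assert [(c, r) for _g, c, r in placed] == [(3, "S")]

    def test_uniform_over_acceptors(self, rng):
        aln = build_alignment({"a": "SASAS"}, {"a": [1]})
        params = HotspotParams()
        counts = {1: 0, 3: 0, 5: 0}
        n = 3000
        for _ in range(n):
            (_g, col, _r), = permute_sites(aln, params, rng)
            counts[col] += 1
        for col in counts:
            assert counts[col] / n == pytest.approx(1 / 3, abs=0.03)

    def test_per_type_totals_conserved(self, rng):
        aln = build_alignment(
            {"a": "STYSA", "b": "SSTYY"}, {"a": [1, 3], "b": [2, 4]}
        )
        observed = {}
        for pairs in aln.sites.values():
            for _c, r in pairs:
                observed[r] = observed.get(r, 0) + 1
        for scope in ("per_sequence", "per_alignment"):
            params = HotspotParams(permutation_scope=scope)
            placed = permute_sites(aln, params, rng)
            got = {}
            for _g, _c, r in placed:
                got[r] = got.get(r, 0) + 1
            assert got == observed

    def test_per_row_totals_conserved_in_sequence_scope(self, rng):
        aln = build_alignment({"a": "SSSTT", "b": "SSTTT"}, {"a": [1, 4], "b": [3]})
        params = HotspotParams()
        placed = permute_sites(aln, params, rng)
        per_row = {}
        for g, _c, _r in placed:
            rid = g.rsplit(":", 1)[0]
            per_row[rid] = per_row.get(rid, 0) + 1
        assert per_row == {"a/1-5": 2, "b/1-5": 1}


class TestNullStats:
    def test_saturated_alignment_degenerates(self):
        # every acceptor phosphorylated: all permutations identical
        aln = build_alignment({"a": "SAS", "b": "ASA"}, {"a": [1, 3], "b": [2]})
        params = HotspotParams(permutations=20, rng_seed=7)
        m, s = null_stats(aln, params)
        np.testing.assert_array_equal(s, 0.0)
        np.testing.assert_allclose(m, window_profile(aln, params.window))

    def test_bit_reproducible(self):
        aln = build_alignment(
            {"a": "SATAYSS", "b": "SSTAYA-"}, {"a": [1, 5], "b": [3]}
        )
        params = HotspotParams(permutations=50, rng_seed=11)
        m1, s1 = null_stats(aln, params)
        m2, s2 = null_stats(aln, params)
        assert np.array_equal(m1, m2) and np.array_equal(s1, s2)

    def test_matches_exhaustive_enumeration(self):
        """Sampled null median/sd vs the exact placement distribution."""
        aln = build_alignment({"a": "SASAS--T", "b": "-ASATTYA"}, {"a": [1], "b": [5]})
        params = HotspotParams(permutations=10_000, rng_seed=3)
        exact = enumerate_null_profiles(aln, params)
        m_exact = np.median(exact, axis=0)
        s_exact = exact.std(axis=0)
        m, s = null_stats(aln, params)
        B = params.permutations
        delta = 3 * np.sqrt(0.25 / B)
        lo = np.quantile(exact, 0.5 - delta, axis=0, method="lower")
        hi = np.quantile(exact, 0.5 + delta, axis=0, method="higher")
        assert np.all(m >= lo - 1e-12) and np.all(m <= hi + 1e-12)
        mu = exact.mean(axis=0)
        mu4 = ((exact - mu) ** 4).mean(axis=0)
        var = exact.var(axis=0)
        # finite-sample Var(S^2) = (mu4 - sigma^4 (B-3)/(B-1)) / B
        var_s2 = np.maximum(mu4 - var**2 * (B - 3) / (B - 1), 0.0) / B
        se_sd = np.zeros_like(var)
        live = var > 0
        se_sd[live] = np.sqrt(var_s2[live]) / (2 * np.sqrt(var[live]))
        assert np.all(np.abs(s - s_exact) <= 3 * se_sd + 1e-9)

    def test_population_sd_divisor(self):
        aln = build_alignment({"a": "SAS"}, {"a": [1]})
        params = HotspotParams(permutations=4, rng_seed=0)
        rng = np.random.default_rng(0)
        profiles = null_window_profiles(aln, params, rng)
        _m, s = null_stats(aln, params)
        np.testing.assert_allclose(s, profiles.std(axis=0, ddof=0))


class TestPositionPvalues:
    def test_center_and_tail(self):
        z, p = position_pvalues(
            np.array([1.0, 3.0]), np.array([1.0, 1.0]), np.array([0.5, 1.0]), 100
        )
        assert p[0] == pytest.approx(0.5)
        assert z[1] == pytest.approx(2.0)
        assert p[1] == pytest.approx(0.0227501, abs=1e-6)

    def test_degenerate_conventions(self):
        z, p = position_pvalues(
            np.array([1.0, 2.0, 0.5]),
            np.array([1.0, 1.0, 1.0]),
            np.array([0.0, 0.0, 0.0]),
            100,
        )
        assert p[0] == 1.0           # s=0, W == m
        assert p[1] == pytest.approx(1 / 101)  # s=0, W > m
        assert p[2] == 1.0           # s=0, W < m (depletion never flagged)
        assert z[1] == np.inf

    def test_depletion_never_significant(self):
        z, p = position_pvalues(np.array([0.0]), np.array([5.0]), np.array([1.0]), 100)
        assert p[0] == pytest.approx(norm.sf(-5.0))
        assert p[0] > 0.999

    @given(st.floats(0.1, 5.0), st.floats(0.0, 3.0), st.floats(0.05, 2.0))
    def test_monotone_in_observed_density(self, m, w, s):
        """More phosphosites in a window never increases the p-value."""
        _z, p = position_pvalues(
            np.array([w, w + 0.5]), np.array([m, m]), np.array([s, s]), 100
        )
        assert p[1] <= p[0]


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, n, expected",
        [(0.01, 100, 1e-4), (0.05, 1, 0.05), (0.01, 149_254, 6.70e-8)],
    )
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-3)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.01, 0)


class TestRegionCalling:
    def test_run_extension(self):
        regions = merge_significant_columns([10, 11, 12], 100, 2)
        assert regions == [(8, 14, (10, 11, 12))]

    def test_boundary_clipping(self):
        regions = merge_significant_columns([5], 6, 2)
        assert regions == [(3, 6, (5,))]

    def test_touching_extended_intervals_merge(self):
        regions = merge_significant_columns([10, 11, 15], 100, 2)
        assert regions == [(8, 17, (10, 11, 15))]

    def test_no_significant_columns(self):
        assert merge_significant_columns([], 50, 2) == []

    def test_effect_size_filter_blocks_low_density_columns(self):
        aln = build_alignment(
            {f"r{i}": "SAAAAAAS" for i in range(3)}, {f"r{i}": [1] for i in range(3)}
        )
        params = HotspotParams(permutations=30, effect_min=100.0, rng_seed=5)
        prof = family_profile(aln, params)
        regions, _thr, _n = call_hotspots({"FAM": prof}, params)
        assert regions == []

    def test_region_summaries_cover_significant_columns(self):
        rows = {f"r{i}": "SSAAAAAAAASS" for i in range(6)}
        sites = {f"r{i}": [1, 2] for i in range(6)}
        aln = build_alignment(rows, sites)
        params = HotspotParams(permutations=200, alpha=0.5, effect_min=0.5, rng_seed=9)
        prof = family_profile(aln, params)
        regions, thr, n_tests = call_hotspots({"FAM": prof}, params)
        assert n_tests == 12
        for r in regions:
            assert r.start_col <= min(r.significant_cols)
            assert r.end_col >= max(r.significant_cols)
            idx = [c - 1 for c in r.significant_cols]
            assert r.min_p == pytest.approx(min(prof.p[idx]))
            assert r.mean_W == pytest.approx(np.mean(prof.W[idx]))
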