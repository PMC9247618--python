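"""sPCA, Spearman machinery, effect sizes, pooled BH and the scan wiring."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from chemobiome.correlation import (bh_adjust, correlated_read_fraction,
                                    gate_pcs, group_effect_size, pc_anova,
                                    quartile_effect_size, run_correlation_scan,
                                    spca, spearman_matrix, spearman_test)


class TestSpca:
    def test_dense_path_matches_eigendecomposition(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.normal(size=(20, 8))
            X -= X.mean(0)
            res = spca(X, 4)
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            ref = U[:, :4] * s[:4]
            for j in range(4):
                got = res.scores.to_numpy()[:, j]
                assert (np.allclose(got, ref[:, j], atol=1e-8)
                        or np.allclose(got, -ref[:, j], atol=1e-8))

    def test_loading_columns_unit_norm(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 10))
        for keep in (None, 4):
            res = spca(X - X.mean(0), 3, keep_per_component=keep)
            norms = np.linalg.norm(res.loadings.to_numpy(), axis=0)
            assert np.allclose(norms, 1.0, atol=1e-12)

    def test_sparsity_limits_active_variables(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 12))
        res = spca(X - X.mean(0), 3, keep_per_component=4)
        active = (np.abs(res.loadings.to_numpy()) > 1e-12).sum(axis=0)
        assert (active <= 4).all()

    def test_too_many_components_raises(self):
        with pytest.raises(ValueError):
            spca(np.zeros((4, 3)) + np.eye(4, 3), 5)


class TestGate:
    def test_threshold_rule(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        res = spca(X - X.mean(0), 3)
        res.variance_fraction = np.array([0.50, 0.30, 0.02])
        assert gate_pcs(res) == ["PC1", "PC2"]

    def test_all_below_gate_warns_empty(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        res = spca(X - X.mean(0), 2)
        res.variance_fraction = np.array([0.01, 0.005])
        with pytest.warns(UserWarning):
            assert gate_pcs(res) == []


class TestPcAnova:
    def test_constant_scores(self):
        assert pc_anova([1.0] * 8, ["a"] * 4 + ["b"] * 4) == (0.0, 1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 32), rng.normal(5, 1, 32)])
        g = ["a"] * 32 + ["b"] * 32
        _, p = pc_anova(y, g)
        assert p < 1e-6

    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = [pc_anova(rng.normal(size=24), ["a"] * 8 + ["b"] * 8 + ["c"] * 8)[1]
              for _ in range(200)]
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_level_raises(self):
        with pytest.raises(ValueError):
            pc_anova([1.0, 2.0], ["a", "a"])


def _naive_spearman(x, y):
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_test(x, x)[0] == pytest.approx(1.0)
        assert spearman_test(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_example_matches_rank_oracle(self):
        x = [1, 2, 2, 3, 5]
        y = [1, 3, 2, 4, 4]
        rho, _, _ = spearman_test(x, y)
        assert rho == pytest.approx(_naive_spearman(x, y), abs=1e-12)

    def test_ci_brackets_rho(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 1, 40)
        rho, p, (lo, hi) = spearman_test(x, y)
        assert lo <= rho <= hi

    def test_bootstrap_ci_reproducible(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 2, 30)
        a = spearman_test(x, y, ci_method="bootstrap", seed=42)
        b = spearman_test(x, y, ci_method="bootstrap", seed=42)
        assert a == b

    def test_zero_variance_returns_nan(self):
        rho, p, _ = spearman_test([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(rho)

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.integers(0, 5, (20, 4)).astype(float))
        Y = pd.DataFrame(rng.normal(size=(20, 3)))
        rho, p = spearman_matrix(X, Y)
        for i in X.columns:
            for j in Y.columns:
                r_ref, p_ref = scipy.stats.spearmanr(X[i], Y[j])
                assert rho.loc[i, j] == pytest.approx(r_ref, abs=1e-12)
                assert p.loc[i, j] == pytest.approx(p_ref, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(size=25)
        y = rng.normal(size=25)
        r1 = spearman_test(x, y)[0]
        r2 = spearman_test(np.log(x), y)[0]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestEffectSizes:
    def test_quartile_hand_example(self):
        v = np.arange(1, 17, dtype=float)
        # Q1 mean 2.5, Q4 mean 14.5, sample SD of 1..16 = sqrt(16*17/12)
        expected = 12.0 / np.sqrt(16 * 17 / 12)
        assert quartile_effect_size(v, v) == pytest.approx(expected, abs=1e-9)
        assert quartile_effect_size(v, v) == pytest.approx(2.52, abs=0.01)

    def test_quartile_constant_fungal_zero(self):
        assert quartile_effect_size(np.arange(8.0), np.ones(8)) == 0.0

    def test_quartile_symmetric_under_chem_reversal(self):
        rng = np.random.default_rng(11)
        chem = rng.normal(size=16)
        fungal = rng.normal(size=16)
        assert quartile_effect_size(chem, fungal) == pytest.approx(
            quartile_effect_size(-chem, fungal), abs=1e-12)

    def test_group_hand_example(self):
        vals = [0, 0, 0, 1, 1, 1]
        es = group_effect_size(vals, ["a"] * 3 + ["b"] * 3)
        assert es == pytest.approx(1.0 / np.std(vals, ddof=1), abs=1e-12)
        assert es == pytest.approx(1.826, abs=0.001)

    def test_group_equal_means_zero(self):
        assert group_effect_size([1, 2, 1, 2], ["a", "a", "b", "b"]) == 0.0

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_group_scale_invariant(self, k):
        vals = np.array([0.0, 1.0, 2.0, 5.0, 3.0, 4.0])
        groups = ["a", "a", "a", "b", "b", "b"]
        assert group_effect_size(vals * k, groups) == pytest.approx(
            group_effect_size(vals, groups), rel=1e-9)


def _naive_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj


class TestBH:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04, atol=1e-12)

    def test_equal_and_single(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(bh_adjust(p), _naive_bh(p), atol=1e-12)

    def test_order_preserving(self):
        # sorting by raw p sorts the adjusted values monotonically
        rng = np.random.default_rng(13)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _toy_scan(seed=0, n=24, with_factors=False):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    comp = rng.dirichlet(np.ones(6), size=n)
    from chemobiome.community import clr as _clr, ilr as _ilr
    fungal_clr = {"genus": pd.DataFrame(_clr(comp), index=samples,
                                        columns=[f"g{i}" for i in range(6)])}
    fungal_ilr = {"genus": pd.DataFrame(_ilr(comp), index=samples)}
    chem = pd.DataFrame(rng.lognormal(size=(n, 8)), index=samples,
                        columns=[f"F{i}" for i in range(8)])
    annotated = pd.Series([True] * 4 + [False] * 4, index=chem.columns)
    diversity = pd.DataFrame({"shannon": rng.normal(size=n)}, index=samples)
    factors = None
    if with_factors:
        factors = pd.DataFrame({"accession": (["a"] * (n // 2) + ["b"] * (n // 2))},
                               index=samples)
    return fungal_clr, fungal_ilr, chem, annotated, diversity, factors


class TestScan:
    def test_diversity_only_in_rawcordf(self):
        args = _toy_scan(seed=1)
        res = run_correlation_scan(*args)
        div = res.records[res.records["fungal_level"] == "diversity"]
        assert len(div) > 0
        assert set(div["approach"]) == {"rawcordf"}

    def test_direct_tests_respect_feature_restriction(self):
        fungal_clr, fungal_ilr, chem, annotated, diversity, _ = _toy_scan(seed=2)
        res = run_correlation_scan(fungal_clr, fungal_ilr, chem,
                                   annotated=annotated, diversity=diversity)
        raw = res.records[res.records["approach"] == "rawcordf"]
        mean = chem.mean(axis=0)
        rsd = chem.std(axis=0, ddof=1) / mean
        allowed = set(chem.columns[annotated | (rsd > 0.66)])
        assert set(raw["chem_id"]) <= allowed

    def test_pooled_family_counts_all_tests(self):
        fungal_clr, fungal_ilr, chem, annotated, diversity, factors = _toy_scan(
            seed=3, with_factors=True)
        extra = [0.2, 0.4]
        res = run_correlation_scan(fungal_clr, fungal_ilr, chem,
                                   annotated=annotated, diversity=diversity,
                                   factors=factors, extra_pvalues=extra)
        assert res.pooled_n == len(res.records) + len(res.anova) + len(extra)
        assert res.extra_n == 2
        assert (res.records["p_adj"] >= res.records["p"] - 1e-15).all()

    def test_rawcordf_records_carry_effect_sizes(self):
        res = run_correlation_scan(*_toy_scan(seed=4))
        raw = res.records[res.records["approach"] == "rawcordf"]
        other = res.records[res.records["approach"] != "rawcordf"]
        assert raw["effect_size"].notna().all()
        assert (raw["effect_size"] >= 0).all()
        assert other["effect_size"].isna().all()

    def test_misaligned_samples_raise(self):
        fungal_clr, fungal_ilr, chem, annotated, diversity, _ = _toy_scan(seed=5)
        chem_bad = chem.copy()
        chem_bad.index = [f"x{i}" for i in range(len(chem_bad))]
        with pytest.raises(ValueError, match="misaligned"):
            run_correlation_scan(fungal_clr, fungal_ilr, chem_bad,
                                 annotated=annotated)

    def test_scan_reproducible_under_seed(self):
        args = _toy_scan(seed=6)
        a = run_correlation_scan(*args, seed=9)
        b = run_correlation_scan(*args, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestReadFraction:
    def _records(self, sig_taxa):
        return pd.DataFrame({
            "approach": ["rawcordf"] * len(sig_taxa),
            "fungal_level": ["genus"] * len(sig_taxa),
            "fungal_id": sig_taxa,
            "chem_id": ["F1"] * len(sig_taxa),
            "significant": [True] * len(sig_taxa),
        })

    def test_all_taxa_significant_is_one(self):
        counts = pd.DataFrame({"g1": [5, 5], "g2": [3, 7]})
        assert correlated_read_fraction(self._records(["g1", "g2"]), counts,
                                        "genus") == 1.0

    def test_no_significant_is_zero(self):
        counts = pd.DataFrame({"g1": [5, 5]})
        assert correlated_read_fraction(self._records([]), counts, "genus") == 0.0

    def test_partial_fraction(self):
        counts = pd.DataFrame({"g1": [6, 4], "g2": [3, 7]})
        assert correlated_read_fraction(self._records(["g1"]), counts,
                                        "genus") == pytest.approx(0.5)

    def test_unknown_taxon_raises(self):
        counts = pd.DataFrame({"g1": [5, 5]})
        with pytest.raises(ValueError):
            correlated_read_fraction(self._records(["gX"]), counts, "genus")
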