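"""ASV filtering, aggregation, zero imputation and log-ratio geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemobiome.community import (aggregate_taxa, bayesian_multiplicative_replace,
                                  clr, default_prevalence_grid, filter_control_asvs,
                                  filter_taxonomy, ilr, ilr_basis, ilr_inverse,
                                  optimize_prevalence_filter, RANKS)

from .conftest import make_asv_table


class TestControlFilter:
    def _table(self, control_counts, real_counts):
        counts = np.vstack([real_counts, control_counts])
        return make_asv_table(counts, ["horseradish_site1", "negative_control"][::1]
                              if len(counts) == 2 else None)

    @pytest.mark.parametrize("ctrl_row, discarded", [
        # control total 2000: 30 reads (1.5%) -> discarded
        ([30, 1970], ["asv0"]),
        # 20 reads (1.0%) fails the read minimum -> kept
        ([20, 1980], []),
    ])
    def test_rule_small_control(self, ctrl_row, discarded):
        table = make_asv_table([[100, 100], ctrl_row],
                               ["horseradish_site1", "negative_control"])
        _, got = filter_control_asvs(table)
        assert sorted(set(got) - {"asv1"}) == discarded

    def test_rule_large_control_fraction_minimum(self):
        # control total 20000: 30 reads is 0.15% -> kept
        table = make_asv_table([[100, 100], [30, 19970]],
                               ["horseradish_site1", "negative_control"])
        filtered, got = filter_control_asvs(table)
        assert "asv0" not in got
        assert "asv0" in filtered.counts.columns

    def test_no_controls_warns_noop(self):
        table = make_asv_table([[5, 5]], ["horseradish_site1"])
        with pytest.warns(UserWarning):
            filtered, got = filter_control_asvs(table)
        assert got == []
        assert filtered.counts.equals(table.counts)

    def test_sample_order_invariance(self, full_dataset):
        _, _, asv, _ = full_dataset
        _, base = filter_control_asvs(asv)
        perm = asv.subset_samples(list(asv.counts.index)[::-1])
        _, flipped = filter_control_asvs(perm)
        assert base == flipped

    def test_recovers_planted_contaminants(self, full_dataset):
        _, _, asv, truth = full_dataset
        _, discarded = filter_control_asvs(asv)
        assert sorted(discarded) == sorted(truth.expected_discarded_asvs)


class TestTaxonomyFilter:
    def _tax(self, rows):
        tax = pd.DataFrame.from_dict(rows, orient="index")
        counts = pd.DataFrame(
            np.ones((1, len(rows)), dtype=np.int64),
            index=["s0"], columns=list(rows))
        samples = pd.DataFrame({"type": ["horseradish_site1"],
                                "accession": [""], "year": [2018]}, index=["s0"])
        from chemobiome.community import AsvTable
        return AsvTable(counts, samples, tax)

    @staticmethod
    def _row(confs):
        labels = {"kingdom": "Fungi", "phylum": "P", "class": "C",
                  "order": "O", "family": "F", "genus": "G"}
        return {**{r: labels[r] for r in RANKS},
                **{f"conf_{r}": confs[i] for i, r in enumerate(RANKS)}}

    def test_confident_genus_retained(self):
        out = filter_taxonomy(self._tax({"a": self._row([1, 1, 1, 1, 1, 0.95])}))
        assert out.taxonomy.loc["a", "genus"] == "G"

    def test_low_genus_truncated_to_family(self):
        out = filter_taxonomy(self._tax({"a": self._row([1, 1, 1, 1, 0.90, 0.60])}))
        assert out.taxonomy.loc["a", "genus"] == ""
        assert out.taxonomy.loc["a", "family"] == "F"

    def test_kingdom_only_removed(self):
        out = filter_taxonomy(self._tax({"a": self._row([0.99, 0.5, 0.9, 0.9, 0.9, 0.9])}))
        assert "a" not in out.counts.columns

    def test_failed_rank_blocks_deeper_ranks(self):
        # order fails: family/genus dropped even though individually confident
        out = filter_taxonomy(self._tax({"a": self._row([1, 1, 1, 0.5, 0.95, 0.95])}))
        assert out.taxonomy.loc["a", "family"] == ""
        assert out.taxonomy.loc["a", "class"] == "C"


class TestAggregation:
    def _table(self):
        tax = {
            "asv0": {"kingdom": "Fungi", "phylum": "Asc", "class": "S", "order": "Hyp",
                     "family": "Nectriaceae", "genus": "Fusarium"},
            "asv1": {"kingdom": "Fungi", "phylum": "Asc", "class": "S", "order": "Hyp",
                     "family": "Nectriaceae", "genus": "Fusarium"},
            "asv2": {"kingdom": "Fungi", "phylum": "Asc", "class": "S", "order": "Hyp",
                     "family": "Nectriaceae", "genus": ""},
        }
        rows = {}
        for a, labels in tax.items():
            rows[a] = {**labels, **{f"conf_{r}": 0.99 for r in RANKS}}
        tax_df = pd.DataFrame.from_dict(rows, orient="index")
        return make_asv_table([[10, 5, 7], [1, 2, 3]],
                              ["horseradish_site1", "horseradish_site1"],
                              taxonomy=tax_df)

    def test_same_genus_pools_counts(self):
        agg = aggregate_taxa(self._table(), "genus")
        assert agg.counts.loc["s0", "g__Fusarium"] == 15

    def test_unresolved_falls_back_with_prefix(self):
        agg = aggregate_taxa(self._table(), "genus")
        assert "f__Nectriaceae" in agg.counts.columns
        assert agg.provenance["f__Nectriaceae"] == ["asv2"]

    @pytest.mark.parametrize("rank", ["phylum", "order", "genus"])
    def test_reads_conserved(self, full_dataset, rank):
        _, _, asv, _ = full_dataset
        filtered = filter_taxonomy(asv)
        agg = aggregate_taxa(filtered, rank)
        assert agg.counts.to_numpy().sum() == filtered.counts.to_numpy().sum()

    def test_unknown_rank_raises(self):
        with pytest.raises(ValueError):
            aggregate_taxa(self._table(), "species")


class TestPrevalenceOptimizer:
    def test_noop_chosen_when_already_dense(self):
        from chemobiome.community import AggregatedCommunity
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 5, (10, 6)))
        counts.iloc[0] += 1  # ensure no all-zero taxa
        agg = AggregatedCommunity(counts, "genus")
        assert (counts.to_numpy() == 0).mean() < 0.5
        params, filtered, _ = optimize_prevalence_filter(agg, [(0.0, 1), (0.5, 5)])
        assert params == (0.0, 1)
        assert filtered.to_numpy().sum() == counts.to_numpy().sum()

    def test_tie_on_reads_broken_by_taxa(self):
        from chemobiome.community import AggregatedCommunity
        counts = pd.DataFrame({"a": [10, 10, 10], "b": [1, 1, 1]})
        agg = AggregatedCommunity(counts, "genus")
        # both points keep all reads; the first keeps fewer taxa
        params, filtered, report = optimize_prevalence_filter(
            agg, [(1.0, 1), (0.5, 1)])
        assert filtered.shape[1] == 2

    def test_sparse_genus_matrix_reaches_half_zero(self, full_dataset):
        _, _, asv, _ = full_dataset
        filtered = filter_taxonomy(filter_control_asvs(asv)[0])
        bio = filtered.subset_samples(
            filtered.samples.index[filtered.samples["type"] == "horseradish_site1"])
        agg = aggregate_taxa(bio, "genus")
        assert (agg.counts.to_numpy() == 0).mean() > 0.6
        _, kept, _ = optimize_prevalence_filter(agg, default_prevalence_grid())
        assert (kept.to_numpy() == 0).mean() < 0.5

    def test_unreachable_target_raises_with_best(self):
        from chemobiome.community import AggregatedCommunity
        counts = pd.DataFrame(np.eye(6, dtype=np.int64) * 5)
        agg = AggregatedCommunity(counts, "genus")
        with pytest.raises(ValueError, match="best achieved"):
            optimize_prevalence_filter(agg, [(0.0, 1)])


class TestZeroReplacement:
    def test_zero_free_row_is_plain_closure(self):
        counts = pd.DataFrame([[2, 3, 5]])
        out = bayesian_multiplicative_replace(counts)
        assert np.allclose(out.to_numpy(), [[0.2, 0.3, 0.5]], atol=1e-15)

    def test_ratios_of_observed_parts_preserved(self):
        counts = pd.DataFrame([[0, 5, 20, 0, 10]])
        out = bayesian_multiplicative_replace(counts).to_numpy()[0]
        assert out[2] / out[1] == pytest.approx(4.0, rel=1e-12)
        assert out[4] / out[1] == pytest.approx(2.0, rel=1e-12)

    def test_uniform_prior_strength_one_oracle(self):
        # row [0,5,5], total 10, uniform prior, s=1: posterior-expected
        # proportion of the zero part is (1/3)/(10+1) = 1/33 < 0.5
        counts = pd.DataFrame([[0, 5, 5]])
        out = bayesian_multiplicative_replace(counts, prior_strength=1.0).to_numpy()[0]
        assert out[0] == pytest.approx(1 / 33, rel=1e-12)
        assert out[0] < 0.5

    def test_rows_on_simplex_and_replacements_below_minimum(self, full_dataset):
        _, _, asv, _ = full_dataset
        bio = asv.subset_samples(
            asv.samples.index[asv.samples["type"] == "horseradish_site1"])
        agg = aggregate_taxa(filter_taxonomy(bio), "genus")
        _, kept, _ = optimize_prevalence_filter(agg)
        out = bayesian_multiplicative_replace(kept)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        P = kept.to_numpy() / kept.to_numpy().sum(axis=1, keepdims=True)
        for i in range(kept.shape[0]):
            zeros = kept.iloc[i].to_numpy() == 0
            if zeros.any():
                assert out.iloc[i][zeros].max() < P[i][~zeros].min()

    def test_all_zero_row_raises(self):
        with pytest.raises(ValueError):
            bayesian_multiplicative_replace(pd.DataFrame([[0, 0], [1, 1]]))


class TestLogRatio:
    def test_clr_equal_composition_is_zero(self):
        assert np.allclose(clr(np.array([[0.25] * 4])), 0.0, atol=1e-15)

    def test_clr_hand_example(self):
        x = np.array([1.0, 2.0, 4.0])
        out = clr(x / x.sum())
        assert np.allclose(out, [-np.log(2), 0.0, np.log(2)], atol=1e-12)

    def test_clr_matches_scikit_bio(self):
        from skbio.stats.composition import clr as skbio_clr
        rng = np.random.default_rng(1)
        comp = rng.dirichlet(np.ones(8), size=10)
        assert np.allclose(clr(comp), skbio_clr(comp), atol=1e-12)

    def test_clr_nonpositive_raises(self):
        with pytest.raises(ValueError):
            clr(np.array([0.5, 0.5, 0.0]))

    def test_ilr_two_part_closed_form(self):
        for x in (0.2, 0.5, 0.9):
            z = ilr(np.array([x, 1 - x]))
            assert z[0] == pytest.approx(np.log(x / (1 - x)) / np.sqrt(2), rel=1e-12)

    def test_ilr_basis_orthonormal_and_centered(self):
        V = ilr_basis(7)
        assert np.allclose(V.T @ V, np.eye(6), atol=1e-12)
        assert np.allclose(V.sum(axis=0), 0.0, atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ilr_isometry_and_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        comp = rng.dirichlet(np.ones(6), size=5)
        Z = ilr(comp)
        C = clr(comp)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(Z), pdist(C), atol=1e-9)
        assert np.allclose(ilr_inverse(Z), comp, atol=1e-9)

    def test_clr_is_not_subcompositionally_coherent(self):
        # documented behavior: dropping a part changes the clr of the rest
        comp = np.array([0.5, 0.3, 0.2])
        sub = comp[:2] / comp[:2].sum()
        assert not np.allclose(clr(comp)[:2], clr(sub), atol=1e-3)
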