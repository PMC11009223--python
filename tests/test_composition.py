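"""Relative abundance, rank aggregation, gut fraction and display summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import lineage, make_table, make_tax
from nasogut.composition import (
    RelAbundTable,
    aggregate_by_rank,
    gut_fraction,
    rank_by_prevalence,
    select_taxa_by_mean,
    stratum_stats,
    summarize_orders,
    to_relative,
)
from nasogut.iotab import Lineage


def _rel(values, asv_ids=None, sample_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_s, n_a = values.shape
    return RelAbundTable(
        sample_ids or [f"s{i+1}" for i in range(n_s)],
        asv_ids or [f"asv{j+1}" for j in range(n_a)],
        values,
    )


CLOSTRIDIA = lineage("Clostridiales", "Ruminococcaceae", "Oscillospira",
                     phylum="Firmicutes", cls="Clostridia")
MORAXELLA = lineage("Pseudomonadales", "Moraxellaceae", "Moraxella",
                    phylum="Proteobacteria", cls="Gammaproteobacteria")


class TestToRelative:
    def test_simple_arithmetic(self):
        rel = to_relative(make_table([[2, 3, 5]]))
        assert np.allclose(rel.values, [[0.2, 0.3, 0.5]])

    def test_single_asv_sample(self):
        rel = to_relative(make_table([[7]]))
        assert rel.values[0, 0] == 1.0

    def test_zero_depth_sample_is_named_in_error(self):
        with pytest.raises(ValueError, match="s2"):
            to_relative(make_table([[1, 2], [0, 0]]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(50, 200))
        counts[:, 0] += 1  # no zero-depth rows
        rel = to_relative(make_table(counts))
        assert np.allclose(rel.values.sum(axis=1), 1.0, atol=1e-12)

    def test_constructor_rejects_off_simplex_rows(self):
        with pytest.raises(ValueError):
            RelAbundTable(["s1"], ["a"], np.array([[0.5]]))


class TestAggregateByRank:
    def test_sums_within_genus(self):
        rel = _rel([[0.10, 0.05, 0.85]])
        tax = make_tax(["asv1", "asv2", "asv3"],
                       [lineage(), lineage(), CLOSTRIDIA])
        agg = aggregate_by_rank(rel, tax, "genus")
        assert agg.loc["Prevotella", "s1"] == pytest.approx(0.15)

    def test_unclassified_at_rank_uses_deepest_named_ancestor(self):
        lin = Lineage(("Bacteria", "Bacteroidetes", "Bacteroidia",
                       "Bacteroidales", "", "", ""))
        rel = _rel([[0.4, 0.6]])
        tax = make_tax(["asv1", "asv2"], [lin, CLOSTRIDIA])
        agg = aggregate_by_rank(rel, tax, "genus")
        assert agg.loc["Bacteroidales (unclass.)", "s1"] == pytest.approx(0.4)

    def test_invalid_rank_is_hard_error(self):
        rel = _rel([[1.0]])
        with pytest.raises(ValueError, match="rank"):
            aggregate_by_rank(rel, make_tax(["asv1"]), "strain")

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           rank=st.sampled_from(["phylum", "order", "family", "genus"]))
    def test_conserves_per_sample_totals(self, seed, rank):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 40, size=(6, 12))
        rel = to_relative(make_table(counts))
        pool = [lineage(), CLOSTRIDIA, MORAXELLA,
                Lineage(("Bacteria", "Firmicutes", "Clostridia",
                         "Clostridiales", "Lachnospiraceae", "", ""))]
        tax = make_tax(rel.asv_ids, [pool[rng.integers(0, 4)] for _ in range(12)])
        agg = aggregate_by_rank(rel, tax, rank)
        assert np.allclose(agg.sum(axis=0), 1.0, atol=1e-9)


class TestGutFraction:
    def test_pure_prevotella_sample(self):
        rel = _rel([[1.0]])
        frac = gut_fraction(rel, make_tax(["asv1"]))
        assert frac.loc["s1", "bacteroidales"] == 1.0
        assert frac.loc["s1", "clostridiales"] == 0.0

    def test_no_gut_orders(self):
        rel = _rel([[1.0]])
        frac = gut_fraction(rel, make_tax(["asv1"], [MORAXELLA]))
        assert frac.loc["s1"].tolist() == [0.0, 0.0]

    def test_invariant_to_column_permutation_and_asv_splitting(self):
        rel = _rel([[0.3, 0.7]], asv_ids=["a", "b"])
        tax = make_tax(["a", "b"], [lineage(), MORAXELLA])
        base = gut_fraction(rel, tax).loc["s1"]
        permuted = _rel([[0.7, 0.3]], asv_ids=["b", "a"])
        tax_p = make_tax(["b", "a"], [MORAXELLA, lineage()])
        assert gut_fraction(permuted, tax_p).loc["s1"].equals(base)
        split = _rel([[0.1, 0.2, 0.7]], asv_ids=["a1", "a2", "b"])
        tax_s = make_tax(["a1", "a2", "b"], [lineage(), lineage(), MORAXELLA])
        assert np.allclose(gut_fraction(split, tax_s).loc["s1"], base)

    def test_stratum_stats_uses_sample_sd(self):
        frac = pd.DataFrame({"bacteroidales": [0.1, 0.2, 0.3]},
                            index=["s1", "s2", "s3"])
        stats = stratum_stats(frac, {"all": ["s1", "s2", "s3"]})
        assert stats.loc[0, "mean"] == pytest.approx(0.2)
        assert stats.loc[0, "sd_n_minus_1"] == pytest.approx(0.1)

    def test_empty_stratum_is_hard_error(self):
        frac = pd.DataFrame({"bacteroidales": [0.1]}, index=["s1"])
        with pytest.raises(ValueError, match="empty stratum"):
            stratum_stats(frac, {"none": []})


class TestSummarizeOrders:
    def test_threshold_on_mean_splits_other_and_low_abundant(self):
        # three non-gut orders with means 40% / 35% / 25% ... third below 1%
        lins = [
            MORAXELLA,
            lineage("Pasteurellales", "Pasteurellaceae", "Glaesserella",
                    phylum="Proteobacteria", cls="Gammaproteobacteria"),
            lineage("Lactobacillales", "Lactobacillaceae", "Lactobacillus",
                    phylum="Firmicutes", cls="Bacilli"),
        ]
        rel = _rel([[0.40, 0.595, 0.005]])
        summary = summarize_orders(rel, make_tax(rel.asv_ids, lins))
        assert summary.loc["s1", "other"] == pytest.approx(0.995)
        assert summary.loc["s1", "low_abundant"] == pytest.approx(0.005)
        assert summary.loc["s1", "bacteroidales"] == 0.0

    def test_gut_orders_reported_separately_even_below_threshold(self):
        rel = _rel([[0.005, 0.995]])
        tax = make_tax(rel.asv_ids, [lineage(), MORAXELLA])
        summary = summarize_orders(rel, tax)
        assert summary.loc["s1", "bacteroidales"] == pytest.approx(0.005)

    def test_all_mass_in_clostridiales(self):
        rel = _rel([[1.0]])
        summary = summarize_orders(rel, make_tax(["asv1"], [CLOSTRIDIA]))
        assert summary.loc["s1"].tolist() == [0.0, 1.0, 0.0, 0.0]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_threshold_outside_open_interval_rejected(self, bad):
        rel = _rel([[1.0]])
        with pytest.raises(ValueError):
            summarize_orders(rel, make_tax(["asv1"]), display_threshold=bad)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_components_partition_the_simplex(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, size=(5, 10))
        rel = to_relative(make_table(counts))
        pool = [lineage(), CLOSTRIDIA, MORAXELLA]
        tax = make_tax(rel.asv_ids, [pool[rng.integers(0, 3)] for _ in range(10)])
        summary = summarize_orders(rel, tax)
        assert np.allclose(summary.sum(axis=1), 1.0, atol=1e-9)


class TestTaxonSelection:
    def test_mean_threshold(self):
        agg = pd.DataFrame({"s1": [0.02, 0.004]}, index=["A", "B"])
        assert select_taxa_by_mean(agg, 0.005) == ["A"]

    def test_zero_threshold_returns_all_by_descending_mean(self):
        agg = pd.DataFrame({"s1": [0.1, 0.9]}, index=["A", "B"])
        assert select_taxa_by_mean(agg, 0.0) == ["B", "A"]

    def test_or_predicate_across_groups(self):
        agg = pd.DataFrame(
            {"dna1": [0.0005], "rna1": [0.002]}, index=["A"]
        )
        kept = select_taxa_by_mean(
            agg, 0.001, groups={"DNA": ["dna1"], "RNA": ["rna1"]}
        )
        assert kept == ["A"]

    def test_prevalence_ordering_rules(self):
        agg = pd.DataFrame(
            {f"s{i}": [1.0 if i < 5 else 0.0, 1.0 if i < 3 else 0.0]
             for i in range(5)},
            index=["A", "B"],
        )
        agg = agg.div(agg.sum(axis=0).replace(0, 1), axis=1)
        order = rank_by_prevalence(agg)
        assert order.index("A") < order.index("B")

    def test_prevalence_tie_broken_by_mean(self):
        agg = pd.DataFrame({"s1": [0.3, 0.1, 0.6], "s2": [0.3, 0.1, 0.6]},
                           index=["A", "B", "C"])
        assert rank_by_prevalence(agg) == ["C", "A", "B"]

    def test_full_ordering_matches_brute_force(self):
        rng = np.random.default_rng(3)
        agg = pd.DataFrame(
            rng.choice([0.0, 0.05, 0.2], size=(6, 7)),
            index=list("ABCDEF"),
        )
        detection = 0.01
        expected = sorted(
            agg.index,
            key=lambda t: (
                -float((agg.loc[t] > detection).mean()),
                -float(agg.loc[t].mean()),
                t,
            ),
        )
        assert rank_by_prevalence(agg, detection) == expected
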