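from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcd_essentiality.errors import ValidationError
from rcd_essentiality.essentiality import (
    Category,
    ClassificationThresholds,
    call_essentiality,
    categorize_frequency,
    classify_genes,
    essentiality_frequency,
    global_category_counts,
    summarize_pathways,
)
from rcd_essentiality.types import GeneSetCollection

import _oracle
from conftest import make_matrix, random_matrix


class TestCallEssentiality:
    def test_strict_cutoff_and_missing_propagation(self):
        m = make_matrix([[-1.5, -1.0, np.nan]], symbols=["A", "B", "C"])
        calls = call_essentiality(m).calls.iloc[0]
        assert calls.iloc[0] == True          # below -1 -> essential
        assert calls.iloc[1] == False         # exactly -1 -> non-essential
        assert pd.isna(calls.iloc[2])         # missing score -> missing call

    def test_empty_matrix_rejected(self):
        m = make_matrix(np.empty((0, 2)), model_ids=[], symbols=["A", "B"])
        with pytest.raises(ValidationError):
            call_essentiality(m)


class TestFrequency:
    def test_counts_only_evaluable_calls(self):
        freq, n_eval, n_ess = essentiality_frequency(
            [True, True, False, False])
        assert (freq, n_eval, n_ess) == (Fraction(1, 2), 4, 2)
        freq, n_eval, n_ess = essentiality_frequency(
            [True, None, False, None])
        assert (freq, n_eval, n_ess) == (Fraction(1, 2), 2, 1)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValidationError, match="frequency undefined"):
            essentiality_frequency([None, None])


class TestCategorize:
    @pytest.mark.parametrize("freq, expected", [
        (Fraction(95, 100), Category.AEG),
        (Fraction(9, 10), Category.PEG),    # boundary is PEG, not AEG
        (Fraction(1, 10), Category.PEG),    # boundary is PEG, not REG
        (Fraction(5, 100), Category.REG),
        (Fraction(0), Category.REG),
        (Fraction(1), Category.AEG),
    ])
    def test_trichotomy_boundaries(self, freq, expected):
        assert categorize_frequency(freq) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            categorize_frequency(1.5)

    def test_thresholds_validated(self):
        with pytest.raises(ValidationError):
            ClassificationThresholds(aeg_bound=Fraction(1, 10),
                                     reg_bound=Fraction(9, 10))


class TestClassifyGenes:
    def test_three_gene_fixture(self, tiny_matrix):
        table = classify_genes(tiny_matrix).set_index("gene_symbol")
        assert table.loc["G1", "category"] == Category.AEG.value
        assert table.loc["G1", "frequency"] == 1.0
        assert table.loc["G2", "category"] == Category.PEG.value
        assert table.loc["G2", "frequency"] == 0.2
        assert table.loc["G3", "category"] == Category.REG.value

    def test_cell_line_permutation_invariance(self, tiny_matrix):
        base = classify_genes(tiny_matrix)
        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_matrix.shape[0])
        shuffled = make_matrix(
            tiny_matrix.scores.to_numpy()[perm],
            model_ids=[tiny_matrix.cell_line_ids[i] for i in perm],
            symbols=[g.symbol for g in tiny_matrix.genes])
        pd.testing.assert_frame_equal(base, classify_genes(shuffled))

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 15, 10, missing_rate=0.1)
        lo = classify_genes(m, ClassificationThresholds(score_cutoff=-3.0))
        hi = classify_genes(m, ClassificationThresholds(score_cutoff=-1.0))
        assert (lo["n_essential"] <= hi["n_essential"]).all()

    def test_all_missing_gene_reported_not_classified(self):
        values = np.array([[np.nan, -2.0], [np.nan, 0.0]])
        m = make_matrix(values, symbols=["DEAD", "OK"])
        table = classify_genes(m)
        assert table["gene_symbol"].tolist() == ["OK"]
        assert table.attrs["all_missing_genes"] == ["DEAD"]


class TestPathwaySummary:
    def test_counts_on_fixture(self, tiny_matrix, tiny_gene_sets):
        table = classify_genes(tiny_matrix)
        summary = summarize_pathways(table, tiny_gene_sets).iloc[0]
        assert (summary["n_aeg"], summary["n_peg"], summary["n_reg"]) == (1, 1, 1)
        assert summary["n_present"] == 3

    def test_absent_gene_goes_to_missing(self, tiny_matrix):
        table = classify_genes(tiny_matrix)
        gs = GeneSetCollection({"P": ["G1", "G2", "G3", "GHOST"]})
        summary = summarize_pathways(table, gs).iloc[0]
        assert summary["n_annotated"] == 4
        assert summary["n_present"] == 3
        assert summary["missing_genes"] == ["GHOST"]

    def test_empty_pathway_is_warning_not_error(self, tiny_matrix):
        table = classify_genes(tiny_matrix)
        gs = GeneSetCollection({"P": ["NOPE"]})
        summary = summarize_pathways(table, gs).iloc[0]
        assert summary["n_present"] == 0


class TestGlobalCounts:
    def test_multi_pathway_gene_counted_once_in_unique(self, tiny_matrix):
        table = classify_genes(tiny_matrix)
        gs = GeneSetCollection({"P1": ["G1", "G2"], "P2": ["G2", "G3"]})
        counts = global_category_counts(table, gs)
        # G2 is a PEG in both pathways: once in unique, twice in sums
        assert counts.unique[Category.PEG.value] == 1
        assert counts.pathway_sums[Category.PEG.value] == 2
        assert counts.n_multi_pathway == 1
        assert counts.n_union == 3

    def test_disjoint_pathways_make_totals_equal(self, tiny_matrix):
        table = classify_genes(tiny_matrix)
        gs = GeneSetCollection({"P1": ["G1"], "P2": ["G2", "G3"]})
        counts = global_category_counts(table, gs)
        assert counts.unique == counts.pathway_sums
        assert counts.n_multi_pathway == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.sampled_from([0.0, 0.25]))
def test_pipeline_matches_double_loop_oracle(seed, missing_rate):
    """Vectorized classification equals a literal per-cell loop."""
    rng = np.random.default_rng(seed)
    n_lines = int(rng.integers(3, 15))
    n_genes = int(rng.integers(2, 12))
    m = random_matrix(rng, n_lines, n_genes, missing_rate=missing_rate)
    symbols = [g.symbol for g in m.genes]
    scores = [[None if np.isnan(v) else float(v) for v in row]
              for row in m.scores.to_numpy()]
    expected = _oracle.oracle_classify(scores, symbols)
    table = classify_genes(m).set_index("gene_symbol")
    assert set(table.index) == set(expected)
    for sym, (freq, n_eval, n_ess, cat) in expected.items():
        row = table.loc[sym]
        assert Fraction(int(row["n_essential"]), int(row["n_evaluable"])) == freq
        assert (row["n_evaluable"], row["n_essential"]) == (n_eval, n_ess)
        assert row["category"] == cat


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_partition_and_conservation_properties(seed):
    """Each gene gets exactly one category; pathway counts sum to n_present."""
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, int(rng.integers(3, 12)), int(rng.integers(3, 15)),
                      missing_rate=0.1)
    table = classify_genes(m)
    assert table["category"].isin([c.value for c in Category]).all()
    assert ((0 <= table["frequency"]) & (table["frequency"] <= 1)).all()
    symbols = [g.symbol for g in m.genes]
    picks = rng.permutation(symbols)
    gs = GeneSetCollection({
        "P1": list(picks[: max(1, len(picks) // 2)]) + ["ABSENT1"],
        "P2": list(picks[len(picks) // 3:]) or [symbols[0]],
    })
    summary = summarize_pathways(table, gs)
    assert (summary["n_aeg"] + summary["n_peg"] + summary["n_reg"]
            == summary["n_present"]).all()
    assert (summary["n_present"] <= summary["n_annotated"]).all()
    counts = global_category_counts(table, gs)
    for cat in counts.unique:
        assert counts.unique[cat] <= counts.pathway_sums[cat]
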