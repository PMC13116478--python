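from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from rcd_essentiality.errors import ValidationError
from rcd_essentiality.essentiality import call_essentiality, classify_genes
from rcd_essentiality.pathway_context import (
    PathwayFractionProfile,
    SeparationConfig,
    cancer_type_enrichment,
    detect_separation,
    otsu_split,
    pathway_fraction_profile,
)
from rcd_essentiality.types import CellLineTable, GeneSetCollection

import _oracle
from conftest import make_matrix, random_matrix


def _profile_from(values: dict[str, list[float]], ids=None):
    n = len(next(iter(values.values())))
    ids = ids or [f"L{i}" for i in range(n)]
    fractions = pd.DataFrame(values, index=pd.Index(ids, name="model_id"))
    meta = pd.DataFrame({"pathway": list(values), "n_present": 10,
                         "n_aeg_peg": 5}).set_index("pathway")
    return PathwayFractionProfile(fractions=fractions, meta=meta)


class TestFractionProfile:
    def test_reg_genes_excluded_from_numerator(self):
        # pathway {A:AEG, B:PEG, C:REG, D:REG}; line 0 has A and C essential
        # -> fraction 1/4 (C does not count, denominator keeps all four)
        scores = np.array([
            [-2.0, 0.0, -2.0, 0.0],
            *([[-2.0, -2.0, 0.0, 0.0]] * 4),
            *([[-2.0, 0.0, 0.0, 0.0]] * 6),
        ])
        m = make_matrix(scores, symbols=["A", "B", "C", "D"])
        gs = GeneSetCollection({"P": ["A", "B", "C", "D"]})
        calls = call_essentiality(m)
        classification = classify_genes(m)
        cats = dict(zip(classification["gene_symbol"],
                        classification["category"]))
        assert cats == {"A": "always_essential", "B": "partially_essential",
                        "C": "rarely_essential", "D": "rarely_essential"}
        profile = pathway_fraction_profile(calls, classification, gs)
        assert profile.fractions.iloc[0, 0] == 0.25

    def test_pathway_without_aeg_peg_is_all_zero(self):
        m = make_matrix(np.zeros((12, 3)), symbols=["A", "B", "C"])
        gs = GeneSetCollection({"P": ["A", "B", "C"]})
        profile = pathway_fraction_profile(
            call_essentiality(m), classify_genes(m), gs)
        assert (profile.fractions["P"] == 0.0).all()
        assert profile.meta.loc["P", "n_aeg_peg"] == 0

    def test_missing_calls_count_as_non_essential(self):
        scores = np.array([[np.nan, -2.0]] + [[-2.0, -2.0]] * 5)
        m = make_matrix(scores, symbols=["A", "B"])
        gs = GeneSetCollection({"P": ["A", "B"]})
        profile = pathway_fraction_profile(
            call_essentiality(m), classify_genes(m), gs)
        # line 0: A missing (not counted), B essential -> 1/2
        assert profile.fractions.iloc[0, 0] == 0.5

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(21)
        m = random_matrix(rng, 15, 12, missing_rate=0.15)
        symbols = [g.symbol for g in m.genes]
        gs = GeneSetCollection({
            "P1": symbols[:7] + ["ABSENT"],
            "P2": symbols[4:],
        })
        profile = pathway_fraction_profile(
            call_essentiality(m), classify_genes(m), gs)
        scores = [[None if np.isnan(v) else float(v) for v in row]
                  for row in m.scores.to_numpy()]
        expected = _oracle.oracle_fractions(
            scores, symbols, {n: list(g) for n, g in gs.items()})
        for (i, name), frac in expected.items():
            assert profile.fractions.iloc[i][name] == float(frac)
            meta = profile.meta.loc[name]
            assert frac <= Fraction(int(meta["n_aeg_peg"]),
                                    int(meta["n_present"]))


class TestOtsuSplit:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.uniform(0, 1, rng.integers(5, 40))
            thr, score, _ = otsu_split(vals)
            o_thr, o_score = _oracle.oracle_best_split(vals.tolist())
            assert thr == pytest.approx(o_thr)
            assert score == pytest.approx(o_score)

    def test_constant_values_have_no_split(self):
        thr, score, _ = otsu_split(np.full(20, 0.3))
        assert thr is None and score == 0.0

    def test_two_point_masses_score_one(self):
        vals = np.array([0.0] * 10 + [0.4] * 10)
        thr, score, n_upper = otsu_split(vals)
        assert score == pytest.approx(1.0)
        assert 0.0 < thr < 0.4
        assert n_upper == 10


class TestDetectSeparation:
    def test_planted_bimodal_detected_with_upper_group(self):
        rng = np.random.default_rng(7)
        low = rng.uniform(0.00, 0.05, 50)
        high = rng.uniform(0.45, 0.55, 50)
        ids = [f"LO{i}" for i in range(50)] + [f"HI{i}" for i in range(50)]
        profile = _profile_from({"P": np.concatenate([low, high]).tolist()},
                                ids=ids)
        result = detect_separation(profile)["P"]
        assert result.separated
        assert set(result.selected_lines) == {f"HI{i}" for i in range(50)}
        assert all(profile.fractions.loc[l, "P"] >= result.split_value
                   for l in result.selected_lines)

    def test_unimodal_uniform_not_separated(self):
        rng = np.random.default_rng(8)
        profile = _profile_from({"P": rng.uniform(0, 0.1, 100).tolist()})
        result = detect_separation(profile)["P"]
        assert not result.separated
        assert result.selected_lines == ()
        # best-split ratio of unimodal uniform data hovers near 0.75
        assert result.separation_score < SeparationConfig().min_score

    def test_constant_fractions_not_separated(self):
        profile = _profile_from({"P": [0.2] * 30})
        result = detect_separation(profile)["P"]
        assert not result.separated and result.split_value is None

    def test_min_group_size_enforced(self):
        # perfect two-point split but only 2 lines in the upper group
        profile = _profile_from({"P": [0.0] * 28 + [0.5] * 2})
        assert not detect_separation(profile)["P"].separated
        cfg = SeparationConfig(min_group=2)
        assert detect_separation(profile, cfg)["P"].separated

    def test_requires_ten_lines(self):
        profile = _profile_from({"P": [0.0, 1.0] * 4})
        with pytest.raises(ValidationError):
            detect_separation(profile)


class TestEnrichment:
    def test_strictly_above_half_is_enriched(self):
        table = CellLineTable(pd.DataFrame({
            "model_id": [f"L{i}" for i in range(12)],
            "cancer_type": ["X"] * 4 + ["Y"] * 4 + ["Z"] * 4,
        }))
        selected = {"L0", "L1", "L2",        # X: 3/4 -> enriched
                    "L4", "L5"}              # Y: 2/4 -> NOT enriched (exactly half)
        result = cancer_type_enrichment(selected, table).set_index("cancer_type")
        assert bool(result.loc["X", "enriched"])
        assert not bool(result.loc["Y", "enriched"])
        assert result.loc["Z", "n_selected"] == 0
        assert result["n_selected"].sum() == len(selected)

    def test_sorted_by_fraction_then_name(self, annotations6):
        result = cancer_type_enrichment(
            {"ACH-000006", "ACH-000001"}, annotations6)
        assert result["cancer_type"].tolist() == ["Z", "X", "Y"]

    def test_unknown_selected_ids_dropped(self, annotations6):
        result = cancer_type_enrichment({"GHOST-1", "ACH-000001"}, annotations6)
        assert result["n_selected"].sum() == 1

    def test_empty_selection_gives_zero_table(self, annotations6):
        result = cancer_type_enrichment(set(), annotations6)
        assert len(result) == 3
        assert (result["n_selected"] == 0).all()
        assert not result["enriched"].any()
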