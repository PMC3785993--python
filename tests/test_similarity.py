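"""Weighted Gower similarity: dispatch rules, formula, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frailtymap as fm
from _util import (brute_force_gower, make_instance, make_stack, mini_schema,
                   random_mixed_stack)


class TestNormalizeUnits:
    def test_identity_and_metric_conversion(self, schema):
        inst = make_instance(1, {})
        inst = inst.with_values({
            "weight": fm.VariableValue.present(70.0),
            "size": fm.VariableValue.present(1.62, unit="m"),
        })
        other = make_instance(2, {})
        other = other.with_values({
            "weight": fm.VariableValue.present(70000.0, unit="g")})
        stack = fm.PatientStack(schema, (inst, other))
        out = fm.normalize_units(stack)
        assert out.get(1).value("weight").value == 70.0
        assert out.get(1).value("size").value == pytest.approx(162.0)
        assert out.get(2).value("weight").value == pytest.approx(70.0)
        assert out.get(2).value("weight").unit is None

    def test_ranges_recomputed_after_conversion(self, schema):
        a = make_instance(1, {}).with_values(
            {"weight": fm.VariableValue.present(60.0)})
        b = make_instance(2, {}).with_values(
            {"weight": fm.VariableValue.present(80000.0, unit="g")})
        out = fm.normalize_units(fm.PatientStack(schema, (a, b)))
        assert fm.quantitative_ranges(out)["weight"] == pytest.approx(20.0)

    def test_unknown_unit_names_variable(self, schema):
        a = make_instance(1, {}).with_values(
            {"weight": fm.VariableValue.present(11.0, unit="stone")})
        with pytest.raises(fm.UnitConversionError, match="weight"):
            fm.normalize_units(fm.PatientStack(schema, (a,)))


class TestVariableSimilarity:
    QUANT = fm.VariableSpec("q", "nutritional", "quantitative", unit="u")
    BIN = fm.VariableSpec("b", "geriatric_syndromes", "binary")
    QUAL = fm.VariableSpec("c", "functional", "qualitative",
                           categories=("a", "b"))

    def pv(self, v):
        return fm.VariableValue.present(v)

    def test_quantitative_identical(self):
        s, d = fm.variable_similarity(self.pv(3.0), self.pv(3.0), self.QUANT, 10.0)
        assert (s, d) == (1.0, 1)

    def test_quantitative_range_extremes(self):
        s, d = fm.variable_similarity(self.pv(0.0), self.pv(10.0), self.QUANT, 10.0)
        assert (s, d) == (0.0, 1)

    def test_quantitative_zero_range_scores_one(self):
        s, d = fm.variable_similarity(self.pv(5.0), self.pv(5.0), self.QUANT, 0.0)
        assert (s, d) == (1.0, 1)

    def test_missing_side_not_comparable(self):
        s, d = fm.variable_similarity(self.pv(1.0), fm.VariableValue.missing(),
                                      self.QUANT, 10.0)
        assert d == 0

    def test_qualitative_match_and_mismatch(self):
        assert fm.variable_similarity(self.pv("a"), self.pv("a"), self.QUAL)[0] == 1.0
        assert fm.variable_similarity(self.pv("a"), self.pv("b"), self.QUAL)[0] == 0.0

    @pytest.mark.parametrize("a,b,expected_s,expected_d", [
        (True, True, 1.0, 1),
        (True, False, 0.0, 1),
        (False, False, 1.0, 1),
    ])
    def test_binary_symmetric(self, a, b, expected_s, expected_d):
        s, d = fm.variable_similarity(self.pv(a), self.pv(b), self.BIN)
        assert (s, d) == (expected_s, expected_d)

    def test_binary_asymmetric_co_absence_not_comparable(self):
        cfg = fm.SimilarityConfig(binary_mode="asymmetric")
        s, d = fm.variable_similarity(self.pv(False), self.pv(False),
                                      self.BIN, config=cfg)
        assert d == 0
        s, d = fm.variable_similarity(self.pv(True), self.pv(True),
                                      self.BIN, config=cfg)
        assert (s, d) == (1.0, 1)
        s, d = fm.variable_similarity(self.pv(True), self.pv(False),
                                      self.BIN, config=cfg)
        assert (s, d) == (0.0, 1)


class TestGowerCoefficient:
    def test_identical_instances_score_one(self):
        schema = mini_schema(("q", "quantitative"), ("b", "binary"),
                             ("c", "qualitative"))
        inst = make_instance(1, {"q": 2.0, "b": True, "c": "a"})
        twin = make_instance(2, {"q": 2.0, "b": True, "c": "a"})
        ref = make_instance(3, {"q": 7.0, "b": False, "c": "b"})
        stack = make_stack(schema, inst, twin, ref)
        pair = fm.gower_similarity(1, 2, stack, fm.WeightProfile.uniform(schema))
        assert pair.coefficient == 1.0

    def test_half_similarity_by_formula(self):
        # one variable identical, one at the stack's range extremes: (1+0)/2
        schema = mini_schema(("q1", "quantitative"), ("q2", "quantitative"))
        a = make_instance(1, {"q1": 5.0, "q2": 0.0})
        b = make_instance(2, {"q1": 5.0, "q2": 10.0})
        stack = make_stack(schema, a, b)
        pair = fm.gower_similarity(1, 2, stack, fm.WeightProfile.uniform(schema))
        assert pair.coefficient == pytest.approx(0.5)
        assert pair.effective_weight == pytest.approx(2.0)

    def test_missing_variable_drops_out_of_both_sums(self):
        schema = mini_schema(("q1", "quantitative"), ("q2", "quantitative"),
                             ("q3", "quantitative"))
        a = make_instance(1, {"q1": 1.0, "q2": 2.0, "q3": 9.0})
        b = make_instance(2, {"q1": 1.0, "q2": 2.0, "q3": None})
        stack = make_stack(schema, a, b,
                           make_instance(3, {"q1": 0.0, "q2": 0.0, "q3": 0.0}))
        pair = fm.gower_similarity(1, 2, stack, fm.WeightProfile.uniform(schema))
        assert pair.coefficient == 1.0
        assert pair.effective_weight == pytest.approx(2.0)

    def test_incomparable_pair_raises(self):
        schema = mini_schema(("q1", "quantitative"), ("q2", "quantitative"))
        a = make_instance(1, {"q1": 1.0, "q2": None})
        b = make_instance(2, {"q1": None, "q2": 2.0})
        stack = make_stack(schema, a, b)
        with pytest.raises(fm.IncomparablePairError):
            fm.gower_similarity(1, 2, stack, fm.WeightProfile.uniform(schema))

    def test_zero_weight_makes_variable_irrelevant(self):
        schema = mini_schema(("q1", "quantitative"), ("q2", "quantitative"))
        a = make_instance(1, {"q1": 3.0, "q2": 0.0})
        b = make_instance(2, {"q1": 3.0, "q2": 10.0})
        stack = make_stack(schema, a, b)
        profile = fm.WeightProfile({"q1": 1.0, "q2": 0.0})
        pair = fm.gower_similarity(1, 2, stack, profile)
        assert pair.coefficient == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        stack = random_mixed_stack(rng, int(rng.integers(2, 7)),
                                   int(rng.integers(2, 9)))
        weights = fm.WeightProfile(
            {n: float(rng.uniform(0.1, 1.0)) for n in stack.schema.names})
        ranges = fm.quantitative_ranges(stack)
        mode = "asymmetric" if seed % 2 else "symmetric"
        cfg = fm.SimilarityConfig(binary_mode=mode)
        for i in range(len(stack)):
            for j in range(i + 1, len(stack)):
                a, b = stack.instances[i], stack.instances[j]
                expected = brute_force_gower(a, b, stack.schema, weights,
                                             ranges, mode)
                if expected is None:
                    with pytest.raises(fm.IncomparablePairError):
                        fm.gower_similarity(a, b, stack, weights, cfg, ranges)
                    continue
                pair = fm.gower_similarity(a, b, stack, weights, cfg, ranges)
                assert pair.coefficient == pytest.approx(
                    min(max(expected[0], 0.0), 1.0), abs=1e-12)
                assert pair.effective_weight == pytest.approx(expected[1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        stack = random_mixed_stack(rng, 4, 6, missing_rate=0.3)
        weights = fm.WeightProfile.uniform(stack.schema)
        ranges = fm.quantitative_ranges(stack)
        for i in range(len(stack)):
            for j in range(len(stack)):
                try:
                    ij = fm.gower_similarity(stack.instances[i],
                                             stack.instances[j], stack,
                                             weights, ranges=ranges)
                    ji = fm.gower_similarity(stack.instances[j],
                                             stack.instances[i], stack,
                                             weights, ranges=ranges)
                except fm.IncomparablePairError:
                    continue
                assert ij.coefficient == pytest.approx(ji.coefficient, abs=1e-15)
                assert 0.0 <= ij.coefficient <= 1.0
                if i == j:
                    assert ij.coefficient == 1.0


class TestMatrixAndRanking:
    def test_identical_pair_matrix(self):
        schema = mini_schema(("q", "quantitative"))
        stack = make_stack(schema, make_instance(1, {"q": 2.0}),
                           make_instance(2, {"q": 2.0}))
        matrix = fm.similarity_matrix(stack, fm.WeightProfile.uniform(schema))
        np.testing.assert_array_equal(matrix.values, np.ones((2, 2)))

    def test_matrix_matches_pairwise_recomputation(self, resolved_table_stack):
        weights = fm.WeightProfile.uniform(resolved_table_stack.schema)
        matrix = fm.similarity_matrix(resolved_table_stack, weights)
        ranges = fm.quantitative_ranges(resolved_table_stack)
        rng = np.random.default_rng(0)
        ids = list(matrix.index)
        for _ in range(30):
            i, j = rng.choice(ids, size=2, replace=False)
            pair = fm.gower_similarity(int(i), int(j), resolved_table_stack,
                                       weights, ranges=ranges)
            assert matrix.loc[i, j] == pytest.approx(pair.coefficient)
        assert np.allclose(matrix.values, matrix.values.T, equal_nan=True)
        assert np.allclose(np.diag(matrix.values), 1.0)

    def test_incomparable_cell_flagged_as_nan(self):
        schema = mini_schema(("q1", "quantitative"), ("q2", "quantitative"))
        stack = make_stack(schema,
                           make_instance(1, {"q1": 1.0, "q2": None}),
                           make_instance(2, {"q1": None, "q2": 2.0}),
                           make_instance(3, {"q1": 3.0, "q2": 4.0}))
        matrix = fm.similarity_matrix(stack, fm.WeightProfile.uniform(schema))
        assert np.isnan(matrix.loc[1, 2])
        assert not np.isnan(matrix.loc[1, 3])

    def test_ranking_order_and_tie_break(self):
        # ids 5 and 3 tie above id 2; ties break by ascending instance id
        schema = mini_schema(("q", "quantitative"))
        stack = make_stack(schema,
                           make_instance(1, {"q": 0.0}),
                           make_instance(5, {"q": 1.0}),
                           make_instance(2, {"q": 3.0}),
                           make_instance(3, {"q": 1.0}))
        ranked = fm.rank_neighbors(1, stack, fm.WeightProfile.uniform(schema))
        assert [p.j for p in ranked] == [3, 5, 2]

    def test_single_candidate_and_full_exclusion(self):
        schema = mini_schema(("q", "quantitative"))
        stack = make_stack(schema, make_instance(1, {"q": 0.0}),
                           make_instance(2, {"q": 1.0}))
        assert [p.j for p in fm.rank_neighbors(1, stack,
                                               fm.WeightProfile.uniform(schema))] == [2]
        assert fm.rank_neighbors(1, stack, fm.WeightProfile.uniform(schema),
                                 exclude={2}) == []
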