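"""Tests of the MPT engine: parsing, category probabilities, likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bindmpt as bm
from bindmpt.mpt_core import (
    CATEGORIES,
    ConditionKey,
    EQNParseError,
    conditions_for,
    counts_array,
    parse_eqn,
)

UNIT = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def enumerate_branch_products(model, params, condition):
    """Independent oracle: walk the branch list and sum raw products."""
    out = dict.fromkeys(CATEGORIES, 0.0)
    for br in model.branches:
        if br.condition != condition:
            continue
        prob = 1.0
        for name, complement in br.factors:
            v = model.constants.get(name, params.get(name))
            prob *= (1.0 - v) if complement else v
        out[br.category] += prob
    return np.array([out[c] for c in CATEGORIES])


class TestParseEqn:
    def test_single_branch_identity(self):
        m = parse_eqn("c1 target P_B")
        assert m.free_parameters == ("P_B",)
        probs = bm.category_probabilities(m, {"P_B": 0.3}, "c1")
        assert probs == pytest.approx([0.3, 0.0, 0.0])

    def test_constants_block(self, dep_e1):
        assert dep_e1.constants == {"g_B": 0.5, "g_I": 0.5}

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("c1 target", "line 1"),
            ("c1 target P_B\nc1 oops P_I", "unknown category"),
            ("c1 target P_B*+Q", "malformed factor"),
            ("const g = 2.0\nc1 target g", "outside"),
            ("# only a comment", "no branches"),
        ],
    )
    def test_malformed_text_rejected(self, text, fragment):
        with pytest.raises(EQNParseError, match=fragment):
            parse_eqn(text)

    def test_shipped_models_have_eight_free_parameters(self, dep_e1, ind_e1, dep_e2):
        for m in (dep_e1, ind_e1, dep_e2):
            assert len(m.free_parameters) == 8
            assert len(m.conditions) == 4
            assert all(p.startswith(("P_B_", "P_I_")) for p in m.free_parameters)


class TestConditionKeys:
    def test_four_cells_per_experiment(self):
        assert len(conditions_for("E1")) == 4
        assert len(conditions_for("E2")) == 4

    def test_e1_carries_probe_not_consistency(self):
        with pytest.raises(ValueError):
            ConditionKey("E1", "intrinsic", consistency="consistent")

    def test_e2_shape_probe_only(self):
        with pytest.raises(ValueError):
            ConditionKey("E2", "intrinsic", probe="colour", consistency="consistent")
        key = ConditionKey("E2", "extrinsic", consistency="inconsistent")
        assert key.label == "extrinsic_inconsistent"


class TestCategoryProbabilities:
    def _full(self, model, pb, pi):
        return {
            **{f"P_B_{c}": pb for c in model.conditions},
            **{f"P_I_{c}": pi for c in model.conditions},
        }

    def test_perfect_memory_hits_target(self, dep_e1, ind_e1):
        for m in (dep_e1, ind_e1):
            probs = bm.category_probabilities(m, self._full(m, 1.0, 1.0), m.conditions[0])
            assert probs == pytest.approx([1.0, 0.0, 0.0])

    def test_item_without_binding_guesses_evenly(self, dep_e1):
        probs = bm.category_probabilities(
            dep_e1, self._full(dep_e1, 0.0, 1.0), "intrinsic_shape"
        )
        assert probs == pytest.approx([0.5, 0.5, 0.0])

    def test_dependence_hand_derived_triple(self, dep_e1):
        # P_I=0.8, P_B=0.6, g=0.5 worked through the tree by hand:
        # target .8*.6 + .8*.4*.5 + .2*.5*.5 ; lure .8*.4*.5 + .2*.5*.5 ; new .2*.5
        probs = bm.category_probabilities(
            dep_e1, self._full(dep_e1, 0.6, 0.8), "extrinsic_colour"
        )
        assert probs == pytest.approx([0.69, 0.21, 0.10], abs=1e-12)

    def test_missing_parameter_named_in_error(self, dep_e1):
        with pytest.raises(KeyError, match="P_I_intrinsic_shape"):
            bm.category_probabilities(dep_e1, {}, "intrinsic_shape")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(pb=UNIT, pi=UNIT)
    def test_normalisation_property(self, dep_e1, ind_e1, pb, pi):
        for m in (dep_e1, ind_e1):
            params = self._full(m, pb, pi)
            for cond in m.conditions:
                total = bm.category_probabilities(m, params, cond).sum()
                assert abs(total - 1.0) < 1e-12

    def test_target_monotone_in_binding_memory(self, dep_e1, ind_e1):
        grid = np.linspace(0, 1, 41)
        for m in (dep_e1, ind_e1):
            for pi in (0.0, 0.3, 0.8, 1.0):
                targets = [
                    bm.category_probabilities(m, self._full(m, pb, pi), "intrinsic_shape")[0]
                    for pb in grid
                ]
                assert np.all(np.diff(targets) >= -1e-12)

    def test_matches_branch_enumeration_oracle(self, dep_e1, ind_e1):
        rng = np.random.default_rng(7)
        for m in (dep_e1, ind_e1):
            for _ in range(500):
                params = {p: rng.random() for p in m.free_parameters}
                for cond in m.conditions:
                    got = bm.category_probabilities(m, params, cond)
                    want = enumerate_branch_products(m, params, cond)
                    np.testing.assert_allclose(got, want, atol=1e-14)


class TestLogLikelihood:
    def test_certain_outcome_contributes_zero(self):
        m = parse_eqn("c1 target P")
        table = pd.DataFrame(
            [{"participant": 0, "condition": "c1", "target": 5, "lure": 0, "new": 0}]
        )
        assert bm.log_likelihood(m, {"P": 1.0}, table) == 0.0

    def test_all_zero_counts_is_empty_sum(self, dep_e1):
        rows = [
            {"participant": 0, "condition": c, "target": 0, "lure": 0, "new": 0}
            for c in dep_e1.conditions
        ]
        params = {p: 0.4 for p in dep_e1.free_parameters}
        assert bm.log_likelihood(dep_e1, params, pd.DataFrame(rows)) == 0.0

    def test_impossible_observation_is_minus_inf(self):
        m = parse_eqn("c1 target P")  # lure has structural probability 0
        table = pd.DataFrame(
            [{"participant": 0, "condition": "c1", "target": 1, "lure": 2, "new": 0}]
        )
        assert bm.log_likelihood(m, {"P": 0.7}, table) == -np.inf

    def test_matches_naive_term_by_term_sum(self, dep_e1):
        rng = np.random.default_rng(11)
        params = {p: rng.uniform(0.05, 0.95) for p in dep_e1.free_parameters}
        rows = []
        for pid in range(3):
            for c in dep_e1.conditions:
                t, l, n = rng.integers(0, 30, size=3)
                rows.append(
                    {"participant": pid, "condition": c, "target": t, "lure": l, "new": n}
                )
        table = pd.DataFrame(rows)
        # independent naive summation
        expected = 0.0
        for row in rows:
            probs = enumerate_branch_products(dep_e1, params, row["condition"])
            for cat, p in zip(CATEGORIES, probs):
                if row[cat] > 0:
                    expected += row[cat] * np.log(p)
        assert bm.log_likelihood(dep_e1, params, table) == pytest.approx(expected)


class TestFrequencyTable:
    def test_missing_condition_reported(self, dep_e1):
        rows = [
            {"participant": 0, "condition": c, "target": 1, "lure": 1, "new": 1}
            for c in dep_e1.conditions[:3]
        ]
        with pytest.raises(ValueError, match="no counts for condition"):
            counts_array(pd.DataFrame(rows), dep_e1)

    def test_duplicate_rows_rejected(self, dep_e1):
        rows = [
            {"participant": 0, "condition": c, "target": 1, "lure": 1, "new": 1}
            for c in dep_e1.conditions
        ]
        rows.append(rows[0])
        with pytest.raises(ValueError, match="duplicate"):
            counts_array(pd.DataFrame(rows), dep_e1)

    def test_negative_counts_rejected(self, dep_e1):
        rows = [
            {"participant": 0, "condition": c, "target": -1, "lure": 1, "new": 1}
            for c in dep_e1.conditions
        ]
        with pytest.raises(ValueError, match="negative"):
            counts_array(pd.DataFrame(rows), dep_e1)
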