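"""Constraint coding: discretization, incremental/dummy coding, design
assembly, coefficient recovery and effect-curve semantics."""

import numpy as np
import pandas as pd
import pytest

from glmqc.model_spec import (
    ConstraintCase,
    DataError,
    ModelSpec,
    SpecError,
    TermSpec,
    VariableSpec,
    build_design,
    coding_matrix,
    discretize,
    effect_curve,
    effect_surface,
    encode_dummy,
    encode_incremental,
    recover_coefficients,
)

from conftest import MONOTONE_CASES, feasible_steps


AGE = VariableSpec("age", "continuous-discretized", bin_edges=[18, 35, 50, 65, 120])


class TestDiscretize:
    def test_interval_membership(self):
        assert discretize(np.array([40.0]), AGE)[0] == 2

    def test_interior_edge_goes_right(self):
        # half-open [35, 50) convention
        assert discretize(np.array([35.0]), AGE)[0] == 2

    def test_brute_force_scan(self):
        vals = np.array([20.0, 70.0, 34.999, 64.9, 19.0])
        # oracle: linear scan over the intervals
        edges = AGE.bin_edges
        expected = [
            next(k + 1 for k in range(4) if edges[k] <= v < edges[k + 1])
            for v in vals
        ]
        assert discretize(vals, AGE).tolist() == expected

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            lev = discretize(np.array([10.0, 500.0]), AGE)
        assert lev.tolist() == [1, 4]

    def test_non_finite_rejected_with_row(self):
        with pytest.raises(DataError, match=r"\[1\]"):
            discretize(np.array([40.0, np.nan]), AGE)


class TestIncrementalCoding:
    @pytest.mark.parametrize("case", MONOTONE_CASES, ids=lambda c: f"{c.monotonicity[:3]}-{c.sign[:3]}")
    @pytest.mark.parametrize("K", [2, 3, 4, 6])
    def test_reference_end_maps_to_zero_row(self, case, K):
        ref = 1 if case.reference_end == "first" else K
        Z, _ = encode_incremental(np.array([ref]), K, case)
        assert not Z.any()

    def test_increasing_positive_row(self):
        Z, bounds = encode_incremental(
            np.array([3]), 4, ConstraintCase("increasing", "positive")
        )
        assert Z[0].tolist() == [1, 1, 0]
        assert bounds.tolist() == [1, 1, 1]

    def test_decreasing_negative_row(self):
        Z, bounds = encode_incremental(
            np.array([4]), 4, ConstraintCase("decreasing", "negative")
        )
        assert Z[0].tolist() == [1, 1, 1]
        assert bounds.tolist() == [-1, -1, -1]

    def test_unrestricted_sign_frees_first_step(self):
        _, bounds = encode_incremental(
            np.array([1]), 4, ConstraintCase("increasing", "unrestricted")
        )
        assert bounds.tolist() == [0, 1, 1]

    def test_k_below_two_invalid(self):
        with pytest.raises(SpecError):
            encode_incremental(np.array([1]), 1, MONOTONE_CASES[0])

    @pytest.mark.parametrize("case", MONOTONE_CASES, ids=lambda c: f"{c.monotonicity[:3]}-{c.sign[:3]}")
    def test_effect_enumeration_oracle(self, case, rng):
        # enumerate all levels: implied effect = coded row @ steps must equal
        # the cumulative-sum curve and satisfy the declared constraints
        K = 5
        steps = feasible_steps(case, K - 1, rng)
        Z, _ = encode_incremental(np.arange(1, K + 1), K, case)
        curve = Z @ steps
        # cases with unrestricted sign anchor via a free first step, so the
        # monotone shape is guaranteed from the second level onward
        diffs = np.diff(curve) if case.sign != "unrestricted" else np.diff(curve)[1:]
        if case.monotonicity == "increasing":
            assert np.all(diffs >= -1e-12)
        else:
            assert np.all(diffs <= 1e-12)
        if case.sign == "positive":
            assert np.all(curve >= -1e-12)
        elif case.sign == "negative":
            assert np.all(curve <= 1e-12)


class TestDummyCoding:
    def test_reference_is_zero_row(self):
        Z, _ = encode_dummy(np.array([1]), 3, reference=1)
        assert not Z.any()

    def test_indicator_position(self):
        Z, _ = encode_dummy(np.array([3]), 3, reference=1)
        assert Z[0].tolist() == [0, 1]

    def test_sign_bound_shared(self):
        _, bounds = encode_dummy(np.array([2]), 4, reference=2, sign="positive")
        assert bounds.tolist() == [1, 1, 1]


def two_var_spec(constraint_ab=ConstraintCase("none", "unrestricted")):
    va = VariableSpec("a", "continuous-discretized", bin_edges=[0, 1, 2, 3])
    vb = VariableSpec("b", "continuous-discretized", bin_edges=[0, 1, 2, 3])
    return ModelSpec(
        outcome="y",
        family="gaussian",
        treatment="a",
        variables=[va, vb],
        terms=[TermSpec(("a",)), TermSpec(("b",)), TermSpec(("a", "b"), constraint_ab)],
    )


class TestBuildDesign:
    def test_single_binary_variable_one_column(self):
        spec = ModelSpec(
            "y", "gaussian", "t",
            [VariableSpec("t", "binary")], [TermSpec(("t",))],
        )
        d = build_design(pd.DataFrame({"t": [0, 1, 1]}), spec)
        assert d.X.shape == (3, 1)

    def test_interaction_dimensions_and_kronecker(self, rng):
        spec = two_var_spec(ConstraintCase("decreasing", "negative"))
        df = pd.DataFrame({"a": rng.uniform(0, 3, 50), "b": rng.uniform(0, 3, 50)})
        d = build_design(df, spec)
        assert d.X.shape[1] == 2 + 2 + 4
        ba = d.block_for("a", "b")
        case = ConstraintCase("decreasing", "negative")
        A1 = coding_matrix(3, case)
        np.testing.assert_array_equal(ba.A, np.kron(A1, A1))
        # brute-force check: interaction columns are all pairwise products
        Za, _ = encode_incremental(
            spec.variable("a").level_index(df["a"]), 3, case
        )
        Zb, _ = encode_incremental(
            spec.variable("b").level_index(df["b"]), 3, case
        )
        brute = np.column_stack([Za[:, i] * Zb[:, j] for i in range(2) for j in range(2)])
        np.testing.assert_array_equal(d.X[:, ba.sl], brute)

    def test_interaction_predictor_matches_brute_force(self, rng):
        # Kronecker-reparametrized block with eta = (A (x) A)^-1 gamma gives the
        # same predictor as the dummy-product design with coefficients gamma
        case = ConstraintCase("increasing", "positive")
        spec = two_var_spec(case)
        df = pd.DataFrame({"a": rng.uniform(0, 3, 80), "b": rng.uniform(0, 3, 80)})
        d = build_design(df, spec)
        blk = d.block_for("a", "b")
        gamma = rng.normal(size=4)
        eta_work = np.linalg.solve(blk.A, gamma)
        la = spec.variable("a").level_index(df["a"])
        lb = spec.variable("b").level_index(df["b"])
        Da, _ = encode_dummy(la, 3, 1)
        Db, _ = encode_dummy(lb, 3, 1)
        brute = np.column_stack(
            [Da[:, i] * Db[:, j] for i in range(2) for j in range(2)]
        )
        np.testing.assert_allclose(
            d.X[:, blk.sl] @ eta_work, brute @ gamma, atol=1e-10
        )

    def test_empty_table_rejected(self):
        spec = two_var_spec()
        with pytest.raises(DataError, match="empty"):
            build_design(pd.DataFrame({"a": [], "b": []}), spec)

    def test_missing_column_named(self):
        spec = two_var_spec()
        with pytest.raises(DataError, match="'b'"):
            build_design(pd.DataFrame({"a": [1.0, 2.0]}), spec)

    def test_na_rejected_with_row(self):
        spec = two_var_spec()
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
        with pytest.raises(DataError, match="row 1"):
            build_design(df, spec)

    def test_unseen_categorical_level_rejected(self):
        spec = ModelSpec(
            "y", "gaussian", "r",
            [VariableSpec("r", "categorical", levels=[1, 2, 3])],
            [TermSpec(("r",))],
        )
        with pytest.raises(DataError, match="unseen level"):
            build_design(pd.DataFrame({"r": [1, 9]}), spec)


class TestRecovery:
    def test_zero_maps_to_zero(self, rng):
        spec = two_var_spec()
        df = pd.DataFrame({"a": rng.uniform(0, 3, 10), "b": rng.uniform(0, 3, 10)})
        d = build_design(df, spec)
        rec = recover_coefficients(np.zeros(d.p), d)
        assert all(not v.any() for v in rec.values())

    def test_lower_triangular_cumsum(self):
        A = np.tril(np.ones((3, 3)))
        zeta = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(A @ zeta, [1.0, 3.0, 6.0])

    def test_round_trip_machine_precision(self, rng):
        for case in MONOTONE_CASES:
            for K in range(2, 7):
                A = coding_matrix(K, case)
                zeta = rng.normal(size=K - 1)
                np.testing.assert_allclose(
                    np.linalg.solve(A, A @ zeta), zeta, atol=1e-13
                )


class TestEffectCurve:
    def _block(self, case, K=4):
        v = VariableSpec("x", "ordinal", levels=list(range(1, K + 1)))
        spec = ModelSpec(
            "y", "gaussian", "x", [v], [TermSpec(("x",), case)]
        )
        d = build_design(pd.DataFrame({"x": list(range(1, K + 1))}), spec)
        return d.blocks[0]

    def test_zero_steps_flat_curve(self):
        blk = self._block(ConstraintCase("increasing", "positive"))
        np.testing.assert_array_equal(effect_curve(blk, np.zeros(3)), np.zeros(4))

    def test_cumulative_sum_oracle(self):
        blk = self._block(ConstraintCase("increasing", "positive"))
        np.testing.assert_allclose(
            effect_curve(blk, np.array([0.2, 0.0, 0.5])), [0.0, 0.2, 0.2, 0.7]
        )

    def test_decreasing_negative_curve_shape(self, rng):
        case = ConstraintCase("decreasing", "negative")
        blk = self._block(case)
        curve = effect_curve(blk, feasible_steps(case, 3, rng))
        assert np.all(np.diff(curve) <= 1e-12) and np.all(curve <= 1e-12)

    def test_dummy_curve_zero_at_declared_reference(self):
        v = VariableSpec("x", "ordinal", levels=[1, 2, 3], reference_level=2)
        spec = ModelSpec("y", "gaussian", "x", [v], [TermSpec(("x",))])
        d = build_design(pd.DataFrame({"x": [1, 2, 3]}), spec)
        curve = effect_curve(d.blocks[0], np.array([0.3, -0.4]))
        np.testing.assert_allclose(curve, [0.3, 0.0, -0.4])

    def test_surface_reshape(self, rng):
        spec = two_var_spec(ConstraintCase("decreasing", "negative"))
        df = pd.DataFrame({"a": rng.uniform(0, 3, 30), "b": rng.uniform(0, 3, 30)})
        blk = build_design(df, spec).block_for("a", "b")
        eta = rng.normal(size=4)
        assert effect_surface(blk, eta).shape == (2, 2)


class TestConstraintSemanticsProperty:
    """Table-driven semantics: feasible steps <=> constrained curves."""

    @pytest.mark.parametrize("case", MONOTONE_CASES, ids=lambda c: f"{c.monotonicity[:3]}-{c.sign[:3]}")
    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    def test_feasible_steps_give_valid_curves_and_back(self, case, K, rng):
        Z, _ = encode_incremental(np.arange(1, K + 1), K, case)
        A = coding_matrix(K, case)
        for _ in range(50):
            steps = feasible_steps(case, K - 1, rng)
            curve = Z @ steps
            d = np.diff(curve) if case.sign != "unrestricted" else np.diff(curve)[1:]
            if case.monotonicity == "increasing":
                assert np.all(d >= -1e-10)
            else:
                assert np.all(d <= 1e-10)
            if case.sign == "positive":
                assert np.all(curve >= -1e-10)
            elif case.sign == "negative":
                assert np.all(curve <= 1e-10)
            # representability: the curve's non-reference values are A @ steps;
            # solving back must reproduce feasible steps exactly
            ref_first = case.reference_end == "first"
            beta = curve[1:] if ref_first else curve[:-1]
            back = np.linalg.solve(A, beta)
            np.testing.assert_allclose(back, steps, atol=1e-10)


class TestSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = two_var_spec(ConstraintCase("increasing", "positive"))
        p = tmp_path / "spec.yaml"
        spec.to_file(p)
        back = ModelSpec.from_file(p)
        assert back.to_dict() == spec.to_dict()

    def test_treatment_must_appear(self):
        with pytest.raises(SpecError, match="treatment"):
            ModelSpec(
                "y", "gaussian", "w",
                [VariableSpec("w", "binary"), VariableSpec("x", "binary")],
                [TermSpec(("x",))],
            )

    def test_monotone_interaction_requires_sign(self, rng):
        spec = two_var_spec(ConstraintCase("increasing", "unrestricted"))
        df = pd.DataFrame({"a": rng.uniform(0, 3, 5), "b": rng.uniform(0, 3, 5)})
        with pytest.raises(SpecError, match="declared sign"):
            build_design(df, spec)
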