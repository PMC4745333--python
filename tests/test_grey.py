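"""Unit and property tests of the GM(0,N) machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greyhrv import (
    InvalidInputError,
    RawSequence,
    SingularSystemError,
    UnderdeterminedSystemError,
    ago,
    background,
    build_design,
    solve_weights,
)

finite_values = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


def seq(values, label="x"):
    return RawSequence(label, values)


class TestAgo:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 1, 1, 1], [1, 2, 3, 4]),
            # first two pre-phase PSI entries of the averaged table
            ([38.09, 82.06], [38.09, 120.15]),
        ],
    )
    def test_cumulative_sums(self, values, expected):
        acc = ago(seq(values))
        assert np.allclose(acc.values, expected)
        assert acc.values[0] == values[0]

    def test_rejects_short_and_nonfinite(self):
        with pytest.raises(InvalidInputError):
            ago(seq([5.0]))
        with pytest.raises(InvalidInputError):
            seq([1.0, float("nan")])
        with pytest.raises(InvalidInputError):
            seq([1.0, float("inf"), 2.0])

    @given(st.lists(finite_values, min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_first_difference_inverts_accumulation(self, values):
        """Differencing the accumulated sequence recovers the input exactly."""
        acc = np.asarray(ago(seq(values)).values)
        recovered = np.diff(np.concatenate([[0.0], acc]))
        assert np.allclose(recovered, values, rtol=0, atol=1e-6 * (1 + np.abs(values).max()))

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_input_gives_nondecreasing_output(self, values):
        acc = np.asarray(ago(seq(values)).values)
        assert np.all(np.diff(acc) >= 0)


class TestBackground:
    @pytest.mark.parametrize(
        "acc,expected",
        [
            ([1, 2, 3, 4], [1.5, 2.5, 3.5]),
            ([38.09, 120.15], [79.12]),
            ([7.5, 7.5], [7.5]),
        ],
    )
    def test_adjacent_means(self, acc, expected):
        z = background(ago(seq(np.diff(np.concatenate([[0], acc])).tolist())))
        assert np.allclose(z, expected)

    def test_length_is_one_less(self):
        z = background(ago(seq([3.0, 1.0, 4.0, 1.0, 5.0])))
        assert len(z) == 4


class TestBuildDesign:
    def test_all_ones_example(self):
        d = build_design(seq([1, 1, 1], "PSI"), [seq([1, 1, 1], "TP")])
        assert np.allclose(d.background, [1.5, 2.5])
        assert np.allclose(np.asarray(d.design)[:, 0], [2, 3])
        assert d.factor_labels == ("TP",)

    def test_study_shape(self, table_pre):
        from greyhrv import to_sequences

        major, influences = to_sequences(table_pre)
        d = build_design(major, influences)
        assert d.n_equations == 44
        assert d.n_factors == 4
        assert d.factor_labels == ("TP", "VLF", "LF", "HF")

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            build_design(seq([1, 2, 3]), [seq([1, 2])])
        with pytest.raises(UnderdeterminedSystemError):
            build_design(
                seq([1, 2, 3]), [seq([1, 2, 3], "a"), seq([2, 1, 3], "b"), seq([1, 3, 2], "c")]
            )
        with pytest.raises(InvalidInputError, match="duplicated"):
            build_design(seq([1, 2, 3]), [seq([1, 2, 3], "a"), seq([4, 5, 6], "a")])
        with pytest.raises(InvalidInputError):
            build_design(seq([1, 2, 3]), [])


class TestSolveWeights:
    def test_exact_system_recovered_to_machine_precision(self):
        rng = np.random.default_rng(7)
        x1 = rng.uniform(1, 10, 6)
        x2 = rng.uniform(1, 10, 6)
        X1, X2 = np.cumsum(x1), np.cumsum(x2)
        lam_true = np.array([2.0, -1.0])
        # craft a major sequence whose background equals X @ lam exactly
        target_z = X1[1:] * 2.0 + X2[1:] * -1.0
        acc0 = np.empty(6)
        acc0[0] = target_z[0]  # free choice; background only constrains pairs
        for k in range(1, 6):
            acc0[k] = 2 * target_z[k - 1] - acc0[k - 1]
        major = np.diff(np.concatenate([[0.0], acc0]))
        res = solve_weights(
            build_design(seq(major.tolist(), "y"), [seq(x1.tolist(), "a"), seq(x2.tolist(), "b")])
        )
        assert np.allclose([res.weights["a"], res.weights["b"]], lam_true, atol=1e-9)
        assert res.residual_norm <= 1e-10 * (target_z @ target_z)

    def test_matches_normal_equation_oracle_small_instance(self):
        """4-point, 2-factor instance checked against explicit (X'X)^-1 X'z."""
        major = seq([3.0, 1.0, 4.0, 1.5], "y")
        infl = [seq([2.0, 0.5, 1.0, 3.0], "a"), seq([1.0, 2.0, 0.5, 1.0], "b")]
        d = build_design(major, infl)
        X, z = d.design_array(), d.background_array()
        oracle = np.linalg.solve(X.T @ X, X.T @ z)
        res = solve_weights(d)
        assert np.allclose([res.weights["a"], res.weights["b"]], oracle, rtol=1e-10)

    @given(st.integers(0, 1000), st.integers(5, 10), st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_random_instances(self, rng_seed, L, n_factors):
        """Random full-rank instances agree with the normal-equation solution."""
        rng = np.random.default_rng(rng_seed)
        major = seq(rng.uniform(0.5, 10, L).tolist(), "y")
        infl = [seq(rng.uniform(0.5, 10, L).tolist(), f"f{j}") for j in range(n_factors)]
        d = build_design(major, infl)
        X, z = d.design_array(), d.background_array()
        if np.linalg.cond(X.T @ X) > 1e10:
            return
        oracle = np.linalg.solve(X.T @ X, X.T @ z)
        res = solve_weights(d)
        got = np.array([res.weights[f"f{j}"] for j in range(n_factors)])
        assert np.allclose(got, oracle, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("c", [0.5, 3.0, 100.0])
    def test_scaling_equivariance(self, c):
        rng = np.random.default_rng(11)
        major = rng.uniform(1, 5, 8)
        x = [rng.uniform(1, 5, 8) for _ in range(2)]
        base = solve_weights(
            build_design(seq(major.tolist(), "y"), [seq(v.tolist(), f"f{j}") for j, v in enumerate(x)])
        )
        # scaling the major sequence scales every weighting
        scaled_major = solve_weights(
            build_design(
                seq((c * major).tolist(), "y"),
                [seq(v.tolist(), f"f{j}") for j, v in enumerate(x)],
            )
        )
        for j in range(2):
            assert scaled_major.weights[f"f{j}"] == pytest.approx(c * base.weights[f"f{j}"])
        # scaling influence j divides its own weighting, leaves others unchanged
        scaled_infl = solve_weights(
            build_design(
                seq(major.tolist(), "y"),
                [seq((c * x[0]).tolist(), "f0"), seq(x[1].tolist(), "f1")],
            )
        )
        assert scaled_infl.weights["f0"] == pytest.approx(base.weights["f0"] / c)
        assert scaled_infl.weights["f1"] == pytest.approx(base.weights["f1"])

    def test_singular_design_names_offending_columns(self):
        major = seq([1.0, 2.0, 3.0, 4.0, 5.0], "y")
        a = [1.0, 2.0, 1.0, 3.0, 2.0]
        doubled = [2 * v for v in a]
        with pytest.raises(SingularSystemError) as err:
            solve_weights(build_design(major, [seq(a, "a"), seq(doubled, "b")]))
        assert err.value.columns  # at least one collinear column named
        assert set(err.value.columns) <= {"a", "b"}

    def test_ranking_orders_by_magnitude_with_canonical_tiebreak(self):
        from greyhrv.grey import GreyDesign, solve_weights as sw

        d = GreyDesign(
            background=(1.0, 2.0, 3.0),
            design=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
            factor_labels=("HF", "TP", "LF"),
        )
        res = sw(d)
        assert res.ranking == ("LF", "TP", "HF")
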