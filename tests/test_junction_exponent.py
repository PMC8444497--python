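"""Solver for the junction exponent d0^k = d1^k + d2^k."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veinlaw import (
    Case,
    KKind,
    JunctionExponentSolver,
    classify,
    mixed_argmin_oracle,
    solve_k,
    solve_table,
    symmetric_oracle,
)

# frozen oracle values (computed with an independent bracketed bisection /
# closed forms before the solver was written)
ROOT_09_05 = 2.2463636756416037
K_SYM_11 = -7.272540897341717
ARGMIN_105_0999 = -78.06741623111644
ARGMIN_11_06 = 2.7698275758204893
MURRAY_CHILD = 2.0 ** (-1.0 / 3.0)
DAVINCI_CHILD = 2.0 ** (-1.0 / 2.0)


class TestClassify:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((100, 80, 80), Case.STANDARD),
            ((100, 110, 110), Case.BOTH_WIDER),
            ((100, 105, 99.9), Case.MIXED),
            ((100, 99.9, 105), Case.MIXED),
            ((100, 100, 50), Case.DEGENERATE),
            ((100, 50, 100), Case.DEGENERATE),
            ((100, 100, 100), Case.DEGENERATE),
        ],
    )
    def test_case_taxonomy(self, triple, expected):
        assert classify(*triple) is expected

    def test_child_order_never_affects_label(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            d0 = rng.uniform(1, 1000)
            d1, d2 = rng.uniform(0.2, 1.8, 2) * d0
            assert classify(d0, d1, d2) is classify(d0, d2, d1)

    @pytest.mark.parametrize("triple", [(0, 1, 1), (1, -2, 1), (1, 1, 0.0)])
    def test_nonpositive_diameter_rejected(self, triple):
        with pytest.raises(ValueError, match="positive"):
            classify(*triple)


class TestSolveK:
    @pytest.mark.parametrize(
        "triple, expected, tol",
        [
            ((1.0, MURRAY_CHILD, MURRAY_CHILD), 3.0, 1e-9),
            ((1.0, DAVINCI_CHILD, DAVINCI_CHILD), 2.0, 1e-9),
            ((1.0, 0.9, 0.5), ROOT_09_05, 1e-9),
            ((1.0, 1.1, 1.1), K_SYM_11, 1e-9),
            ((1.0, 1.05, 0.999), ARGMIN_105_0999, 1e-6),
            ((1.0, 1.1, 0.6), ARGMIN_11_06, 1e-6),
        ],
    )
    def test_reference_forks(self, triple, expected, tol):
        res = solve_k(*triple)
        assert res.k == pytest.approx(expected, abs=tol)

    def test_standard_fork_is_exact_positive_root(self):
        res = solve_k(1.0, 0.9, 0.5)
        assert res.case is Case.STANDARD
        assert res.k_kind is KKind.EXACT_ROOT
        assert res.k > 0
        assert res.residual <= 1e-9

    def test_both_wider_fork_is_exact_negative_root(self):
        res = solve_k(1.0, 1.2, 1.4)
        assert res.case is Case.BOTH_WIDER
        assert res.k_kind is KKind.EXACT_ROOT
        assert res.k < 0
        assert res.residual <= 1e-9

    def test_mixed_fork_reports_argmin_not_root(self):
        res = solve_k(1.0, 1.1, 0.6)
        assert res.case is Case.MIXED
        assert res.k_kind is KKind.ARGMIN
        # at the argmin f stays above 1: no real root exists
        assert (1.1**res.k + 0.6**res.k) > 1.0

    def test_degenerate_and_uncomputable_have_no_k(self):
        deg = solve_k(100.0, 100.0, 50.0)
        assert deg.case is Case.DEGENERATE and math.isnan(deg.k)
        unc = solve_k(100.0, 100.0000001, 99.99999999)
        assert unc.case is Case.UNCOMPUTABLE and math.isnan(unc.k)

    def test_child_symmetry(self):
        a = solve_k(100.0, 90.0, 50.0)
        b = solve_k(100.0, 50.0, 90.0)
        assert a.k == pytest.approx(b.k, abs=1e-12)
        assert a.case is b.case

    def test_power_of_two_rescaling_is_exact(self):
        # binary scaling leaves the diameter ratios bit-identical
        base = solve_k(1.0, 0.9, 0.5)
        for c in (0.25, 2.0, 64.0):
            assert solve_k(c, 0.9 * c, 0.5 * c).k == base.k


@settings(derandomize=True, max_examples=300)
@given(ratio=st.floats(0.05, 0.95), d0=st.floats(1.0, 1000.0))
def test_symmetric_closed_form_agreement(ratio, d0):
    """For equal children the solver must match ln2/ln(d0/d_child)."""
    res = solve_k(d0, ratio * d0, ratio * d0)
    assert res.k == pytest.approx(symmetric_oracle(d0, ratio * d0), abs=1e-9)


@settings(derandomize=True, max_examples=300)
@given(
    a=st.floats(1.001, 3.0),
    b=st.floats(0.05, 0.999),
    k=st.floats(-50, 50),
)
def test_mixed_lemma_no_real_root(a, b, k):
    """a^k + b^k > 1 for all real k when a > 1 > b: mixed forks have no root."""
    assert a**k + b**k > 1.0


@settings(derandomize=True, max_examples=300)
@given(a=st.floats(1.001, 3.0), b=st.floats(0.05, 0.999))
def test_mixed_argmin_matches_closed_form(a, b):
    res = solve_k(1.0, a, b)
    if res.case is Case.MIXED:
        assert res.k == pytest.approx(mixed_argmin_oracle(a, b), abs=1e-6)


@settings(derandomize=True, max_examples=200)
@given(
    r1=st.floats(0.2, 0.95),
    r2=st.floats(0.2, 0.95),
    c=st.floats(1e-3, 1e3),
)
def test_scale_invariance(r1, r2, c):
    """The solver sees only ratios, so rescaling all diameters is a no-op."""
    k0 = solve_k(1.0, r1, r2).k
    k1 = solve_k(c, r1 * c, r2 * c).k
    assert k1 == pytest.approx(k0, rel=1e-9)


def test_monotone_in_symmetric_child():
    """k grows strictly with the (equal) child diameter below d0."""
    ratios = np.linspace(0.3, 0.95, 40)
    ks = [solve_k(1.0, r, r).k for r in ratios]
    assert np.all(np.diff(ks) > 0)


def test_argmin_of_reciprocal_pair_is_zero():
    for a in (1.5, 2.0, 7.3):
        assert mixed_argmin_oracle(a, 1.0 / a) == pytest.approx(0.0, abs=1e-12)


def test_symmetric_oracle_contract():
    assert symmetric_oracle(1.0, 0.5) == pytest.approx(1.0, abs=1e-12)
    assert symmetric_oracle(2.0, 1.0) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="degenerate"):
        symmetric_oracle(1.0, 1.0)


class TestSolverTransformer:
    def test_transform_appends_solution_columns(self, ten_row_table):
        assert {"k", "case", "k_kind", "residual"} <= set(ten_row_table.columns)
        assert len(ten_row_table) == 10

    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = JunctionExponentSolver(tol=1e-10)
        assert clone(est).get_params()["tol"] == 1e-10

    def test_rejects_nonpositive_rows(self):
        import pandas as pd

        bad = pd.DataFrame({"d0": [1.0, 1.0], "d1": [0.5, -1.0], "d2": [0.5, 0.5]})
        with pytest.raises(ValueError, match="non-positive"):
            JunctionExponentSolver().fit_transform(bad)

    def test_solve_is_deterministic(self, ten_row_table):
        again = solve_table(ten_row_table[["d0", "d1", "d2"]])
        assert (again["k"].fillna(0) == ten_row_table["k"].fillna(0)).all()
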