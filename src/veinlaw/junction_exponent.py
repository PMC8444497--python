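"""Junction exponent of a vein bifurcation.

A parent vessel of internal diameter ``d0`` splitting into children ``d1``
and ``d2`` is summarised by the junction exponent ``k`` solving

    d0**k == d1**k + d2**k

``k == 3`` is Murray's Law (transport capacity conserved across the fork),
``k == 2`` is da Vinci's Law (flow velocity conserved), ``k == 4`` conserves
resistance.  Working in the normalised ratios ``a = d1/d0`` and
``b = d2/d0`` the equation becomes ``f(k) = a**k + b**k = 1``.

The geometry of the fork decides whether a real root exists:

* both children narrower than the parent (``a, b < 1``): ``f`` is strictly
  decreasing from ``f(0) = 2`` to 0, so a unique root ``k > 0`` exists;
* both children wider (``a, b > 1``): by the mirrored argument a unique
  root ``k < 0`` exists;
* one wider, one narrower (``a > 1 > b``): ``f(k) > 1`` for every real k
  (for k > 0 the wide child alone exceeds 1, for k < 0 the narrow child
  does, and ``f(0) = 2``), so no root exists.  We report the best-fit
  exponent instead: the argmin of ``f``, available in closed form as
  ``k* = ln(ln(1/b)/ln a) / ln(a/b)``.

A child exactly as wide as the parent is degenerate (the remaining child
would need ``d = 0``); exponents beyond a magnitude cap are flagged
uncomputable, mirroring forks whose best-fit exponent underflows any
practical solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Case",
    "KKind",
    "ExponentResult",
    "classify",
    "solve_k",
    "solve_table",
    "symmetric_oracle",
    "mixed_argmin_oracle",
    "JunctionExponentSolver",
]


class Case(str, Enum):
    """Geometric class of a bifurcation."""

    STANDARD = "standard"          # d1 < d0 and d2 < d0
    BOTH_WIDER = "both_wider"      # d1 > d0 and d2 > d0
    MIXED = "mixed"                # one child wider, one narrower
    DEGENERATE = "degenerate"      # a child diameter equals d0 exactly
    UNCOMPUTABLE = "uncomputable"  # |k| beyond bound or solver failure


class KKind(str, Enum):
    EXACT_ROOT = "exact_root"
    ARGMIN = "argmin"
    NONE = "none"


@dataclass(frozen=True)
class ExponentResult:
    """Solved junction exponent with solver diagnostics.

    ``k`` is NaN when no exponent is reported (degenerate/uncomputable).
    ``residual`` is ``|a**k + b**k - 1|`` at the returned ``k``.
    """

    k: float
    case: Case
    k_kind: KKind
    residual: float
    iterations: int


def _check_diameters(d0: float, d1: float, d2: float) -> None:
    if not (d0 > 0 and d1 > 0 and d2 > 0):
        raise ValueError(
            f"diameters must be positive, got d0={d0}, d1={d1}, d2={d2}"
        )


def classify(d0: float, d1: float, d2: float) -> Case:
    """Classify the fork geometry; symmetric in the two children."""
    _check_diameters(d0, d1, d2)
    if d1 == d0 or d2 == d0:
        return Case.DEGENERATE
    wider = (d1 > d0) + (d2 > d0)
    if wider == 0:
        return Case.STANDARD
    if wider == 2:
        return Case.BOTH_WIDER
    return Case.MIXED


def symmetric_oracle(d0: float, d_child: float) -> float:
    """Closed-form exponent for an equal-children fork: ln2 / ln(d0/d_child)."""
    if d0 <= 0 or d_child <= 0:
        raise ValueError("diameters must be positive")
    if d_child == d0:
        raise ValueError("degenerate fork: child diameter equals parent")
    return math.log(2.0) / math.log(d0 / d_child)


def mixed_argmin_oracle(a: float, b: float) -> float:
    """Minimizer of f(k) = a**k + b**k for a > 1 > b > 0.

    Setting f'(k) = 0 gives a**k ln a = -b**k ln b, hence
    k* = ln(ln(1/b)/ln a) / ln(a/b).
    """
    if not (a > 1.0 > b > 0.0):
        raise ValueError(f"mixed case requires a > 1 > b > 0, got a={a}, b={b}")
    return math.log(math.log(1.0 / b) / math.log(a)) / math.log(a / b)


def _f(k: float, log_a: float, log_b: float) -> float:
    return math.exp(k * log_a) + math.exp(k * log_b)


def solve_k(
    d0: float,
    d1: float,
    d2: float,
    tol: float = 1e-12,
    k_bound: float = 1e6,
) -> ExponentResult:
    """Solve ``(d1/d0)**k + (d2/d0)**k = 1`` for the junction exponent.

    Standard and both-wider forks get the exact bracketed root (bisection-
    safe Brent on the monotone f); equal children use the closed form with
    no iteration; mixed forks get the closed-form argmin of f, flagged
    ``k_kind='argmin'``.  The solver works on the ratios only, so it is
    exactly scale invariant.
    """
    case = classify(d0, d1, d2)
    nan = float("nan")
    if case is Case.DEGENERATE:
        return ExponentResult(nan, case, KKind.NONE, nan, 0)

    a = d1 / d0
    b = d2 / d0
    log_a = math.log(a)
    log_b = math.log(b)

    if case is Case.MIXED:
        hi, lo = (a, b) if a > b else (b, a)
        k_star = mixed_argmin_oracle(hi, lo)
        if abs(k_star) > k_bound or not math.isfinite(k_star):
            return ExponentResult(nan, Case.UNCOMPUTABLE, KKind.NONE, nan, 0)
        residual = abs(_f(k_star, log_a, log_b) - 1.0)
        return ExponentResult(k_star, case, KKind.ARGMIN, residual, 0)

    if d1 == d2:
        k = math.log(2.0) / (-log_a)
        if abs(k) > k_bound:
            return ExponentResult(nan, Case.UNCOMPUTABLE, KKind.NONE, nan, 0)
        residual = abs(_f(k, log_a, log_b) - 1.0)
        return ExponentResult(k, case, KKind.EXACT_ROOT, residual, 0)

    # f is strictly monotone; the root lies on the side where both ratios
    # sit relative to 1.  Grow the bracket geometrically from k=0 (f=2).
    sign = 1.0 if case is Case.STANDARD else -1.0
    hi = 1.0
    evals = 0
    while _f(sign * hi, log_a, log_b) > 1.0:
        hi *= 2.0
        evals += 1
        if hi > k_bound:
            return ExponentResult(nan, Case.UNCOMPUTABLE, KKind.NONE, nan, evals)
    lo_k, hi_k = sorted((0.0, sign * hi))
    try:
        k, res = brentq(
            lambda kk: _f(kk, log_a, log_b) - 1.0,
            lo_k,
            hi_k,
            xtol=tol,
            rtol=4 * np.finfo(float).eps,
            full_output=True,
        )
    except (ValueError, RuntimeError):
        return ExponentResult(nan, Case.UNCOMPUTABLE, KKind.NONE, nan, evals)
    residual = abs(_f(k, log_a, log_b) - 1.0)
    return ExponentResult(
        float(k), case, KKind.EXACT_ROOT, residual, evals + res.iterations
    )


def solve_table(frame: pd.DataFrame, tol: float = 1e-12, k_bound: float = 1e6) -> pd.DataFrame:
    """Append columns ``k``, ``case``, ``k_kind``, ``residual`` to a
    measurement table with ``d0``, ``d1``, ``d2`` columns.  Deterministic:
    no randomness anywhere in the solve."""
    required = {"d0", "d1", "d2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing diameter columns: {sorted(missing)}")
    out = frame.copy()
    results = [
        solve_k(row.d0, row.d1, row.d2, tol=tol, k_bound=k_bound)
        for row in frame[["d0", "d1", "d2"]].itertuples(index=False)
    ]
    out["k"] = [r.k for r in results]
    out["case"] = [r.case.value for r in results]
    out["k_kind"] = [r.k_kind.value for r in results]
    out["residual"] = [r.residual for r in results]
    return out


class JunctionExponentSolver(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: measurement table in, solved table out.

    Parameters
    ----------
    tol : float
        Root residual tolerance passed to the bracketed solver.
    k_bound : float
        Magnitude cap on |k|; beyond it a fork is flagged uncomputable.
    """

    def __init__(self, tol: float = 1e-12, k_bound: float = 1e6):
        self.tol = tol
        self.k_bound = k_bound

    def fit(self, X: pd.DataFrame, y=None) -> "JunctionExponentSolver":
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._validate(X)
        return solve_table(X, tol=self.tol, k_bound=self.k_bound)

    @staticmethod
    def _validate(X: pd.DataFrame) -> None:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a pandas DataFrame of measurements")
        missing = {"d0", "d1", "d2"} - set(X.columns)
        if missing:
            raise ValueError(f"missing diameter columns: {sorted(missing)}")
        bad = X[["d0", "d1", "d2"]].le(0).any(axis=1)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} rows have non-positive diameters"
            )
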