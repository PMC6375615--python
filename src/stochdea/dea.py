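"""Variable-returns-to-scale DEA: envelopment form, two phases, both orientations.

For DMU ``k`` with input matrix ``X`` (n x m) and output matrix ``Y``
(n x s), phase 1 solves the BCC envelopment program

* input orientation:  min theta  s.t.  X'lam <= theta * x_k,
  Y'lam >= y_k,  1'lam = 1,  lam >= 0
* output orientation: max phi    s.t.  X'lam <= x_k,
  Y'lam >= phi * y_k,  1'lam = 1,  lam >= 0

and phase 2 fixes the radial objective and maximizes the total slack, so
frontier units with nonzero residual slacks can be told apart (weakly
efficient) from fully efficient ones.  The reported RTE score is
``theta`` (input) or ``1 / phi`` (output), so both orientations live on
a common [0, 1] scale with 1 = frontier.

LPs are solved with scipy's HiGHS backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import linprog

from .exceptions import SolverError, ValidationError

Orientation = Literal["input", "output"]

#: boundary tolerance for the efficient classification
DEFAULT_TOL = 1e-6
#: floor applied to inputs so the LPs stay well-posed when interpreted
#: values hit zero (rates can be 0 in sparse areas)
INPUT_EPS = 1e-9


@dataclass(frozen=True)
class DEAProblem:
    """One DEA instance: inputs, outputs and the orientation to score."""

    X: np.ndarray
    Y: np.ndarray
    orientation: Orientation = "input"

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if X.ndim != 2 or Y.ndim != 2:
            raise ValidationError("X and Y must be 2-D matrices")
        if X.shape[0] != Y.shape[0]:
            raise ValidationError(
                f"X has {X.shape[0]} DMUs but Y has {Y.shape[0]}"
            )
        if X.shape[0] < 1 or X.shape[1] < 1 or Y.shape[1] < 1:
            raise ValidationError("need at least one DMU, one input and one output")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValidationError("NaN in DEA data")
        if (Y < 0).any():
            raise ValidationError("outputs must be non-negative")
        object.__setattr__(self, "X", np.maximum(X, INPUT_EPS))
        object.__setattr__(self, "Y", Y)
        if self.orientation not in ("input", "output"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class DEAResult:
    """Score, peers and slacks for one DMU."""

    rte: float
    raw_objective: float
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    efficiency_class: str  # "efficient" | "weakly_efficient" | "inefficient"

    @property
    def slack_sum(self) -> float:
        return float(self.input_slacks.sum() + self.output_slacks.sum())


def classify(rte: float, slack_sum: float, tol: float = DEFAULT_TOL) -> str:
    """Efficiency class from the score and the total slack."""
    if abs(rte - 1.0) < tol:
        return "efficient" if slack_sum < tol else "weakly_efficient"
    return "inefficient"


def _lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise SolverError(f"LP failed: {res.message}")
    return res


def solve_vrs(
    problem: DEAProblem,
    k: int,
    tol: float = DEFAULT_TOL,
    phase2: Literal["always", "boundary", "never"] = "always",
) -> DEAResult:
    """Score DMU ``k`` against the VRS frontier of all DMUs.

    ``phase2`` controls the slack-maximization phase: ``"always"`` runs
    it for every unit, ``"boundary"`` only when the radial score is at
    the frontier (the only case where slacks change the classification),
    ``"never"`` reports the phase-1 residual slacks.
    """
    X, Y = problem.X, problem.Y
    n, m = X.shape
    s = Y.shape[1]
    if not 0 <= k < n:
        raise ValidationError(f"DMU index {k} out of range [0, {n})")
    xk, yk = X[k], Y[k]
    inp = problem.orientation == "input"

    # phase 1 — radial program; variables: [objective, lambda_1..lambda_n]
    if inp:
        c = np.r_[1.0, np.zeros(n)]
        A_ub = np.block([
            [-xk[:, None], X.T],          # X'lam - theta*xk <= 0
            [np.zeros((s, 1)), -Y.T],     # -Y'lam <= -yk
        ])
        b_ub = np.r_[np.zeros(m), -yk]
    else:
        c = np.r_[-1.0, np.zeros(n)]      # max phi
        A_ub = np.block([
            [np.zeros((m, 1)), X.T],      # X'lam <= xk
            [yk[:, None], -Y.T],          # phi*yk - Y'lam <= 0
        ])
        b_ub = np.r_[xk, np.zeros(s)]
    A_eq = np.r_[0.0, np.ones(n)][None, :]
    res1 = _lp(c, A_ub, b_ub, A_eq, [1.0], bounds=[(0, None)] * (n + 1))
    obj = float(res1.x[0])
    lambdas = res1.x[1:]

    # phase 2 — fix the radial objective, maximize total slack
    # variables: [lambda (n), s_in (m), s_out (s)]
    target_x = obj * xk if inp else xk
    target_y = yk if inp else obj * yk
    run2 = phase2 == "always" or (
        phase2 == "boundary" and abs(obj - 1.0) < tol
    )
    if run2:
        A_eq2 = np.block([
            [X.T, np.eye(m), np.zeros((m, s))],   # X'lam + s_in = target_x
            [Y.T, np.zeros((s, m)), -np.eye(s)],  # Y'lam - s_out = target_y
            [np.ones((1, n)), np.zeros((1, m + s))],
        ])
        b_eq2 = np.r_[target_x, target_y, 1.0]
        c2 = np.r_[np.zeros(n), -np.ones(m + s)]
        res2 = _lp(c2, A_eq=A_eq2, b_eq=b_eq2, bounds=[(0, None)] * (n + m + s))
        lambdas = res2.x[:n]
        s_in = res2.x[n : n + m]
        s_out = res2.x[n + m :]
    else:
        s_in = np.maximum(target_x - X.T @ lambdas, 0.0)
        s_out = np.maximum(Y.T @ lambdas - target_y, 0.0)

    rte = obj if inp else 1.0 / obj
    rte = float(np.clip(rte, 0.0, 1.0))
    slack_sum = float(s_in.sum() + s_out.sum())
    return DEAResult(
        rte=rte,
        raw_objective=obj,
        lambdas=lambdas,
        input_slacks=s_in,
        output_slacks=s_out,
        efficiency_class=classify(rte, slack_sum, tol),
    )


def solve_all(
    problem: DEAProblem,
    tol: float = DEFAULT_TOL,
    phase2: Literal["always", "boundary", "never"] = "always",
) -> list[DEAResult]:
    """Score every DMU; results are index-aligned with the rows of X/Y."""
    return [solve_vrs(problem, k, tol=tol, phase2=phase2) for k in range(problem.n)]
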