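"""Thin deterministic LP layer over scipy's HiGHS interface.

All flux problems in this package are of the form

    max c.v   s.t.  S v = 0,  lb <= v <= ub

optionally with extra rows.  HiGHS is deterministic for a fixed problem, so
identical inputs give identical solutions; feasibility/optimality tolerances
are pinned at 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

FEAS_TOL = 1e-9

_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEAS_TOL,
    "dual_feasibility_tolerance": FEAS_TOL,
}


@dataclass
class LPResult:
    status: str           # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    x: np.ndarray | None


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    *,
    maximize: bool = True,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> LPResult:
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=dict(_OPTIONS),
    )
    if res.status == 0:
        return LPResult("optimal", sign * res.fun, res.x)
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    raise RuntimeError(f"LP solver failure: {res.message}")
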