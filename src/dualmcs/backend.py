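"""Solver adapter: translate a :class:`MilpModel` for scipy's HiGHS MILP.

The adapter contract: honor variable bounds, senses, binaries and indicator
links, accept a random seed, and report optimal/infeasible status
faithfully.  HiGHS (through :func:`scipy.optimize.milp`) has no native
indicator constraints, so models still carrying indicator links are lowered
to their big-M form here, at translation time, without mutating the input
model.  The seed permutes the variable order handed to the solver, which
perturbs branching and tie-breaking; the *set* of solutions found across an
enumeration is seed-invariant (a tested contract), only discovery order may
change.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .milp_variants import MilpModel, encode_big_m
from .validation import SolverError

__all__ = ["solve_milp"]


def solve_milp(
    model: MilpModel,
    seed: int = 0,
    time_limit: float | None = None,
) -> tuple[str, dict[str, float] | None]:
    """Solve; returns ("optimal", values-by-name) or ("infeasible", None)."""
    if model.indicators:
        model = encode_big_m(model)

    names = [v.name for v in model.variables]
    order = np.random.default_rng(seed).permutation(len(names))
    names = [names[k] for k in order]
    pos = {name: j for j, name in enumerate(names)}
    nvar = len(names)

    c = np.zeros(nvar)
    for z in model.objective:
        c[pos[z]] = 1.0
    integrality = np.zeros(nvar)
    lb = np.full(nvar, -np.inf)
    ub = np.full(nvar, np.inf)
    for var in model.variables:
        j = pos[var.name]
        lb[j], ub[j] = var.lb, var.ub
        if var.kind == "binary":
            integrality[j] = 1

    ncons = len(model.constraints)
    A = np.zeros((ncons, nvar))
    clo = np.full(ncons, -np.inf)
    chi = np.full(ncons, np.inf)
    for k, con in enumerate(model.constraints):
        for name, coef in con.coeffs.items():
            A[k, pos[name]] += coef
        if con.sense == "=":
            clo[k] = chi[k] = con.rhs
        elif con.sense == "<=":
            chi[k] = con.rhs
        else:
            clo[k] = con.rhs

    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=c,
        constraints=LinearConstraint(A, clo, chi) if ncons else (),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    if res.status == 0:
        return "optimal", {name: float(res.x[pos[name]]) for name in names}
    if res.status == 2:
        return "infeasible", None
    if res.status == 1:
        raise SolverError("MILP terminated on a time/iteration limit (suboptimal)")
    raise SolverError(f"MILP solver failed with status {res.status}: {res.message}")
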