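"""Certification of candidate cut sets by linear programs.

A candidate knockout set is a valid (constrained) MCS iff three LP checks
pass:

* it is a cut set — the target region becomes infeasible under the
  knockouts;
* it is minimal — dropping any single knockout makes the target feasible
  again;
* when a desired region is given, at least one desired flux vector survives
  the knockouts.

Feasibility questions are decided with HiGHS (scipy.optimize.linprog);
"infeasible" requires solver-certified infeasibility, never a mere failure
to find a solution.  For disputes on desk-scale systems an exact rational
fallback based on extreme-ray enumeration of the homogenized region is
available (:func:`exact_region_feasible`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .model_io import (
    CutSet,
    DualMcsError,
    LinearConstraintRegion,
    MCSProblem,
    MetabolicNetwork,
)

logger = logging.getLogger(__name__)

#: feasibility tolerance handed to HiGHS
LP_TOL = 1e-9


class SolverError(DualMcsError):
    """The LP/MILP backend failed in a way that cannot be interpreted."""


@dataclass
class ValidationReport:
    """Outcome of the three certification LPs for one candidate."""

    is_cut: bool
    is_minimal: bool
    desired_feasible: bool | None
    witness: np.ndarray | None = None

    @property
    def is_valid_mcs(self) -> bool:
        return (
            self.is_cut
            and self.is_minimal
            and (self.desired_feasible is None or self.desired_feasible)
        )

    def flags(self) -> tuple[bool, bool, bool | None]:
        return (self.is_cut, self.is_minimal, self.desired_feasible)


def _to_float(x: Fraction) -> float:
    return float(x)


def lp_feasible(
    region: LinearConstraintRegion,
    network: MetabolicNetwork,
    knockouts: frozenset[int] | set[int] = frozenset(),
) -> tuple[bool, np.ndarray | None]:
    """Decide feasibility of a region under knockouts; return (flag, witness).

    The polyhedron checked is {r | N r = 0, r_i >= 0 for i in Irrev,
    region rows satisfied, lb <= r <= ub, r_j = 0 for j in knockouts}.
    Applying the raw flux box is harmless for the target region (whose rows
    already contain the folded bounds) and required for the desired region.
    """
    n = network.n
    if region.k and len(region.matrix[0]) != n:
        raise DualMcsError("region column count does not match network")
    A_eq = np.array([[float(x) for x in row] for row in network.N], dtype=float)
    b_eq = np.zeros(network.m)
    A_ub = np.array([[float(x) for x in row] for row in region.matrix], dtype=float)
    b_ub = np.array([float(x) for x in region.rhs], dtype=float)
    irrev = network.irrev
    bounds = []
    for i in range(n):
        if i in knockouts:
            bounds.append((0.0, 0.0))
            continue
        lo = network.lb[i]
        hi = network.ub[i]
        lo_f = 0.0 if (i in irrev and (lo is None or lo < 0)) else (
            -np.inf if lo is None else float(lo)
        )
        if i in irrev and lo is not None:
            lo_f = max(lo_f, float(lo))
        hi_f = np.inf if hi is None else float(hi)
        bounds.append((lo_f, hi_f))

    kwargs = dict(
        c=np.zeros(n),
        A_eq=A_eq if network.m else None,
        b_eq=b_eq if network.m else None,
        A_ub=A_ub if region.k else None,
        b_ub=b_ub if region.k else None,
        bounds=bounds,
        method="highs",
    )
    res = linprog(**kwargs, options={"primal_feasibility_tolerance": LP_TOL})
    if res.status == 0:
        return True, res.x
    if res.status == 2:
        return False, None
    # numerical trouble: retry once at a tighter tolerance before giving up
    res = linprog(**kwargs, options={"primal_feasibility_tolerance": 1e-11})
    if res.status == 0:
        return True, res.x
    if res.status == 2:
        return False, None
    raise SolverError(f"LP solver failed with status {res.status}: {res.message}")


def validate_cutset(problem: MCSProblem, candidate: CutSet) -> ValidationReport:
    """Run the three certification LPs for one candidate knockout set."""
    if not candidate.indices:
        raise DualMcsError("cannot validate an empty candidate")
    net = problem.network
    cut_feasible, _ = lp_feasible(problem.target, net, candidate.indices)
    is_cut = not cut_feasible
    is_minimal = True
    for j in sorted(candidate.indices):
        reduced = frozenset(candidate.indices - {j})
        still_cut, _ = lp_feasible(problem.target, net, reduced)
        if not still_cut:
            is_minimal = False
            break
    desired_feasible: bool | None = None
    witness = None
    if problem.desired is not None:
        desired_feasible, witness = lp_feasible(
            problem.desired, net, candidate.indices
        )
    return ValidationReport(
        is_cut=is_cut,
        is_minimal=is_minimal,
        desired_feasible=desired_feasible,
        witness=witness,
    )


def exact_region_feasible(
    region: LinearConstraintRegion,
    network: MetabolicNetwork,
    knockouts: frozenset[int] | set[int] = frozenset(),
) -> bool:
    """Exact rational feasibility via extreme rays of the homogenized region.

    The region {N r = 0, r_Irrev >= 0, A r <= b, box bounds, knockouts} is
    feasible iff the cone {(r, y, s) >= partial | N r = 0, A r + s = b y,
    y >= 0} (s slack, y homogenizing) has a generator with y > 0.  Intended
    for desk-scale dispute resolution and tests, not production runs.
    """
    from .reference_enumeration import extreme_rays_mixed

    n = network.n
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for row, b in zip(region.matrix, region.rhs):
        rows.append(list(row))
        rhs.append(b)
    for i in range(n):
        lo, hi = network.lb[i], network.ub[i]
        if hi is not None:
            r = [Fraction(0)] * n
            r[i] = Fraction(1)
            rows.append(r)
            rhs.append(hi)
        if lo is not None and lo != 0:
            r = [Fraction(0)] * n
            r[i] = Fraction(-1)
            rows.append(r)
            rhs.append(-lo)
    k = len(rows)
    # variables: r (n) | y (1) | s (k); equalities: N r = 0 (after knockouts),
    # A r - b y + s = 0
    nvar = n + 1 + k
    eq: list[list[Fraction]] = []
    for row in network.N:
        eq.append(list(row) + [Fraction(0)] * (1 + k))
    for j, (row, b) in enumerate(zip(rows, rhs)):
        slack = [Fraction(0)] * k
        slack[j] = Fraction(1)
        eq.append(list(row) + [-b] + slack)
    for j in sorted(knockouts):
        r = [Fraction(0)] * nvar
        r[j] = Fraction(1)
        eq.append(r)
    nonneg = set(network.irrev) | {n} | {n + 1 + j for j in range(k)}
    rays = extreme_rays_mixed(eq, nvar, nonneg)
    return any(ray[n] > 0 for ray in rays)
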