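"""Solver-independent ground truth for MCS computations.

Two independent reference routes are provided:

* full enumeration of the elementary modes (support-minimal rays) of a dual
  system's cone with the double description method in exact integer
  arithmetic, followed by the support/coordinated-support extraction rules —
  this is the classical "MCS as EMs of a dual network" route;

* a brute-force knockout oracle that tests every reaction subset up to a
  cardinality limit with feasibility LPs — completely independent of any
  dual construction and used to certify every other path.

Both are deliberately exact and deliberately desk-scale: exactness beats
speed for an oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb, gcd

from .dual_construction import (
    DualSolution,
    FlbDualSystem,
    NbDualSystem,
    build_flb_dual,
    build_nb_dual,
    cutsets_from_dual_solutions,
)
from .exact_linalg import Matrix
from .model_io import CutSet, DualMcsError, MCSProblem
from .validation import lp_feasible

logger = logging.getLogger(__name__)

__all__ = [
    "PolyhedralCone",
    "ScaleError",
    "extreme_rays_nonneg",
    "extreme_rays_mixed",
    "enumerate_extreme_rays",
    "enumerate_dual_ems",
    "full_dual_mcs_enumeration",
    "brute_force_mcs",
]


class ScaleError(DualMcsError):
    """The instance exceeds the configured desk-scale enumeration budget."""


@dataclass
class PolyhedralCone:
    """{x | eq @ x = 0, x_i >= 0 for i in nonneg, x_j free otherwise}."""

    eq_matrix: Matrix
    dim: int
    nonneg: frozenset[int]

    def __post_init__(self):
        self.nonneg = frozenset(self.nonneg)
        if any(len(row) != self.dim for row in self.eq_matrix):
            raise DualMcsError("cone equality rows disagree with dimension")

    @property
    def free(self) -> frozenset[int]:
        return frozenset(range(self.dim)) - self.nonneg


def _int_rows(eq_matrix: Matrix) -> list[tuple[int, ...]]:
    """Scale each rational row to coprime integers (empty rows dropped)."""
    out = []
    for row in eq_matrix:
        denom = 1
        for x in row:
            f = Fraction(x)
            denom = denom * f.denominator // gcd(denom, f.denominator)
        ints = [int(Fraction(x) * denom) for x in row]
        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        if g == 0:
            continue
        out.append(tuple(v // g for v in ints))
    return out


def _reduce_ray(vec: list[int]) -> tuple[int, ...]:
    g = 0
    for v in vec:
        g = gcd(g, abs(v))
    if g > 1:
        vec = [v // g for v in vec]
    return tuple(vec)


def extreme_rays_nonneg(
    eq_matrix: Matrix, dim: int, max_rays: int = 2_000_000
) -> list[tuple[int, ...]]:
    """Extreme rays of the pointed cone {x >= 0 | eq @ x = 0}.

    Double description with the combinatorial adjacency test: rays r1, r2
    are adjacent iff no third ray's support is contained in
    supp(r1) | supp(r2).  Equality rows are processed in their given order
    (deterministic); rays are coprime integer vectors.
    """
    rays: list[tuple[int, ...]] = [
        tuple(1 if j == i else 0 for j in range(dim)) for i in range(dim)
    ]
    for a in _int_rows(eq_matrix):
        vals = [sum(ai * ri for ai, ri in zip(a, r)) for r in rays]
        keep = [r for r, v in zip(rays, vals) if v == 0]
        pos = [(r, v) for r, v in zip(rays, vals) if v > 0]
        neg = [(r, v) for r, v in zip(rays, vals) if v < 0]
        supports = [
            sum(1 << j for j, x in enumerate(r) if x != 0) for r in rays
        ]
        new: dict[tuple[int, ...], None] = {}
        for rp, vp in pos:
            sp = sum(1 << j for j, x in enumerate(rp) if x != 0)
            for rn, vn in neg:
                sn = sum(1 << j for j, x in enumerate(rn) if x != 0)
                union = sp | sn
                adjacent = True
                for s, r in zip(supports, rays):
                    if r is rp or r is rn:
                        continue
                    if s & ~union == 0:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = [vp * x - vn * y for x, y in zip(rn, rp)]
                new[_reduce_ray(combo)] = None
        pool = {r: None for r in keep}
        pool.update(new)
        rays = list(pool)
        if len(rays) > max_rays:
            raise ScaleError(
                f"double description exceeded {max_rays} intermediate rays"
            )
    return rays


def extreme_rays_mixed(
    eq_matrix: Matrix,
    dim: int,
    nonneg: set[int] | frozenset[int],
    max_rays: int = 2_000_000,
) -> list[tuple[Fraction, ...]]:
    """Elementary modes of a cone with free variables.

    Free variables are split into differences of two nonnegative parts, the
    split cone's extreme rays are enumerated, the parts are re-merged
    (x_j = x_j^+ - x_j^-), zero vectors (futile split cycles) dropped and
    duplicates removed by their exact coprime-integer representation.  The
    result is the set of support-minimal solutions of the original system,
    with both sign orientations of purely reversible modes retained.
    """
    nonneg = frozenset(nonneg)
    free = [j for j in range(dim) if j not in nonneg]
    # column layout: originals first (nonneg vars use their own column; free
    # vars use it as the + part), then one extra - column per free var
    split_dim = dim + len(free)
    neg_col = {j: dim + k for k, j in enumerate(free)}
    split_eq: Matrix = []
    for row in eq_matrix:
        ext = list(row) + [-row[j] for j in free]
        split_eq.append(ext)
    rays = extreme_rays_nonneg(split_eq, split_dim, max_rays=max_rays)
    merged: dict[tuple[int, ...], None] = {}
    for r in rays:
        vec = list(r[:dim])
        for j in free:
            vec[j] -= r[neg_col[j]]
        if all(v == 0 for v in vec):
            continue
        merged[_reduce_ray(vec)] = None
    return [tuple(Fraction(v) for v in r) for r in merged]


def enumerate_extreme_rays(
    cone: PolyhedralCone, max_rays: int = 2_000_000
) -> list[tuple[Fraction, ...]]:
    return extreme_rays_mixed(cone.eq_matrix, cone.dim, cone.nonneg, max_rays)


def enumerate_dual_ems(
    system: NbDualSystem | FlbDualSystem,
    max_variables: int = 24,
    max_rays: int = 2_000_000,
) -> list[DualSolution]:
    """All elementary modes of a dual system's cone (exact rationals).

    The threshold row t^T w <= -c is *not* part of the cone; it is applied
    later as a filter on the enumerated modes.  Refuses instances beyond the
    desk-scale variable limit — use the MILP path for those.
    """
    nvar = system.num_variables
    if nvar > max_variables:
        raise ScaleError(
            f"dual system has {nvar} variables (limit {max_variables}); "
            "use the MILP enumeration path for instances of this size"
        )
    cone = PolyhedralCone(
        eq_matrix=system.eq_matrix,
        dim=nvar,
        nonneg=frozenset(system.nonneg_variables()),
    )
    rays = enumerate_extreme_rays(cone, max_rays=max_rays)
    vs, ws = system.v_slice, system.w_slice
    return [
        DualSolution(v=list(r[vs]), w=list(r[ws]), source=system.source)
        for r in rays
    ]


def full_dual_mcs_enumeration(
    problem: MCSProblem,
    path: str = "nb",
    max_variables: int = 24,
    max_rays: int = 2_000_000,
) -> list[CutSet]:
    """Complete MCS enumeration through a dual system's elementary modes.

    Pipeline: enumerate dual EMs -> threshold filter + (coordinated) support
    extraction + minimality -> restrict to knockable reactions -> when a
    desired region exists, keep only candidates under which it stays
    LP-feasible.  Returns the full MCS set, all cardinalities, sorted by
    (size, indices).
    """
    if path == "nb":
        system = build_nb_dual(problem, orientation="em_path")
    elif path == "flb":
        system = build_flb_dual(problem)
    else:
        raise ValueError(f"unknown dual path {path!r}")
    ems = enumerate_dual_ems(system, max_variables=max_variables, max_rays=max_rays)
    cutsets = cutsets_from_dual_solutions(ems, system)

    knockable = problem.knockable
    if knockable != frozenset(range(problem.n)):
        allowed = [cs.indices for cs in cutsets if cs.indices <= knockable]
        cutsets = [
            CutSet(indices=s, provenance=f"dual-em:{path}") for s in allowed
        ]

    if problem.desired is not None:
        kept = []
        for cs in cutsets:
            ok, _ = lp_feasible(problem.desired, problem.network, cs.indices)
            if ok:
                cs.validation = (True, True, True)
                kept.append(cs)
        cutsets = kept
    return sorted(cutsets, key=lambda cs: (cs.size, sorted(cs.indices)))


def brute_force_mcs(
    problem: MCSProblem, max_size: int, subset_budget: int = 500_000
) -> list[CutSet]:
    """Independent oracle: test every knockout subset up to ``max_size``.

    A subset S is an MCS iff the target region is LP-infeasible under S and
    no strict subset of S is a cut set; it is additionally *constrained*
    iff the desired region (when present) stays LP-feasible under S.
    Supersets of any discovered cut set are pruned (they cannot be minimal,
    and desired-infeasibility is inherited by supersets).
    """
    net = problem.network
    pool = sorted(problem.knockable)
    total = sum(comb(len(pool), q) for q in range(1, max_size + 1))
    if total > subset_budget:
        raise ScaleError(
            f"{total} subsets exceed the brute-force budget {subset_budget}"
        )
    cuts: list[frozenset[int]] = []  # every discovered cut set, for pruning
    result: list[CutSet] = []
    for q in range(1, max_size + 1):
        for combo in combinations(pool, q):
            S = frozenset(combo)
            if any(c <= S for c in cuts):
                continue
            target_ok, _ = lp_feasible(problem.target, net, S)
            if target_ok:
                continue
            cuts.append(S)
            desired_flag: bool | None = None
            if problem.desired is not None:
                desired_flag, _ = lp_feasible(problem.desired, net, S)
                if not desired_flag:
                    continue
            result.append(
                CutSet(
                    indices=S,
                    provenance="brute-force",
                    validation=(True, True, desired_flag),
                )
            )
    return result
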