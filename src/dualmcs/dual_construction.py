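"""Dual systems whose elementary modes encode minimal cut sets.

Two constructions are provided:

* the Farkas-lemma-based (FLB) dual: an equality system over variables
  (u, v, s, w) with blocks (N^T | I | -I_Irrev | T^T) and n equality rows;
  cut sets are the supports of the v-part of its elementary modes that
  satisfy t^T w < 0 and are support-minimal in v;

* the nullspace-based (NB) dual: the far smaller system over (v, w) with
  n - m equality rows built from a kernel matrix K of N.  In the
  enumeration orientation the equality block is (K^T | -K^T T^T) and cut
  sets are the minimal *coordinated supports* of v (negative entries cut
  for irreversible reactions, any nonzero entry cuts for reversible ones);
  in the MILP orientation the block is (K^T | +K^T T^T) and the convention
  mirrors to positive entries.  Both orientations yield identical MCS and
  are cross-validated against each other in the test suite rather than
  silently unified.

The threshold row t^T w <= -c (c > 0 arbitrary, default 1) anchors the
inhomogeneous part; the signed support of solutions — and hence the MCS —
is identical for any c > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Literal, Sequence

from .exact_linalg import (
    KernelBasis,
    Matrix,
    Vector,
    dot,
    identity,
    mat_mul,
    rational_kernel,
    transpose,
)
from .model_io import CutSet, DualMcsError, MCSProblem

Orientation = Literal["em_path", "milp_path"]
Convention = Literal["negative_cut", "positive_cut"]

__all__ = [
    "FlbDualSystem",
    "NbDualSystem",
    "DualSolution",
    "build_flb_dual",
    "build_nb_dual",
    "coordinated_support",
    "cutsets_from_dual_solutions",
    "reduce_flb_to_nb",
    "kernel_of",
]

@lru_cache(maxsize=None)
def kernel_of(problem: MCSProblem) -> KernelBasis:
    """Kernel basis of the problem's stoichiometric matrix (cached per problem)."""
    basis = rational_kernel(problem.network.matrix())
    if basis.dim == 0:
        raise DualMcsError(
            "the network admits no nonzero steady-state flux; "
            "the MCS problem is degenerate"
        )
    return basis


@dataclass
class FlbDualSystem:
    """FLB dual equality system with variable layout u | v | s | w."""

    eq_matrix: Matrix  # n rows, m + n + |Irrev| + t columns
    threshold: Vector  # coefficients of t^T w <= -c over all dual variables
    c: Fraction
    m: int
    n: int
    irrev: tuple[int, ...]  # primal irreversible indices, sorted
    t: int
    rev: frozenset[int] = frozenset()
    source: str = "flb"

    @property
    def num_variables(self) -> int:
        return self.m + self.n + len(self.irrev) + self.t

    @property
    def num_equalities(self) -> int:
        return len(self.eq_matrix)

    @property
    def num_inequalities(self) -> int:
        return 1

    @property
    def v_slice(self) -> slice:
        return slice(self.m, self.m + self.n)

    @property
    def w_slice(self) -> slice:
        start = self.m + self.n + len(self.irrev)
        return slice(start, start + self.t)

    def nonneg_variables(self) -> set[int]:
        """Indices of sign-restricted dual variables (v_Irrev, s, w)."""
        out = {self.m + i for i in self.irrev}
        base = self.m + self.n
        out |= set(range(base, base + len(self.irrev)))  # s
        out |= set(range(base + len(self.irrev), self.num_variables))  # w
        return out

    @property
    def solution_space_dim(self) -> int:
        """Nullspace dimension of the dual equality block: m + |Irrev| + t."""
        return self.m + len(self.irrev) + self.t


@dataclass
class NbDualSystem:
    """NB dual equality system with variable layout v | w."""

    eq_matrix: Matrix  # n - m rows, n + t columns
    threshold: Vector
    c: Fraction
    n: int
    m: int
    t: int
    orientation: Orientation = "em_path"
    rev: frozenset[int] = frozenset()
    source: str = "nb"

    @property
    def sigma(self) -> int:
        return -1 if self.orientation == "em_path" else 1

    @property
    def num_variables(self) -> int:
        return self.n + self.t

    @property
    def num_equalities(self) -> int:
        return len(self.eq_matrix)

    @property
    def num_inequalities(self) -> int:
        return 1

    @property
    def v_slice(self) -> slice:
        return slice(0, self.n)

    @property
    def w_slice(self) -> slice:
        return slice(self.n, self.n + self.t)

    def nonneg_variables(self) -> set[int]:
        return set(range(self.n, self.n + self.t))

    @property
    def solution_space_dim(self) -> int:
        """Nullspace dimension of the dual equality block: m + t."""
        return self.num_variables - self.num_equalities


@dataclass
class DualSolution:
    """A solution of a dual system, reduced to its meaningful (v, w) parts."""

    v: Vector
    w: Vector | None
    source: str = "nb"


def build_flb_dual(problem: MCSProblem) -> FlbDualSystem:
    """Assemble the FLB dual equality block (N^T | I | -I_Irrev | T^T)."""
    net = problem.network
    n, m = net.n, net.m
    irrev = tuple(sorted(net.irrev))
    T = problem.target.dense()
    tdim = len(T)
    Nt = transpose(net.matrix())
    I = identity(n)
    Tt = transpose(T)
    eq: Matrix = []
    for i in range(n):
        neg_itilde = [Fraction(0)] * len(irrev)
        if i in net.irrev:
            neg_itilde[irrev.index(i)] = Fraction(-1)
        eq.append(Nt[i] + I[i] + neg_itilde + Tt[i])
    nvar = m + n + len(irrev) + tdim
    threshold = [Fraction(0)] * nvar
    wbase = m + n + len(irrev)
    for j in range(tdim):
        threshold[wbase + j] = problem.target.rhs[j]
    return FlbDualSystem(
        eq_matrix=eq,
        threshold=threshold,
        c=problem.c,
        m=m,
        n=n,
        irrev=irrev,
        t=tdim,
        rev=net.rev,
    )


def build_nb_dual(
    problem: MCSProblem, orientation: Orientation = "em_path"
) -> NbDualSystem:
    """Assemble the NB dual equality block (K^T | sigma K^T T^T)."""
    if orientation not in ("em_path", "milp_path"):
        raise ValueError(f"unknown orientation {orientation!r}")
    net = problem.network
    basis = kernel_of(problem)
    Kt = transpose(basis.K)
    T = problem.target.dense()
    tdim = len(T)
    KtTt = mat_mul(Kt, transpose(T))
    sigma = -1 if orientation == "em_path" else 1
    eq: Matrix = [
        Kt[r] + [sigma * x for x in KtTt[r]] for r in range(len(Kt))
    ]
    threshold = [Fraction(0)] * (net.n + tdim)
    for j in range(tdim):
        threshold[net.n + j] = problem.target.rhs[j]
    return NbDualSystem(
        eq_matrix=eq,
        threshold=threshold,
        c=problem.c,
        n=net.n,
        m=net.m,
        t=tdim,
        orientation=orientation,
        rev=net.rev,
    )


def coordinated_support(
    p: Sequence[Fraction],
    rev: Iterable[int],
    convention: Convention = "negative_cut",
) -> frozenset[int]:
    """Knockout set induced by a dual vector over the primal reactions.

    negative_cut: {j | p_j < 0} union {j in Rev | p_j != 0} — irreversible
    reactions are cut by negative entries only, reversible ones by any
    nonzero entry.  positive_cut mirrors the sign (the convention the MILP
    indicator constraints use).
    """
    rev = set(rev)
    if convention == "negative_cut":
        return frozenset(
            j for j, x in enumerate(p) if x < 0 or (j in rev and x != 0)
        )
    if convention == "positive_cut":
        return frozenset(
            j for j, x in enumerate(p) if x > 0 or (j in rev and x != 0)
        )
    raise ValueError(f"unknown convention {convention!r}")


def _check_solution(system, sol: DualSolution) -> None:
    x = list(sol.v) + (list(sol.w) if sol.w is not None else [])
    ncols = len(system.eq_matrix[0]) if system.eq_matrix else 0
    if len(x) != ncols:
        # reduced (v, w) projection of a wider system (FLB drops u and s);
        # such solutions are verified exactly at enumeration time instead
        if len(sol.v) != system.n:
            raise DualMcsError("solution length does not match dual system")
        return
    for row in system.eq_matrix:
        resid = dot(row, x)
        if isinstance(resid, Fraction):
            ok = resid == 0
        else:  # float-contaminated solution
            ok = abs(resid) <= 1e-8
        if not ok:
            raise DualMcsError(
                f"dual solution violates system equalities (residual {resid})"
            )


def _minimal_antichain(candidates: list[frozenset[int]]) -> list[frozenset[int]]:
    """Deduplicate and drop strict supersets (quadratic; fine at desk scale)."""
    uniq = sorted(set(candidates), key=lambda s: (len(s), sorted(s)))
    kept: list[frozenset[int]] = []
    for cand in uniq:
        if not any(k < cand or k == cand for k in kept):
            kept.append(cand)
    return kept


def cutsets_from_dual_solutions(
    solutions: Sequence[DualSolution],
    system: FlbDualSystem | NbDualSystem,
) -> list[CutSet]:
    """Map dual solutions to minimal candidate cut sets.

    Pipeline: (1) keep solutions with t^T w < 0 (a sign-symmetric
    homogeneous solution, w absent, contributes both orientations);
    (2) map each survivor to a candidate set — FLB: plain support of v
    (v_Irrev >= 0 makes this correct), NB em_path: negative-cut coordinated
    support, NB milp_path: positive-cut; (3) drop duplicates and strict
    supersets.
    """
    t_rhs = [system.threshold[j] for j in range(*system.w_slice.indices(system.num_variables))]
    candidates: list[frozenset[int]] = []
    for sol in solutions:
        vectors: list[Vector] = []
        if sol.w is None:
            vectors = [list(sol.v), [-x for x in sol.v]]
        else:
            _check_solution(system, sol)
            tw = dot(t_rhs, sol.w)
            if not tw < 0:
                continue
            vectors = [list(sol.v)]
        for v in vectors:
            if isinstance(system, FlbDualSystem):
                cand = frozenset(j for j, x in enumerate(v) if x != 0)
            else:
                conv = "negative_cut" if system.orientation == "em_path" else "positive_cut"
                cand = coordinated_support(v, system.rev, conv)
            if cand:
                candidates.append(cand)
    return [
        CutSet(indices=s, provenance=f"dual-em:{system.source}")
        for s in _minimal_antichain(candidates)
    ]


def reduce_flb_to_nb(problem: MCSProblem) -> tuple[Matrix, Matrix]:
    """Left-multiply the FLB equality block (N^T | I | T^T) by K^T.

    Returns (reduced, expected) where reduced = K^T (N^T | I | T^T) and
    expected = (0 | K^T | K^T T^T); the N^T block is annihilated exactly
    because K^T N^T = (N K)^T = 0, which is the derivation that turns the
    FLB MILP into the NB MILP.  The two matrices are asserted equal.
    """
    net = problem.network
    basis = kernel_of(problem)
    Kt = transpose(basis.K)
    T = problem.target.dense()
    Nt = transpose(net.matrix())
    block = [Nt[i] + identity(net.n)[i] + transpose(T)[i] for i in range(net.n)]
    reduced = mat_mul(Kt, block)
    KtTt = mat_mul(Kt, transpose(T))
    expected = [
        [Fraction(0)] * net.m + Kt[r] + KtTt[r] for r in range(len(Kt))
    ]
    if reduced != expected:
        raise AssertionError("FLB->NB reduction identity violated")
    return reduced, expected
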