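"""Exact rational linear algebra.

All matrices in this package that feed the dual constructions are kept as
dense lists of :class:`fractions.Fraction` rows.  Floating-point kernels are
deliberately avoided: the nullspace-based dual system rests on exact
equalities ``N K = 0`` and an approximate kernel would corrupt them silently.

A matrix is ``list[list[Fraction]]`` (row major).  Networks here are
desk-scale (tens of reactions), so dense fraction-free elimination is more
than fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

Rational = Fraction
Matrix = list[list[Fraction]]
Vector = list[Fraction]


def as_fraction(x) -> Fraction:
    """Convert ``x`` to an exact fraction.

    Floats are converted via their decimal string representation, so an input
    of ``0.1`` becomes exactly 1/10 (not the binary float it rounds to).
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, bool):
        raise TypeError("boolean is not a rational scalar")
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        if x != x or x in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite value {x!r} is not a rational scalar")
        return Fraction(str(x))
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot convert {type(x).__name__} to Fraction")


def mat(rows: Iterable[Iterable]) -> Matrix:
    return [[as_fraction(x) for x in row] for row in rows]


def zeros(r: int, c: int) -> Matrix:
    return [[Fraction(0)] * c for _ in range(r)]


def identity(n: int) -> Matrix:
    out = zeros(n, n)
    for i in range(n):
        out[i][i] = Fraction(1)
    return out


def transpose(A: Matrix) -> Matrix:
    return [list(col) for col in zip(*A)] if A else []


def mat_mul(A: Matrix, B: Matrix) -> Matrix:
    nb = len(B)
    if A and nb != len(A[0]):
        raise ValueError(f"shape mismatch: {len(A)}x{len(A[0])} @ {nb}x{len(B[0])}")
    Bt = transpose(B)
    return [[sum(a * b for a, b in zip(row, col)) for col in Bt] for row in A]


def mat_vec(A: Matrix, x: Sequence[Fraction]) -> Vector:
    return [sum(a * b for a, b in zip(row, x)) for row in A]


def dot(a: Sequence[Fraction], b: Sequence[Fraction]) -> Fraction:
    return sum(x * y for x, y in zip(a, b))


def is_zero_matrix(A: Matrix) -> bool:
    return all(x == 0 for row in A for x in row)


def rref(A: Matrix) -> tuple[Matrix, list[int]]:
    """Reduced row echelon form with a fixed pivot rule.

    Pivots are chosen as the first (leftmost) column containing a nonzero
    entry, taking the smallest remaining row index — deterministic for a
    fixed input, which makes every kernel basis downstream reproducible.

    Returns ``(R, pivot_columns)``.
    """
    R = [row[:] for row in A]
    nrows = len(R)
    ncols = len(R[0]) if R else 0
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        pr = next((i for i in range(r, nrows) if R[i][c] != 0), None)
        if pr is None:
            continue
        R[r], R[pr] = R[pr], R[r]
        piv = R[r][c]
        R[r] = [x / piv for x in R[r]]
        for i in range(nrows):
            if i != r and R[i][c] != 0:
                f = R[i][c]
                R[i] = [x - f * y for x, y in zip(R[i], R[r])]
        pivots.append(c)
        r += 1
        if r == nrows:
            break
    return R, pivots


def rank(A: Matrix) -> int:
    return len(rref(A)[1])


def integerize(v: Sequence[Fraction], sign_normalize: bool = True) -> Vector:
    """Rescale a rational vector to coprime integers.

    The first nonzero entry is made positive when ``sign_normalize`` is set
    (basis-vector convention; never applied to signed dual solutions, whose
    sign carries meaning).
    """
    denom = 1
    for x in v:
        denom = denom * x.denominator // gcd(denom, x.denominator)
    ints = [int(x * denom) for x in v]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    if sign_normalize:
        lead = next((x for x in ints if x != 0), 0)
        if lead < 0:
            ints = [-x for x in ints]
    return [Fraction(x) for x in ints]


@dataclass
class KernelBasis:
    """A rational basis ``K`` of the nullspace of a stoichiometric matrix.

    ``K`` is n x (n - rank(N)); columns are integer vectors with gcd 1 and a
    positive leading entry (echelon basis, free variables in column order).
    """

    K: Matrix
    pivot_columns: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.K)

    @property
    def dim(self) -> int:
        return len(self.K[0]) if self.K and self.K[0] else 0

    def columns(self) -> Matrix:
        return transpose(self.K)


def rational_kernel(N: Matrix) -> KernelBasis:
    """Exact nullspace basis of ``N``: returns K with ``N K = 0``.

    The basis is the standard reduced-echelon one: each free column of the
    RREF contributes a basis vector with 1 in its own position and the
    negated pivot-row entries elsewhere, rescaled to coprime integers.
    """
    if not N:
        raise ValueError("empty matrix has no well-defined column count")
    ncols = len(N[0])
    R, pivots = rref(N)
    free = [c for c in range(ncols) if c not in pivots]
    cols: Matrix = []
    for f in free:
        v = [Fraction(0)] * ncols
        v[f] = Fraction(1)
        for i, p in enumerate(pivots):
            v[p] = -R[i][f]
        cols.append(integerize(v))
    K = transpose(cols) if cols else [[] for _ in range(ncols)]
    basis = KernelBasis(K=K, pivot_columns=pivots)
    # exact zero residual is a construction invariant, not a tolerance check
    if cols and not is_zero_matrix(mat_mul(N, K)):
        raise AssertionError("kernel construction produced a nonzero residual")
    return basis


@dataclass
class ExtendedKernel:
    """Kernel of the homogenized target system.

    The target region {N r = 0, r_Irrev >= 0, T r <= t} is rewritten with
    slacks w >= 0 and a homogenizing variable y = 1 as the equality system
    N_e (v, w, y) = 0 with

        N_e = [[N, 0, 0],
               [T, I, -t]]

    whose kernel is assembled blockwise from a kernel K of N as

        K_e = [[K,    0],
               [-T K, t],
               [0,    1]].
    """

    K_e: Matrix
    N_e: Matrix

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.K_e), len(self.K_e[0])


def extended_kernel(
    basis: KernelBasis, T: Matrix, t: Vector, N: Matrix | None = None
) -> ExtendedKernel:
    """Assemble the extended kernel K_e and system matrix N_e blockwise.

    When ``N`` is not supplied, a canonical full-row-rank representative of
    the row space is derived as the (transposed) kernel of K^T; any such
    choice yields the same extended system up to row operations.  The exact
    identity ``N_e K_e = 0`` is asserted before returning.
    """
    n = basis.n
    if any(len(row) != n for row in T):
        raise ValueError(f"target matrix must have {n} columns")
    if len(t) != len(T):
        raise ValueError("target rhs length must equal target row count")
    K = basis.K
    k = basis.dim
    nTK = [[-x for x in row] for row in mat_mul(T, K)]
    K_e: Matrix = []
    for i in range(n):
        K_e.append(K[i][:] + [Fraction(0)])
    for j in range(len(T)):
        K_e.append(nTK[j][:] + [t[j]])
    K_e.append([Fraction(0)] * k + [Fraction(1)])

    if N is None:
        # null(K^T) is the orthogonal complement of col(K), i.e. rowspace(N)
        N = transpose(rational_kernel(transpose(K)).K) if k < n else []
    tdim = len(T)
    N_e: Matrix = []
    for row in N:
        N_e.append(list(row) + [Fraction(0)] * tdim + [Fraction(0)])
    for j in range(tdim):
        slack = [Fraction(0)] * tdim
        slack[j] = Fraction(1)
        N_e.append(T[j][:] + slack + [-t[j]])
    ek = ExtendedKernel(K_e=K_e, N_e=N_e)
    if not is_zero_matrix(mat_mul(N_e, ek.K_e)):
        raise AssertionError("extended kernel violates N_e K_e = 0")
    return ek


def matrix_to_tsv(A: Matrix) -> str:
    """Debug dump of a rational matrix as TSV (fractions printed verbatim)."""
    return "\n".join("\t".join(str(x) for x in row) for row in A)
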