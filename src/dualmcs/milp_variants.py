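"""Solver-neutral MILP formulations for shortest-MCS search.

Six formulations are assembled from the same building blocks:

====================  =========================================================
variant               dual equality block (continuous dual variables)
====================  =========================================================
flb condensed         (N^T | I | T^T) over (u, v, w); v free, indicators gate v
flb split             irreversible rows relaxed to >=, v_Irrev >= 0, reversible
                      v split into nonnegative (v^p, v^n)
nb condensed          (K^T | K^T T^T) over (v, w); n - m rows only
nb split              reversible v split as above, irreversible v kept free
====================  =========================================================

plus, orthogonally, the desired region encoded either through the
stoichiometric matrix (variables r with N r = 0, D r <= d) or through the
kernel (variables a with r = K a, rows D K a <= d), with the knockout
coupling (1 - z_i) lb_i <= r_i <= (1 - z_i) ub_i in either flux or kernel
coordinates.

Every variant minimizes the number of cuts sum(z_i); z_i = 1 marks reaction
i as knocked out, which the indicator constraints tie to the dual variables
(z_i = 0 -> v_i <= 0 for irreversible i, v_i = 0 for reversible i).  Only
one binary per reaction is used and no explicit z_i = 1 condition exists:
the objective keeps spurious ones out of optimal supports.

The model is a plain data structure; adapters (see :mod:`dualmcs.backend`)
translate it for a concrete solver.  Indicator links can be rewritten into
big-M inequalities with :func:`encode_big_m` for solvers without native
indicator support; every emitted MCS is re-validated by exact LPs, so an
undersized M can only cause missed (never wrong) sets, which the oracle
cross-checks catch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Literal

from .dual_construction import kernel_of
from .exact_linalg import mat_mul, transpose
from .model_io import DualMcsError, MCSProblem

__all__ = ["MilpModel", "VariantSpec", "Variable", "Constraint", "IndicatorLink",
           "build_milp", "encode_big_m", "to_lp_string"]

INF = float("inf")


@dataclass
class Variable:
    name: str
    kind: Literal["continuous", "binary"] = "continuous"
    lb: float = -INF
    ub: float = INF


@dataclass
class Constraint:
    coeffs: dict[str, float]
    sense: Literal["=", "<=", ">="]
    rhs: float
    tag: str = ""


@dataclass
class IndicatorLink:
    """z = 0 activates the linear condition coeffs . x (sense) rhs."""

    binary: str
    coeffs: dict[str, float]
    sense: Literal["=", "<="]
    rhs: float = 0.0


@dataclass
class VariantSpec:
    dual: Literal["flb", "nb"] = "nb"
    split_reversible: bool = False
    desired_encoding: Literal["stoichiometric", "kernel", "none"] = "none"
    indicator_mode: Literal["native", "big_m"] = "native"
    big_m_value: float | None = None  # default 1000 * c, fixed at build time
    bound_surrogate: float = 1000.0  # replaces infinite bounds in the coupling

    @property
    def tag(self) -> str:
        split = "split" if self.split_reversible else "condensed"
        return f"{self.dual}-{split}-{self.desired_encoding}-{self.indicator_mode}"


@dataclass
class MilpModel:
    variables: list[Variable]
    constraints: list[Constraint]
    indicators: list[IndicatorLink]
    objective: list[str]  # variable names, each with coefficient 1 (minimize)
    variant: str
    desired_encoding: str
    n_reactions: int
    big_m_value: float
    is_big_m: bool = False

    def copy(self) -> "MilpModel":
        return copy.deepcopy(self)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    # --- dimension bookkeeping (structural rows exclude bounds/indicators) --

    def count_continuous(self) -> int:
        return sum(1 for v in self.variables if v.kind == "continuous")

    def count_binary(self) -> int:
        return sum(1 for v in self.variables if v.kind == "binary")

    def count_structural_rows(self) -> int:
        """Structural (in)equality count: dual block + threshold + desired
        block, excluding flux-bound couplings and indicator rows."""
        tags = {"dual", "threshold", "desired_steady", "desired_region"}
        return sum(1 for c in self.constraints if c.tag in tags)


def _f(x) -> float:
    return float(x)


def build_milp(problem: MCSProblem, spec: VariantSpec) -> MilpModel:
    """Assemble the MILP for one formulation variant."""
    net = problem.network
    n, m = net.n, net.m
    irrev = sorted(net.irrev)
    rev = sorted(net.rev)
    T = problem.target.dense()
    t_rhs = problem.target.rhs_vector()
    tdim = len(T)
    c = float(problem.c)
    big_m = spec.big_m_value if spec.big_m_value is not None else 1000.0 * c

    if spec.desired_encoding != "none" and problem.desired is None:
        raise DualMcsError("desired encoding requested but problem has no desired region")
    if spec.desired_encoding == "none" and problem.desired is not None:
        # permitted: enumerate plain MCS, desired handled by post-validation
        pass

    variables: list[Variable] = []
    constraints: list[Constraint] = []
    indicators: list[IndicatorLink] = []

    zname = [f"z_{i}" for i in range(n)]
    for i in range(n):
        ub = 1.0 if i in problem.knockable else 0.0
        variables.append(Variable(zname[i], "binary", 0.0, ub))

    # ----- dual block ------------------------------------------------------
    if spec.dual == "flb":
        Nt = transpose(net.matrix())
        Tt = transpose(T)
        uname = [f"u_{j}" for j in range(m)]
        wname = [f"w_{j}" for j in range(tdim)]
        variables += [Variable(u) for u in uname]
        if not spec.split_reversible:
            vname = [f"v_{i}" for i in range(n)]
            variables += [Variable(v) for v in vname]
            variables += [Variable(w, lb=0.0) for w in wname]
            for i in range(n):
                coeffs = {uname[j]: _f(Nt[i][j]) for j in range(m) if Nt[i][j] != 0}
                coeffs[vname[i]] = 1.0
                for j in range(tdim):
                    if Tt[i][j] != 0:
                        coeffs[wname[j]] = _f(Tt[i][j])
                constraints.append(Constraint(coeffs, "=", 0.0, "dual"))
            for i in range(n):
                sense = "<=" if i in net.irrev else "="
                indicators.append(IndicatorLink(zname[i], {vname[i]: 1.0}, sense))
        else:
            viname = {i: f"vI_{i}" for i in irrev}
            vpname = {i: f"vp_{i}" for i in rev}
            vnname = {i: f"vn_{i}" for i in rev}
            variables += [Variable(viname[i], lb=0.0) for i in irrev]
            variables += [Variable(vpname[i], lb=0.0) for i in rev]
            variables += [Variable(vnname[i], lb=0.0) for i in rev]
            variables += [Variable(w, lb=0.0) for w in wname]
            for i in range(n):
                coeffs = {uname[j]: _f(Nt[i][j]) for j in range(m) if Nt[i][j] != 0}
                for j in range(tdim):
                    if Tt[i][j] != 0:
                        coeffs[wname[j]] = _f(Tt[i][j])
                if i in net.irrev:
                    coeffs[viname[i]] = 1.0
                    constraints.append(Constraint(coeffs, ">=", 0.0, "dual"))
                    indicators.append(IndicatorLink(zname[i], {viname[i]: 1.0}, "="))
                else:
                    coeffs[vpname[i]] = 1.0
                    coeffs[vnname[i]] = -1.0
                    constraints.append(Constraint(coeffs, "=", 0.0, "dual"))
                    indicators.append(IndicatorLink(zname[i], {vpname[i]: 1.0}, "="))
                    indicators.append(IndicatorLink(zname[i], {vnname[i]: 1.0}, "="))
    else:  # nb
        basis = kernel_of(problem)
        Kt = transpose(basis.K)
        KtTt = mat_mul(Kt, transpose(T))
        nrows = len(Kt)
        wname = [f"w_{j}" for j in range(tdim)]
        if not spec.split_reversible:
            vname = [f"v_{i}" for i in range(n)]
            variables += [Variable(v) for v in vname]
            variables += [Variable(w, lb=0.0) for w in wname]
            for r in range(nrows):
                coeffs = {vname[i]: _f(Kt[r][i]) for i in range(n) if Kt[r][i] != 0}
                for j in range(tdim):
                    if KtTt[r][j] != 0:
                        coeffs[wname[j]] = _f(KtTt[r][j])
                constraints.append(Constraint(coeffs, "=", 0.0, "dual"))
            for i in range(n):
                sense = "<=" if i in net.irrev else "="
                indicators.append(IndicatorLink(zname[i], {vname[i]: 1.0}, sense))
        else:
            viname = {i: f"vI_{i}" for i in irrev}  # free, indicator caps at 0
            vpname = {i: f"vp_{i}" for i in rev}
            vnname = {i: f"vn_{i}" for i in rev}
            variables += [Variable(viname[i]) for i in irrev]
            variables += [Variable(vpname[i], lb=0.0) for i in rev]
            variables += [Variable(vnname[i], lb=0.0) for i in rev]
            variables += [Variable(w, lb=0.0) for w in wname]
            for r in range(nrows):
                coeffs: dict[str, float] = {}
                for i in irrev:
                    if Kt[r][i] != 0:
                        coeffs[viname[i]] = _f(Kt[r][i])
                for i in rev:
                    if Kt[r][i] != 0:
                        coeffs[vpname[i]] = _f(Kt[r][i])
                        coeffs[vnname[i]] = -_f(Kt[r][i])
                for j in range(tdim):
                    if KtTt[r][j] != 0:
                        coeffs[wname[j]] = _f(KtTt[r][j])
                constraints.append(Constraint(coeffs, "=", 0.0, "dual"))
            for i in irrev:
                indicators.append(IndicatorLink(zname[i], {viname[i]: 1.0}, "<="))
            for i in rev:
                indicators.append(IndicatorLink(zname[i], {vpname[i]: 1.0}, "="))
                indicators.append(IndicatorLink(zname[i], {vnname[i]: 1.0}, "="))

    # threshold row t^T w <= -c
    thr = {wname[j]: _f(t_rhs[j]) for j in range(tdim) if t_rhs[j] != 0}
    constraints.append(Constraint(thr, "<=", -c, "threshold"))

    # ----- desired block ---------------------------------------------------
    if spec.desired_encoding != "none":
        D = problem.desired.dense()
        d_rhs = problem.desired.rhs_vector()
        sur = spec.bound_surrogate

        def coupling_bounds(i: int) -> tuple[float, float]:
            lo = net.lb[i]
            hi = net.ub[i]
            lo_f = -sur if lo is None else _f(lo)
            hi_f = sur if hi is None else _f(hi)
            return lo_f, hi_f

        if spec.desired_encoding == "stoichiometric":
            rname = [f"r_{i}" for i in range(n)]
            variables += [Variable(r) for r in rname]
            for row in net.N:
                coeffs = {rname[i]: _f(row[i]) for i in range(n) if row[i] != 0}
                constraints.append(Constraint(coeffs, "=", 0.0, "desired_steady"))
            for row, b in zip(D, d_rhs):
                coeffs = {rname[i]: _f(row[i]) for i in range(n) if row[i] != 0}
                constraints.append(Constraint(coeffs, "<=", _f(b), "desired_region"))
            for i in range(n):
                lo_f, hi_f = coupling_bounds(i)
                constraints.append(
                    Constraint({rname[i]: 1.0, zname[i]: hi_f}, "<=", hi_f, "coupling")
                )
                constraints.append(
                    Constraint({rname[i]: -1.0, zname[i]: -lo_f}, "<=", -lo_f, "coupling")
                )
        else:  # kernel
            basis = kernel_of(problem)
            K = basis.K
            kdim = basis.dim
            aname = [f"a_{j}" for j in range(kdim)]
            variables += [Variable(a) for a in aname]
            DK = mat_mul(D, K)
            for row, b in zip(DK, d_rhs):
                coeffs = {aname[j]: _f(row[j]) for j in range(kdim) if row[j] != 0}
                constraints.append(Constraint(coeffs, "<=", _f(b), "desired_region"))
            for i in range(n):
                lo_f, hi_f = coupling_bounds(i)
                krow = {aname[j]: _f(K[i][j]) for j in range(kdim) if K[i][j] != 0}
                up = dict(krow)
                up[zname[i]] = up.get(zname[i], 0.0) + hi_f
                constraints.append(Constraint(up, "<=", hi_f, "coupling"))
                lo_c = {k: -v for k, v in krow.items()}
                lo_c[zname[i]] = lo_c.get(zname[i], 0.0) - lo_f
                constraints.append(Constraint(lo_c, "<=", -lo_f, "coupling"))

    model = MilpModel(
        variables=variables,
        constraints=constraints,
        indicators=indicators,
        objective=list(zname),
        variant=spec.tag,
        desired_encoding=spec.desired_encoding,
        n_reactions=n,
        big_m_value=big_m,
    )
    return model


def encode_big_m(model: MilpModel, M: float | None = None) -> MilpModel:
    """Rewrite indicator links as big-M inequalities (returns a new model).

    z = 0 -> expr <= 0 becomes expr - M z <= 0; z = 0 -> expr = 0 becomes
    the pair -M z <= expr <= M z (one side suffices when the variable is
    already sign-restricted).  All dual continuous variables get box bounds
    +-M so the relaxation stays bounded; the model is flagged so downstream
    validation is mandatory.
    """
    M = model.big_m_value if M is None else M
    if M <= 0:
        raise DualMcsError("big-M constant must be positive")
    out = model.copy()
    out.big_m_value = M
    dual_prefixes = ("u_", "v_", "vI_", "vp_", "vn_", "w_")
    for var in out.variables:
        if var.kind == "continuous" and var.name.startswith(dual_prefixes):
            var.lb = max(var.lb, -M)
            var.ub = min(var.ub, M)
    for link in out.indicators:
        upper = dict(link.coeffs)
        upper[link.binary] = upper.get(link.binary, 0.0) - M
        out.constraints.append(Constraint(upper, "<=", link.rhs, "bigm"))
        if link.sense == "=":
            (vname, coef), = link.coeffs.items() if len(link.coeffs) == 1 else [(None, None)]
            already_nonneg = (
                vname is not None and coef == 1.0 and out.variable(vname).lb >= 0
            )
            if not already_nonneg:
                lower = {k: -v for k, v in link.coeffs.items()}
                lower[link.binary] = lower.get(link.binary, 0.0) - M
                out.constraints.append(Constraint(lower, "<=", -link.rhs, "bigm"))
    out.indicators = []
    out.is_big_m = True
    return out


def to_lp_string(model: MilpModel) -> str:
    """Export as LP-format text (CPLEX dialect; indicators written natively)."""

    def term(coef: float, name: str) -> str:
        sign = "+" if coef >= 0 else "-"
        return f"{sign} {abs(coef):g} {name}"

    def expr(coeffs: dict[str, float]) -> str:
        return " ".join(term(v, k) for k, v in coeffs.items() if v != 0) or "0 " + model.objective[0]

    lines = ["Minimize", " obj: " + expr({z: 1.0 for z in model.objective}), "Subject To"]
    op = {"=": "=", "<=": "<=", ">=": ">="}
    for k, con in enumerate(model.constraints):
        lines.append(f" c{k}: {expr(con.coeffs)} {op[con.sense]} {con.rhs:g}")
    for k, link in enumerate(model.indicators):
        lines.append(
            f" i{k}: {link.binary} = 0 -> {expr(link.coeffs)} {op[link.sense]} {link.rhs:g}"
        )
    lines.append("Bounds")
    for var in model.variables:
        if var.kind == "binary":
            continue
        lo = "-inf" if var.lb == -INF else f"{var.lb:g}"
        hi = "+inf" if var.ub == INF else f"{var.ub:g}"
        lines.append(f" {lo} <= {var.name} <= {hi}")
    binaries = [v.name for v in model.variables if v.kind == "binary"]
    if binaries:
        lines.append("Binaries")
        lines.append(" " + " ".join(binaries))
    lines.append("End")
    return "\n".join(lines) + "\n"
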