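"""Problem representation and I/O for minimal-cut-set computations.

A problem consists of a stoichiometric network (matrix N, reversibilities,
flux bounds), a *target region* of steady-state flux vectors that the
knockouts must render infeasible, and optionally a *desired region* of which
at least one flux vector must survive the knockouts (constrained MCS).

Conventions applied during preprocessing, in order:

1. direction normalization — every reaction gets ub_i >= 0 by flipping
   columns whose upper bound is negative;
2. removal of conservation relations — dependent rows of N are dropped so
   that N has full row rank (the nullspace is unchanged);
3. region assembly — user target rows, extra linear constraints and the
   *inhomogeneous* flux bounds (finite, non-zero; written as r_i <= ub_i and
   -r_i <= -lb_i) are folded into (T, t).  Pure irreversibility (lb_i = 0)
   stays in the Irrev index set.  A reaction with ub_i = 0 after
   normalization is pre-blocked: its column is kept for index stability and
   the row r_i <= 0 is folded so that every consumer of (T, t) sees the
   blocked flux.  Flux bounds are never folded into the desired region
   (there they are coupled to the knockout indicators instead);
4. zero-vector guard — the target region must exclude the zero flux vector
   (some t_j < 0), otherwise no cut set can exist.

All stoichiometric and region data are exact rationals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exact_linalg import (
    Matrix,
    Vector,
    as_fraction,
    rank,
    rref,
    transpose,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DualMcsError",
    "SchemaError",
    "ModelError",
    "ReferenceIdError",
    "MetabolicNetwork",
    "LinearConstraintRegion",
    "MCSProblem",
    "CutSet",
    "normalize_directions",
    "remove_conservation_relations",
    "assemble_regions",
    "check_target_excludes_zero",
    "build_problem",
    "load_problem",
    "load_problem_tsv",
    "write_problem",
    "mcs_to_tsv",
    "mcs_to_json",
    "from_cobra_model",
    "load_sbml",
]


class DualMcsError(Exception):
    """Base class for all package errors."""


class SchemaError(DualMcsError):
    """A problem file violates the expected schema; names the offending field."""


class ModelError(DualMcsError):
    """The model itself is inconsistent (bad bounds, zero vector in target, ...)."""


class ReferenceIdError(ModelError):
    """A region row references an unknown reaction id."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometric network: N (m x n), flux bounds, reversibility split.

    ``lb``/``ub`` entries are exact rationals or ``None`` for an unbounded
    side (lb None = -inf, ub None = +inf).  ``flipped`` records reactions
    whose direction was reversed during normalization.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    N: tuple[tuple[Fraction, ...], ...]
    lb: tuple[Fraction | None, ...]
    ub: tuple[Fraction | None, ...]
    flipped: frozenset[int] = frozenset()

    def __post_init__(self):
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if len(self.N) != m or any(len(row) != n for row in self.N):
            raise ModelError(f"stoichiometric matrix must be {m}x{n}")
        if len(self.lb) != n or len(self.ub) != n:
            raise ModelError("bound vectors must have one entry per reaction")
        for i, (lo, hi) in enumerate(zip(self.lb, self.ub)):
            if lo is not None and hi is not None and lo > hi:
                raise ModelError(
                    f"reaction {self.reaction_ids[i]!r}: lb {lo} > ub {hi}"
                )

    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def irrev(self) -> frozenset[int]:
        """Indices with lb_i >= 0 (irreversible after normalization)."""
        return frozenset(
            i for i, lo in enumerate(self.lb) if lo is not None and lo >= 0
        )

    @property
    def rev(self) -> frozenset[int]:
        return frozenset(range(self.n)) - self.irrev

    def matrix(self) -> Matrix:
        return [list(row) for row in self.N]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ReferenceIdError(f"unknown reaction id {rid!r}") from None


@dataclass(frozen=True)
class LinearConstraintRegion:
    """An inequality system ``matrix @ r <= rhs`` over the n reaction fluxes.

    ``role`` is "target" or "desired"; ``row_labels`` tag each row's
    provenance (user constraint, folded flux bound, folded extra constraint).
    """

    matrix: tuple[tuple[Fraction, ...], ...]
    rhs: tuple[Fraction, ...]
    role: str
    row_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.role not in ("target", "desired"):
            raise ModelError(f"region role must be target/desired, got {self.role!r}")
        if len(self.matrix) != len(self.rhs):
            raise ModelError("region matrix and rhs disagree in row count")
        if self.role == "target" and len(self.matrix) == 0:
            raise ModelError("target region needs at least one row")

    @property
    def k(self) -> int:
        return len(self.matrix)

    def dense(self) -> Matrix:
        return [list(row) for row in self.matrix]

    def rhs_vector(self) -> Vector:
        return list(self.rhs)


@dataclass(frozen=True)
class MCSProblem:
    """A fully preprocessed MCS problem: network + assembled regions."""

    network: MetabolicNetwork
    target: LinearConstraintRegion
    desired: LinearConstraintRegion | None = None
    c: Fraction = Fraction(1)
    knockable: frozenset[int] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.c <= 0:
            raise ModelError("duality threshold c must be positive")
        if self.knockable is None:
            object.__setattr__(self, "knockable", frozenset(range(self.network.n)))

    @property
    def n(self) -> int:
        return self.network.n

    @property
    def m(self) -> int:
        return self.network.m


@dataclass
class CutSet:
    """A candidate or certified (constrained) minimal cut set.

    ``validation`` is ``(is_cut, is_minimal, desired_feasible)`` once the
    three certification LPs have run; ``desired_feasible`` is None when the
    problem has no desired region.
    """

    indices: frozenset[int]
    provenance: str = ""
    validation: tuple[bool, bool, bool | None] | None = None

    def __post_init__(self):
        self.indices = frozenset(self.indices)
        if not self.indices:
            raise ModelError("a cut set must contain at least one reaction")

    @property
    def size(self) -> int:
        return len(self.indices)

    def ids(self, network: MetabolicNetwork) -> tuple[str, ...]:
        return tuple(network.reaction_ids[i] for i in sorted(self.indices))


# ---------------------------------------------------------------------------
# preprocessing operations


def normalize_directions(network: MetabolicNetwork) -> MetabolicNetwork:
    """Flip every reaction with a negative upper bound so that ub_i >= 0.

    Flipping negates the column of N and maps (lb, ub) to (-ub, -lb); the
    flipped index set is recorded so reports can refer to original
    directions.
    """
    cols = [list(col) for col in zip(*network.N)] if network.N else [[] for _ in range(network.n)]
    lb, ub = list(network.lb), list(network.ub)
    flipped = set(network.flipped)
    for i in range(network.n):
        hi = ub[i]
        if hi is not None and hi < 0:
            cols[i] = [-x for x in cols[i]]
            lb[i], ub[i] = (-hi, None if lb[i] is None else -lb[i])
            flipped.symmetric_difference_update({i})
            logger.info("flipped direction of reaction %s", network.reaction_ids[i])
    N = tuple(tuple(row) for row in zip(*cols)) if cols and cols[0] else network.N
    if network.m == 0:
        N = network.N
    return replace(
        network, N=N, lb=tuple(lb), ub=tuple(ub), flipped=frozenset(flipped)
    )


def remove_conservation_relations(network: MetabolicNetwork) -> MetabolicNetwork:
    """Drop dependent metabolite rows of N so rank(N) = row count.

    Kept rows are those whose index is a pivot column of rref(N^T); the
    nullspace of N — and therefore every MCS — is unchanged.
    """
    if network.m == 0:
        return network
    _, pivots = rref(transpose(network.matrix()))
    keep = sorted(pivots)
    if len(keep) == network.m:
        return network
    dropped = [network.metabolite_ids[i] for i in range(network.m) if i not in set(keep)]
    logger.info("removed %d conservation relation(s): %s", len(dropped), dropped)
    return replace(
        network,
        metabolite_ids=tuple(network.metabolite_ids[i] for i in keep),
        N=tuple(network.N[i] for i in keep),
    )


RowSpec = tuple[Vector, Fraction]  # dense coefficients over reactions, rhs


def _fold_bound_rows(network: MetabolicNetwork) -> list[tuple[Vector, Fraction, str]]:
    """Inhomogeneous flux bounds as target rows per r_i <= ub_i, -r_i <= -lb_i.

    Folded: finite non-zero bounds, plus ub_i = 0 (pre-blocked reaction,
    column kept).  lb_i = 0 is pure irreversibility and stays in Irrev.
    """
    rows: list[tuple[Vector, Fraction, str]] = []
    n = network.n
    for i in range(n):
        hi, lo = network.ub[i], network.lb[i]
        rid = network.reaction_ids[i]
        if hi is not None and hi == 0:
            logger.info("reaction %s is pre-blocked (ub = 0); folding r <= 0", rid)
        if hi is not None:
            row = [Fraction(0)] * n
            row[i] = Fraction(1)
            rows.append((row, hi, f"folded flux bound: {rid} <= {hi}"))
        if lo is not None and lo != 0:
            row = [Fraction(0)] * n
            row[i] = Fraction(-1)
            rows.append((row, -lo, f"folded flux bound: {rid} >= {lo}"))
    return rows


def assemble_regions(
    network: MetabolicNetwork,
    user_target_rows: Sequence[RowSpec],
    user_desired_rows: Sequence[RowSpec] = (),
    extra_constraints: Sequence[RowSpec] = (),
) -> tuple[LinearConstraintRegion, LinearConstraintRegion | None]:
    """Assemble (T, t) and optionally (D, d).

    Target = user rows + extra constraints + folded inhomogeneous flux
    bounds; desired = user desired rows + extra constraints only (bounds are
    coupled to knockouts inside the MILP instead of being folded).
    """
    if not user_target_rows:
        raise ModelError("target region needs at least one user row")

    t_rows: list[Vector] = []
    t_rhs: list[Fraction] = []
    t_labels: list[str] = []
    for coeffs, rhs in user_target_rows:
        t_rows.append(list(coeffs))
        t_rhs.append(rhs)
        t_labels.append("user constraint")
    for coeffs, rhs in extra_constraints:
        t_rows.append(list(coeffs))
        t_rhs.append(rhs)
        t_labels.append("folded extra constraint")
    for row, rhs, label in _fold_bound_rows(network):
        t_rows.append(row)
        t_rhs.append(rhs)
        t_labels.append(label)
    target = LinearConstraintRegion(
        matrix=tuple(tuple(r) for r in t_rows),
        rhs=tuple(t_rhs),
        role="target",
        row_labels=tuple(t_labels),
    )

    desired: LinearConstraintRegion | None = None
    if user_desired_rows:
        d_rows: list[Vector] = []
        d_rhs: list[Fraction] = []
        d_labels: list[str] = []
        for coeffs, rhs in user_desired_rows:
            d_rows.append(list(coeffs))
            d_rhs.append(rhs)
            d_labels.append("user constraint")
        for coeffs, rhs in extra_constraints:
            d_rows.append(list(coeffs))
            d_rhs.append(rhs)
            d_labels.append("folded extra constraint")
        desired = LinearConstraintRegion(
            matrix=tuple(tuple(r) for r in d_rows),
            rhs=tuple(d_rhs),
            role="desired",
            row_labels=tuple(d_labels),
        )
    return target, desired


def check_target_excludes_zero(target: LinearConstraintRegion) -> bool:
    """True iff the zero flux vector violates some target row.

    T @ 0 = 0, and steady state / irreversibility hold trivially at 0, so
    zero is excluded exactly when some rhs entry is strictly negative.
    """
    return any(x < 0 for x in target.rhs)


# ---------------------------------------------------------------------------
# problem construction


def build_problem(
    network: MetabolicNetwork,
    target_rows: Sequence[RowSpec],
    desired_rows: Sequence[RowSpec] = (),
    extra_constraints: Sequence[RowSpec] = (),
    c: Fraction | int = 1,
    knockable: Iterable[int] | None = None,
    check_desired_nonempty: bool = True,
) -> MCSProblem:
    """Preprocess a network + raw region rows into an :class:`MCSProblem`.

    Row coefficients refer to the network's *current* reaction directions;
    callers providing rows in pre-normalization directions must pass the
    pre-normalization network (the pipeline adjusts signs for flipped
    columns).
    """
    flipped_before = set(network.flipped)
    network = normalize_directions(network)
    newly_flipped = set(network.flipped) - flipped_before

    def adjust(rows: Sequence[RowSpec]) -> list[RowSpec]:
        out = []
        for coeffs, rhs in rows:
            coeffs = list(coeffs)
            for i in newly_flipped:
                coeffs[i] = -coeffs[i]
            out.append((coeffs, rhs))
        return out

    target_rows = adjust(target_rows)
    desired_rows = adjust(desired_rows)
    extra_constraints = adjust(extra_constraints)

    network = remove_conservation_relations(network)
    if rank(network.matrix()) != network.m:
        raise ModelError("conservation-relation removal failed to reach full row rank")

    target, desired = assemble_regions(
        network, target_rows, desired_rows, extra_constraints
    )
    if not check_target_excludes_zero(target):
        raise ModelError(
            "zero vector in target region (every target rhs is nonnegative); "
            "knockouts cannot block the zero flux vector"
        )
    problem = MCSProblem(
        network=network,
        target=target,
        desired=desired,
        c=as_fraction(c),
        knockable=None if knockable is None else frozenset(knockable),
    )
    if desired is not None and check_desired_nonempty:
        from .validation import lp_feasible  # late import: validation needs our types

        feasible, _ = lp_feasible(desired, network, frozenset())
        if not feasible:
            raise ModelError(
                "desired region is infeasible before any knockout; "
                "no constrained MCS can exist"
            )
    return problem


# ---------------------------------------------------------------------------
# JSON problem files


def _parse_bound(value, side: str):
    if value is None:
        return None
    if isinstance(value, str):
        s = value.strip().lower()
        if s in ("inf", "+inf", "infinity"):
            return None if side == "ub" else _schema_fail("lb", "lb cannot be +inf")
        if s in ("-inf", "-infinity"):
            return None if side == "lb" else _schema_fail("ub", "ub cannot be -inf")
        return as_fraction(value)
    if isinstance(value, float) and value in (float("inf"), float("-inf")):
        return None
    return as_fraction(value)


def _schema_fail(fieldname: str, msg: str):
    raise SchemaError(f"field {fieldname!r}: {msg}")


def _parse_region_rows(
    entries, reaction_ids: Sequence[str], fieldname: str, default_c: Fraction
) -> list[RowSpec]:
    n = len(reaction_ids)
    index = {rid: i for i, rid in enumerate(reaction_ids)}
    rows: list[RowSpec] = []
    if isinstance(entries, Mapping):
        entries = [entries]
    if not isinstance(entries, list):
        _schema_fail(fieldname, "must be a list of row objects")
    for entry in entries:
        if not isinstance(entry, Mapping):
            _schema_fail(fieldname, "rows must be objects")
        if "block_reaction" in entry:
            rid = entry["block_reaction"]
            if rid not in index:
                raise ReferenceIdError(
                    f"{fieldname}: unknown reaction id {rid!r} in block_reaction"
                )
            c = as_fraction(entry.get("c", default_c))
            if c <= 0:
                _schema_fail(fieldname, "block_reaction threshold c must be positive")
            row = [Fraction(0)] * n
            row[index[rid]] = Fraction(-1)
            rows.append((row, -c))
        elif "coeffs" in entry:
            row = [Fraction(0)] * n
            for rid, val in entry["coeffs"].items():
                if rid not in index:
                    raise ReferenceIdError(
                        f"{fieldname}: unknown reaction id {rid!r} in coeffs"
                    )
                row[index[rid]] = as_fraction(val)
            if "rhs" not in entry:
                _schema_fail(fieldname, "row object lacks 'rhs'")
            rows.append((row, as_fraction(entry["rhs"])))
        else:
            _schema_fail(fieldname, "row object needs 'coeffs' or 'block_reaction'")
    return rows


def network_from_dict(data: Mapping) -> MetabolicNetwork:
    for key in ("metabolites", "reactions"):
        if key not in data:
            _schema_fail(key, "missing")
    met_ids = list(data["metabolites"])
    if len(set(met_ids)) != len(met_ids):
        _schema_fail("metabolites", "duplicate metabolite ids")
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rxn_ids: list[str] = []
    lb: list[Fraction | None] = []
    ub: list[Fraction | None] = []
    cols: list[Vector] = []
    for rxn in data["reactions"]:
        if "id" not in rxn:
            _schema_fail("reactions", "reaction object lacks 'id'")
        rxn_ids.append(rxn["id"])
        lb.append(_parse_bound(rxn.get("lb", 0), "lb"))
        ub.append(_parse_bound(rxn.get("ub"), "ub"))
        col = [Fraction(0)] * len(met_ids)
        for mid, coef in rxn.get("stoich", {}).items():
            if mid not in met_index:
                _schema_fail("reactions", f"unknown metabolite {mid!r} in stoich")
            col[met_index[mid]] = as_fraction(coef)
        cols.append(col)
    if len(set(rxn_ids)) != len(rxn_ids):
        _schema_fail("reactions", "duplicate reaction ids")
    N = tuple(tuple(row) for row in zip(*cols)) if cols else ()
    if not cols:
        _schema_fail("reactions", "at least one reaction is required")
    return MetabolicNetwork(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        N=N,
        lb=tuple(lb),
        ub=tuple(ub),
    )


def problem_from_dict(data: Mapping) -> MCSProblem:
    network = network_from_dict(data)
    if "target" not in data:
        _schema_fail("target", "missing")
    default_c = as_fraction(data.get("c", 1))
    target_rows = _parse_region_rows(data["target"], network.reaction_ids, "target", default_c)
    desired_rows = _parse_region_rows(
        data.get("desired", []), network.reaction_ids, "desired", default_c
    )
    extra = _parse_region_rows(
        data.get("extra_constraints", []), network.reaction_ids, "extra_constraints", default_c
    )
    knockable = None
    if "knockable" in data:
        knockable = frozenset(network.reaction_index(r) for r in data["knockable"])
    return build_problem(
        network,
        target_rows,
        desired_rows,
        extra,
        c=default_c,
        knockable=knockable,
    )


def load_problem(path) -> MCSProblem:
    """Load and fully preprocess a JSON problem file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    return problem_from_dict(data)


def _fraction_repr(x: Fraction | None):
    if x is None:
        return None
    if x.denominator == 1:
        return int(x)
    return str(x)


def problem_to_dict(problem: MCSProblem) -> dict:
    """Serialize a problem canonically (user/extra rows only; bounds refold on load)."""
    net = problem.network
    reactions = []
    for i, rid in enumerate(net.reaction_ids):
        stoich = {
            net.metabolite_ids[j]: _fraction_repr(net.N[j][i])
            for j in range(net.m)
            if net.N[j][i] != 0
        }
        reactions.append(
            {
                "id": rid,
                "lb": _fraction_repr(net.lb[i]),
                "ub": _fraction_repr(net.ub[i]),
                "stoich": stoich,
            }
        )

    def region_rows(region: LinearConstraintRegion, keep: str) -> list[dict]:
        rows = []
        for row, rhs, label in zip(region.matrix, region.rhs, region.row_labels):
            if not label.startswith(keep):
                continue
            rows.append(
                {
                    "coeffs": {
                        net.reaction_ids[i]: _fraction_repr(v)
                        for i, v in enumerate(row)
                        if v != 0
                    },
                    "rhs": _fraction_repr(rhs),
                }
            )
        return rows

    out = {
        "metabolites": list(net.metabolite_ids),
        "reactions": reactions,
        "target": region_rows(problem.target, "user"),
        "c": _fraction_repr(problem.c),
    }
    extra = region_rows(problem.target, "folded extra")
    if extra:
        out["extra_constraints"] = extra
    if problem.desired is not None:
        out["desired"] = region_rows(problem.desired, "user")
    if problem.knockable != frozenset(range(net.n)):
        out["knockable"] = [net.reaction_ids[i] for i in sorted(problem.knockable)]
    return out


def write_problem(problem: MCSProblem, path) -> None:
    Path(path).write_text(json.dumps(problem_to_dict(problem), indent=1) + "\n")


# ---------------------------------------------------------------------------
# TSV variant


def load_problem_tsv(stoich_path, reactions_path, regions_path) -> MCSProblem:
    """TSV alternative: stoichiometry matrix + reactions (id, lb, ub) + region rows.

    The stoichiometry TSV has a header of reaction ids and one row per
    metabolite (first column = metabolite id).  The regions TSV has columns
    role / rhs / one column per reaction id.
    """
    stoich_lines = Path(stoich_path).read_text().strip().splitlines()
    header = stoich_lines[0].split("\t")
    if header[0] != "":
        header = header[1:] if header[0].lower() in ("metabolite", "met", "id") else header
    rxn_ids = [h for h in header if h]
    met_ids, N_rows = [], []
    for line in stoich_lines[1:]:
        parts = line.split("\t")
        met_ids.append(parts[0])
        N_rows.append([as_fraction(x) for x in parts[1 : 1 + len(rxn_ids)]])

    lb = {}
    ub = {}
    rxn_lines = Path(reactions_path).read_text().strip().splitlines()
    for line in rxn_lines[1:]:
        parts = line.split("\t")
        rid = parts[0]
        lo = parts[1] if len(parts) > 1 else ""
        hi = parts[2] if len(parts) > 2 else ""
        lb[rid] = _parse_bound(lo if lo != "" else None, "lb")
        ub[rid] = _parse_bound(hi if hi != "" else None, "ub")
    missing = [r for r in rxn_ids if r not in lb]
    if missing:
        _schema_fail("reactions", f"bounds missing for {missing}")

    network = MetabolicNetwork(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        N=tuple(tuple(row) for row in N_rows),
        lb=tuple(lb[r] for r in rxn_ids),
        ub=tuple(ub[r] for r in rxn_ids),
    )

    target_rows, desired_rows, extra = [], [], []
    reg_lines = Path(regions_path).read_text().strip().splitlines()
    reg_header = reg_lines[0].split("\t")
    col_of = {rid: k for k, rid in enumerate(reg_header)}
    for line in reg_lines[1:]:
        parts = line.split("\t")
        role = parts[col_of["role"]]
        rhs = as_fraction(parts[col_of["rhs"]])
        row = [Fraction(0)] * network.n
        for i, rid in enumerate(rxn_ids):
            cell = parts[col_of[rid]] if col_of.get(rid) is not None else "0"
            row[i] = as_fraction(cell) if cell not in ("", None) else Fraction(0)
        if role == "target":
            target_rows.append((row, rhs))
        elif role == "desired":
            desired_rows.append((row, rhs))
        elif role == "extra":
            extra.append((row, rhs))
        else:
            _schema_fail("regions", f"unknown role {role!r}")
    return build_problem(network, target_rows, desired_rows, extra)


# ---------------------------------------------------------------------------
# result output


def mcs_to_tsv(cutsets: Sequence[CutSet], network: MetabolicNetwork) -> str:
    """MCS table: one row per cut set (size, comma-joined ids, validation flags)."""
    lines = ["size\treactions\tis_cut\tis_minimal\tdesired_feasible\tprovenance"]
    for cs in cutsets:
        if cs.validation is None:
            flags = ["?", "?", "?"]
        else:
            flags = [
                "na" if v is None else str(v).lower() for v in cs.validation
            ]
        lines.append(
            "\t".join(
                [str(cs.size), ",".join(cs.ids(network)), *flags, cs.provenance]
            )
        )
    return "\n".join(lines) + "\n"


def mcs_to_json(cutsets: Sequence[CutSet], network: MetabolicNetwork) -> str:
    out = []
    for cs in cutsets:
        entry = {"size": cs.size, "reactions": list(cs.ids(network))}
        if cs.validation is not None:
            entry["is_cut"], entry["is_minimal"], entry["desired_feasible"] = cs.validation
        if cs.provenance:
            entry["provenance"] = cs.provenance
        out.append(entry)
    return json.dumps(out, indent=1) + "\n"


# ---------------------------------------------------------------------------
# optional SBML import (via cobrapy, when installed)


def from_cobra_model(model, target_rows, desired_rows=(), extra_constraints=(), c=1):
    """Build a problem from a cobrapy model; region rows use reaction ids.

    Reactions lacking explicit bounds get the conventional defaults
    (0/+1000 irreversible, -1000/+1000 reversible), logged.
    """
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_index = {mid: j for j, mid in enumerate(met_ids)}
    cols, lb, ub = [], [], []
    for rxn in model.reactions:
        col = [Fraction(0)] * len(met_ids)
        for met, coef in rxn.metabolites.items():
            col[met_index[met.id]] = as_fraction(coef)
        cols.append(col)
        lo, hi = rxn.bounds
        if lo is None or hi is None:
            logger.info("reaction %s lacks bounds; using defaults", rxn.id)
            lo = 0 if (lo is None and (hi is None or hi >= 0)) else -1000
            hi = 1000 if hi is None else hi
        lb.append(None if lo == float("-inf") else as_fraction(lo))
        ub.append(None if hi == float("inf") else as_fraction(hi))
    network = MetabolicNetwork(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rxn_ids),
        N=tuple(tuple(row) for row in zip(*cols)),
        lb=tuple(lb),
        ub=tuple(ub),
    )

    def to_dense(rows):
        return _parse_region_rows(list(rows), rxn_ids, "target", as_fraction(c))

    return build_problem(
        network, to_dense(target_rows), to_dense(desired_rows) if desired_rows else (),
        to_dense(extra_constraints) if extra_constraints else (), c=c,
    )


def load_sbml(path, target_rows, desired_rows=(), extra_constraints=(), c=1):
    """Read an SBML file through cobrapy (optional dependency) and build a problem."""
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise DualMcsError(
            "SBML import needs the optional 'cobra' dependency"
        ) from exc
    model = cobra.io.read_sbml_model(str(path))
    return from_cobra_model(model, target_rows, desired_rows, extra_constraints, c)
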