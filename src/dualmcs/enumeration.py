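"""Populate-by-size enumeration of MCS through repeated MILP solves.

The ladder fixes the cut cardinality to q = 1, 2, ... with an equality
sum(z) = q, repeatedly solves, records each optimal support {i | z_i = 1},
and adds the integer-cut exclusion constraint

    sum_{j in C} z_j <= |C| - 1

before re-solving, which forbids the found set and all of its supersets.
When size q is exhausted (infeasible), q is incremented; the ladder runs to
``max_size`` even across empty sizes (true MCS size spectra have no gaps
under exclusion, but rejected candidates could create apparent ones, so we
defend anyway).

Every candidate is certified by the three validation LPs before being
emitted; a failing candidate signals a numerical incident, is logged,
excluded, and not returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .backend import solve_milp
from .milp_variants import Constraint, MilpModel, VariantSpec, build_milp, encode_big_m
from .model_io import CutSet, DualMcsError, MCSProblem
from .validation import validate_cutset

logger = logging.getLogger(__name__)

__all__ = [
    "EnumerationConfig",
    "EnumerationResult",
    "enumerate_mcs",
    "enumerate_size_q",
    "add_exclusion_constraint",
]


@dataclass
class EnumerationConfig:
    max_size: int = 3
    max_count: int | None = None
    seed: int = 0
    variant: VariantSpec = field(default_factory=VariantSpec)
    time_limit: float | None = None  # per MILP solve, seconds

    def __post_init__(self):
        if self.max_size < 1:
            raise DualMcsError("max_size must be >= 1")


@dataclass
class EnumerationResult:
    cutsets: list[CutSet]
    status: str  # complete_to_max_size | count_limit
    per_size_counts: dict[int, int]
    incidents: list[str] = field(default_factory=list)

    def index_sets(self) -> set[frozenset[int]]:
        return {cs.indices for cs in self.cutsets}


def add_exclusion_constraint(model: MilpModel, cutset: CutSet | frozenset[int]) -> MilpModel:
    """Append the integer cut for ``cutset``; forbids it and every superset."""
    indices = cutset.indices if isinstance(cutset, CutSet) else frozenset(cutset)
    if not indices:
        raise DualMcsError("cannot exclude an empty cut set")
    coeffs = {f"z_{j}": 1.0 for j in sorted(indices)}
    model.constraints.append(
        Constraint(coeffs, "<=", float(len(indices) - 1), "exclusion")
    )
    return model


def enumerate_size_q(
    model: MilpModel,
    q: int,
    seed: int = 0,
    time_limit: float | None = None,
    max_solutions: int = 100_000,
) -> list[frozenset[int]]:
    """All size-q supports of the model (solution-pool emulation).

    The model must already carry the exclusion constraints from sizes < q.
    A working copy is constrained with sum(z) = q and solved repeatedly;
    each solution's support is excluded immediately — equivalent in results
    to end-of-iteration exclusion because all size-q supports are distinct.
    """
    working = model.copy()
    n = working.n_reactions
    working.constraints.append(
        Constraint({f"z_{i}": 1.0 for i in range(n)}, "=", float(q), "cardinality")
    )
    supports: list[frozenset[int]] = []
    for _ in range(max_solutions):
        status, values = solve_milp(working, seed=seed, time_limit=time_limit)
        if status == "infeasible":
            return supports
        support = frozenset(i for i in range(n) if values[f"z_{i}"] > 0.5)
        if len(support) != q or support in supports:
            raise DualMcsError(
                f"solver returned an inconsistent size-{q} support {sorted(support)}"
            )
        supports.append(support)
        add_exclusion_constraint(working, support)
    raise DualMcsError(f"more than {max_solutions} solutions at size {q}")


def enumerate_mcs(problem: MCSProblem, config: EnumerationConfig) -> EnumerationResult:
    """Enumerate (constrained) MCS in order of nondecreasing cardinality."""
    spec = config.variant
    model = build_milp(problem, spec)
    if spec.indicator_mode == "big_m":
        model = encode_big_m(model, spec.big_m_value)

    cutsets: list[CutSet] = []
    per_size: dict[int, int] = {}
    incidents: list[str] = []
    status = "complete_to_max_size"
    done = False
    for q in range(1, config.max_size + 1):
        supports = enumerate_size_q(
            model, q, seed=config.seed, time_limit=config.time_limit
        )
        per_size[q] = 0
        for support in supports:
            add_exclusion_constraint(model, support)
            candidate = CutSet(indices=support, provenance=f"milp:{spec.tag}")
            report = validate_cutset(problem, candidate)
            if not report.is_valid_mcs:
                msg = (
                    f"candidate {sorted(support)} failed validation "
                    f"{report.flags()} (variant {spec.tag}); excluded"
                )
                logger.warning(msg)
                incidents.append(msg)
                continue
            candidate.validation = report.flags()
            cutsets.append(candidate)
            per_size[q] += 1
            if config.max_count is not None and len(cutsets) >= config.max_count:
                status = "count_limit"
                done = True
                break
        logger.info("size %d: %d MCS", q, per_size[q])
        if done:
            break
    return EnumerationResult(
        cutsets=cutsets,
        status=status,
        per_size_counts=per_size,
        incidents=incidents,
    )
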