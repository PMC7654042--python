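"""Synthetic desk-scale MCS problems and packaged toy fixtures.

The generator emits small connected metabolic networks built from a linear
backbone (uptake -> M1 -> ... -> Mm -> secretion) plus random internal
reactions with small integer stoichiometry (coefficients in {-2..2}) and a
configurable reversible fraction.  The backbone guarantees a nonzero
steady-state route from uptake to at least one secretion, which is
re-verified by LP after construction.  Small integer coefficients keep the
exact rational arithmetic fast and the LPs well conditioned.

Three hand-written fixtures with oracle-derived MCS ground truth are also
packaged (and shipped as JSON under ``dualmcs/data``):

* TOY-CHAIN — 3-reaction linear pathway, every reaction is a single-cut MCS;
* TOY-BRANCH — a branch point where the desired region eliminates the
  uptake reaction from the constrained MCS;
* REV10 — 10 reactions with reversible steps, a 2-row target and a 1-row
  desired region plus a finite uptake bound (inhomogeneous constraint).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np

from .model_io import (
    DualMcsError,
    MCSProblem,
    MetabolicNetwork,
    LinearConstraintRegion,
    build_problem,
    problem_from_dict,
)
from .validation import lp_feasible

__all__ = [
    "GeneratorConfig",
    "GeneratorError",
    "generate_network",
    "generate_problem",
    "generate",
    "toy_chain",
    "toy_branch",
    "rev10",
    "packaged_fixture",
    "packaged_golden",
    "study_corpus",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("toy_chain", "toy_branch", "rev10")

PROBLEM_KINDS = (
    "target_reaction",
    "yield_region",
    "synthetic_lethal_like",
    "with_desired",
)


class GeneratorError(DualMcsError):
    """No feasible network/problem could be generated within the attempt budget."""


@dataclass
class GeneratorConfig:
    n_metabolites: int = 5
    n_reactions: int = 10
    reversible_fraction: float = 0.25
    n_exchange: int = 3
    bound_style: str = "homogeneous"  # or "inhomogeneous"
    problem_kind: str = "target_reaction"
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions <= self.n_metabolites:
            raise DualMcsError("need n_reactions > n_metabolites (nontrivial kernel)")
        if self.n_exchange < 2:
            raise DualMcsError("need at least one uptake and one secretion")
        if not 0 <= self.reversible_fraction <= 1:
            raise DualMcsError("reversible_fraction must lie in [0, 1]")
        if self.bound_style not in ("homogeneous", "inhomogeneous"):
            raise DualMcsError(f"unknown bound_style {self.bound_style!r}")
        if self.problem_kind not in PROBLEM_KINDS:
            raise DualMcsError(f"unknown problem_kind {self.problem_kind!r}")
        backbone = 1 + (self.n_metabolites - 1) + (self.n_exchange - 1)
        if self.n_reactions < backbone:
            raise DualMcsError(
                f"n_reactions must be >= {backbone} for this backbone layout"
            )


def _region_for(network: MetabolicNetwork, rows, rhs) -> LinearConstraintRegion:
    return LinearConstraintRegion(
        matrix=tuple(tuple(Fraction(x) for x in row) for row in rows),
        rhs=tuple(Fraction(x) for x in rhs),
        role="target",
        row_labels=tuple("user constraint" for _ in rows),
    )


def generate_network(config: GeneratorConfig) -> MetabolicNetwork:
    """Random connected network; deterministic for a fixed config + seed."""
    rng = np.random.default_rng(config.seed)
    m, n = config.n_metabolites, config.n_reactions
    for attempt in range(100):
        met_ids = [f"M{j + 1}" for j in range(m)]
        rxn_ids: list[str] = []
        cols: list[list[Fraction]] = []
        lb: list[Fraction | None] = []
        ub: list[Fraction | None] = []

        def add(rid, stoich, reversible, hi=None):
            rxn_ids.append(rid)
            col = [Fraction(0)] * m
            for j, coef in stoich.items():
                col[j] = Fraction(coef)
            cols.append(col)
            lb.append(None if reversible else Fraction(0))
            ub.append(None if hi is None else Fraction(hi))

        inhom = config.bound_style == "inhomogeneous"
        add("EX_in", {0: 1}, False, hi=10 if inhom else None)
        for j in range(m - 1):
            add(
                f"C{j + 1}",
                {j: -1, j + 1: 1},
                rng.random() < config.reversible_fraction,
            )
        sec_targets = [m - 1]
        others = list(range(1, m - 1))
        rng.shuffle(others)
        sec_targets += others[: config.n_exchange - 2]
        for k, j in enumerate(sec_targets):
            add(f"EX_M{j + 1}", {j: -1}, False)
        n_extra = n - len(rxn_ids)
        for k in range(n_extra):
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            mets = rng.permutation(m)
            subs = mets[:n_sub]
            prods = mets[n_sub : n_sub + n_prod]
            stoich = {int(j): -int(rng.integers(1, 3)) for j in subs}
            stoich.update({int(j): int(rng.integers(1, 3)) for j in prods})
            add(f"X{k + 1}", stoich, rng.random() < config.reversible_fraction)
        if inhom and n_extra:
            # one finite internal bound makes the folded target inhomogeneous
            idx = rxn_ids.index("X1")
            ub[idx] = Fraction(int(rng.integers(5, 9)))

        network = MetabolicNetwork(
            metabolite_ids=tuple(met_ids),
            reaction_ids=tuple(rxn_ids),
            N=tuple(tuple(row) for row in zip(*cols)),
            lb=tuple(lb),
            ub=tuple(ub),
        )
        secretions = [i for i, r in enumerate(rxn_ids) if r.startswith("EX_M")]
        ok = False
        for h in secretions:
            row = [Fraction(0)] * network.n
            row[h] = Fraction(-1)
            region = _region_for(network, [row], [-1])
            feasible, _ = lp_feasible(region, network)
            if feasible:
                ok = True
                break
        if ok:
            return network
    raise GeneratorError("no feasible network after 100 attempts")


def _secretion_indices(network: MetabolicNetwork) -> list[int]:
    return [
        i for i, r in enumerate(network.reaction_ids) if r.startswith("EX_M")
    ]


def generate_problem(network: MetabolicNetwork, config: GeneratorConfig) -> MCSProblem:
    """Attach a target (and optionally desired) region of the configured kind."""
    rng = np.random.default_rng([config.seed, 1])
    n = network.n
    secretions = _secretion_indices(network)
    uptake = network.reaction_ids.index("EX_in")

    def unit_row(i, sign=-1):
        row = [Fraction(0)] * n
        row[i] = Fraction(sign)
        return row

    def feasible_rows(rows, rhs) -> bool:
        region = _region_for(network, rows, rhs)
        flag, _ = lp_feasible(region, network)
        return flag

    kind = config.problem_kind
    order = list(rng.permutation(len(secretions)))
    if kind in ("target_reaction", "synthetic_lethal_like", "with_desired"):
        candidates = (
            [secretions[k] for k in order]
            if kind != "synthetic_lethal_like"
            else [secretions[-1]] + [secretions[k] for k in order]
        )
        for h in candidates:
            target_rows = [(unit_row(h), Fraction(-1))]
            if not feasible_rows([r for r, _ in target_rows], [-1]):
                continue
            if kind != "with_desired":
                return build_problem(network, target_rows)
            for g in [s for s in secretions if s != h]:
                desired_rows = [(unit_row(g), Fraction(-1))]
                try:
                    return build_problem(network, target_rows, desired_rows)
                except DualMcsError:
                    continue
        raise GeneratorError(f"could not build a {kind} problem on this network")
    if kind == "yield_region":
        for k in order:
            p = secretions[k]
            for alpha in (Fraction(1, 2), Fraction(1), Fraction(2)):
                row1 = [Fraction(0)] * n
                row1[p] = Fraction(1)
                row1[uptake] = -alpha
                rows = [(row1, Fraction(0)), (unit_row(uptake), Fraction(-1))]
                if feasible_rows([r for r, _ in rows], [0, -1]):
                    return build_problem(network, rows)
        raise GeneratorError("could not build a feasible yield_region target")
    raise DualMcsError(f"unknown problem_kind {kind!r}")


def generate(config: GeneratorConfig) -> MCSProblem:
    """Convenience: network + problem in one deterministic step."""
    return generate_problem(generate_network(config), config)


# ---------------------------------------------------------------------------
# packaged fixtures


def _network(met_ids, reactions) -> MetabolicNetwork:
    """reactions: list of (id, {met: coef}, lb, ub) with None = unbounded."""
    met_index = {mid: j for j, mid in enumerate(met_ids)}
    cols, lb, ub, rids = [], [], [], []
    for rid, stoich, lo, hi in reactions:
        rids.append(rid)
        col = [Fraction(0)] * len(met_ids)
        for mid, coef in stoich.items():
            col[met_index[mid]] = Fraction(coef)
        cols.append(col)
        lb.append(None if lo is None else Fraction(lo))
        ub.append(None if hi is None else Fraction(hi))
    return MetabolicNetwork(
        metabolite_ids=tuple(met_ids),
        reaction_ids=tuple(rids),
        N=tuple(tuple(row) for row in zip(*cols)),
        lb=tuple(lb),
        ub=tuple(ub),
    )


def toy_chain() -> MCSProblem:
    """Linear pathway -> A -> B -> ; target: block r3 >= 1."""
    net = _network(
        ["A", "B"],
        [
            ("R1", {"A": 1}, 0, None),
            ("R2", {"A": -1, "B": 1}, 0, None),
            ("R3", {"B": -1}, 0, None),
        ],
    )
    row = [Fraction(0), Fraction(0), Fraction(-1)]
    return build_problem(net, [(row, Fraction(-1))])


def toy_branch(with_desired: bool = True) -> MCSProblem:
    """Branch point A -> {B, C}; target blocks r4 >= 1, desired keeps r5 >= 1."""
    net = _network(
        ["A", "B", "C"],
        [
            ("R1", {"A": 1}, 0, None),
            ("R2", {"A": -1, "B": 1}, 0, None),
            ("R3", {"A": -1, "C": 1}, 0, None),
            ("R4", {"B": -1}, 0, None),
            ("R5", {"C": -1}, 0, None),
        ],
    )
    target = [([Fraction(0)] * 3 + [Fraction(-1), Fraction(0)], Fraction(-1))]
    desired = (
        [([Fraction(0)] * 4 + [Fraction(-1)], Fraction(-1))] if with_desired else []
    )
    return build_problem(net, target, desired)


def rev10() -> MCSProblem:
    """10 reactions, reversible steps, 2-row target, 1-row desired, finite uptake.

    Target region: D secretion of at least 1 with C secretion not exceeding
    it (r6 >= 1, r7 <= r6); desired region: C secretion of at least 1.
    """
    net = _network(
        ["A", "B", "C", "D"],
        [
            ("R1", {"A": 1}, 0, 10),
            ("R2", {"A": -1, "B": 1}, None, None),
            ("R3", {"B": -1, "C": 1}, 0, None),
            ("R4", {"A": -1, "C": 1}, 0, None),
            ("R5", {"C": -1, "D": 1}, None, None),
            ("R6", {"D": -1}, 0, None),
            ("R7", {"C": -1}, 0, None),
            ("R8", {"B": -1, "D": 1}, 0, None),
            ("R9", {"A": -1, "D": 1}, 0, None),
            ("R10", {"B": -1}, 0, None),
        ],
    )
    n = 10
    row1 = [Fraction(0)] * n
    row1[5] = Fraction(-1)  # -r6 <= -1
    row2 = [Fraction(0)] * n
    row2[6] = Fraction(1)  # r7 - r6 <= 0
    row2[5] = Fraction(-1)
    drow = [Fraction(0)] * n
    drow[6] = Fraction(-1)  # -r7 <= -1
    return build_problem(
        net, [(row1, Fraction(-1)), (row2, Fraction(0))], [(drow, Fraction(-1))]
    )


def study_corpus(
    seed: int = 0, count: int = 20
) -> list[tuple[GeneratorConfig, MCSProblem]]:
    """Deterministic corpus of desk-scale problems covering all problem kinds.

    Cycles through the four problem kinds with metabolite counts 4-7,
    reaction counts 9-14, alternating reversible fractions and bound styles.
    These are the study conditions under which the cross-route agreement
    checks run; the master ``seed`` shifts every per-problem seed.
    """
    kinds = list(PROBLEM_KINDS)
    out: list[tuple[GeneratorConfig, MCSProblem]] = []
    for i in range(count):
        m = 4 + (i % 4)
        backbone = 1 + (m - 1) + 2  # uptake + chain + two secretions
        cfg = GeneratorConfig(
            n_metabolites=m,
            n_reactions=backbone + 3 + (i % 3),
            reversible_fraction=0.25 if i % 3 else 0.0,
            n_exchange=3,
            bound_style="inhomogeneous" if i % 5 == 0 else "homogeneous",
            problem_kind=kinds[i % 4],
            seed=(seed * 1009 + i) % (2**31 - 1),
        )
        out.append((cfg, generate(cfg)))
    return out


_BUILDERS = {"toy_chain": toy_chain, "toy_branch": toy_branch, "rev10": rev10}


def packaged_fixture(name: str) -> MCSProblem:
    """Load a packaged fixture problem from its shipped JSON file."""
    if name not in FIXTURE_NAMES:
        raise DualMcsError(f"unknown fixture {name!r}")
    text = resources.files("dualmcs").joinpath(f"data/{name}.json").read_text()
    return problem_from_dict(json.loads(text))


def packaged_golden(name: str) -> list[frozenset[str]]:
    """Oracle-derived MCS ground truth for a packaged fixture (reaction ids)."""
    if name not in FIXTURE_NAMES:
        raise DualMcsError(f"unknown fixture {name!r}")
    text = resources.files("dualmcs").joinpath(f"data/{name}.golden.json").read_text()
    return [frozenset(entry) for entry in json.loads(text)["mcs"]]


def fixture_builder(name: str) -> MCSProblem:
    """Build a fixture programmatically (bypasses the shipped JSON)."""
    return _BUILDERS[name]()
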