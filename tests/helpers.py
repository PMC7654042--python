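"""Shared helpers for the test suite."""

from __future__ import annotations

from fractions import Fraction

from dualmcs.model_io import MetabolicNetwork


def index_sets(cutsets) -> set[frozenset[int]]:
    return {cs.indices for cs in cutsets}


def id_sets(problem, cutsets) -> set[frozenset[str]]:
    return {frozenset(cs.ids(problem.network)) for cs in cutsets}


def make_network(met_ids, reactions) -> MetabolicNetwork:
    """reactions: (id, {met: coef}, lb, ub); None = unbounded side."""
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


def unit_row(n: int, i: int, sign: int = -1) -> list[Fraction]:
    row = [Fraction(0)] * n
    row[i] = Fraction(sign)
    return row
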