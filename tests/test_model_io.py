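"""Problem loading, preprocessing conventions, and round-trips."""

import json
from fractions import Fraction

import pytest

from dualmcs.model_io import (
    MetabolicNetwork,
    ModelError,
    ReferenceIdError,
    SchemaError,
    assemble_regions,
    check_target_excludes_zero,
    load_problem,
    load_problem_tsv,
    mcs_to_tsv,
    normalize_directions,
    problem_to_dict,
    remove_conservation_relations,
    write_problem,
)
from dualmcs.exact_linalg import mat, rank, rational_kernel, transpose
from dualmcs.reference_enumeration import brute_force_mcs

from helpers import id_sets, make_network, unit_row

CHAIN_JSON = {
    "metabolites": ["A", "B"],
    "reactions": [
        {"id": "R1", "lb": 0, "ub": None, "stoich": {"A": 1}},
        {"id": "R2", "lb": 0, "ub": None, "stoich": {"A": -1, "B": 1}},
        {"id": "R3", "lb": 0, "ub": None, "stoich": {"B": -1}},
    ],
    "target": [{"coeffs": {"R3": -1}, "rhs": -1}],
}

BRANCH_JSON = {
    "metabolites": ["A", "B", "C"],
    "reactions": [
        {"id": "R1", "lb": 0, "stoich": {"A": 1}},
        {"id": "R2", "lb": 0, "stoich": {"A": -1, "B": 1}},
        {"id": "R3", "lb": 0, "stoich": {"A": -1, "C": 1}},
        {"id": "R4", "lb": 0, "stoich": {"B": -1}},
        {"id": "R5", "lb": 0, "stoich": {"C": -1}},
    ],
    "target": [{"coeffs": {"R4": -1}, "rhs": -1}],
    "desired": [{"coeffs": {"R5": -1}, "rhs": -1}],
}


class TestLoadProblem:
    def test_toy_chain_file(self, tmp_path):
        path = tmp_path / "chain.json"
        path.write_text(json.dumps(CHAIN_JSON))
        p = load_problem(path)
        assert (p.m, p.n) == (2, 3)
        assert p.network.irrev == frozenset({0, 1, 2})
        assert p.target.k == 1
        assert p.desired is None

    def test_toy_branch_file(self, tmp_path):
        path = tmp_path / "branch.json"
        path.write_text(json.dumps(BRANCH_JSON))
        p = load_problem(path)
        assert (p.m, p.n) == (3, 5)
        assert p.target.k == 1
        assert p.desired.k == 1

    def test_zero_vector_in_target_rejected(self, tmp_path):
        bad = dict(CHAIN_JSON, target=[{"coeffs": {"R3": -1}, "rhs": 0}])
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(ModelError, match="zero vector"):
            load_problem(path)

    def test_block_reaction_shorthand(self, tmp_path):
        data = dict(CHAIN_JSON, target={"block_reaction": "R3", "c": 2})
        path = tmp_path / "p.json"
        path.write_text(json.dumps(data))
        p = load_problem(path)
        assert p.target.matrix[0] == (Fraction(0), Fraction(0), Fraction(-1))
        assert p.target.rhs[0] == -2

    def test_unknown_reaction_reference(self, tmp_path):
        bad = dict(CHAIN_JSON, target=[{"coeffs": {"R9": -1}, "rhs": -1}])
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(ReferenceIdError, match="R9"):
            load_problem(path)

    def test_bad_bounds_rejected(self, tmp_path):
        bad = json.loads(json.dumps(CHAIN_JSON))
        bad["reactions"][0]["lb"] = 5
        bad["reactions"][0]["ub"] = 1
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(ModelError, match="lb"):
            load_problem(path)

    def test_schema_error_names_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"metabolites": ["A"]}))
        with pytest.raises(SchemaError, match="reactions"):
            load_problem(path)

    def test_float_coefficients_become_exact_fractions(self, tmp_path):
        data = json.loads(json.dumps(CHAIN_JSON))
        data["reactions"][0]["stoich"]["A"] = 0.1
        path = tmp_path / "p.json"
        path.write_text(json.dumps(data))
        p = load_problem(path)
        assert p.network.N[0][0] == Fraction(1, 10)


class TestNormalizeDirections:
    def test_negative_ub_flipped(self):
        net = make_network(
            ["A", "B"], [("R1", {"A": 1, "B": -1}, -5, -1), ("R2", {"A": -1}, 0, None)]
        )
        out = normalize_directions(net)
        assert out.lb[0] == 1 and out.ub[0] == 5
        assert out.N[0][0] == -1 and out.N[1][0] == 1
        assert out.flipped == frozenset({0})

    @pytest.mark.parametrize("bounds", [(0, 10), (-3, 7)])
    def test_nonnegative_ub_unchanged(self, bounds):
        lo, hi = bounds
        net = make_network(["A"], [("R1", {"A": 1}, lo, hi), ("R2", {"A": -1}, 0, None)])
        out = normalize_directions(net)
        assert out.N == net.N and out.lb == net.lb and out.ub == net.ub
        assert out.flipped == frozenset()


class TestRemoveConservationRelations:
    def test_conserved_pair_row_removed(self):
        net = make_network(
            ["A", "B"],
            [("R1", {"A": 1, "B": -1}, 0, None), ("R2", {"A": -1, "B": 1}, 0, None)],
        )
        out = remove_conservation_relations(net)
        assert out.m == 1
        assert rank(out.matrix()) == 1

    def test_full_rank_matrix_unchanged(self, chain):
        out = remove_conservation_relations(chain.network)
        assert out == chain.network

    def test_duplicated_row_dropped_kernel_preserved(self):
        import numpy as np

        rng = np.random.default_rng(5)
        base = [[int(x) for x in rng.integers(-2, 3, size=8)] for _ in range(5)]
        rows = base + [list(base[2])]  # duplicate one row
        net = MetabolicNetwork(
            metabolite_ids=tuple(f"M{i}" for i in range(6)),
            reaction_ids=tuple(f"R{i}" for i in range(8)),
            N=tuple(tuple(Fraction(x) for x in row) for row in rows),
            lb=(Fraction(0),) * 8,
            ub=(None,) * 8,
        )
        out = remove_conservation_relations(net)
        assert out.m == rank(mat(rows))
        k_before = rational_kernel(mat(rows))
        k_after = rational_kernel(out.matrix())
        # same span: mutual containment via ranks of stacked column sets
        A, B = k_before.columns(), k_after.columns()
        assert rank(transpose(A)) == rank(transpose(B)) == rank(transpose(A + B))


class TestAssembleRegions:
    def test_no_bounds_to_fold(self):
        net = make_network(
            ["A"], [("R1", {"A": 1}, 0, None), ("R2", {"A": -1}, 0, None)]
        )
        target, desired = assemble_regions(
            net, [(unit_row(2, 1), Fraction(-1))]
        )
        assert target.k == 1
        assert desired is None

    def test_finite_ub_folded_per_direction(self):
        net = make_network(
            ["A"], [("R1", {"A": 1}, 0, None), ("R2", {"A": -1}, 0, 10)]
        )
        target, _ = assemble_regions(net, [(unit_row(2, 1), Fraction(-1))])
        assert target.k == 2
        folded = [
            (row, rhs)
            for row, rhs, lab in zip(target.matrix, target.rhs, target.row_labels)
            if lab.startswith("folded flux bound")
        ]
        assert folded == [((Fraction(0), Fraction(1)), Fraction(10))]

    def test_finite_nonzero_lb_folded_but_not_pure_reversibility(self):
        net = make_network(
            ["A"],
            [
                ("R1", {"A": 1}, 2, None),  # forced flux: lb folded
                ("R2", {"A": -1}, 0, None),  # pure irreversibility: not folded
            ],
        )
        target, _ = assemble_regions(net, [(unit_row(2, 1), Fraction(-1))])
        labels = [l for l in target.row_labels if l.startswith("folded")]
        assert len(labels) == 1 and "R1 >= 2" in labels[0]

    def test_desired_region_never_gets_bounds(self):
        net = make_network(
            ["A"], [("R1", {"A": 1}, 0, 10), ("R2", {"A": -1}, 0, 10)]
        )
        target, desired = assemble_regions(
            net,
            [(unit_row(2, 1), Fraction(-1))],
            user_desired_rows=[(unit_row(2, 0), Fraction(-1))],
        )
        assert desired.k == 1
        assert all(lab == "user constraint" for lab in desired.row_labels)


class TestZeroVectorCheck:
    @pytest.mark.parametrize(
        "rhs, expected",
        [((-1,), True), ((5, -1), True), ((0, 2), False)],
    )
    def test_rule(self, rhs, expected):
        from dualmcs.model_io import LinearConstraintRegion

        region = LinearConstraintRegion(
            matrix=tuple((Fraction(1),) for _ in rhs),
            rhs=tuple(Fraction(x) for x in rhs),
            role="target",
            row_labels=tuple("user constraint" for _ in rhs),
        )
        assert check_target_excludes_zero(region) is expected


class TestRoundTrip:
    def test_fixture_round_trips(self, all_fixtures, tmp_path):
        for name, problem in all_fixtures.items():
            path = tmp_path / f"{name}.json"
            write_problem(problem, path)
            again = load_problem(path)
            assert again == problem, name

    def test_tsv_loader_matches_json(self, chain, tmp_path):
        stoich = tmp_path / "stoich.tsv"
        stoich.write_text(
            "\tR1\tR2\tR3\nA\t1\t-1\t0\nB\t0\t1\t-1\n"
        )
        rxns = tmp_path / "rxns.tsv"
        rxns.write_text("id\tlb\tub\nR1\t0\t\nR2\t0\t\nR3\t0\t\n")
        regions = tmp_path / "regions.tsv"
        regions.write_text(
            "role\trhs\tR1\tR2\tR3\ntarget\t-1\t0\t0\t-1\n"
        )
        p = load_problem_tsv(stoich, rxns, regions)
        assert p == chain


class TestFlipConsistency:
    def test_preflipped_reversible_reaction_same_mcs(self, rev10_problem):
        """Negating a reversible column leaves the MCS set unchanged."""
        base = rev10_problem
        data = problem_to_dict(base)
        for rxn in data["reactions"]:
            if rxn["id"] == "R5":
                rxn["stoich"] = {k: -v for k, v in rxn["stoich"].items()}
        from dualmcs.model_io import problem_from_dict

        flipped = problem_from_dict(data)
        assert id_sets(base, brute_force_mcs(base, 3)) == id_sets(
            flipped, brute_force_mcs(flipped, 3)
        )

    def test_preflipped_target_reaction_same_mcs(self, rev10_problem):
        """Flip R6 (in the target rows): column and row signs negated."""
        base = rev10_problem
        data = problem_to_dict(base)
        for rxn in data["reactions"]:
            if rxn["id"] == "R6":
                rxn["stoich"] = {k: -v for k, v in rxn["stoich"].items()}
                rxn["lb"], rxn["ub"] = None, 0
        for row in data["target"]:
            if "R6" in row["coeffs"]:
                row["coeffs"]["R6"] = -row["coeffs"]["R6"]
        from dualmcs.model_io import problem_from_dict

        flipped = problem_from_dict(data)
        assert id_sets(base, brute_force_mcs(base, 3)) == id_sets(
            flipped, brute_force_mcs(flipped, 3)
        )


def test_conservation_removal_preserves_mcs():
    """Brute-force MCS before/after dropping a redundant metabolite row agree."""
    from dualmcs.model_io import build_problem

    # chain network with a redundant "shadow" metabolite tracking -A
    redundant = make_network(
        ["A", "B", "Ashadow"],
        [
            ("R1", {"A": 1, "Ashadow": -1}, 0, None),
            ("R2", {"A": -1, "B": 1, "Ashadow": 1}, 0, None),
            ("R3", {"B": -1}, 0, None),
        ],
    )
    reduced = make_network(
        ["A", "B"],
        [
            ("R1", {"A": 1}, 0, None),
            ("R2", {"A": -1, "B": 1}, 0, None),
            ("R3", {"B": -1}, 0, None),
        ],
    )
    row = unit_row(3, 2)
    p_red = build_problem(redundant, [(row, Fraction(-1))])
    p_min = build_problem(reduced, [(row, Fraction(-1))])
    assert p_red.m == 2  # dependent row was removed
    assert id_sets(p_red, brute_force_mcs(p_red, 2)) == id_sets(
        p_min, brute_force_mcs(p_min, 2)
    )


def test_mcs_table_uses_reaction_ids(chain):
    cutsets = brute_force_mcs(chain, 1)
    text = mcs_to_tsv(cutsets, chain.network)
    assert "R1" in text and "R2" in text and "R3" in text
    assert "\t0\t" not in text  # no bare indices
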