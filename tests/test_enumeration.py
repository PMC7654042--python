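"""Populate-by-size MILP enumeration: completeness, exclusions, contracts."""

import pytest

from dualmcs.enumeration import (
    EnumerationConfig,
    add_exclusion_constraint,
    enumerate_mcs,
    enumerate_size_q,
)
from dualmcs.milp_variants import VariantSpec, build_milp
from dualmcs.model_io import DualMcsError

from helpers import id_sets, index_sets


class TestLadder:
    def test_chain_singletons_then_exhaustion(self, chain):
        res = enumerate_mcs(chain, EnumerationConfig(max_size=3))
        assert id_sets(chain, res.cutsets) == {
            frozenset({"R1"}),
            frozenset({"R2"}),
            frozenset({"R3"}),
        }
        # every pair is a superset of an excluded singleton
        assert res.per_size_counts == {1: 3, 2: 0, 3: 0}
        assert res.status == "complete_to_max_size"

    def test_branch_without_desired(self, branch_plain):
        res = enumerate_mcs(branch_plain, EnumerationConfig(max_size=2))
        assert id_sets(branch_plain, res.cutsets) == {
            frozenset({"R1"}),
            frozenset({"R2"}),
            frozenset({"R4"}),
        }

    def test_branch_with_desired_drops_uptake(self, branch):
        spec = VariantSpec(dual="nb", desired_encoding="stoichiometric")
        res = enumerate_mcs(branch, EnumerationConfig(max_size=2, variant=spec))
        assert id_sets(branch, res.cutsets) == {
            frozenset({"R2"}),
            frozenset({"R4"}),
        }

    def test_max_count_limit(self, rev10_problem):
        spec = VariantSpec(dual="nb", desired_encoding="stoichiometric")
        res = enumerate_mcs(
            rev10_problem,
            EnumerationConfig(max_size=3, max_count=1, variant=spec),
        )
        assert len(res.cutsets) == 1
        assert res.status == "count_limit"

    def test_validated_flags_attached(self, branch):
        spec = VariantSpec(dual="flb", desired_encoding="stoichiometric")
        res = enumerate_mcs(branch, EnumerationConfig(max_size=1, variant=spec))
        assert all(cs.validation == (True, True, True) for cs in res.cutsets)


class TestExclusionConstraint:
    def test_pair_exclusion_coefficients(self, chain):
        model = build_milp(chain, VariantSpec(dual="nb"))
        add_exclusion_constraint(model, frozenset({0, 2}))
        con = model.constraints[-1]
        assert con.coeffs == {"z_0": 1.0, "z_2": 1.0}
        assert con.sense == "<=" and con.rhs == 1.0 and con.tag == "exclusion"

    def test_singleton_exclusion_fixes_binary_to_zero(self, chain):
        model = build_milp(chain, VariantSpec(dual="nb"))
        add_exclusion_constraint(model, frozenset({2}))
        con = model.constraints[-1]
        assert con.coeffs == {"z_2": 1.0} and con.rhs == 0.0

    def test_all_singletons_excluded_makes_size_one_infeasible(self, chain):
        model = build_milp(chain, VariantSpec(dual="nb"))
        for i in range(3):
            add_exclusion_constraint(model, frozenset({i}))
        assert enumerate_size_q(model, 1) == []

    def test_empty_exclusion_rejected(self, chain):
        model = build_milp(chain, VariantSpec(dual="nb"))
        with pytest.raises(DualMcsError):
            add_exclusion_constraint(model, frozenset())


class TestSizeQ:
    def test_chain_size_one_supports(self, chain):
        model = build_milp(chain, VariantSpec(dual="nb"))
        supports = enumerate_size_q(model, 1)
        assert set(supports) == {frozenset({0}), frozenset({1}), frozenset({2})}

    def test_branch_with_desired_size_one(self, branch):
        model = build_milp(
            branch, VariantSpec(dual="nb", desired_encoding="stoichiometric")
        )
        supports = enumerate_size_q(model, 1)
        assert set(supports) == {frozenset({1}), frozenset({3})}  # R2, R4


class TestResultContracts:
    def test_antichain_and_nondecreasing_sizes(self, rev10_problem):
        spec = VariantSpec(dual="flb", desired_encoding="stoichiometric")
        res = enumerate_mcs(rev10_problem, EnumerationConfig(max_size=4, variant=spec))
        sizes = [cs.size for cs in res.cutsets]
        assert sizes == sorted(sizes)
        sets = [cs.indices for cs in res.cutsets]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                assert not (a <= b or b <= a)

    def test_seed_invariance_of_result_set(self, rev10_problem):
        spec = VariantSpec(dual="nb", desired_encoding="kernel")
        results = [
            index_sets(
                enumerate_mcs(
                    rev10_problem,
                    EnumerationConfig(max_size=4, variant=spec, seed=seed),
                ).cutsets
            )
            for seed in (0, 7, 123)
        ]
        assert results[0] == results[1] == results[2]

    def test_non_knockable_reactions_never_cut(self, chain):
        from dataclasses import replace

        restricted = replace(chain, knockable=frozenset({0, 1}))
        res = enumerate_mcs(restricted, EnumerationConfig(max_size=3))
        assert index_sets(res.cutsets) == {frozenset({0}), frozenset({1})}

    def test_no_knockable_reactions_yields_empty_complete_result(self, chain):
        from dataclasses import replace

        blocked = replace(chain, knockable=frozenset())
        res = enumerate_mcs(blocked, EnumerationConfig(max_size=2))
        assert res.cutsets == []
        assert res.status == "complete_to_max_size"
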