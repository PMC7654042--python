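"""Double description oracle, dual-EM enumeration, brute force."""

from fractions import Fraction

import pytest

from dualmcs.dual_construction import build_nb_dual
from dualmcs.exact_linalg import mat
from dualmcs.reference_enumeration import (
    ScaleError,
    brute_force_mcs,
    enumerate_dual_ems,
    extreme_rays_mixed,
    extreme_rays_nonneg,
    full_dual_mcs_enumeration,
)

from helpers import id_sets, index_sets


class TestDoubleDescription:
    def test_single_ray_cone(self):
        rays = extreme_rays_nonneg(mat([[1, -1]]), 2)
        assert rays == [(1, 1)]

    def test_orthant_unconstrained(self):
        rays = extreme_rays_nonneg([], 3)
        assert set(rays) == {(1, 0, 0), (0, 1, 0), (0, 0, 1)}

    def test_rays_satisfy_equalities_exactly(self):
        eq = mat([[1, -1, 0, 2, 0], [0, 1, -1, 0, -1]])
        rays = extreme_rays_nonneg(eq, 5)
        assert rays
        for r in rays:
            for a in eq:
                assert sum(x * y for x, y in zip(a, r)) == 0

    def test_supports_form_antichain(self):
        eq = mat([[1, -1, 0, 2, 0], [0, 1, -1, 0, -1]])
        rays = extreme_rays_nonneg(eq, 5)
        supports = [frozenset(j for j, x in enumerate(r) if x) for r in rays]
        for i, a in enumerate(supports):
            for b in supports[i + 1 :]:
                assert not (a < b or b < a)

    def test_exhaustive_support_minimality_small_cone(self):
        """Cross-check EM supports against enumeration of all sign patterns."""
        from itertools import combinations

        eq = mat([[1, -1, 0, 2, 0], [0, 1, -1, 0, -1]])
        dim = 5
        rays = extreme_rays_nonneg(eq, dim)
        supports = {frozenset(j for j, x in enumerate(r) if x) for r in rays}
        # a support S is EM-feasible iff the system restricted to S has a
        # strictly positive kernel vector; test all small supports directly
        from dualmcs.exact_linalg import rational_kernel

        feasible = set()
        for size in range(1, dim + 1):
            for S in map(frozenset, combinations(range(dim), size)):
                if any(t < S for t in feasible):
                    continue  # not support-minimal
                cols = sorted(S)
                sub = [[row[j] for j in cols] for row in eq]
                basis = rational_kernel(sub)
                for col in basis.columns():
                    if all(x > 0 for x in col) or all(x < 0 for x in col):
                        feasible.add(S)
                        break
        assert supports == feasible

    def test_mixed_free_variable_splitting(self):
        # x1 free, x2 >= 0, constraint x1 - x2 = 0: two modes +-(1,1)? no:
        # x2 >= 0 pins the sign, single mode (1, 1)
        rays = extreme_rays_mixed(mat([[1, -1]]), 2, nonneg={1})
        assert set(rays) == {(Fraction(1), Fraction(1))}

    def test_mixed_fully_free_keeps_both_orientations(self):
        rays = extreme_rays_mixed(mat([[1, -1]]), 2, nonneg=set())
        assert set(rays) == {
            (Fraction(1), Fraction(1)),
            (Fraction(-1), Fraction(-1)),
        }


class TestDualEmEnumeration:
    def test_chain_em_supports_cover_all_singletons(self, chain):
        sys = build_nb_dual(chain, orientation="em_path")
        ems = enumerate_dual_ems(sys)
        from dualmcs.dual_construction import cutsets_from_dual_solutions

        out = index_sets(cutsets_from_dual_solutions(ems, sys))
        assert out == {frozenset({0}), frozenset({1}), frozenset({2})}

    def test_scale_limit_enforced(self, rev10_problem):
        from dualmcs.dual_construction import build_flb_dual

        sys = build_flb_dual(rev10_problem)  # 25 variables
        with pytest.raises(ScaleError):
            enumerate_dual_ems(sys, max_variables=24)


class TestFullEnumeration:
    def test_chain_nb_path(self, chain):
        out = id_sets(chain, full_dual_mcs_enumeration(chain, "nb"))
        assert out == {frozenset({"R1"}), frozenset({"R2"}), frozenset({"R3"})}

    def test_branch_nb_path_with_desired(self, branch):
        out = id_sets(branch, full_dual_mcs_enumeration(branch, "nb"))
        assert out == {frozenset({"R2"}), frozenset({"R4"})}

    def test_flb_path_matches_nb_path(self, branch):
        nb = index_sets(full_dual_mcs_enumeration(branch, "nb"))
        flb = index_sets(full_dual_mcs_enumeration(branch, "flb"))
        assert nb == flb


class TestBruteForce:
    def test_chain(self, chain):
        out = id_sets(chain, brute_force_mcs(chain, 2))
        assert out == {frozenset({"R1"}), frozenset({"R2"}), frozenset({"R3"})}

    def test_branch_without_desired(self, branch_plain):
        out = id_sets(branch_plain, brute_force_mcs(branch_plain, 2))
        assert out == {frozenset({"R1"}), frozenset({"R2"}), frozenset({"R4"})}

    def test_branch_with_desired(self, branch):
        out = id_sets(branch, brute_force_mcs(branch, 2))
        assert out == {frozenset({"R2"}), frozenset({"R4"})}

    def test_budget_guard(self, rev10_problem):
        with pytest.raises(ScaleError):
            brute_force_mcs(rev10_problem, 4, subset_budget=10)


class TestTripleAgreementMini:
    def test_brute_force_matches_nb_em_on_corpus(self, mini_corpus):
        for cfg, problem in mini_corpus:
            bf = index_sets(brute_force_mcs(problem, 3))
            em = index_sets(full_dual_mcs_enumeration(problem, "nb", max_variables=40))
            em3 = {s for s in em if len(s) <= 3}
            assert bf == em3, cfg
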