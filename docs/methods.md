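# Methods

## Problem setting

A metabolic network with `m` metabolites and `n` reactions is described by
its stoichiometric matrix `N` (m x n). At steady state a flux vector `r`
satisfies `N r = 0`, irreversible reactions obey `r_i >= 0`, and fluxes may
carry bounds `lb_i <= r_i <= ub_i`. A **target region** is the
sub-polyhedron `{r : N r = 0, r_Irrev >= 0, T r <= t}` whose every flux
vector the knockouts must eliminate; a **desired region** `{D r <= d, ...}`
is one of which at least one vector must survive. A **minimal cut set
(MCS)** is an inclusion-minimal knockout set that blocks the whole target
region; a **constrained MCS** additionally keeps the desired region
feasible. Because knockouts cannot eliminate the zero flux vector, the
target region must exclude it — equivalently, at least one entry of `t`
must be strictly negative, which the loader enforces.

## Preprocessing conventions

1. **Direction normalization.** Any reaction with `ub_i < 0` is flipped
   (column negated, bounds mirrored) so that `ub_i >= 0` holds everywhere;
   flipped indices are recorded and reports always use reaction ids in the
   normalized orientation.
2. **Conservation relations.** Dependent rows of `N` are removed (pivot
   rows of the echelon form of `N^T` are kept) so that `N` has full row
   rank; the nullspace, and hence every MCS, is unchanged.
3. **Bound folding.** Finite, non-zero flux bounds are folded into the
   target rows as `r_i <= ub_i` and `-r_i <= -lb_i`. Pure irreversibility
   (`lb_i = 0`) stays in the `Irrev` index set. A reaction with `ub_i = 0`
   is pre-blocked: its column is kept for index stability and the row
   `r_i <= 0` is folded, so the dual constructions and the LP oracles see
   the same region. Bounds are never folded into the desired region; there
   they are coupled to the knockout indicators inside the MILP.

All stoichiometric and region data are stored as exact rationals
(`fractions.Fraction`); floats in input files are converted through their
decimal representation, so `0.1` means exactly 1/10.

## Dual systems

**Farkas-lemma-based (FLB) dual.** Infeasibility of the target region is
certified by a solution of the equality system
`(N^T | I | -I_Irrev | T^T) (u, v, s, w) = 0` with `v_Irrev, s, w >= 0` and
the threshold `t^T w <= -c` for an arbitrary constant `c > 0` (default 1).
The system has `m + n + |Irrev| + t` variables and `n + 1` (in)equalities.
MCS are the supports of the `v`-part of its elementary modes (EMs) that
pass the threshold filter and are support-minimal in `v`.

**Nullspace-based (NB) dual.** With a kernel matrix `K` of `N`
(`N K = 0`), the same certificates live in the far smaller system
`(K^T | -K^T T^T) (v, w) = 0`, `w >= 0`, `t^T w <= -c`, with `n + t`
variables and only `n - m + 1` (in)equalities. This arises from
homogenizing the target region with slacks `w` and a scaling variable `y`
and writing down the block kernel

    K_e = [[K, 0], [-T K, t], [0, 1]]

of the extended system `N_e = [[N, 0, 0], [T, I, -t]]`; both identities
`N K = 0` and `N_e K_e = 0` are asserted with exactly zero rational
residual at construction. A feasible `v` always decomposes as
`v = N^T g + T^T w` for some row-space coefficient vector `g` (never
materialized). MCS are the minimal *coordinated supports* of the `v`-parts
of the EMs passing the threshold filter: an irreversible reaction is cut by
a negative entry, a reversible one by any nonzero entry.

**Orientation.** The enumeration-oriented system uses the block
`-K^T T^T` with negative-entry cuts; the MILP formulation uses `+K^T T^T`
with positive-entry cuts (mirroring the FLB sign convention where
`v_Irrev >= 0`). Both orientations are implemented explicitly and
cross-validated against each other and the brute-force oracle rather than
silently unified — this is the subtlest sign convention in the whole
construction and an implicit unification would hide sign bugs.

**Reduction.** Left-multiplying the FLB equality block `(N^T | I | T^T)`
by `K^T` annihilates the `u`-block exactly (`K^T N^T = (N K)^T = 0`) and
yields the NB block — the formal bridge between the two MILP families,
asserted as an exact matrix identity on every fixture and generated
problem.

## MILP formulations

Shortest MCS are found by minimizing `sum z_i` over binary indicators
`z_i` tied to the dual variables by

    z_i = 0  ->  v_i <= 0   (i irreversible)
    z_i = 0  ->  v_i  = 0   (i reversible)

with only one binary per reaction and no explicit `z_i = 1` condition (the
objective keeps spurious ones out of optimal supports). Six formulations
are assembled from three orthogonal choices:

* **dual system** — FLB (`2n + m + t` continuous variables,
  `n + 1 + m + d` structural rows with a stoichiometric desired block) or
  NB (`2n + t` continuous, `n + 1 + d` rows);
* **reversible splitting** — condensed (one free `v_i` each) or split
  (`v_Rev = v^p - v^n` with `v^p, v^n >= 0`; in the FLB split variant the
  irreversible rows relax to `>=` with `v_Irrev >= 0`, in the NB split
  variant `v_Irrev` stays free);
* **desired-region encoding** — stoichiometric (`N r = 0`, `D r <= d`,
  coupling `(1 - z_i) lb_i <= r_i <= (1 - z_i) ub_i`) or kernel
  (`r = K a`, rows `D K a <= d`, coupling on `K_{i,.} a`), or none.

The desired-region variables that a knockout forces to zero make the MILP
return *constrained* MCS directly; supersets of desired-infeasible cut
sets are themselves desired-infeasible, so the constrained-MCS set equals
the set of MCS that keep the desired region feasible, and the MILP, the
EM post-filter and the brute-force oracle provably agree.

**Indicator handling.** The model is a pure data structure; adapters
translate it to a concrete solver. The bundled backend is HiGHS through
`scipy.optimize.milp`, which has no native indicator constraints, so
indicator links are lowered to big-M inequalities — either up front
(`indicator_mode="big_m"`, via `encode_big_m`) or transparently inside the
adapter (`indicator_mode="native"`, which keeps the links in the model for
export and indicator-capable backends). The default `M = 1000 c` is
anchored by the threshold row `t^T w <= -c`, which fixes the scale of
every dual certificate; an undersized `M` can only *miss* cut sets, never
produce wrong ones, and misses are caught by the validation LPs and the
oracle cross-checks. Infinite bounds in the desired coupling are replaced
by configurable surrogates (default ±1000) because `(1 - z) * inf` is
ill-defined; the surrogate only matters if a desired witness needs a flux
beyond it, which the desk-scale generator never produces.

**Enumeration ladder.** MCS are enumerated in order of nondecreasing size:
for `q = 1, 2, ...` the cardinality is fixed with `sum z = q`, the MILP is
solved repeatedly, and each found support `C` is excluded with the integer
cut `sum_{j in C} z_j <= |C| - 1` (which also forbids every superset)
before re-solving; exhaustion at `q` moves the ladder to `q + 1` up to
`max_size`. Adding exclusions immediately within an iteration is
equivalent in results to adding them at the end, because all size-q
supports are distinct. The ladder does not stop at an empty size: true MCS
size spectra have no gaps under exclusion, but a rejected candidate could
create an apparent one, so the ladder defends anyway. Every candidate is
certified before emission (below); failures are logged as numerical
incidents, excluded, and not returned. The solver seed only perturbs
variable order (branching/tie-breaks); the returned *set* of MCS is
seed-invariant, a tested contract.

## Validation

Three LPs certify each candidate `C`:

1. *cut* — the target region is infeasible under the knockouts in `C`;
2. *minimal* — removing any single knockout restores target feasibility;
3. *desired* — the desired region (when given) stays feasible under `C`.

Feasibility is decided by HiGHS (`scipy.optimize.linprog`) at tolerance
1e-9; "infeasible" requires solver-certified infeasibility, and a numerical
failure is retried once at 1e-11 before raising. For disputes, an exact
rational fallback decides region feasibility through extreme rays of the
homogenized region (feasible iff some generator has a positive homogenizing
coordinate); the LP and exact routes are compared exhaustively on all small
knockout subsets of the fixtures in the test suite. Strict inequalities
never occur: target rows are closed with strictly negative right-hand
sides, which is what the constant `c > 0` provides.

## Reference enumeration (oracles)

* **Double description.** Elementary modes of a dual cone are computed by
  the double description method in exact integer arithmetic: free
  variables are split into differences of nonnegative parts, equality rows
  are processed in their given order, adjacency uses the combinatorial
  support test, and merged rays are deduplicated by their coprime-integer
  representation (both sign orientations of purely reversible modes are
  kept; the threshold filter selects the meaningful one). Exactness beats
  speed for an oracle; the default refuses systems beyond 24 variables and
  directs callers to the MILP path.
* **Brute force.** Every knockout subset up to a cardinality cap is tested
  with the feasibility LPs, pruning supersets of discovered cut sets. This
  oracle is completely independent of any dual construction and anchors
  the cross-route agreement checks.

## Synthetic data

The generator emulates desk-scale metabolic networks: a linear backbone
(uptake, chain of conversions, terminal secretion) guarantees connectivity
and a nonzero steady-state route (re-verified by LP, with regeneration on
failure), random internal reactions with stoichiometric coefficients in
{-2..2} add alternative routes, and a configurable fraction of reactions
is reversible. Problem kinds: `target_reaction` (block one secretion),
`yield_region` (block a low-yield regime, two target rows),
`synthetic_lethal_like` (block a growth-like flux above a threshold, no
desired region), and `with_desired` (target one secretion, protect
another). Defaults: 5 metabolites, 10 reactions, reversible fraction 0.25,
3 exchanges, unit thresholds (`c = 1`, demands of 1 flux unit), chosen as
typical of textbook-scale pathway examples. The study corpus used by the
agreement checks cycles metabolite counts 4-7 and reaction counts 9-14
with alternating reversible fractions and bound styles, and enumerates MCS
up to size 4 — sizes at which the brute-force oracle with hundreds of LPs
per problem stays comfortable on a single CPU.

What the generator does *not* emulate: genome-scale sparsity patterns,
cofactor coupling, gene-protein-reaction mappings, thermodynamic
constraints, or realistic biomass compositions. Passing the agreement
checks therefore certifies the *algorithmic* correctness of the dual
constructions and MILPs at desk scale, not their runtime behavior on
genome-scale models, which is hardware- and solver-dependent and out of
scope here.

## Numerical choices and edge cases

* Kernel bases use the reduced-echelon pivot rule (first nonzero column,
  smallest row index), with columns rescaled to coprime integers with a
  positive leading entry — deterministic and reproducible; any basis
  yields the same MCS, and basis-independence is exercised by the
  cross-route tests. Kernel sparsification is deliberately not attempted.
* A network whose kernel is zero-dimensional admits no nonzero steady
  state; the MCS problem is degenerate and raises a model error.
* Reactions with `lb_i = ub_i = 0` are kept (pre-blocked), not removed,
  to preserve index stability.
* `c` is configurable but fixed to 1 by default; the signed support of
  dual solutions — and hence every MCS — is invariant under any `c > 0`,
  and under joint positive rescaling of `(t, c)`, both tested.
* The reduced kernel-desired formulation omits the flux vector `r`
  entirely (it is fully substituted by `K a`).
* Minimality filtering of EM-derived candidates uses subset testing over
  index sets sorted by cardinality — quadratic and entirely adequate at
  desk scale.

## Known limitations

* Gene-level MCS, multiple target/desired regions, and network
  compression beyond conservation-relation removal are out of scope.
* The EM oracles are exponential by nature and enforce desk-scale limits;
  genome-scale enumeration must use the MILP ladder with an
  industrial-strength solver.
* No performance claims are made for the condensed vs split or FLB vs NB
  variants: relative solver speed is hardware- and instance-dependent;
  this package guarantees only that all variants return identical MCS
  sets.
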