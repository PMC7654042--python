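# dualmcs

Computation of **(constrained) minimal cut sets** in stoichiometric
metabolic networks by duality — for systems and synthetic biologists who
design knockout strains (growth-coupled production, synthetic lethals) and
for method developers who need exact, cross-validated reference
implementations of the dual-system machinery.

## The problem and the method

A metabolic network at steady state satisfies `N r = 0` with
irreversibilities `r_i >= 0 (i in Irrev)` and flux bounds
`lb <= r <= ub`. A **target region** `T r <= t` (together with the steady
state and sign constraints) collects the flux behaviors to be eliminated —
e.g. "product secretion below a yield threshold" or "growth above 1% of
maximum". A **minimal cut set (MCS)** is an inclusion-minimal set of
reaction knockouts that leaves no feasible flux vector in the target
region; a **constrained MCS** additionally keeps a **desired region**
`D r <= d` feasible (e.g. "the production route still works").

MCS are elementary modes (support-minimal solutions) of a *dual* system.
Two duals are implemented:

* the **Farkas-lemma-based (FLB) dual**
  `(N^T | I | -I_Irrev | T^T)(u, v, s, w) = 0`, `t^T w <= -c`, with
  `m + n + |Irrev| + t` variables — MCS are supports of the `v`-part;
* the **nullspace-based (NB) dual** `(K^T | -K^T T^T)(v, w) = 0`,
  `t^T w <= -c`, built on a kernel matrix `K` of `N` (`N K = 0`), with
  only `n + t` variables and `n - m + 1` rows — MCS are the minimal
  *coordinated supports* `{j : v_j < 0} ∪ {j in Rev : v_j != 0}`.

For small systems both duals are enumerated completely by an exact
double-description method. For everything else, six MILP formulations
minimize the number of cuts `sum z_i` under indicator constraints
(`z_i = 0 -> v_i <= 0` or `v_i = 0`), covering {FLB, NB} x {condensed,
split reversible variables} x {stoichiometric, kernel} desired-region
encodings, enumerated in order of increasing cardinality with integer-cut
exclusions `sum_{j in C} z_j <= |C| - 1`. Every emitted set is certified
by three LPs (is a cut, is minimal, desired stays feasible), and a
brute-force knockout oracle provides solver-independent ground truth.
All stoichiometric algebra (kernels, dual blocks, the extended-system
kernel identity `N_e K_e = 0`) is exact rational arithmetic.

See `docs/methods.md` for the full account of conventions, formulations
and limitations.

## Worked example

Generate a random problem with a protected (desired) flux, enumerate
constrained MCS with the NB split MILP, and cross-check with the oracle:

```
$ dualmcs generate --seed 7 --kind with_desired --out prob.json
wrote prob.json (m=5, n=10)

$ dualmcs enumerate --problem prob.json --variant nb-split --max-size 3 --out mcs.tsv
size 1: 1 MCS
size 2: 5 MCS
size 3: 1 MCS
status: complete_to_max_size

$ cat mcs.tsv
size  reactions   is_cut  is_minimal  desired_feasible  provenance
1     EX_M5       true    true        true              milp:nb-split-stoichiometric-native
2     EX_in,C4    true    true        true              milp:nb-split-stoichiometric-native
2     C4,X3       true    true        true              milp:nb-split-stoichiometric-native
2     C4,X2       true    true        true              milp:nb-split-stoichiometric-native
2     C3,X1       true    true        true              milp:nb-split-stoichiometric-native
2     C3,C4       true    true        true              milp:nb-split-stoichiometric-native
3     C2,X1,X3    true    true        true              milp:nb-split-stoichiometric-native

$ dualmcs oracle --problem prob.json --method dual-em --path nb --max-variables 40
```

Reading the table: knocking out the secretion `EX_M5` alone blocks every
target flux while the desired secretion stays feasible (all three
validation flags true); six further constrained MCS of sizes 2-3 combine
backbone steps (`C2`-`C4`) with internal bypasses (`X1`-`X3`). The oracle
command re-derives the same seven sets from the elementary modes of the
nullspace-based dual cone — independently of any MILP solver.

The same workflows are available as a library:

```python
import dualmcs as dm

problem = dm.load_problem("prob.json")
spec = dm.VariantSpec(dual="nb", split_reversible=True,
                      desired_encoding="stoichiometric")
result = dm.enumerate_mcs(problem, dm.EnumerationConfig(max_size=3, variant=spec))
for cs in result.cutsets:
    print(cs.size, cs.ids(problem.network), cs.validation)
```

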