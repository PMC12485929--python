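# enzymech

Prediction of ranked, multi-step enzymatic reaction mechanisms from overall
reaction stoichiometry, by integer linear programming over a library of
elementary chemical rules.

## The scientific problem

Enzyme databases record *overall* reactions — substrates in, products out —
but rarely the *mechanism*: the ordered sequence of elementary steps
(proton transfers, nucleophilic additions, eliminations, …) by which the
active site converts one into the other. Given an overall reaction and a
library of known elementary steps, `enzymech` asks: **what is the most
parsimonious ordered sequence of elementary steps that exactly accounts for
the observed chemical change?**

The package encodes molecules as counts of *moieties* — non-hydrogen atoms
classified by their first bonding shell (element, formal charge, hydrogen
count, and the multiset of bonded neighbors with bond orders). A reaction
becomes a sparse integer vector **T°** of moiety changes (products minus
substrates), each elementary rule *r* a column **T**<sub>·r</sub> of the same
kind, and mechanism search becomes integer programming.

## Core model

Let *y*<sub>r</sub> ∈ ℤ<sub>≥0</sub> count how often rule *r* is used and
*z*<sub>k,r</sub> ∈ {0,1} assign rule *r* to ordered step *k*. The monolithic
formulation solves

```
min  Σ_r y_r                                        (parsimony)
s.t. Σ_r T_{m,r} y_r = T°_m              ∀ moieties m   (net balance)
     C⁰_m + Σ_{j≤k} Σ_r T_{m,r} z_{j,r} ≥ 0
                         ∀ k, ∀ m ∉ M*   (prefix feasibility)
     Σ_r z_{k,r} ≤ 1                     ∀ k            (one rule per step)
     steps used contiguously from k = 1                 (contiguity)
     Σ_k z_{k,r} = y_r                   ∀ r            (linking)
     Σ_r y_r ≤ W                                        (step budget, W = 20)
```

where **C⁰** counts moieties available at the start and **M\*** is the set of
*labeled* (catalytic) moieties — enzyme machinery such as active-site
histidine that may be consumed before it is regenerated, and is therefore
exempt from prefix non-negativity.

In practice the package solves a decomposed pair: a small *min-rules* master
(net balance only) proposes a multiset of rules, and an *ordering*
feasibility program checks whether that multiset can be sequenced. Integer
cuts exclude each found solution and the loop enumerates the top-N
mechanisms in order of increasing step count. Candidates are then
*re-ranked* by unordered multiset-Jaccard similarity to a database of known
mechanisms, so that a slightly longer mechanism with a close known analog
can overtake a shorter but unprecedented one.

All integer programs are solved with the HiGHS backend shipped in
`scipy.optimize.milp`.

## Worked example

The built-in toy esterase fixture models ester hydrolysis with three
catalytic strategies: direct water attack through a tetrahedral
intermediate, and two general-base-assisted acyl-enzyme routes (His- or
Asp-activated serine). Catalytic moieties (Ser, His, Asp states) are
labeled, so they may be consumed before being regenerated:

```python
from enzymech import SolverConfig, enumerate_mechanisms, build_step_network
from enzymech.fixtures import toy_esterase

matrix, problem, expected = toy_esterase()
result = enumerate_mechanisms(problem, SolverConfig(max_rules=4, top_n=10, time_limit=60))
print("outcome:", result.outcome)
for mech in result.mechanisms:
    print(f"rank {mech.parsimony_rank}: steps {list(mech.sequence)} "
          f"({mech.total_steps} elementary steps)")

net = build_step_network(
    list(result.mechanisms), problem, generic_moieties=expected["generic_moieties"]
)
print("network:", len(net.graph.nodes), "states,", len(net.graph.edges),
      "transitions,", len(net.branch_points), "branch point(s)")
```

Output:

```
outcome: complete
rank 1: steps [4, 5] (2 elementary steps)
rank 2: steps [0, 1] (2 elementary steps)
rank 3: steps [2, 3] (2 elementary steps)
network: 4 states, 4 transitions, 1 branch point(s)
```

All three two-step strategies are enumerated; compiling them into a step
network (with the general acid/base variants projected out) merges the
His- and Asp-assisted acylations onto a single branching transition.

### Command line

The `enzymech` console script wraps the same machinery:

```sh
enzymech encode --smiles "CC(=O)OC"
```

```
C+0H0(-C+0,-O+0,=O+0)	1
C+0H3(-C+0)	1
C+0H3(-O+0)	1
O+0H0(-C+0,-C+0)	1
O+0H0(=C+0)	1
```

Given a rule file (JSON or CSV, see `enzymech.rules.write_rules`), predict a
single reaction:

```sh
enzymech predict --reaction "CC(=O)OC.O>>CC(=O)O.CO" --rules rules.json --top 3
```

```json
{
 "candidates": [
  {
   "best_match": "",
   "parsimony_rank": 1,
   "score": 0.0,
   "sequence": [0],
   "similarity_rank": 1,
   "total_steps": 1
  }
 ],
 "detail": "complete",
 "incompatible_moieties": [],
 "reaction_id": "reaction",
 "status": "predicted"
}
```

`enzymech batch` processes a two-column TSV/CSV of reactions and classifies
every row as `predicted`, `timeout`, `incompatible`, `unbalanced`,
`no_net_change`, `infeasible`, or `error`; `enzymech network` compiles
predicted candidates to GraphML or DOT; `enzymech simulate` generates a
synthetic solvable instance with a known planted mechanism.

## Package layout

| Module | Contents |
| --- | --- |
| `enzymech.moieties` | moiety encoding, moiety vectors, reaction deltas, balance checks |
| `enzymech.rules` | elementary rules, rule matrices, protonation closure, JSON/CSV I/O |
| `enzymech.solver` | MILP formulations, integer cuts, ranked enumeration |
| `enzymech.rerank` | unordered similarity scoring and candidate re-ranking |
| `enzymech.pipeline` | end-to-end prediction, batch runs, step-network compilation |
| `enzymech.fixtures` | synthetic instance generator, brute-force oracle, toy esterase |

See `docs/methods.md` for the full model description, parameter defaults,
and limitations.
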