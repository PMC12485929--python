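# Methods

This document describes the model implemented by `enzymech`, the numerical
choices made, the defaults and their rationale, and the limitations of the
approach. Nothing here claims empirical performance beyond what the test
suite and `scripts/acceptance.py` actually compute.

## 1. Moiety encoding

Every non-hydrogen atom in a molecule is classified by its **first bonding
shell**:

* element symbol,
* formal charge,
* total hydrogen count (implicit + explicit),
* the sorted multiset of `(bond order, neighbor element, neighbor formal
  charge)` descriptors over its non-hydrogen neighbors.

The classification is serialized to a canonical text key,

```
El{charge:+d}H{nH}({sorted neighbor descriptors})
```

for example `C+0H2(-C+0,-O+0)` for a methylene bridging carbon and oxygen,
or `O-1H1()` for hydroxide. Bond orders use `-` (single), `=` (double),
`#` (triple), and `:` (aromatic). A *labeled* (catalytic) moiety carries a
tag prefix, `tag::key`, so that chemically identical environments on the
enzyme and on the substrate remain distinguishable. Synthetic fixtures use
opaque `abstract:name` keys that never collide with chemical ones.

Rationale for a textual key rather than a fragment-SMILES: the key is
canonical by construction (sorted fields), trivially parseable (a single
regular expression recovers element, charge, H count, and neighbors), and
this parseability is load-bearing — protonation-rule validation checks that
paired moieties differ by exactly one hydrogen and one unit of charge
directly on the parsed fields.

A molecule maps to a sparse non-negative integer **moiety vector**; a
reaction with positive integer coefficients maps to the difference
**T° = Σ products − Σ substrates**. Stereochemistry is stripped at parse
time, so enantiomer/epimer pairs encode identically and a stereo-only
transformation yields a zero delta (surfaced as `no_net_change` by the
pipeline rather than being sent to the solver). Elemental and net-charge
balance are checked *before* encoding, since the moiety delta of an
unbalanced reaction is not meaningful.

Invariants guaranteed by the encoding (and tested): invariance under atom
renumbering and stereo flips; the total moiety count equals the heavy-atom
count; the delta of any identity reaction is zero; step deltas of a
multi-step mechanism sum telescopically to the overall reaction delta.

## 2. Elementary rules

An elementary rule is a signed sparse moiety delta with an identifier,
direction, and provenance string. A `RuleMatrix` collects rules with unique
identifiers **and unique deltas** (two rules with identical deltas are
indistinguishable to the solver, so the builder rejects the duplicate and
logs it). Building a matrix can optionally close the set under reversal
(negated delta, flipped direction) and append protonation rules for a set
of proton carriers (default: H₃O⁺/H₂O and H₂O/OH⁻), each as a mutually
inverse pair.

Rule files round-trip through either a JSON document or a single CSV
dialect with a `record` column discriminating `meta`/`delta`/`labeled`
rows; read errors name the offending line.

## 3. Optimization formulations

Let *R* be the rule set, *y*<sub>r</sub> ∈ ℤ<sub>≥0</sub> usage counts,
*z*<sub>k,r</sub> ∈ {0,1} step assignments, *W* the step budget, and
*K* the ordering horizon.

**Monolithic (`solve_min_order_rules`).** Minimizes Σ*y* subject to net
balance **Ty = T°**, prefix non-negativity of every unlabeled moiety after
each step (starting from the initial counts **C⁰**), at most one rule per
step, contiguous step usage, the linking constraint Σ<sub>k</sub>*z*<sub>k,r</sub> = *y*<sub>r</sub>,
and Σ*y* ≤ W. This is the reference formulation: it returns a provably
minimum-length *ordered* mechanism.

**Decomposed (`solve_min_rules` + `solve_order_rules`).** The master
minimizes Σ*y* under net balance and the budget only; the subproblem is a
pure feasibility program over K = Σ*y* steps that either orders the
proposed multiset or proves it unorderable. The decomposition is what makes
top-N enumeration affordable: the master is small, and most of the work of
the monolithic model (the K·|R| assignment binaries) is only paid for
candidate multisets.

**Catalytic exemption.** Moieties in **M\*** (labeled moieties plus any
problem-level exemptions) are excluded from prefix non-negativity. This
encodes that enzyme machinery may be transiently consumed — e.g. a general
base deprotonated in step 1 and restored in step 3 — without the mechanism
being rejected. The test suite contains an instance that is orderable *only*
under the exemption, verified independently by exhaustive search.

### Integer cuts and enumeration

`enumerate_mechanisms` loops master → ordering, excluding each found
solution with an integer cut and re-solving, until N mechanisms are found,
the master goes infeasible (enumeration `complete`), or time runs out
(`timeout`). Parsimony rank is the 1-based discovery order, which is
non-decreasing in step count.

Two user-selectable cut styles exclude a found solution with support *S*:

* `as_printed` (default): Σ<sub>r∈S</sub> *y*<sub>r</sub> ≤ |S| − 1.
  Cheap (one row), but it also removes every solution whose support is a
  *superset* of S and every solution that re-uses rules of S at higher
  multiplicity.
* `support_exact`: binary indicators *u*<sub>r</sub> linked to *y* by
  *y*<sub>r</sub> ≤ W·*u*<sub>r</sub> and *u*<sub>r</sub> ≤ *y*<sub>r</sub>,
  with Σ<sub>r∈S</sub>*u* − Σ<sub>r∉S</sub>*u* ≤ |S| − 1. Excludes exactly
  the solutions with support *equal* to S, at the cost of |R| extra
  binaries per cut.

The two styles provably diverge; the tests include a worked instance where
a cut on support {A, B} leaves `support_exact` a valid optimum (y<sub>A</sub> = 2)
that `as_printed` removes.

**Unorderable multisets** are a third case: the master proposes a count
vector whose ordering subproblem is infeasible. Cutting it with either
public style would also remove *different* count vectors that happen to be
orderable, silently breaking the guarantee that enumeration finds the true
minimum. The package therefore excludes unorderable proposals with an
internal exact no-good cut on the count vector itself (`count_exact`):
per rule, indicator binaries *e*<sub>r</sub> ("*y*<sub>r</sub> ≥ c<sub>r</sub>+1",
enforced by *y*<sub>r</sub> − (c<sub>r</sub>+1)·*e*<sub>r</sub> ≥ 0) and
*f*<sub>r</sub> ("*y*<sub>r</sub> ≤ c<sub>r</sub>−1", enforced by
*y*<sub>r</sub> + (W−c<sub>r</sub>+1)·*f*<sub>r</sub> ≤ W), with
Σ(*e* + *f*) ≥ 1. This removes exactly the one proposed count vector and
nothing else, preserving equivalence with the brute-force oracle — the
property the acceptance suite checks on hundreds of random instances.

### MILP backend and determinism

All programs are solved with `scipy.optimize.milp` (HiGHS). Models are
rebuilt from scratch at every enumeration iteration with variables and
constraints added in a fixed, sorted order, so repeated runs produce
identical models. HiGHS exposes no random-seed option through SciPy; the
`solver_seed` configuration field is accepted for interface stability but
determinism comes from stable model construction. Batch outputs are written
with sorted keys and fixed indentation, and re-runs are byte-identical (a
tested property).

Solver statuses are mapped conservatively: HiGHS status 0 → optimal,
2 → infeasible, 1 (time limit) → `SolveTimeout`, anything else → error.

## 4. Parameter defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| `max_rules` (W) | 20 | Step budget; generous upper bound on mechanism length for single overall transformations. Also serves as the big-M in indicator linking, so it should stay small. |
| `max_steps` (K) | = W | Ordering horizon; must be ≥ W since every used rule occupies one step. |
| `top_n` | 10 | Candidates retained for re-ranking; enough for similarity to overturn parsimony without exploding enumeration cost. |
| `time_limit` | 1200 s | Per-reaction wall budget for the whole enumeration loop. |
| `per_order_time_limit` | `time_limit`/10 | Caps any single ordering subproblem so one hard multiset cannot consume the whole budget. |
| `cut_style` | `as_printed` | Cheapest cut; switch to `support_exact` when distinct-multiplicity solutions over the same support must be kept. |
| proton carriers | H₃O⁺/H₂O, H₂O/OH⁻ | Aqueous general acid/base chemistry. |

The acceptance computations use much smaller limits (W = K = 4, 10–60 s)
because the synthetic instances are small by construction; these sizes are
the package's own choice, set so the whole script finishes in seconds on
one CPU.

## 5. Synthetic instance generator

`generate_instance` (NumPy `default_rng`, fully seed-deterministic) draws
`n_rules` distinct sparse rule deltas (2–3 moieties each, entries ±1/±2)
over `n_moieties` abstract moieties, a fraction of which are labeled
catalytic. It plants a mechanism by sampling a rule sequence of
`planted_length`, setting the target to the sequence's telescoping sum, and
setting the initial counts of each unlabeled moiety to the negated running
minimum of its prefix sums — which guarantees, by construction, that the
planted sequence is a feasible ordered mechanism. Zero-delta targets are
resampled. An independent prefix-sum validator (`validate_planted`)
re-checks every emitted instance.

**What the generator emulates:** the combinatorial core of mechanism search
— sparse integer rule deltas, catalytic exemptions, prefix feasibility, and
the existence of a known-feasible solution of known length, enabling exact
recovery tests against a brute-force oracle.

**What it does not emulate:** real chemistry. Abstract moieties carry no
valence, element, or charge semantics; rule deltas are not constrained to
chemically sensible transformations; the distribution of rule sparsity and
mechanism length is not fitted to any curated reaction corpus. Results on
synthetic instances certify solver correctness, not chemical accuracy.

The brute-force oracle enumerates all rule sequences up to a length bound
(`itertools.product`, with a guard refusing > 10⁶ sequences) and is the
ground truth for the equivalence and recovery tests.

## 6. Similarity re-ranking

A mechanism is summarized as the multiset of its step identifiers (rule ids
by default, or rule deltas keyed by their canonical signature to be stable
across rule-file numberings). Similarity between two mechanisms is the
multiset Jaccard index Σ min(mult)/Σ max(mult) (variants: set Jaccard,
Dice). A candidate's score is its maximum similarity over a database of
known mechanisms — the closest known analog — with the first database
record winning ties. Re-ranking sorts candidates by descending score with
ties broken by parsimony rank (a stable permutation; tested axioms:
symmetry, [0,1] bounds, score 1 ⇔ equal multisets, score 0 ⇔ disjoint
step sets).

The similarity is *unordered* by design: mechanism databases rarely agree
on step ordering conventions, and the multiset view is invariant to them.
The cost is that two mechanisms using the same steps in chemically
different orders are indistinguishable to the re-ranker.

## 7. Pipeline and step networks

`predict` classifies every reaction into exactly one status: `unbalanced`
(element/charge audit fails), `no_net_change` (zero moiety delta),
`incompatible` (target touches moieties no rule can produce or consume,
reported explicitly), `infeasible` (MILP proves no mechanism within the
budget), `timeout`, `error` (parse failures etc., never raised out of a
batch), or `predicted` with ranked candidates. Batch runs never abort on a
bad row and write deterministic JSON.

`build_step_network` compiles the top candidates into a directed graph
whose nodes are cumulative moiety states projected onto non-generic
moieties. Projecting out *generic* moieties (e.g. the general acid/base
states of His vs. Asp) merges mechanistic variants that differ only in
which catalytic group performs a step, so alternative strategies appear as
branch points in a single network. Every source→sink path telescopes to
the projected target (a tested invariant). Export formats: GraphML and DOT.

## 8. Limitations

* **First-shell encoding is lossy.** Moieties see one bond shell; two
  different molecules can share a moiety vector, and a balanced rule
  multiset is necessary but not sufficient for a real mechanism. The
  solver reasons about counts, not bonds — it cannot verify atom mappings
  or transition-state geometry.
* **Stereochemistry is invisible.** Stereo-only transformations
  (racemases, epimerases) yield zero deltas and are deliberately surfaced
  as `no_net_change` rather than predicted.
* **Rule library coverage bounds recall.** A reaction whose delta needs a
  moiety outside the library's span is `incompatible`; the package reports
  the missing moieties but cannot invent rules.
* **Parsimony is a heuristic.** The shortest mechanism is not always the
  biological one; re-ranking mitigates but does not eliminate this, and is
  itself only as good as the mechanism database.
* **Exact enumeration limits scale.** `support_exact` and `count_exact`
  cuts add |R| binaries each; with hundreds of rules and large N the
  master grows noticeably. The per-order time limit keeps single
  subproblems bounded but hard instances may return `timeout` with a
  partial candidate list.
* **No solver-level randomness control.** Determinism relies on stable
  model construction; a future SciPy/HiGHS exposing seeds could be wired
  to `solver_seed` without interface changes.
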