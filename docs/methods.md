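# Methods

## Boolean producibility semantics

The network is an AND/OR system: reactions are conjunctions over their
input compounds and catalyzing enzymes, compounds are disjunctions over
their producing reactions, sources (compounds with no producer) are
constants fixed at 1, and enzymes are the free decisions (0 = inhibited).
A 0/1 labeling satisfying these conditions is a *valid assignment*; on
cyclic networks there may be several, because a cycle that feeds itself
satisfies the local conditions with every cycle node at 1.

`propagate` computes the **least** fixed point, and every damage number in
the package is defined against it.  The choice is forced by the intended
biology: a metabolite is produced only if material actually flows to it
from seed compounds, so an active label must be witnessed by a finite
derivation — self-sustaining cycles are not producible.  The worked
example's own narrative depends on this reading (stopping R2 makes C2
non-producible even though C2 and C7 sit on a cycle that could formally
sustain itself).  The least fixed point is unique and order-independent;
`propagate` reaches it with a worklist algorithm (counters of unmet
requirements per reaction) in time linear in network size.

*Damage* counts knocked-out **non-target compounds only**.  Reactions and
enzymes never enter the count, and a target forced to 0 is the goal, not
a cost.  `damage` does not require the targets to be stopped — it just
measures; `stops_targets` checks the goal separately.

## ILP formulation

Per node x, complementary binaries T(x), F(x) with T(x)+F(x)=1.  Boolean
gates become linear rows via the standard CNF route — each clause
`a ∨ b ∨ …` is one row `sum of matching T/F variables ≥ 1`:

- reaction r with requirement set Q (inputs ∪ enzymes):
  `T(r) + Σ_{q∈Q} F(q) ≥ 1` and, per q, `F(r) + T(q) ≥ 1`;
- compound c with producer set P (|P| ≥ 2):
  `F(c) + Σ_{p∈P} T(p) ≥ 1` and, per p, `T(c) + F(p) ≥ 1`;
- single-requirement gates collapse to the copy equality `T(out) = T(in)`
  (one row);
- sources: `T = 1`; targets: `F = 1`; requirement-free reactions:
  `T(r) = 1` (constant-active; nothing can stop them).

Objective: **minimize Σ F(c) over non-target compounds** — exactly the
damage.  Targets are excluded from the sum because their F is already
pinned to 1; including them would only shift the objective by a constant.
The enzyme variables are the only genuinely free decisions; the optimal
inhibition set is read off as the enzymes with T = 0.

Base model size is exactly `2(m+n+l)` binaries and, on the worked
example, 37 rows — both counted exactly in the tests.

### Acyclic-support ("levels") extension

The rows above encode fixed-point *consistency* only.  Because the
objective rewards producibility, a damage-minimizing optimum over a
cyclic network can label an unfed cycle all-active — a solution that is
feasible for the constraint system but not a least fixed point.  The
default `acyclic_encoding="levels"` removes these:

- a level variable `L(x) ∈ [0, m+n]` per compound and reaction
  (continuous is sufficient; sources pinned to 0);
- per (compound c, producing reaction r) a binary support indicator
  `y_{c,r} ≤ T(r)`, with `Σ_r y_{c,r} ≥ T(c)`: an active compound selects
  an active supporter;
- big-M ordering rows `L(c) ≥ L(r) + 1 − M(1 − y_{c,r})` and, per input
  u of r, `L(r) ≥ L(u) + 1 − M(1 − T(r))`, with `M = m+n+1`.

An active cycle would need strictly increasing levels around a loop, so
every active node must trace back to level-0 sources — precisely
least-support.  The extension adds at most `(m+n)` level variables plus
one indicator per compound–producer edge, keeping the model linear in
network size for degree-bounded networks.

With `acyclic_encoding="none"` the literal consistency-only system is
solved instead; `solve_eci` then always re-verifies the reported optimum
against `propagate` and, if a cycle artefact is detected, retries once
with levels.  The verify-and-retry path is kept because it demonstrates
*why* the extension is needed (see the cycle fixture test); levels is the
default because it is correct without a second solve.

### Solver

The backend is HiGHS via `scipy.optimize.milp`, selected by
`backend="highs"` (the only bundled backend; the option exists so other
MILP backends can be added behind the same interface).  Variable columns
follow declaration order and HiGHS runs single-threaded here, so repeated
solves of the same instance return the same optimum among ties.  Among
equal-damage enzyme sets the ILP reports one arbitrary optimum; the
brute-force oracle instead fixes ties deterministically (smallest
cardinality, then lexicographic), so cross-checks compare damage values,
not sets.  `build_ilp(...)` exposes `to_lp_string()` (CPLEX LP text
format) for debugging.

## Exhaustive oracle

`brute_force_eci` enumerates enzyme subsets in increasing cardinality and
lexicographic order, keeping the first subset attaining the minimum
damage among those stopping all targets.  It is exponential by design —
the independent ground truth for the ILP on small instances — and guards
itself with a subset cap (default 2^20) unless a `max_set_size` bound is
given.  An instance is *infeasible* when even inhibiting every enzyme
leaves some target producible (e.g. a target fed by an enzyme-free
reaction chain from sources); both routes report `status="infeasible"`.

## Edge-cover reduction

The NP-completeness argument is executable: `reduce_mec_to_eci` maps an
undirected graph to a network with one compound per edge, one
AND-reaction per vertex (inputs = incident edge-compounds, product = a
single target `c_t`).  Stopping `c_t` forces every vertex-reaction off,
i.e. knocks out at least one incident edge-compound per vertex — an edge
cover — and minimum damage equals minimum cover size.  The original
argument reasons about deleting compounds directly (its enzyme set is
empty); to drive the construction through the ordinary enzyme-centric
solver, each edge-compound gets a private production channel — one
universal source `s`, a virtual reaction per edge catalyzed by a virtual
enzyme — so "delete compound c_i" becomes "inhibit enzyme ê_i".  Every
knocked-out compound of any solution is then an edge-compound, making the
size correspondence literal (asserted in the tests).  `brute_force_mec`
is the exhaustive cover oracle, cross-checked against networkx's
matching-based `min_edge_cover` in the tests.  The hardness claim's
degree-2 refinement needs a gadget this construction does not include
(reaction indegree equals vertex degree here); it is out of scope.

## Random network generator

The generator emulates small KEGG-like topologies for testing: a seed
layer of source compounds, reactions wired forward so each draws inputs
from compounds already producible, every non-source compound assigned at
least one producer, 1–2 catalyzing enzymes per reaction drawn from the
enzyme pool, and degree caps (default 2, echoing degree-bounded
pathways).  Wiring is acyclic first; with probability
`cycle_probability` one compound–reaction cycle is injected by reserving
the last reaction as a *cycle closer* that consumes a compound strictly
downstream of some non-source d and re-produces d.  Because d keeps its
original acyclic producer, injection preserves two postconditions that
hold for every emitted network: `validate` reports nothing, and with no
inhibition every compound is producible (`damage(∅) = 0`).  Same seed and
config give a structurally identical network.

What the generator does *not* emulate: reaction reversibility,
stoichiometry, compartments, currency metabolites, hub-dominated degree
distributions, or realistic pathway sizes.  Passing the
generator-based equivalence suites therefore shows the solver is correct
on the model class, not that the model captures any particular organism's
metabolism.

## Problem sizes and study conditions

The equivalence suites run at sizes where the exhaustive oracles are
exact and fast: ILP-vs-brute-force on 50 seeded instances with m ≤ 12,
n ≤ 10, l ≤ 6 across cycle regimes {0, 0.5, 1}; reduction-vs-cover on
100+ seeded graphs with at most 8 vertices.  These sizes make the
oracle's 2^l and 2^|E| enumerations trivial while still covering cyclic,
multi-producer, and infeasible cases.  The ILP itself has no such limit —
model size grows linearly and MILP solving is the only scaling cost.

Real pathways are encoded by hand in the network format (identifiers are
opaque case-sensitive strings, so database ids like `C02165` or
`E3.3.2.6` pass through verbatim), one `reaction` line per
irreversible step with its substrates, catalyzing enzymes, and products.
Published pathway analyses depend on the specific database version the
topology was drawn from, so no real-pathway result is bundled; the test
suite instead includes a small synthetic fragment with database-style
identifiers demonstrating the encoding workflow end to end.

## Numerical and design notes

- Binary values are read back with a 0.5 threshold; HiGHS returns
  integral values well within default tolerances at these sizes, and
  every reported optimum is additionally re-verified by exact integer
  propagation before being returned.
- A reported objective is never trusted directly: `verify_solution`
  recomputes the knockout set from the inhibition set by propagation and
  compares it exactly.
- Sources are derived (no producing reaction), never declared, removing
  an inconsistency channel from input files.  A target that is a source
  is rejected at instance construction — no enzyme set can stop it.
- Reactions with an empty enzyme set are allowed (spontaneous steps; the
  reduction relies on them).  A reaction with no inputs and no enzymes is
  constant-active.
- Damage counted over non-targets is not monotone in the target set:
  enlarging the target set removes the new target from the counting set,
  so optimal damage can drop by exactly the compounds promoted to
  targets.  The monotonicity test compares both optima under the original
  instance's accounting.
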