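# ecinet — minimum-damage enzyme combination identification

`ecinet` answers a drug-target question on Boolean metabolic networks:
**which set of enzymes should be inhibited so that a given set of
disease-associated target compounds can no longer be produced, while
stopping the production of as few other metabolites as possible?**

The number of non-target compounds rendered non-producible by an
inhibition is its *damage* — a proxy for side-effects.  Finding the
minimum-damage enzyme set is NP-complete (the package ships an executable
reduction from minimum edge cover), so `ecinet` solves it exactly with an
integer linear program, cross-checked by an exhaustive-search oracle on
small instances.

## The model

A metabolic network is a directed graph over compounds *C* (|C| = m),
reactions *R* (|R| = n), and enzymes *E* (|E| = l).  Every node carries a
Boolean value:

- a **reaction** is an AND node — active iff all of its input compounds
  and all of its catalyzing enzymes are 1;
- a **compound** is an OR node — producible iff at least one reaction
  producing it is active; compounds with no producing reaction are
  **sources** (seed metabolites) and are always 1;
- an **enzyme** is 0 iff it is in the inhibited set *X*.

Producibility is the **least fixed point** of this system: a compound
counts as producible only if it has a finite derivation from the sources,
so a self-sustaining cycle with no external feed is *not* producible.

The optimization is encoded with a complementary binary pair per node,
T(x) + F(x) = 1, and one linear row per Boolean clause: each reaction
contributes `T(r) + Σ F(req) ≥ 1` and `F(r) + T(req) ≥ 1` per
requirement, each multi-producer compound the dual OR rows, single-input
gates collapse to copy equalities, sources are pinned `T = 1` and targets
`F = 1`.  The objective minimizes `Σ F(c)` over non-target compounds —
the damage.  The base model has exactly `2(m+n+l)` binaries, linear in
network size.  On cyclic networks an acyclic-support ("levels") extension
is enabled by default so that the ILP optimum coincides with
least-fixed-point propagation; see `docs/methods.md`.

## Worked example

The bundled hypothetical network (`ecinet.fig1_network()`) has nine
compounds, three reactions, two enzymes, and a compound–reaction cycle
C2 → R2 → C7 → R1 → C2:

```text
reaction R1 inputs=C1,C7 enzymes=E2 products=C2
reaction R2 inputs=C2,C3 enzymes=E1 products=C4,C5,C7
reaction R3 inputs=C6    enzymes=E1 products=C7,C8,C9
```

Sources are C1, C3, C6; the target is C5.  Either enzyme stops C5, but at
different cost — inhibiting E1 kills R2 and R3 and takes down C2, C4, C7,
C8, C9 (damage 5), while inhibiting E2 only stops C2 and C4 (C7 survives
through R3), damage 2:

```sh
$ ecinet optimize fig1.net --targets C5
{
 "backend": "highs",
 "damage": 2,
 "inhibited": ["E2"],
 "instance": "fig1.net",
 "knocked_out": ["C2", "C4"],
 "status": "optimal",
 "targets": ["C5"],
 "wall_time": 0.0028
}
```

So the optimal drug target is **{E2} with damage 2**: stopping C5 costs
the cell only C2 and C4.  The same library calls are
`ecinet.solve_eci(instance)` (ILP) and `ecinet.brute_force_eci(instance)`
(exhaustive oracle); `ecinet.damage(network, {"E1"}, {"C5"})` returns
`(5, {C2, C4, C7, C8, C9})` for the costlier alternative.

Other subcommands: `ecinet validate`, `ecinet simulate --inhibit ...`,
`ecinet gen-random` (seeded random networks), and `ecinet reduce-mec`
(turn an edge-cover graph into an equivalent network — the
NP-completeness reduction, runnable end to end).

Real pathways can be encoded in the same line-oriented format using their
database identifiers verbatim (e.g. compounds `C02165`, enzymes
`E3.3.2.6` — dots and mixed case are preserved); see the format notes in
`docs/methods.md`.

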