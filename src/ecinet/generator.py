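"""Seeded random Boolean metabolic network generator.

Networks are wired acyclically first — each reaction draws its inputs from
compounds already producible at that point (sources or products of earlier
reactions) — which guarantees by construction that every non-source
compound has a producing reaction and that every compound is producible
when nothing is inhibited.  A compound-reaction cycle is then injected,
with probability ``cycle_probability``, by reserving the last reaction as
a *cycle closer*: it consumes a compound downstream of some non-source d
and re-produces d.  Because d keeps its original (acyclic) producer, the
cyclic producer is redundant and injection never destroys producibility,
so the generator's two postconditions hold simultaneously: ``validate``
returns no violations and ``damage(∅) = 0``.

Same seed + same config → structurally identical network.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import GenerationError
from .network import MetabolicNetwork, Reaction

__all__ = ["GeneratorConfig", "generate_random_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the random generator.

    ``m``/``n``/``l``: compound, reaction, and enzyme counts.  Degree
    bounds cap a reaction's input count (``max_indegree``) and product
    count (``max_outdegree``).  ``cycle_probability`` is the chance of
    injecting one compound-reaction cycle; injection needs n >= 3 and
    m >= 4 (producer, consumer, and closer reactions around at least two
    non-source compounds).
    """

    m: int
    n: int
    l: int
    max_indegree: int = 2
    max_outdegree: int = 2
    cycle_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n < 0 or self.l < 0:
            raise GenerationError("m must be >= 1 and n, l >= 0")
        if self.max_indegree < 1 or self.max_outdegree < 1:
            raise GenerationError("degree bounds must be >= 1")
        if not 0.0 <= self.cycle_probability <= 1.0:
            raise GenerationError("cycle_probability must lie in [0, 1]")


def generate_random_network(config: GeneratorConfig) -> MetabolicNetwork:
    """Deterministically generate a valid network from a seeded config."""
    rng = random.Random(config.seed)
    m, n, l = config.m, config.n, config.l
    compounds = tuple(f"C{i + 1}" for i in range(m))
    enzymes = tuple(f"E{i + 1}" for i in range(l))
    if n == 0:
        return MetabolicNetwork(compounds, (), enzymes)
    if m < 2:
        raise GenerationError(
            "need m >= 2 with reactions present (at least one source and "
            "one produced compound)"
        )

    want_cycle = rng.random() < config.cycle_probability
    if want_cycle and (n < 3 or m < 4):
        raise GenerationError(
            "cycle injection needs n >= 3 reactions and m >= 4 compounds"
        )
    # the cycle closer consumes one reaction slot; with a cycle the first
    # reaction is pinned to a single product so a consumer still has a
    # fresh compound to emit
    wiring_reactions = n - 1 if want_cycle else n
    if want_cycle:
        q_max = min(m - 1, 1 + (wiring_reactions - 1) * config.max_outdegree)
        q_min = 2
    else:
        q_max = min(m - 1, wiring_reactions * config.max_outdegree)
        q_min = 1
    if q_max < q_min:
        raise GenerationError(
            f"degree bounds too tight to produce {q_min} non-source "
            f"compound(s) with {wiring_reactions} wiring reaction(s)"
        )
    q = rng.randint(q_min, q_max)  # number of non-source compounds
    sources = list(compounds[: m - q])
    non_sources = list(compounds[m - q :])

    def pick_enzymes() -> tuple[str, ...]:
        if l == 0:
            return ()
        k = rng.randint(1, min(2, l))
        return tuple(sorted(rng.sample(enzymes, k)))

    reactions: list[Reaction] = []
    available = list(sources)  # compounds producible so far, in order
    produced: list[str] = []  # non-sources, in production order
    todo = list(non_sources)
    # (input d consumed by a reaction that produces c != d)
    cycle_candidate: tuple[str, str] | None = None

    for k in range(wiring_reactions):
        slots_after = (wiring_reactions - k - 1) * config.max_outdegree
        lo = max(1 if todo else 0, len(todo) - slots_after)
        hi = min(config.max_outdegree, len(todo))
        if want_cycle and k == 0:
            take = 1  # leave fresh compounds for the consumer reaction
        else:
            take = rng.randint(lo, hi) if hi else 0
        if take:
            products = tuple(todo[:take])
            todo = todo[take:]
            pool = available
        else:  # everything covered: add a redundant producer; feeding it
            # from sources only keeps the wiring acyclic regardless of
            # where its product sits in the dependency order
            products = (rng.choice(produced),)
            pool = list(sources)

        n_inputs = rng.randint(1, min(config.max_indegree, len(pool)))
        inputs = rng.sample(pool, n_inputs)
        if want_cycle and cycle_candidate is None and k > 0:
            # steer this reaction to consume a non-source so a cycle closes
            d = rng.choice(produced)
            if d not in inputs:
                inputs[0] = d
            fresh = [p for p in products if p != d]
            if fresh:
                cycle_candidate = (d, fresh[0])
        inputs = tuple(inputs)

        reactions.append(Reaction(f"R{k + 1}", inputs, pick_enzymes(), products))
        for c in products:
            if c not in available:
                available.append(c)
                produced.append(c)

    if want_cycle:
        if cycle_candidate is None:  # guaranteed by the k==0 pinning
            raise AssertionError("cycle candidate must exist")
        d, c = cycle_candidate
        # closer: consumes c (strictly downstream of d), re-produces d,
        # forming the cycle d -> consumer -> c -> closer -> d
        reactions.append(Reaction(f"R{n}", (c,), pick_enzymes(), (d,)))

    return MetabolicNetwork(compounds, tuple(reactions), enzymes)
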