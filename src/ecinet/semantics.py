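"""Ground-truth producibility semantics and the exhaustive-search solver.

Producibility is the *least* fixed point of the AND/OR system: a compound
is producible only if it has a finite derivation from the source compounds
through active reactions.  The fixed-point conditions alone ("a compound is
1 iff some producing reaction is 1; a reaction is 1 iff all its inputs and
enzymes are 1") admit spurious solutions on cycles — a self-sustaining
cycle could label itself all-1 with no external feed.  The least fixed
point excludes these, which is the semantics the damage model needs: a
metabolite locked in a cycle with no path from seed compounds is not
actually being produced.

``brute_force_eci`` enumerates enzyme subsets and is deliberately
exponential: it is the small-instance oracle against which the ILP
formulation is cross-validated.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

from .errors import CapacityError
from .network import ECIInstance, MetabolicNetwork

__all__ = [
    "BooleanAssignment",
    "ECISolution",
    "propagate",
    "damage",
    "stops_targets",
    "brute_force_eci",
]

#: refuse exhaustive enumeration beyond this many enzyme subsets
DEFAULT_ENUMERATION_CAP = 2**20


@dataclass(frozen=True)
class BooleanAssignment:
    """A 0/1 labeling of every node (compound, reaction, enzyme).

    Instances returned by :func:`propagate` are the least fixed point under
    the given inhibition set: sources are 1, non-inhibited enzymes are 1,
    and every other 1 has a finite derivation from the sources.
    """

    value: dict[str, int]

    def __getitem__(self, node: str) -> int:
        return self.value[node]

    def ones(self) -> frozenset[str]:
        return frozenset(k for k, v in self.value.items() if v == 1)

    def zeros(self) -> frozenset[str]:
        return frozenset(k for k, v in self.value.items() if v == 0)


@dataclass(frozen=True)
class ECISolution:
    """Result of an enzyme-combination search.

    ``damage`` counts knocked-out *non-target compounds* only; reactions
    and enzymes never contribute.  ``assignment`` is the least fixed point
    under ``inhibited``; when ``status == "optimal"`` every target carries
    value 0 in it.
    """

    inhibited: frozenset[str]
    damage: int
    knocked_out: frozenset[str]
    assignment: BooleanAssignment | None
    status: str  # "optimal" | "infeasible"
    backend: str = "brute-force"
    extra: dict = field(default_factory=dict, compare=False)


def propagate(
    network: MetabolicNetwork, inhibited: frozenset[str] | set[str]
) -> BooleanAssignment:
    """Least fixed point of the AND/OR system under an inhibition set.

    Worklist algorithm: start from the sources and the non-inhibited
    enzymes, fire a reaction once its remaining-requirement counter drops
    to zero, mark its products producible, repeat.  Each node is visited a
    bounded number of times, so the run time is linear in network size; the
    result is independent of iteration order (the least fixed point is
    unique).

    Raises ``ValueError`` if ``inhibited`` names an undeclared enzyme.
    """
    inhibited = frozenset(inhibited)
    unknown = inhibited - network.enzyme_set
    if unknown:
        raise ValueError(f"unknown enzyme id(s) in inhibited set: {sorted(unknown)}")

    value = {c: 0 for c in network.compounds}
    value.update({r.id: 0 for r in network.reactions})
    value.update({e: (0 if e in inhibited else 1) for e in network.enzymes})

    # reactions indexed by each requirement; counters of unmet requirements
    waiting: dict[str, list[int]] = {}
    remaining: list[int] = []
    for i, r in enumerate(network.reactions):
        reqs = set(r.requirements())
        unmet = {x for x in reqs if not value.get(x, 0)}
        remaining.append(len(unmet))
        for x in reqs:
            waiting.setdefault(x, []).append(i)

    queue: deque[str] = deque()

    def fire(i: int) -> None:
        r = network.reactions[i]
        value[r.id] = 1
        for c in r.products:
            if value[c] == 0:
                value[c] = 1
                queue.append(c)

    for i, k in enumerate(remaining):
        if k == 0:  # no compound inputs, no inhibited enzyme: constant-1
            fire(i)
    for c in network.sources():
        if value[c] == 0:
            value[c] = 1
            queue.append(c)

    while queue:
        node = queue.popleft()  # node just became 1; exactly once per node
        for i in waiting.get(node, ()):
            remaining[i] -= 1
            if remaining[i] == 0 and value[network.reactions[i].id] == 0:
                fire(i)

    return BooleanAssignment(value)


def damage(
    network: MetabolicNetwork,
    inhibited: frozenset[str] | set[str],
    targets: frozenset[str] | set[str],
) -> tuple[int, frozenset[str]]:
    """Damage of an inhibition set: knocked-out non-target compounds.

    Returns ``(count, knocked_out)`` where ``knocked_out`` is the set of
    non-target compounds carrying value 0 in the least fixed point.  Does
    not require the targets to actually be stopped.
    """
    assignment = propagate(network, inhibited)
    knocked = frozenset(
        c for c in network.compounds if assignment[c] == 0 and c not in targets
    )
    return len(knocked), knocked


def stops_targets(
    network: MetabolicNetwork,
    inhibited: frozenset[str] | set[str],
    targets: frozenset[str] | set[str],
) -> bool:
    """True iff every target compound has value 0 under the inhibition."""
    assignment = propagate(network, inhibited)
    return all(assignment[t] == 0 for t in targets)


def brute_force_eci(
    instance: ECIInstance,
    max_set_size: int | None = None,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> ECISolution:
    """Exact minimum-damage search by exhaustive subset enumeration.

    Enumerates enzyme subsets in increasing cardinality, lexicographic id
    order within a cardinality; among subsets stopping all targets, returns
    the first one attaining the minimum damage — which fixes the
    deterministic tie-break (fewest enzymes, then lexicographically
    smallest).  When ``max_set_size`` is given only subsets up to that size
    are searched (and optimality is relative to that bound); otherwise a
    guard refuses instances with more than ``enumeration_cap`` subsets.
    """
    network = instance.network
    enzymes = sorted(network.enzymes)
    if max_set_size is None:
        if 2 ** len(enzymes) > enumeration_cap:
            raise CapacityError(
                f"2^{len(enzymes)} enzyme subsets exceed the cap of "
                f"{enumeration_cap}; pass max_set_size to bound the search"
            )
        max_size = len(enzymes)
    else:
        max_size = min(max_set_size, len(enzymes))

    best: ECISolution | None = None
    for k in range(max_size + 1):
        for combo in itertools.combinations(enzymes, k):
            inhibited = frozenset(combo)
            if not stops_targets(network, inhibited, instance.targets):
                continue
            count, knocked = damage(network, inhibited, instance.targets)
            if best is None or count < best.damage:
                best = ECISolution(
                    inhibited=inhibited,
                    damage=count,
                    knocked_out=knocked,
                    assignment=propagate(network, inhibited),
                    status="optimal",
                )
    if best is None:
        return ECISolution(
            inhibited=frozenset(),
            damage=0,
            knocked_out=frozenset(),
            assignment=None,
            status="infeasible",
        )
    return best
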