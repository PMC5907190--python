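"""Minimum edge cover (MEC) and its reduction to enzyme identification.

Minimum-damage enzyme combination identification is NP-complete, shown by
reduction from MEC: given an undirected graph, build a network with one
compound per edge and one AND-reaction per vertex whose inputs are that
vertex's incident edge-compounds, all feeding a single target compound
c_t.  Stopping c_t forces every vertex-reaction off, i.e. at least one
incident edge-compound of every vertex must be knocked out — exactly an
edge cover — and the minimum damage equals the minimum cover size.

The proof reasons about removing compounds directly (its enzyme set is
empty).  To run the reduced instance through the ordinary enzyme-centric
solver, each edge-compound c_i is given a private production channel: one
universal source compound s and a virtual reaction r̂_i (input s,
catalyzed by virtual enzyme ê_i, product c_i).  Inhibiting ê_i is then
precisely "remove c_i", and the knocked-out set of any solution consists
of edge-compounds only, so damage equals cover size literally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import CapacityError, NetworkParseError, ReductionError
from .network import ECIInstance, MetabolicNetwork, Reaction
from .semantics import DEFAULT_ENUMERATION_CAP

__all__ = [
    "MECEdge",
    "MECInstance",
    "parse_edge_list",
    "reduce_mec_to_eci",
    "brute_force_mec",
    "edge_compound",
    "virtual_enzyme",
    "TARGET_COMPOUND",
    "SOURCE_COMPOUND",
]

TARGET_COMPOUND = "c_t"
SOURCE_COMPOUND = "s"


@dataclass(frozen=True)
class MECEdge:
    """An undirected edge; endpoints are unordered and distinct."""

    id: str
    u: str
    v: str

    def endpoints(self) -> frozenset[str]:
        return frozenset({self.u, self.v})


@dataclass(frozen=True)
class MECInstance:
    """An undirected graph for the edge-cover problem (no self-loops)."""

    vertices: tuple[str, ...]
    edges: tuple[MECEdge, ...]

    def __post_init__(self):
        vset = set(self.vertices)
        for e in self.edges:
            if e.u == e.v:
                raise ReductionError(f"self-loop on edge {e.id!r}")
            if e.u not in vset or e.v not in vset:
                raise ReductionError(f"edge {e.id!r} references undeclared vertex")

    def isolated_vertices(self) -> frozenset[str]:
        covered = {x for e in self.edges for x in (e.u, e.v)}
        return frozenset(v for v in self.vertices if v not in covered)

    def incident(self, vertex: str) -> tuple[MECEdge, ...]:
        return tuple(e for e in self.edges if vertex in (e.u, e.v))


def parse_edge_list(document: str) -> MECInstance:
    """Parse the ``edge <id> <u> <v>`` TSV dialect (# comments allowed).

    Vertices are implied by edge endpoints; an explicit ``vertex <id>``
    record may declare an isolated vertex (for which no cover exists).
    """
    vertices: list[str] = []
    edges: list[MECEdge] = []
    seen: set[str] = set()

    def add_vertex(v: str) -> None:
        if v not in seen:
            seen.add(v)
            vertices.append(v)

    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if fields[0] == "edge" and len(fields) == 4:
            _, eid, u, v = fields
            add_vertex(u)
            add_vertex(v)
            edges.append(MECEdge(eid, u, v))
        elif fields[0] == "vertex" and len(fields) == 2:
            add_vertex(fields[1])
        else:
            raise NetworkParseError(
                "expected 'edge <id> <u> <v>' or 'vertex <id>'", lineno
            )
    return MECInstance(tuple(vertices), tuple(edges))


def edge_compound(edge_id: str) -> str:
    return f"c_{edge_id}"


def virtual_enzyme(edge_id: str) -> str:
    return f"e_{edge_id}"


def reduce_mec_to_eci(graph: MECInstance) -> ECIInstance:
    """Build the enzyme-identification instance equivalent to a MEC.

    Linear in |V|+|E|: one edge-compound per edge, one vertex-reaction per
    vertex (indegree = vertex degree), plus the per-edge virtual
    source/enzyme channel.  The optimal damage of the result equals the
    minimum edge cover size; raises on isolated vertices (no cover
    exists).
    """
    isolated = graph.isolated_vertices()
    if isolated:
        raise ReductionError(
            f"no edge cover exists: isolated vertices {sorted(isolated)}"
        )
    if not graph.edges:
        raise ReductionError("graph has no edges")

    compounds = tuple(edge_compound(e.id) for e in graph.edges) + (
        TARGET_COMPOUND,
        SOURCE_COMPOUND,
    )
    enzymes = tuple(virtual_enzyme(e.id) for e in graph.edges)
    vertex_reactions = tuple(
        Reaction(
            id=f"r_{v}",
            inputs=tuple(edge_compound(e.id) for e in graph.incident(v)),
            enzymes=(),
            products=(TARGET_COMPOUND,),
        )
        for v in graph.vertices
    )
    virtual_reactions = tuple(
        Reaction(
            id=f"rhat_{e.id}",
            inputs=(SOURCE_COMPOUND,),
            enzymes=(virtual_enzyme(e.id),),
            products=(edge_compound(e.id),),
        )
        for e in graph.edges
    )
    network = MetabolicNetwork(
        compounds=compounds,
        reactions=vertex_reactions + virtual_reactions,
        enzymes=enzymes,
    )
    return ECIInstance(network, frozenset({TARGET_COMPOUND}))


def brute_force_mec(
    graph: MECInstance, enumeration_cap: int = DEFAULT_ENUMERATION_CAP
) -> tuple[int, frozenset[str]]:
    """Exact minimum edge cover by subset enumeration.

    Subsets are scanned in increasing cardinality, lexicographic edge-id
    order within a cardinality, and the first cover found is returned —
    fixing the deterministic tie-break.  Raises on isolated vertices (no
    cover) and when 2^|E| exceeds the cap.
    """
    isolated = graph.isolated_vertices()
    if isolated:
        raise ReductionError(
            f"no edge cover exists: isolated vertices {sorted(isolated)}"
        )
    if 2 ** len(graph.edges) > enumeration_cap:
        raise CapacityError(
            f"2^{len(graph.edges)} edge subsets exceed the cap of {enumeration_cap}"
        )
    by_id = {e.id: e for e in graph.edges}
    ids = sorted(by_id)
    vset = set(graph.vertices)
    for k in range(len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            covered = {x for eid in combo for x in (by_id[eid].u, by_id[eid].v)}
            if covered == vset:
                return k, frozenset(combo)
    raise AssertionError("unreachable: the full edge set is a cover")
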