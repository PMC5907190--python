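"""Boolean metabolic network model, validation, and file I/O.

A metabolic network is a directed AND/OR graph over three disjoint node
classes: compounds (OR nodes — producible iff at least one producing
reaction is active), reactions (AND nodes — active iff every input compound
and every catalyzing enzyme is active), and enzymes (free 0/1 decisions:
inhibited or not).  Enzymes are stored as reaction *requirements* alongside
input compounds, which is the semantics the AND constraints impose.

Source compounds are derived, not declared: a compound is a source exactly
when no reaction produces it.  Sources are the seed metabolites and are
always producible.

Two interchangeable file dialects are supported: a line-oriented TSV-style
format (``compound``/``enzyme``/``reaction`` records, ``#`` comments) and a
JSON document with top-level ``compounds``, ``enzymes``, ``reactions`` keys.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .errors import NetworkParseError, NetworkValidationError

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "ECIInstance",
    "parse_network",
    "write_network",
    "identify_sources",
    "validate",
]


@dataclass(frozen=True)
class Reaction:
    """A reaction: AND over its input compounds and catalyzing enzymes.

    ``enzymes`` may be empty (a spontaneous / uncatalyzed step); such a
    reaction can never be switched off by enzyme inhibition directly.
    ``products`` is non-empty: a productless reaction has no effect in a
    producibility model.
    """

    id: str
    inputs: tuple[str, ...]
    enzymes: tuple[str, ...]
    products: tuple[str, ...]

    def requirements(self) -> tuple[str, ...]:
        """All AND-inputs of this reaction: input compounds then enzymes."""
        return self.inputs + self.enzymes


@dataclass(frozen=True)
class MetabolicNetwork:
    """An ordered, validated-on-demand Boolean metabolic network.

    Declaration order of compounds (m of them), reactions (n) and enzymes
    (l) is preserved so serialization and model construction are
    deterministic.
    """

    compounds: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    enzymes: tuple[str, ...]

    # --- derived views -------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.compounds)

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def l(self) -> int:
        return len(self.enzymes)

    @property
    def compound_set(self) -> frozenset[str]:
        return frozenset(self.compounds)

    @property
    def enzyme_set(self) -> frozenset[str]:
        return frozenset(self.enzymes)

    def producers(self) -> dict[str, list[Reaction]]:
        """Map each compound to the reactions producing it (order kept)."""
        prod: dict[str, list[Reaction]] = {c: [] for c in self.compounds}
        for r in self.reactions:
            for c in r.products:
                if c in prod:
                    prod[c].append(r)
        return prod

    def sources(self) -> frozenset[str]:
        return identify_sources(self)


def identify_sources(network: MetabolicNetwork) -> frozenset[str]:
    """Compounds produced by no reaction — the seed metabolites.

    Their producibility is axiomatic: they carry value 1 in every valid
    assignment.
    """
    produced = {c for r in network.reactions for c in r.products}
    return frozenset(c for c in network.compounds if c not in produced)


def validate(network: MetabolicNetwork) -> list[str]:
    """Check the structural invariants; violations are data, not exceptions.

    Returns a list of human-readable violation descriptions, empty iff the
    network is valid.  Checked: identifier-class disjointness, duplicate
    declarations, non-empty product sets, and that every id referenced in a
    reaction is declared.  "Every non-source compound has a producing
    reaction" holds by construction because sources are derived.
    """
    violations: list[str] = []

    def dupes(ids):
        seen, d = set(), []
        for x in ids:
            if x in seen:
                d.append(x)
            seen.add(x)
        return d

    for kind, ids in (
        ("compound", network.compounds),
        ("enzyme", network.enzymes),
        ("reaction", [r.id for r in network.reactions]),
    ):
        for x in dupes(ids):
            violations.append(f"duplicate {kind} id {x!r}")

    cset = set(network.compounds)
    eset = set(network.enzymes)
    rset = {r.id for r in network.reactions}
    for x in sorted(cset & eset):
        violations.append(f"id {x!r} declared as both compound and enzyme")
    for x in sorted(cset & rset):
        violations.append(f"id {x!r} declared as both compound and reaction")
    for x in sorted(eset & rset):
        violations.append(f"id {x!r} declared as both enzyme and reaction")

    for r in network.reactions:
        if not r.products:
            violations.append(f"reaction {r.id!r} has no products")
        for c in r.inputs:
            if c not in cset:
                violations.append(
                    f"reaction {r.id!r} input {c!r} is not a declared compound"
                )
        for c in r.products:
            if c not in cset:
                violations.append(
                    f"reaction {r.id!r} product {c!r} is not a declared compound"
                )
        for e in r.enzymes:
            if e not in eset:
                violations.append(
                    f"reaction {r.id!r} enzyme {e!r} is not a declared enzyme"
                )
    return violations


@dataclass(frozen=True)
class ECIInstance:
    """A network plus the non-empty set of target compounds to stop.

    Targets must be declared, non-source compounds: a source compound is
    producible by definition and no enzyme set can ever stop it, so a
    source target is rejected here rather than surfacing later as solver
    infeasibility.
    """

    network: MetabolicNetwork
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.targets:
            raise NetworkValidationError(["target set is empty"])
        problems = []
        cset = self.network.compound_set
        srcs = self.network.sources()
        for t in sorted(self.targets):
            if t not in cset:
                problems.append(f"target {t!r} is not a declared compound")
            elif t in srcs:
                problems.append(
                    f"target {t!r} is a source compound and can never be stopped"
                )
        if problems:
            raise NetworkValidationError(problems)

    @property
    def non_targets(self) -> tuple[str, ...]:
        return tuple(c for c in self.network.compounds if c not in self.targets)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_REACTION_RE = re.compile(
    r"^reaction\s+(?P<id>\S+)\s+inputs=(?P<inputs>\S*)\s+"
    r"enzymes=(?P<enzymes>\S*)\s+products=(?P<products>\S+)$"
)


def _split_ids(csv: str) -> tuple[str, ...]:
    return tuple(x for x in csv.split(",") if x)


def parse_network(document: str) -> MetabolicNetwork:
    """Parse a network document (TSV or JSON dialect) and validate it.

    The dialect is auto-detected: a document whose first non-blank
    character is ``{`` is parsed as JSON.  Raises
    :class:`~ecinet.errors.NetworkParseError` on malformed input (naming
    the offending line for the TSV dialect) and
    :class:`~ecinet.errors.NetworkValidationError` when the parsed
    structure breaks an invariant.
    """
    stripped = document.lstrip()
    if stripped.startswith("{"):
        net = _parse_json(document)
    else:
        net = _parse_tsv(document)
    violations = validate(net)
    if violations:
        raise NetworkValidationError(violations)
    return net


def _parse_tsv(document: str) -> MetabolicNetwork:
    compounds: list[str] = []
    enzymes: list[str] = []
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split(None, 1)
        kind = fields[0]
        rest = fields[1] if len(fields) > 1 else ""
        if kind == "compound":
            if not rest or len(rest.split()) != 1:
                raise NetworkParseError("expected 'compound <id>'", lineno)
            compounds.append(rest)
        elif kind == "enzyme":
            if not rest or len(rest.split()) != 1:
                raise NetworkParseError("expected 'enzyme <id>'", lineno)
            enzymes.append(rest)
        elif kind == "reaction":
            m = _REACTION_RE.match(line)
            if not m:
                raise NetworkParseError(
                    "expected 'reaction <id> inputs=... enzymes=... products=...'",
                    lineno,
                )
            reactions.append(
                Reaction(
                    id=m.group("id"),
                    inputs=_split_ids(m.group("inputs")),
                    enzymes=_split_ids(m.group("enzymes")),
                    products=_split_ids(m.group("products")),
                )
            )
        else:
            raise NetworkParseError(f"unknown record type {kind!r}", lineno)
    return MetabolicNetwork(tuple(compounds), tuple(reactions), tuple(enzymes))


def _parse_json(document: str) -> MetabolicNetwork:
    try:
        data = json.loads(document)
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise NetworkParseError("JSON document must be an object")
    try:
        compounds = tuple(str(c) for c in data.get("compounds", []))
        enzymes = tuple(str(e) for e in data.get("enzymes", []))
        reactions = tuple(
            Reaction(
                id=str(r["id"]),
                inputs=tuple(str(x) for x in r.get("inputs", [])),
                enzymes=tuple(str(x) for x in r.get("enzymes", [])),
                products=tuple(str(x) for x in r["products"]),
            )
            for r in data.get("reactions", [])
        )
    except (KeyError, TypeError) as exc:
        raise NetworkParseError(f"malformed reaction record: {exc}") from exc
    return MetabolicNetwork(compounds, reactions, enzymes)


def write_network(network: MetabolicNetwork) -> str:
    """Serialize to the canonical TSV dialect.

    ``parse_network(write_network(x)) == x`` for every valid network, and a
    second serialization is byte-identical (the format is canonical:
    declaration order, single spaces, no comments).
    """
    lines = [f"compound {c}" for c in network.compounds]
    lines += [f"enzyme {e}" for e in network.enzymes]
    lines += [
        "reaction {} inputs={} enzymes={} products={}".format(
            r.id, ",".join(r.inputs), ",".join(r.enzymes), ",".join(r.products)
        )
        for r in network.reactions
    ]
    return "\n".join(lines) + "\n"


def write_network_json(network: MetabolicNetwork) -> str:
    """Serialize to the JSON dialect (same schema as accepted on input)."""
    return json.dumps(
        {
            "compounds": list(network.compounds),
            "enzymes": list(network.enzymes),
            "reactions": [
                {
                    "id": r.id,
                    "inputs": list(r.inputs),
                    "enzymes": list(r.enzymes),
                    "products": list(r.products),
                }
                for r in network.reactions
            ],
        },
        indent=1,
    )
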