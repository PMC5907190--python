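"""ILP encoding of minimum-damage enzyme combination identification.

Every node x gets a complementary pair of binaries T(x), F(x) with
T(x)+F(x)=1 (T = active/producible, F = inactive).  Boolean gates become
linear rows through the standard CNF translation: each disjunction
``a ∨ b ∨ ...`` over literals is one row ``sum of the matching T/F
variables ≥ 1``.  A reaction (AND over inputs and enzymes) contributes
``T(r) + Σ F(req) ≥ 1`` plus one row ``F(r) + T(req) ≥ 1`` per
requirement; a compound (OR over its producing reactions) contributes
``F(c) + Σ T(prod) ≥ 1`` plus ``T(c) + F(prod) ≥ 1`` per producer.  A
single-input gate collapses to the copy equality T(out) = T(in).  Sources
are pinned T=1, targets F=1, and the objective minimizes the number of
non-producible non-target compounds (the damage).

The base model has exactly 2(m+n+l) binaries — linear in network size.

Cyclic networks need one extension: the consistency rows above admit any
fixed point, so a damage-minimizing optimum may declare a self-sustaining
cycle producible even though nothing feeds it from the sources.  The
default ``acyclic_encoding="levels"`` adds an ordering variable L(x) per
compound/reaction and per-producer support indicators: an active compound
must select an active producing reaction strictly below it in the order,
and an active reaction must sit strictly above all its inputs, with
sources at level 0.  Circular support then has no consistent ordering and
is excluded, so ILP optima coincide with least-fixed-point propagation.
``acyclic_encoding="none"`` keeps the literal consistency-only system;
:func:`solve_eci` then verifies the optimum by propagation and retries
with levels if a cycle artefact is detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import SolverError
from .network import ECIInstance
from .semantics import BooleanAssignment, ECISolution, propagate

__all__ = [
    "LinearRow",
    "ILPModel",
    "clause_and",
    "clause_or",
    "build_ilp",
    "solve_eci",
    "verify_solution",
]

SUPPORTED_BACKENDS = ("highs",)


@dataclass(frozen=True)
class LinearRow:
    """One linear constraint: lb ≤ Σ coeffs[v]·v ≤ ub."""

    coeffs: dict[str, float]
    lb: float
    ub: float
    name: str = ""

    @classmethod
    def ge(cls, coeffs: dict[str, float], rhs: float, name: str = "") -> "LinearRow":
        return cls(coeffs, rhs, np.inf, name)

    @classmethod
    def eq(cls, coeffs: dict[str, float], rhs: float, name: str = "") -> "LinearRow":
        return cls(coeffs, rhs, rhs, name)


def _T(node: str) -> str:
    return f"T_{node}"


def _F(node: str) -> str:
    return f"F_{node}"


def clause_and(output: str, inputs: list[str]) -> list[LinearRow]:
    """Rows encoding ``output = AND(inputs)`` over T/F binaries.

    For a single input this is the copy equality T(out) = T(in); otherwise
    one activation row T(out)+ΣF(in)≥1 and one deactivation row
    F(out)+T(in)≥1 per input.
    """
    if not inputs:
        raise ValueError("clause_and requires at least one input")
    if len(inputs) == 1:
        return [
            LinearRow.eq({_T(output): 1, _T(inputs[0]): -1}, 0, f"copy_{output}")
        ]
    rows = [
        LinearRow.ge(
            {_T(output): 1, **{_F(x): 1 for x in inputs}}, 1, f"and_up_{output}"
        )
    ]
    rows += [
        LinearRow.ge({_F(output): 1, _T(x): 1}, 1, f"and_dn_{output}_{x}")
        for x in inputs
    ]
    return rows


def clause_or(output: str, inputs: list[str]) -> list[LinearRow]:
    """Rows encoding ``output = OR(inputs)``; dual of :func:`clause_and`."""
    if not inputs:
        raise ValueError("clause_or requires at least one input")
    if len(inputs) == 1:
        return [
            LinearRow.eq({_T(output): 1, _T(inputs[0]): -1}, 0, f"copy_{output}")
        ]
    rows = [
        LinearRow.ge(
            {_F(output): 1, **{_T(x): 1 for x in inputs}}, 1, f"or_dn_{output}"
        )
    ]
    rows += [
        LinearRow.ge({_T(output): 1, _F(x): 1}, 1, f"or_up_{output}_{x}")
        for x in inputs
    ]
    return rows


@dataclass
class ILPModel:
    """A constructed model: ordered variables, rows, minimization objective.

    ``variables`` maps name -> (lb, ub, is_integer); insertion order fixes
    the column order handed to the solver, which keeps repeated solves
    deterministic.  ``base_binary_count`` counts only the T/F pairs —
    2(m+n+l) — excluding the optional level/support machinery.
    """

    variables: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    rows: list[LinearRow] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    base_binary_count: int = 0
    acyclic_encoding: str = "levels"

    def add_binary(self, name: str) -> None:
        self.variables[name] = (0.0, 1.0, True)

    def add_continuous(self, name: str, lb: float, ub: float) -> None:
        self.variables[name] = (lb, ub, False)

    @property
    def num_variables(self) -> int:
        return len(self.variables)

    @property
    def num_rows(self) -> int:
        return len(self.rows)

    def to_lp_string(self) -> str:
        """Export in CPLEX LP text format (debugging aid)."""
        out = ["Minimize", " obj: " + _lp_expr(self.objective), "Subject To"]
        for i, row in enumerate(self.rows):
            expr = _lp_expr(row.coeffs)
            label = row.name or f"c{i}"
            if row.lb == row.ub:
                out.append(f" {label}: {expr} = {row.lb:g}")
            elif np.isinf(row.ub):
                out.append(f" {label}: {expr} >= {row.lb:g}")
            else:
                out.append(f" {label}: {expr} <= {row.ub:g}")
        out.append("Bounds")
        for name, (lb, ub, _) in self.variables.items():
            out.append(f" {lb:g} <= {name} <= {ub:g}")
        out.append("Binaries")
        binaries = [n for n, (lb, ub, isint) in self.variables.items()
                    if isint and (lb, ub) == (0.0, 1.0)]
        for i in range(0, len(binaries), 8):
            out.append(" " + " ".join(binaries[i : i + 8]))
        out.append("End")
        return "\n".join(out) + "\n"


def _lp_expr(coeffs: dict[str, float]) -> str:
    parts = []
    for name, c in coeffs.items():
        sign = "-" if c < 0 else "+"
        mag = abs(c)
        term = name if mag == 1 else f"{mag:g} {name}"
        parts.append(f"{sign} {term}")
    s = " ".join(parts)
    return s[2:] if s.startswith("+ ") else s


def build_ilp(instance: ECIInstance, acyclic_encoding: str = "levels") -> ILPModel:
    """Construct the damage-minimization model for an ECI instance.

    Rows, in order: per-target F=1; per-reaction AND gate; per-non-source
    compound OR gate over its producers; per-source T=1; per-node
    complement T+F=1; then (levels only) the acyclic-support rows.
    """
    if acyclic_encoding not in ("levels", "none"):
        raise ValueError(f"unknown acyclic_encoding {acyclic_encoding!r}")
    net = instance.network
    model = ILPModel(acyclic_encoding=acyclic_encoding)

    nodes = list(net.compounds) + [r.id for r in net.reactions] + list(net.enzymes)
    for x in nodes:
        model.add_binary(_T(x))
        model.add_binary(_F(x))
    model.base_binary_count = 2 * len(nodes)

    for t in sorted(instance.targets):
        model.rows.append(LinearRow.eq({_F(t): 1}, 1, f"target_{t}"))

    for r in net.reactions:
        reqs = list(r.requirements())
        if reqs:
            model.rows.extend(clause_and(r.id, reqs))
        else:  # no inputs, no enzymes: constant-active
            model.rows.append(LinearRow.eq({_T(r.id): 1}, 1, f"const_{r.id}"))

    producers = net.producers()
    sources = net.sources()
    for c in net.compounds:
        if c in sources:
            continue
        model.rows.extend(clause_or(c, [r.id for r in producers[c]]))
    for c in net.compounds:
        if c in sources:
            model.rows.append(LinearRow.eq({_T(c): 1}, 1, f"source_{c}"))

    for x in nodes:
        model.rows.append(LinearRow.eq({_T(x): 1, _F(x): 1}, 1, f"compl_{x}"))

    model.objective = {_F(c): 1.0 for c in instance.non_targets}

    if acyclic_encoding == "levels":
        _add_level_rows(model, instance)
    return model


def _add_level_rows(model: ILPModel, instance: ECIInstance) -> None:
    """Acyclic-support extension: big-M ordering of active nodes.

    L(x) ∈ [0, m+n] per compound/reaction (sources pinned at 0); one
    binary support indicator per (compound, producing reaction) edge.  An
    active compound selects an active producer one level below it; an
    active reaction lies strictly above every input.  M = m+n+1 makes the
    rows vacuous for inactive nodes.
    """
    net = instance.network
    horizon = net.m + net.n
    big_m = horizon + 1
    sources = net.sources()

    for c in net.compounds:
        model.add_continuous(f"L_{c}", 0.0, 0.0 if c in sources else float(horizon))
    for r in net.reactions:
        model.add_continuous(f"L_{r.id}", 0.0, float(horizon))

    producers = net.producers()
    for c in net.compounds:
        if c in sources:
            continue
        prods = producers[c]
        sup = {}
        for r in prods:
            y = f"y_{c}_{r.id}"
            model.add_binary(y)
            sup[r.id] = y
            # support only through an active reaction
            model.rows.append(
                LinearRow.ge({_T(r.id): 1, y: -1}, 0, f"sup_act_{c}_{r.id}")
            )
            # L(c) >= L(r) + 1 - M(1 - y)
            model.rows.append(
                LinearRow.ge(
                    {f"L_{c}": 1, f"L_{r.id}": -1, y: -big_m},
                    1 - big_m,
                    f"sup_ord_{c}_{r.id}",
                )
            )
        # an active compound must select at least one supporter
        model.rows.append(
            LinearRow.ge(
                {**{y: 1 for y in sup.values()}, _T(c): -1}, 0, f"sup_sel_{c}"
            )
        )
    for r in net.reactions:
        for u in set(r.inputs):
            # L(r) >= L(u) + 1 - M(1 - T(r))
            model.rows.append(
                LinearRow.ge(
                    {f"L_{r.id}": 1, f"L_{u}": -1, _T(r.id): -big_m},
                    1 - big_m,
                    f"ord_{r.id}_{u}",
                )
            )


def _solve_model(model: ILPModel, time_limit: float | None) -> tuple[str, dict | None]:
    """Run HiGHS on the model; returns (status, values-by-name or None)."""
    names = list(model.variables)
    index = {name: i for i, name in enumerate(names)}
    lb = np.array([model.variables[n][0] for n in names])
    ub = np.array([model.variables[n][1] for n in names])
    integrality = np.array(
        [1 if model.variables[n][2] else 0 for n in names], dtype=int
    )
    c = np.zeros(len(names))
    for name, coef in model.objective.items():
        c[index[name]] = coef

    data, rows_idx, cols_idx, lo, hi = [], [], [], [], []
    for i, row in enumerate(model.rows):
        for name, coef in row.coeffs.items():
            rows_idx.append(i)
            cols_idx.append(index[name])
            data.append(coef)
        lo.append(row.lb)
        hi.append(row.ub)
    a_mat = sp.csr_array(
        (data, (rows_idx, cols_idx)), shape=(len(model.rows), len(names))
    )

    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=c,
        constraints=LinearConstraint(a_mat, np.array(lo), np.array(hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    if res.status == 2:
        return "infeasible", None
    if res.status == 1:
        raise SolverError(
            "MILP time limit reached"
            + ("" if res.x is None else " (incumbent available)")
        )
    if not res.success:
        raise SolverError(f"MILP solve failed: {res.message}")
    values = {name: float(res.x[i]) for i, name in enumerate(names)}
    return "optimal", values


def _extract_solution(
    instance: ECIInstance, values: dict[str, float], backend: str
) -> ECISolution:
    net = instance.network
    inhibited = frozenset(e for e in net.enzymes if values[_T(e)] < 0.5)
    knocked = frozenset(
        c
        for c in instance.non_targets
        if values[_T(c)] < 0.5
    )
    assignment = BooleanAssignment(
        {
            x: (1 if values[_T(x)] > 0.5 else 0)
            for x in list(net.compounds)
            + [r.id for r in net.reactions]
            + list(net.enzymes)
        }
    )
    return ECISolution(
        inhibited=inhibited,
        damage=len(knocked),
        knocked_out=knocked,
        assignment=assignment,
        status="optimal",
        backend=backend,
    )


def solve_eci(
    instance: ECIInstance,
    backend: str = "highs",
    acyclic_encoding: str = "levels",
    time_limit: float | None = None,
) -> ECISolution:
    """Solve minimum-damage enzyme combination identification exactly.

    Builds the ILP, solves it, and re-verifies the reported optimum by
    least-fixed-point propagation before returning it.  Under
    ``acyclic_encoding="none"`` a verification failure (a cycle counted as
    producible by the consistency-only system) triggers one retry with the
    levels encoding; under ``"levels"`` verification failure would indicate
    a bug and raises.
    """
    if backend not in SUPPORTED_BACKENDS:
        raise SolverError(
            f"backend {backend!r} not available; supported: {SUPPORTED_BACKENDS}"
        )
    model = build_ilp(instance, acyclic_encoding=acyclic_encoding)
    status, values = _solve_model(model, time_limit)
    if status == "infeasible":
        return ECISolution(
            inhibited=frozenset(),
            damage=0,
            knocked_out=frozenset(),
            assignment=None,
            status="infeasible",
            backend=backend,
        )
    solution = _extract_solution(instance, values, backend)
    if verify_solution(instance, solution):
        return solution
    if acyclic_encoding == "none":
        return solve_eci(
            instance,
            backend=backend,
            acyclic_encoding="levels",
            time_limit=time_limit,
        )
    raise SolverError(
        "levels-encoded optimum failed propagation verification (internal error)"
    )


def verify_solution(instance: ECIInstance, solution: ECISolution) -> bool:
    """Check a claimed solution against ground-truth propagation.

    True iff, under ``solution.inhibited``, every target is stopped, the
    knocked-out non-target set matches exactly, and the damage count is its
    cardinality.
    """
    net = instance.network
    assignment = propagate(net, solution.inhibited)
    if any(assignment[t] != 0 for t in instance.targets):
        return False
    knocked = frozenset(
        c for c in instance.non_targets if assignment[c] == 0
    )
    return knocked == solution.knocked_out and solution.damage == len(knocked)
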