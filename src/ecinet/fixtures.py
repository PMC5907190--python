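"""Hand-built example networks used throughout the test suite and docs.

``fig1_network`` is the canonical small hypothetical network: nine
compounds, three reactions, two enzymes, with a compound-reaction cycle
(C2 → R2 → C7 → R1 → C2) and a single target C5.  Inhibiting E2 stops C5
at damage 2 (C2 and C4 are lost); inhibiting E1 also stops C5 but at
damage 5 — so {E2} is the optimal enzyme set.

``cycle_network`` isolates the degenerate case that motivates the
acyclic-support encoding: a two-compound cycle (A ⇄ B through reactions
with no enzymes) that receives no feed from any source.  Under
least-fixed-point semantics A and B are never producible, yet the bare
fixed-point constraints would happily label the cycle all-active.
"""

from __future__ import annotations

from .network import ECIInstance, MetabolicNetwork, Reaction

__all__ = ["fig1_network", "fig1_instance", "cycle_network", "cycle_instance"]


def fig1_network() -> MetabolicNetwork:
    return MetabolicNetwork(
        compounds=("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9"),
        reactions=(
            Reaction("R1", inputs=("C1", "C7"), enzymes=("E2",), products=("C2",)),
            Reaction(
                "R2", inputs=("C2", "C3"), enzymes=("E1",), products=("C4", "C5", "C7")
            ),
            Reaction("R3", inputs=("C6",), enzymes=("E1",), products=("C7", "C8", "C9")),
        ),
        enzymes=("E1", "E2"),
    )


def fig1_instance() -> ECIInstance:
    """The worked example: stop C5 with minimum collateral damage."""
    return ECIInstance(fig1_network(), frozenset({"C5"}))


def cycle_network() -> MetabolicNetwork:
    """Source-fed target branch plus an unsupported two-compound cycle."""
    return MetabolicNetwork(
        compounds=("S", "X", "A", "B"),
        reactions=(
            Reaction("RT", inputs=("S",), enzymes=("E",), products=("X",)),
            Reaction("RA", inputs=("B",), enzymes=(), products=("A",)),
            Reaction("RB", inputs=("A",), enzymes=(), products=("B",)),
        ),
        enzymes=("E",),
    )


def cycle_instance() -> ECIInstance:
    return ECIInstance(cycle_network(), frozenset({"X"}))
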