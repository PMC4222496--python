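"""Shared fixtures: a hand-built mechanism star network and oracle helpers."""

from __future__ import annotations

import pytest

from rcr import AMBIGUOUS, CausalEdge, Hyp, PopulationStats, collapse_edges


@pytest.fixture
def star_hyp() -> Hyp:
    """One controller U over six measured RNAs, one via conflicting edges.

    Downstream signs: A +1, B +1, C ambiguous, D -1, E +1, F +1.
    """
    return Hyp(
        upstream="U",
        downstream={
            "r(A)": 1,
            "r(B)": 1,
            "r(C)": AMBIGUOUS,
            "r(D)": -1,
            "r(E)": 1,
            "r(F)": 1,
        },
    )


@pytest.fixture
def star_states() -> dict[str, int]:
    """States making A, D, F imply an increased controller, B a decreased
    one, C an ambiguity, and leaving E unchanged."""
    return {"r(A)": 1, "r(B)": -1, "r(C)": 1, "r(D)": -1, "r(E)": 0, "r(F)": 1}


@pytest.fixture
def star_graph(star_hyp):
    """The star network as a collapsed causal graph (ambiguity via dual edges)."""
    edges = []
    for node, sign in star_hyp.downstream.items():
        if sign == AMBIGUOUS:
            edges.append(CausalEdge("U", "increases", node))
            edges.append(CausalEdge("U", "decreases", node))
        elif sign == 1:
            edges.append(CausalEdge("U", "increases", node))
        else:
            edges.append(CausalEdge("U", "decreases", node))
    return collapse_edges(edges)


def make_pop(N: int, m: int) -> PopulationStats:
    """A population of N anonymous RNA nodes with m state changes."""
    return PopulationStats(
        population=frozenset(f"r(POP:{i})" for i in range(N)), m=m
    )
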