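"""Mechanism hypothesis (HYP) generation and population bookkeeping.

A HYP is a one-controller star network: an upstream node together with its
immediate (path length 1) signed edges to downstream measurable RNA nodes
that were actually measured in the experiment.  Only controllers with at
least ``min_possible`` (default 4) such downstream nodes are eligible.  The
*population* — the universe for the enrichment test — is the union of all
HYPs' downstream sets, and HYP generation depends only on graph topology and
the measured-node set, never on the differential states, so a single HYP set
serves both real and randomized data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .graph import AMBIGUOUS, CausalGraph, Sign

DEFAULT_MIN_POSSIBLE = 4


@dataclass(frozen=True)
class Hyp:
    """One mechanism hypothesis: an upstream controller and its signed targets."""

    upstream: str
    downstream: dict[str, Sign] = field(hash=False)

    @property
    def possible(self) -> int:
        """Number of measured downstream RNA nodes."""
        return len(self.downstream)


@dataclass(frozen=True)
class PopulationStats:
    """Shared enrichment universe: all nodes downstream of at least one HYP."""

    population: frozenset[str]
    m: int  # state changes within the population

    @property
    def N(self) -> int:
        return len(self.population)

    def __post_init__(self) -> None:
        if self.m > self.N:
            raise ValueError(f"m={self.m} exceeds population size N={self.N}")


def generate_hyps(
    graph: CausalGraph,
    measured: set[str],
    min_possible: int = DEFAULT_MIN_POSSIBLE,
) -> list[Hyp]:
    """Derive one HYP per controller with enough measured downstream RNAs.

    Downstream signs are copied from the collapsed graph edges (including
    ambiguous).  Output is sorted by upstream id for determinism.  A
    controller may itself be an RNA node; its own state never enters its HYP
    because self-edges were dropped at collapse time.
    """
    if min_possible < 1:
        raise ValueError("min_possible must be >= 1")
    targets_by_source: dict[str, dict[str, Sign]] = {}
    for (s, t), sign in graph.edges.items():
        if graph.is_measurable_rna(t) and t in measured:
            targets_by_source.setdefault(s, {})[t] = sign
    hyps = [
        Hyp(upstream=u, downstream=dict(sorted(dn.items())))
        for u, dn in targets_by_source.items()
        if len(dn) >= min_possible
    ]
    hyps.sort(key=lambda h: h.upstream)
    return hyps


def compute_population(hyps: list[Hyp], states: dict[str, int]) -> PopulationStats:
    """Compute N (union of downstream sets) and m (state changes within it)."""
    if not hyps:
        raise ValueError("population undefined: no HYPs were generated")
    union: set[str] = set()
    for h in hyps:
        union.update(h.downstream)
    m = sum(1 for node in union if states.get(node, 0) != 0)
    return PopulationStats(population=frozenset(union), m=m)


def dump_hyps_tsv(hyps: list[Hyp], path: str | Path) -> None:
    """Write an audit TSV: upstream, downstream, sign (ambiguous as '?')."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("upstream\tdownstream\tsign\n")
        for h in hyps:
            for node, sign in h.downstream.items():
                label = "?" if sign == AMBIGUOUS else f"{sign:+d}"
                fh.write(f"{h.upstream}\t{node}\t{label}\n")
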