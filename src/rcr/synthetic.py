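"""Synthetic causal graphs and expression tables with planted mechanisms.

The generator emulates the statistical structure the scoring model assumes:
a set of controllers, each wired to a random set of RNA abundance nodes by
signed (occasionally conflicting) causal edges, and an expression experiment
in which the RNAs downstream of *planted* controllers respond with a given
penetrance while unrelated RNAs change at a low background rate.  Downstream
responses are independent given the controller's direction, mirroring the
naive-Bayes-like independence assumption of the mechanism model.

Changed rows draw |fold change| uniformly in [1.5, 4], adjusted p in
[1e-6, 0.04] and abundance in [50, 1000] — comfortably inside the default
significance criteria; unchanged rows draw |fold change| in [1.0, 1.25] and
adjusted p in [0.1, 0.99], violating two criteria.  The exact magnitudes are
irrelevant to the trinary pipeline; only which side of the thresholds a row
falls on matters.

Everything is deterministic per seed: the same spec yields byte-identical
TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import AMBIGUOUS, CausalGraph

_CHANGED_FC = (1.5, 4.0)
_CHANGED_P = (1e-6, 0.04)
_CHANGED_ABUND = (50.0, 1000.0)
_UNCHANGED_FC = (1.0, 1.25)
_UNCHANGED_P = (0.1, 0.99)


def controller_name(i: int) -> str:
    return f"act(SYN:C{i})"


def rna_name(j: int) -> str:
    return f"r(SYN:G{j})"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a modest single-perturbation experiment: 20 candidate
    controllers over 500 measured RNAs, 10–30 targets each, 30% repressive
    edges, 5% conflicting-evidence edges, one strongly planted mechanism
    (penetrance 0.8) and a 2% background differential-expression rate.
    """

    n_controllers: int = 20
    n_rna: int = 500
    out_degree: tuple[int, int] = (10, 30)
    sign_mix: float = 0.3
    ambiguous_frac: float = 0.05
    planted: tuple[tuple[str, int, float], ...] = (
        (controller_name(0), 1, 0.8),
    )
    background_change_rate: float = 0.02
    duplicate_probe_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.out_degree
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid out_degree range {self.out_degree}")
        if hi > self.n_rna:
            raise ValueError(
                f"out_degree max {hi} exceeds number of RNA nodes {self.n_rna}"
            )
        for p in (
            self.sign_mix,
            self.ambiguous_frac,
            self.background_change_rate,
            self.duplicate_probe_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for ctrl, direction, pen in self.planted:
            if direction not in (-1, 1):
                raise ValueError(f"planted direction must be +/-1, got {direction}")
            if not 0.0 <= pen <= 1.0:
                raise ValueError(f"penetrance {pen} outside [0, 1]")


@dataclass
class Fixture:
    """In-memory fixture: the collapsed graph plus raw tables for the TSVs."""

    spec: FixtureSpec
    graph: CausalGraph
    edge_rows: list[tuple[str, str, str]]  # source, relation, target
    mapping_rows: list[tuple[str, str]]  # measurement_id, node_id

    def write_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("source\trelation\ttarget\n")
            for row in self.edge_rows:
                fh.write("\t".join(row) + "\n")

    def write_mapping_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("measurement_id\tnode_id\n")
            for row in self.mapping_rows:
                fh.write("\t".join(row) + "\n")


def generate_graph(spec: FixtureSpec) -> Fixture:
    """Draw the causal graph and probe mapping for a fixture spec.

    Controllers are named ``act(SYN:C{i})`` and RNAs ``r(SYN:G{j})``.  Each
    controller receives a uniform out-degree in ``spec.out_degree`` and that
    many distinct RNA targets; each edge is repressive with probability
    ``sign_mix`` and double-signed (ambiguous) with probability
    ``ambiguous_frac``.  One probe per RNA, plus an optional fraction of
    duplicate probes for multi-probe tests.
    """
    rng = np.random.default_rng(spec.seed)
    edge_rows: list[tuple[str, str, str]] = []
    edges: dict[tuple[str, str], int | str] = {}
    planted_names = {c for c, _, _ in spec.planted}
    known = {controller_name(i) for i in range(spec.n_controllers)}
    unknown = planted_names - known
    if unknown:
        raise ValueError(f"planted controller(s) not in the graph: {sorted(unknown)}")

    for i in range(spec.n_controllers):
        ctrl = controller_name(i)
        degree = int(rng.integers(spec.out_degree[0], spec.out_degree[1] + 1))
        targets = rng.choice(spec.n_rna, size=degree, replace=False)
        for j in sorted(int(t) for t in targets):
            rna = rna_name(j)
            if rng.random() < spec.ambiguous_frac:
                edge_rows.append((ctrl, "increases", rna))
                edge_rows.append((ctrl, "decreases", rna))
                edges[(ctrl, rna)] = AMBIGUOUS
            else:
                sign = -1 if rng.random() < spec.sign_mix else 1
                rel = "increases" if sign == 1 else "decreases"
                edge_rows.append((ctrl, rel, rna))
                edges[(ctrl, rna)] = sign

    mapping_rows = []
    for j in range(spec.n_rna):
        mapping_rows.append((f"P{j}", rna_name(j)))
        if rng.random() < spec.duplicate_probe_frac:
            mapping_rows.append((f"P{j}b", rna_name(j)))

    graph = CausalGraph(edges=edges)
    return Fixture(spec=spec, graph=graph, edge_rows=edge_rows, mapping_rows=mapping_rows)


def _planted_node_states(fixture: Fixture, rng: np.random.Generator) -> dict[str, int]:
    """Trinary state per RNA node implied by planted mechanisms + background."""
    spec = fixture.spec
    states: dict[str, int] = {rna_name(j): 0 for j in range(spec.n_rna)}
    for ctrl, direction, penetrance in spec.planted:
        for rna, sign in sorted(fixture.graph.successors(ctrl).items()):
            if sign == AMBIGUOUS:
                continue
            if rng.random() < penetrance:
                states[rna] = direction * sign
    for j in range(spec.n_rna):
        rna = rna_name(j)
        if states[rna] == 0 and rng.random() < spec.background_change_rate:
            states[rna] = 1 if rng.random() < 0.5 else -1
    return states


def simulate_de_table(
    fixture: Fixture, path: str | Path | None = None
) -> "pd.DataFrame":
    """Simulate the differential-expression table for a fixture.

    Returns the table as a DataFrame with columns id, fold_change, adj_p,
    avg_abundance (linear fold-change scale) and optionally writes it as TSV.
    Every probe of a changed RNA meets all three significance criteria with
    the RNA's sign; probes of unchanged RNAs fail the fold-change and
    p-value criteria.
    """
    import pandas as pd

    spec = fixture.spec
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    node_states = _planted_node_states(fixture, rng)

    rows = []
    for probe, rna in fixture.mapping_rows:
        s = node_states[rna]
        if s != 0:
            fc = s * rng.uniform(*_CHANGED_FC)
            p = rng.uniform(*_CHANGED_P)
        else:
            fc = (1 if rng.random() < 0.5 else -1) * rng.uniform(*_UNCHANGED_FC)
            p = rng.uniform(*_UNCHANGED_P)
        abund = rng.uniform(*_CHANGED_ABUND)
        rows.append((probe, round(fc, 4), float(f"{p:.3e}"), round(abund, 1)))
    df = pd.DataFrame(rows, columns=["id", "fold_change", "adj_p", "avg_abundance"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def make_fixture_bundle(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the three pipeline TSVs (edges, mapping, DE table) to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = generate_graph(spec)
    paths = {
        "edges": outdir / "edges.tsv",
        "mapping": outdir / "mapping.tsv",
        "de": outdir / "de.tsv",
    }
    fixture.write_edge_tsv(paths["edges"])
    fixture.write_mapping_tsv(paths["mapping"])
    simulate_de_table(fixture, paths["de"])
    return paths
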