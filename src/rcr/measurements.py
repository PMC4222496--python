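"""Differential-expression tables and trinary state calling.

Each measurement (e.g. a microarray probe set) carries a signed linear fold
change, a multiplicity-adjusted p-value and an average abundance.  A
measurement is called significantly increased (+1) or decreased (-1) only when
all three criteria hold — |fold change| >= 1.3, adjusted p <= 0.05 and average
abundance >= 32 by default — otherwise it contributes no state change (0).
Measurements are then mapped (possibly many-to-one) onto measurable RNA nodes
of the causal graph: a node changes if at least one of its measurements meets
the criteria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .graph import CausalGraph

logger = logging.getLogger(__name__)

DEFAULT_FC_MIN = 1.3
DEFAULT_P_MAX = 0.05
DEFAULT_ABUND_MIN = 32.0

DE_COLUMNS = ("id", "fold_change", "adj_p", "avg_abundance")


@dataclass(frozen=True)
class MeasurementRecord:
    """One differential-expression result row.

    fold_change is a signed linear ratio (|fc| >= 1 by convention; negative
    means down-regulated); adj_p is the BH-adjusted p-value supplied by the
    upstream analysis (never re-adjusted here); avg_abundance is the
    normalized expression level in platform units.
    """

    measurement_id: str
    fold_change: float
    adj_p: float
    avg_abundance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(
                f"{self.measurement_id}: adj_p must be in [0, 1], got {self.adj_p}"
            )
        if self.fold_change == 0:
            raise ValueError(f"{self.measurement_id}: fold_change must be nonzero")


@dataclass(frozen=True)
class NodeState:
    """Trinary differential state of one measurable RNA node."""

    node_id: str
    state: int  # +1, -1 or 0

    def __post_init__(self) -> None:
        if self.state not in (-1, 0, 1):
            raise ValueError(f"state must be -1, 0 or +1, got {self.state}")


def log2_to_linear(log2fc: float) -> float:
    """Convert a log2 fold change to a signed linear ratio (sign(x) * 2^|x|)."""
    if log2fc == 0:
        raise ValueError("log2 fold change of exactly 0 has no direction")
    return math.copysign(2.0 ** abs(log2fc), log2fc)


def load_de_table(path: str | Path, fc_scale: str = "linear") -> list[MeasurementRecord]:
    """Read a DE results TSV with columns id, fold_change, adj_p, avg_abundance.

    With ``fc_scale="log2"`` the fold-change column is converted to a signed
    linear ratio.  Missing columns and non-numeric cells are hard errors.
    """
    if fc_scale not in ("linear", "log2"):
        raise ValueError(f"fc_scale must be 'linear' or 'log2', got {fc_scale!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        vals = {}
        for col in ("fold_change", "adj_p", "avg_abundance"):
            v = getattr(row, col)
            try:
                vals[col] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {v!r} in column {col!r} at row {idx}"
                ) from None
            if math.isnan(vals[col]):
                raise ValueError(
                    f"{path}: missing value in column {col!r} at row {idx}"
                )
        fc = vals["fold_change"]
        if fc_scale == "log2":
            fc = log2_to_linear(fc)
        records.append(
            MeasurementRecord(
                measurement_id=str(row.id),
                fold_change=fc,
                adj_p=vals["adj_p"],
                avg_abundance=vals["avg_abundance"],
            )
        )
    return records


def load_mapping_table(path: str | Path) -> dict[str, str]:
    """Read a measurement-id -> node-id TSV (columns measurement_id, node_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ("measurement_id", "node_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return dict(zip(df["measurement_id"], df["node_id"]))


def call_state(
    rec: MeasurementRecord,
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    abund_min: float = DEFAULT_ABUND_MIN,
) -> int:
    """Call one measurement's trinary state from the three significance criteria."""
    if fc_min <= 0 or p_max <= 0 or abund_min < 0:
        raise ValueError("thresholds must be positive")
    if rec.adj_p > p_max or rec.avg_abundance < abund_min:
        return 0
    if rec.fold_change >= fc_min:
        return 1
    if rec.fold_change <= -fc_min:
        return -1
    return 0


def map_to_nodes(
    records: list[MeasurementRecord],
    mapping: dict[str, str],
    graph: CausalGraph,
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    abund_min: float = DEFAULT_ABUND_MIN,
) -> list[NodeState]:
    """Map measurements onto graph nodes and call one trinary state per node.

    A node is +1 (resp. -1) if at least one mapped measurement calls +1
    (resp. -1) and none calls the opposite.  When measurements for one node
    call opposite directions, the call with the smallest adjusted p wins,
    ties broken by larger |fold change|, then state 0 with a warning.
    Unmapped measurement ids and mappings to unknown nodes are dropped with a
    logged count.
    """
    graph_nodes = graph.nodes
    per_node: dict[str, list[MeasurementRecord]] = {}
    n_unmapped = 0
    n_unknown_node = 0
    for rec in records:
        node = mapping.get(rec.measurement_id)
        if node is None:
            n_unmapped += 1
            continue
        if node not in graph_nodes:
            n_unknown_node += 1
            continue
        if not graph.is_measurable_rna(node):
            n_unknown_node += 1
            continue
        per_node.setdefault(node, []).append(rec)
    if n_unmapped:
        logger.info("%d measurement(s) without a node mapping dropped", n_unmapped)
    if n_unknown_node:
        logger.warning(
            "%d measurement(s) mapped to nodes absent from the graph "
            "(or not measurable RNA) dropped",
            n_unknown_node,
        )

    states = []
    for node in sorted(per_node):
        recs = per_node[node]
        calls = [(call_state(r, fc_min, p_max, abund_min), r) for r in recs]
        up = [r for s, r in calls if s == 1]
        down = [r for s, r in calls if s == -1]
        if up and down:
            best_up = min(up, key=lambda r: (r.adj_p, -abs(r.fold_change)))
            best_down = min(down, key=lambda r: (r.adj_p, -abs(r.fold_change)))
            key_up = (best_up.adj_p, -abs(best_up.fold_change))
            key_down = (best_down.adj_p, -abs(best_down.fold_change))
            if key_up < key_down:
                state = 1
            elif key_down < key_up:
                state = -1
            else:
                logger.warning(
                    "node %s: conflicting equally-supported calls, state set to 0",
                    node,
                )
                state = 0
        elif up:
            state = 1
        elif down:
            state = -1
        else:
            state = 0
        states.append(NodeState(node_id=node, state=state))
    return states


def states_as_dict(states: list[NodeState]) -> dict[str, int]:
    """Convenience view: node id -> state."""
    return {s.node_id: s.state for s in states}
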