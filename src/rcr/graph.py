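"""Causal knowledge graph: loading, BEL statement parsing, and edge collapsing.

The knowledge base is a directed graph whose nodes are opaque BEL-style term
strings (e.g. ``p(HGNC:TNF)``, ``r(MGI:Igfbp1)``) and whose edges carry one of
four causal relations.  For mechanism inference the four relations collapse to
a sign: *increases* / *directlyIncreases* become +1, *decreases* /
*directlyDecreases* become -1.  A node pair supported by edges of both sign
classes collapses to a single *ambiguous* edge.

No namespace or ortholog resolution is performed: node identity is the exact
term string, and cross-platform identity must be resolved in the
measurement-to-node mapping table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

logger = logging.getLogger(__name__)

#: Sentinel sign for a node pair with conflicting causal evidence.
AMBIGUOUS = "ambiguous"

#: Relations that imply the downstream node moves with the upstream node.
_POSITIVE_RELATIONS = frozenset({"increases", "directlyIncreases"})
#: Relations that imply the downstream node moves against the upstream node.
_NEGATIVE_RELATIONS = frozenset({"decreases", "directlyDecreases"})

ALLOWED_RELATIONS = _POSITIVE_RELATIONS | _NEGATIVE_RELATIONS

#: BEL short forms accepted by the one-line statement parser.
SHORT_FORM_RELATIONS = {
    "->": "increases",
    "=>": "directlyIncreases",
    "-|": "decreases",
    "=|": "directlyDecreases",
}

#: Term prefixes that mark a node as a measurable RNA abundance.
DEFAULT_RNA_PREFIXES = ("r(", "rnaAbundance(")

Sign = Union[int, str]  # +1, -1 or AMBIGUOUS


@dataclass(frozen=True)
class CausalEdge:
    """One raw causal statement: ``source relation target``."""

    source: str
    relation: str
    target: str

    def __post_init__(self) -> None:
        if self.relation not in ALLOWED_RELATIONS:
            raise ValueError(
                f"unknown relation {self.relation!r}; allowed: "
                f"{sorted(ALLOWED_RELATIONS)}"
            )

    @property
    def sign(self) -> int:
        return +1 if self.relation in _POSITIVE_RELATIONS else -1


@dataclass
class CausalGraph:
    """Collapsed causal graph: one signed (or ambiguous) edge per node pair."""

    edges: dict[tuple[str, str], Sign] = field(default_factory=dict)
    rna_prefixes: tuple[str, ...] = DEFAULT_RNA_PREFIXES

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s, t in self.edges:
            out.add(s)
            out.add(t)
        return out

    def is_measurable_rna(self, node: str) -> bool:
        """True if the term denotes an RNA abundance (``r(...)`` by default)."""
        return node.startswith(self.rna_prefixes)

    def successors(self, node: str) -> dict[str, Sign]:
        """Outgoing collapsed edges of *node* as a target -> sign map."""
        return {t: sign for (s, t), sign in self.edges.items() if s == node}


def load_edge_table(path: str | Path) -> list[CausalEdge]:
    """Read causal edges from a 3-column TSV (source, relation, target).

    A header row is recognised by the literal column names ``source``,
    ``relation``, ``target``; ``#``-prefixed lines are skipped.  Node id
    strings are preserved byte-for-byte.
    """
    path = Path(path)
    edges: list[CausalEdge] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}: {line!r}"
                )
            source, relation, target = fields[0], fields[1], fields[2]
            if lineno == 1 and (source, relation, target) == (
                "source",
                "relation",
                "target",
            ):
                continue
            try:
                edges.append(CausalEdge(source, relation, target))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return edges


def parse_bel_line(line: str, allow_short_forms: bool = True) -> CausalEdge:
    """Parse a one-line causal statement ``TERM REL TERM``.

    Each TERM is a balanced-parenthesis BEL term kept as an opaque string;
    REL is one of the four causal relations, long form or (optionally) the
    BEL short form (``->``, ``=>``, ``-|``, ``=|``).  Annotations, evidence
    lines and nested statements are out of scope.
    """
    text = line.strip()
    if not text:
        raise ValueError("empty statement")
    subject, pos = _read_term(text, 0)
    # locate the relation token after the subject term
    rest = text[pos:].lstrip()
    rel_start = len(text) - len(rest)
    token = rest.split(None, 1)
    if not token:
        raise ValueError(f"missing relation after position {pos} in {line!r}")
    rel = token[0]
    if rel in SHORT_FORM_RELATIONS:
        if not allow_short_forms:
            raise ValueError(f"short-form relation {rel!r} not enabled")
        rel = SHORT_FORM_RELATIONS[rel]
    if rel not in ALLOWED_RELATIONS:
        raise ValueError(
            f"unknown relation {rel!r} at position {rel_start} in {line!r}"
        )
    obj_text = token[1].strip() if len(token) > 1 else ""
    if not obj_text:
        raise ValueError(f"missing object term in {line!r}")
    obj, end = _read_term(obj_text, 0)
    if obj_text[end:].strip():
        raise ValueError(
            f"trailing content after object term in {line!r}: "
            f"{obj_text[end:].strip()!r}"
        )
    return CausalEdge(subject, rel, obj)


def _read_term(text: str, start: int) -> tuple[str, int]:
    """Read one balanced-parenthesis term starting at *start*.

    Returns the term string and the index one past its end.  Quoted values
    (``"..."``) may contain parentheses and spaces.
    """
    i = start
    depth = 0
    in_quote = False
    n = len(text)
    while i < n:
        c = text[i]
        if in_quote:
            if c == '"':
                in_quote = False
        elif c == '"':
            in_quote = True
        elif c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {i} in {text!r}")
            if depth == 0:
                return text[start : i + 1], i + 1
        elif c.isspace() and depth == 0:
            break
        i += 1
    if depth != 0 or in_quote:
        raise ValueError(f"unbalanced term starting at position {start} in {text!r}")
    term = text[start:i]
    if not term:
        raise ValueError(f"expected a term at position {start} in {text!r}")
    return term, i


def load_bel_lines(path: str | Path, allow_short_forms: bool = True) -> list[CausalEdge]:
    """Read one causal statement per line; blank and ``#`` lines skipped."""
    path = Path(path)
    edges = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                edges.append(parse_bel_line(line, allow_short_forms=allow_short_forms))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return edges


def collapse_edges(
    edges: Iterable[CausalEdge],
    rna_prefixes: tuple[str, ...] = DEFAULT_RNA_PREFIXES,
) -> CausalGraph:
    """Collapse raw causal statements to one signed edge per node pair.

    Same-sign duplicates (e.g. *increases* plus *directlyIncreases*)
    deduplicate to a single signed edge; pairs supported by both sign classes
    become ambiguous; self-edges are dropped with a warning.
    """
    signs: dict[tuple[str, str], set[int]] = {}
    n_self = 0
    for e in edges:
        if e.source == e.target:
            n_self += 1
            continue
        signs.setdefault((e.source, e.target), set()).add(e.sign)
    if n_self:
        logger.warning("dropped %d self-edge(s) during collapsing", n_self)
    collapsed: dict[tuple[str, str], Sign] = {
        pair: (AMBIGUOUS if len(ss) == 2 else next(iter(ss)))
        for pair, ss in signs.items()
    }
    return CausalGraph(edges=collapsed, rna_prefixes=rna_prefixes)
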