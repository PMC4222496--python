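"""Direction assignment and the two HYP evaluation statistics.

Each observed state change downstream of a controller implies a direction for
the controller: a node on a +1 edge that increased implies the controller
increased; on a -1 edge it implies the controller decreased; on an ambiguous
edge it implies nothing.  The controller's *direction* is the majority of
these implied directions.

Two p-values then evaluate the mechanism:

* **concordance** — the upper tail of Binomial(correct + contra, p = 0.5) at
  the *correct* count: the probability of predicting at least this many
  directions right by coin-flipping.  Nodes on ambiguous edges and unchanged
  nodes are excluded from the trials, so ambiguity never penalises (nor
  rewards) directional consistency.
* **richness** — the upper tail of Hypergeometric(N, m, possible) at the
  *observed* count (ambiguous included): classical enrichment of state
  changes among the controller's targets relative to the population.

Both are exact discrete tails computed by scipy's survival functions, which
work in log space internally and remain accurate far below double-precision
epsilon (tails of 1e-25 are representable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy import stats

from .graph import AMBIGUOUS
from .hyps import Hyp, PopulationStats
from .report import format_sci

DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class ScoredHyp:
    """A mechanism hypothesis with its inferred direction and statistics."""

    upstream: str
    direction: int  # +1, -1 or 0 (none)
    correct: int
    contra: int
    ambiguous: int
    possible: int
    richness: float
    concordance: float

    @property
    def observed(self) -> int:
        return self.correct + self.contra + self.ambiguous


def assign_direction(
    hyp: Hyp, states: dict[str, int]
) -> tuple[int, int, int, int, int]:
    """Infer the controller's direction from its downstream state changes.

    Returns (direction, correct, contra, ambiguous, observed).  A node whose
    state is missing from *states* counts as unchanged.  On a tie (or no
    non-ambiguous evidence) direction is 0 and correct is set to the larger
    (tied) count so the concordance trial count still covers all evidence.
    """
    n_up = 0
    n_down = 0
    n_ambig = 0
    for node, sign in hyp.downstream.items():
        s = states.get(node, 0)
        if s == 0:
            continue
        if sign == AMBIGUOUS:
            n_ambig += 1
        elif s * sign > 0:
            n_up += 1
        else:
            n_down += 1
    if n_up > n_down:
        direction, correct, contra = 1, n_up, n_down
    elif n_down > n_up:
        direction, correct, contra = -1, n_down, n_up
    else:
        direction, correct, contra = 0, n_up, n_down
    observed = correct + contra + n_ambig
    return direction, correct, contra, n_ambig, observed


def concordance_pvalue(
    correct: int, contra: int, ambiguous: int = 0, p: float = 0.5
) -> float:
    """Upper binomial tail of *correct* among correct + contra trials.

    Ambiguous-edge observations are excluded from the trials entirely (the
    *ambiguous* argument is accepted for interface symmetry and validation
    only).  With zero trials the tail is empty and the p-value is 1.
    """
    for name, v in (("correct", correct), ("contra", contra), ("ambiguous", ambiguous)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    trials = correct + contra
    if trials == 0:
        return 1.0
    return float(stats.binom.sf(correct - 1, trials, p))


def richness_pvalue(observed: int, possible: int, pop: PopulationStats) -> float:
    """Upper hypergeometric tail: P(X >= observed), X ~ Hypergeom(N, m, possible)."""
    N, m = pop.N, pop.m
    if possible > N:
        raise ValueError(f"possible={possible} exceeds population N={N}")
    if observed > possible:
        raise ValueError(f"observed={observed} exceeds possible={possible}")
    if observed > m:
        raise ValueError(f"observed={observed} exceeds population state changes m={m}")
    if observed == 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, N, m, possible))


def score_hyp(hyp: Hyp, states: dict[str, int], pop: PopulationStats) -> ScoredHyp:
    direction, correct, contra, ambiguous, observed = assign_direction(hyp, states)
    return ScoredHyp(
        upstream=hyp.upstream,
        direction=direction,
        correct=correct,
        contra=contra,
        ambiguous=ambiguous,
        possible=hyp.possible,
        richness=richness_pvalue(observed, hyp.possible, pop),
        concordance=concordance_pvalue(correct, contra, ambiguous),
    )


def score_all(
    hyps: list[Hyp], states: dict[str, int], pop: PopulationStats
) -> list[ScoredHyp]:
    """Score every HYP; output sorted by (concordance, richness) ascending."""
    scored = [score_hyp(h, states, pop) for h in hyps]
    scored.sort(key=lambda s: (s.concordance, s.richness, s.upstream))
    return scored


def filter_significant(
    scored: list[ScoredHyp], alpha: float = DEFAULT_ALPHA
) -> list[ScoredHyp]:
    """Keep HYPs with both richness <= alpha and concordance <= alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return [s for s in scored if s.richness <= alpha and s.concordance <= alpha]


RESULT_COLUMNS = (
    "mechanism",
    "direction",
    "correct",
    "richness",
    "concordance",
    "ambiguous",
    "contra",
    "possible",
    "observed",
)


def write_results_tsv(scored: list[ScoredHyp], path: str | Path) -> None:
    """Write the scored-mechanism table; p-values at 2 significant figures."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for s in scored:
            fh.write(
                f"{s.upstream}\t{s.direction}\t{s.correct}\t"
                f"{format_sci(s.richness)}\t{format_sci(s.concordance)}\t"
                f"{s.ambiguous}\t{s.contra}\t{s.possible}\t{s.observed}\n"
            )
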