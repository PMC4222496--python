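"""False-positive calibration by matched random state sets.

Random data carry no biological signal, so the number of mechanisms passing
a significance threshold under randomization estimates the false-positive
yield of that threshold.  Each random data set keeps the population and the
HYP set fixed and permutes only *which* population nodes changed, preserving
the real data's exact counts of significantly increased and decreased nodes.

The same machinery drives two diagnostics of size bias: the Pearson
correlation between log10 p-values and HYP size (*possible*) on random
scores, and an optional LOESS-based adjusted concordance (the fitted
log-concordance-vs-size trend subtracted from the raw log concordance).
The adjustment is reported alongside — never replacing — raw concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .hyps import Hyp, PopulationStats
from .scoring import ScoredHyp, filter_significant, score_all

DEFAULT_THRESHOLDS = (0.2, 0.15, 0.1, 0.05, 0.01, 0.005)


@dataclass(frozen=True)
class RandomizationConfig:
    iterations: int = 1000
    seed: int = 0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    loess_span: float = 0.75

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class ThresholdRow:
    threshold: float
    random_median: float
    real_count: int

    @property
    def ratio(self) -> float | None:
        """random_median / real_count, or None when the real count is zero."""
        if self.real_count == 0:
            return None
        return self.random_median / self.real_count


@dataclass(frozen=True)
class ThresholdSweep:
    rows: tuple[ThresholdRow, ...]
    iterations: int
    seed: int

    def as_tsv(self, path: str | Path) -> None:
        """Write the sweep table: threshold, random_median, real_count, ratio.

        Ratios are rendered as whole percentages, N/A when undefined.
        """
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("threshold\trandom_median\treal_count\tratio\n")
            for row in self.rows:
                ratio = "N/A" if row.ratio is None else f"{round(100 * row.ratio)}%"
                fh.write(
                    f"{row.threshold}\t{row.random_median}\t{row.real_count}\t{ratio}\n"
                )


def sample_random_states(
    pop: PopulationStats, n_up: int, n_down: int, rng: np.random.Generator
) -> dict[str, int]:
    """Draw a matched random state map over the population.

    Samples n_up + n_down distinct nodes uniformly without replacement,
    assigns +1 to the first n_up and -1 to the rest; every other population
    node is 0.  The node list is sorted before sampling so a given generator
    state always yields the same draw regardless of set iteration order.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("state-change counts must be >= 0")
    total = n_up + n_down
    if total > pop.N:
        raise ValueError(
            f"cannot place {total} state changes in a population of {pop.N}"
        )
    nodes = sorted(pop.population)
    chosen = rng.choice(len(nodes), size=total, replace=False)
    states = {node: 0 for node in nodes}
    for i in chosen[:n_up]:
        states[nodes[i]] = 1
    for i in chosen[n_up:]:
        states[nodes[i]] = -1
    return states


def _iteration_rngs(seed: int, iterations: int) -> list[np.random.Generator]:
    """Independent per-iteration generators spawned from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(iterations)]


def score_random_sets(
    hyps: list[Hyp],
    pop: PopulationStats,
    n_up: int,
    n_down: int,
    cfg: RandomizationConfig,
) -> list[list[ScoredHyp]]:
    """Score all HYPs on each of cfg.iterations matched random state maps.

    Every random draw places exactly n_up + n_down state changes in the
    population, so the enrichment universe for these scores carries
    m = n_up + n_down regardless of what the supplied stats recorded.
    """
    rand_pop = PopulationStats(population=pop.population, m=n_up + n_down)
    out = []
    for rng in _iteration_rngs(cfg.seed, cfg.iterations):
        random_states = sample_random_states(rand_pop, n_up, n_down, rng)
        out.append(score_all(hyps, random_states, rand_pop))
    return out


def threshold_sweep(
    hyps: list[Hyp],
    pop: PopulationStats,
    real_states: dict[str, int],
    cfg: RandomizationConfig,
) -> ThresholdSweep:
    """Median significant-HYP counts over random sets versus the real data.

    The random draws match the real data's up/down state-change counts
    within the population; the HYP set and population are identical across
    all iterations.
    """
    pop_nodes = pop.population
    n_up = sum(1 for n in pop_nodes if real_states.get(n, 0) == 1)
    n_down = sum(1 for n in pop_nodes if real_states.get(n, 0) == -1)

    # real and random data share the population and the state-change count m
    real_pop = PopulationStats(population=pop.population, m=n_up + n_down)
    real_scored = score_all(hyps, real_states, real_pop)
    real_counts = {
        t: len(filter_significant(real_scored, t)) for t in cfg.thresholds
    }

    random_counts: dict[float, list[int]] = {t: [] for t in cfg.thresholds}
    for scored in score_random_sets(hyps, pop, n_up, n_down, cfg):
        for t in cfg.thresholds:
            random_counts[t].append(len(filter_significant(scored, t)))

    rows = tuple(
        ThresholdRow(
            threshold=t,
            random_median=float(np.median(random_counts[t])),
            real_count=real_counts[t],
        )
        for t in sorted(cfg.thresholds, reverse=True)
    )
    return ThresholdSweep(rows=rows, iterations=cfg.iterations, seed=cfg.seed)


@dataclass(frozen=True)
class SizeBiasReport:
    """Pearson correlations of log10 p-value with HYP size on random scores."""

    richness_corr: float
    concordance_corr: float
    concordance_corr_observed_ge4: float | None
    n_scores: int
    n_scores_observed_ge4: int


def size_bias_report(scored_random: list[list[ScoredHyp]]) -> SizeBiasReport:
    """Correlate log10 p-values with *possible* across all random scores.

    Degenerate inputs (fewer than 3 points, or zero variance in either
    variable) raise; the observed >= 4 restriction is reported as None when
    too few scores qualify.
    """
    flat = [s for iteration in scored_random for s in iteration]
    if len(flat) < 3:
        raise ValueError("need at least 3 scored HYPs for a correlation")
    possible = np.array([s.possible for s in flat], dtype=float)
    if np.ptp(possible) == 0:
        raise ValueError("all HYPs have the same size; correlation undefined")
    log_rich = np.log10([s.richness for s in flat])
    log_conc = np.log10([s.concordance for s in flat])

    rich_r = stats.pearsonr(possible, log_rich).statistic
    conc_r = stats.pearsonr(possible, log_conc).statistic

    mask = np.array([s.observed >= 4 for s in flat])
    conc_r_ge4: float | None = None
    if mask.sum() >= 3 and np.ptp(possible[mask]) > 0:
        conc_r_ge4 = stats.pearsonr(possible[mask], log_conc[mask]).statistic
    return SizeBiasReport(
        richness_corr=float(rich_r),
        concordance_corr=float(conc_r),
        concordance_corr_observed_ge4=(
            None if conc_r_ge4 is None else float(conc_r_ge4)
        ),
        n_scores=len(flat),
        n_scores_observed_ge4=int(mask.sum()),
    )


def loess_adjust_concordance(
    scored_random: list[list[ScoredHyp]],
    scored_real: list[ScoredHyp],
    span: float = 0.75,
) -> dict[str, float]:
    """Size-adjusted log10 concordance for each real HYP.

    Fits a LOESS curve to log10 concordance versus HYP size on the random
    scores and returns, per mechanism, the raw log10 concordance minus the
    fitted trend at that mechanism's size.  A mechanism sitting exactly on
    the trend gets 0; more-significant-than-expected mechanisms get negative
    values.  Raw concordance is never modified.
    """
    flat = [s for iteration in scored_random for s in iteration]
    if len(flat) < 3:
        raise ValueError("need at least 3 random scores to fit the trend")
    x = np.array([s.possible for s in flat], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all random HYP sizes identical")
    y = np.log10([s.concordance for s in flat])
    fitted = lowess(y, x, frac=span, return_sorted=True)
    grid_x, grid_y = fitted[:, 0], fitted[:, 1]

    out = {}
    for s in scored_real:
        trend = float(np.interp(s.possible, grid_x, grid_y))
        out[s.upstream] = float(np.log10(s.concordance) - trend)
    return out
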