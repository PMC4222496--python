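# Methods

## The model

The package infers upstream controllers of observed differential gene
expression by *reverse causal reasoning* over a signed causal knowledge
graph. The knowledge graph is a set of statements `source relation target`
with `relation ∈ {increases, directlyIncreases, decreases,
directlyDecreases}`. Direct and indirect relations carry the same sign for
inference, so statements collapse to one edge per ordered node pair with
sign +1, −1, or *ambiguous* when the graph contains conflicting evidence
(both sign classes) for the pair. Self-edges are dropped: a node is never
its own downstream readout.

A *mechanism hypothesis* is a depth-1 star: one upstream controller node
together with its collapsed edges to downstream **measured RNA abundance
nodes** (terms beginning `r(` or `rnaAbundance(`; the prefix list is
configurable). Only controllers with at least `min_possible` (default 4)
such targets are evaluated. The star is treated like a naive-Bayes
classifier: downstream nodes are assumed conditionally independent given
the controller's state. Multi-edge causal paths, edge types other than the
four above, and joining of significant mechanisms into larger networks are
out of scope.

## State calling

The differential-expression table supplies, per measurement, a signed
linear fold change (log2 input is converted as sign(x)·2^|x|), a
BH-adjusted p-value (adjustment happens upstream and is never redone), and
an average abundance. A measurement is called +1/−1 only if all three
criteria hold: |fc| ≥ 1.3, adjusted p ≤ 0.05, abundance ≥ 32 (all
thresholds configurable; boundaries inclusive). Measurements map
many-to-one onto RNA nodes; a node changes if at least one of its
measurements is called. When measurements for one node disagree in
direction, the call with the smallest adjusted p wins, then the larger
|fc|, then state 0 with a warning — a deterministic strongest-evidence rule
for a case the underlying procedure leaves open.

## Direction and the two statistics

Each changed downstream node implies a controller direction: its state
times the edge sign (ambiguous edges imply nothing). The controller's
*direction* is the majority of implied directions; a tie (or
ambiguous-only evidence) yields direction *none* with the tied counts kept
so the trial count still reflects all evidence. Writing `correct` k,
`contra`, `ambiguous` l, `observed` = k + contra + l, `possible` n per
mechanism, and N (population = union of all mechanisms' downstream sets)
with m state changes in the population:

* **concordance** = P(X ≥ k), X ~ Binomial(k + contra, ½) — the chance a
  coin-flipping predictor gets at least k directions right. Ambiguous-edge
  observations are excluded from the trials entirely, so conflicting prior
  knowledge neither supports nor penalises a mechanism's directional
  consistency. Zero trials give p = 1.
* **richness** = P(X ≥ observed), X ~ Hypergeometric(N, m, n) — classical
  enrichment of state changes among the mechanism's targets. Ambiguous
  observations *do* count here. Zero observed gives p = 1.

Both tails are exact discrete survival functions (`scipy.stats`), accurate
far into the underflow range (1e-25 tails are routinely needed); no normal
approximation, no mid-p. The tail includes the observed point, so p-values
lie in (0, 1] and the null calibration is conservative. A mechanism is
significant when **both** p-values are ≤ α (default 0.1, inclusive). No
multiple-testing correction is applied across mechanisms: the threshold is
calibrated by randomization instead, and the statistics are a filter for
manual review, not a ranking.

Report TSVs render p-values at two significant figures in scientific
notation with decimal half-up ties (`rcr.report.round_sig`), the convention
of the published mechanism tables; full precision is kept internally.

## Randomization

Matched random data sets keep the graph, the mechanism set and the
population fixed and permute only which population nodes changed: exactly
n_up nodes get +1 and n_down get −1, drawn uniformly without replacement,
matching the real data's counts. Because the design fixes the change count,
the enrichment universe for random (and matched real) scoring uses
m = n_up + n_down. A master seed spawns independent per-iteration
generators (`numpy.random.SeedSequence.spawn`), so any iteration is
reproducible in isolation. The threshold sweep reports, per cutoff in
{0.2, 0.15, 0.1, 0.05, 0.01, 0.005}, the median significant-mechanism
count over the random sets, the real-data count, and their ratio
(rendered as a whole percentage; N/A when the real count is 0).

Size-bias diagnostics correlate log10 p-values with mechanism size
(*possible*) on random scores, overall and restricted to mechanisms with
observed ≥ 4 (the minimum at which concordance can reach 0.1). An optional
LOESS adjustment fits log10 concordance versus size on the random scores
(statsmodels `lowess`, frac 0.75, local-linear) and reports raw log10
concordance minus the fitted trend; it never replaces raw concordance and
is off by default.

## Synthetic studies

The fixture generator emulates the structure the model assumes, not
microarray physics. Controllers `act(SYN:Ci)` are wired to RNAs `r(SYN:Gj)`
with uniform out-degree in a configured range; each edge is repressive with
probability `sign_mix` (default 0.3) and double-signed with probability
`ambiguous_frac` (default 0.05). A *planted* controller flips each
non-ambiguous target with probability `penetrance`, independently, in the
direction implied by its edge sign; unrelated RNAs change at
`background_change_rate` with uniform sign. Changed rows draw |fc| in
[1.5, 4], adjusted p in [1e-6, 0.04], abundance in [50, 1000]; unchanged
rows draw |fc| in [1.0, 1.25] and p in [0.1, 0.99]. Only which side of the
thresholds a row falls on matters to the trinary pipeline, so these simple
uniform draws are sufficient. Defaults describe a modest single-perturbation
study — 20 controllers, 500 RNAs, out-degree 10–30, one planted mechanism at
penetrance 0.8, 2% background — sized so a planted mechanism is recoverable
but not trivial. Everything is deterministic per seed (byte-identical TSVs).

What passing tests on these fixtures show: the pipeline recovers a planted
controller with its direction under realistic signal, the null is
calibrated, and the size-bias structure matches expectation. What they do
not show: robustness to correlated downstream genes, probe
cross-hybridisation, normalisation artefacts, or curation bias in real
knowledge bases — none of which the generator models.

## Numerical and design choices

* Thresholds compare inclusively (≤ / ≥) throughout, matching the
  "p < = 0.1" usage of the published threshold table.
* Direction ties keep the tied count as `correct`, so concordance is ≈ 0.5
  or larger — a tied mechanism can never appear spuriously significant.
* Scored output is sorted by (concordance, richness, mechanism id); all
  generated collections are sorted before iteration or sampling so results
  are independent of set/dict ordering.
* Population validation: `possible > N`, `observed > possible`,
  `observed > m`, and `m > N` are hard errors rather than silent clamps.
* Test problem sizes: null calibration uses a 25-controller / 400-RNA
  signal-free fixture with 1000 matched draws; recovery uses 200 replicate
  studies at generator defaults. These sizes give stable empirical
  fractions (±1% at α = 0.05) while keeping the suite quick.

## Known limitations

* Only depth-1 mechanisms; no propagation through intermediate unmeasured
  nodes.
* Node identity is the exact term string; orthology and namespace
  equivalence must be resolved before input.
* The abundance criterion applies to the single supplied average-abundance
  column, not per-group means.
* Concordance remains size-biased (larger mechanisms can reach smaller
  p-values); the LOESS adjustment is diagnostic, not a correction applied
  to reported results.
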