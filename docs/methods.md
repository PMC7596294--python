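# Methods

## Core-area prioritization

The spatial prioritization is a greedy reverse-stepwise ranking. All valid
cells start "protected"; at each iteration the cell whose removal costs the
least is dropped, where the marginal loss of cell *i* over the remaining
set *S* is

δᵢ = maxⱼ [ wⱼ · Qᵢⱼ(S) / cᵢ ],  Qᵢⱼ(S) = pᵢⱼ / Σₖ∈S pₖⱼ.

Scoring a cell by its *single best* remaining feature (the max, not a sum)
is what makes this a core-area rule: as a feature's distribution is eroded,
Q of its remaining cells rises toward 1, so the last strongholds of every
positively weighted feature — however rare — are retained to the end. The
formula simultaneously encodes the four qualitative removal preferences
(lower occurrence first, lower weight first, less-eroded features first,
higher cost first).

Numerical choices:

* **Tie-breaking.** Cells with equal δ are removed lowest row-major index
  first. Any rule would do; a deterministic one makes rankings
  reproducible, and `numpy.argmin`'s first-minimum semantics implements it
  directly.
* **Granularity.** Exactly one cell is removed per iteration (no batch
  removal). Grids at the scale this package targets (10³–10⁴ cells) rank in
  well under a second with the vectorized per-iteration recomputation.
* **Degenerate inputs.** Features whose remaining total is zero are skipped
  in the max; if every feature total is zero the remaining cells are
  removed in index order with a warning. NODATA / non-finite cells are
  excluded from S at initialization and never ranked.
* **Criteria stacks.** When a criteria list gives an importance order but
  no weights, ranks map to geometric weights 2^(R−r), so each criterion
  strictly dominates all lower-ranked ones in the max — a faithful reading
  of "ordered from highest to lowest importance". Exclusion criteria
  (areas disallowed by existing legal instruments) become validity-mask
  removals rather than weighted features.

Top-fraction masks take the ceil(f·n) cells removed last; being suffixes of
one removal order they are nested across fractions by construction.

## Refuge network checks

Each design principle is one check with one verdict plus diagnostics.
Defaults (all configurable): habitat representation lower bound 10 % (the
30 % upper bound is reported as guidance, not failure); ≥3 refuges
containing each habitat per bioregion, with within-subdivision habitat
duplicity ≥2 reported alongside; 50-km corridor subdivisions; recovery
thresholds 10 yr (herbivores/planktivores) and 25 yr
(carnivores/piscivores); compactness warning threshold 0.3 on the
Polsby–Popper index (a 10:1 rectangle scores ≈0.26, a square ≈0.785), with
an exemption flag for refuges spanning whole ecological units such as
estuaries.

* **Size adequacy** uses the species' adult home range when known,
  otherwise the 100 km² (10-km-long) fallback for fish up to 167 cm total
  length; the area criterion governs the verdict, since "10 km long" is
  ambiguous for narrow shapes. A species is served if at least one refuge
  meets its minimum; undersized refuges are listed per species.
* **Larval connectivity** reduces the corridor to one dimension: each
  refuge's position is its centroid projected onto a supplied baseline
  polyline. Gaps between consecutive positions must not exceed the
  species' dispersal distance — linear between (2 wk, 50 km) and
  (8 wk, 200 km), clamped outside — and every subdivision midpoint must
  have a refuge on its upstream side (direction configurable, since
  larvae-bearing currents reverse seasonally). No oceanographic transport
  is simulated; connectivity is the distance rule only.
* **Raster intersection** counts a cell as protected when its center lies
  inside a refuge. At the 2-km demo resolution this is accurate to a cell;
  finer rasters sharpen it.
* Climate-resilient siting and avoidance of impacted areas have no
  quantitative criterion in the design guidance, so they are implemented as
  user-supplied boolean suitability rasters: each refuge needs a minimum
  fraction (default 0.5) of suitable cells.

## Quota-prioritization suite

* **Feasibility screen.** Excludes multispecific fisheries and long-lived /
  late-maturing stocks (defaults: max age ≥ 25 yr or age at first maturity
  ≥ 7 yr, both configurable); sedentary species are annotated as favorable.
  Ranged life-history values in the bundled table collapse to the upper
  bound for maximum age but the lower bound for maturity age, so a range
  triggers exclusion only when clearly warranted.
* **PSA.** Axis scores are the weighted mean Σ(a·w)/Σw of attributes scored
  1–3 with weights 0–4 (0 removes an attribute; the conventional default
  weight is 2). Vulnerability is the Euclidean distance
  √((p−3)² + (s−1)²) from the least-vulnerable corner (p=3, s=1), range
  [0, √8]. Data-quality scores (1 best … 5 worst) are averaged over active
  attributes and reported alongside vulnerability, never folded into it —
  there is no defensible single formula for that, so uncertainty stays
  visible and separate.
* **Froese indicators.** Per-fish classification against three bands:
  mature (length ≥ the 90 %-maturity length, defaulting to the length at
  first maturity when no separate estimate is supplied), optimum
  (within ±10 % of L_opt), megaspawners (above 1.1·L_opt — the complement
  of the optimum band; the threshold factor is configurable). L_opt may be
  given directly or derived as L_max·3/(3 + M/K). Reliability flags:
  `insufficient` below 30 records, `low_n` below 300 (such estimates carry
  a higher degree of uncertainty), `ok` otherwise. Status classification:
  mature ≥ 90 % acceptable / 100 % at target; optimum 100 % at target;
  megaspawners 0 % at the harvest target, < 20 % a lower-limit breach,
  30–40 % a healthy age structure when the catch mirrors the stock.
* **SEASALT.** Attribute state (and trend) is the mean of its criterion
  scores on the 0–5 questionnaire scales, rounded with exact halves going
  down; indeterminate (0) responses are excluded from the mean and
  flagged. Transferability always returns a not-applicable marker.
* **Composite ranking.** Included species sort by ascending vulnerability,
  then descending count of Froese indicators at/above target, then
  descending mean SEASALT state. The composite is a presentation order
  only; all three component analyses are reported unaggregated so users can
  apply their own weighting.

## Surrogate operating model

The simulator is deliberately minimal: per functional group *g* and box
*b*, an annual step of logistic surplus production
B ← B + rB(1 − B/K), harvest of the fraction 1 − e^(−F) split across
fleets, then diffusive movement along box adjacencies. F is the baseline
fleet-specific fishing mortality scaled by (1 − reduction) from the
reduction start year and by the closure factor (none 1.0, partial 0.5,
full 0.0) from the refuge start year, both maintained to the end of the
horizon. Movement follows the depletion gradient: the pairwise flux between
adjacent boxes is m·(Bⱼ/Kⱼ − Bᵢ/Kᵢ)·min(Kᵢ, Kⱼ)/2. This conserves mass
exactly (antisymmetric fluxes), produces no flow between equally depleted
boxes, and never pushes a box above its carrying capacity — which is what
guarantees that unfished biomass rises monotonically toward capacity.

This model carries the *scenario logic* — implementation years, closure
schedules, inclusive 26-year horizons, snapshots 5/10/15 years after
refuge implementation (truncated to the final year with a warning when
they overrun) — and the indicator accounting. It has no biogeochemistry,
predation, age structure, or recruitment dynamics, and makes no claim of
reproducing any published end-to-end ecosystem-model trajectory. Body size
in the catch uses each group's static mean-weight proxy, a stand-in for
weight-at-age accounting.

**Q-90 biodiversity.** Groups are ranked by descending abundance
(zero-abundance groups excluded), the cumulative abundance is logged
(base 10), and the statistic is the two-point slope of that curve between
the interpolated 10th and 90th percentile ranks, r_q = 1 + q·(n−1). A
community dominated by a few groups saturates the cumulative curve early
and scores near zero; a perfectly even community maximizes the slope, which
then depends only on the number of groups (log₁₀(r₉₀/r₁₀)/(r₉₀ − r₁₀)).
Requiring ≥3 positive groups keeps the percentile span non-degenerate.

**Trade-off normalization.** Indicators are min–max rescaled to [0, 1]
across scenarios at the chosen snapshot year; an indicator constant across
scenarios maps to 0.5 with an explicit note, so radar plots stay readable
without implying a difference.

## Synthetic data

The generators emulate the character of the planning inputs, not any real
geography:

* **Landscapes** (default 20×40 cells at 2 km): per-feature occurrence
  fields are Gaussian-smoothed (σ = 2 cells) uniform noise — smooth,
  strictly positive, spatially autocorrelated like species-distribution
  probability surfaces, which also keeps top-fraction masks spatially
  coherent in typical draws; cost is log-normal fishing intensity
  (log-sd 0.75); the exclusion mask removes an exact 10 % band of cells.
* **Catch samples** are truncated normal on (0, L_max], centered on L_opt
  with a 25 % coefficient of variation by default — a plausible shape for
  a size-selective fishery — with generating parameters recoverable for
  tests.
* **The demo refuge network** (twelve refuges, three per 50-km section,
  one large refuge per section sized above the widest home range) is
  constructed to satisfy all seven principles, so it serves as a positive
  control; the tests construct failing networks separately.
* **The ecosystem** has 12 functional groups spanning pelagic, demersal
  and invertebrate guilds over trophic levels 2–4.3, with intrinsic growth
  rates 0.15–0.8 yr⁻¹ and carrying capacities split across 8 boxes (4 in
  the corridor) by a mildly seeded Dirichlet draw; commercial groups carry
  a baseline F of 0.25 yr⁻¹ split 70/30 across two gear fleets, which
  leaves stocks measurably depleted but not collapsed over the horizon.

What passing tests on these inputs shows: the rules, formulas and
simulation contracts are implemented correctly and behave as specified
under controlled conditions. What it does not show: performance on real
corridor data — real distribution layers are patchier, real catch samples
are multimodal and size-biased, and real ecosystems have predation and
recruitment feedbacks the surrogate omits.

## Known limitations

* Raster I/O supports the ESRI ASCII grid dialect only.
* The priority engine implements the core-area removal rule only — no
  additive-benefit mode, boundary-length penalties, or condition layers.
* Connectivity is a 1-D along-corridor distance rule, not a dispersal
  simulation.
* The operating model's simplicity means scenario results rank management
  options qualitatively; absolute biomass numbers carry no empirical
  weight.
* Participatory post-edits of masks (stakeholder-negotiated boundary
  changes) are out of scope; masks can be edited downstream as polygons.
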