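"""Data-limited quota-prioritization suite.

Four semi-quantitative screens decide which target species are good
candidates for catch quotas and in what order:

* a **life-history feasibility screen** — multispecific fisheries and
  long-lived, late-maturing species are poor quota candidates;
* **productivity–susceptibility analysis (PSA)** — attributes scored 1–3 on
  each axis, weighted 0–4, combined as the weighted mean per axis; the
  vulnerability score is the Euclidean distance of (p, s) from the
  least-vulnerable corner (p=3, s=1), so it ranges 0 to √8. Data-quality
  scores (1 best … 5 worst) are carried alongside, never folded in;
* three **length-based Froese sustainability indicators** from catch
  length-frequency samples — % mature, % caught within ±10 % of the optimum
  harvest length, % megaspawners above that band;
* **SEASALT** management-attribute scoring (Secure, Exclusive, All sources,
  Scaled, Accountable, Limited; Transferability is not applicable because
  quotas are non-transferable under Mexican law), each attribute scored 0–5
  for state and 0–5 for perceived trend.

The final quota-priority table ranks included species by ascending
vulnerability, then by how many Froese indicators sit at/above target, then
by mean SEASALT state; the three component analyses are always reported
unaggregated next to the rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class StockToolError(ValueError):
    """Raised for violated stock-tool preconditions."""


# ---------------------------------------------------------------------------
# feasibility screen

# thresholds reverse-engineered from the one documented exclusion case
# (max age 28 yr, age at first maturity 7 yr); both configurable.
DEFAULT_MAX_AGE_LIMIT = 25.0
DEFAULT_MATURITY_AGE_LIMIT = 7.0


@dataclass
class FeasibilityVerdict:
    species_id: str
    include: bool
    reasons: list[str]
    notes: list[str] = field(default_factory=list)
    indeterminate: bool = False


def feasibility_screen(
    record: dict,
    max_age_limit: float = DEFAULT_MAX_AGE_LIMIT,
    maturity_age_limit: float = DEFAULT_MATURITY_AGE_LIMIT,
) -> FeasibilityVerdict:
    """Screen one species' life history for quota feasibility.

    ``record`` carries ``species_id`` plus any of ``multispecies`` (bool),
    ``max_age`` (yr), ``age_first_maturity`` (yr) and ``movement``
    ("sedentary" | "migratory" | "coastal" | None). A species is excluded
    when its fishery is multispecific, or when it is long-lived / late
    maturing (defaults: max age >= 25 yr or maturity >= 7 yr — quota
    benefits would lag the management horizon). Sedentary species are
    annotated as favorable (biomass and areas are easier to pin down).
    """
    sid = record.get("species_id", "?")
    fields = ("multispecies", "max_age", "age_first_maturity", "movement")
    if all(_missing(record.get(f)) for f in fields):
        return FeasibilityVerdict(sid, False, ["no life-history data"], indeterminate=True)

    reasons: list[str] = []
    if record.get("multispecies"):
        reasons.append("multispecies fishery")
    max_age = record.get("max_age")
    maturity = record.get("age_first_maturity")
    if not _missing(max_age) and float(max_age) >= max_age_limit:
        reasons.append("long life history / late maturity")
    elif not _missing(maturity) and float(maturity) >= maturity_age_limit:
        reasons.append("long life history / late maturity")

    notes = []
    movement = record.get("movement")
    if isinstance(movement, str) and movement.lower() == "sedentary":
        notes.append("sedentary: favors quota management areas")
    elif isinstance(movement, str) and movement.lower() == "migratory":
        notes.append("migratory: quotas hard to apply across full range")
    return FeasibilityVerdict(sid, not reasons, reasons, notes)


def _missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PsaAttribute:
    """One scored PSA attribute on the productivity or susceptibility axis."""

    name: str
    axis: str  # "productivity" | "susceptibility"
    score: int  # 1..3
    weight: int = 2  # 0..4; 0 removes the attribute
    data_quality: int = 3  # 1 (best) .. 5 (worst)

    def __post_init__(self) -> None:
        if self.axis not in ("productivity", "susceptibility"):
            raise StockToolError(f"unknown PSA axis {self.axis!r}")
        if self.score not in (1, 2, 3):
            raise StockToolError(f"attribute score must be 1-3, got {self.score}")
        if self.weight not in range(5):
            raise StockToolError(f"attribute weight must be 0-4, got {self.weight}")
        if self.data_quality not in range(1, 6):
            raise StockToolError(f"data_quality must be 1-5, got {self.data_quality}")


@dataclass
class PsaResult:
    productivity: float
    susceptibility: float
    vulnerability: float
    mean_data_quality: float


def psa_axis_score(attributes: list[PsaAttribute]) -> float:
    """Weighted-mean axis score Σ(a·w)/Σw; weight 0 removes an attribute."""
    if not attributes:
        raise StockToolError("no attributes supplied")
    w = np.array([a.weight for a in attributes], dtype=float)
    a = np.array([a.score for a in attributes], dtype=float)
    if w.sum() == 0:
        raise StockToolError("all attribute weights are zero")
    return float((a * w).sum() / w.sum())


def vulnerability(p: float, s: float) -> float:
    """Distance of (p, s) from the least-vulnerable corner (p=3, s=1).

    0 = productive and unexposed; √8 ≈ 2.83 = worst case (p=1, s=3).
    """
    if not (1 <= p <= 3 and 1 <= s <= 3):
        raise StockToolError(f"axis scores must lie in [1, 3], got p={p}, s={s}")
    return math.sqrt((p - 3.0) ** 2 + (s - 1.0) ** 2)


def psa_score(attributes: list[PsaAttribute]) -> PsaResult:
    """Full PSA for one species from its scored attribute table."""
    prod = [a for a in attributes if a.axis == "productivity"]
    susc = [a for a in attributes if a.axis == "susceptibility"]
    if not prod or not susc:
        raise StockToolError("need attributes on both PSA axes")
    p = psa_axis_score(prod)
    s = psa_axis_score(susc)
    active = [a for a in attributes if a.weight > 0]
    dq = float(np.mean([a.data_quality for a in active]))
    return PsaResult(p, s, vulnerability(p, s), dq)


# ---------------------------------------------------------------------------
# Froese length-based indicators

LOW_N_THRESHOLD = 300  # below: indicators carry a higher degree of uncertainty
INSUFFICIENT_N_THRESHOLD = 30  # below: sample too small to report


@dataclass
class LengthSample:
    """Length-frequency sample of one species' catch.

    ``l_mat`` is the length at first maturity, ``l_opt`` the optimum harvest
    length (where unfished cohort biomass peaks) and ``l_max`` the maximum
    theoretical length. ``l_mat90`` optionally gives the length at which
    90–100 % of individuals are mature; it defaults to ``l_mat``.
    """

    species_id: str
    lengths: np.ndarray
    l_mat: float
    l_opt: float
    l_max: float
    l_mat90: float | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.size and np.any(self.lengths <= 0):
            raise StockToolError(f"{self.species_id}: lengths must be positive")
        if not self.l_mat < self.l_opt < self.l_max:
            raise StockToolError(
                f"{self.species_id}: need l_mat < l_opt < l_max "
                f"({self.l_mat}, {self.l_opt}, {self.l_max})"
            )

    @property
    def maturity_length(self) -> float:
        return self.l_mat if self.l_mat90 is None else self.l_mat90


@dataclass
class FroeseResult:
    species_id: str
    pct_mature: float
    pct_optimal: float
    pct_megaspawners: float
    n: int
    reliability_flag: str  # ok | low_n | insufficient


def derive_l_opt(l_max: float, m_over_k: float) -> float:
    """Optimum harvest length from growth/mortality: L_max * 3 / (3 + M/K)."""
    if l_max <= 0 or m_over_k <= 0:
        raise StockToolError("l_max and M/K must be positive")
    return l_max * 3.0 / (3.0 + m_over_k)


def froese_indicators(sample: LengthSample, mega_factor: float = 1.1) -> FroeseResult:
    """The three length-based catch sustainability indicators.

    * % mature: lengths at or above the 90 %-maturity length;
    * % optimum: lengths within ±10 % of the optimum harvest length;
    * % megaspawners: lengths above ``mega_factor``·l_opt (the band's upper
      edge), the large old spawners a healthy fishery should not catch.

    ``reliability_flag`` is ``insufficient`` below 30 records and ``low_n``
    below 300 (length-based indicators from such samples carry a higher
    degree of uncertainty).
    """
    n = sample.lengths.size
    if n == 0:
        raise StockToolError(f"{sample.species_id}: empty length sample")
    lengths = sample.lengths
    lo, hi = 0.9 * sample.l_opt, mega_factor * sample.l_opt
    pct_mature = 100.0 * np.count_nonzero(lengths >= sample.maturity_length) / n
    pct_optimal = 100.0 * np.count_nonzero((lengths >= lo) & (lengths <= hi)) / n
    pct_mega = 100.0 * np.count_nonzero(lengths > hi) / n
    if n < INSUFFICIENT_N_THRESHOLD:
        flag = "insufficient"
    elif n < LOW_N_THRESHOLD:
        flag = "low_n"
    else:
        flag = "ok"
    return FroeseResult(sample.species_id, pct_mature, pct_optimal, pct_mega, int(n), flag)


MEGASPAWNER_LOWER_LIMIT = 20.0
MEGASPAWNER_HEALTHY_BAND = (30.0, 40.0)
MATURE_ACCEPTABLE = 90.0


def froese_status(result: FroeseResult) -> dict[str, str]:
    """Classify each indicator against its management target.

    * mature — target 100 % (let every fish spawn once); >= 90 % acceptable;
    * optimal — target 100 % within the optimum band;
    * megaspawners — harvest target 0 %; if the catch mirrors the stock's age
      structure, 30–40 % indicates a healthy population and < 20 % breaches
      the lower limit.
    """
    if result.pct_mature >= 100.0:
        mature = "at_target"
    elif result.pct_mature >= MATURE_ACCEPTABLE:
        mature = "acceptable"
    else:
        mature = "below_target"
    optimal = "at_target" if result.pct_optimal >= 100.0 else "below_target"
    m = result.pct_megaspawners
    if m == 0.0:
        mega = "at_harvest_target"
    elif m < MEGASPAWNER_LOWER_LIMIT:
        mega = "below_lower_limit"
    elif MEGASPAWNER_HEALTHY_BAND[0] <= m <= MEGASPAWNER_HEALTHY_BAND[1]:
        mega = "healthy_age_structure"
    else:
        mega = "intermediate"
    return {"mature": mature, "optimal": optimal, "megaspawners": mega}


# ---------------------------------------------------------------------------
# SEASALT

SEASALT_ATTRIBUTES = ("Secure", "Exclusive", "All sources", "Scaled", "Accountable", "Limited")
NOT_APPLICABLE = "not_applicable"


@dataclass
class SeasaltScore:
    """Per-attribute state and trend on the 0–5 questionnaire scales.

    State: 5 superior … 1 critical, 0 indeterminate. Trend: 5 strong
    positive outlook … 1 strong negative, 0 indeterminate. Transferability
    is always the not-applicable marker (quotas are not transferable under
    Mexican law).
    """

    state: dict[str, int | None]
    trend: dict[str, int | None]
    indeterminate: dict[str, list[str]]
    transferability: str = NOT_APPLICABLE

    def mean_state(self) -> float:
        vals = [v for v in self.state.values() if v is not None]
        if not vals:
            return float("nan")
        return float(np.mean(vals))


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def seasalt_evaluate(answers: dict[str, dict[str, tuple[int, int]]]) -> SeasaltScore:
    """Aggregate per-criterion questionnaire responses into attribute scores.

    ``answers`` maps attribute -> {criterion: (state, trend)} with both
    scores on 0–5 scales. Per attribute, the state (and trend) is the
    rounded mean of its criterion scores, exact halves rounding down;
    indeterminate (0) responses are excluded from the mean and flagged. An
    attribute whose every response is indeterminate scores ``None``.
    """
    state: dict[str, int | None] = {}
    trend: dict[str, int | None] = {}
    flagged: dict[str, list[str]] = {}
    for attr, crits in answers.items():
        if attr.lower() == "transferability":
            continue  # always the NA marker
        if not crits:
            raise StockToolError(f"attribute {attr!r} has no criterion responses")
        for crit, (st, tr) in crits.items():
            if not (0 <= st <= 5 and 0 <= tr <= 5):
                raise StockToolError(f"{attr}/{crit}: scores must be 0-5, got {(st, tr)}")
        sts = [st for st, _ in crits.values() if st > 0]
        trs = [tr for _, tr in crits.values() if tr > 0]
        indet = [c for c, (st, tr) in crits.items() if st == 0 or tr == 0]
        if indet:
            flagged[attr] = indet
        state[attr] = _round_half_down(float(np.mean(sts))) if sts else None
        trend[attr] = _round_half_down(float(np.mean(trs))) if trs else None
    if not state:
        raise StockToolError("no scorable attributes in responses")
    return SeasaltScore(state, trend, flagged)


# ---------------------------------------------------------------------------
# quota priority table


def quota_priority_table(
    species: dict[str, dict],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank included species for quota implementation.

    ``species`` maps species_id to a dict with keys ``feasibility``
    (:class:`FeasibilityVerdict`), and optionally ``psa``
    (:class:`PsaResult`), ``froese`` (:class:`FroeseResult`) and ``seasalt``
    (:class:`SeasaltScore`). Returns (ranked_included, excluded) frames.

    Ranking keys, in order: ascending PSA vulnerability; descending count of
    Froese indicators at/above target; descending mean SEASALT state. The
    component scores are reported unaggregated alongside the rank.
    """
    if not species:
        raise StockToolError("no species supplied")
    rows, excluded_rows = [], []
    for sid, parts in species.items():
        verdict: FeasibilityVerdict = parts["feasibility"]
        if not verdict.include:
            excluded_rows.append({
                "species_id": sid,
                "reasons": "; ".join(verdict.reasons),
                "indeterminate": verdict.indeterminate,
            })
            continue
        psa: PsaResult | None = parts.get("psa")
        froese: FroeseResult | None = parts.get("froese")
        seasalt: SeasaltScore | None = parts.get("seasalt")
        n_at_target = np.nan
        if froese is not None:
            status = froese_status(froese)
            n_at_target = sum(
                s in ("at_target", "acceptable", "at_harvest_target", "healthy_age_structure")
                for s in status.values()
            )
        rows.append({
            "species_id": sid,
            "vulnerability": psa.vulnerability if psa else np.nan,
            "productivity": psa.productivity if psa else np.nan,
            "susceptibility": psa.susceptibility if psa else np.nan,
            "mean_data_quality": psa.mean_data_quality if psa else np.nan,
            "pct_mature": froese.pct_mature if froese else np.nan,
            "pct_optimal": froese.pct_optimal if froese else np.nan,
            "pct_megaspawners": froese.pct_megaspawners if froese else np.nan,
            "froese_reliability": froese.reliability_flag if froese else "",
            "froese_at_target": n_at_target,
            "seasalt_mean_state": seasalt.mean_state() if seasalt else np.nan,
            "notes": "; ".join(verdict.notes),
        })
    included = pd.DataFrame(rows)
    if not included.empty:
        included = included.sort_values(
            by=["vulnerability", "froese_at_target", "seasalt_mean_state", "species_id"],
            ascending=[True, False, False, True],
            na_position="last",
        ).reset_index(drop=True)
        included.insert(0, "rank", np.arange(1, len(included) + 1))
    excluded = pd.DataFrame(excluded_rows)
    return included, excluded
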