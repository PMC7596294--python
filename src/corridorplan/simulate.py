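"""Surrogate multi-box operating model and trade-off indicators.

Management scenarios — fleet/species fishing-mortality reductions and
refuge closures of spatial boxes — are run on a deliberately simple,
spatially explicit operating model: per box and functional group, annual
logistic biomass growth, harvest as the fraction ``1 - exp(-F)`` of biomass
with F scaled by the scenario's reductions and closures, and proportional
diffusion of biomass between adjacent boxes. The model is a surrogate: it
carries the scenario logic (implementation years, closure schedules,
snapshots 5/10/15 years after refuge start) and the ten ecosystem
indicators, not the biogeochemistry or age structure of a full end-to-end
ecosystem model.

The ten indicators, five of ecosystem structure/resilience and five of
fishery health:

======================  =====================================================
total_biomass           summed biomass, all groups and boxes (t)
biodiversity_q90        Q-90 slope of the cumulative abundance curve
juvenile_proportion     biomass-weighted juvenile fraction of fish groups
mean_trophic_level      biomass-weighted mean trophic level
pelagic_demersal_ratio  pelagic : demersal fish biomass
catch_trophic_level     catch-weighted mean trophic level
max_size_in_catch       largest mean body size among caught groups (kg)
catch_value             Σ price · catch (value units)
total_catch             summed catch, all groups/boxes/fleets (t)
commercial_biomass      summed biomass of commercial groups (t)
======================  =====================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ScenarioError(ValueError):
    """Raised for invalid ecosystem or scenario definitions."""


INDICATOR_NAMES = (
    "total_biomass",
    "biodiversity_q90",
    "juvenile_proportion",
    "mean_trophic_level",
    "pelagic_demersal_ratio",
    "catch_trophic_level",
    "max_size_in_catch",
    "catch_value",
    "total_catch",
    "commercial_biomass",
)

FISH_GUILDS = ("pelagic", "demersal")

#: closure level -> multiplier on fishing mortality inside the box
CLOSURE_FACTORS = {"none": 1.0, "partial": 0.5, "full": 0.0}


@dataclass
class FunctionalGroup:
    """One model group: species aggregated by trophic/life-history similarity."""

    group_id: str
    guild: str  # pelagic | demersal | invertebrate | other
    trophic_level: float
    carrying_capacity: np.ndarray  # tonnes per box
    intrinsic_growth: float  # 1/yr
    mean_weight_kg: float = 1.0
    price: float = 0.0  # value per tonne
    commercial: bool = False
    juvenile_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.carrying_capacity = np.asarray(self.carrying_capacity, dtype=float)
        if self.intrinsic_growth <= 0:
            raise ScenarioError(f"{self.group_id}: intrinsic_growth must be > 0")
        if np.any(self.carrying_capacity <= 0):
            raise ScenarioError(f"{self.group_id}: carrying capacity must be > 0")
        if self.trophic_level < 1:
            raise ScenarioError(f"{self.group_id}: trophic_level must be >= 1")
        if not 0 <= self.juvenile_fraction <= 1:
            raise ScenarioError(f"{self.group_id}: juvenile_fraction must lie in [0, 1]")


@dataclass
class BoxPolygon:
    """One spatial box of the model domain."""

    box_id: int
    area_km2: float
    inside_corridor: bool = False


@dataclass
class Ecosystem:
    """Groups, boxes, adjacency, baseline fishing mortality and movement."""

    groups: list[FunctionalGroup]
    boxes: list[BoxPolygon]
    fleets: list[str]
    base_f: dict[tuple[str, str], float]  # (group_id, fleet) -> F (1/yr)
    adjacency: list[tuple[int, int]] = field(default_factory=list)  # box index pairs
    movement_rate: float = 0.1  # fraction of biomass gradient diffused per yr
    initial_depletion: float = 0.5  # B0 as a fraction of K

    def __post_init__(self) -> None:
        n_boxes = len(self.boxes)
        for g in self.groups:
            if g.carrying_capacity.size != n_boxes:
                raise ScenarioError(
                    f"{g.group_id}: capacity vector length {g.carrying_capacity.size} "
                    f"!= {n_boxes} boxes"
                )
        for f in self.base_f.values():
            if f < 0:
                raise ScenarioError("baseline fishing mortality must be >= 0")
        if not 0 <= self.movement_rate < 0.5:
            raise ScenarioError("movement_rate must lie in [0, 0.5)")

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]


@dataclass
class Scenario:
    """One management scenario: F reductions plus a refuge closure schedule.

    ``f_reductions`` maps (group_id, fleet) to the relative reduction of
    fishing mortality (0.10 = ten percent less F); the wildcard "*" matches
    any group or fleet. ``refuge_network`` maps box_id to a closure level
    ("none" | "partial" | "full") applied per fleet, or to a
    {fleet: level} mapping for gear-specific restrictions.
    """

    name: str
    f_reductions: dict[tuple[str, str], float] = field(default_factory=dict)
    reduction_start_year: int | None = None
    refuge_network: dict[int, object] = field(default_factory=dict)
    refuge_start_year: int | None = None
    horizon: tuple[int, int] = (2008, 2033)

    def __post_init__(self) -> None:
        lo, hi = self.horizon
        if hi < lo:
            raise ScenarioError(f"empty horizon {self.horizon}")
        for red in self.f_reductions.values():
            if not 0 <= red <= 1:
                raise ScenarioError(f"reductions must lie in [0, 1], got {red}")
        for year in (self.reduction_start_year, self.refuge_start_year):
            if year is not None and not lo <= year <= hi:
                raise ScenarioError(f"start year {year} outside horizon {self.horizon}")

    def reduction_for(self, group_id: str, fleet: str) -> float:
        for key in ((group_id, fleet), (group_id, "*"), ("*", fleet), ("*", "*")):
            if key in self.f_reductions:
                return self.f_reductions[key]
        return 0.0

    def closure_for(self, box_id: int, fleet: str) -> str:
        entry = self.refuge_network.get(box_id, "none")
        if isinstance(entry, dict):
            return entry.get(fleet, entry.get("*", "none"))
        return entry


@dataclass
class ScenarioResult:
    """Annual biomass/catch trajectories and indicator vectors."""

    scenario: str
    years: np.ndarray  # (T,)
    biomass: np.ndarray  # (T, n_groups, n_boxes), start-of-year
    catch: np.ndarray  # (T, n_groups, n_boxes, n_fleets), taken during year
    group_ids: list[str]
    fleets: list[str]
    indicators: pd.DataFrame  # index: year, columns: INDICATOR_NAMES
    snapshot_years: list[int]

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise ScenarioError(f"year {year} was not simulated")
        return int(idx[0])


# ---------------------------------------------------------------------------
# dynamics


def _effective_f(ecosystem: Ecosystem, scenario: Scenario, year: int) -> np.ndarray:
    """(n_groups, n_boxes, n_fleets) fishing mortality after scenario rules."""
    n_g, n_b, n_f = len(ecosystem.groups), len(ecosystem.boxes), len(ecosystem.fleets)
    f = np.zeros((n_g, n_b, n_f))
    reducing = scenario.reduction_start_year is not None and year >= scenario.reduction_start_year
    closing = scenario.refuge_start_year is not None and year >= scenario.refuge_start_year
    for gi, g in enumerate(ecosystem.groups):
        for fi, fleet in enumerate(ecosystem.fleets):
            base = ecosystem.base_f.get((g.group_id, fleet), 0.0)
            if reducing:
                base = base * (1.0 - scenario.reduction_for(g.group_id, fleet))
            for bi, box in enumerate(ecosystem.boxes):
                scale = 1.0
                if closing:
                    level = scenario.closure_for(box.box_id, fleet)
                    try:
                        scale = CLOSURE_FACTORS[level]
                    except KeyError:
                        raise ScenarioError(f"unknown closure level {level!r}") from None
                f[gi, bi, fi] = base * scale
    return f


def step_dynamics(
    biomass: np.ndarray,
    ecosystem: Ecosystem,
    scenario: Scenario,
    year: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance biomass one year; returns (next_biomass, catch).

    Order within the year: logistic surplus production on the start-of-year
    biomass, then harvest of the fraction ``1 - exp(-F)`` per fleet, then
    diffusive movement along box adjacencies. Movement follows the depletion
    gradient (B/K), with antisymmetric pairwise fluxes, so it conserves mass
    and never pushes a box above its carrying capacity; with no fishing,
    biomass therefore rises monotonically toward capacity. Catch is exactly
    zero wherever a full closure is in force.
    """
    if np.any(biomass < 0):
        raise ScenarioError("negative biomass state")
    n_g, n_b = biomass.shape
    f = _effective_f(ecosystem, scenario, year)
    r = np.array([g.intrinsic_growth for g in ecosystem.groups])[:, None]
    k = np.stack([g.carrying_capacity for g in ecosystem.groups])
    grown = biomass + r * biomass * (1.0 - biomass / k)
    harvest_frac = 1.0 - np.exp(-f)  # (g, b, fleet)
    total_frac = harvest_frac.sum(axis=2)
    # guard: total harvested fraction cannot exceed available biomass
    total_frac = np.clip(total_frac, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(
            harvest_frac.sum(axis=2, keepdims=True) > 0,
            harvest_frac / np.maximum(harvest_frac.sum(axis=2, keepdims=True), 1e-300),
            0.0,
        )
    catch = grown[:, :, None] * total_frac[:, :, None] * share
    after_catch = grown - catch.sum(axis=2)
    after_catch = np.maximum(after_catch, 0.0)
    # movement: antisymmetric diffusion along the depletion gradient
    moved = after_catch.copy()
    m = ecosystem.movement_rate
    if m > 0:
        depletion = after_catch / k
        for i, j in ecosystem.adjacency:
            cap = np.minimum(k[:, i], k[:, j])
            flux = m * (depletion[:, j] - depletion[:, i]) * cap / 2.0
            moved[:, i] += flux
            moved[:, j] -= flux
        moved = np.maximum(moved, 0.0)
    return moved, catch


def run_scenario(scenario: Scenario, ecosystem: Ecosystem) -> ScenarioResult:
    """Simulate a scenario over its full horizon (inclusive years).

    Fishing-mortality reductions apply from ``reduction_start_year`` onward
    and closures from ``refuge_start_year`` onward, both maintained through
    the end of the simulation. Snapshot years are recorded 5, 10 and 15
    years after the refuge start; snapshots beyond the horizon are truncated
    to the final year with a warning.
    """
    lo, hi = scenario.horizon
    years = np.arange(lo, hi + 1)
    n_g, n_b = len(ecosystem.groups), len(ecosystem.boxes)
    n_f = len(ecosystem.fleets)
    biomass = np.empty((len(years), n_g, n_b))
    catch = np.zeros((len(years), n_g, n_b, n_f))
    k = np.stack([g.carrying_capacity for g in ecosystem.groups])
    state = ecosystem.initial_depletion * k
    for t, year in enumerate(years):
        biomass[t] = state
        state, catch[t] = step_dynamics(state, ecosystem, scenario, int(year))

    snapshots: list[int] = []
    if scenario.refuge_start_year is not None:
        for offset in (5, 10, 15):
            y = scenario.refuge_start_year + offset
            if y > hi:
                warnings.warn(
                    f"snapshot {y} beyond horizon end {hi}; truncated to {hi}",
                    stacklevel=2,
                )
                y = hi
            if y not in snapshots:
                snapshots.append(y)

    rows = [indicator_vector_from_arrays(biomass[t], catch[t], ecosystem) for t in range(len(years))]
    indicators = pd.DataFrame(rows, index=pd.Index(years, name="year"))
    return ScenarioResult(
        scenario=scenario.name,
        years=years,
        biomass=biomass,
        catch=catch,
        group_ids=ecosystem.group_ids,
        fleets=list(ecosystem.fleets),
        indicators=indicators,
        snapshot_years=snapshots,
    )


# ---------------------------------------------------------------------------
# indicators


def q90_statistic(abundances: np.ndarray) -> float:
    """Q-90 biodiversity slope of the cumulative abundance curve.

    Groups are ranked by descending abundance (zero-abundance groups are
    excluded), the cumulative abundance is taken on a log10 scale, and the
    statistic is the slope of the straight line between the curve's values
    at the 10th and 90th percentile ranks (linear interpolation between
    adjacent ranks). A community dominated by few groups saturates the
    curve early and scores near zero; the statistic is maximal for a
    perfectly even community, where it depends only on the number of groups.
    """
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    n = a.size
    if n < 3:
        raise ScenarioError(f"Q-90 needs >= 3 positive-abundance groups, got {n}")
    ranked = np.sort(a)[::-1]
    log_cum = np.log10(np.cumsum(ranked))
    ranks = np.arange(1, n + 1, dtype=float)
    r10 = 1.0 + 0.1 * (n - 1)
    r90 = 1.0 + 0.9 * (n - 1)
    y10 = float(np.interp(r10, ranks, log_cum))
    y90 = float(np.interp(r90, ranks, log_cum))
    return (y90 - y10) / (r90 - r10)


def indicator_vector_from_arrays(
    biomass: np.ndarray, catch: np.ndarray, ecosystem: Ecosystem
) -> dict[str, float]:
    """The ten trade-off indicators from one year's (group, box[, fleet]) arrays."""
    groups = ecosystem.groups
    b_group = biomass.sum(axis=1)  # per group
    c_group = catch.sum(axis=(1, 2))  # per group over boxes and fleets
    total_b = float(b_group.sum())
    total_c = float(c_group.sum())

    tl = np.array([g.trophic_level for g in groups])
    fish = np.array([g.guild in FISH_GUILDS for g in groups])
    pelagic = np.array([g.guild == "pelagic" for g in groups])
    demersal = np.array([g.guild == "demersal" for g in groups])
    juv = np.array([g.juvenile_fraction for g in groups])
    commercial = np.array([g.commercial for g in groups])
    price = np.array([g.price for g in groups])
    size = np.array([g.mean_weight_kg for g in groups])

    fish_b = float(b_group[fish].sum())
    dem_b = float(b_group[demersal].sum())
    out: dict[str, float] = {
        "total_biomass": total_b,
        "biodiversity_q90": q90_statistic(b_group) if (b_group > 0).sum() >= 3 else float("nan"),
        "juvenile_proportion": float((juv[fish] * b_group[fish]).sum() / fish_b)
        if fish_b > 0 else float("nan"),
        "mean_trophic_level": float((tl * b_group).sum() / total_b) if total_b > 0 else float("nan"),
        "pelagic_demersal_ratio": float(b_group[pelagic].sum() / dem_b)
        if dem_b > 0 else float("nan"),
        "catch_trophic_level": float((tl * c_group).sum() / total_c)
        if total_c > 0 else float("nan"),
        "max_size_in_catch": float(size[c_group > 0].max()) if (c_group > 0).any() else 0.0,
        "catch_value": float((price * c_group).sum()),
        "total_catch": total_c,
        "commercial_biomass": float(b_group[commercial].sum()),
    }
    return out


def indicator_vector(result: ScenarioResult, year: int, ecosystem: Ecosystem) -> dict[str, float]:
    """The ten named indicators for one simulated year of a scenario run."""
    t = result.year_index(year)
    return indicator_vector_from_arrays(result.biomass[t], result.catch[t], ecosystem)


def tradeoff_table(
    results: dict[str, ScenarioResult],
    year: int,
    ecosystem: Ecosystem,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Min–max normalize the indicator vectors of several scenarios.

    Returns (raw, normalized, notes): indicator matrices with one row per
    scenario, the normalized one rescaled per indicator to [0, 1] across
    scenarios (the radar-plot scale). An indicator constant across
    scenarios normalizes to 0.5 and is noted.
    """
    if len(results) < 2:
        raise ScenarioError("trade-off comparison needs >= 2 scenarios")
    raw = pd.DataFrame(
        {name: indicator_vector(res, year, ecosystem) for name, res in results.items()}
    ).T
    raw = raw[list(INDICATOR_NAMES)]
    notes: list[str] = []
    norm = raw.copy()
    for col in raw.columns:
        lo, hi = raw[col].min(), raw[col].max()
        if np.isclose(hi, lo) or not np.isfinite(hi - lo):
            norm[col] = 0.5
            notes.append(f"{col}: constant across scenarios; normalized to 0.5")
        else:
            norm[col] = (raw[col] - lo) / (hi - lo)
    return raw, norm, notes


def radar_plot(normalized: pd.DataFrame, path: str, title: str = "Scenario trade-offs") -> None:
    """Write a radar (spider) figure of the normalized indicator matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(normalized.columns)
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for name, row in normalized.iterrows():
        vals = row.to_numpy(dtype=float)
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=str(name))
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
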