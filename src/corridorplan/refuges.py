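"""Biophysical design checks for fishery-refuge networks.

A candidate network of no-take / gear-restricted polygons along a coastal
corridor is screened against seven design principles drawn from marine
reserve network guidance for the Gulf of California:

1. habitat representation — 10–30 % of each representative habitat protected;
2. risk dispersion — at least 3 refuges containing each habitat per
   bioregion (and habitat duplicity of at least 2 within each corridor
   subdivision);
3. coverage of the corridor — every subdivision (50-km sections by default)
   holds at least one refuge, so critical life-history areas are reachable
   throughout;
4. size adequacy and larval connectivity — refuges at least as large as the
   adult home range of each priority species (100 km² rule for fish up to
   167 cm total length), with along-corridor gaps no wider than the larval
   dispersal distance (50–200 km for planktonic larval durations of 2–8
   weeks) and upstream larval sources relative to the prevailing current;
5. recovery time — planned duration of at least 10 years for herbivores/
   planktivores and 25 years for carnivores/piscivores;
6–7. climate-resilient siting and avoidance of impacted areas — supplied as
   boolean suitability rasters intersected with the refuges, since no
   quantitative criterion exists.

Compactness (Polsby–Popper 4πA/P²) is reported per refuge to flag shapes
with excessive edge, with an exemption flag for refuges spanning whole
ecological units such as estuaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry


class RefugeDesignError(ValueError):
    """Raised for violated refuge-design preconditions."""


#: the four regulatory refuge categories (gear/time restriction classes)
REFUGE_CATEGORIES = ("total_permanent", "total_temporal", "partial_permanent", "partial_temporal")

TROPHIC_RECOVERY_YEARS = {
    "herbivore": 10.0,
    "planktivore": 10.0,
    "herbivore/planktivore": 10.0,
    "carnivore": 25.0,
    "piscivore": 25.0,
    "carnivore/piscivore": 25.0,
}

#: larval dispersal rule endpoints: (PLD weeks, distance km)
_PLD_LO, _DIST_LO = 2.0, 50.0
_PLD_HI, _DIST_HI = 8.0, 200.0

#: default minimum refuge size for fish up to this total length
_MAX_TL_CM = 167.0
_DEFAULT_MIN_AREA_KM2 = 100.0


@dataclass
class SpeciesProfile:
    """Life-history record of one priority species."""

    species_id: str
    max_total_length: float | None = None  # cm
    home_range_area: float | None = None  # km²
    pld_weeks: float | None = None
    trophic_class: str | None = None  # herbivore/planktivore | carnivore/piscivore
    spawning_season: str | None = None

    def __post_init__(self) -> None:
        if self.home_range_area is not None and self.home_range_area < 0:
            raise RefugeDesignError(f"{self.species_id}: home_range_area must be >= 0")
        if self.pld_weeks is not None and not 0 <= self.pld_weeks <= 52:
            raise RefugeDesignError(f"{self.species_id}: pld_weeks must lie in [0, 52]")


@dataclass
class RefugePolygon:
    """One candidate refuge: geometry in projected km plus design tags."""

    refuge_id: str
    geometry: Polygon
    category: str = "total_permanent"
    habitats_present: set[str] = field(default_factory=set)
    subregion_id: int = 0
    duration_years: float = math.inf  # planned duration; inf = permanent
    whole_ecological_unit: bool = False  # estuary etc.: compactness exempt

    def __post_init__(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid or self.geometry.area <= 0:
            raise RefugeDesignError(f"refuge {self.refuge_id!r} has degenerate geometry")
        self.habitats_present = set(self.habitats_present)

    @property
    def area_km2(self) -> float:
        return float(self.geometry.area)


@dataclass
class CheckResult:
    """Verdict of one design-principle check."""

    name: str
    passed: bool
    diagnostics: dict

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class NetworkReport:
    """One verdict per checked principle, with diagnostics."""

    checks: dict[str, CheckResult]

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def to_dict(self) -> dict:
        return {
            name: {"passed": c.passed, "diagnostics": c.diagnostics}
            for name, c in self.checks.items()
        }


# ---------------------------------------------------------------------------
# elementary design rules


def subdivide_corridor(corridor_length: float, section_length: float = 50.0) -> list[tuple[float, float]]:
    """Split a corridor of given length (km) into contiguous sections.

    Returns ``ceil(length / section)`` intervals that exactly partition
    [0, corridor_length]; all but possibly the last have ``section_length``.
    """
    if corridor_length <= 0 or section_length <= 0:
        raise RefugeDesignError("corridor_length and section_length must be positive")
    n = math.ceil(corridor_length / section_length)
    bounds = [min(i * section_length, corridor_length) for i in range(n + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(n)]


def min_refuge_area(profile: SpeciesProfile, default_area_km2: float = _DEFAULT_MIN_AREA_KM2) -> float:
    """Minimum adequate refuge area (km²) for one species.

    The species-specific adult home range governs when known; otherwise fish
    up to 167 cm total length fall back to the 100 km² (10-km-long) rule.
    A refuge is adequate for the species iff its area >= this value.
    """
    if profile.home_range_area is not None:
        return float(profile.home_range_area)
    if profile.max_total_length is not None:
        # the 10-km-long / 100 km² guidance covers fish up to 167 cm; larger
        # fish without a home-range estimate still require at least that much
        return float(default_area_km2)
    raise RefugeDesignError(
        f"{profile.species_id}: need home_range_area or max_total_length to size a refuge"
    )


def dispersal_distance(pld_weeks: float) -> float:
    """Average larval dispersal distance (km) from planktonic larval duration.

    Linear between (2 wk, 50 km) and (8 wk, 200 km), clamped to the
    endpoints outside that range.
    """
    if pld_weeks < 0:
        raise RefugeDesignError("pld_weeks must be non-negative")
    t = (pld_weeks - _PLD_LO) / (_PLD_HI - _PLD_LO)
    return float(_DIST_LO + (_DIST_HI - _DIST_LO) * min(max(t, 0.0), 1.0))


def recovery_years(profile: SpeciesProfile) -> float:
    """Minimum protection duration (yr) for full recovery, by trophic class."""
    if profile.trophic_class is None:
        raise RefugeDesignError(f"{profile.species_id}: trophic_class not set")
    key = profile.trophic_class.strip().lower()
    try:
        return TROPHIC_RECOVERY_YEARS[key]
    except KeyError:
        raise RefugeDesignError(
            f"{profile.species_id}: unknown trophic class {profile.trophic_class!r}"
        ) from None


def compactness(geometry: BaseGeometry) -> float:
    """Polsby–Popper shape index 4πA/P² in (0, 1]; 1.0 for a disc."""
    if geometry.is_empty or geometry.length <= 0 or geometry.area <= 0:
        raise RefugeDesignError("degenerate geometry has no compactness")
    return float(4.0 * math.pi * geometry.area / geometry.length**2)


# ---------------------------------------------------------------------------
# network-level checks


def _cell_centers(shape: tuple[int, int], origin: tuple[float, float], resolution: float):
    rows, cols = shape
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * resolution
    # row 0 is the top of the grid
    ys = y0 + (rows - np.arange(rows) - 0.5) * resolution
    return np.meshgrid(xs, ys)


def check_representation(
    network: list[RefugePolygon],
    habitat_rasters: dict[str, np.ndarray],
    lower: float = 0.10,
    upper: float = 0.30,
    origin: tuple[float, float] = (0.0, 0.0),
    resolution: float = 1.0,
    cell_area: float = 1.0,
) -> CheckResult:
    """Protected fraction of each habitat's total area.

    Habitat rasters are boolean/area grids co-registered in the projected km
    frame of the refuge geometry; a cell counts as protected when its center
    falls inside any refuge. Pass iff every habitat reaches the ``lower``
    bound; the ``upper`` bound is reported as guidance only.
    """
    import shapely
    from shapely import unary_union

    fractions: dict[str, float] = {}
    union = unary_union([r.geometry for r in network]) if network else None
    for label, grid in habitat_rasters.items():
        grid = np.asarray(grid, dtype=float)
        total = grid.sum() * cell_area
        if total <= 0:
            raise RefugeDesignError(f"habitat {label!r} has no area")
        if union is None:
            fractions[label] = 0.0
            continue
        xs, ys = _cell_centers(grid.shape, origin, resolution)
        inside = shapely.contains_xy(union, xs, ys)
        fractions[label] = float((grid * inside).sum() * cell_area / total)
    passed = all(f >= lower for f in fractions.values())
    return CheckResult(
        "representation",
        passed,
        {"protected_fraction": fractions, "lower": lower, "upper": upper,
         "above_upper": [h for h, f in fractions.items() if f > upper]},
    )


def check_replication(
    network: list[RefugePolygon],
    habitats: list[str],
    per_bioregion_min: int = 3,
    per_subdivision_min: int = 2,
) -> CheckResult:
    """Count refuges containing each habitat per bioregion (risk dispersion).

    Pass iff every (bioregion, habitat) pair has at least ``per_bioregion_min``
    refuges; within-subdivision habitat duplicity against
    ``per_subdivision_min`` is reported in the diagnostics.
    """
    bioregions = sorted({r.subregion_id for r in network})
    counts = {
        (b, h): sum(1 for r in network if r.subregion_id == b and h in r.habitats_present)
        for b in bioregions
        for h in habitats
    }
    deficits = {f"bioregion {b} / {h}": c for (b, h), c in counts.items() if c < per_bioregion_min}
    duplicity_gaps = {
        f"subdivision {b} / {h}": c for (b, h), c in counts.items() if c < per_subdivision_min
    }
    passed = bool(network) and not deficits
    return CheckResult(
        "replication",
        passed,
        {
            "counts": {f"{b}/{h}": c for (b, h), c in counts.items()},
            "per_bioregion_min": per_bioregion_min,
            "deficits": deficits,
            "per_subdivision_min": per_subdivision_min,
            "subdivision_duplicity_gaps": duplicity_gaps,
        },
    )


def along_corridor_position(refuge: RefugePolygon, baseline: LineString) -> float:
    """Corridor coordinate (km) of a refuge: its centroid projected onto the baseline."""
    return float(baseline.project(refuge.geometry.centroid))


def check_connectivity(
    network: list[RefugePolygon],
    profiles: list[SpeciesProfile],
    baseline: LineString,
    current_direction: str = "upstream_low",
    section_length: float = 50.0,
) -> CheckResult:
    """Larval connectivity along the corridor.

    For every species with a planktonic larval duration the nearest-neighbor
    gaps between refuge positions along the corridor baseline must not
    exceed the species' dispersal distance, and each corridor subdivision
    must have at least one refuge upstream of its midpoint so larval sources
    exist under the prevailing current. ``current_direction`` states where
    upstream lies: ``"upstream_low"`` (sources at lower corridor coordinate,
    e.g. south of a northward current) or ``"upstream_high"``.
    """
    if current_direction not in ("upstream_low", "upstream_high"):
        raise RefugeDesignError(f"unknown current_direction {current_direction!r}")
    if not network:
        return CheckResult("connectivity", False, {"reason": "no refuges in network"})
    positions = sorted(along_corridor_position(r, baseline) for r in network)
    gaps = [b - a for a, b in zip(positions, positions[1:])]
    max_gap = max(gaps) if gaps else 0.0

    species_verdicts: dict[str, dict] = {}
    corridor_length = float(baseline.length)
    sections = subdivide_corridor(corridor_length, section_length)
    upstream_gaps = []
    for lo, hi in sections:
        mid = (lo + hi) / 2
        if current_direction == "upstream_low":
            has_source = any(p <= mid for p in positions)
        else:
            has_source = any(p >= mid for p in positions)
        if not has_source:
            upstream_gaps.append((lo, hi))

    for p in profiles:
        if p.pld_weeks is None:
            continue
        reach = dispersal_distance(p.pld_weeks)
        species_verdicts[p.species_id] = {
            "dispersal_km": reach,
            "max_gap_km": max_gap,
            "gaps_ok": max_gap <= reach,
            "upstream_ok": not upstream_gaps,
        }
    passed = bool(species_verdicts) and all(
        v["gaps_ok"] and v["upstream_ok"] for v in species_verdicts.values()
    )
    return CheckResult(
        "connectivity",
        passed,
        {"positions_km": positions, "species": species_verdicts,
         "subdivisions_without_upstream_source": upstream_gaps},
    )


def check_size_adequacy(network: list[RefugePolygon], profiles: list[SpeciesProfile]) -> CheckResult:
    """Each species must find at least one refuge at least as large as its
    home range (or the 100 km² fallback); undersized refuges are listed."""
    per_species: dict[str, dict] = {}
    for p in profiles:
        need = min_refuge_area(p)
        adequate = [r.refuge_id for r in network if r.area_km2 >= need]
        undersized = [r.refuge_id for r in network if r.area_km2 < need]
        per_species[p.species_id] = {
            "min_area_km2": need,
            "adequate_refuges": adequate,
            "undersized_refuges": undersized,
        }
    passed = bool(network) and all(v["adequate_refuges"] for v in per_species.values())
    return CheckResult("size_adequacy", passed, {"species": per_species})


def check_coverage(
    network: list[RefugePolygon],
    baseline: LineString,
    section_length: float = 50.0,
) -> CheckResult:
    """Every corridor subdivision must contain at least one refuge."""
    sections = subdivide_corridor(float(baseline.length), section_length)
    positions = [along_corridor_position(r, baseline) for r in network]
    empty = [
        (lo, hi) for lo, hi in sections if not any(lo <= p <= hi for p in positions)
    ]
    return CheckResult(
        "coverage",
        not empty,
        {"sections_km": sections, "empty_sections": empty},
    )


def check_recovery(network: list[RefugePolygon], profiles: list[SpeciesProfile]) -> CheckResult:
    """Planned refuge durations vs trophic-class recovery requirements.

    A species is served when at least one refuge is planned to last at least
    its required recovery time; refuges falling short are flagged.
    """
    per_species: dict[str, dict] = {}
    for p in profiles:
        if p.trophic_class is None:
            continue
        need = recovery_years(p)
        ok = [r.refuge_id for r in network if r.duration_years >= need]
        short = [r.refuge_id for r in network if r.duration_years < need]
        per_species[p.species_id] = {
            "required_years": need,
            "sufficient_refuges": ok,
            "insufficient_refuges": short,
        }
    passed = bool(per_species) and all(v["sufficient_refuges"] for v in per_species.values())
    return CheckResult("recovery", passed, {"species": per_species})


def check_compactness(network: list[RefugePolygon], warn_below: float = 0.3) -> CheckResult:
    """Polsby–Popper compactness per refuge against a warning threshold.

    Refuges marked as whole ecological units (estuaries) are exempt.
    """
    indices = {r.refuge_id: compactness(r.geometry) for r in network}
    flagged = [
        rid for rid, c in indices.items()
        if c < warn_below and not next(r for r in network if r.refuge_id == rid).whole_ecological_unit
    ]
    return CheckResult(
        "compactness",
        not flagged,
        {"polsby_popper": indices, "warn_below": warn_below, "flagged": flagged},
    )


def check_suitability(
    network: list[RefugePolygon],
    suitable: np.ndarray,
    name: str,
    origin: tuple[float, float] = (0.0, 0.0),
    resolution: float = 1.0,
    min_fraction: float = 0.5,
) -> CheckResult:
    """Fraction of each refuge lying on user-supplied suitable cells.

    Implements the climate-resilience and avoid-impacted-areas principles:
    each refuge must have at least ``min_fraction`` of its sampled cell
    centers on suitable (truthy) cells.
    """
    import shapely

    grid = np.asarray(suitable, dtype=bool)
    xs, ys = _cell_centers(grid.shape, origin, resolution)
    fractions: dict[str, float] = {}
    for r in network:
        inside = shapely.contains_xy(r.geometry, xs, ys)
        n_in = int(inside.sum())
        fractions[r.refuge_id] = float((grid & inside).sum() / n_in) if n_in else 0.0
    flagged = [rid for rid, f in fractions.items() if f < min_fraction]
    return CheckResult(name, not flagged, {"suitable_fraction": fractions, "flagged": flagged})


def check_network(
    network: list[RefugePolygon],
    profiles: list[SpeciesProfile],
    habitat_rasters: dict[str, np.ndarray],
    baseline: LineString,
    origin: tuple[float, float] = (0.0, 0.0),
    resolution: float = 1.0,
    cell_area: float = 1.0,
    section_length: float = 50.0,
    current_direction: str = "upstream_low",
    climate_suitable: np.ndarray | None = None,
    unimpacted: np.ndarray | None = None,
) -> NetworkReport:
    """Run every design-principle check and assemble a NetworkReport.

    The seven core verdicts are representation, replication, coverage,
    size_adequacy, connectivity, recovery, and compactness; climate and
    impact suitability checks join the report when their rasters are given.
    """
    checks = {}
    for c in (
        check_representation(network, habitat_rasters, origin=origin,
                             resolution=resolution, cell_area=cell_area),
        check_replication(network, sorted(habitat_rasters)),
        check_coverage(network, baseline, section_length),
        check_size_adequacy(network, profiles),
        check_connectivity(network, profiles, baseline, current_direction, section_length),
        check_recovery(network, profiles),
        check_compactness(network),
    ):
        checks[c.name] = c
    if climate_suitable is not None:
        c = check_suitability(network, climate_suitable, "climate_resilience",
                              origin, resolution)
        checks[c.name] = c
    if unimpacted is not None:
        c = check_suitability(network, unimpacted, "avoid_impacted_areas",
                              origin, resolution)
        checks[c.name] = c
    return NetworkReport(checks)
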