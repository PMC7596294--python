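"""Deterministic synthetic inputs for every planning tool.

Nothing here is observed data: the generators emulate the *shape* of the
corridor planning inputs — smooth species-distribution probability fields,
log-normal fishing intensity, legally excluded blocks, truncated-normal
catch length-frequencies, and a small multi-box ecosystem — so the whole
toolbox runs end-to-end from a seed. The bundled species tables carry the
published life-history anchor values for the eleven corridor priority
species (adult home ranges, maximum ages, ages at first maturity), which
are the only non-synthetic numbers in the module.

All generators are pure functions of their arguments; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import LineString, box

from corridorplan.landscape import CostLayer, FeatureLayer, Landscape
from corridorplan.refuges import RefugePolygon, SpeciesProfile
from corridorplan.simulate import BoxPolygon, Ecosystem, FunctionalGroup
from corridorplan.stocks import LengthSample


class FixtureError(ValueError):
    """Raised for invalid fixture specifications."""


# ---------------------------------------------------------------------------
# bundled species tables (published anchor values; everything else synthetic)

#: adult home-range areas (km²) of the eight priority fish species
HOME_RANGES_KM2 = {
    "gulf_coney": 178.7,
    "gold_spotted_sand_bass": 6.7,
    "gulf_croaker": 1.08,
    "flatfish": 3.92,
    "brown_smooth_hound_shark": 19.80,
    "pacific_angel_shark": 71.7,
    "guitarfish": 106.7,
    "banded_guitarfish": 16.89,
}


def species_profiles() -> pd.DataFrame:
    """Profiles of the corridor priority species.

    Home-range areas are the published estimates; maximum lengths, larval
    durations, and trophic classes are plausible synthetic stand-ins chosen
    to exercise the design rules (PLDs span the 2–8 week dispersal range).
    """
    rows = [
        # species_id, max TL cm, home range km², pld wk, trophic class
        ("gulf_coney", 110.0, 178.7, 4.0, "carnivore/piscivore"),
        ("gold_spotted_sand_bass", 65.0, 6.7, 3.0, "carnivore/piscivore"),
        ("gulf_croaker", 35.0, 1.08, 3.0, "carnivore/piscivore"),
        ("flatfish", 50.0, 3.92, 2.0, "carnivore/piscivore"),
        ("brown_smooth_hound_shark", 110.0, 19.80, None, "carnivore/piscivore"),
        ("pacific_angel_shark", 120.0, 71.7, None, "carnivore/piscivore"),
        ("guitarfish", 140.0, 106.7, None, "carnivore/piscivore"),
        ("banded_guitarfish", 100.0, 16.89, None, "carnivore/piscivore"),
        ("pink_murex_snail", 15.0, None, 2.0, "herbivore/planktivore"),
        ("black_murex_snail", 15.0, None, 2.0, "herbivore/planktivore"),
        ("brown_crab", 18.0, None, 5.0, "carnivore/piscivore"),
    ]
    return pd.DataFrame(
        rows,
        columns=["species_id", "max_total_length_cm", "home_range_km2",
                 "pld_weeks", "trophic_class"],
    )


def life_history_table() -> pd.DataFrame:
    """Quota-feasibility life-history table for the eleven priority species.

    Ranged published values are collapsed to a single number: maximum ages
    keep the upper bound (a stock is long-lived if it *can* reach that age),
    ages at first maturity keep the lower bound (a range only clearly
    signals late maturity if even its early end does). Missing entries are
    NaN.
    """
    rows = [
        # species_id, movement, max_age, age_first_maturity, multispecies?
        ("pink_murex_snail", "sedentary", 5, 2, False),
        ("black_murex_snail", "sedentary", 5, None, False),
        ("brown_crab", None, 8, 1, False),
        ("flatfish", None, None, None, True),
        ("pacific_angel_shark", "coastal", None, None, False),
        ("banded_guitarfish", "coastal", None, None, False),
        ("guitarfish", None, 16, 5, False),
        ("gulf_coney", None, 28, 7, False),
        ("gold_spotted_sand_bass", None, 24, 4, False),
        ("gulf_croaker", None, 10, None, False),
        ("brown_smooth_hound_shark", None, 14, 3, False),
    ]
    return pd.DataFrame(
        rows,
        columns=["species_id", "movement", "max_age", "age_first_maturity", "multispecies"],
    )


def profiles_from_frame(df: pd.DataFrame) -> list[SpeciesProfile]:
    """Typed SpeciesProfile records from a species_profiles-shaped frame."""
    out = []
    for _, r in df.iterrows():
        out.append(SpeciesProfile(
            species_id=str(r["species_id"]),
            max_total_length=_opt(r.get("max_total_length_cm")),
            home_range_area=_opt(r.get("home_range_km2")),
            pld_weeks=_opt(r.get("pld_weeks")),
            trophic_class=r.get("trophic_class") if isinstance(r.get("trophic_class"), str) else None,
        ))
    return out


def _opt(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


# ---------------------------------------------------------------------------
# raster landscape


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic raster landscape."""

    seed: int = 0
    grid_shape: tuple[int, int] = (20, 40)
    n_features: int = 3
    smooth_sigma: float = 2.0  # Gaussian kernel width (cells) of the SDM fields
    cost_sigma: float = 0.75  # log-sd of the log-normal fishing-intensity cost
    exclusion_fraction: float = 0.1  # fraction of cells legally excluded
    cell_area: float = 4.0  # km² (2-km cells)
    resolution: float = 2.0  # km


def make_landscape(spec: LandscapeSpec) -> Landscape:
    """Smooth positive feature fields + log-normal cost + exclusion block.

    Feature occurrence layers are Gaussian-kernel-smoothed uniform noise
    (smooth, strictly positive — the character of species-distribution
    probability surfaces); the cost layer is log-normal fishing intensity;
    the exclusion mask removes the stated exact fraction of cells as a
    leading row-major band (existing management instruments).
    """
    rows, cols = spec.grid_shape
    if rows <= 0 or cols <= 0:
        raise FixtureError(f"grid_shape must be positive, got {spec.grid_shape}")
    if not 0 <= spec.exclusion_fraction < 1:
        raise FixtureError("exclusion_fraction must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    features = []
    for j in range(spec.n_features):
        noise = rng.uniform(0.05, 1.0, size=(rows, cols))
        field_ = ndimage.gaussian_filter(noise, spec.smooth_sigma, mode="nearest")
        features.append(FeatureLayer(f"sdm_{j}", 1.0, field_))
    cost = np.exp(rng.normal(0.0, spec.cost_sigma, size=(rows, cols)))
    n = rows * cols
    k = int(round(spec.exclusion_fraction * n))
    valid = np.ones(n, dtype=bool)
    valid[:k] = False  # leading band: legally excluded cells
    return Landscape(
        features=features,
        cost=CostLayer(cost),
        valid_mask=valid.reshape(rows, cols),
        cell_area=spec.cell_area,
        resolution=spec.resolution,
    )


# ---------------------------------------------------------------------------
# length-frequency samples


def make_length_sample(
    species_id: str,
    l_mat: float,
    l_opt: float,
    l_max: float,
    n: int,
    seed: int = 0,
    mean: float | None = None,
    sd: float | None = None,
) -> LengthSample:
    """Truncated-normal catch lengths on (0, l_max].

    Defaults center the catch on the optimum harvest length with a 25 %
    coefficient of variation; the generating parameters are recoverable
    from the arguments for parameter-recovery tests.
    """
    if not l_mat < l_opt < l_max:
        raise FixtureError(f"need l_mat < l_opt < l_max, got {(l_mat, l_opt, l_max)}")
    if n < 1:
        raise FixtureError("n must be >= 1")
    mean = l_opt if mean is None else mean
    sd = 0.25 * l_opt if sd is None else sd
    a, b = (0.0 - mean) / sd, (l_max - mean) / sd
    rng = np.random.default_rng(seed)
    lengths = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    lengths = np.clip(lengths, np.nextafter(0.0, 1.0), l_max)
    return LengthSample(species_id, lengths, l_mat, l_opt, l_max)


# ---------------------------------------------------------------------------
# refuge network demo

CORRIDOR_LENGTH_KM = 200.0
CORRIDOR_WIDTH_KM = 20.0
HABITATS = ("rocky", "sandy_muddy", "rhodolith", "mangrove", "wetland")


def corridor_baseline() -> LineString:
    """200-km straight corridor baseline in projected km."""
    return LineString([(0.0, 0.0), (CORRIDOR_LENGTH_KM, 0.0)])


def habitat_rasters(resolution: float = 2.0) -> dict[str, np.ndarray]:
    """Five habitat presence grids as across-corridor stripes.

    Habitats alternate in bands of rows so every full-width refuge contains
    all of them; grids are co-registered with the corridor frame (origin at
    (0, 0), y spanning the corridor width).
    """
    rows = int(CORRIDOR_WIDTH_KM / resolution)
    cols = int(CORRIDOR_LENGTH_KM / resolution)
    out = {}
    for i, label in enumerate(HABITATS):
        grid = np.zeros((rows, cols))
        grid[i * rows // len(HABITATS):(i + 1) * rows // len(HABITATS), :] = 1.0
        out[label] = grid
    return out


def demo_network() -> list[RefugePolygon]:
    """Twelve-refuge demo network along the corridor, three per 50-km section.

    Each section holds one large refuge (adequate for the widest-ranging
    species) and two smaller ones; every refuge spans the corridor width so
    all habitats are represented, and gaps stay below the shortest larval
    dispersal distance.
    """
    refuges = []
    for s in range(4):
        x0 = s * 50.0
        spans = [(x0 + 2.0, 12.0), (x0 + 22.0, 4.0), (x0 + 38.0, 4.0)]
        for i, (start, length) in enumerate(spans):
            refuges.append(RefugePolygon(
                refuge_id=f"R{s + 1}{chr(ord('a') + i)}",
                geometry=box(start, 0.0, start + length, CORRIDOR_WIDTH_KM),
                category="total_permanent" if i == 0 else "partial_permanent",
                habitats_present=set(HABITATS),
                subregion_id=s + 1,
            ))
    return refuges


# ---------------------------------------------------------------------------
# ecosystem


@dataclass
class EcosystemSpec:
    """Parameters of the synthetic multi-box ecosystem."""

    seed: int = 0
    n_boxes: int = 8
    n_corridor_boxes: int = 4
    movement_rate: float = 0.1
    initial_depletion: float = 0.5
    base_f: float = 0.25  # fleet-summed fishing mortality on fished groups (1/yr)


#: group_id, guild, trophic level, total K (kt), r (1/yr), mean wt (kg), price, commercial, juvenile frac
_GROUP_TABLE = [
    ("small_pelagics", "pelagic", 2.8, 400.0, 0.80, 0.05, 300.0, True, 0.35),
    ("medium_pelagics", "pelagic", 3.6, 120.0, 0.45, 2.0, 900.0, True, 0.25),
    ("large_pelagics", "pelagic", 4.3, 60.0, 0.30, 25.0, 1800.0, True, 0.15),
    ("coastal_sciaenids", "demersal", 3.5, 90.0, 0.40, 1.5, 1200.0, True, 0.30),
    ("serranids", "demersal", 4.0, 50.0, 0.25, 8.0, 2500.0, True, 0.20),
    ("flatfishes", "demersal", 3.2, 40.0, 0.35, 1.0, 1000.0, True, 0.30),
    ("small_demersals", "demersal", 2.9, 150.0, 0.70, 0.2, 200.0, False, 0.40),
    ("elasmobranchs", "demersal", 4.1, 45.0, 0.15, 30.0, 800.0, True, 0.15),
    ("murex_snails", "invertebrate", 2.2, 70.0, 0.60, 0.3, 1500.0, True, 0.20),
    ("crabs", "invertebrate", 2.5, 80.0, 0.65, 0.4, 1100.0, True, 0.25),
    ("bivalves", "invertebrate", 2.0, 120.0, 0.55, 0.1, 600.0, False, 0.30),
    ("macrofauna_other", "other", 2.3, 200.0, 0.75, 0.05, 0.0, False, 0.35),
]

FLEETS = ("gillnet", "longline")


def make_ecosystem(spec: EcosystemSpec | None = None) -> Ecosystem:
    """Twelve functional groups on a line of boxes with a corridor subset.

    Guilds span pelagic, demersal and invertebrate groups over trophic
    levels 2–4.3; carrying capacity is split across boxes with a mild
    seeded spatial gradient; commercial groups carry a baseline fishing
    mortality split across two gear fleets.
    """
    spec = spec or EcosystemSpec()
    if spec.n_boxes < 2 or not 0 < spec.n_corridor_boxes <= spec.n_boxes:
        raise FixtureError("need >= 2 boxes and a non-empty corridor subset")
    rng = np.random.default_rng(spec.seed)
    boxes = [
        BoxPolygon(box_id=i, area_km2=500.0, inside_corridor=i < spec.n_corridor_boxes)
        for i in range(spec.n_boxes)
    ]
    groups = []
    for gid, guild, tl, ktot, r, wt, price, comm, juv in _GROUP_TABLE:
        shares = rng.dirichlet(np.full(spec.n_boxes, 20.0))
        groups.append(FunctionalGroup(
            group_id=gid, guild=guild, trophic_level=tl,
            carrying_capacity=1000.0 * ktot * shares,  # tonnes
            intrinsic_growth=r, mean_weight_kg=wt, price=price,
            commercial=comm, juvenile_fraction=juv,
        ))
    base_f = {}
    for g in groups:
        if g.commercial:
            base_f[(g.group_id, "gillnet")] = 0.7 * spec.base_f
            base_f[(g.group_id, "longline")] = 0.3 * spec.base_f
    adjacency = [(i, i + 1) for i in range(spec.n_boxes - 1)]
    return Ecosystem(
        groups=groups,
        boxes=boxes,
        fleets=list(FLEETS),
        base_f=base_f,
        adjacency=adjacency,
        movement_rate=spec.movement_rate,
        initial_depletion=spec.initial_depletion,
    )
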