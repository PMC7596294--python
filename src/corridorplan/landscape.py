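"""Raster landscape containers for spatial prioritization.

A :class:`Landscape` stacks co-registered 2-D grids: one occurrence layer per
biodiversity/use feature (each with a non-negative importance weight), one
strictly positive cost layer, and a boolean validity mask marking the cells
eligible for ranking (sea cells not excluded by law or NODATA).

Cells are addressed by 0-based row-major flat indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class LandscapeError(ValueError):
    """Raised for violated landscape preconditions (shape, sign, mask)."""


@dataclass
class FeatureLayer:
    """One conservation feature: an occurrence grid and its weight.

    ``occurrence`` holds the level of occurrence of the feature in each cell
    (probability of presence, standardized abundance — arbitrary non-negative
    units); ``weight`` expresses the feature's relative importance in the
    marginal-loss formula.
    """

    feature_id: str
    weight: float
    occurrence: np.ndarray

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=float)
        if self.occurrence.ndim != 2:
            raise LandscapeError(f"occurrence grid for {self.feature_id!r} must be 2-D")
        if self.weight < 0:
            raise LandscapeError(f"feature weight must be >= 0, got {self.weight}")
        if np.any(self.occurrence < 0):
            raise LandscapeError(f"negative occurrence in feature {self.feature_id!r}")
        if self.weight > 0 and not np.any(self.occurrence > 0):
            raise LandscapeError(
                f"feature {self.feature_id!r} has positive weight but no positive cell"
            )


@dataclass
class CostLayer:
    """Per-cell cost of retaining the cell in the priority network."""

    cost: np.ndarray

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.ndim != 2:
            raise LandscapeError("cost grid must be 2-D")


@dataclass
class Landscape:
    """Co-registered stack of feature layers, cost, and validity mask.

    Parameters
    ----------
    features
        Ordered feature layers; all grids must share one shape.
    cost
        Strictly positive on every valid cell. ``None`` means uniform cost 1.
    valid_mask
        Boolean grid of rankable cells. ``None`` means all cells valid.
    cell_area
        Area of one grid cell in km².
    origin, resolution
        Georeferencing: (x, y) of the lower-left corner and cell size, used
        when writing ESRI ASCII grids.
    """

    features: list[FeatureLayer]
    cost: CostLayer | None = None
    valid_mask: np.ndarray | None = None
    cell_area: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: float = 1.0
    _shape: tuple[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.features:
            raise LandscapeError("a Landscape needs at least one feature layer")
        shape = self.features[0].occurrence.shape
        for f in self.features:
            if f.occurrence.shape != shape:
                raise LandscapeError(
                    f"feature {f.feature_id!r} shape {f.occurrence.shape} != {shape}"
                )
        if self.cost is None:
            self.cost = CostLayer(np.ones(shape))
        if self.cost.cost.shape != shape:
            raise LandscapeError("cost grid shape differs from feature grids")
        if self.valid_mask is None:
            self.valid_mask = np.ones(shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != shape:
                raise LandscapeError("valid_mask shape differs from feature grids")
        if self.cell_area <= 0:
            raise LandscapeError("cell_area must be positive")
        # NODATA / non-finite cells are never rankable
        finite = np.isfinite(self.cost.cost)
        for f in self.features:
            finite &= np.isfinite(f.occurrence)
        self.valid_mask = self.valid_mask & finite
        if np.any(self.cost.cost[self.valid_mask] <= 0):
            raise LandscapeError("cost must be strictly positive on valid cells")
        self._shape = shape

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self._shape))

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_indices(self) -> np.ndarray:
        """Row-major flat indices of valid cells, ascending."""
        return np.flatnonzero(self.valid_mask.ravel())

    def occurrence_matrix(self) -> np.ndarray:
        """(n_features, n_cells) matrix of flattened occurrence grids."""
        return np.stack([f.occurrence.ravel() for f in self.features])

    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.features], dtype=float)
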