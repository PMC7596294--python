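"""Core-area greedy cell-removal prioritization.

The ranking starts from the full landscape and repeatedly removes the cell
whose loss costs the least, where the marginal loss of cell *i* over the
remaining set *S* is scored by its single most valuable feature:

    delta_i = max_j  w_j * Q_ij(S) / c_i,
    Q_ij(S) = p_ij / sum_{k in S} p_kj

with ``w_j`` the feature weight, ``p_ij`` the occurrence of feature *j* in
cell *i*, and ``c_i`` the cell cost. Because ``Q`` renormalizes over the
shrinking remaining set, cells holding the last of any weighted feature grow
arbitrarily valuable — the rule retains high-quality core areas for every
feature, including rare ones. Ties are broken by removing the lowest
row-major index first, so rankings are fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from corridorplan.landscape import CostLayer, FeatureLayer, Landscape, LandscapeError


@dataclass
class PriorityRanking:
    """Full removal order of the valid cells of one landscape.

    Attributes
    ----------
    removal_order
        Flat cell indices, first removed (lowest priority) first.
    marginal_loss_at_removal
        delta of each cell at the iteration it was removed.
    rank_raster
        Grid of ranks in (0, 1]; higher values were retained longer. Invalid
        cells are NaN.
    shape
        Grid shape of the source landscape.
    """

    removal_order: np.ndarray
    marginal_loss_at_removal: np.ndarray
    rank_raster: np.ndarray
    shape: tuple[int, int]

    @property
    def n_valid(self) -> int:
        return len(self.removal_order)


def marginal_loss(landscape: Landscape, remaining: set[int] | np.ndarray, cell: int) -> float:
    """Marginal loss delta of removing ``cell`` from the ``remaining`` set.

    Features whose total occurrence over ``remaining`` is zero are skipped;
    if every feature total is zero the loss is 0 (with a warning).
    """
    remaining_idx = np.asarray(sorted(remaining), dtype=int)
    if remaining_idx.size == 0:
        raise LandscapeError("remaining set is empty")
    if cell not in set(remaining_idx.tolist()):
        raise LandscapeError(f"cell {cell} is not in the remaining set")
    occ = landscape.occurrence_matrix()
    w = landscape.weights()
    totals = occ[:, remaining_idx].sum(axis=1)
    live = totals > 0
    if not live.any():
        warnings.warn("all feature totals are zero over the remaining set", stacklevel=2)
        return 0.0
    q = occ[live, cell] / totals[live]
    c = landscape.cost.cost.ravel()[cell]
    return float(np.max(w[live] * q) / c)


def rank_landscape(landscape: Landscape, tie_break: str = "row-major") -> PriorityRanking:
    """Rank every valid cell by greedy minimal-marginal-loss removal.

    At each iteration the proportions ``Q`` are recomputed over the shrinking
    remaining set and the valid cell with smallest delta is removed (one cell
    per iteration); ``tie_break="row-major"`` removes the lowest flat index
    among tied minima.
    """
    if tie_break != "row-major":
        raise ValueError(f"unknown tie_break policy {tie_break!r}")
    valid = landscape.valid_indices()
    if valid.size == 0:
        raise LandscapeError("landscape has no valid cells")
    w = landscape.weights()
    if not np.any(w > 0):
        raise LandscapeError("landscape has no feature with positive weight")
    occ = landscape.occurrence_matrix()[:, valid]  # (F, n_valid)
    cost = landscape.cost.cost.ravel()[valid]

    n = valid.size
    alive = np.ones(n, dtype=bool)
    totals = occ.sum(axis=1)
    order = np.empty(n, dtype=int)
    losses = np.empty(n, dtype=float)

    warned = False
    for step in range(n):
        live_f = totals > 0
        if live_f.any():
            # delta over alive cells: max_j w_j p_ij / (total_j c_i)
            scaled = (w[live_f] / totals[live_f])[:, None] * occ[live_f][:, alive]
            delta = scaled.max(axis=0) / cost[alive]
        else:
            if not warned:
                warnings.warn(
                    "all feature totals zero; remaining cells removed in index order",
                    stacklevel=2,
                )
                warned = True
            delta = np.zeros(int(alive.sum()))
        alive_idx = np.flatnonzero(alive)
        pos = int(np.argmin(delta))  # first minimum: row-major tie-break
        pick = alive_idx[pos]
        order[step] = pick
        losses[step] = float(delta[pos])
        alive[pick] = False
        totals = totals - occ[:, pick]
        totals[totals < 0] = 0.0  # guard rounding

    removal_order = valid[order]
    rank_raster = np.full(landscape.n_cells, np.nan)
    rank_raster[removal_order] = (np.arange(n) + 1) / n
    return PriorityRanking(
        removal_order=removal_order,
        marginal_loss_at_removal=losses,
        rank_raster=rank_raster.reshape(landscape.shape),
        shape=landscape.shape,
    )


def top_fraction_mask(ranking: PriorityRanking, fraction: float) -> np.ndarray:
    """Boolean grid of the best ``fraction`` of valid cells (removed last).

    The mask holds exactly ``ceil(fraction * n_valid)`` cells; masks are
    nested across fractions because they are suffixes of one removal order.
    """
    if not 0 < fraction <= 1:
        raise LandscapeError(f"fraction must be in (0, 1], got {fraction}")
    n = ranking.n_valid
    k = int(np.ceil(fraction * n))
    mask = np.zeros(int(np.prod(ranking.shape)), dtype=bool)
    mask[ranking.removal_order[n - k:]] = True
    return mask.reshape(ranking.shape)


def retention_curves(landscape: Landscape, ranking: PriorityRanking) -> dict[str, np.ndarray]:
    """Per-feature retention as cells are removed in ranking order.

    Returns, per feature, an array of length ``n_valid + 1``: entry ``k`` is
    the proportion of the feature's total occurrence still present after the
    first ``k`` removals. Curves start at 1.0, end at 0.0 (for occurrence
    wholly on valid cells) and are non-increasing.
    """
    if ranking.shape != landscape.shape:
        raise LandscapeError("ranking does not match landscape shape")
    occ = landscape.occurrence_matrix()
    valid_total = occ[:, landscape.valid_indices()].sum(axis=1)
    curves: dict[str, np.ndarray] = {}
    for j, layer in enumerate(landscape.features):
        if valid_total[j] == 0:
            curves[layer.feature_id] = np.ones(ranking.n_valid + 1)
            continue
        removed = np.concatenate([[0.0], np.cumsum(occ[j, ranking.removal_order])])
        curves[layer.feature_id] = np.clip(1.0 - removed / valid_total[j], 0.0, 1.0)
    return curves


def apply_criteria_stack(
    criteria: list[dict],
    base: Landscape | None = None,
    cell_area: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    resolution: float = 1.0,
) -> Landscape:
    """Build a Landscape from an ordered criteria stack.

    Each criterion is a dict with keys ``name``, ``grid`` (2-D array),
    ``role`` in {"feature", "cost", "exclusion"}, and optionally ``weight``
    or ``rank`` (1 = most important). Feature criteria without explicit
    weights get geometric weights 2**(R - r) from their importance rank, so
    a higher-priority criterion always outweighs any lower one. Exclusion
    criteria (truthy cells = disallowed by an existing management
    instrument) are removed from the validity mask; cost criteria multiply
    into the cost layer. When ``base`` is given its layers, cost, mask and
    georeferencing seed the stack; an empty criteria list then returns a
    Landscape equal to the base (validity unchanged).
    """
    shape = base.shape if base is not None else None
    for c in criteria:
        g = np.asarray(c["grid"], dtype=float)
        if shape is None:
            shape = g.shape
        elif g.shape != shape:
            raise LandscapeError(
                f"criterion {c.get('name')!r} shape {g.shape} conflicts with {shape}"
            )
    if shape is None:
        raise LandscapeError("criteria stack is empty and no base landscape was given")

    feats = [c for c in criteria if c["role"] == "feature"]
    ranked = [c for c in feats if "weight" not in c]
    ranks = [c.get("rank", i + 1) for i, c in enumerate(ranked)]
    big_r = max(ranks) if ranks else 0

    layers: list[FeatureLayer] = []
    if base is not None:
        layers.extend(FeatureLayer(f.feature_id, f.weight, f.occurrence.copy())
                      for f in base.features)
    for i, c in enumerate(feats):
        if "weight" in c:
            w = float(c["weight"])
        else:
            r = c.get("rank", ranked.index(c) + 1)
            w = float(2 ** (big_r - r))
        layers.append(FeatureLayer(c.get("name", f"criterion_{i}"), w, np.asarray(c["grid"], float)))

    cost = base.cost.cost.copy() if base is not None else np.ones(shape)
    for c in criteria:
        if c["role"] == "cost":
            cost = cost * np.asarray(c["grid"], dtype=float)

    valid = base.valid_mask.copy() if base is not None else np.ones(shape, dtype=bool)
    for c in criteria:
        if c["role"] == "exclusion":
            valid &= ~(np.asarray(c["grid"]) > 0)

    return Landscape(
        features=layers,
        cost=CostLayer(cost),
        valid_mask=valid,
        cell_area=base.cell_area if base is not None else cell_area,
        origin=base.origin if base is not None else origin,
        resolution=base.resolution if base is not None else resolution,
    )
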