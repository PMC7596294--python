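import numpy as np
import pytest

from corridorplan import fixtures as fx
from corridorplan.landscape import CostLayer, FeatureLayer, Landscape


@pytest.fixture
def two_cell_landscape():
    """One feature on two cells with occurrence (0.2, 0.8), uniform cost."""
    return Landscape([FeatureLayer("f", 1.0, np.array([[0.2, 0.8]]))])


@pytest.fixture
def demo_network():
    return fx.demo_network()


@pytest.fixture
def species_profiles():
    return fx.profiles_from_frame(fx.species_profiles())


@pytest.fixture
def ecosystem():
    return fx.make_ecosystem()


def random_landscape(rng, rows=None, cols=None, n_features=None, with_invalid=False):
    """Small random landscape for oracle and property tests."""
    rows = rows or int(rng.integers(1, 4))
    cols = cols or int(rng.integers(1, 4))
    n_features = n_features or int(rng.integers(1, 3))
    feats = []
    for j in range(n_features):
        occ = rng.uniform(0.0, 1.0, size=(rows, cols))
        occ.flat[int(rng.integers(occ.size))] += 0.5  # guarantee a positive cell
        feats.append(FeatureLayer(f"f{j}", float(rng.uniform(0.5, 2.0)), occ))
    cost = CostLayer(rng.uniform(0.5, 2.0, size=(rows, cols)))
    valid = None
    if with_invalid and rows * cols > 1:
        valid = np.ones(rows * cols, dtype=bool)
        valid[int(rng.integers(rows * cols))] = False
        valid = valid.reshape(rows, cols)
    return Landscape(feats, cost, valid_mask=valid)


def brute_force_removal_order(landscape):
    """Independent step-by-step greedy re-evaluation in plain Python.

    Recomputes every cell's marginal loss from scratch each iteration using
    dicts and loops (no shared code with the ranking implementation) and
    removes the minimum, lowest flat index first on ties.
    """
    occ = {j: f.occurrence.ravel().tolist() for j, f in enumerate(landscape.features)}
    w = {j: f.weight for j, f in enumerate(landscape.features)}
    cost = landscape.cost.cost.ravel().tolist()
    remaining = sorted(int(i) for i in landscape.valid_indices())
    order, losses = [], []
    while remaining:
        totals = {j: sum(occ[j][i] for i in remaining) for j in occ}
        best_cell, best_delta = None, None
        for i in remaining:
            deltas = [
                w[j] * occ[j][i] / totals[j] / cost[i]
                for j in occ
                if totals[j] > 0
            ]
            delta = max(deltas) if deltas else 0.0
            if best_delta is None or delta < best_delta - 1e-12:
                best_cell, best_delta = i, delta
        order.append(best_cell)
        losses.append(best_delta)
        remaining.remove(best_cell)
    return order, losses
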