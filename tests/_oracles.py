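"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route disjoint from the library
implementation: geometric Lorenz areas for gini, closed-form spherical caps
for SASA, an exhaustive half-space LP test for Voronoi adjacency, and
all-pairs shortest paths for burial levels.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


def lorenz_gini(y) -> float:
    """Gini via explicit trapezoid areas under the piecewise-linear Lorenz curve."""
    y = np.sort(np.asarray(y, dtype=np.float64))
    n = len(y)
    total = y.sum()
    cum = np.concatenate([[0.0], np.cumsum(y)])
    area_under_curve = 0.0
    for i in range(1, n + 1):
        area_under_curve += 0.5 * (cum[i - 1] + cum[i]) * 1.0  # unit steps on x
    area_under_equality = 0.5 * n * total
    return (area_under_equality - area_under_curve) / area_under_equality


def isolated_sphere_sasa(radius: float, probe: float) -> float:
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_sasa(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Accessible areas of two overlapping spheres (inflated by the probe)."""
    big1, big2 = r1 + probe, r2 + probe
    if d >= big1 + big2:
        return isolated_sphere_sasa(r1, probe), isolated_sphere_sasa(r2, probe)
    assert d > abs(big1 - big2), "one sphere engulfs the other"
    x1 = (d * d + big1 * big1 - big2 * big2) / (2.0 * d)
    h1 = big1 - x1
    h2 = big2 - (d - x1)
    a1 = 4.0 * math.pi * big1**2 - 2.0 * math.pi * big1 * h1
    a2 = 4.0 * math.pi * big2**2 - 2.0 * math.pi * big2 * h2
    return a1, a2


def voronoi_adjacent(points: np.ndarray, a: int, b: int, tol: float = 1e-9) -> bool:
    """Half-space test: do the Voronoi cells of points a and b share a facet?

    Maximizes the margin t such that some x on the (a, b) bisector satisfies
    |x - c|^2 - |x - a|^2 >= t for every other site c.  Adjacency (with a
    facet of positive area) corresponds to a strictly positive optimum.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    norms = np.sum(points**2, axis=1)
    others = [c for c in range(n) if c != a and c != b]
    # variables: x (3), t (1); maximize t
    c_obj = np.array([0.0, 0.0, 0.0, -1.0])
    a_ub = np.zeros((len(others), 4))
    b_ub = np.zeros(len(others))
    for row, c in enumerate(others):
        # 2 x . (c - a) + t <= |c|^2 - |a|^2
        a_ub[row, :3] = 2.0 * (points[c] - points[a])
        a_ub[row, 3] = 1.0
        b_ub[row] = norms[c] - norms[a]
    a_eq = np.zeros((1, 4))
    a_eq[0, :3] = 2.0 * (points[b] - points[a])
    b_eq = np.array([norms[b] - norms[a]])
    # x is unbounded: shared facets of hull-adjacent cells can lie arbitrarily
    # far away (near-degenerate circumcenters); the t <= 1 cap keeps the LP
    # objective bounded even on unbounded cells.
    res = linprog(
        c_obj,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(None, None)] * 3 + [(None, 1.0)],
        method="highs",
    )
    if not res.success:
        return False
    return float(res.x[3]) > tol


def brute_force_contact_edges(
    coord: np.ndarray, radius: np.ndarray, water_diameter: float
) -> set[tuple[int, int]]:
    """{Voronoi-adjacent by exhaustive LP} intersected with the distance rule."""
    n = len(coord)
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            d = float(np.linalg.norm(coord[a] - coord[b]))
            if d > radius[a] + radius[b] + water_diameter:
                continue
            if voronoi_adjacent(coord, a, b):
                edges.add((a, b))
    return edges


def min_distance_to_set(n: int, edges, sources) -> np.ndarray:
    """All-pairs shortest-path oracle: unit-weight distance to the nearest source."""
    rows, cols = [], []
    for a, b in edges:
        rows += [a, b]
        cols += [b, a]
    mat = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(mat, method="FW", unweighted=True)
    sources = np.asarray(sorted(sources), dtype=int)
    best = dist[:, sources].min(axis=1) if len(sources) else np.full(n, np.inf)
    best[sources] = 0.0
    return best
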