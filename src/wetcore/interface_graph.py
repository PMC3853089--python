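"""Contact graph, exposed-water pruning, tripartite interface and burial levels.

The atomic contact graph has one node per atom of a structure.  Two atoms are
in contact iff they are Voronoi neighbors in the 3-D tessellation of the atom
centers AND their distance does not exceed the sum of their radii plus the
diameter of a water molecule (2.75 A by default).

The interface between two chains is a tripartite subgraph: interfacial water
oxygens (contacting both chains), plus each chain's atoms that contact the
other chain or an interfacial water.  The burial level of an atom is its
hop distance in the contact graph to the nearest exposed atom (SASA above a
threshold, 10 A^2 by default).
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

from .errors import ChainNotFoundError, EmptyExposedSetError
from .structure_io import SasaMap, Structure, compute_sasa

logger = logging.getLogger(__name__)

#: diameter of a water molecule added to the contact distance threshold
WATER_DIAMETER = 2.75

#: SASA threshold above which an atom counts as exposed
EXPOSURE_THRESHOLD = 10.0

#: burial level assigned to atoms unreachable from any exposed atom
UNREACHABLE = -1


@dataclass
class ContactGraph:
    """Undirected atomic contact graph over node indices ``0..n_nodes-1``."""

    n_nodes: int
    edges: set[tuple[int, int]]
    adjacency: list[list[int]] = field(repr=False, default_factory=list)

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "ContactGraph":
        norm = {(min(a, b), max(a, b)) for a, b in edges if a != b}
        adj: list[list[int]] = [[] for _ in range(n_nodes)]
        for a, b in norm:
            adj[a].append(b)
            adj[b].append(a)
        return cls(n_nodes=n_nodes, edges=norm, adjacency=adj)

    def neighbors(self, i: int) -> list[int]:
        return self.adjacency[i]

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class TripartiteInterface:
    """Protein-water-protein interface: two side atom sets, interfacial waters, contacts.

    Node identifiers are indices into ``structure``; ``edges`` contains only
    contacts between distinct parts (side1-side2, side1-water, side2-water).
    """

    structure: Structure
    chain1: str
    chain2: str
    side1_atoms: frozenset[int]
    side2_atoms: frozenset[int]
    water_atoms: frozenset[int]
    edges: frozenset[tuple[int, int]]

    @property
    def atoms(self) -> frozenset[int]:
        """All interface atoms I = side1 | side2 | waters."""
        return self.side1_atoms | self.side2_atoms | self.water_atoms

    @property
    def n_atoms(self) -> int:
        """|I| — waters included."""
        return len(self.side1_atoms) + len(self.side2_atoms) + len(self.water_atoms)

    @property
    def n_water(self) -> int:
        """|I_W|."""
        return len(self.water_atoms)

    def water_protein_edges(self) -> list[tuple[int, int]]:
        """Edges (water_index, protein_index)."""
        ww = self.water_atoms
        out = []
        for a, b in self.edges:
            if a in ww and b not in ww:
                out.append((a, b))
            elif b in ww and a not in ww:
                out.append((b, a))
        return out

    def interfacial_residues(self) -> set[tuple[str, int, str]]:
        """Residues with at least one non-water atom in the interface."""
        s = self.structure
        return {s.residue_key(i) for i in (self.side1_atoms | self.side2_atoms)}


@dataclass
class BurialMap:
    """Per-atom burial level: hop distance to the nearest exposed atom.

    ``levels[i]`` is 0 iff atom ``i`` is exposed; atoms with no path to an
    exposed atom carry the sentinel :data:`UNREACHABLE` (-1).
    """

    levels: np.ndarray
    exposed: np.ndarray  # bool mask
    threshold: float

    def __getitem__(self, i):
        return int(self.levels[i])

    @property
    def n_unreachable(self) -> int:
        return int(np.sum(self.levels == UNREACHABLE))


def prune_exposed_waters(
    s: Structure,
    sasa_threshold: float = EXPOSURE_THRESHOLD,
    probe: float = 1.4,
    n_points: int = 960,
    max_iterations: int = 1000,
) -> Structure:
    """Iteratively remove bulk-exposed waters until a fixed point.

    Each round computes SASA on the full retained complex (remaining waters
    occlude) and removes every water whose SASA exceeds ``sasa_threshold``.
    Non-water atoms are never removed.  The returned structure satisfies:
    recomputing SASA leaves no water above the threshold.
    """
    if sasa_threshold <= 0:
        raise ValueError("sasa_threshold must be positive")
    current = s
    for iteration in range(1, max_iterations + 1):
        sasa = compute_sasa(current, probe=probe, n_points=n_points)
        exposed_water = current.is_water & (sasa.values > sasa_threshold)
        if not np.any(exposed_water):
            logger.info(
                "water pruning converged after %d iteration(s); %d water(s) retained",
                iteration - 1 if iteration > 1 else 0,
                int(np.sum(current.is_water)),
            )
            return current
        current = current.subset(~exposed_water)
    raise RuntimeError("water pruning did not converge")


def count_pruning_iterations(
    s: Structure,
    sasa_threshold: float = EXPOSURE_THRESHOLD,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[Structure, int]:
    """Like :func:`prune_exposed_waters`, also returning the number of removal rounds."""
    current = s
    rounds = 0
    while True:
        sasa = compute_sasa(current, probe=probe, n_points=n_points)
        exposed_water = current.is_water & (sasa.values > sasa_threshold)
        if not np.any(exposed_water):
            return current, rounds
        current = current.subset(~exposed_water)
        rounds += 1


def _delaunay_candidate_pairs(coord: np.ndarray) -> set[tuple[int, int]]:
    tri = Delaunay(coord)
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        m = len(simplex)
        for i in range(m):
            for j in range(i + 1, m):
                a, b = int(simplex[i]), int(simplex[j])
                pairs.add((min(a, b), max(a, b)))
    return pairs


def _distance_candidate_pairs(coord: np.ndarray, radius: np.ndarray, water_diameter: float):
    cutoff = 2.0 * float(np.max(radius)) + water_diameter
    tree = cKDTree(coord)
    return {(min(a, b), max(a, b)) for a, b in tree.query_pairs(cutoff)}

def build_contact_graph(
    s: Structure,
    water_diameter: float = WATER_DIAMETER,
) -> ContactGraph:
    """Voronoi-and-distance atomic contact graph of the whole structure.

    Edge (a, b) exists iff a and b are Voronoi neighbors (Delaunay edge of
    the atom-center tessellation) and dist(a, b) <= r_a + r_b + water_diameter.
    Degenerate geometry (all centers coplanar or too few points) falls back
    to the pure distance criterion with a warning, since every pair of a
    2-point set (and cells of degenerate tessellations) are Voronoi-adjacent.
    """
    if len(s) < 2:
        raise ValueError("contact graph requires at least 2 atoms")
    if s.radius is None:
        raise ValueError("radii must be assigned before building the contact graph")
    coord = np.asarray(s.coord, dtype=np.float64)
    try:
        if len(s) < 5:
            raise QhullError("too few points for a 3-D tessellation")
        candidates = _delaunay_candidate_pairs(coord)
    except QhullError as exc:
        warnings.warn(
            f"Voronoi tessellation degenerate ({exc}); "
            "falling back to the pure distance criterion",
            RuntimeWarning,
            stacklevel=2,
        )
        candidates = _distance_candidate_pairs(coord, s.radius, water_diameter)

    radius = np.asarray(s.radius, dtype=np.float64)
    edges = set()
    for a, b in candidates:
        d = float(np.linalg.norm(coord[a] - coord[b]))
        if d <= radius[a] + radius[b] + water_diameter:
            edges.add((a, b))
    return ContactGraph.from_edges(len(s), edges)


def extract_interface(
    g: ContactGraph,
    s: Structure,
    chain1: str,
    chain2: str,
) -> TripartiteInterface:
    """Extract the chain1-chain2 tripartite interface from a contact graph.

    Interfacial waters are waters contacting at least one (non-water) atom of
    each chain; side atoms are each chain's atoms contacting the other chain
    or an interfacial water.  Waters are identified by residue name
    regardless of the chain they are filed under.
    """
    s.require_chain(chain1)
    s.require_chain(chain2)
    if g.n_nodes != len(s):
        raise ValueError("graph/structure size mismatch")

    in1 = s.chain_mask(chain1)
    in2 = s.chain_mask(chain2)
    water = s.is_water

    water_atoms = set()
    for w in np.flatnonzero(water):
        nbrs = g.neighbors(int(w))
        if any(in1[n] for n in nbrs) and any(in2[n] for n in nbrs):
            water_atoms.add(int(w))

    side1, side2 = set(), set()
    for i in np.flatnonzero(in1 | in2):
        i = int(i)
        here1 = bool(in1[i])
        for n in g.neighbors(i):
            if n in water_atoms or (in2[n] if here1 else in1[n]):
                (side1 if here1 else side2).add(i)
                break

    parts = {}
    for i in side1:
        parts[i] = 0
    for i in side2:
        parts[i] = 1
    for i in water_atoms:
        parts[i] = 2
    edges = {
        (a, b)
        for a, b in g.edges
        if a in parts and b in parts and parts[a] != parts[b]
    }
    return TripartiteInterface(
        structure=s,
        chain1=chain1,
        chain2=chain2,
        side1_atoms=frozenset(side1),
        side2_atoms=frozenset(side2),
        water_atoms=frozenset(water_atoms),
        edges=frozenset(edges),
    )


def burial_levels(
    g: ContactGraph,
    sasa: SasaMap,
    threshold: float = EXPOSURE_THRESHOLD,
) -> BurialMap:
    """Multi-source BFS burial levels from the exposed set (SASA > threshold)."""
    if len(sasa.values) != g.n_nodes:
        raise ValueError("SASA map does not cover all graph nodes")
    exposed = np.asarray(sasa.values) > threshold
    if not np.any(exposed):
        raise EmptyExposedSetError(
            f"no atom has SASA above {threshold} A^2; burial levels undefined"
        )
    levels = np.full(g.n_nodes, UNREACHABLE, dtype=np.int64)
    queue: deque[int] = deque()
    for i in np.flatnonzero(exposed):
        levels[int(i)] = 0
        queue.append(int(i))
    while queue:
        i = queue.popleft()
        for n in g.neighbors(i):
            if levels[n] == UNREACHABLE:
                levels[n] = levels[i] + 1
                queue.append(n)
    n_unreachable = int(np.sum(levels == UNREACHABLE))
    if n_unreachable:
        logger.warning("%d atom(s) unreachable from the exposed set", n_unreachable)
    return BurialMap(levels=levels, exposed=exposed, threshold=float(threshold))
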