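"""Toy two-chain complexes with planted ground truth.

The generator builds two parallel atom slabs (chains A and B) on a jittered
cubic lattice separated by a solvent gap, and places water oxygens at chosen
in-plane sites of the mid-gap plane.  Everything downstream of the reader is
thereby testable against construction: which waters are interfacial, how
deeply each lattice atom is buried, which residues the waters touch, and —
after :func:`make_mutant_copy` — which waters were dropped and which region's
B factors were shifted.

Geometry is deliberately crude; the point is planted truth, not realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SyntheticSpecError
from .mutant_compare import RegionPartition
from .structure_io import Structure

_ATOM_NAMES = ("CA", "CB", "CG", "CD")  # cycled within each 4-atom residue

#: radii used by the generator (matches the "simple" table)
SLAB_RADIUS = 1.70  # carbon
WATER_RADIUS = 1.52  # oxygen


@dataclass
class SyntheticSpec:
    """Parameters of a slab-dimer toy complex.

    ``n_core_waters`` sites spiral out from the slab center; ``n_rim_waters``
    sites sit on the in-plane ring ``rim_inset`` lattice steps from the edge.
    Each residue is a 2x2 in-plane block of atoms (CA/CB/CG/CD), so residue-
    level operations are exercised.  Regions are planted around the waters:
    region A holds every residue a core water can touch, region B the rest of
    what a rim water can touch, region D everything else.
    """

    nx: int = 12
    ny: int = 12
    nz: int = 3
    spacing: float = 3.5
    gap: float = 5.0
    n_core_waters: int = 16
    n_rim_waters: int = 0
    rim_inset: int = 1
    b_base: float = 20.0
    b_noise_sd: float = 2.0
    lattice_jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.nx < 4 or self.ny < 4 or self.nz < 2:
            raise SyntheticSpecError("slab must be at least 4 x 4 x 2 atoms")
        if self.nx % 2 or self.ny % 2:
            raise SyntheticSpecError("nx and ny must be even (2x2-block residues)")
        if self.spacing <= 2 * max(SLAB_RADIUS, WATER_RADIUS):
            raise SyntheticSpecError(
                f"spacing {self.spacing} would clash (needs > {2 * SLAB_RADIUS})"
            )
        if self.gap <= 2 * WATER_RADIUS:
            raise SyntheticSpecError("gap too narrow to host a water")
        if self.gap / 2 > SLAB_RADIUS + WATER_RADIUS + 2.75:
            raise SyntheticSpecError("gap too wide: mid-gap waters would contact neither slab")
        n_sites = self.nx * self.ny
        if self.n_core_waters + self.n_rim_waters > n_sites:
            raise SyntheticSpecError("more waters than lattice sites")
        if self.lattice_jitter < 0 or self.lattice_jitter >= 0.25 * self.spacing:
            raise SyntheticSpecError("lattice_jitter must be small and non-negative")


@dataclass
class SlabTruth:
    """Planted ground truth accompanying a generated slab dimer."""

    water_res_ids: list[int]  # all planted waters, by residue id (chain S)
    core_water_res_ids: list[int]
    rim_water_res_ids: list[int]
    water_site: dict[int, tuple[int, int]]  # res_id -> in-plane lattice site
    lattice_depth: dict[int, int]  # atom serial -> min hops to the slab surface
    residue_region: dict[tuple[str, int], str]  # (chain, res_id) -> region name
    # planted contact design: every water surely touches the residues directly
    # facing its site (min), and can touch at most the one-step neighborhood
    # (max) — the tessellation decides the diagonals
    water_contact_residues_min: dict[int, set[tuple[str, int]]]
    water_contact_residues: dict[int, set[tuple[str, int]]]
    regions: RegionPartition = field(repr=False, default=None)


def _spiral_sites(nx: int, ny: int) -> list[tuple[int, int]]:
    """All lattice sites ordered by Chebyshev distance from the center, then angle."""
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    sites = [(i, j) for i in range(nx) for j in range(ny)]
    return sorted(
        sites,
        key=lambda s: (
            max(abs(s[0] - cx), abs(s[1] - cy)),
            math.atan2(s[1] - cy, s[0] - cx),
        ),
    )


def _ring_sites(nx: int, ny: int, inset: int) -> list[tuple[int, int]]:
    lo_x, hi_x = inset, nx - 1 - inset
    lo_y, hi_y = inset, ny - 1 - inset
    ring = [
        (i, j)
        for i in range(nx)
        for j in range(ny)
        if (i in (lo_x, hi_x) and lo_y <= j <= hi_y)
        or (j in (lo_y, hi_y) and lo_x <= i <= hi_x)
    ]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    return sorted(ring, key=lambda s: math.atan2(s[1] - cy, s[0] - cx))


def make_slab_dimer(spec: SyntheticSpec) -> tuple[Structure, SlabTruth]:
    """Generate a two-slab complex with gap waters and its planted truth.

    Deterministic for a fixed ``spec.seed`` (the seed drives the symmetry-
    breaking lattice jitter and the B-factor noise).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a = spec.spacing
    nbx, nby = spec.nx // 2, spec.ny // 2

    def res_of(ix: int, iy: int, iz: int) -> int:
        return iz * nbx * nby + (iy // 2) * nbx + (ix // 2) + 1

    core_sites = _spiral_sites(spec.nx, spec.ny)[: spec.n_core_waters]
    rim_pool = _ring_sites(spec.nx, spec.ny, spec.rim_inset)
    if spec.n_rim_waters > len(rim_pool):
        raise SyntheticSpecError("not enough rim sites for n_rim_waters")
    rim_sites = rim_pool[: spec.n_rim_waters]
    overlap = set(core_sites) & set(rim_sites)
    if overlap:
        raise SyntheticSpecError(f"core and rim water sites overlap: {sorted(overlap)}")

    # planted regions: A = residue blocks a core water can touch (one lattice
    # step around its site), B = likewise for rim waters (minus A), D = rest
    def pad(sites):
        out = set()
        for i, j in sites:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if 0 <= i + di < spec.nx and 0 <= j + dj < spec.ny:
                        out.add((i + di, j + dj))
        return out

    core_pad, rim_pad = pad(core_sites), pad(rim_sites)

    def block_region(bx: int, by: int) -> str:
        block = {(2 * bx + u, 2 * by + v) for u in (0, 1) for v in (0, 1)}
        if block & core_pad:
            return "A"
        if block & rim_pad:
            return "B"
        return "D"

    serial = 1
    rows = []  # (serial, chain, res_id, res_name, atom_name, element, xyz, water)
    depth: dict[int, int] = {}
    residue_region: dict[tuple[str, int], str] = {}

    z_top_a = (spec.nz - 1) * a  # inner face of slab A
    z_bot_b = z_top_a + spec.gap  # inner face of slab B

    for chain, z0, zdir in (("A", z_top_a, -1.0), ("B", z_bot_b, +1.0)):
        for iz in range(spec.nz):  # iz = 0 is the inner face
            for iy in range(spec.ny):
                for ix in range(spec.nx):
                    res_id = res_of(ix, iy, iz)
                    name = _ATOM_NAMES[(iy % 2) * 2 + (ix % 2)]
                    xyz = np.array(
                        [ix * a, iy * a, z0 + zdir * iz * a], dtype=np.float64
                    )
                    xyz += rng.normal(0.0, spec.lattice_jitter, size=3)
                    rows.append(
                        (serial, chain, res_id, "UNK", name, "C", xyz, False)
                    )
                    # hops to the slab surface: outer face, or any in-plane edge
                    depth[serial] = min(
                        spec.nz - 1 - iz,  # to the outer face
                        ix,
                        spec.nx - 1 - ix,
                        iy,
                        spec.ny - 1 - iy,
                    )
                    residue_region[(chain, res_id)] = block_region(ix // 2, iy // 2)
                    serial += 1

    z_mid = z_top_a + spec.gap / 2.0
    water_res_ids, core_ids, rim_ids = [], [], []
    water_site: dict[int, tuple[int, int]] = {}
    wres = 2000
    for site, is_core in [(s, True) for s in core_sites] + [
        (s, False) for s in rim_sites
    ]:
        wres += 1
        xyz = np.array([site[0] * a, site[1] * a, z_mid], dtype=np.float64)
        xyz += rng.normal(0.0, spec.lattice_jitter, size=3)
        rows.append((serial, "S", wres, "HOH", "O", "O", xyz, True))
        water_res_ids.append(wres)
        water_site[wres] = site
        (core_ids if is_core else rim_ids).append(wres)
        serial += 1

    n = len(rows)
    s = Structure(
        serial=np.array([r[0] for r in rows], dtype=np.int64),
        chain_id=np.array([r[1] for r in rows], dtype="U4"),
        res_id=np.array([r[2] for r in rows], dtype=np.int64),
        icode=np.full(n, "", dtype="U1"),
        res_name=np.array([r[3] for r in rows], dtype="U4"),
        atom_name=np.array([r[4] for r in rows], dtype="U4"),
        element=np.array([r[5] for r in rows], dtype="U2"),
        coord=np.stack([r[6] for r in rows]),
        b_factor=spec.b_base + spec.b_noise_sd * rng.standard_normal(n),
        occupancy=np.ones(n, dtype=np.float64),
        is_water=np.array([r[7] for r in rows], dtype=bool),
        hetero=np.array([r[7] for r in rows], dtype=bool),
        structure_id=f"slab-dimer-seed{spec.seed}",
    )

    # planted contact design: a mid-gap water at site (i, j) touches, on each
    # slab's inner face, the atoms within one lattice step of the site
    atom_res: dict[tuple[str, int, int], tuple[str, int]] = {
        (chain, ix, iy): (chain, res_of(ix, iy, 0))
        for chain in ("A", "B")
        for iy in range(spec.ny)
        for ix in range(spec.nx)
    }

    contact_design_max: dict[int, set[tuple[str, int]]] = {}
    contact_design_min: dict[int, set[tuple[str, int]]] = {}
    for wres_id, (i, j) in water_site.items():
        touched = set()
        for chain in ("A", "B"):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    key = (chain, i + di, j + dj)
                    if key in atom_res:
                        touched.add(atom_res[key])
        contact_design_max[wres_id] = touched
        contact_design_min[wres_id] = {
            atom_res[(chain, i, j)] for chain in ("A", "B")
        }

    regions: dict[str, dict[str, set[int]]] = {}
    for (chain, res_id), name in residue_region.items():
        regions.setdefault(name, {}).setdefault(chain, set()).add(res_id)
    partition = RegionPartition.from_dict(
        {name: {c: sorted(rs) for c, rs in chains.items()} for name, chains in regions.items()}
    )

    truth = SlabTruth(
        water_res_ids=water_res_ids,
        core_water_res_ids=core_ids,
        rim_water_res_ids=rim_ids,
        water_site=water_site,
        lattice_depth=depth,
        residue_region=residue_region,
        water_contact_residues_min=contact_design_min,
        water_contact_residues=contact_design_max,
        regions=partition,
    )
    return s, truth


def make_mutant_copy(
    s: Structure,
    jitter_sd: float = 0.0,
    drop_waters: tuple[int, ...] = (),
    bshift: dict[str, float] | None = None,
    regions: RegionPartition | None = None,
    water_bshift: dict[int, float] | None = None,
    seed: int = 0,
) -> Structure:
    """Perturbed copy of a structure: coordinate jitter, dropped waters, B shifts.

    ``drop_waters`` lists water residue ids to delete; ``bshift`` maps region
    names (resolved through ``regions``) to a B-factor increment applied to
    every atom of the region's residues; ``water_bshift`` shifts individual
    waters by residue id.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = s.copy()

    if drop_waters:
        water_ids = set(int(r) for r in s.res_id[s.is_water])
        unknown = [w for w in drop_waters if int(w) not in water_ids]
        if unknown:
            raise SyntheticSpecError(f"unknown water residue id(s): {unknown}")
        drop_mask = out.is_water & np.isin(out.res_id, list(map(int, drop_waters)))
        out = out.subset(~drop_mask)

    if jitter_sd:
        out.coord = out.coord + rng.normal(0.0, jitter_sd, size=out.coord.shape)

    if bshift:
        if regions is None:
            raise SyntheticSpecError("bshift requires a region partition")
        for name, db in bshift.items():
            if name not in regions.regions:
                raise SyntheticSpecError(f"unknown region {name!r} in bshift")
            mask = np.zeros(len(out), dtype=bool)
            for chain, res_ids in regions.regions[name].items():
                mask |= (out.chain_id == chain) & np.isin(out.res_id, sorted(res_ids))
            out.b_factor = out.b_factor + np.where(mask, float(db), 0.0)

    if water_bshift:
        for wres, db in water_bshift.items():
            mask = out.is_water & (out.res_id == int(wres))
            if not np.any(mask):
                raise SyntheticSpecError(f"unknown water residue id: {wres}")
            out.b_factor = out.b_factor + np.where(mask, float(db), 0.0)

    return out


def make_counts(n: int, pattern: str, seed: int = 0, spike: int = 8) -> np.ndarray:
    """Count vectors with analytically known gini for the closed-form patterns.

    ``equal`` -> gini 0; ``single-spike`` -> gini (n-1)/n; ``geometric`` ->
    i.i.d. geometric draws (gini known only through the Lorenz oracle).
    """
    if n < 2:
        raise SyntheticSpecError("need at least 2 counts")
    if pattern == "equal":
        return np.full(n, 2, dtype=np.int64)
    if pattern == "single-spike":
        y = np.zeros(n, dtype=np.int64)
        y[-1] = int(spike)
        return y
    if pattern == "geometric":
        rng = np.random.default_rng(seed)
        y = rng.geometric(0.35, size=n) - 1
        if y.sum() == 0:
            y[0] = 1
        return y.astype(np.int64)
    raise SyntheticSpecError(f"unknown pattern {pattern!r}")
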