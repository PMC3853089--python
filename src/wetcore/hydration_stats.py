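"""Interface hydration descriptors: wetness, rWBL, gini, hydration profile, dSASA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .interface_graph import UNREACHABLE, BurialMap, TripartiteInterface
from .structure_io import Structure, compute_sasa


@dataclass(frozen=True)
class WaterContactCounts:
    """Per non-water interfacial atom: the number of distinct interfacial waters it contacts."""

    atom_indices: np.ndarray  # indices into the interface's structure
    counts: np.ndarray  # y_j, non-negative integers

    @property
    def n(self) -> int:
        return int(len(self.counts))

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class HydrationSummary:
    n_water: int
    n_atoms: int
    wetness: float
    rwbl: float | None
    gini: float | None
    mean_bl_water: float | None
    mean_bl_all: float | None
    delta_sasa: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_water": self.n_water,
            "n_atoms": self.n_atoms,
            "wetness": self.wetness,
            "rwbl": self.rwbl,
            "gini": self.gini,
            "mean_bl_water": self.mean_bl_water,
            "mean_bl_all": self.mean_bl_all,
            "delta_sasa": self.delta_sasa,
        }


def wetness(iface: TripartiteInterface) -> float:
    """|I_W| / |I| — the fraction of interface atoms that are water oxygens."""
    if iface.n_atoms == 0:
        raise UndefinedStatisticError("wetness undefined for an empty interface")
    return iface.n_water / iface.n_atoms


def _interface_levels(iface: TripartiteInterface, bl: BurialMap):
    all_idx = np.fromiter(iface.atoms, dtype=np.int64)
    water_idx = np.fromiter(iface.water_atoms, dtype=np.int64) if iface.n_water else np.empty(0, np.int64)
    lv_all = bl.levels[all_idx]
    lv_water = bl.levels[water_idx]
    # sentinel-carrying atoms are excluded from averages (logged by burial_levels)
    lv_all = lv_all[lv_all != UNREACHABLE]
    lv_water = lv_water[lv_water != UNREACHABLE]
    return lv_water, lv_all


def mean_burial_levels(iface: TripartiteInterface, bl: BurialMap) -> tuple[float, float]:
    """(mean BL over interfacial water oxygens, mean BL over all interface atoms)."""
    lv_water, lv_all = _interface_levels(iface, bl)
    if len(lv_water) == 0:
        raise UndefinedStatisticError("no interfacial water with a finite burial level")
    if len(lv_all) == 0:
        raise UndefinedStatisticError("no interface atom with a finite burial level")
    return float(np.mean(lv_water)), float(np.mean(lv_all))


def rwbl(iface: TripartiteInterface, bl: BurialMap) -> float:
    """Relative water burial level: mean water BL / mean BL of all interface atoms."""
    mean_water, mean_all = mean_burial_levels(iface, bl)
    if mean_all == 0:
        raise UndefinedStatisticError("mean interface burial level is zero; rWBL undefined")
    return mean_water / mean_all


def water_contact_counts(iface: TripartiteInterface) -> WaterContactCounts:
    """y_j per non-water interface atom: distinct interfacial waters in contact."""
    protein_atoms = sorted(iface.side1_atoms | iface.side2_atoms)
    if not protein_atoms and not iface.water_atoms:
        raise UndefinedStatisticError("empty interface")
    touched: dict[int, set[int]] = {j: set() for j in protein_atoms}
    for w, p in iface.water_protein_edges():
        touched[p].add(w)
    idx = np.asarray(protein_atoms, dtype=np.int64)
    counts = np.asarray([len(touched[j]) for j in protein_atoms], dtype=np.int64)
    return WaterContactCounts(atom_indices=idx, counts=counts)


def gini(counts: WaterContactCounts | np.ndarray) -> float:
    """Gini coefficient of the water-contact count distribution.

    Computed as the Lorenz-area ratio X/Y for the piecewise-linear Lorenz
    curve of the counts sorted non-decreasingly, which reduces to
    ``(2 * sum(i * y_i)) / (n * sum(y)) - (n + 1) / n`` with 1-based ranks.
    """
    y = counts.counts if isinstance(counts, WaterContactCounts) else np.asarray(counts)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 2:
        raise UndefinedStatisticError("gini requires at least 2 atoms")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    total = float(np.sum(y))
    if total == 0:
        raise UndefinedStatisticError("gini undefined: no water contacts (sum y = 0)")
    y_sorted = np.sort(y)
    ranks = np.arange(1, n + 1, dtype=np.float64)
    return float(2.0 * np.sum(ranks * y_sorted) / (n * total) - (n + 1.0) / n)


def residue_hydration_profile(
    iface: TripartiteInterface,
) -> dict[tuple[str, int, str], int]:
    """Distinct interfacial waters contacting each interfacial residue."""
    s = iface.structure
    residues = iface.interfacial_residues()
    if not residues and not iface.water_atoms:
        raise UndefinedStatisticError("empty interface")
    waters_of: dict[tuple[str, int, str], set[int]] = {r: set() for r in residues}
    for w, p in iface.water_protein_edges():
        waters_of[s.residue_key(p)].add(w)
    return {r: len(ws) for r, ws in sorted(waters_of.items())}


def delta_sasa(
    s: Structure,
    chain1: str,
    chain2: str,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Interface size: half the SASA buried on binding, over protein atoms only.

    0.5 * [SASA(chain1 alone) + SASA(chain2 alone) - SASA(complex)], with all
    waters excluded from every computation.
    """
    s.require_chain(chain1)
    s.require_chain(chain2)
    if s.radius is None:
        raise ValueError("radii must be assigned")
    m1 = s.chain_mask(chain1)
    m2 = s.chain_mask(chain2)
    alone1 = compute_sasa(s.subset(m1), probe=probe, n_points=n_points).total
    alone2 = compute_sasa(s.subset(m2), probe=probe, n_points=n_points).total
    both = compute_sasa(s.subset(m1 | m2), probe=probe, n_points=n_points).total
    return 0.5 * (alone1 + alone2 - both)


def summarize(
    iface: TripartiteInterface,
    bl: BurialMap,
    delta_sasa_value: float | None = None,
) -> HydrationSummary:
    """Bundle the scalar descriptors of one interface."""
    w = wetness(iface)
    if iface.n_water > 0:
        mean_water, mean_all = mean_burial_levels(iface, bl)
        r = mean_water / mean_all if mean_all else None
        counts = water_contact_counts(iface)
        g = gini(counts) if counts.n >= 2 and counts.total > 0 else None
    else:
        mean_water = None
        lv_all = bl.levels[np.fromiter(iface.atoms, dtype=np.int64)]
        lv_all = lv_all[lv_all != UNREACHABLE]
        mean_all = float(np.mean(lv_all)) if len(lv_all) else None
        r = None
        g = None
    return HydrationSummary(
        n_water=iface.n_water,
        n_atoms=iface.n_atoms,
        wetness=w,
        rwbl=r,
        gini=g,
        mean_bl_water=mean_water,
        mean_bl_all=mean_all,
        delta_sasa=delta_sasa_value,
    )
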