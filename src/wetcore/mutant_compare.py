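"""Wild-type vs mutant comparison: superposition, water reappearance, B* profiles.

Workflow: rigidly superimpose the mutant onto the wild type (sequence-paired
Kabsch fit), pair interfacial waters with a mutual-nearest rule under a
distance cutoff, z-score B factors within each complex against a reference
set far from the mutation site(s), and profile the per-atom change in
normalized B factor by interface region and burial level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import (
    BFactorNormalizationError,
    RegionConfigError,
    SuperpositionError,
)
from .interface_graph import UNREACHABLE, BurialMap, TripartiteInterface
from .structure_io import Structure

ResidueKey = tuple[str, int, str]


# ---------------------------------------------------------------------------
# rigid superposition


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ mobile + t ~ target."""
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    return rot, trans


@dataclass
class SuperpositionResult:
    """Rigid fit of a mobile structure onto a reference, with per-residue RMSDs."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    residue_pairing: list[tuple[ResidueKey, ResidueKey]]  # (reference, mobile)
    per_residue_rmsd: dict[ResidueKey, float]  # keyed by reference residue
    global_rmsd: float
    selection: tuple[str, ...]

    def transform(self, coord: np.ndarray) -> np.ndarray:
        """Map mobile-frame coordinates into the reference frame."""
        return coord @ self.rotation.T + self.translation


_SELECTIONS = {
    "CA": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
}


def _residue_atom_index(s: Structure) -> dict[ResidueKey, dict[str, int]]:
    out: dict[ResidueKey, dict[str, int]] = {}
    for i in range(len(s)):
        if s.is_water[i]:
            continue
        out.setdefault(s.residue_key(i), {})[str(s.atom_name[i])] = i
    return out


def pair_residues(
    reference: Structure,
    mobile: Structure,
    chain_pairs: list[tuple[str, str]] | None = None,
    on_mismatch: str = "error",
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Pair non-water residues by chain and residue number (+ insertion code).

    ``chain_pairs`` maps reference chains to mobile chains; by default every
    common chain id is paired with itself.  With ``on_mismatch="error"``,
    residues present on only one side abort the pairing (listing them);
    ``"ignore"`` silently pairs the intersection.
    """
    if chain_pairs is None:
        common = [c for c in reference.chains if c in mobile.chains]
        chain_pairs = [(c, c) for c in common]
    if not chain_pairs:
        raise SuperpositionError("no common chains to pair")

    ref_idx = _residue_atom_index(reference)
    mob_idx = _residue_atom_index(mobile)
    pairing: list[tuple[ResidueKey, ResidueKey]] = []
    unpaired: list[str] = []
    for rc, mc in chain_pairs:
        reference.require_chain(rc)
        mobile.require_chain(mc)
        ref_res = {(r, ic): (c, r, ic) for (c, r, ic) in ref_idx if c == rc}
        mob_res = {(r, ic): (c, r, ic) for (c, r, ic) in mob_idx if c == mc}
        for key in sorted(ref_res.keys() | mob_res.keys()):
            if key in ref_res and key in mob_res:
                pairing.append((ref_res[key], mob_res[key]))
            elif key in ref_res:
                unpaired.append(f"reference {rc}{key[0]}{key[1]}")
            else:
                unpaired.append(f"mobile {mc}{key[0]}{key[1]}")
    if unpaired and on_mismatch == "error":
        raise SuperpositionError(
            f"sequence length mismatch; unpaired residues: {', '.join(unpaired)}"
        )
    return pairing


def pair_and_superimpose(
    reference: Structure,
    mobile: Structure,
    atom_selection: str | tuple[str, ...] = "CA",
    chain_pairs: list[tuple[str, str]] | None = None,
    on_mismatch: str = "error",
) -> SuperpositionResult:
    """Sequence-paired least-squares superposition of ``mobile`` onto ``reference``.

    The rigid fit uses the atoms named by ``atom_selection`` (default C-alpha;
    ``"backbone"`` selects N/CA/C/O) over all paired residues.  Per-residue
    RMSDs are then computed over all heavy atoms shared by each residue pair
    (so a substitution site contributes only its common atoms).
    """
    if isinstance(atom_selection, str):
        selection = _SELECTIONS.get(atom_selection, (atom_selection,))
    else:
        selection = tuple(atom_selection)
    pairing = pair_residues(reference, mobile, chain_pairs, on_mismatch)
    ref_idx = _residue_atom_index(reference)
    mob_idx = _residue_atom_index(mobile)

    fit_ref, fit_mob = [], []
    for rkey, mkey in pairing:
        ra, ma = ref_idx[rkey], mob_idx[mkey]
        for name in selection:
            if name in ra and name in ma:
                fit_ref.append(reference.coord[ra[name]])
                fit_mob.append(mobile.coord[ma[name]])
    if len(fit_ref) < 3:
        raise SuperpositionError(
            f"only {len(fit_ref)} paired selection atoms; at least 3 required"
        )
    fit_ref = np.asarray(fit_ref)
    fit_mob = np.asarray(fit_mob)
    rot, trans = kabsch(fit_mob, fit_ref)
    moved = fit_mob @ rot.T + trans
    global_rmsd = float(np.sqrt(np.mean(np.sum((moved - fit_ref) ** 2, axis=1))))

    per_residue: dict[ResidueKey, float] = {}
    for rkey, mkey in pairing:
        ra, ma = ref_idx[rkey], mob_idx[mkey]
        shared = sorted(set(ra) & set(ma))
        if not shared:
            continue
        p = reference.coord[[ra[n] for n in shared]]
        q = mobile.coord[[ma[n] for n in shared]] @ rot.T + trans
        per_residue[rkey] = float(np.sqrt(np.mean(np.sum((q - p) ** 2, axis=1))))

    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        residue_pairing=pairing,
        per_residue_rmsd=per_residue,
        global_rmsd=global_rmsd,
        selection=selection,
    )


# ---------------------------------------------------------------------------
# water correspondence


@dataclass
class WaterCorrespondence:
    """Mutual-nearest water pairing between two superposed interfaces.

    ``matched`` holds reappearing waters (mutually nearest and closer than
    ``cutoff``); ``mutual_far`` holds mutually-nearest pairs at or beyond the
    cutoff (observed but non-reappearing); waters without a mutual partner
    are listed in ``unmatched_*``.  All ids are atom indices into the
    respective interface structures.
    """

    matched: list[tuple[int, int, float]]
    mutual_far: list[tuple[int, int, float]]
    unmatched_wt: list[int]
    unmatched_mut: list[int]
    cutoff: float

    @property
    def n_reappearing(self) -> int:
        return len(self.matched)


def water_reappearance(
    wt_iface: TripartiteInterface,
    mut_iface: TripartiteInterface,
    transform: SuperpositionResult | None,
    cutoff: float = 1.0,
) -> WaterCorrespondence:
    """Pair interfacial waters of a superposed wt/mut pair by mutual nearest distance.

    ``transform`` maps mutant coordinates into the wild-type frame (pass
    ``None`` if the structures are already in a common frame).  A wild-type
    water reappears iff its nearest mutant water has it as nearest in return
    and their distance is below ``cutoff``.
    """
    wt_ids = sorted(wt_iface.water_atoms)
    mut_ids = sorted(mut_iface.water_atoms)
    if not wt_ids or not mut_ids:
        return WaterCorrespondence([], [], wt_ids, mut_ids, cutoff)
    wt_xyz = wt_iface.structure.coord[wt_ids]
    mut_xyz = mut_iface.structure.coord[mut_ids]
    if transform is not None:
        mut_xyz = transform.transform(mut_xyz)
    dist = np.linalg.norm(wt_xyz[:, None, :] - mut_xyz[None, :, :], axis=2)
    nearest_mut = np.argmin(dist, axis=1)
    nearest_wt = np.argmin(dist, axis=0)

    matched, mutual_far = [], []
    paired_wt, paired_mut = set(), set()
    for i, j in enumerate(nearest_mut):
        if nearest_wt[j] == i:
            d = float(dist[i, j])
            pair = (wt_ids[i], mut_ids[int(j)], d)
            if d < cutoff:
                matched.append(pair)
                paired_wt.add(wt_ids[i])
                paired_mut.add(mut_ids[int(j)])
            else:
                mutual_far.append(pair)
    unmatched_wt = [w for w in wt_ids if w not in paired_wt]
    unmatched_mut = [w for w in mut_ids if w not in paired_mut]
    return WaterCorrespondence(matched, mutual_far, unmatched_wt, unmatched_mut, cutoff)


# ---------------------------------------------------------------------------
# B-factor normalization


@dataclass
class NormalizedBFactors:
    """Within-complex z-scores of B factors against a far-from-mutation reference set."""

    structure: Structure
    bstar: np.ndarray  # per atom, dimensionless
    reference_mean: float
    reference_sd: float  # population SD of the reference set
    reference_mask: np.ndarray  # bool, atoms used as reference
    site_coords: np.ndarray  # (k, 3) C-gamma positions of the mutation sites


def _site_gamma_coords(s: Structure, mutation_sites) -> np.ndarray:
    coords = []
    for site in mutation_sites:
        if isinstance(site, tuple):
            chains = [site[0]]
            res_id = int(site[1])
        else:
            chains = s.chains
            res_id = int(site)
        found = False
        for c in chains:
            mask = (
                (s.chain_id == c)
                & (s.res_id == res_id)
                & (s.atom_name == "CG")
                & ~s.is_water
            )
            idx = np.flatnonzero(mask)
            if len(idx):
                coords.append(s.coord[int(idx[0])])
                found = True
        if not found:
            raise BFactorNormalizationError(
                f"mutation site {site!r} has no C-gamma (CG) atom"
            )
    return np.asarray(coords, dtype=np.float64)


def normalize_bfactors(
    s: Structure,
    mutation_sites,
    exclusion_radius: float = 15.0,
) -> NormalizedBFactors:
    """z-score every B factor against non-water atoms far from the mutation site(s).

    The reference set contains the non-water atoms whose distance to every
    mutation-site C-gamma is at least ``exclusion_radius``; its mean and
    population standard deviation normalize the whole complex, waters
    included.
    """
    site_coords = _site_gamma_coords(s, mutation_sites)
    d = np.linalg.norm(s.coord[:, None, :] - site_coords[None, :, :], axis=2)
    min_d = d.min(axis=1)
    ref_mask = (~s.is_water) & (min_d >= exclusion_radius)
    n_ref = int(np.sum(ref_mask))
    if n_ref < 10:
        raise BFactorNormalizationError(
            f"reference set has only {n_ref} atoms (need >= 10)"
        )
    mean = float(np.mean(s.b_factor[ref_mask]))
    sd = float(np.std(s.b_factor[ref_mask]))  # population SD
    if sd == 0:
        raise BFactorNormalizationError("reference B factors have zero spread")
    return NormalizedBFactors(
        structure=s,
        bstar=(s.b_factor - mean) / sd,
        reference_mean=mean,
        reference_sd=sd,
        reference_mask=ref_mask,
        site_coords=site_coords,
    )


# ---------------------------------------------------------------------------
# region partition


@dataclass
class RegionPartition:
    """Named interface regions as per-chain residue-number sets (user config)."""

    regions: dict[str, dict[str, set[int]]]

    @classmethod
    def from_dict(cls, d: dict) -> "RegionPartition":
        regions = {
            str(name): {str(c): {int(r) for r in rs} for c, rs in chains.items()}
            for name, chains in d.items()
        }
        seen: dict[tuple[str, int], str] = {}
        for name, chains in regions.items():
            for c, rs in chains.items():
                for r in rs:
                    if (c, r) in seen:
                        raise RegionConfigError(
                            f"residue {c}{r} assigned to both {seen[(c, r)]} and {name}"
                        )
                    seen[(c, r)] = name
        return cls(regions=regions)

    @classmethod
    def from_yaml(cls, text: str) -> "RegionPartition":
        return cls.from_dict(yaml.safe_load(text))

    def region_of(self, chain: str, res_id: int) -> str | None:
        for name, chains in self.regions.items():
            if res_id in chains.get(chain, ()):
                return name
        return None

    def region_of_residue(self, key: ResidueKey) -> str:
        name = self.region_of(key[0], key[1])
        if name is None:
            raise RegionConfigError(
                f"interfacial residue {key[0]}{key[1]}{key[2]} is in no region"
            )
        return name

    def names(self) -> list[str]:
        return sorted(self.regions)


def assign_waters_to_regions(
    iface: TripartiteInterface,
    partition: RegionPartition,
) -> dict[int, str]:
    """Assign each interfacial water to the region of most of its contacting residues.

    Ties go to the region whose residues contact more distinct interfacial
    waters overall, then to the alphabetically first region name.
    """
    s = iface.structure
    residues_of_water: dict[int, set[ResidueKey]] = {w: set() for w in iface.water_atoms}
    region_water_load: dict[str, set[int]] = {}
    for w, p in iface.water_protein_edges():
        rkey = s.residue_key(p)
        residues_of_water[w].add(rkey)
        region_water_load.setdefault(partition.region_of_residue(rkey), set()).add(w)

    assignment: dict[int, str] = {}
    for w, rkeys in residues_of_water.items():
        votes: dict[str, int] = {}
        for rkey in rkeys:
            votes[partition.region_of_residue(rkey)] = (
                votes.get(partition.region_of_residue(rkey), 0) + 1
            )
        if not votes:
            continue
        best = max(
            votes,
            key=lambda name: (
                votes[name],
                len(region_water_load.get(name, ())),
                [-ord(ch) for ch in name],
            ),
        )
        assignment[w] = best
    return assignment


# ---------------------------------------------------------------------------
# delta-B* profiles


def delta_bstar_profile(
    wt: NormalizedBFactors,
    mut: NormalizedBFactors,
    corr: WaterCorrespondence,
    regions: RegionPartition,
    bl: BurialMap,
    wt_iface: TripartiteInterface,
    mut_iface: TripartiteInterface,
    superposition: SuperpositionResult,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Change in normalized B factor after the mutation, profiled two ways.

    Returns ``(water_table, atom_table)``:

    * ``water_table`` — one row per reappearing water: wild-type label,
      delta B* (mutant minus wild type), distance of the wild-type water to
      the nearest mutation-site C-gamma, and its region.
    * ``atom_table`` — mean delta B* of paired non-water interfacial atoms,
      grouped by region and wild-type burial level.
    """
    ws = wt.structure
    ms = mut.structure
    wt_bstar_of = {int(i): float(wt.bstar[i]) for i in range(len(ws))}
    mut_bstar_of = {int(i): float(mut.bstar[i]) for i in range(len(ms))}
    water_region = assign_waters_to_regions(wt_iface, regions)

    rows = []
    for wt_w, mut_w, d in corr.matched:
        dist_site = float(
            np.min(np.linalg.norm(wt.site_coords - ws.coord[wt_w], axis=1))
        )
        rows.append(
            {
                "water": ws.atom_label(wt_w),
                "delta_bstar": mut_bstar_of[mut_w] - wt_bstar_of[wt_w],
                "distance_to_mutation": dist_site,
                "pair_distance": d,
                "region": water_region.get(wt_w),
            }
        )
    water_table = pd.DataFrame(
        rows,
        columns=["water", "delta_bstar", "distance_to_mutation", "pair_distance", "region"],
    )

    # pair non-water interface atoms through the residue pairing + atom names
    mob_idx = _residue_atom_index(ms)
    pair_of = dict(superposition.residue_pairing)
    atom_rows = []
    for i in sorted(wt_iface.side1_atoms | wt_iface.side2_atoms):
        rkey = ws.residue_key(i)
        mkey = pair_of.get(rkey)
        if mkey is None:
            continue
        j = mob_idx.get(mkey, {}).get(str(ws.atom_name[i]))
        if j is None:
            continue
        level = int(bl.levels[i])
        if level == UNREACHABLE:
            continue
        atom_rows.append(
            {
                "region": regions.region_of_residue(rkey),
                "burial_level": level,
                "delta_bstar": mut_bstar_of[j] - wt_bstar_of[i],
            }
        )
    atoms = pd.DataFrame(atom_rows, columns=["region", "burial_level", "delta_bstar"])
    if len(atoms):
        atom_table = (
            atoms.groupby(["region", "burial_level"])["delta_bstar"]
            .agg(["mean", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_delta_bstar", "count": "n_atoms"})
        )
    else:
        atom_table = pd.DataFrame(
            columns=["region", "burial_level", "mean_delta_bstar", "n_atoms"]
        )
    return water_table, atom_table


# ---------------------------------------------------------------------------
# trajectory-frame RMSD


def rmsd_over_frames(
    frames: list[Structure],
    reference: Structure,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares-superposed RMSD of each frame against a reference.

    ``selection`` is a boolean mask over the reference atoms (default: all
    non-water atoms); each frame must have the same atom count as the
    reference, in the same order (multi-model PDB convention).
    """
    if selection is None:
        selection = ~reference.is_water
    selection = np.asarray(selection, dtype=bool)
    if selection.shape != (len(reference),):
        raise ValueError("selection mask does not match the reference atom count")
    if not np.any(selection):
        raise ValueError("empty selection")
    ref_xyz = reference.coord[selection]
    out = np.empty(len(frames), dtype=np.float64)
    for k, frame in enumerate(frames):
        if len(frame) != len(reference):
            raise SuperpositionError(
                f"frame {k}: atom count {len(frame)} != reference {len(reference)}"
            )
        xyz = frame.coord[selection]
        rot, trans = kabsch(xyz, ref_xyz)
        moved = xyz @ rot.T + trans
        out[k] = float(np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1))))
    return out


def region_selection(
    reference: Structure,
    partition: RegionPartition,
    region: str,
) -> np.ndarray:
    """Boolean mask selecting the non-water atoms of one named region."""
    if region not in partition.regions:
        raise RegionConfigError(f"unknown region {region!r}")
    chains = partition.regions[region]
    mask = np.zeros(len(reference), dtype=bool)
    for c, res_ids in chains.items():
        mask |= (
            (reference.chain_id == c)
            & np.isin(reference.res_id, sorted(res_ids))
            & ~reference.is_water
        )
    return mask
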