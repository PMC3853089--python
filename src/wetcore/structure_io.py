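"""Reading, normalizing and measuring crystal structures.

A :class:`Structure` is a flat, array-backed collection of heavy atoms
(hydrogens are dropped on read; crystallographic waters are kept).  Solvent
accessible surface area is computed per atom with a deterministic
sphere-sampling method (Shrake-Rupley with a Fibonacci point set, via
biotite), so that repeated runs with the same sampling resolution agree
bit-for-bit.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np

import biotite.structure as _bst
import biotite.structure.io.pdb as _bpdb

from .errors import (
    ChainNotFoundError,
    EmptyModelError,
    PDBParseError,
    RadiusAssignmentError,
)
from .radii import lookup_radii

#: residue names treated as water molecules
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL", "TIP3"})

#: elements removed on read (heavy atoms only)
_HYDROGEN_ELEMENTS = frozenset({"H", "D", "T"})


@dataclass
class Structure:
    """Heavy-atom coordinate set with per-atom annotations.

    All fields are parallel arrays of length ``n_atoms``; ``subset`` returns a
    new :class:`Structure` restricted to a boolean mask, preserving order and
    the persistent ``serial`` identifiers.
    """

    serial: np.ndarray  # int, unique per atom
    chain_id: np.ndarray  # str
    res_id: np.ndarray  # int
    icode: np.ndarray  # str, insertion code ('' if none)
    res_name: np.ndarray  # str, 3-letter code
    atom_name: np.ndarray  # str
    element: np.ndarray  # str, upper-case symbol
    coord: np.ndarray  # (n, 3) float64, Angstrom
    b_factor: np.ndarray  # float, Angstrom^2
    occupancy: np.ndarray  # float
    is_water: np.ndarray  # bool
    hetero: np.ndarray  # bool (HETATM record)
    radius: np.ndarray | None = None  # float, Angstrom; None until assigned
    structure_id: str = ""
    resolution: float | None = None
    radii_table: str | None = None

    def __len__(self) -> int:
        return int(self.coord.shape[0])

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers of non-water atoms, in order of first appearance."""
        mask = ~self.is_water
        seen: dict[str, None] = {}
        for c in self.chain_id[mask]:
            seen.setdefault(str(c))
        return list(seen)

    def chain_mask(self, chain: str, include_water: bool = False) -> np.ndarray:
        mask = self.chain_id == chain
        if not include_water:
            mask = mask & ~self.is_water
        return mask

    def require_chain(self, chain: str) -> None:
        if not np.any((self.chain_id == chain) & ~self.is_water):
            raise ChainNotFoundError(
                f"chain {chain!r} not found (available: {', '.join(self.chains)})"
            )

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape != (len(self),):
            raise ValueError("boolean mask length mismatch")
        return replace(
            self,
            serial=self.serial[mask],
            chain_id=self.chain_id[mask],
            res_id=self.res_id[mask],
            icode=self.icode[mask],
            res_name=self.res_name[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            coord=self.coord[mask],
            b_factor=self.b_factor[mask],
            occupancy=self.occupancy[mask],
            is_water=self.is_water[mask],
            hetero=self.hetero[mask],
            radius=None if self.radius is None else self.radius[mask],
        )

    def copy(self) -> "Structure":
        return self.subset(np.ones(len(self), dtype=bool))

    def residue_key(self, i: int) -> tuple[str, int, str]:
        """(chain_id, res_id, icode) of atom ``i`` — the residue identity."""
        return (str(self.chain_id[i]), int(self.res_id[i]), str(self.icode[i]))

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [self.residue_key(i) for i in range(len(self))]

    def atom_label(self, i: int) -> str:
        """Human-readable atom label, e.g. ``A:GLU104:CG`` or ``B2077`` for waters."""
        if self.is_water[i]:
            return f"{self.chain_id[i]}{self.res_id[i]}"
        return f"{self.chain_id[i]}:{self.res_name[i]}{self.res_id[i]}{self.icode[i]}:{self.atom_name[i]}"


@dataclass(frozen=True)
class SasaMap:
    """Per-atom solvent accessible surface area (A^2) and its sampling parameters."""

    values: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(np.sum(self.values))

    def __getitem__(self, i):
        return self.values[i]


_RESOLUTION_RE = re.compile(r"REMARK\s+2\s+RESOLUTION\.\s+([\d.]+)\s+ANGSTROM")


def _find_bad_line(pdb_text: str) -> str | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            return f"line {lineno}: truncated record: {line!r}"
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            return f"line {lineno}: unparsable coordinates: {line!r}"
    return None


def read_structure(
    pdb_text: str,
    model_index: int = 1,
    *,
    keep_hetero: bool = False,
    structure_id: str = "",
) -> Structure:
    """Parse PDB-format text into a heavy-atom :class:`Structure`.

    Hydrogens are always dropped.  Non-water heteroatoms (ligands, ions) are
    dropped unless ``keep_hetero`` is set; waters are always kept.  Alternate
    locations are resolved to the highest-occupancy conformer (ties broken by
    altloc label order).  ``model_index`` is 1-based, selecting the MODEL
    record of multi-model files.

    Raises
    ------
    PDBParseError
        Malformed ATOM/HETATM record (the message names the line) or a
        missing model.
    EmptyModelError
        The selected model has no atoms.
    """
    try:
        pfile = _bpdb.PDBFile.read(io.StringIO(pdb_text))
        arr = _bpdb.get_structure(
            pfile,
            model=model_index,
            altloc="occupancy",
            extra_fields=["b_factor", "occupancy", "atom_id"],
        )
    except Exception as exc:  # biotite raises several types; re-raise with context
        detail = _find_bad_line(pdb_text)
        if detail is not None:
            raise PDBParseError(detail) from exc
        raise PDBParseError(f"cannot parse PDB text (model {model_index}): {exc}") from exc

    if arr.array_length() == 0:
        raise EmptyModelError(f"model {model_index} contains no atoms")

    element = np.char.upper(arr.element.astype("U4"))
    res_name = np.char.upper(arr.res_name.astype("U4"))
    is_water = np.isin(res_name, sorted(WATER_RESNAMES))

    keep = ~np.isin(element, sorted(_HYDROGEN_ELEMENTS))
    if not keep_hetero:
        keep &= ~arr.hetero | is_water

    resolution = None
    m = _RESOLUTION_RE.search(pdb_text)
    if m:
        resolution = float(m.group(1))

    n = int(np.sum(keep))
    if n == 0:
        raise EmptyModelError(f"model {model_index} contains no retained heavy atoms")

    return Structure(
        serial=arr.atom_id[keep].astype(np.int64),
        chain_id=arr.chain_id[keep].astype("U4"),
        res_id=arr.res_id[keep].astype(np.int64),
        icode=arr.ins_code[keep].astype("U1"),
        res_name=res_name[keep],
        atom_name=arr.atom_name[keep].astype("U4"),
        element=element[keep],
        coord=np.asarray(arr.coord[keep], dtype=np.float64),
        b_factor=arr.b_factor[keep].astype(np.float64),
        occupancy=arr.occupancy[keep].astype(np.float64),
        is_water=is_water[keep],
        hetero=arr.hetero[keep].astype(bool),
        structure_id=structure_id,
        resolution=resolution,
    )


def assign_radii(s: Structure, radii_table: str | dict = "protor") -> Structure:
    """Return a copy of ``s`` with per-atom radii from ``radii_table``.

    ``radii_table`` is either the name of a shipped table (``"protor"``,
    ``"single"``, ``"simple"``) or a mapping ``element -> radius`` with an
    optional ``"*"`` default key.  The table identity is recorded on the
    structure so downstream reports can state it.
    """
    radii = lookup_radii(s.res_name, s.atom_name, s.element, radii_table)
    if np.any(radii <= 0) or np.any(~np.isfinite(radii)):
        bad = int(np.flatnonzero((radii <= 0) | ~np.isfinite(radii))[0])
        raise RadiusAssignmentError(
            f"no positive radius for atom {s.atom_label(bad)} (element {s.element[bad]})"
        )
    out = s.copy()
    out.radius = radii
    out.radii_table = radii_table if isinstance(radii_table, str) else "custom"
    return out


def _to_atom_array(s: Structure) -> _bst.AtomArray:
    # Throwaway array for the SASA kernel.  Radii are passed explicitly, so
    # names are irrelevant — but biotite silently deletes atoms it classifies
    # as solvent/ions (by residue name) from the computation, so every atom is
    # disguised as a generic non-hetero residue to keep waters as first-class
    # occluders and SASA targets.
    arr = _bst.AtomArray(len(s))
    arr.coord = np.asarray(s.coord, dtype=np.float32)
    arr.chain_id = s.chain_id
    arr.res_id = s.res_id
    arr.res_name = np.full(len(s), "UNK", dtype="U4")
    arr.atom_name = s.atom_name
    arr.element = s.element
    arr.hetero = np.zeros(len(s), dtype=bool)
    return arr


def compute_sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaMap:
    """Per-atom solvent accessible surface area of the whole structure.

    Every atom of ``s`` (waters included) occludes every other; the result is
    deterministic for a fixed ``n_points`` (Fibonacci sphere sampling).
    """
    if s.radius is None:
        raise RadiusAssignmentError("radii must be assigned before computing SASA")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    arr = _to_atom_array(s)
    values = _bst.sasa(
        arr,
        probe_radius=float(probe),
        point_number=int(n_points),
        point_distr="Fibonacci",
        vdw_radii=np.asarray(s.radius, dtype=np.float64),
        ignore_ions=False,
    )
    values = np.asarray(values, dtype=np.float64)
    if np.any(~np.isfinite(values)):
        raise RuntimeError("SASA kernel returned non-finite values")
    return SasaMap(values=values, probe_radius=float(probe), n_points=int(n_points))


def to_pdb(s: Structure) -> str:
    """Serialize a :class:`Structure` as PDB-format text (single model)."""
    lines = []
    for i in range(len(s)):
        record = "HETATM" if s.hetero[i] else "ATOM"
        name = str(s.atom_name[i])
        # PDB convention: 1-char element names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 and len(str(s.element[i])) == 1 else f"{name:<4s}"
        x, y, z = s.coord[i]
        lines.append(
            f"{record:<6s}{int(s.serial[i]) % 100000:>5d} {name_field}"
            f"{'':1s}{str(s.res_name[i]):<3s} {str(s.chain_id[i])[:1]:1s}"
            f"{int(s.res_id[i]) % 10000:>4d}{str(s.icode[i]):1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{s.occupancy[i]:6.2f}{s.b_factor[i]:6.2f}"
            f"          {str(s.element[i]):>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def frames_to_pdb(frames: list[Structure]) -> str:
    """Serialize a list of conformers of the same topology as a multi-model PDB."""
    chunks = []
    for k, f in enumerate(frames, start=1):
        body = to_pdb(f).replace("END\n", "")
        chunks.append(f"MODEL     {k:>4d}\n{body}ENDMDL\n")
    return "".join(chunks) + "END\n"


def read_frames(pdb_text: str, **kwargs) -> list[Structure]:
    """Read every model of a multi-model PDB as a list of :class:`Structure`."""
    pfile = _bpdb.PDBFile.read(io.StringIO(pdb_text))
    n_models = pfile.get_model_count()
    return [read_structure(pdb_text, model_index=k, **kwargs) for k in range(1, n_models + 1)]
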