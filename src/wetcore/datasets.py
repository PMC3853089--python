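"""Locating accession coordinate files (bundled, local, or downloaded).

Lookup order for an accession like ``2JK2``:

1. ``$WETCORE_PDB_DIR/<code>.pdb``
2. the package's bundled ``data/pdb`` directory
3. a ``data/pdb`` directory under the current working directory
4. download from RCSB (requires network; cached next to 1 or 3)

Raises :class:`~wetcore.errors.DataUnavailableError` when none succeeds.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
from pathlib import Path

from .errors import DataUnavailableError
from .structure_io import Structure, read_structure

_RCSB_URL = "https://files.rcsb.org/download/{code}.pdb"


def _candidate_dirs() -> list[Path]:
    dirs = []
    env = os.environ.get("WETCORE_PDB_DIR")
    if env:
        dirs.append(Path(env))
    dirs.append(Path(__file__).parent / "data" / "pdb")
    dirs.append(Path.cwd() / "data" / "pdb")
    return dirs


def accession_path(code: str) -> Path | None:
    """Return the path of a cached accession file, or None."""
    code = code.upper()
    for d in _candidate_dirs():
        for name in (f"{code}.pdb", f"{code.lower()}.pdb"):
            p = d / name
            if p.is_file():
                return p
    return None


def fetch_accession(code: str, timeout: float = 30.0) -> Path:
    """Locate or download the PDB file of an accession."""
    code = code.upper()
    p = accession_path(code)
    if p is not None:
        return p
    url = _RCSB_URL.format(code=code)
    last_err: Exception | None = None
    payload: bytes | None = None
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            payload = resp.read()
    except (urllib.error.URLError, OSError, ValueError) as exc:
        last_err = exc
    if payload:
        for d in _candidate_dirs():
            try:
                d.mkdir(parents=True, exist_ok=True)
                target = d / f"{code}.pdb"
                target.write_bytes(payload)
                return target
            except OSError as exc:
                last_err = exc
    raise DataUnavailableError(
        f"accession {code} is not bundled and could not be downloaded from {url} "
        f"({last_err}); place {code}.pdb in $WETCORE_PDB_DIR or ./data/pdb"
    )


def load_accession(code: str, **read_kwargs) -> Structure:
    """Read an accession into a :class:`Structure` (see :func:`fetch_accession`)."""
    path = fetch_accession(code)
    return read_structure(
        path.read_text(), structure_id=code.upper(), **read_kwargs
    )
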