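"""Heavy-atom van der Waals radii tables.

Shipped tables:

``"protor"``
    The ProtOr united-atom group radii (Tsai/Taylor/Chothia/Gerstein set as
    distributed with biotite), resolved per residue/atom name, with an
    element-based fallback for atoms outside the table (waters, unusual
    names).  This is the default.
``"single"``
    Element-based radii (Bondi-style single-atom set from biotite).
``"simple"``
    A small element table commonly used for protein SASA work
    (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80).

A custom ``dict`` mapping element symbols to radii is also accepted; the key
``"*"`` provides a default for unlisted elements.
"""

from __future__ import annotations

import numpy as np

from biotite.structure.info import vdw_radius_protor, vdw_radius_single

from .errors import RadiusAssignmentError

SIMPLE_TABLE: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

_TABLE_NAMES = ("protor", "single", "simple")


def _single_radius(element: str) -> float | None:
    try:
        return vdw_radius_single(element.capitalize())
    except Exception:
        return None


def lookup_radii(res_name, atom_name, element, radii_table="protor") -> np.ndarray:
    """Resolve a radius for every atom; raises on unknown elements without default."""
    n = len(element)
    out = np.empty(n, dtype=np.float64)

    if isinstance(radii_table, dict):
        for i in range(n):
            el = str(element[i]).upper()
            r = radii_table.get(el, radii_table.get("*"))
            if r is None:
                raise RadiusAssignmentError(
                    f"element {el!r} not in custom radii table and no '*' default"
                )
            out[i] = float(r)
        return out

    if radii_table not in _TABLE_NAMES:
        raise RadiusAssignmentError(
            f"unknown radii table {radii_table!r}; available: {_TABLE_NAMES}"
        )

    cache: dict[tuple[str, str], float] = {}
    for i in range(n):
        el = str(element[i]).upper()
        if radii_table == "simple":
            r = SIMPLE_TABLE.get(el)
            if r is None:
                r = _single_radius(el)
        elif radii_table == "single":
            r = _single_radius(el)
        else:  # protor with element fallback
            key = (str(res_name[i]).upper(), str(atom_name[i]).upper())
            r = cache.get(key)
            if r is None:
                try:
                    r = vdw_radius_protor(key[0], key[1])
                except Exception:
                    r = None
                if r is None:
                    r = _single_radius(el)
                if r is not None:
                    cache[key] = r
        if r is None:
            raise RadiusAssignmentError(
                f"no radius for element {el!r} (residue {res_name[i]}, atom {atom_name[i]}) "
                f"in table {radii_table!r}"
            )
        out[i] = float(r)
    return out
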