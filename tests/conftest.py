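import numpy as np
import pytest

from wetcore.structure_io import Structure


def build_structure(
    coords,
    elements=None,
    waters=None,
    chains=None,
    res_ids=None,
    atom_names=None,
    res_names=None,
    b_factors=None,
    radii=None,
):
    """Construct a Structure directly from arrays (test scaffolding)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    waters = np.asarray(waters if waters is not None else [False] * n, dtype=bool)
    elements = np.asarray(
        elements if elements is not None else ["O" if w else "C" for w in waters],
        dtype="U2",
    )
    if res_names is None:
        res_names = ["HOH" if w else "UNK" for w in waters]
    if atom_names is None:
        atom_names = ["O" if w else "CA" for w in waters]
    s = Structure(
        serial=np.arange(1, n + 1, dtype=np.int64),
        chain_id=np.asarray(chains if chains is not None else ["A"] * n, dtype="U4"),
        res_id=np.asarray(
            res_ids if res_ids is not None else np.arange(1, n + 1), dtype=np.int64
        ),
        icode=np.full(n, "", dtype="U1"),
        res_name=np.asarray(res_names, dtype="U4"),
        atom_name=np.asarray(atom_names, dtype="U4"),
        element=elements,
        coord=coords,
        b_factor=np.asarray(
            b_factors if b_factors is not None else np.zeros(n), dtype=np.float64
        ),
        occupancy=np.ones(n, dtype=np.float64),
        is_water=waters,
        hetero=waters.copy(),
        structure_id="test",
    )
    if radii is not None:
        s.radius = np.asarray(radii, dtype=np.float64)
    else:
        s.radius = np.where(s.is_water, 1.52, 1.7)
    return s


def pdb_line(
    record="ATOM",
    serial=1,
    name="CA",
    altloc=" ",
    res_name="GLY",
    chain="A",
    res_id=1,
    icode=" ",
    xyz=(0.0, 0.0, 0.0),
    occupancy=1.0,
    b=20.0,
    element="C",
):
    """One fixed-width PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{res_name:>3s} {chain}"
        f"{res_id:>4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{b:6.2f}          {element:>2s}"
    )


def cascade_tube():
    """Open tube sheltering two stacked waters; pruning removes them in 2 rounds.

    The outer water (z = 4.2) sits at the mouth and is bulk-exposed; it covers
    the only open cap of the inner water (z = 2.0).  Geometry was chosen so
    that, with probe 1.4 A and the 10 A^2 threshold: outer SASA ~ 43, inner
    SASA ~ 0 (outer present) and ~ 14 (outer removed).
    """
    ring_radius = 4.2
    coords = []
    for k in range(2):  # rings at z = 0 and z = 2
        for a in range(12):
            th = 2 * np.pi * a / 12 + (np.pi / 12 if k % 2 else 0)
            coords.append(
                [ring_radius * np.cos(th), ring_radius * np.sin(th), 2.0 * k]
            )
    for r, na in [(0.0, 1), (1.9, 8)]:  # floor plug at z = -2
        for a in range(na):
            th = 2 * np.pi * a / na
            coords.append([r * np.cos(th), r * np.sin(th), -2.0])
    n_protein = len(coords)
    coords.append([0.0, 0.0, 2.0])  # inner water
    coords.append([0.0, 0.0, 4.2])  # outer water
    waters = [False] * n_protein + [True, True]
    return build_structure(coords, waters=waters)


def closed_cage(center=(0.0, 0.0, 0.0)):
    """A 3x3x3 carbon lattice (spacing 3.5) with a water in the vacant center."""
    center = np.asarray(center, dtype=np.float64)
    coords = []
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if i == j == k == 0:
                    continue
                coords.append(center + 3.5 * np.array([i, j, k], dtype=np.float64))
    coords.append(center)
    waters = [False] * 26 + [True]
    return build_structure(coords, waters=waters)


@pytest.fixture(scope="session")
def slab_wet_core():
    from wetcore.synthetic_data import SyntheticSpec, make_slab_dimer

    return make_slab_dimer(SyntheticSpec(seed=7, n_core_waters=16, n_rim_waters=0))


@pytest.fixture(scope="session")
def slab_dry_core():
    from wetcore.synthetic_data import SyntheticSpec, make_slab_dimer

    return make_slab_dimer(SyntheticSpec(seed=7, n_core_waters=0, n_rim_waters=12))


@pytest.fixture(scope="session")
def wet_core_result(slab_wet_core):
    from wetcore.pipeline import PipelineConfig, run_interface_pipeline

    s, _ = slab_wet_core
    return run_interface_pipeline(s, "A", "B", PipelineConfig(radii_table="simple"))
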