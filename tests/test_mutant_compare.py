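import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wetcore.errors import (
    BFactorNormalizationError,
    RegionConfigError,
    SuperpositionError,
)
from wetcore.mutant_compare import (
    RegionPartition,
    assign_waters_to_regions,
    delta_bstar_profile,
    kabsch,
    normalize_bfactors,
    pair_and_superimpose,
    region_selection,
    rmsd_over_frames,
    water_reappearance,
)
from wetcore.pipeline import PipelineConfig, run_interface_pipeline
from wetcore.synthetic_data import SyntheticSpec, make_mutant_copy, make_slab_dimer

from conftest import build_structure


def rigid_copy(s, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    out = s.copy()
    out.coord = s.coord @ rot.T + shift
    return out


CFG = PipelineConfig(radii_table="simple")


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot, trans = kabsch(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0, atol=1e-10)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 3))
        true_rot = Rotation.random(random_state=rng).as_matrix()
        moved = pts @ true_rot.T + [3.0, -1.0, 8.0]
        rot, trans = kabsch(moved, pts)
        assert np.allclose(moved @ rot.T + trans, pts, atol=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)


class TestPairAndSuperimpose:
    def test_identical_structures(self, slab_wet_core):
        s, _ = slab_wet_core
        sup = pair_and_superimpose(s, s)
        assert sup.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in sup.per_residue_rmsd.values())

    def test_rigid_copy_rmsd_zero(self, slab_wet_core):
        s, _ = slab_wet_core
        sup = pair_and_superimpose(s, rigid_copy(s, seed=3))
        assert sup.global_rmsd == pytest.approx(0.0, abs=1e-8)

    def test_pairing_one_to_one(self, slab_wet_core):
        s, _ = slab_wet_core
        sup = pair_and_superimpose(s, s)
        refs = [r for r, _ in sup.residue_pairing]
        mobs = [m for _, m in sup.residue_pairing]
        assert len(refs) == len(set(refs)) and len(mobs) == len(set(mobs))

    def test_length_mismatch_errors_listing_residues(self, slab_wet_core):
        s, _ = slab_wet_core
        truncated = s.subset(~((s.chain_id == "A") & (s.res_id == 1)))
        with pytest.raises(SuperpositionError, match="A1"):
            pair_and_superimpose(s, truncated)
        sup = pair_and_superimpose(s, truncated, on_mismatch="ignore")
        assert sup.global_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_atoms_errors(self):
        s = build_structure([[0, 0, 0], [3, 0, 0]], res_ids=[1, 2])
        with pytest.raises(SuperpositionError):
            pair_and_superimpose(s, s)

    def test_cross_chain_self_comparison(self, slab_wet_core):
        # homodimer-style check: chain B is a rigidly moved copy of chain A,
        # so superimposing B onto A by residue number gives zero RMSD
        s, _ = slab_wet_core
        a_only = s.subset(s.chain_mask("A"))
        b_copy = rigid_copy(a_only, seed=12)
        b_copy.chain_id = np.full(len(b_copy), "B", dtype="U4")
        b_copy.serial = b_copy.serial + len(a_only)
        import dataclasses

        both = dataclasses.replace(
            a_only,
            serial=np.concatenate([a_only.serial, b_copy.serial]),
            chain_id=np.concatenate([a_only.chain_id, b_copy.chain_id]),
            res_id=np.concatenate([a_only.res_id, b_copy.res_id]),
            icode=np.concatenate([a_only.icode, b_copy.icode]),
            res_name=np.concatenate([a_only.res_name, b_copy.res_name]),
            atom_name=np.concatenate([a_only.atom_name, b_copy.atom_name]),
            element=np.concatenate([a_only.element, b_copy.element]),
            coord=np.concatenate([a_only.coord, b_copy.coord]),
            b_factor=np.concatenate([a_only.b_factor, b_copy.b_factor]),
            occupancy=np.concatenate([a_only.occupancy, b_copy.occupancy]),
            is_water=np.concatenate([a_only.is_water, b_copy.is_water]),
            hetero=np.concatenate([a_only.hetero, b_copy.hetero]),
            radius=None,
        )
        sup = pair_and_superimpose(both, both, chain_pairs=[("A", "B")])
        assert sup.global_rmsd == pytest.approx(0.0, abs=1e-8)
        assert set(k[0] for k in sup.per_residue_rmsd) == {"A"}


class TestWaterReappearance:
    def test_identical_sets_all_matched_at_zero(self, wet_core_result):
        iface = wet_core_result.interface
        corr = water_reappearance(iface, iface, None)
        assert corr.n_reappearing == iface.n_water
        assert all(d == pytest.approx(0.0) for _, _, d in corr.matched)
        assert not corr.unmatched_wt and not corr.unmatched_mut

    def test_mutually_nearest_but_far_not_matched(self):
        wt = build_structure([[0, 0, 0], [20, 0, 0], [0, 0, 9]],
                             chains=["A", "B", "S"], waters=[False, False, True])
        mut = build_structure([[0, 0, 0], [20, 0, 0], [1.5, 0, 9]],
                              chains=["A", "B", "S"], waters=[False, False, True])
        from wetcore.interface_graph import TripartiteInterface

        wt_iface = TripartiteInterface(wt, "A", "B", frozenset({0}), frozenset({1}),
                                       frozenset({2}), frozenset())
        mut_iface = TripartiteInterface(mut, "A", "B", frozenset({0}), frozenset({1}),
                                        frozenset({2}), frozenset())
        corr = water_reappearance(wt_iface, mut_iface, None, cutoff=1.0)
        assert corr.n_reappearing == 0
        assert len(corr.mutual_far) == 1
        assert corr.mutual_far[0][2] == pytest.approx(1.5)

    def test_symmetry(self, slab_wet_core):
        s, truth = slab_wet_core
        mut = make_mutant_copy(s, jitter_sd=0.15, seed=11)
        wt_res = run_interface_pipeline(s, "A", "B", CFG)
        mut_res = run_interface_pipeline(mut, "A", "B", CFG)
        fwd = water_reappearance(wt_res.interface, mut_res.interface, None)
        rev = water_reappearance(mut_res.interface, wt_res.interface, None)
        assert {(a, b) for a, b, _ in fwd.matched} == {(b, a) for a, b, _ in rev.matched}

    def test_cutoff_monotonicity(self, slab_wet_core):
        s, _ = slab_wet_core
        mut = make_mutant_copy(s, jitter_sd=0.4, seed=5)
        wt_res = run_interface_pipeline(s, "A", "B", CFG)
        mut_res = run_interface_pipeline(mut, "A", "B", CFG)
        counts = [
            water_reappearance(wt_res.interface, mut_res.interface, None, cutoff=c).n_reappearing
            for c in (0.1, 0.3, 0.6, 1.0, 2.0)
        ]
        assert counts == sorted(counts)

    def test_empty_side_all_unmatched(self, wet_core_result):
        from wetcore.interface_graph import TripartiteInterface

        iface = wet_core_result.interface
        empty = TripartiteInterface(
            iface.structure, "A", "B", iface.side1_atoms, iface.side2_atoms,
            frozenset(), frozenset(),
        )
        corr = water_reappearance(iface, empty, None)
        assert corr.n_reappearing == 0
        assert set(corr.unmatched_wt) == set(iface.water_atoms)


def site_structure(n=40, seed=2):
    """Linear chain with a CG-bearing residue at one end."""
    rng = np.random.default_rng(seed)
    coords = [[2.0 * i, 0.0, 0.0] for i in range(n)]
    atom_names = ["CG" if i == 0 else "CA" for i in range(n)]
    res_ids = list(range(1, n + 1))
    b = 10.0 + rng.uniform(0, 10, size=n)
    return build_structure(coords, atom_names=atom_names, res_ids=res_ids, b_factors=b)


class TestNormalizeBFactors:
    def test_zscore_trivials(self):
        s = site_structure()
        nb = normalize_bfactors(s, [1], exclusion_radius=15.0)
        ref_b = s.b_factor[nb.reference_mask]
        i = int(np.flatnonzero(nb.reference_mask)[0])
        s2 = s.copy()
        s2.b_factor[i] = nb.reference_mean
        # recompute on modified copy: that atom must land at ~0 under old stats
        assert (s.b_factor[i] - nb.reference_mean) / nb.reference_sd == pytest.approx(nb.bstar[i])
        assert nb.reference_mean == pytest.approx(float(np.mean(ref_b)))
        assert nb.reference_sd == pytest.approx(float(np.std(ref_b)))

    def test_hand_arithmetic(self):
        coords = [[0, 0, 0]] + [[20 + i, 0, 0] for i in range(12)]
        names = ["CG"] + ["CA"] * 12
        b = [50.0] + [10, 12, 14, 10, 12, 14, 10, 12, 14, 10, 12, 14]
        s = build_structure(coords, atom_names=names, res_ids=range(1, 14), b_factors=b)
        nb = normalize_bfactors(s, [1], exclusion_radius=15.0)
        mean, sd = 12.0, np.std([10, 12, 14] * 4)
        assert nb.reference_mean == pytest.approx(mean)
        assert nb.reference_sd == pytest.approx(sd)
        assert nb.bstar[0] == pytest.approx((50 - mean) / sd)
        assert nb.bstar[1] == pytest.approx((10 - mean) / sd)

    def test_shift_invariance_and_scale_equivariance(self):
        s = site_structure(seed=4)
        nb = normalize_bfactors(s, [1])
        shifted = s.copy()
        shifted.b_factor = s.b_factor + 7.5
        assert np.allclose(normalize_bfactors(shifted, [1]).bstar, nb.bstar)
        scaled = s.copy()
        scaled.b_factor = s.b_factor * 3.0
        assert np.allclose(normalize_bfactors(scaled, [1]).bstar, nb.bstar)

    def test_waters_normalized_but_not_reference(self):
        s = site_structure()
        s.is_water[-1] = True
        nb = normalize_bfactors(s, [1])
        assert not nb.reference_mask[-1]
        assert np.isfinite(nb.bstar[-1])

    def test_missing_cg_errors(self):
        s = build_structure([[0, 0, 0], [30, 0, 0]], res_ids=[1, 2])
        with pytest.raises(BFactorNormalizationError, match="C-gamma"):
            normalize_bfactors(s, [1])

    def test_small_reference_set_errors(self):
        s = site_structure(n=5)
        with pytest.raises(BFactorNormalizationError):
            normalize_bfactors(s, [1], exclusion_radius=15.0)

    def test_zero_spread_errors(self):
        s = site_structure()
        s.b_factor[:] = 20.0
        with pytest.raises(BFactorNormalizationError):
            normalize_bfactors(s, [1])


class TestRegionPartition:
    def test_yaml_roundtrip_and_lookup(self):
        text = "A:\n  A: [1, 2]\n  B: [1, 2]\nD:\n  A: [3]\n  B: [3]\n"
        part = RegionPartition.from_yaml(text)
        assert part.region_of("A", 2) == "A"
        assert part.region_of("B", 3) == "D"
        assert part.region_of("A", 99) is None
        assert part.names() == ["A", "D"]

    def test_overlap_rejected(self):
        with pytest.raises(RegionConfigError):
            RegionPartition.from_dict({"A": {"A": [1]}, "B": {"A": [1]}})

    def test_uncovered_residue_errors(self):
        part = RegionPartition.from_dict({"A": {"A": [1]}})
        with pytest.raises(RegionConfigError):
            part.region_of_residue(("A", 5, ""))

    def test_region_selection_mask(self, slab_wet_core):
        s, truth = slab_wet_core
        mask = region_selection(s, truth.regions, "A")
        assert mask.any()
        for i in np.flatnonzero(mask):
            assert truth.residue_region[(str(s.chain_id[i]), int(s.res_id[i]))] == "A"

    def test_unknown_region_errors(self, slab_wet_core):
        s, truth = slab_wet_core
        with pytest.raises(RegionConfigError):
            region_selection(s, truth.regions, "Z")


class TestWaterRegionAssignment:
    def test_majority_vote(self, slab_wet_core):
        s, truth = slab_wet_core
        res = run_interface_pipeline(s, "A", "B", CFG)
        assignment = assign_waters_to_regions(res.interface, truth.regions)
        # core waters sit among region-A residues by construction
        pruned = res.structure
        core = set(truth.core_water_res_ids)
        for w, region in assignment.items():
            if int(pruned.res_id[w]) in core:
                assert region == "A"


def central_region_sites(s, truth, region="A", k=4):
    """Residues of a region closest to its in-plane centroid (mutation-site stand-ins)."""
    in_region = np.array(
        [
            not s.is_water[i]
            and truth.residue_region[(str(s.chain_id[i]), int(s.res_id[i]))] == region
            for i in range(len(s))
        ]
    )
    centroid = s.coord[in_region][:, :2].mean(axis=0)
    cg = {}
    for i in np.flatnonzero(in_region):
        if s.chain_id[i] == "A" and s.atom_name[i] == "CG":
            d = float(np.linalg.norm(s.coord[i][:2] - centroid))
            rid = int(s.res_id[i])
            if rid not in cg or d < cg[rid]:
                cg[rid] = d
    return sorted(cg, key=cg.get)[:k]


class TestDeltaBstarProfile:
    def test_identical_structures_all_zero(self, slab_wet_core):
        s, truth = slab_wet_core
        res = run_interface_pipeline(s, "A", "B", CFG)
        site = min(r for (c, r), reg in truth.residue_region.items()
                   if reg == "A" and c == "A")
        nb = normalize_bfactors(res.structure, [site])
        sup = pair_and_superimpose(res.structure, res.structure)
        corr = water_reappearance(res.interface, res.interface, sup)
        waters_tbl, atoms_tbl = delta_bstar_profile(
            nb, nb, corr, truth.regions, res.burial, res.interface, res.interface, sup
        )
        assert np.allclose(waters_tbl["delta_bstar"], 0.0)
        assert np.allclose(atoms_tbl["mean_delta_bstar"], 0.0)

    def test_region_shift_localized(self, slab_wet_core):
        s, truth = slab_wet_core
        shift = 8.0
        mut = make_mutant_copy(s, bshift={"A": shift}, regions=truth.regions, seed=3)
        wt_res = run_interface_pipeline(s, "A", "B", CFG)
        mut_res = run_interface_pipeline(mut, "A", "B", CFG)
        sites = central_region_sites(s, truth)
        wt_nb = normalize_bfactors(wt_res.structure, sites)
        mut_nb = normalize_bfactors(mut_res.structure, sites)
        sup = pair_and_superimpose(wt_res.structure, mut_res.structure)
        corr = water_reappearance(wt_res.interface, mut_res.interface, sup)
        _, atoms_tbl = delta_bstar_profile(
            wt_nb, mut_nb, corr, truth.regions, wt_res.burial,
            wt_res.interface, mut_res.interface, sup,
        )
        by_region = atoms_tbl.groupby("region")["mean_delta_bstar"].mean()
        assert by_region["A"] > 1.5
        for name in by_region.index:
            if name != "A":
                assert abs(by_region[name]) < 0.5


class TestRmsdOverFrames:
    def test_identical_frames_zero(self, slab_wet_core):
        s, _ = slab_wet_core
        out = rmsd_over_frames([s, s, s], s)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_rigid_motion_zero(self, slab_wet_core):
        s, _ = slab_wet_core
        out = rmsd_over_frames([rigid_copy(s, seed=k) for k in range(3)], s)
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_single_displacement_bound(self, slab_wet_core):
        s, _ = slab_wet_core
        sel = ~s.is_water
        n = int(sel.sum())
        d = 2.0
        frame = s.copy()
        i = int(np.flatnonzero(sel)[0])
        frame.coord[i] += [d, 0, 0]
        pre = float(np.sqrt(np.mean(np.sum(
            (frame.coord[sel] - s.coord[sel]) ** 2, axis=1))))
        assert pre == pytest.approx(d / np.sqrt(n))
        out = rmsd_over_frames([frame], s, selection=sel)
        assert 0 < out[0] <= pre + 1e-9

    def test_region_selection_series(self, slab_wet_core):
        s, truth = slab_wet_core
        rng = np.random.default_rng(8)
        frame = s.copy()
        mask_a = region_selection(s, truth.regions, "A")
        frame.coord = frame.coord + np.where(mask_a[:, None], rng.normal(0, 1.0, (len(s), 3)), 0.0)
        rmsd_a = rmsd_over_frames([frame], s, selection=mask_a)[0]
        mask_d = region_selection(s, truth.regions, "D")
        rmsd_d = rmsd_over_frames([frame], s, selection=mask_d)[0]
        assert rmsd_a > 0.5 > rmsd_d

    def test_atom_count_mismatch_names_frame(self, slab_wet_core):
        s, _ = slab_wet_core
        bad = s.subset(np.arange(len(s)) != 0)
        with pytest.raises(SuperpositionError, match="frame 1"):
            rmsd_over_frames([s, bad], s)
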