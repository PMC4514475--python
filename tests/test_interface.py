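"""Interface distances, dCintra, ligand monitors and orientation, ions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from porescope import (
    classify_ligand_orientation,
    dcintra,
    interface_distances,
    ion_occupancy,
    ion_z_distribution,
    ligand_contacts,
)
from porescope.errors import AbsenceError, TopologyError
from porescope.geometry import AxisFrame, apply_rigid_motion, symmetry_axis
from porescope.hydration import PoreRegion
from porescope.interface import ContactMonitor, SelSpec
from porescope.model import StructureFrame, Trajectory
from porescope import synthetic as syn

import oracles
from conftest import make_frame


def lab_axis():
    return AxisFrame(origin=np.zeros(3), z_axis=np.array([0.0, 0.0, 1.0]))


class TestInterfaceDistances:
    def test_open_pentamer_matches_direct_arithmetic(self, open_pentamer, topo):
        frame, _ = open_pentamer
        out = interface_distances(frame, topo)
        for chain_i, chain in enumerate(topo.chain_ids):
            pro = frame.coords[frame.indices(chain=chain, resseq=256, name="CA")][0]
            cys = frame.coords[frame.indices(chain=chain, resseq=(122, 136),
                                             name="CA")].mean(axis=0)
            lys = frame.coords[frame.indices(chain=chain, resseq=40, name="CA")][0]
            assert out["Pro256-CysLoop"][chain_i] == pytest.approx(
                np.linalg.norm(pro - cys), abs=1e-10)
            assert out["Pro256-Lys40"][chain_i] == pytest.approx(
                np.linalg.norm(pro - lys), abs=1e-10)

    def test_translation_invariance(self, open_pentamer, topo):
        frame, _ = open_pentamer
        base = interface_distances(frame, topo)
        moved = apply_rigid_motion(frame, np.eye(3), np.array([7.0, -3.0, 12.0]))
        after = interface_distances(moved, topo)
        for key in base:
            assert np.allclose(after[key], base[key], atol=1e-10)

    def test_missing_residue_raises(self, topo):
        f = make_frame([[0, 0, 0]], names=["CA"], resseqs=[1], chains=["A"])
        with pytest.raises(TopologyError):
            interface_distances(f, topo)


class TestDcintra:
    def test_constructed_separation_recovered(self, topo):
        for d in (14.6, 16.0):
            frame, gt = syn.build_pentamer(syn.open_blueprint(dcintra=d), topo)
            assert np.allclose(dcintra(frame, topo), d, atol=1e-9)

    def test_coincident_coms_give_zero(self, topo):
        frame, _ = syn.build_pentamer(syn.open_blueprint(dcintra=1e-12), topo)
        assert np.allclose(dcintra(frame, topo), 0.0, atol=1e-9)

    def test_randomized_fixture_matches_direct_arithmetic(self, open_pentamer,
                                                          topo, rng):
        frame, _ = open_pentamer
        jittered = frame.with_coords(
            frame.coords + rng.normal(scale=0.5, size=frame.coords.shape))
        vals = dcintra(jittered, topo)
        for i, chain in enumerate(topo.chain_ids):
            c = jittered.coords[jittered.indices(chain=chain, resseq=(179, 188),
                                                 name="CA")].mean(axis=0)
            b = jittered.coords[jittered.indices(chain=chain, resseq=(139, 140),
                                                 name="CA")].mean(axis=0)
            assert vals[i] == pytest.approx(np.linalg.norm(c - b), abs=1e-10)


class TestLigandContacts:
    def test_pair_distance(self, topo):
        f = make_frame([[0, 0, 0], [4.5, 0, 0]], names=["N1", "OH"],
                       resnames=["EPI", "TYR"], resseqs=[900, 87],
                       chains=["A", "A"], elements=["N", "O"])
        table = [ContactMonitor(
            "EPI-N1/TYR87-OH",
            a=SelSpec(names=["N1"], resname="EPI"),
            b=SelSpec(names=["OH"], resseq=87),
        )]
        out = ligand_contacts(f, topo, table, site_chains=["A"])
        assert out["EPI-N1/TYR87-OH"][0] == pytest.approx(4.5, abs=1e-12)

    def test_ring_centroid_equals_vertex_mean(self, open_pentamer, topo):
        frame, _ = open_pentamer
        names = [f"CR{i}" for i in range(1, 7)]
        spec = SelSpec(names=names, resseq=189, resname="TYR")
        centroid = spec.resolve(frame, topo, "A")
        idx = frame.indices(chain="A", resseq=189, name=names)
        assert np.allclose(centroid, frame.coords[idx].mean(axis=0), atol=1e-12)

    def test_full_monitor_set_matches_direct_arithmetic(self, open_pentamer, topo):
        frame, _ = open_pentamer
        table = [
            ContactMonitor("EPI-N1/TRP143-O",
                           a=SelSpec(names=["N1"], resname="EPI"),
                           b=SelSpec(names=["O"], resseq=143, resname="TRP")),
            ContactMonitor("EPI-CL/LEU103-N",
                           a=SelSpec(names=["CL"], resname="EPI"),
                           b=SelSpec(names=["N"], resseq=103, chain_offset=1)),
            ContactMonitor("EPI-bridge/TYR189-ring",
                           a=SelSpec(names=[f"C{i}" for i in range(1, 7)],
                                     resname="EPI"),
                           b=SelSpec(names=[f"CR{i}" for i in range(1, 7)],
                                     resseq=189, resname="TYR")),
        ]
        out = ligand_contacts(frame, topo, table)
        for mon in table:
            for s, chain in enumerate(topo.chain_ids):
                a = mon.a.resolve(frame, topo, chain)
                b = mon.b.resolve(frame, topo, chain)
                assert out[mon.name][s] == pytest.approx(
                    np.linalg.norm(a - b), abs=1e-10)

    def test_missing_ligand_raises(self, topo):
        f = make_frame([[0, 0, 0]], names=["CA"], resseqs=[87], chains=["A"])
        table = [ContactMonitor("x", a=SelSpec(names=["N1"], resname="EPI"),
                                b=SelSpec(names=["CA"], resseq=87))]
        with pytest.raises(AbsenceError):
            ligand_contacts(f, topo, table, site_chains=["A"])


class TestLigandOrientation:
    @pytest.mark.parametrize("orient", ["axial_up", "axial_down", "equatorial"])
    def test_constructed_orientations_recovered(self, topo, orient):
        frame, gt = syn.build_pentamer(
            syn.open_blueprint(ligand_orientation=orient), topo)
        classes = classify_ligand_orientation(frame, topo,
                                              symmetry_axis(frame, topo))
        assert classes == [orient] * 5

    def test_classes_partition_every_site(self, topo, rng):
        frame, _ = syn.build_pentamer(
            syn.open_blueprint(noise_sigma=0.5, seed=5), topo)
        classes = classify_ligand_orientation(frame, topo,
                                              symmetry_axis(frame, topo))
        assert len(classes) == 5
        assert all(c in ("axial_up", "axial_down", "equatorial", "intermediate")
                   for c in classes)

    def test_missing_reference_atom_raises(self, topo, open_pentamer):
        frame, _ = open_pentamer
        with pytest.raises(AbsenceError):
            classify_ligand_orientation(frame, topo,
                                        symmetry_axis(frame, topo),
                                        reference_atom="BR")


def ion_frame(cat_pos, an_pos):
    pos = list(cat_pos) + list(an_pos)
    n_c, n_a = len(cat_pos), len(an_pos)
    return make_frame(
        pos,
        names=["SOD"] * n_c + ["CLA"] * n_a,
        resnames=["SOD"] * n_c + ["CLA"] * n_a,
        resseqs=list(range(1, n_c + n_a + 1)),
        chains=["I"] * (n_c + n_a),
        elements=["NA"] * n_c + ["CL"] * n_a,
    )


def static_traj(frame, n=10):
    return Trajectory(frame, np.repeat(frame.coords[None], n, axis=0),
                      np.arange(n) * 0.1)


class TestIons:
    def test_fixed_cations_pool_into_one_bin(self):
        f = ion_frame([[0, 0, -25.0]] * 3, [])
        # distinct serials/resseqs already ensured by ion_frame
        traj = static_traj(f, n=10)
        edges, counts = ion_z_distribution(traj, lab_axis(), "cation",
                                           (-30, 0), bin_width=2.0)
        assert counts.sum() == 30
        b = np.searchsorted(edges, -25.0, side="right") - 1
        assert counts[b] == 30

    def test_no_anions_gives_empty_histogram(self):
        f = ion_frame([[0, 0, -25.0]], [])
        traj = static_traj(f, 5)
        _, counts = ion_z_distribution(traj, lab_axis(), "anion", (-30, 0), 2.0)
        assert counts.sum() == 0

    def test_random_placements_match_brute_force_binning(self, rng):
        pos = np.column_stack([rng.uniform(-5, 5, 20), rng.uniform(-5, 5, 20),
                               rng.uniform(-28, -2, 20)])
        f = ion_frame(pos, [])
        traj = static_traj(f, 3)
        edges, counts = ion_z_distribution(traj, lab_axis(), "cation",
                                           (-30, 0), 2.0, lateral_radius=10.0)
        keep = np.hypot(pos[:, 0], pos[:, 1]) <= 10.0
        expect = oracles.bin_counts(pos[keep, 2], edges) * 3
        assert np.array_equal(counts, expect)

    def test_histogram_sum_equals_inrange_ions_times_frames(self, rng):
        pos = np.column_stack([rng.uniform(-3, 3, 15), rng.uniform(-3, 3, 15),
                               rng.uniform(-29, -1, 15)])
        traj = static_traj(ion_frame(pos, []), 7)
        _, counts = ion_z_distribution(traj, lab_axis(), "cation", (-30, 0), 2.0)
        assert counts.sum() == 15 * 7

    def test_unknown_species_rejected(self):
        traj = static_traj(ion_frame([[0, 0, -5.0]], []), 2)
        with pytest.raises(ValueError):
            ion_z_distribution(traj, lab_axis(), "proton", (-30, 0), 2.0)

    def test_occupancy_of_scripted_walk(self):
        # one cation walks down the axis and crosses the −10<z<0 region
        f = ion_frame([[0, 0, 10.0]], [])
        zs = np.linspace(10, -20, 16)
        coords = np.array([[[0, 0, z]] for z in zs])
        traj = Trajectory(f, coords, np.arange(16) * 0.1)
        region = PoreRegion("below9p", -10.0, 0.0, 10.0)
        series = ion_occupancy(traj, lab_axis(), region, "cation")
        expect = ((zs >= -10) & (zs < 0)).astype(int)
        assert np.array_equal(series.values, expect)
        assert series.flags["max_simultaneous"] == 1

    def test_two_cations_in_region_counted_simultaneously(self):
        f = ion_frame([[0, 0, -5.0], [1.0, 0, -7.0]], [])
        traj = static_traj(f, 3)
        region = PoreRegion("below9p", -10.0, 0.0, 10.0)
        series = ion_occupancy(traj, lab_axis(), region, "cation")
        assert np.all(series.values == 2)
        assert series.flags["max_simultaneous"] == 2

    def test_histogram_invariant_under_frame_reordering(self, rng):
        pos1 = np.column_stack([rng.uniform(-3, 3, 8), rng.uniform(-3, 3, 8),
                                rng.uniform(-28, -2, 8)])
        pos2 = pos1 + np.array([0, 0, 3.0])
        f = ion_frame(pos1, [])
        coords_a = np.array([pos1, pos2])
        coords_b = np.array([pos2, pos1])
        ta = Trajectory(f, coords_a, np.array([0.0, 0.1]))
        tb = Trajectory(f, coords_b, np.array([0.0, 0.1]))
        _, ca = ion_z_distribution(ta, lab_axis(), "cation", (-30, 0), 2.0)
        _, cb = ion_z_distribution(tb, lab_axis(), "cation", (-30, 0), 2.0)
        assert np.array_equal(ca, cb)
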