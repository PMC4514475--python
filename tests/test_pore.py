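"""Crossed distances, pore-radius profile, tilt decomposition, twist."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from porescope import (
    crossed_distances,
    distance_distribution,
    m2_helix_axis,
    pore_radius_profile,
    tilt_angles,
    twist_angle,
)
from porescope.errors import TopologyError
from porescope.geometry import AxisFrame, apply_rigid_motion, symmetry_axis
from porescope.model import DescriptorSeries
from porescope.pore import VDW_RADII, resolve_ring
from porescope import synthetic as syn

from conftest import make_frame

PENTAGON_CHORD = 2 * np.sin(np.radians(72))  # crossed distance / circumradius


def pentagon_frame(R, resseq=246, z=0.0):
    """Five single-atom 'residues', one per chain, at regular pentagon
    vertices of circumradius R."""
    coords, chains = [], []
    for i, c in enumerate("ABCDE"):
        t = np.radians(72 * i)
        coords.append([R * np.cos(t), R * np.sin(t), z])
        chains.append(c)
    return make_frame(coords, names=["CA"] * 5, resseqs=[resseq] * 5,
                      chains=chains, elements=["C"] * 5)


class TestCrossedDistances:
    def test_regular_pentagon_chord(self, topo):
        f = pentagon_frame(10.0)
        d = crossed_distances(f, topo, 13, "calpha")
        assert np.allclose(d, 10.0 * PENTAGON_CHORD, atol=1e-10)
        assert d == pytest.approx([19.021130] * 5, abs=1e-5)

    def test_homogeneity_under_scaling(self, topo):
        d1 = crossed_distances(pentagon_frame(10.0), topo, 13, "calpha")
        d2 = crossed_distances(pentagon_frame(5.0), topo, 13, "calpha")
        assert np.allclose(d2, d1 / 2, atol=1e-12)

    def test_displaced_vertex_matches_direct_arithmetic(self, topo):
        f = pentagon_frame(10.0)
        f.coords[0] *= 1.1  # chain A moved radially outward by 1 Å
        d = crossed_distances(f, topo, 13, "calpha")
        pos = {c: f.coords[i] for i, c in enumerate("ABCDE")}
        expect = [np.linalg.norm(pos[a] - pos[b])
                  for a, b in topo.non_adjacent_pairs()]
        assert np.allclose(d, expect, atol=1e-12)
        # only the two pairs containing A changed
        base = 10.0 * PENTAGON_CHORD
        changed = [i for i, (a, b) in enumerate(topo.non_adjacent_pairs())
                   if "A" in (a, b)]
        for i in range(5):
            if i in changed:
                assert abs(d[i] - base) > 0.1
            else:
                assert d[i] == pytest.approx(base, abs=1e-10)

    def test_c5_symmetric_structure_gives_equal_values(self, open_pentamer, topo):
        frame, _ = open_pentamer
        for mode in ("residue_com", "calpha"):
            d = crossed_distances(frame, topo, 13, mode)
            assert np.ptp(d) < 1e-8

    def test_com_and_calpha_modes_order_presets_identically(self, topo,
                                                            open_pentamer,
                                                            collapsed_pentamer):
        fo, _ = open_pentamer
        fc, _ = collapsed_pentamer
        for mode in ("residue_com", "calpha"):
            do = crossed_distances(fo, topo, 13, mode).mean()
            dc = crossed_distances(fc, topo, 13, mode).mean()
            assert do > dc

    def test_unresolvable_prime_raises(self, topo):
        with pytest.raises(TopologyError):
            crossed_distances(pentagon_frame(10.0, resseq=999), topo, 13)


def lab_axisframe():
    return AxisFrame(origin=np.zeros(3), z_axis=np.array([0.0, 0.0, 1.0]))


class TestPoreRadiusProfile:
    def test_coaxial_cylinder_is_analytic(self):
        f = syn.cylinder_fixture(8.0)
        prof = pore_radius_profile(f, lab_axisframe(), (-8, 8), spacing=0.5)
        assert np.allclose(prof.radius, 8.0 - VDW_RADII["C"], atol=1e-10)
        assert not prof.empty_slab.any()

    def test_empty_slab_is_flagged_maximum(self):
        f = syn.cylinder_fixture(8.0, z_range=(-10, -5))
        prof = pore_radius_profile(f, lab_axisframe(), (0, 5), spacing=1.0,
                                   max_radius=12.0)
        assert prof.empty_slab.all()
        assert np.all(prof.radius == 12.0)

    def test_funnel_profile_linear_within_spacing(self):
        slope, r0 = 0.2, 6.0
        f = syn.cylinder_fixture(lambda z: r0 + slope * z, n_rings=161)
        spacing = 0.5
        prof = pore_radius_profile(f, lab_axisframe(), (-8, 8), spacing=spacing)
        expect = r0 + slope * prof.z - VDW_RADII["C"]
        assert np.all(np.abs(prof.radius - expect) <= slope * spacing + 1e-9)

    def test_vdw_radius_of_elements_respected(self):
        f = syn.cylinder_fixture(8.0, element="O")
        prof = pore_radius_profile(f, lab_axisframe(), (-5, 5))
        assert np.allclose(prof.radius, 8.0 - VDW_RADII["O"], atol=1e-10)

    def test_open_preset_gate_radius(self, open_pentamer, topo):
        frame, gt = open_pentamer
        ax = symmetry_axis(frame, topo)
        prof = pore_radius_profile(frame, ax, (1, 11), spacing=0.5,
                                   ligand_resname="EPI")
        assert prof.radius.min() == pytest.approx(gt["gate_min_pore_radius"],
                                                  abs=0.5)

    def test_collapsed_preset_minimum_at_9prime(self, collapsed_pentamer, topo):
        frame, gt = collapsed_pentamer
        ax = symmetry_axis(frame, topo)
        prof = pore_radius_profile(frame, ax, (-16, 16), spacing=0.5,
                                   ligand_resname="EPI")
        z_min, r_min = prof.minimum()
        ring9_z = float(ax.axial_coordinate(
            resolve_ring(frame, topo, 9, "calpha").mean(axis=0))[0])
        assert abs(z_min - ring9_z) <= 1.0
        assert r_min == pytest.approx(gt["pore_radius"][9], abs=0.5)


def ideal_helix(n=23, rise=1.5, turn=100.0, wheel=2.3, R=None):
    j = np.arange(n)
    t = np.radians(j * turn)
    pts = np.column_stack([wheel * np.cos(t), wheel * np.sin(t),
                           (j - (n - 1) / 2) * rise])
    return pts - pts.mean(axis=0)


def helix_frame(pts, topo):
    lo, _ = topo.m2_range
    return make_frame(pts, names=["CA"] * len(pts),
                      resseqs=np.arange(lo, lo + len(pts)),
                      chains=["A"] * len(pts), elements=["C"] * len(pts))


class TestM2HelixAxis:
    def test_ideal_helix_along_z(self, topo):
        f = helix_frame(ideal_helix(), topo)
        axis = m2_helix_axis(f, topo, "A")
        angle = np.degrees(np.arccos(np.clip(axis @ [0, 0, 1], -1, 1)))
        assert angle < 0.5

    def test_equivariance_under_rotation(self, topo):
        R = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        f = helix_frame(ideal_helix() @ R.T, topo)
        axis = m2_helix_axis(f, topo, "A", orient_along=R @ [0, 0, 1])
        expect = R @ [0, 0, 1]
        angle = np.degrees(np.arccos(np.clip(axis @ expect, -1, 1)))
        assert angle < 0.5

    def test_noisy_helix_within_two_degrees(self, topo, rng):
        pts = ideal_helix() + rng.normal(scale=0.3, size=(23, 3))
        axis = m2_helix_axis(helix_frame(pts, topo), topo, "A")
        angle = np.degrees(np.arccos(np.clip(axis @ [0, 0, 1], -1, 1)))
        assert angle < 2.0

    def test_missing_calpha_raises(self, topo):
        f = make_frame([[0, 0, 0]], names=["CA"], resseqs=[231], chains=["A"])
        with pytest.raises(TopologyError):
            m2_helix_axis(f, topo, "A")


class TestTiltAngles:
    @pytest.mark.parametrize(
        "polar,azim",
        [(0.0, 0.0), (10.0, 0.0), (10.0, 45.0), (5.0, -10.0), (-5.0, 0.0)],
    )
    def test_constructed_tilt_recovered(self, topo, polar, azim):
        bp = syn.open_blueprint(polar_tilt=polar, azimuthal_tilt=azim)
        frame, gt = syn.build_pentamer(bp, topo)
        t = tilt_angles(frame, symmetry_axis(frame, topo), topo)
        assert np.allclose(t.polar, gt["polar_tilt"]["A"], atol=0.5)
        if gt["azimuthal_degenerate"]:
            assert t.azimuthal_degenerate.all()
            assert np.allclose(t.azimuthal, 0.0)
        else:
            da = (t.azimuthal - gt["azimuthal_tilt"]["A"] + 180) % 360 - 180
            assert np.all(np.abs(da) < 0.5)

    @pytest.mark.parametrize(
        "direction,expect_polar,expect_azim,expect_degen",
        [
            ([0, 0, 1], 0.0, 0.0, True),  # parallel to z → flagged 0
            ("x10", 10.0, 0.0, False),  # 10° toward radial +x
            ("y10", 0.0, 90.0, False),  # 10° toward tangential +y
        ],
    )
    def test_readout_conventions(self, topo, direction, expect_polar,
                                 expect_azim, expect_degen):
        """Sign conventions on hand-built helices: tilt toward local +x is
        positive polar; tilt toward +y appears as azimuth +90 at zero polar."""
        if direction == "x10":
            v = np.array([np.sin(np.radians(10)), 0, np.cos(np.radians(10))])
        elif direction == "y10":
            v = np.array([0, np.sin(np.radians(10)), np.cos(np.radians(10))])
        else:
            v = np.asarray(direction, dtype=float)
        rot, _ = Rotation.align_vectors(v[None], np.array([[0.0, 0.0, 1.0]]))
        pts = ideal_helix() @ rot.as_matrix().T + np.array([20.0, 0, 0])
        lo, _ = topo.m2_range
        f = make_frame(pts, names=["CA"] * 23,
                       resseqs=np.arange(lo, lo + 23), chains=["A"] * 23)
        from porescope.geometry import HelixFrame

        ax = AxisFrame(
            origin=np.zeros(3), z_axis=np.array([0, 0, 1.0]),
            helix_frames={c: HelixFrame(np.array([20.0, 0, 0]),
                                        np.array([1.0, 0, 0]),
                                        np.array([0, 1.0, 0]),
                                        np.array([0, 0, 1.0]))
                          for c in topo.chain_ids},
        )
        f5 = f
        for c in "BCDE":
            g = make_frame(pts, names=["CA"] * 23,
                           resseqs=np.arange(lo, lo + 23), chains=[c] * 23)
            from porescope.synthetic import _concat

            f5 = _concat(f5, g)
        t = tilt_angles(f5, ax, topo)
        assert t.polar[0] == pytest.approx(expect_polar, abs=0.2)
        if expect_degen:
            assert t.azimuthal_degenerate[0]
            assert t.azimuthal[0] == 0.0
        else:
            assert t.azimuthal[0] == pytest.approx(expect_azim, abs=2.0)

    def test_axis_parallel_to_z_is_degenerate(self, topo):
        frame, _ = syn.build_pentamer(
            syn.open_blueprint(polar_tilt=0.0, azimuthal_tilt=0.0), topo)
        t = tilt_angles(frame, symmetry_axis(frame, topo), topo)
        assert t.azimuthal_degenerate.all()
        assert np.allclose(t.polar, 0.0, atol=0.2)


class TestTwistAngle:
    def test_constructed_twist_recovered(self, topo):
        for twist in (10.0, 21.0):
            frame, gt = syn.build_pentamer(syn.open_blueprint(twist=twist), topo)
            per, mean = twist_angle(frame, symmetry_axis(frame, topo), topo,
                                    syn.TWIST_LBD_SPAN, syn.TWIST_TMD_SPAN)
            assert mean == pytest.approx(gt["twist_mean"], abs=0.5)
            assert np.allclose(per, [gt["twist"][c] for c in topo.chain_ids],
                               atol=0.5)

    def test_parallel_projections_give_zero(self, topo):
        # zero prescribed offset and an azimuthally symmetric construction
        # would give zero; here we check rigid-motion invariance instead on
        # the realized value
        frame, gt = syn.build_pentamer(syn.open_blueprint(), topo)
        ax = symmetry_axis(frame, topo)
        per0, mean0 = twist_angle(frame, ax, topo, syn.TWIST_LBD_SPAN,
                                  syn.TWIST_TMD_SPAN)
        R = Rotation.from_euler("z", 72, degrees=True).as_matrix()
        moved = apply_rigid_motion(frame, R, np.array([3.0, -1.0, 2.0]))
        per1, mean1 = twist_angle(moved, symmetry_axis(moved, topo), topo,
                                  syn.TWIST_LBD_SPAN, syn.TWIST_TMD_SPAN)
        assert mean1 == pytest.approx(mean0, abs=1e-8)

    def test_twist_scales_with_prescribed_offset(self, topo):
        frames = {
            t: syn.build_pentamer(syn.open_blueprint(twist=t), topo)
            for t in (10.0, 25.0)
        }
        means = {}
        for t, (frame, _) in frames.items():
            _, means[t] = twist_angle(frame, symmetry_axis(frame, topo), topo,
                                      syn.TWIST_LBD_SPAN, syn.TWIST_TMD_SPAN)
        assert means[25.0] - means[10.0] == pytest.approx(15.0, abs=0.5)


class TestDistanceDistribution:
    def test_constant_series_occupies_single_bin(self):
        s = DescriptorSeries("d", "Å", np.full(50, 7.3), np.arange(50) * 0.1)
        h = distance_distribution(s, 0.5)
        assert (h.mass > 0).sum() == 1
        lo = h.edges[:-1][h.mass > 0][0]
        assert lo <= 7.3 < lo + 0.5

    def test_merged_pairs_give_equal_bimodal_masses(self):
        vals = np.column_stack([np.full(40, 10.0), np.full(40, 14.0)])
        s = DescriptorSeries("d", "Å", vals, np.arange(40) * 0.1)
        h = distance_distribution(s, 0.5, merge_subunits=True)
        occupied = h.mass[h.mass > 0]
        assert occupied.shape == (2,)
        assert np.allclose(occupied, 0.5)

    def test_masses_sum_to_one(self, rng):
        s = DescriptorSeries("d", "Å", rng.normal(12, 2, size=(100, 5)),
                             np.arange(100) * 0.1)
        h = distance_distribution(s, 0.3)
        assert h.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_bin_width_rejected(self):
        s = DescriptorSeries("d", "Å", np.ones(3), np.arange(3) * 0.1)
        with pytest.raises(ValueError):
            distance_distribution(s, 0.0)
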