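"""Synthetic pentamer and trajectory generator with closed-form ground truth.

Generates five ideal α-helical M2 segments (canonical rise 1.5 Å/residue,
100°/residue turn, Cα wheel radius 2.3 Å) on a circle, each carrying a single
side-chain proxy atom placed exactly at a prescribed radial distance from the
pore axis at its ring — the proxies form the pore wall, so pore-radius ground
truth is closed-form.  A sparse ligand-binding-domain proxy cloud (Cys-loop,
β1-β2, C-loop, backwall, binding-pocket residues) supports twist, dCintra,
interface-distance and ligand monitors; pore waters, vestibule ions and a
bound-ligand proxy complete the fixture.  Every builder returns a ground-truth
record computed by direct arithmetic on the construction parameters.

Nothing here aims at physical realism (no sterics, no membrane, no
electrostatics): these are test fixtures with known answers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .model import StructureFrame, Trajectory
from .topology import ChannelTopology, default_topology

RISE = 1.5  # Å per residue (fixed: keeps ground truth closed-form)
TURN = 100.0  # degrees per residue
WHEEL_RADIUS = 2.3  # Å, Cα distance from the ideal helix axis
PROXY_VDW = 1.70  # the side-chain proxy is a carbon
WATER_OH = 0.957  # Å
WATER_ANGLE = 104.5  # degrees

#: Residue names at the conserved pore-lining rings (α7-like); other M2
#: positions are alanine.
RING_RESNAMES = {
    -2: "GLY", 2: "SER", 6: "THR", 9: "LEU", 10: "SER",
    12: "THR", 13: "VAL", 16: "LEU", 20: "GLU",
}

GATE_PRIMES = (9, 10, 11, 12, 13, 14, 15, 16)

#: Default Cα spans used for the quaternary-twist measurement on synthetic
#: pentamers (whole LBD proxy cloud vs M2 + M2-M3).
TWIST_LBD_SPAN = (38, 188)
TWIST_TMD_SPAN = (231, 259)


def _tilt_vector(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Helix-axis direction with the prescribed polar/azimuthal tilt in the
    local (x radial, y tangential, z axis) frame.  Inverse of the angle
    measurement: atan2(vx, vz) = polar and, for positive polar,
    atan2(vy, vx) = azimuthal."""
    if polar_deg != 0.0 and abs(azim_deg) >= 89.0:
        # azimuth ±90 means a purely tangential xy-projection, which forces
        # the xz-projection (hence the polar angle) to zero: inconsistent
        raise ValueError("azimuthal tilt must lie in (-89, 89) for nonzero polar tilt")
    a = np.radians(polar_deg)
    b = np.radians(azim_deg)
    t = np.tan(a) / np.cos(b)
    v = np.array([t * np.cos(b), t * np.sin(b), 1.0])
    return v / np.linalg.norm(v)


def measured_angles(v: np.ndarray) -> tuple[float, float, bool]:
    """Closed-form (polar, azimuthal, degenerate) readout of an axis vector."""
    polar = float(np.degrees(np.arctan2(v[0], v[2])))
    if np.hypot(v[0], v[1]) < 1e-12:
        return polar, 0.0, True
    return polar, float(np.degrees(np.arctan2(v[1], v[0]))), False


@dataclass
class PentamerBlueprint:
    """Construction parameters for one synthetic pentamer conformation.

    ``ring_radii`` prescribes the radial distance of the pore-lining proxy
    atom at each prime ring — these atoms form the pore wall, so the pore
    radius at ring p is ``ring_radii[p] − 1.7`` (carbon vdW).  The helix-axis
    circle radius is separate (``helix_radius``): a rigid ideal helix cannot
    satisfy arbitrary per-ring Cα radii, so the backbone stays ideal and the
    proxies carry the pore geometry.
    """

    name: str = "custom"
    ring_radii: dict[int, float] = field(
        default_factory=lambda: {p: 6.7 for p in range(-2, 21)}
    )
    helix_radius: float = 9.5
    polar_tilt: float = 0.0  # degrees, all helices
    azimuthal_tilt: float = 0.0
    twist: float = 15.0  # degrees, LBD→TMD, positive CCW from extracellular
    dcintra: float = 14.6  # Å, C-loop COM to backwall COM
    n_waters_pore: int = 60  # full M2 lumen (incl. gate)
    n_waters_gate: int = 4  # 13′ ± 5 Å constriction region
    water_cylinder_radius: float | None = None  # default: min ring radius − 0.5
    n_cations: int = 8
    n_anions: int = 8
    cation_z_range: tuple[float, float] = (-20.0, 0.0)
    anion_z_range: tuple[float, float] = (-30.0, -20.0)
    ion_lateral_radius: float = 6.0
    ligand_orientation: str = "axial_up"
    tense_pair_distance: float = 4.5  # Å, scripted inter-subunit H-bond pair
    noise_sigma: float = 0.0  # Å, i.i.d. Gaussian on protein+ligand atoms
    seed: int = 0
    require_monotone_radii: bool = False

    def __post_init__(self) -> None:
        self.ring_radii = {int(k): float(v) for k, v in self.ring_radii.items()}
        if any(r <= 0 for r in self.ring_radii.values()):
            raise ValueError("ring radii must be positive")
        if self.n_waters_gate > self.n_waters_pore:
            raise ValueError("gate water count cannot exceed the full-pore count")
        if self.require_monotone_radii:
            radii = [self.ring_radii[p] for p in sorted(self.ring_radii)]
            if not (np.all(np.diff(radii) >= 0) or np.all(np.diff(radii) <= 0)):
                raise ValueError("ring radii are not monotone but a funnel was requested")

    @property
    def water_radius(self) -> float:
        if self.water_cylinder_radius is not None:
            return self.water_cylinder_radius
        return min(self.ring_radii.values()) - 0.5


def open_blueprint(**overrides) -> PentamerBlueprint:
    """Putative-open preset: wide hydrophobic gate (pore radius ≈ 5 Å over
    9′–16′), ≈3 Å constriction at the intracellular −2′ entrance, fully
    hydrated lumen, smaller quaternary twist, slightly positive polar tilt."""
    radii = {p: 6.2 for p in range(-2, 21)}
    radii.update({p: 6.7 for p in GATE_PRIMES})
    radii.update({-2: 4.7, -1: 4.7, 0: 4.7})
    params = dict(
        name="open",
        ring_radii=radii,
        helix_radius=9.5,
        polar_tilt=1.1,
        azimuthal_tilt=5.0,
        twist=21.0,
        dcintra=15.5,
        n_waters_pore=115,
        n_waters_gate=40,
        tense_pair_distance=4.5,
    )
    params.update(overrides)
    return PentamerBlueprint(**params)


def collapsed_blueprint(**overrides) -> PentamerBlueprint:
    """Collapsed preset: 9′ constriction of pore radius ≈ 2 Å, ≈3 Å gate
    elsewhere, dewetted lumen, larger twist, slightly negative polar tilt,
    tense inter-subunit contacts formed."""
    radii = {p: 5.7 for p in range(-2, 21)}
    radii.update({9: 3.7, 13: 4.7, 16: 4.7})
    params = dict(
        name="collapsed",
        ring_radii=radii,
        helix_radius=9.0,
        polar_tilt=-2.0,
        azimuthal_tilt=0.0,
        twist=24.0,
        dcintra=14.6,
        n_waters_pore=60,
        n_waters_gate=4,
        tense_pair_distance=2.8,
    )
    params.update(overrides)
    return PentamerBlueprint(**params)


def free_blueprint(**overrides) -> PentamerBlueprint:
    """Open-like preset at the relaxed hydration level of unbiased runs."""
    return open_blueprint(
        name="free", n_waters_pore=95, n_waters_gate=30, **overrides
    )


# ---- construction ------------------------------------------------------------


class _AtomList:
    def __init__(self):
        self.rows = []

    def add(self, name, resname, resseq, chain, element, xyz):
        self.rows.append((name, resname, int(resseq), chain, element,
                          float(xyz[0]), float(xyz[1]), float(xyz[2])))

    def to_frame(self) -> StructureFrame:
        n = len(self.rows)
        return StructureFrame(
            serial=np.arange(1, n + 1),
            name=np.array([r[0] for r in self.rows]),
            resname=np.array([r[1] for r in self.rows]),
            resseq=np.array([r[2] for r in self.rows]),
            chain=np.array([r[3] for r in self.rows]),
            element=np.array([r[4] for r in self.rows]),
            coords=np.array([r[5:8] for r in self.rows]),
        )


def _chain_basis(phi: float):
    x = np.array([np.cos(phi), np.sin(phi), 0.0])
    y = np.array([-np.sin(phi), np.cos(phi), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    return x, y, z


def _hexagon(center, radius=1.4, normal=np.array([0.0, 0.0, 1.0])):
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, n)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    ang = np.radians(np.arange(6) * 60.0)
    return [center + radius * (np.cos(t) * u + np.sin(t) * v) for t in ang]


def build_pentamer(
    blueprint: PentamerBlueprint,
    topology: ChannelTopology | None = None,
) -> tuple[StructureFrame, dict]:
    """Build one pentamer conformation; returns (frame, ground-truth record)."""
    bp = blueprint
    topo = topology or default_topology()
    rng = np.random.default_rng(bp.seed)
    atoms = _AtomList()
    primes = sorted(bp.ring_radii)
    n_res = len(primes)
    v_local = _tilt_vector(bp.polar_tilt, bp.azimuthal_tilt)
    if np.allclose(v_local, [0, 0, 1]):
        R_tilt = np.eye(3)
    else:
        axis = np.cross([0, 0, 1], v_local)
        axis = axis / np.linalg.norm(axis)
        ang = np.arccos(np.clip(v_local[2], -1, 1))
        R_tilt = Rotation.from_rotvec(ang * axis).as_matrix()

    chain_phis = {c: np.radians(72.0 * i) for i, c in enumerate(topo.chain_ids)}
    ring_positions_com: dict[int, dict[str, np.ndarray]] = {p: {} for p in primes}
    ring_positions_ca: dict[int, dict[str, np.ndarray]] = {p: {} for p in primes}
    tmd_ca: dict[str, list] = {c: [] for c in topo.chain_ids}
    lbd_ca: dict[str, list] = {c: [] for c in topo.chain_ids}

    from .model import element_mass

    # ideal-helix local coordinates, centered so the Cα mean is exactly the
    # helix center (keeps the analysis local frames free of wheel bias)
    thetas = np.radians(np.arange(n_res) * TURN)
    local_pts = np.column_stack(
        [
            WHEEL_RADIUS * np.cos(thetas),
            WHEEL_RADIUS * np.sin(thetas),
            (np.arange(n_res) - (n_res - 1) / 2) * RISE,
        ]
    )
    local_pts = local_pts - local_pts.mean(axis=0)

    for chain in topo.chain_ids:
        phi = chain_phis[chain]
        xc, yc, zc = _chain_basis(phi)
        M = np.column_stack([xc, yc, zc])
        center = bp.helix_radius * xc
        for j, p in enumerate(primes):
            resseq = topo.resid_for_prime(p)
            resname = RING_RESNAMES.get(p, "ALA")
            ca = center + M @ (R_tilt @ local_pts[j])
            atoms.add("CA", resname, resseq, chain, "C", ca)
            tmd_ca[chain].append(ca)
            # pore-lining proxy at the prescribed ring radius, same azimuth
            phi_ca = np.arctan2(ca[1], ca[0])
            rp = bp.ring_radii[p]
            cb = np.array([rp * np.cos(phi_ca), rp * np.sin(phi_ca), ca[2]])
            atoms.add("CB", resname, resseq, chain, "C", cb)
            res_atoms = [("C", ca), ("C", cb)]
            if resname in ("SER", "THR"):
                og = np.array(
                    [(rp + 0.5) * np.cos(phi_ca), (rp + 0.5) * np.sin(phi_ca),
                     ca[2] + 0.5]
                )
                og_name = "OG" if resname == "SER" else "OG1"
                atoms.add(og_name, resname, resseq, chain, "O", og)
                res_atoms.append(("O", og))
            w = np.array([element_mass(e) for e, _ in res_atoms])
            com = (np.array([x for _, x in res_atoms]) * w[:, None]).sum(axis=0) / w.sum()
            ring_positions_com[p][chain] = com
            ring_positions_ca[p][chain] = ca

    z_top = (len(primes) - 1) / 2 * RISE

    # --- M2-M3 loop (residues above M2) + scripted tense-contact pair -------
    m2m3_lo, m2m3_hi = topo.loop_span("M2-M3")
    n_m2m3 = m2m3_hi - m2m3_lo + 1
    for chain in topo.chain_ids:
        phi = chain_phis[chain]
        for k, resseq in enumerate(range(m2m3_lo, m2m3_hi + 1)):
            ang = phi + np.radians(6.0 * (k - (n_m2m3 - 1) / 2))
            r = bp.helix_radius + 1.0
            pos = np.array([r * np.cos(ang), r * np.sin(ang), z_top + 1.5 + 0.8 * k])
            resname = "PRO" if resseq == topo.key_residue("Pro256") else "ALA"
            atoms.add("CA", resname, resseq, chain, "C", pos)
    # tense pair: O on residue (m2m3_hi−1) of chain i, N on residue m2m3_hi of
    # chain i+1, separated by the scripted distance across the interface
    for i, chain in enumerate(topo.chain_ids):
        nxt = topo.chain_ids[(i + 1) % 5]
        mid_ang = chain_phis[chain] + np.radians(36.0)
        r = bp.helix_radius + 2.0
        mid = np.array([r * np.cos(mid_ang), r * np.sin(mid_ang), z_top + 4.0])
        t_hat = np.array([-np.sin(mid_ang), np.cos(mid_ang), 0.0])
        atoms.add("O", "ALA", m2m3_hi - 1, chain, "O",
                  mid - 0.5 * bp.tense_pair_distance * t_hat)
        atoms.add("N", "ALA", m2m3_hi, nxt, "N",
                  mid + 0.5 * bp.tense_pair_distance * t_hat)

    # --- LBD proxy cloud (rotated by −twist so LBD→TMD signed angle = twist)
    twist_truth = {}
    dcintra_truth = {}
    iface_truth = {}
    for chain in topo.chain_ids:
        phi_l = chain_phis[chain] - np.radians(bp.twist)
        xl, yl, zl = _chain_basis(phi_l)

        def place_arc(resseq_lo, resseq_hi, radius, z0, resname_map=None):
            pts = []
            nresl = resseq_hi - resseq_lo + 1
            for k, rs in enumerate(range(resseq_lo, resseq_hi + 1)):
                ang = phi_l + np.radians(4.0 * (k - (nresl - 1) / 2))
                pos = np.array(
                    [radius * np.cos(ang), radius * np.sin(ang), z0 + 0.3 * k]
                )
                rn = (resname_map or {}).get(rs, "ALA")
                atoms.add("CA", rn, rs, chain, "C", pos)
                pts.append(pos)
            return np.array(pts)

        b12_lo, b12_hi = topo.loop_span("beta1-beta2")
        place_arc(b12_lo, b12_hi, 12.0, 24.0,
                  {topo.key_residue("Lys40"): "LYS"})
        cys_lo, cys_hi = topo.loop_span("Cys-loop")
        cys_pts = place_arc(cys_lo, cys_hi, 11.5, 21.0)
        bw_lo, bw_hi = topo.loop_span("backwall")
        bw_pts = place_arc(bw_lo, bw_hi, 10.0, 40.0)
        bw_com = bw_pts.mean(axis=0)

        # C-loop placed so its Cα COM sits exactly dcintra from the backwall COM
        d_hat = 0.8 * xl + 0.6 * zl
        d_hat /= np.linalg.norm(d_hat)
        cl_com = bw_com + bp.dcintra * d_hat
        cl_lo, cl_hi = topo.loop_span("C-loop")
        ncl = cl_hi - cl_lo + 1
        for k, rs in enumerate(range(cl_lo, cl_hi + 1)):
            off = (k - (ncl - 1) / 2)
            pos = cl_com + off * 0.9 * yl
            atoms.add("CA", "TYR" if rs == 182 else "ALA", rs, chain, "C", pos)
        dcintra_truth[chain] = float(bp.dcintra)

        # binding-pocket residues (principal side)
        pocket_ang = phi_l + np.radians(30.0)
        pr = 13.0

        def pocket_point(dz, dang=0.0, dr=0.0):
            a = pocket_ang + np.radians(dang)
            return np.array(
                [(pr + dr) * np.cos(a), (pr + dr) * np.sin(a), 35.0 + dz]
            )

        # Tyr87: CA + side-chain OH + aromatic ring
        p87 = pocket_point(-2.0, -8.0)
        atoms.add("CA", "TYR", 87, chain, "C", p87)
        atoms.add("OH", "TYR", 87, chain, "O", p87 + np.array([0, 0, 1.5]))
        for q, pos in enumerate(_hexagon(p87 + np.array([0, 0, 0.7]))):
            atoms.add(f"CR{q + 1}", "TYR", 87, chain, "C", pos)
        # Trp143: CA + backbone O + indole-ring proxy
        p143 = pocket_point(1.0, 6.0)
        atoms.add("CA", "TRP", 143, chain, "C", p143)
        atoms.add("O", "TRP", 143, chain, "O", p143 + np.array([0, 0, -1.4]))
        for q, pos in enumerate(_hexagon(p143 + np.array([0.8, 0, 0.5]))):
            atoms.add(f"CR{q + 1}", "TRP", 143, chain, "C", pos)
        # Tyr189 and Tyr182 (182 lies inside the C-loop span, whose Cα is
        # placed with the loop arc above; only its side chain sits here)
        for rs, dz, dang in ((189, 3.0, -3.0), (182, 4.5, 4.0)):
            prs = pocket_point(dz, dang)
            if rs != 182:
                atoms.add("CA", "TYR", rs, chain, "C", prs)
            atoms.add("OH", "TYR", rs, chain, "O", prs + np.array([0, 0, 1.5]))
            for q, pos in enumerate(_hexagon(prs + np.array([0, 0.6, 0.6]))):
                atoms.add(f"CR{q + 1}", "TYR", rs, chain, "C", pos)

        # complementary-side leucines carry backbone N for the chlorine monitor
        i = topo.chain_ids.index(chain)
        comp = topo.chain_ids[(i + 1) % 5]
        for rs, dz in ((103, -1.0), (113, -3.0)):
            pos = pocket_point(dz, 14.0, 1.0)
            atoms.add("CA", "LEU", rs, comp, "C", pos)
            atoms.add("N", "LEU", rs, comp, "N", pos + np.array([0, 0, 0.8]))

    # --- ligand: bridge ring + pyrimidine ring + N1/N2 + chlorine -----------
    orientation_truth = {}
    for i, chain in enumerate(topo.chain_ids):
        phi_l = chain_phis[chain] - np.radians(bp.twist)
        pocket_ang = phi_l + np.radians(30.0)
        c0 = np.array([13.0 * np.cos(pocket_ang), 13.0 * np.sin(pocket_ang), 37.0])
        radial_in = -np.array([np.cos(pocket_ang), np.sin(pocket_ang), 0.0])
        if bp.ligand_orientation == "axial_up":
            u = np.array([0.0, 0.0, 1.0])
        elif bp.ligand_orientation == "axial_down":
            u = np.array([0.0, 0.0, -1.0])
        elif bp.ligand_orientation == "equatorial":
            u = radial_in
        else:
            raise ValueError(f"unknown ligand orientation {bp.ligand_orientation!r}")
        a_off = np.array([1.6, 0.0, 0.0])
        b_off = np.array([0.0, 1.2, 0.0])
        resseq = 900
        for q, pos in enumerate(_hexagon(c0 + a_off, radius=1.2)):
            atoms.add(f"C{q + 1}", "EPI", resseq, chain, "C", pos)
        for q, pos in enumerate(_hexagon(c0 - a_off, radius=1.2)):
            atoms.add(f"CP{q + 1}", "EPI", resseq, chain, "C", pos)
        atoms.add("N1", "EPI", resseq, chain, "N", c0 + b_off)
        atoms.add("N2", "EPI", resseq, chain, "N", c0 - b_off)
        atoms.add("CL", "EPI", resseq, chain, "CL", c0 + 2.0 * u)
        orientation_truth[chain] = bp.ligand_orientation

    frame = atoms.to_frame()

    # twist ground truth by direct arithmetic on the noise-free construction
    # (the LBD cloud is intentionally not azimuthally uniform, so the realized
    # twist differs from the prescribed offset by a constant geometric shift)
    ca_mask = (frame.name == "CA") & np.isin(frame.chain, list(topo.chain_ids))
    com_all_xy = frame.coords[ca_mask][:, :2].mean(axis=0)
    for chain in topo.chain_ids:
        vs = []
        for span in (TWIST_LBD_SPAN, TWIST_TMD_SPAN):
            m = (
                ca_mask
                & (frame.chain == chain)
                & (frame.resseq >= span[0])
                & (frame.resseq <= span[1])
            )
            vs.append(frame.coords[m][:, :2].mean(axis=0) - com_all_xy)
        v1, v2 = vs
        twist_truth[chain] = float(
            np.degrees(np.arctan2(v1[0] * v2[1] - v1[1] * v2[0], np.dot(v1, v2)))
        )

    if bp.noise_sigma > 0:
        frame.coords[:] += rng.normal(0.0, bp.noise_sigma, frame.coords.shape)

    # --- waters and ions (never noised; placement is already stochastic) ----
    solvent = _AtomList()
    _place_waters(solvent, bp, rng, z_top)
    _place_ions(solvent, bp, rng)
    sol_frame = solvent.to_frame() if solvent.rows else None
    if sol_frame is not None:
        frame = _concat(frame, sol_frame)

    gt = {
        "name": bp.name,
        "seed": int(bp.seed),
        "ring_radii": {p: bp.ring_radii[p] for p in primes},
        "pore_radius": {p: max(0.0, bp.ring_radii[p] - PROXY_VDW) for p in primes},
        "gate_min_pore_radius": min(
            max(0.0, bp.ring_radii[p] - PROXY_VDW) for p in GATE_PRIMES
        ),
        "crossed_com": {
            p: _pentagon_distances(ring_positions_com[p], topo) for p in primes
        },
        "crossed_calpha": {
            p: _pentagon_distances(ring_positions_ca[p], topo) for p in primes
        },
        "polar_tilt": {c: measured_angles(v_local)[0] for c in topo.chain_ids},
        "azimuthal_tilt": {c: measured_angles(v_local)[1] for c in topo.chain_ids},
        "azimuthal_degenerate": measured_angles(v_local)[2],
        "twist_prescribed": float(bp.twist),
        "twist": twist_truth,
        "twist_mean": float(np.mean(list(twist_truth.values()))),
        "dcintra": dcintra_truth,
        "water_counts": {"pore": int(bp.n_waters_pore), "gate": int(bp.n_waters_gate)},
        "ion_counts": {"cation": int(bp.n_cations), "anion": int(bp.n_anions)},
        "ligand_orientation": orientation_truth,
        "tense_pair_distance": float(bp.tense_pair_distance),
        "z_top": float(z_top),
        "gate_z": (float((13 + 2 - 11) * RISE - 5.0), float((13 + 2 - 11) * RISE + 5.0)),
    }
    return frame, gt


def _pentagon_distances(ring: dict[str, np.ndarray], topo) -> list[float]:
    return [
        float(np.linalg.norm(ring[a] - ring[b]))
        for a, b in topo.non_adjacent_pairs()
    ]


def _concat(a: StructureFrame, b: StructureFrame) -> StructureFrame:
    n = a.n_atoms
    return StructureFrame(
        serial=np.concatenate([a.serial, b.serial + n]),
        name=np.concatenate([a.name, b.name]),
        resname=np.concatenate([a.resname, b.resname]),
        resseq=np.concatenate([a.resseq, b.resseq]),
        chain=np.concatenate([a.chain, b.chain]),
        element=np.concatenate([a.element, b.element]),
        coords=np.vstack([a.coords, b.coords]),
        time=a.time,
    )


def _water_positions(bp, rng, z_top, n_gate=None, n_outer=None):
    """Water oxygen positions: exact counts inside the gate slab (13′ ± 5 Å)
    and in the rest of the lumen, with a 0.2 Å margin off every boundary."""
    g_lo, g_hi = (13 + 2 - 11) * RISE - 5.0, (13 + 2 - 11) * RISE + 5.0
    n_gate = bp.n_waters_gate if n_gate is None else n_gate
    n_outer = (bp.n_waters_pore - bp.n_waters_gate) if n_outer is None else n_outer
    rad = bp.water_radius
    out = []

    def sample_disk(n):
        r = rad * np.sqrt(rng.uniform(0, 1, n))
        t = rng.uniform(0, 2 * np.pi, n)
        return r * np.cos(t), r * np.sin(t)

    x, y = sample_disk(n_gate)
    z = rng.uniform(g_lo + 0.2, g_hi - 0.2, n_gate)
    out.append(np.column_stack([x, y, z]))
    lo_len = (g_lo - 0.2) - (-z_top + 0.2)
    hi_len = (z_top - 0.2) - (g_hi + 0.2)
    n_lo = rng.binomial(n_outer, lo_len / (lo_len + hi_len)) if n_outer else 0
    x, y = sample_disk(n_lo)
    z = rng.uniform(-z_top + 0.2, g_lo - 0.2, n_lo)
    out.append(np.column_stack([x, y, z]))
    n_hi = n_outer - n_lo
    x, y = sample_disk(n_hi)
    z = rng.uniform(g_hi + 0.2, z_top - 0.2, n_hi)
    out.append(np.column_stack([x, y, z]))
    return np.vstack(out)


def _water_sites(o_pos: np.ndarray, rng) -> np.ndarray:
    """3-site geometry (O + 2 H, 0.957 Å, 104.5°) at random orientations."""
    n = o_pos.shape[0]
    half = np.radians(WATER_ANGLE / 2)
    h1 = WATER_OH * np.array([np.sin(half), 0, np.cos(half)])
    h2 = WATER_OH * np.array([-np.sin(half), 0, np.cos(half)])
    sites = np.empty((n, 3, 3))
    for i in range(n):
        R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        sites[i, 0] = o_pos[i]
        sites[i, 1] = o_pos[i] + R @ h1
        sites[i, 2] = o_pos[i] + R @ h2
    return sites


def _place_waters(atoms, bp, rng, z_top, positions=None):
    pos = _water_positions(bp, rng, z_top) if positions is None else positions
    sites = _water_sites(pos, rng)
    for i in range(sites.shape[0]):
        atoms.add("O", "TIP3", i + 1, "W", "O", sites[i, 0])
        atoms.add("H1", "TIP3", i + 1, "W", "H", sites[i, 1])
        atoms.add("H2", "TIP3", i + 1, "W", "H", sites[i, 2])


def _ion_positions(n, z_range, lateral, rng):
    r = lateral * np.sqrt(rng.uniform(0, 1, n))
    t = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(z_range[0] + 0.2, z_range[1] - 0.2, n)
    return np.column_stack([r * np.cos(t), r * np.sin(t), z])


def _place_ions(atoms, bp, rng):
    cat = _ion_positions(bp.n_cations, bp.cation_z_range, bp.ion_lateral_radius, rng)
    an = _ion_positions(bp.n_anions, bp.anion_z_range, bp.ion_lateral_radius, rng)
    for i, p in enumerate(cat):
        atoms.add("SOD", "SOD", i + 1, "I", "NA", p)
    for i, p in enumerate(an):
        atoms.add("CLA", "CLA", bp.n_cations + i + 1, "I", "CL", p)


# ---- trajectories ------------------------------------------------------------


def build_trajectory(
    start: PentamerBlueprint,
    end: PentamerBlueprint,
    n_frames: int,
    noise_sigma: float | None = None,
    seed: int | None = None,
    frame_interval: float = 0.1,
    topology: ChannelTopology | None = None,
) -> tuple[Trajectory, dict]:
    """Linear interpolation between two conformations plus thermal noise.

    Protein and ligand coordinates interpolate between the two noise-free
    constructions; i.i.d. Gaussian noise of width ``noise_sigma`` (default:
    the start blueprint's sigma) is added per atom per frame.  Waters are
    re-placed each frame at the linearly interpolated occupancy (uniform in
    the pore cylinder); the water atom allocation is fixed at the maximum
    occupancy and surplus waters are parked in a bulk shell far outside every
    counting region, so the Trajectory keeps a constant atom count while the
    counted occupancy tracks the schedule exactly.  When the occupancy is
    constant the frame-0 water placement is kept, so noise-free
    equal-endpoint trajectories have strictly constant descriptors.
    """
    topo = topology or default_topology()
    seed = start.seed if seed is None else seed
    sigma = start.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)

    s_dry = copy.deepcopy(start)
    e_dry = copy.deepcopy(end)
    for bpx in (s_dry, e_dry):
        bpx.noise_sigma = 0.0
        bpx.n_waters_pore = 0
        bpx.n_waters_gate = 0
        bpx.n_cations = start.n_cations
        bpx.n_anions = start.n_anions
        bpx.seed = seed  # identical ion draws at both endpoints' layouts
    frame_s, gt_s = build_pentamer(s_dry, topo)
    frame_e, gt_e = build_pentamer(e_dry, topo)
    if frame_s.n_atoms != frame_e.n_atoms or not np.array_equal(
        frame_s.name, frame_e.name
    ):
        raise ValueError("start and end blueprints have mismatched atom layouts")

    gate_sched = np.rint(
        np.linspace(start.n_waters_gate, end.n_waters_gate, n_frames)
    ).astype(int)
    outer_sched = np.rint(
        np.linspace(
            start.n_waters_pore - start.n_waters_gate,
            end.n_waters_pore - end.n_waters_gate,
            n_frames,
        )
    ).astype(int)
    alloc = int(gate_sched.max() + outer_sched.max())
    z_top = gt_s["z_top"]
    park_base = np.array([30.0, 0.0, 0.0])

    water_bp = copy.deepcopy(start)

    coords = []
    template = None
    prev_key = None
    prev_sites = None
    for i in range(n_frames):
        t = i / (n_frames - 1) if n_frames > 1 else 0.0
        prot = (1 - t) * frame_s.coords + t * frame_e.coords
        if sigma > 0:
            prot = prot + rng.normal(0.0, sigma, prot.shape)
        key = (int(gate_sched[i]), int(outer_sched[i]))
        if key != prev_key or prev_sites is None:
            active = _water_positions(
                water_bp, rng, z_top, n_gate=key[0], n_outer=key[1]
            )
            n_park = alloc - active.shape[0]
            park = park_base + np.column_stack(
                [np.zeros(n_park), 4.0 * np.arange(n_park), np.zeros(n_park)]
            )
            prev_sites = _water_sites(np.vstack([active, park]) if n_park else active,
                                      rng)
            prev_key = key
        wat = prev_sites.reshape(-1, 3)
        coords.append(np.vstack([prot, wat]))
        if template is None:
            solvent = _AtomList()
            for w in range(alloc):
                solvent.add("O", "TIP3", w + 1, "W", "O", (0, 0, 0))
                solvent.add("H1", "TIP3", w + 1, "W", "H", (0, 0, 0))
                solvent.add("H2", "TIP3", w + 1, "W", "H", (0, 0, 0))
            template = _concat(frame_s, solvent.to_frame())
    traj = Trajectory(
        template=template,
        coords=np.array(coords),
        times=np.arange(n_frames) * frame_interval,
        origin=f"{start.name}->{end.name}",
    )
    gt = {
        "start": gt_s,
        "end": gt_e,
        "gate_schedule": gate_sched.tolist(),
        "pore_schedule": (gate_sched + outer_sched).tolist(),
        "noise_sigma": float(sigma),
        "seed": int(seed),
        "start_water_counts": {"pore": start.n_waters_pore, "gate": start.n_waters_gate},
        "end_water_counts": {"pore": end.n_waters_pore, "gate": end.n_waters_gate},
        "tense_pair_distance": [
            float((1 - i / (n_frames - 1 or 1)) * start.tense_pair_distance
                  + (i / (n_frames - 1 or 1)) * end.tense_pair_distance)
            for i in range(n_frames)
        ],
    }
    return traj, gt


def place_hbond_fixture(
    pattern, mode: str = "water_residue", frame_interval: float = 0.1
) -> Trajectory:
    """Tiny donor/acceptor system toggled by a per-frame on/off schedule.

    ``water_residue``: a serine hydroxyl and one water, H···O distance 1.8 Å
    (on) or 4.5 Å heavy-atom shift (off).  ``intra_protein``: two residues
    with a backbone N donor and O acceptor at 2.8 Å (on) / 4.5 Å (off).
    Persistence ground truth equals the schedule duty cycle exactly.
    """
    pattern = np.asarray(pattern, dtype=bool)
    if pattern.size == 0:
        raise ValueError("schedule must be non-empty")

    def frame_for(on: bool) -> StructureFrame:
        a = _AtomList()
        if mode == "water_residue":
            a.add("CA", "SER", 10, "A", "C", (0.0, 0.0, 0.0))
            a.add("OG", "SER", 10, "A", "O", (1.4, 0.0, 0.0))
            a.add("HG", "SER", 10, "A", "H", (2.35, 0.0, 0.0))
            shift = 0.0 if on else 3.0
            h1 = np.array([1.4 + 1.8 + shift, 0.0, 0.0])
            o = h1 + np.array([WATER_OH, 0.0, 0.0])
            a.add("O", "TIP3", 1, "W", "O", o)
            a.add("H1", "TIP3", 1, "W", "H", h1)
            a.add("H2", "TIP3", 1, "W", "H", o + np.array([0.3, 0.9, 0.0]))
        elif mode == "intra_protein":
            d = 2.8 if on else 4.5
            a.add("CA", "ALA", 1, "A", "C", (0.0, 0.0, 0.0))
            a.add("N", "ALA", 1, "A", "N", (1.0, 0.0, 0.0))
            a.add("CA", "ALA", 2, "A", "C", (1.0 + d + 1.2, 0.0, 0.0))
            a.add("O", "ALA", 2, "A", "O", (1.0 + d, 0.0, 0.0))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return a.to_frame()

    on_f, off_f = frame_for(True), frame_for(False)
    coords = np.array([(on_f if p else off_f).coords for p in pattern])
    return Trajectory(
        template=on_f,
        coords=coords,
        times=np.arange(pattern.size) * frame_interval,
        origin=f"hbond_fixture_{mode}",
    )


# ---- analytic pore fixtures --------------------------------------------------


def cylinder_fixture(
    radius, z_range=(-10.0, 10.0), n_rings=41, n_per_ring=12, element="C"
) -> StructureFrame:
    """Atoms on a coaxial cylinder (or funnel when ``radius`` is callable in
    z) for analytic pore-profile checks."""
    a = _AtomList()
    zs = np.linspace(z_range[0], z_range[1], n_rings)
    rs = 1
    for i, z in enumerate(zs):
        r = radius(z) if callable(radius) else float(radius)
        for k in range(n_per_ring):
            t = 2 * np.pi * k / n_per_ring
            a.add("X", "CYL", rs, "A", element,
                  (r * np.cos(t), r * np.sin(t), z))
            rs += 1
    return a.to_frame()
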