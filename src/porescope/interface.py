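"""LBD–TMD interface distances, C-loop closure, ligand monitors and ions.

Covers the interface descriptors used to read the gating state off a
conformation: the M2-M3 loop position relative to the Cys-loop and the
β1-β2 loop, the C-loop/backwall closure distance (dCintra), ligand contact
monitors, ligand orientation classification, and axial ion distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AbsenceError, TopologyError
from .geometry import AxisFrame, center_of_mass
from .model import DescriptorSeries, StructureFrame, Trajectory
from .topology import ChannelTopology

ORIENTATION_CLASSES = ("axial_up", "axial_down", "equatorial", "intermediate")
#: Cone half-angles (deg) operationalizing the qualitative axial/equatorial
#: description; this classification is this package's own convention.
AXIAL_CONE_DEG = 45.0
EQUATORIAL_CONE_DEG = 67.5


def _span_ca_com(frame, chain, span) -> np.ndarray:
    from .errors import SelectionError

    try:
        idx = frame.indices(chain=chain, resseq=span, name="CA")
    except SelectionError:
        raise TopologyError(f"span {span} unresolvable on chain {chain}") from None
    return frame.coords[idx].mean(axis=0)


def interface_distances(
    frame: StructureFrame, topology: ChannelTopology
) -> dict[str, np.ndarray]:
    """Per-subunit M2-M3 loop position at the LBD–TMD interface.

    Returns the distance from the Pro256 Cα to (i) the Cα center of mass of
    the Cys-loop (residues 122–136) and (ii) the Lys40 Cα on the β1-β2 loop.
    """
    pro = topology.key_residue("Pro256")
    lys = topology.key_residue("Lys40")
    cys_span = topology.loop_span("Cys-loop")
    d_cys, d_lys = [], []
    for chain in topology.chain_ids:
        try:
            pro_ca = frame.coords[frame.indices(chain=chain, resseq=pro, name="CA")][0]
            lys_ca = frame.coords[frame.indices(chain=chain, resseq=lys, name="CA")][0]
        except Exception as exc:
            raise TopologyError(f"named residue unresolvable on chain {chain}: {exc}")
        cys_com = _span_ca_com(frame, chain, cys_span)
        d_cys.append(np.linalg.norm(pro_ca - cys_com))
        d_lys.append(np.linalg.norm(pro_ca - lys_ca))
    return {
        "Pro256-CysLoop": np.array(d_cys),
        "Pro256-Lys40": np.array(d_lys),
    }


def dcintra(frame: StructureFrame, topology: ChannelTopology) -> np.ndarray:
    """C-loop closure: distance between the Cα COM of the C-loop (179–188)
    and the Cα COM of the backwall residues (139–140), per subunit."""
    c_span = topology.loop_span("C-loop")
    b_span = topology.loop_span("backwall")
    return np.array(
        [
            np.linalg.norm(
                _span_ca_com(frame, chain, c_span) - _span_ca_com(frame, chain, b_span)
            )
            for chain in topology.chain_ids
        ]
    )


def dcintra_series(traj: Trajectory, topology: ChannelTopology) -> DescriptorSeries:
    vals = np.array([dcintra(f, topology) for f in traj])
    return DescriptorSeries(
        label="dCintra", units="Å", values=vals, times=traj.times,
        columns=[f"P{i + 1}" for i in range(5)],
    )


# ---- ligand monitors ---------------------------------------------------------


@dataclass
class SelSpec:
    """One side of a contact monitor: atoms resolved by residue and name(s).

    Multi-atom selections (aromatic rings) are reduced to their centroid.
    ``chain=None`` means "use the chain being iterated" so one monitor table
    covers all five binding sites; ``chain_offset`` shifts to the adjacent
    (complementary) subunit.
    """

    names: list[str]
    resseq: int | None = None
    resname: str | None = None
    chain: str | None = None
    chain_offset: int = 0

    def resolve(self, frame, topology, site_chain) -> np.ndarray:
        chain = self.chain
        if chain is None:
            i = topology.chain_ids.index(site_chain)
            chain = topology.chain_ids[(i + self.chain_offset) % 5]
        m = frame.mask(chain=chain, resseq=self.resseq, resname=self.resname,
                       name=self.names)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise AbsenceError(
                f"monitor atoms {self.names} (res {self.resname or self.resseq}) "
                f"absent on chain {chain}"
            )
        return frame.coords[idx].mean(axis=0)


@dataclass
class ContactMonitor:
    name: str
    a: SelSpec
    b: SelSpec


def ligand_contacts(
    frame: StructureFrame,
    topology: ChannelTopology,
    contact_table: list[ContactMonitor],
    site_chains: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Named atom-pair (or ring-centroid) distances, one value per binding
    site.  Returns monitor name → distances over sites."""
    sites = site_chains or list(topology.chain_ids)
    out = {}
    for mon in contact_table:
        out[mon.name] = np.array(
            [
                np.linalg.norm(
                    mon.a.resolve(frame, topology, c) - mon.b.resolve(frame, topology, c)
                )
                for c in sites
            ]
        )
    return out


def pooled_summary(per_site_series: np.ndarray) -> tuple[float, float]:
    """Mean ± s.d. pooled over subunits and frames (Table-style summaries)."""
    flat = np.ravel(per_site_series)
    return float(flat.mean()), float(flat.std())


def classify_ligand_orientation(
    frame: StructureFrame,
    topology: ChannelTopology,
    axisframe: AxisFrame,
    reference_atom: str = "CL",
    axial_cone: float = AXIAL_CONE_DEG,
    equatorial_cone: float = EQUATORIAL_CONE_DEG,
) -> list[str]:
    """Classify each bound-ligand copy by where its reference atom points.

    The unit vector from the ligand centroid to the reference atom (the
    chlorine for epibatidine) is compared against the symmetry axis:
    within ``axial_cone`` of +z → axial_up, of −z → axial_down; more than
    ``equatorial_cone`` away from both poles and dominated by the
    radial-inward component → equatorial; everything else → intermediate.
    """
    lig_mask = frame.resname == topology.ligand_resname
    if not np.any(lig_mask):
        raise AbsenceError(f"ligand {topology.ligand_resname!r} absent")
    z = axisframe.z_axis
    cos_axial = np.cos(np.radians(axial_cone))
    cos_equat = np.cos(np.radians(equatorial_cone))
    classes = []
    keys = sorted(
        set(zip(frame.chain[lig_mask], frame.resseq[lig_mask])), key=str
    )
    for chain, resseq in keys:
        m = lig_mask & (frame.chain == chain) & (frame.resseq == resseq)
        centroid = frame.coords[m].mean(axis=0)
        ref = np.flatnonzero(m & (frame.name == reference_atom))
        if ref.size == 0:
            raise AbsenceError(f"reference atom {reference_atom!r} absent from ligand")
        u = frame.coords[ref[0]] - centroid
        u = u / np.linalg.norm(u)
        c = float(np.dot(u, z))
        if c > cos_axial:
            classes.append("axial_up")
        elif c < -cos_axial:
            classes.append("axial_down")
        elif abs(c) < cos_equat:
            radial = centroid - axisframe.origin
            radial = radial - np.dot(radial, z) * z
            rn = np.linalg.norm(radial)
            if rn < 1e-8:
                classes.append("intermediate")
                continue
            inward = -radial / rn
            tangential = np.cross(z, inward)
            if np.dot(u, inward) > abs(np.dot(u, tangential)):
                classes.append("equatorial")
            else:
                classes.append("intermediate")
        else:
            classes.append("intermediate")
    return classes


@dataclass
class LigandPose:
    """Per-frame ligand orientation classes and monitored distances."""

    classes: list[list[str]]
    distances: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frame_classes in self.classes:
            for c in frame_classes:
                if c not in ORIENTATION_CLASSES:
                    raise ValueError(f"unknown orientation class {c!r}")


# ---- ions --------------------------------------------------------------------

_SPECIES = {"cation": "is_cation", "anion": "is_anion"}


def _ion_indices(frame: StructureFrame, species: str) -> np.ndarray:
    try:
        return np.flatnonzero(getattr(frame, _SPECIES[species]))
    except KeyError:
        raise ValueError(f"unknown ion species {species!r}") from None


def ion_z_distribution(
    traj: Trajectory,
    axisframe: AxisFrame,
    species: str,
    z_range: tuple[float, float],
    bin_width: float = 2.0,
    lateral_radius: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-over-frames histogram of ion axial coordinates.

    Only ions within ``lateral_radius`` of the axis are counted.  Returns
    (bin edges, counts)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    idx = _ion_indices(traj.template, species)
    for f in traj:
        if idx.size == 0:
            break
        pos = f.coords[idx]
        z = axisframe.axial_coordinate(pos)
        rho = axisframe.radial_distance(pos)
        keep = (rho <= lateral_radius) & (z >= z_range[0]) & (z < z_range[1])
        c, _ = np.histogram(z[keep], bins=edges)
        counts += c
    return edges, counts


def ion_occupancy(
    traj: Trajectory,
    axisframe: AxisFrame,
    region,
    species: str,
) -> DescriptorSeries:
    """Per-frame count of ions of one species inside a pore region; the
    maximum simultaneous occupancy is stored in the series flags."""
    idx = _ion_indices(traj.template, species)
    vals = np.zeros(traj.n_frames, dtype=int)
    for i, f in enumerate(traj):
        if idx.size == 0:
            break
        pos = f.coords[idx]
        z = axisframe.axial_coordinate(pos)
        rho = axisframe.radial_distance(pos)
        vals[i] = int(
            ((z >= region.z_lo) & (z < region.z_hi) & (rho <= region.radius)).sum()
        )
    return DescriptorSeries(
        label=f"{species}_occupancy_{region.name}",
        units="count",
        values=vals,
        times=traj.times,
        flags={"max_simultaneous": int(vals.max()) if vals.size else 0},
    )
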