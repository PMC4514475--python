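"""Gate-state descriptors: crossed distances, pore-radius profile, M2 tilt
decomposition and quaternary twist.

Sign conventions (documented so literature comparisons keep their signs):

* polar tilt — signed angle between the local z axis and the projection of the
  helix axis on the local xz plane, positive when the helix top leans toward
  the radial-outward x direction;
* azimuthal tilt — signed angle from local x to the projection of the helix
  axis on the local xy plane, positive toward the tangential +y direction;
* twist — signed angle from the LBD center-of-mass projection to the TMD one
  in the plane perpendicular to the symmetry axis, positive counter-clockwise
  viewed from the extracellular side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, TopologyError
from .geometry import AxisFrame, center_of_mass
from .model import DescriptorSeries, StructureFrame
from .topology import ChannelTopology

#: Van der Waals radii (Å, Bondi) used by the pore-radius profile.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "CL": 1.75,
    "NA": 2.27,
}
DEFAULT_VDW = 1.70


@dataclass
class PoreProfile:
    """Pore radius r(z) sampled at uniformly spaced axial stations."""

    z: np.ndarray
    radius: np.ndarray
    spacing: float
    empty_slab: np.ndarray  # True where no atom fell in the slab

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.empty_slab = np.asarray(self.empty_slab, dtype=bool)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("stations must be strictly increasing")
        if np.any(self.radius < 0):
            raise ValueError("pore radius must be non-negative")

    def minimum(self) -> tuple[float, float]:
        """(z, r) of the narrowest sampled station."""
        i = int(np.argmin(self.radius))
        return float(self.z[i]), float(self.radius[i])

    def radius_at(self, z: float) -> float:
        """Radius at the station nearest to z."""
        return float(self.radius[int(np.argmin(np.abs(self.z - z)))])


@dataclass
class TiltAngles:
    """Per-helix polar and azimuthal tilt components (degrees)."""

    polar: np.ndarray
    azimuthal: np.ndarray
    azimuthal_degenerate: np.ndarray
    chains: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.polar) >= 90):
            raise ValueError("polar tilt out of (−90, 90)")


def resolve_ring(
    frame: StructureFrame,
    topology: ChannelTopology,
    prime_index: int,
    selection_mode: str = "residue_com",
) -> np.ndarray:
    """Positions (5, 3) of a prime ring, one per chain: whole-residue center
    of mass (``residue_com``, mass-weighted) or the Cα atom (``calpha``)."""
    resid = topology.resid_for_prime(prime_index)
    out = []
    for chain in topology.chain_ids:
        m = frame.mask(chain=chain, resseq=resid)
        if selection_mode == "calpha":
            m &= frame.name == "CA"
        elif selection_mode != "residue_com":
            raise ValueError(f"unknown selection mode {selection_mode!r}")
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise TopologyError(
                f"prime {prime_index}' (residue {resid}) unresolvable on chain {chain}"
            )
        weighting = "geometric" if selection_mode == "calpha" else "mass"
        out.append(center_of_mass(frame, idx, weighting=weighting))
    return np.array(out)


def crossed_distances(
    frame: StructureFrame,
    topology: ChannelTopology,
    prime_index: int,
    selection_mode: str = "residue_com",
) -> np.ndarray:
    """The five distances between equivalent residues on non-adjacent chains,
    in the stable pair order P1–P3, P2–P4, P3–P5, P4–P1, P5–P2."""
    ring = resolve_ring(frame, topology, prime_index, selection_mode)
    pos = {c: ring[i] for i, c in enumerate(topology.chain_ids)}
    return np.array(
        [np.linalg.norm(pos[a] - pos[b]) for a, b in topology.non_adjacent_pairs()]
    )


def crossed_distance_series(
    traj, topology, prime_index, selection_mode="residue_com"
) -> DescriptorSeries:
    vals = np.array(
        [crossed_distances(f, topology, prime_index, selection_mode) for f in traj]
    )
    pairs = [f"{a}-{b}" for a, b in topology.non_adjacent_pairs()]
    return DescriptorSeries(
        label=f"crossed_{prime_index}p_{selection_mode}",
        units="Å",
        values=vals,
        times=traj.times,
        columns=pairs,
    )


def pore_radius_profile(
    frame: StructureFrame,
    axisframe: AxisFrame,
    z_range: tuple[float, float],
    spacing: float = 0.5,
    vdw_table: dict[str, float] | None = None,
    max_radius: float = 15.0,
    ligand_resname: str | None = None,
) -> PoreProfile:
    """Axis-sampling minimal-clearance pore radius profile.

    At each axial station the radius is the smallest protein-atom clearance,
    ``distance(atom center, axis line) − r_vdW``, over atoms whose axial
    coordinate falls in the slab of half-width ``spacing/2`` around the
    station; floored at zero.  Stations with no atom in the slab report
    ``max_radius`` and are flagged.  This is a straight-pore variant of the
    classic sphere-tracing profile algorithms: the probe center stays on the
    symmetry axis instead of wandering, which is adequate for the M2 lumen.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    vdw = dict(VDW_RADII)
    if vdw_table:
        vdw.update({k.upper(): float(v) for k, v in vdw_table.items()})
    mask = frame.protein_mask(ligand_resname)
    coords = frame.coords[mask]
    elements = frame.element[mask]
    zc = axisframe.axial_coordinate(coords)
    rho = axisframe.radial_distance(coords)
    radii = np.array([vdw.get(str(e).upper(), DEFAULT_VDW) for e in elements])

    z_lo, z_hi = z_range
    stations = np.arange(z_lo, z_hi + 1e-9, spacing)
    out = np.empty(stations.size)
    empty = np.zeros(stations.size, dtype=bool)
    half = spacing / 2.0
    for i, z in enumerate(stations):
        in_slab = np.abs(zc - z) <= half
        if not np.any(in_slab):
            out[i] = max_radius
            empty[i] = True
            continue
        out[i] = max(0.0, float(np.min(rho[in_slab] - radii[in_slab])))
    return PoreProfile(z=stations, radius=out, spacing=spacing, empty_slab=empty)


def m2_helix_axis(
    frame: StructureFrame,
    topology: ChannelTopology,
    chain: str,
    orient_along: np.ndarray | None = None,
    method: str = "cylinder",
) -> np.ndarray:
    """Direction of one M2 helix, oriented by positive dot product with
    ``orient_along`` (default: laboratory z).

    ``method='pca'`` returns the first principal component of the M2 Cα
    coordinates.  The default ``'cylinder'`` refines the PCA direction by
    least-squares cylinder fitting (minimize the variance of the Cα radial
    distances about the axis): an α-helix covering a non-integer number of
    turns biases the raw principal component toward the side where the Cα
    wheel is over-represented, while the Cα radial distance is constant for
    an ideal helix regardless of phase, making the cylinder fit unbiased.
    """
    lo, hi = topology.m2_range
    m = frame.mask(chain=chain, resseq=(lo, hi), name="CA")
    idx = np.flatnonzero(m)
    if idx.size < 3:
        raise TopologyError(f"M2 Cα atoms missing on chain {chain}")
    pts = frame.coords[idx]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if method == "cylinder":
        from scipy.optimize import least_squares

        u, v = vt[1], vt[2]

        def residuals(p):
            tx, ty, cx, cy = p
            w = axis + tx * u + ty * v
            w = w / np.linalg.norm(w)
            rel = centered - (cx * u + cy * v)
            perp = rel - np.outer(rel @ w, w)
            r = np.linalg.norm(perp, axis=1)
            return r - r.mean()

        sol = least_squares(residuals, np.zeros(4), method="lm")
        axis = axis + sol.x[0] * u + sol.x[1] * v
        axis = axis / np.linalg.norm(axis)
    elif method != "pca":
        raise ValueError(f"unknown method {method!r}")
    ref = np.array([0.0, 0.0, 1.0]) if orient_along is None else np.asarray(orient_along)
    if np.dot(axis, ref) < 0:
        axis = -axis
    return axis


def tilt_angles(
    frame: StructureFrame,
    axisframe: AxisFrame,
    topology: ChannelTopology,
) -> TiltAngles:
    """Decompose each M2 helix orientation into polar and azimuthal tilt.

    The helix axis is expressed in the helix's local (x radial, y tangential,
    z channel-axis) frame; see the module docstring for sign conventions.
    Helices parallel to z have an undefined azimuth, reported as 0 with the
    degeneracy flag set.
    """
    polar, azim, degen = [], [], []
    for chain in topology.chain_ids:
        hf = axisframe.helix_frames[chain]
        v = m2_helix_axis(frame, topology, chain, orient_along=hf.z)
        vx, vy, vz = np.dot(v, hf.x), np.dot(v, hf.y), np.dot(v, hf.z)
        polar.append(np.degrees(np.arctan2(vx, vz)))
        if np.hypot(vx, vy) < 1e-8:
            azim.append(0.0)
            degen.append(True)
        else:
            azim.append(np.degrees(np.arctan2(vy, vx)))
            degen.append(False)
    return TiltAngles(
        polar=np.array(polar),
        azimuthal=np.array(azim),
        azimuthal_degenerate=np.array(degen),
        chains=topology.chain_ids,
    )


def twist_angle(
    frame: StructureFrame,
    axisframe: AxisFrame,
    topology: ChannelTopology,
    lbd_span: tuple[int, int],
    tmd_span: tuple[int, int],
) -> tuple[np.ndarray, float]:
    """Quaternary twist between the ligand-binding and transmembrane domains.

    Per subunit, the vectors from the whole-protein Cα center of mass to the
    subunit's LBD and TMD Cα centers of mass are projected on the plane
    perpendicular to the symmetry axis; the twist is the signed angle between
    the projections.  Returns (per-subunit array, mean)."""
    z = axisframe.z_axis
    prot = frame.protein_mask(topology.ligand_resname)
    ca_all = np.flatnonzero(prot & (frame.name == "CA"))
    com_all = frame.coords[ca_all].mean(axis=0)
    per = []
    for chain in topology.chain_ids:
        angles = []
        for span in (lbd_span, tmd_span):
            idx = frame.indices(chain=chain, resseq=span, name="CA")
            v = frame.coords[idx].mean(axis=0) - com_all
            v = v - np.dot(v, z) * z
            if np.linalg.norm(v) < 1e-8:
                raise GeometryError(
                    f"domain COM projection degenerate on chain {chain}"
                )
            angles.append(v)
        v1, v2 = angles
        signed = np.degrees(
            np.arctan2(np.dot(z, np.cross(v1, v2)), np.dot(v1, v2))
        )
        per.append(signed)
    per = np.array(per)
    return per, float(per.mean())


@dataclass
class Histogram:
    """Normalized histogram: per-bin probability mass sums to 1."""

    edges: np.ndarray
    mass: np.ndarray

    @property
    def density(self) -> np.ndarray:
        return self.mass / np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def distance_distribution(
    series: DescriptorSeries,
    bin_width: float,
    merge_subunits: bool = True,
) -> Histogram:
    """Histogram of a distance series; ``merge_subunits`` pools all pair or
    subunit columns before binning (so individual-subunit transitions are not
    blurred by averaging)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if series.n_frames == 0:
        raise ValueError("empty series")
    data = series.merged() if merge_subunits else np.asarray(series.values, dtype=float)
    data = np.ravel(data)
    lo = np.floor(data.min() / bin_width) * bin_width
    hi = np.ceil(data.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(data, bins=edges)
    return Histogram(edges=edges, mass=counts / counts.sum())
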