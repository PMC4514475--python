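"""Geometric substrate: centers of mass, the channel axis frame, optimal
rigid-body superposition (Kabsch), RMSD and RMSF.

The channel reference frame follows the convention used throughout the
pentameric-channel literature: the global z axis is the protein (pseudo-C5)
symmetry axis oriented intracellular → extracellular, and each M2 helix
carries a local frame centered on its center of mass with x pointing radially
outward from the pore axis and y = z × x completing a right-handed triad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, SelectionError
from .model import DescriptorSeries, StructureFrame, Trajectory
from .topology import ChannelTopology


def center_of_mass(
    frame: StructureFrame,
    selection: np.ndarray,
    weighting: str = "mass",
) -> np.ndarray:
    """Weighted mean position of a selection (atom indices or boolean mask).

    ``weighting='geometric'`` treats all atoms equally; ``'mass'`` weights by
    standard atomic masses of the elements.
    """
    idx = np.asarray(selection)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise SelectionError("empty selection for center of mass")
    pos = frame.coords[idx]
    if weighting == "geometric":
        return pos.mean(axis=0)
    if weighting == "mass":
        w = frame.masses[idx]
        return (pos * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class HelixFrame:
    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


@dataclass
class AxisFrame:
    """Global symmetry axis plus per-helix local frames."""

    origin: np.ndarray
    z_axis: np.ndarray
    helix_frames: dict[str, HelixFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        n = np.linalg.norm(self.z_axis)
        if n < 1e-12:
            raise GeometryError("zero-length symmetry axis")
        self.z_axis = self.z_axis / n
        for hf in self.helix_frames.values():
            for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
                if abs(np.dot(getattr(hf, a), getattr(hf, b))) > 1e-10:
                    raise GeometryError("helix frame axes not orthonormal")

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        """z coordinate of points along the symmetry axis (origin = 0)."""
        return np.atleast_2d(points - self.origin) @ self.z_axis

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.origin
        z = d @ self.z_axis
        perp = d - np.outer(z, self.z_axis)
        return np.linalg.norm(perp, axis=1)


def m2_calpha_indices(
    frame: StructureFrame, topology: ChannelTopology, chain: str
) -> np.ndarray:
    lo, hi = topology.m2_range
    return frame.indices(chain=chain, resseq=(lo, hi), name="CA")


def symmetry_axis(
    frame: StructureFrame,
    topology: ChannelTopology,
    method: str = "ring_chord",
) -> AxisFrame:
    """Build the channel axis frame from a structure.

    ``ring_chord`` (default): z is the unit vector from the Cα-ring center of
    mass at −2′ to the one at 20′ — robust when the extracellular domain is
    asymmetric.  ``pca``: first principal axis of all M2 Cα coordinates.
    The frame origin is the center of mass of all M2 Cα atoms.
    """
    primes = topology.prime_indices
    lo_res = topology.resid_for_prime(primes[0])
    hi_res = topology.resid_for_prime(primes[-1])
    lo_ring, hi_ring, all_ca = [], [], []
    for chain in topology.chain_ids:
        lo_ring.append(frame.coords[frame.indices(chain=chain, resseq=lo_res, name="CA")].mean(axis=0))
        hi_ring.append(frame.coords[frame.indices(chain=chain, resseq=hi_res, name="CA")].mean(axis=0))
        all_ca.append(frame.coords[m2_calpha_indices(frame, topology, chain)])
    lo_com = np.mean(lo_ring, axis=0)
    hi_com = np.mean(hi_ring, axis=0)
    origin = np.concatenate(all_ca).mean(axis=0)
    if method == "ring_chord":
        chord = hi_com - lo_com
        if np.linalg.norm(chord) < 1e-6:
            raise GeometryError("degenerate ring geometry: −2′ and 20′ ring COMs coincide")
        z = chord / np.linalg.norm(chord)
    elif method == "pca":
        pts = np.concatenate(all_ca) - origin
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        z = vt[0]
        if np.dot(z, hi_com - lo_com) < 0:
            z = -z
    else:
        raise ValueError(f"unknown axis method {method!r}")

    helix_frames = {}
    for chain in topology.chain_ids:
        idx = m2_calpha_indices(frame, topology, chain)
        h_origin = center_of_mass(frame, idx, weighting="mass")
        radial = h_origin - origin
        radial = radial - np.dot(radial, z) * z
        nr = np.linalg.norm(radial)
        if nr < 1e-8:
            raise GeometryError(f"helix {chain} center lies on the pore axis")
        x = radial / nr
        y = np.cross(z, x)
        helix_frames[chain] = HelixFrame(origin=h_origin, x=x, y=y, z=z.copy())
    return AxisFrame(origin=origin, z_axis=z, helix_frames=helix_frames)


# ---- superposition -----------------------------------------------------------


def superpose(
    mobile: StructureFrame,
    reference: StructureFrame,
    selection: np.ndarray,
    ref_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the fitted coordinates given by
    ``mobile.coords @ R.T + t``; ``rmsd`` is the post-fit RMSD over the
    selection.  Standard Kabsch algorithm via SVD, with the determinant
    correction for proper rotations.
    """
    sel_m = np.asarray(selection)
    if sel_m.dtype == bool:
        sel_m = np.flatnonzero(sel_m)
    sel_r = sel_m if ref_selection is None else np.asarray(ref_selection)
    if sel_r.dtype == bool:
        sel_r = np.flatnonzero(sel_r)
    if sel_m.size != sel_r.size:
        raise SelectionError("selection size mismatch between mobile and reference")
    if sel_m.size < 3:
        raise GeometryError("need at least 3 atoms for superposition")
    P = mobile.coords[sel_m]
    Q = reference.coords[sel_r]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: StructureFrame,
    selection: np.ndarray,
    per_subunit: bool = False,
    topology: ChannelTopology | None = None,
) -> DescriptorSeries:
    """Per-frame post-superposition Cα RMSD from a reference structure.

    ``per_subunit`` fits and scores each chain independently (requires a
    topology for the chain bookkeeping); roto-translational body motion is
    removed before each measurement.
    """
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if per_subunit:
        if topology is None:
            raise ValueError("per_subunit RMSD requires a topology")
        chains = reference.chain[sel]
        groups = [sel[chains == c] for c in topology.chain_ids]
        vals = np.empty((traj.n_frames, 5))
        for i, frame in enumerate(traj):
            for j, g in enumerate(groups):
                vals[i, j] = superpose(frame, reference, g)[2]
        return DescriptorSeries(
            label="rmsd_per_subunit", units="Å", values=vals, times=traj.times,
            columns=[f"P{j + 1}" for j in range(5)],
        )
    vals = np.array([superpose(f, reference, sel)[2] for f in traj])
    return DescriptorSeries(label="rmsd", units="Å", values=vals, times=traj.times)


def rmsf(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[int, int] | None = None,
) -> DescriptorSeries:
    """Per-atom root-mean-square fluctuation about the window-average structure.

    Frames in the (closed) window are iteratively aligned to the running
    average (two passes), the standard two-pass procedure; the RMSF is then
    the per-atom RMS deviation from the converged average.
    """
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    lo, hi = (0, traj.n_frames - 1) if window is None else window
    if lo < 0 or hi >= traj.n_frames or hi < lo:
        raise ValueError(f"window {window} outside trajectory of {traj.n_frames} frames")
    frames = [traj.frame(i) for i in range(lo, hi + 1)]
    ref = frames[0].coords[sel].copy()
    aligned = None
    for _ in range(2):
        aligned = []
        ref_frame = frames[0].with_coords(
            np.zeros_like(frames[0].coords)
        )  # container for ref coords
        ref_frame.coords[sel] = ref
        for f in frames:
            R, t, _ = superpose(f, ref_frame, sel)
            aligned.append(f.coords[sel] @ R.T + t)
        ref = np.mean(aligned, axis=0)
    dev = np.asarray(aligned) - ref
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return DescriptorSeries(
        label="rmsf", units="Å", values=per_atom[None, :],
        times=np.array([traj.times[lo]]),
        columns=[f"atom{int(i)}" for i in sel],
    )


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation (test helper)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return R, t


def apply_rigid_motion(frame: StructureFrame, R: np.ndarray, t: np.ndarray) -> StructureFrame:
    return frame.with_coords(frame.coords @ R.T + t, time=frame.time)
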