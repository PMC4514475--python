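"""Flat-bottom quadratic crossed-distance restraint.

The pore-opening restraint acts on the center-of-mass distances between the
hydrophobic-gate residues (Leu16′ and Val13′) of non-adjacent subunit pairs.
Each pair contributes

    U_i = ½ k (d_i − d0_i)²   if d_i < d0_i,   else 0,

so the potential penalizes gate contraction only and is flat above the
threshold.  Thresholds are calibrated on a reference (open) structure and the
default force constant is k = 10 kcal/mol/Å².  With the ½ convention the
restoring force magnitude at a 1 Å violation is exactly k; the
``convention='k_full'`` switch selects U = k (d − d0)² instead.

Forces are the analytic gradient of U distributed onto the atoms of each COM
group by mass fraction (the standard COM-restraint chain rule), so the
restraint obeys Newton's third law pair by pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import GeometryError, TopologyError
from .model import StructureFrame, Trajectory
from .topology import ChannelTopology

DEFAULT_FORCE_CONSTANT = 10.0  # kcal/mol/Å²
DEFAULT_PRIMES = (16, 13)


@dataclass
class RestraintPair:
    prime_index: int
    chain_a: str
    chain_b: str
    selection_mode: str = "residue_com"
    d0: float | None = None  # Å; None until calibrated


@dataclass
class RestraintSpec:
    pairs: list[RestraintPair]
    k: float = DEFAULT_FORCE_CONSTANT
    convention: str = "half_k"  # or "k_full"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if self.convention not in ("half_k", "k_full"):
            raise ValueError(f"unknown convention {self.convention!r}")
        for p in self.pairs:
            if p.d0 is not None and p.d0 <= 0:
                raise ValueError("thresholds must be positive")

    def calibrated(self) -> bool:
        return all(p.d0 is not None for p in self.pairs)

    # -- serialization --

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "convention": self.convention,
            "pairs": [
                {
                    "prime_index": p.prime_index,
                    "chain_a": p.chain_a,
                    "chain_b": p.chain_b,
                    "selection_mode": p.selection_mode,
                    "d0": p.d0,
                }
                for p in self.pairs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RestraintSpec":
        return cls(
            pairs=[RestraintPair(**p) for p in d["pairs"]],
            k=d.get("k", DEFAULT_FORCE_CONSTANT),
            convention=d.get("convention", "half_k"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RestraintSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_spec(
    topology: ChannelTopology,
    primes: tuple[int, ...] = DEFAULT_PRIMES,
    k: float = DEFAULT_FORCE_CONSTANT,
    selection_mode: str = "residue_com",
) -> RestraintSpec:
    """Uncalibrated spec covering the 5 non-adjacent pairs at each prime ring
    (default 16′ and 13′ — the Leu/Val hydrophobic gate)."""
    pairs = [
        RestraintPair(prime_index=p, chain_a=a, chain_b=b, selection_mode=selection_mode)
        for p in primes
        for a, b in topology.non_adjacent_pairs()
    ]
    return RestraintSpec(pairs=pairs, k=k)


def _group_indices(
    frame: StructureFrame, topology: ChannelTopology, chain: str, pair: RestraintPair
) -> np.ndarray:
    resid = topology.resid_for_prime(pair.prime_index)
    m = frame.mask(chain=chain, resseq=resid)
    if pair.selection_mode == "calpha":
        m &= frame.name == "CA"
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise TopologyError(
            f"restraint pair {pair.prime_index}' {chain}: residue {resid} unresolvable"
        )
    return idx


def _pair_geometry(frame, topology, pair):
    ia = _group_indices(frame, topology, pair.chain_a, pair)
    ib = _group_indices(frame, topology, pair.chain_b, pair)
    if pair.selection_mode == "calpha":
        wa = np.ones(ia.size)
        wb = np.ones(ib.size)
    else:
        wa = frame.masses[ia]
        wb = frame.masses[ib]
    ca = (frame.coords[ia] * wa[:, None]).sum(axis=0) / wa.sum()
    cb = (frame.coords[ib] * wb[:, None]).sum(axis=0) / wb.sum()
    return ia, ib, wa / wa.sum(), wb / wb.sum(), ca, cb


@dataclass
class RestraintEnergy:
    total: float
    per_pair: np.ndarray
    distances: np.ndarray
    active: np.ndarray


def restraint_energy(
    frame: StructureFrame, spec: RestraintSpec, topology: ChannelTopology
) -> RestraintEnergy:
    """Total and per-pair restraint energy (kcal/mol) with activity flags."""
    if not spec.calibrated():
        raise ValueError("spec has uncalibrated thresholds; run calibrate_thresholds")
    pref = 0.5 if spec.convention == "half_k" else 1.0
    e, d, act = [], [], []
    for pair in spec.pairs:
        *_, ca, cb = _pair_geometry(frame, topology, pair)
        di = float(np.linalg.norm(ca - cb))
        d.append(di)
        below = di < pair.d0
        act.append(below)
        e.append(pref * spec.k * (di - pair.d0) ** 2 if below else 0.0)
    e = np.array(e)
    return RestraintEnergy(
        total=float(e.sum()), per_pair=e, distances=np.array(d), active=np.array(act)
    )


def restraint_forces(
    frame: StructureFrame, spec: RestraintSpec, topology: ChannelTopology
) -> np.ndarray:
    """Analytic forces (kcal/mol/Å), shape (n_atoms, 3).

    For an active pair, dU/dd = k(d−d0) (½k convention); the force on group A
    is −dU/dd · (c_A − c_B)/d, distributed over the group's atoms by mass
    fraction, and opposite on group B."""
    if not spec.calibrated():
        raise ValueError("spec has uncalibrated thresholds; run calibrate_thresholds")
    dpref = 1.0 if spec.convention == "half_k" else 2.0
    forces = np.zeros_like(frame.coords)
    for pair in spec.pairs:
        ia, ib, fa, fb, ca, cb = _pair_geometry(frame, topology, pair)
        delta = ca - cb
        di = float(np.linalg.norm(delta))
        if di < 1e-10:
            raise GeometryError("coincident restraint group centers")
        if di >= pair.d0:
            continue
        dudd = dpref * spec.k * (di - pair.d0)  # negative when violated
        f_on_a = -dudd * delta / di
        forces[ia] += fa[:, None] * f_on_a
        forces[ib] -= fb[:, None] * f_on_a
    return forces


def calibrate_thresholds(
    reference: StructureFrame, spec_template: RestraintSpec, topology: ChannelTopology
) -> RestraintSpec:
    """Set every pair's threshold d0 to its distance in the reference (the
    initial, open structure)."""
    pairs = []
    for pair in spec_template.pairs:
        *_, ca, cb = _pair_geometry(reference, topology, pair)
        pairs.append(replace(pair, d0=float(np.linalg.norm(ca - cb))))
    return RestraintSpec(pairs=pairs, k=spec_template.k, convention=spec_template.convention)


@dataclass
class RestraintActivity:
    """Per-frame per-pair restraint log (distances, energies, activity)."""

    times: np.ndarray
    distances: np.ndarray  # (F, P)
    energies: np.ndarray  # (F, P)
    active: np.ndarray  # (F, P) bool
    pair_labels: list[str] = field(default_factory=list)

    def total_energy(self) -> np.ndarray:
        return self.energies.sum(axis=1)

    def inactive_frames(self) -> np.ndarray:
        """Frames where no pair is active (used to seed free trajectories)."""
        return np.flatnonzero(~self.active.any(axis=1))

    def to_dataframe(self):
        import pandas as pd

        data = {"time": self.times}
        for j, lab in enumerate(self.pair_labels):
            data[f"d_{lab}"] = self.distances[:, j]
            data[f"U_{lab}"] = self.energies[:, j]
            data[f"active_{lab}"] = self.active[:, j].astype(int)
        return pd.DataFrame(data)


def restraint_activity_series(
    traj: Trajectory, spec: RestraintSpec, topology: ChannelTopology
) -> RestraintActivity:
    F, P = traj.n_frames, len(spec.pairs)
    distances = np.empty((F, P))
    energies = np.empty((F, P))
    active = np.empty((F, P), dtype=bool)
    for i, frame in enumerate(traj):
        res = restraint_energy(frame, spec, topology)
        distances[i] = res.distances
        energies[i] = res.per_pair
        active[i] = res.active
    labels = [f"{p.prime_index}p_{p.chain_a}{p.chain_b}" for p in spec.pairs]
    return RestraintActivity(
        times=traj.times, distances=distances, energies=energies, active=active,
        pair_labels=labels,
    )
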