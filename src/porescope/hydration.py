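"""Pore hydration and hydrogen-bond analysis.

Water counting in axial pore regions, ring-proximity water counts,
distance-criterion hydrogen-bond detection and persistence, and
hysteresis-based wetting/dewetting event detection.

Hydrogen bonds are purely distance-based, with two distinct criteria:

* water–residue: formed when the minimum hydrogen-to-heavy-atom distance over
  all donor/acceptor combinations between the water and the residue is below
  2.0 Å (a 2.0 Å heavy–heavy separation would be sterically impossible, so
  the cutoff is read as H···acceptor);
* intra-protein: formed when the heavy donor–acceptor distance is below
  3.0 Å.

No angular criterion is applied.  Both cutoffs are configurable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import TopologyError, TypingError
from .geometry import AxisFrame
from .model import DescriptorSeries, StructureFrame, Trajectory
from .topology import ChannelTopology

WATER_RESIDUE_CUTOFF = 2.0  # Å, H to heavy acceptor
INTRA_PROTEIN_CUTOFF = 3.0  # Å, heavy donor to heavy acceptor
RING_PROXIMITY_CUTOFF = 3.0  # Å, any water atom to any ring atom


@dataclass
class PoreRegion:
    """Axial slab [z_lo, z_hi) in channel-axis coordinates with a lateral
    cylinder bound."""

    name: str
    z_lo: float
    z_hi: float
    radius: float = 8.0

    def __post_init__(self) -> None:
        if self.z_hi <= self.z_lo:
            raise ValueError("region must have z_lo < z_hi")
        if self.radius <= 0:
            raise ValueError("lateral radius must be positive")


def region_from_ring(
    frame: StructureFrame,
    axisframe: AxisFrame,
    topology: ChannelTopology,
    prime_index: int,
    half_width: float = 5.0,
    radius: float = 8.0,
    name: str | None = None,
) -> PoreRegion:
    """A slab of total width 2×half_width centered on a prime ring's Cα COM
    (e.g. the 13′ ± 5 Å constriction-point region)."""
    from .pore import resolve_ring

    ring = resolve_ring(frame, topology, prime_index, "calpha")
    z0 = float(axisframe.axial_coordinate(ring.mean(axis=0))[0])
    return PoreRegion(
        name=name or f"ring{prime_index}p",
        z_lo=z0 - half_width,
        z_hi=z0 + half_width,
        radius=radius,
    )


def water_count(frame: StructureFrame, axisframe: AxisFrame, region: PoreRegion) -> int:
    """Number of waters whose oxygen lies in the axial slab [z_lo, z_hi) and
    within the lateral radius of the axis."""
    oxy = frame.water_oxygen_indices()
    if oxy.size == 0:
        return 0
    pos = frame.coords[oxy]
    z = axisframe.axial_coordinate(pos)
    rho = axisframe.radial_distance(pos)
    inside = (z >= region.z_lo) & (z < region.z_hi) & (rho <= region.radius)
    return int(inside.sum())


def water_count_series(
    traj: Trajectory, axisframe: AxisFrame, region: PoreRegion
) -> DescriptorSeries:
    vals = np.array([water_count(f, axisframe, region) for f in traj])
    return DescriptorSeries(
        label=f"waters_{region.name}", units="count", values=vals, times=traj.times
    )


def ring_proximity_water_count(
    frame: StructureFrame,
    topology: ChannelTopology,
    prime_index: int,
    cutoff: float = RING_PROXIMITY_CUTOFF,
) -> int:
    """Waters with any atom within ``cutoff`` of any atom of the five residues
    forming a prime ring; each water counted once."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    resid = topology.resid_for_prime(prime_index)
    ring_mask = frame.mask(chain=list(topology.chain_ids), resseq=resid)
    if not np.any(ring_mask):
        raise TopologyError(f"ring {prime_index}' unresolvable")
    wat_idx = np.flatnonzero(frame.is_water)
    if wat_idx.size == 0:
        return 0
    tree = cKDTree(frame.coords[ring_mask])
    d, _ = tree.query(frame.coords[wat_idx], k=1, distance_upper_bound=cutoff)
    near = d < cutoff
    keys = set(zip(frame.chain[wat_idx[near]], frame.resseq[wat_idx[near]]))
    return len(keys)


# ---- hydrogen bonds ----------------------------------------------------------


class HBondTyping:
    """Donor/acceptor typing loaded from the shipped (or a user) YAML table."""

    def __init__(self, table: dict):
        self.default = table.get("protein_default", {"donors": [], "acceptors": []})
        self.water = table.get("water", {"donors": [], "acceptors": []})
        self.residues = table.get("residues", {})

    @classmethod
    def load(cls, path=None) -> "HBondTyping":
        if path is None:
            ref = importlib.resources.files("porescope.data").joinpath("hbond_types.yaml")
            return cls(yaml.safe_load(ref.read_text()))
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def for_residue(self, resname: str) -> dict:
        extra = self.residues.get(resname, {"donors": [], "acceptors": []})
        return {
            "donors": list(self.default.get("donors", [])) + list(extra.get("donors", [])),
            "acceptors": list(self.default.get("acceptors", []))
            + list(extra.get("acceptors", [])),
        }


def _residue_groups(frame: StructureFrame, selection: np.ndarray):
    """Group a selection's atom indices by (chain, resseq, resname)."""
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    groups: dict[tuple, list[int]] = {}
    for i in sel:
        key = (str(frame.chain[i]), int(frame.resseq[i]), str(frame.resname[i]))
        groups.setdefault(key, []).append(int(i))
    return groups


def detect_hbonds(
    frame: StructureFrame,
    mode: str,
    selection: np.ndarray,
    partner_selection: np.ndarray | None = None,
    cutoff: float | None = None,
    typing: HBondTyping | None = None,
) -> list[tuple]:
    """Hydrogen bonds formed in one frame.

    ``water_residue`` mode pairs every water against the protein residues in
    ``selection`` and returns ``((water chain, resseq), (res chain, resseq))``
    pairs; ``intra_protein`` mode returns ``(donor atom index, acceptor atom
    index)`` pairs within/between the atom selections (same-residue pairs
    excluded).
    """
    typing = typing or HBondTyping.load()
    if mode == "water_residue":
        cutoff = WATER_RESIDUE_CUTOFF if cutoff is None else cutoff
        return _water_residue_hbonds(frame, selection, cutoff, typing)
    if mode == "intra_protein":
        cutoff = INTRA_PROTEIN_CUTOFF if cutoff is None else cutoff
        return _intra_protein_hbonds(frame, selection, partner_selection, cutoff, typing)
    raise ValueError(f"unknown mode {mode!r}")


def _water_residue_hbonds(frame, selection, cutoff, typing):
    res_groups = _residue_groups(frame, selection)
    wat_groups = _residue_groups(frame, frame.is_water)
    # water hydrogens / oxygens
    pairs = []
    for rkey, ratoms in res_groups.items():
        spec = typing.for_residue(rkey[2])
        names = {str(frame.name[i]): i for i in ratoms}
        acceptors = [names[a] for a in spec["acceptors"] if a in names]
        donor_hs = [names[h] for d, h in spec["donors"] if h in names and d in names]
        if not acceptors and not donor_hs:
            raise TypingError(f"no donors/acceptors typed for residue {rkey}")
        acc_pos = frame.coords[acceptors] if acceptors else None
        dh_pos = frame.coords[donor_hs] if donor_hs else None
        for wkey, watoms in wat_groups.items():
            wnames = {str(frame.name[i]): i for i in watoms}
            w_hs = [wnames[h] for _, h in typing.water["donors"] if h in wnames]
            w_acc = [wnames[a] for a in typing.water["acceptors"] if a in wnames]
            dmin = np.inf
            if acc_pos is not None and w_hs:
                d = np.linalg.norm(
                    frame.coords[w_hs][:, None, :] - acc_pos[None, :, :], axis=2
                )
                dmin = min(dmin, float(d.min()))
            if dh_pos is not None and w_acc:
                d = np.linalg.norm(
                    dh_pos[:, None, :] - frame.coords[w_acc][None, :, :], axis=2
                )
                dmin = min(dmin, float(d.min()))
            if dmin < cutoff:
                pairs.append(((wkey[0], wkey[1]), (rkey[0], rkey[1])))
    return pairs


def _intra_protein_hbonds(frame, selection, partner_selection, cutoff, typing):
    def typed(sel):
        donors, acceptors = [], []
        for rkey, ratoms in _residue_groups(frame, sel).items():
            spec = typing.for_residue(rkey[2])
            names = {str(frame.name[i]): i for i in ratoms}
            donors += [names[d] for d, _ in spec["donors"] if d in names]
            acceptors += [names[a] for a in spec["acceptors"] if a in names]
        return donors, acceptors

    d1, a1 = typed(selection)
    if partner_selection is None:
        d2, a2 = d1, a1
    else:
        d2, a2 = typed(partner_selection)
    if not (d1 or a1) or not (d2 or a2):
        raise TypingError("selection lacks typed donors/acceptors")
    pairs = set()
    for donors, acceptors in ((d1, a2), (d2, a1)):
        if not donors or not acceptors:
            continue
        dd = np.linalg.norm(
            frame.coords[donors][:, None, :] - frame.coords[acceptors][None, :, :],
            axis=2,
        )
        for i, j in zip(*np.nonzero(dd < cutoff)):
            di, aj = donors[i], acceptors[j]
            same_res = (
                frame.chain[di] == frame.chain[aj]
                and frame.resseq[di] == frame.resseq[aj]
            )
            if not same_res:
                pairs.add((di, aj))
    return sorted(pairs)


@dataclass
class HBondRecord:
    """One candidate bond with its per-frame formation record."""

    donor: object
    acceptor: object
    formed: np.ndarray
    persistence: float  # % of analyzed frames

    def __post_init__(self) -> None:
        assert 0.0 <= self.persistence <= 100.0


def hbond_persistence(
    traj: Trajectory,
    mode: str,
    selection: np.ndarray,
    partner_selection: np.ndarray | None = None,
    cutoff: float | None = None,
    typing: HBondTyping | None = None,
    min_persistence: float = 0.0,
) -> list[HBondRecord]:
    """Persistence (% of frames formed) of every bond observed at least once.

    The field convention for a "persistently formed" bond is >60%; pass
    ``min_persistence`` to filter."""
    typing = typing or HBondTyping.load()
    per_frame = [
        detect_hbonds(f, mode, selection, partner_selection, cutoff, typing)
        for f in traj
    ]
    candidates: dict[tuple, np.ndarray] = {}
    for i, pairs in enumerate(per_frame):
        for p in pairs:
            if p not in candidates:
                candidates[p] = np.zeros(traj.n_frames, dtype=bool)
            candidates[p][i] = True
    records = []
    for (donor, acceptor), formed in sorted(candidates.items(), key=str):
        pct = 100.0 * formed.mean()
        if pct >= min_persistence:
            records.append(
                HBondRecord(donor=donor, acceptor=acceptor, formed=formed, persistence=pct)
            )
    return records


# ---- wetting / dewetting events ---------------------------------------------


def detect_wetting_events(
    series: DescriptorSeries,
    low: float = 10.0,
    high: float = 30.0,
    min_duration: int = 5,
) -> list[tuple[str, tuple[int, int]]]:
    """Hysteresis threshold-crossing events on a water-count series.

    A dewetting event is a run of ≥ ``min_duration`` frames below ``low``
    entered from the wet state (count previously above ``high``); rewetting is
    symmetric.  Returns ``(event type, (start frame, end frame))`` with a
    closed frame span covering the sustained run.
    """
    if not high > low >= 0:
        raise ValueError("need high > low >= 0")
    x = np.ravel(np.asarray(series.values, dtype=float))
    events = []
    # initial state from the first decisive sample
    state = None
    for v in x:
        if v > high:
            state = "wet"
            break
        if v < low:
            state = "dry"
            break
    if state is None:
        return events
    i = 0
    n = x.size
    while i < n:
        if state == "wet" and x[i] < low:
            j = i
            while j < n and x[j] < low:
                j += 1
            if j - i >= min_duration:
                events.append(("dewetting", (i, j - 1)))
                state = "dry"
                i = j
                continue
            i = j
        elif state == "dry" and x[i] > high:
            j = i
            while j < n and x[j] > high:
                j += 1
            if j - i >= min_duration:
                events.append(("rewetting", (i, j - 1)))
                state = "wet"
                i = j
                continue
            i = j
        else:
            i += 1
    return events
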