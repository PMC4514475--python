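"""Readers and writers: PDB structures, DCD / multi-model PDB trajectories,
descriptor CSV.  File parsing is delegated to MDAnalysis; this module only
converts to and from the package's in-memory containers."""

from __future__ import annotations

import pathlib
import warnings

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader

from .errors import FormatError, TopologyError
from .model import DescriptorSeries, StructureFrame, Trajectory
from .topology import ChannelTopology


def _guess_element(name: str) -> str:
    name = name.strip()
    if name[:2].upper() in ("CL", "NA") and len(name) <= 2:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_structure(path, topology: ChannelTopology | None = None) -> StructureFrame:
    """Read a PDB file into a :class:`StructureFrame`.

    When a topology is given, every chain it names must be present and the
    prime-map residues must resolve on each chain.
    """
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    atoms = u.atoms
    try:
        elements = np.array([e if e else _guess_element(n)
                             for e, n in zip(atoms.elements, atoms.names)])
    except (AttributeError, mda.exceptions.NoDataError):
        elements = np.array([_guess_element(n) for n in atoms.names])
    try:
        chains = np.array(atoms.chainIDs)
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.array([s.strip() for s in atoms.segids])
    serials = np.asarray(atoms.ids, dtype=int)
    if len(np.unique(serials)) != len(serials):
        raise FormatError(f"duplicate atom serial numbers in {path}")
    frame = StructureFrame(
        serial=serials,
        name=np.array(atoms.names),
        resname=np.array(atoms.resnames),
        resseq=np.asarray(atoms.resids, dtype=int),
        chain=chains,
        element=elements,
        coords=np.asarray(atoms.positions, dtype=float),
    )
    if topology is not None:
        validate_against_topology(frame, topology)
    return frame


def validate_against_topology(frame: StructureFrame, topology: ChannelTopology) -> None:
    present = set(frame.chain)
    missing = [c for c in topology.chain_ids if c not in present]
    if missing:
        raise TopologyError(f"chains missing from structure: {missing}")
    for chain in topology.chain_ids:
        chain_resids = set(frame.resseq[frame.chain == chain])
        absent = [p for p, r in topology.prime_map.items() if r not in chain_resids]
        if absent:
            raise TopologyError(
                f"chain {chain}: prime positions unresolvable: {sorted(absent)}"
            )


def read_trajectory(
    structure: StructureFrame,
    path,
    stride: int = 1,
    frame_interval: float | None = None,
    origin: str | None = None,
) -> Trajectory:
    """Read a DCD or multi-model PDB trajectory against a structure's atom table.

    ``frame_interval`` (ns) overrides any time information in the file; frames
    keep the time stamp of their original (unstrided) index.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    path = str(path)
    suffix = pathlib.Path(path).suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".dcd":
            reader = DCDReader(path)
        elif suffix in (".pdb", ".ent"):
            reader = PDBReader(path)
        else:
            raise FormatError(f"unsupported trajectory format: {suffix}")
        if reader.n_atoms != structure.n_atoms:
            reader.close()
            raise FormatError(
                f"trajectory has {reader.n_atoms} atoms, structure has "
                f"{structure.n_atoms}"
            )
        coords, times = [], []
        for i, ts in enumerate(reader):
            if i % stride:
                continue
            coords.append(ts.positions.astype(float).copy())
            if frame_interval is not None:
                times.append(i * frame_interval)
            else:
                times.append(float(ts.time) if ts.time is not None else float(i))
        reader.close()
    times = np.asarray(times, dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float) * stride
    return Trajectory(
        template=structure,
        coords=np.array(coords),
        times=times,
        origin=origin or pathlib.Path(path).stem,
    )


# ---- writing -----------------------------------------------------------------


def _to_universe(frame: StructureFrame) -> "mda.Universe":
    # residues = consecutive runs of (chain, resseq)
    keys = list(zip(frame.chain, frame.resseq))
    resindex = np.zeros(frame.n_atoms, dtype=int)
    res_first = [0]
    for i in range(1, frame.n_atoms):
        if keys[i] != keys[i - 1]:
            res_first.append(i)
        resindex[i] = len(res_first) - 1
    n_res = len(res_first)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            frame.n_atoms,
            n_residues=n_res,
            atom_resindex=resindex,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", frame.name.astype(str))
        u.add_TopologyAttr("elements", frame.element.astype(str))
        u.add_TopologyAttr("chainIDs", frame.chain.astype(str))
        u.add_TopologyAttr("resnames", [str(frame.resname[i]) for i in res_first])
        u.add_TopologyAttr("resids", [int(frame.resseq[i]) for i in res_first])
        u.add_TopologyAttr("ids", frame.serial.astype(int))
        u.add_TopologyAttr("occupancies", np.ones(frame.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(frame.n_atoms))
        u.atoms.positions = frame.coords
    return u


def write_structure(frame: StructureFrame, path) -> None:
    """Write a single-model PDB file."""
    u = _to_universe(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as DCD or multi-model PDB (by extension)."""
    path = str(path)
    u = _to_universe(traj.template)
    suffix = pathlib.Path(path).suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=traj.template.n_atoms,
                        multiframe=(suffix == ".pdb")) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i]
                u.trajectory.ts.time = traj.times[i]
                w.write(u.atoms)


# ---- descriptor series CSV ----------------------------------------------------


def _fmt(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))


def write_series(series: DescriptorSeries, path) -> None:
    """Write a descriptor series as CSV (full-precision floats, header with
    label and units).  Round-trips bit-exactly through :func:`read_series`."""
    if series.n_frames == 0:
        raise ValueError("refusing to write an empty series")
    values = series.values if series.values.ndim == 2 else series.values[:, None]
    cols = series.columns or (
        ["value"] if values.shape[1] == 1
        else [f"v{i + 1}" for i in range(values.shape[1])]
    )
    with open(path, "w") as fh:
        fh.write(f"# label: {series.label}\n")
        fh.write(f"# units: {series.units}\n")
        fh.write("time," + ",".join(cols) + "\n")
        for t, row in zip(series.times, values):
            fh.write(",".join([_fmt(t)] + [_fmt(v) for v in row]) + "\n")


def read_series(path) -> DescriptorSeries:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    values = df.iloc[:, 1:].to_numpy()
    if values.shape[1] == 1:
        values = values[:, 0]
    return DescriptorSeries(
        label=meta.get("label", ""),
        units=meta.get("units", ""),
        values=values,
        times=df["time"].to_numpy(dtype=float),
        columns=None if values.ndim == 1 else list(df.columns[1:]),
    )
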