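"""In-memory containers: single structures, trajectories and descriptor time series.

All coordinates are in Å and all times in ns.  A :class:`StructureFrame` is a
flat atom table (numpy columns), a :class:`Trajectory` shares one atom table
across frames and stores a ``(n_frames, n_atoms, 3)`` coordinate block, and a
:class:`DescriptorSeries` is a labelled per-frame scalar or fixed-width vector
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import FormatError, SelectionError

#: Residue names recognised as water / ions (naming dialects differ between
#: force fields; CHARMM uses TIP3/SOD/CLA, amber and PDB conventions differ).
WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})
CATION_RESNAMES = frozenset({"SOD", "NA"})
ANION_RESNAMES = frozenset({"CLA", "CL"})
ION_RESNAMES = CATION_RESNAMES | ANION_RESNAMES

#: Standard atomic masses (amu) keyed by element symbol.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "F": 18.998,
}


def element_mass(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 12.011)


@dataclass
class StructureFrame:
    """Atom table for one time point.

    Columns are parallel numpy arrays; ``coords`` has shape ``(n_atoms, 3)``.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resseq: np.ndarray
    chain: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    time: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError("coords must have shape (n_atoms, 3)")
        n = self.coords.shape[0]
        for col in ("serial", "name", "resname", "resseq", "chain", "element"):
            arr = np.asarray(getattr(self, col))
            if arr.shape[0] != n:
                raise FormatError(f"column {col!r} length {arr.shape[0]} != {n} atoms")
            setattr(self, col, arr)
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        if len(np.unique(self.serial)) != n:
            raise FormatError("duplicate atom serial numbers")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.element])

    # ---- masks ------------------------------------------------------------

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.resname, sorted(WATER_RESNAMES))

    @property
    def is_ion(self) -> np.ndarray:
        return np.isin(self.resname, sorted(ION_RESNAMES))

    @property
    def is_cation(self) -> np.ndarray:
        return np.isin(self.resname, sorted(CATION_RESNAMES))

    @property
    def is_anion(self) -> np.ndarray:
        return np.isin(self.resname, sorted(ANION_RESNAMES))

    def protein_mask(self, ligand_resname: str | None = None) -> np.ndarray:
        mask = ~(self.is_water | self.is_ion)
        if ligand_resname is not None:
            mask &= self.resname != ligand_resname
        return mask

    def mask(
        self,
        chain: str | Sequence[str] | None = None,
        resseq: int | tuple[int, int] | Sequence[int] | None = None,
        name: str | Sequence[str] | None = None,
        resname: str | Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms; ``resseq`` may be an int, a closed
        ``(lo, hi)`` interval, or an explicit list."""
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= np.isin(self.chain, [chain] if isinstance(chain, str) else list(chain))
        if resseq is not None:
            if isinstance(resseq, tuple) and len(resseq) == 2:
                m &= (self.resseq >= resseq[0]) & (self.resseq <= resseq[1])
            elif np.isscalar(resseq):
                m &= self.resseq == resseq
            else:
                m &= np.isin(self.resseq, list(resseq))
        if name is not None:
            m &= np.isin(self.name, [name] if isinstance(name, str) else list(name))
        if resname is not None:
            m &= np.isin(
                self.resname, [resname] if isinstance(resname, str) else list(resname)
            )
        return m

    def indices(self, **kwargs) -> np.ndarray:
        """Atom indices matching :meth:`mask` criteria; errors when empty."""
        idx = np.flatnonzero(self.mask(**kwargs))
        if idx.size == 0:
            raise SelectionError(f"empty selection: {kwargs}")
        return idx

    def water_oxygen_indices(self) -> np.ndarray:
        """One oxygen index per water molecule (validates the one-oxygen rule)."""
        wat = self.is_water
        oxy = wat & (np.char.upper(self.element.astype(str)) == "O")
        n_res = len(set(zip(self.chain[wat], self.resseq[wat])))
        if int(oxy.sum()) != n_res:
            raise FormatError("each water residue must contain exactly one oxygen")
        return np.flatnonzero(oxy)

    def with_coords(self, coords: np.ndarray, time: float | None = None) -> "StructureFrame":
        return replace(self, coords=np.asarray(coords, dtype=float), time=time)


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``times`` are ns and must
    be strictly increasing.
    """

    template: StructureFrame
    coords: np.ndarray
    times: np.ndarray
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("trajectory coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.template.n_atoms:
            raise FormatError(
                f"atom count mismatch: frames have {self.coords.shape[1]} atoms, "
                f"template has {self.template.n_atoms}"
            )
        if self.times.shape[0] != self.coords.shape[0]:
            raise FormatError("times length != frame count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> StructureFrame:
        return self.template.with_coords(self.coords[i], time=float(self.times[i]))

    def __iter__(self) -> Iterator[StructureFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be a positive integer")
        return Trajectory(
            self.template, self.coords[::stride], self.times[::stride], self.origin
        )


@dataclass
class DescriptorSeries:
    """Per-frame scalar or fixed-width vector time series with label and units."""

    label: str
    units: str
    values: np.ndarray
    times: np.ndarray
    columns: list[str] | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values and times must have equal length")
        if self.values.ndim == 2 and self.columns is not None:
            if len(self.columns) != self.values.shape[1]:
                raise ValueError("columns must match value width")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    def merged(self) -> np.ndarray:
        """All values pooled into one flat array (subunit/pair merging)."""
        return np.ravel(self.values)
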