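"""Channel topology: chains, prime-index residue bookkeeping, loop spans.

Pore-lining positions on the M2 helix are indexed with the prime notation
(−2′ … 20′), counted from a conserved intracellular reference so positions are
comparable across the pentameric ligand-gated ion channel family.  The default
configuration shipped with the package maps the α7 nicotinic receptor M2 helix
with the 13′ constriction at Val246.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import TopologyError


@dataclass
class ChannelTopology:
    """Residue bookkeeping for one pentamer.

    ``prime_map`` maps prime index → author residue number; the same numbering
    is used on all five chains (homopentamer).  Loop spans are closed residue
    intervals in author numbering.
    """

    chain_ids: tuple[str, ...]
    prime_map: dict[int, int]
    m2_range: tuple[int, int]
    loops: dict[str, tuple[int, int]] = field(default_factory=dict)
    ligand_resname: str = "EPI"
    key_residues: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chain_ids = tuple(self.chain_ids)
        if len(self.chain_ids) != 5:
            raise TopologyError(f"expected exactly 5 chains, got {len(self.chain_ids)}")
        if len(set(self.chain_ids)) != 5:
            raise TopologyError("chain identifiers must be unique")
        self.prime_map = {int(k): int(v) for k, v in self.prime_map.items()}
        primes = sorted(self.prime_map)
        resids = [self.prime_map[p] for p in primes]
        if any(b <= a for a, b in zip(resids, resids[1:])):
            raise TopologyError("prime_map must be strictly increasing in residue number")
        self.m2_range = (int(self.m2_range[0]), int(self.m2_range[1]))
        clean_loops = {}
        for name, span in self.loops.items():
            lo, hi = int(span[0]), int(span[1])
            if hi < lo:
                raise TopologyError(f"loop {name!r} span is empty")
            clean_loops[name] = (lo, hi)
        self.loops = clean_loops
        self.key_residues = {k: int(v) for k, v in self.key_residues.items()}

    # ---- prime bookkeeping -------------------------------------------------

    @property
    def prime_indices(self) -> list[int]:
        return sorted(self.prime_map)

    def resid_for_prime(self, prime_index: int) -> int:
        try:
            return self.prime_map[int(prime_index)]
        except KeyError:
            raise TopologyError(f"prime index {prime_index}' not in topology") from None

    def loop_span(self, name: str) -> tuple[int, int]:
        try:
            return self.loops[name]
        except KeyError:
            raise TopologyError(f"loop {name!r} not defined in topology") from None

    def key_residue(self, name: str) -> int:
        try:
            return self.key_residues[name]
        except KeyError:
            raise TopologyError(f"key residue {name!r} not defined") from None

    # ---- pentamer adjacency ------------------------------------------------

    def non_adjacent_pairs(self) -> list[tuple[str, str]]:
        """The five crossed (non-adjacent) chain pairs, in stable order
        P1–P3, P2–P4, P3–P5, P4–P1, P5–P2."""
        c = self.chain_ids
        return [(c[i], c[(i + 2) % 5]) for i in range(5)]

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        c = self.chain_ids
        return [(c[i], c[(i + 1) % 5]) for i in range(5)]

    # ---- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "chain_ids": list(self.chain_ids),
            "prime_map": dict(self.prime_map),
            "m2_range": list(self.m2_range),
            "loops": {k: list(v) for k, v in self.loops.items()},
            "ligand_resname": self.ligand_resname,
            "key_residues": dict(self.key_residues),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelTopology":
        return cls(
            chain_ids=tuple(d["chain_ids"]),
            prime_map={int(k): int(v) for k, v in d["prime_map"].items()},
            m2_range=tuple(d["m2_range"]),
            loops={k: tuple(v) for k, v in d.get("loops", {}).items()},
            ligand_resname=d.get("ligand_resname", "EPI"),
            key_residues=d.get("key_residues", {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "ChannelTopology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_topology() -> ChannelTopology:
    """The α7 nicotinic-receptor ring map shipped with the package (author
    numbering anchored at Val246 = 13′)."""
    ref = importlib.resources.files("porescope.data").joinpath("alpha7.yaml")
    return ChannelTopology.from_dict(yaml.safe_load(ref.read_text()))
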