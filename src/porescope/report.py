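"""Run configuration and the end-to-end descriptor report.

``run_report`` executes the full descriptor battery — crossed distances,
pore-radius profile, water counts, ring-proximity counts, tense-contact
hydrogen-bond persistence, twist/tilt angles, dCintra, interface distances and
restraint activity — over one or more trajectories (synthetic presets or
files) and writes per-descriptor CSVs plus a pooled mean ± s.d. summary
table.  The report is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import hydration, interface, pore, restraint, synthetic
from .geometry import symmetry_axis
from .io import read_structure, read_trajectory, write_series
from .model import DescriptorSeries, Trajectory
from .topology import ChannelTopology, default_topology

log = logging.getLogger("porescope")

_PRESETS = {
    "open": synthetic.open_blueprint,
    "collapsed": synthetic.collapsed_blueprint,
    "free": synthetic.free_blueprint,
}


@dataclass
class RunConfig:
    """Report configuration; defaults are the analysis constants used
    throughout (3 Å ring proximity, 2.0/3.0 Å H-bond cutoffs,
    k = 10 kcal/mol/Å²)."""

    output_dir: str = "report_out"
    presets: list[str] = field(default_factory=lambda: ["open", "collapsed"])
    inputs: list[dict] = field(default_factory=list)
    topology_path: str | None = None
    n_frames: int = 30
    noise_sigma: float = 0.15
    seed: int = 0
    crossed_primes: tuple[int, ...] = (13, 16)
    hydrophilic_primes: tuple[int, ...] = (2, 6, 10, 12)
    ring_proximity_cutoff: float = 3.0
    water_residue_cutoff: float = 2.0
    intra_protein_cutoff: float = 3.0
    force_constant: float = 10.0
    gate_half_width: float = 5.0
    lateral_radius: float = 8.0
    profile_spacing: float = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for cut in (
            self.ring_proximity_cutoff,
            self.water_residue_cutoff,
            self.intra_protein_cutoff,
            self.gate_half_width,
            self.lateral_radius,
            self.profile_spacing,
        ):
            if cut <= 0:
                raise ValueError("all cutoffs and spacings must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "crossed_primes" in d:
            d["crossed_primes"] = tuple(d["crossed_primes"])
        if "hydrophilic_primes" in d:
            d["hydrophilic_primes"] = tuple(d["hydrophilic_primes"])
        return cls(**d)

    def topology(self) -> ChannelTopology:
        if self.topology_path:
            return ChannelTopology.from_yaml(self.topology_path)
        return default_topology()


@dataclass
class ReportBundle:
    summary: pd.DataFrame
    output_dir: pathlib.Path
    tables: dict[str, dict] = field(default_factory=dict)


def _gather_trajectories(config: RunConfig, topo) -> dict[str, Trajectory]:
    trajs: dict[str, Trajectory] = {}
    for i, preset in enumerate(config.presets):
        try:
            bp = _PRESETS[preset]()
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}") from None
        bp.seed = config.seed + i
        traj, _ = synthetic.build_trajectory(
            bp, bp, config.n_frames, noise_sigma=config.noise_sigma,
            seed=config.seed + i, topology=topo,
        )
        trajs[preset] = traj
    for spec in config.inputs:
        structure = read_structure(spec["structure"], topo)
        trajs[spec.get("name", pathlib.Path(spec["trajectory"]).stem)] = (
            read_trajectory(
                structure, spec["trajectory"],
                stride=int(spec.get("stride", 1)),
                frame_interval=spec.get("frame_interval"),
            )
        )
    return trajs


def analyze_trajectory(
    name: str, traj: Trajectory, topo: ChannelTopology, config: RunConfig, outdir
) -> dict:
    """Run the descriptor battery on one trajectory; returns summary scalars."""
    outdir = pathlib.Path(outdir)
    first = traj.frame(0)
    axis = symmetry_axis(first, topo)
    results: dict[str, float] = {}

    def save(series: DescriptorSeries, stem: str):
        write_series(series, outdir / f"{name}_{stem}.csv")

    # crossed distances + their merged distributions
    for p in config.crossed_primes:
        series = pore.crossed_distance_series(traj, topo, p, "residue_com")
        save(series, f"crossed_{p}p")
        results[f"crossed_{p}p_mean"] = float(series.values.mean())
        results[f"crossed_{p}p_sd"] = float(series.values.std())
        hist = pore.distance_distribution(series, bin_width=0.5)
        pd.DataFrame(
            {"bin_left": hist.edges[:-1], "bin_right": hist.edges[1:],
             "density": hist.density}
        ).to_csv(outdir / f"{name}_crossed_{p}p_hist.csv", index=False)

    # pore radius profile on the final frame
    primes = topo.prime_indices
    ring_lo = pore.resolve_ring(first, topo, primes[0], "calpha").mean(axis=0)
    ring_hi = pore.resolve_ring(first, topo, primes[-1], "calpha").mean(axis=0)
    z_lo = float(axis.axial_coordinate(ring_lo)[0])
    z_hi = float(axis.axial_coordinate(ring_hi)[0])
    last = traj.frame(traj.n_frames - 1)
    profile = pore.pore_radius_profile(
        last, symmetry_axis(last, topo), (z_lo, z_hi),
        spacing=config.profile_spacing, ligand_resname=topo.ligand_resname,
    )
    pd.DataFrame({"z": profile.z, "radius": profile.radius,
                  "empty_slab": profile.empty_slab.astype(int)}).to_csv(
        outdir / f"{name}_pore_profile.csv", index=False)
    ring13_z = float(
        axis.axial_coordinate(pore.resolve_ring(last, topo, 13, "calpha").mean(axis=0))[0]
    )
    gate = (ring13_z - config.gate_half_width, ring13_z + config.gate_half_width)
    in_gate = (profile.z >= gate[0]) & (profile.z <= gate[1])
    results["gate_min_pore_radius"] = float(profile.radius[in_gate].min())
    results["min_pore_radius"] = float(profile.minimum()[1])

    # hydration
    full_region = hydration.PoreRegion("pore", z_lo, z_hi, config.lateral_radius)
    gate_region = hydration.PoreRegion("gate", gate[0], gate[1], config.lateral_radius)
    for region in (full_region, gate_region):
        series = hydration.water_count_series(traj, axis, region)
        save(series, f"waters_{region.name}")
        results[f"waters_{region.name}_mean"] = float(series.values.mean())
    for p in config.hydrophilic_primes:
        counts = np.array(
            [hydration.ring_proximity_water_count(
                f, topo, p, config.ring_proximity_cutoff) for f in traj]
        )
        series = DescriptorSeries(
            label=f"ring_waters_{p}p", units="count", values=counts, times=traj.times
        )
        save(series, f"ring_waters_{p}p")
        results[f"ring_waters_{p}p_mean"] = float(counts.mean())

    # tense-contact hydrogen-bond persistence (M2-M3 interface region)
    m2m3 = topo.loop_span("M2-M3")
    sel = traj.template.mask(chain=list(topo.chain_ids), resseq=m2m3)
    records = hydration.hbond_persistence(
        traj, "intra_protein", sel, cutoff=config.intra_protein_cutoff
    )
    results["tense_hbond_persistence"] = float(
        max((r.persistence for r in records), default=0.0)
    )
    results["n_persistent_hbonds"] = float(
        sum(1 for r in records if r.persistence > 60.0)
    )

    # twist / tilt
    twists, polars = [], []
    for f in traj:
        ax_f = symmetry_axis(f, topo)
        per, _ = pore.twist_angle(
            f, ax_f, topo, synthetic.TWIST_LBD_SPAN, synthetic.TWIST_TMD_SPAN
        )
        twists.append(per)
        polars.append(pore.tilt_angles(f, ax_f, topo).polar)
    twists, polars = np.array(twists), np.array(polars)
    save(DescriptorSeries("twist", "deg", twists, traj.times,
                          [f"P{i+1}" for i in range(5)]), "twist")
    save(DescriptorSeries("polar_tilt", "deg", polars, traj.times,
                          [f"P{i+1}" for i in range(5)]), "polar_tilt")
    results["twist_mean"] = float(twists.mean())
    results["polar_tilt_mean"] = float(polars.mean())

    # LBD descriptors
    dc = interface.dcintra_series(traj, topo)
    save(dc, "dcintra")
    results["dcintra_mean"] = float(dc.values.mean())
    iface = interface.interface_distances(first, topo)
    for key, vals in iface.items():
        results[f"{key}_mean"] = float(np.mean(vals))

    # restraint activity, thresholds calibrated on the first frame
    spec = restraint.calibrate_thresholds(
        first, restraint.default_spec(topo, k=config.force_constant), topo
    )
    activity = restraint.restraint_activity_series(traj, spec, topo)
    activity.to_dataframe().to_csv(outdir / f"{name}_restraint.csv", index=False)
    results["restraint_energy_mean"] = float(activity.total_energy().mean())
    return results


def run_report(config: RunConfig) -> ReportBundle:
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    topo = config.topology()
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    trajs = _gather_trajectories(config, topo)
    tables = {}
    for name, traj in trajs.items():
        log.info("analyzing trajectory %s (%d frames)", name, traj.n_frames)
        tables[name] = analyze_trajectory(name, traj, topo, config, outdir)
    summary = pd.DataFrame(tables)
    summary.index.name = "descriptor"
    summary.to_csv(outdir / "summary.csv", float_format="%.10g")
    log.info("report written to %s", outdir)
    return ReportBundle(summary=summary, output_dir=outdir, tables=tables)
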