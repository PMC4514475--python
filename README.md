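# porescope

Gating descriptors and pore-opening restraint analysis for pentameric
ligand-gated ion channels (pLGICs / Cys-loop receptors).

## The problem

Whether a pLGIC conformation is conductive cannot be read off a single
number.  In simulations the pore-lining M2 helices of receptors such as the
α7 nicotinic receptor readily collapse into a dewetted, non-conductive state,
and telling a putative open structure from a collapsed one requires a battery
of geometric and hydration descriptors evaluated along trajectories:

* **crossed distances** — distances between equivalent pore-lining residues
  (center of mass or Cα) on *non-adjacent* subunits of the pentamer, a direct
  proxy for gate aperture at each ring (prime positions −2′…20′, with the
  hydrophobic gate at Leu9′/Val13′/Leu16′);
* **pore radius profile** r(z) along the channel axis, computed here with an
  axis-sampling minimal-clearance algorithm
  (r(z) = min over atoms in the slab of ‖d⊥‖ − r_vdW);
* **water counts** in the full M2 lumen and in the constriction region, plus
  counts within 3 Å of the hydrophilic Ser/Thr rings, and hysteresis-based
  dewetting/rewetting event detection;
* **M2 tilt** decomposed into polar and azimuthal components in a per-helix
  frame (x radial, y tangential, z = channel axis) and the **quaternary
  twist** between the ligand-binding and transmembrane domains;
* **interface and ligand monitors** — Pro256↔Cys-loop / Lys40 distances,
  C-loop closure (dCintra), ligand contact distances and axial/equatorial
  orientation, ion axial distributions;
* **hydrogen-bond persistence** — % of frames a bond is formed, with purely
  distance-based criteria (2.0 Å H···acceptor for water–residue bonds, 3.0 Å
  donor–acceptor for intra-protein bonds).

The package also implements the **flat-bottom quadratic restraint** used to
hold such channels open: for each non-adjacent pair at the 16′ and 13′ rings,

    U_i = ½ k (d_i − d0_i)²  if d_i < d0_i,  else 0

with k = 10 kcal/mol/Å² and thresholds d0 calibrated on a reference (open)
structure, together with its analytic per-atom forces (COM chain rule).

Because deposited trajectories are rarely available, a **synthetic generator**
builds pentamers with fully known ground truth — ideal α-helical M2 bundles
with prescribed per-ring pore radii, tilts, twist, pore waters, vestibule
ions and a bound-ligand proxy — so every descriptor is testable at desk scale.

## Worked example

```python
from porescope import RunConfig, run_report

config = RunConfig(output_dir="demo", n_frames=25, noise_sigma=0.15, seed=1)
bundle = run_report(config)
print(bundle.summary.round(2))
```

This generates an "open" and a "collapsed" synthetic trajectory (25 frames,
0.15 Å thermal noise) and runs the full descriptor battery, writing one CSV
per descriptor plus `summary.csv`:

```
                           open  collapsed
descriptor
gate_min_pore_radius       4.59       2.68
waters_pore_mean         115.00      60.00
waters_gate_mean          40.00       4.00
crossed_13p_mean          16.64      13.98
twist_mean                21.05      24.08
polar_tilt_mean            1.10      -2.00
dcintra_mean              15.49      14.61
tense_hbond_persistence    0.00      84.00
```

The open preset shows a wide hydrated gate (pore radius ≈ 5 Å before noise,
≈ 115 lumen waters), larger crossed distances, a smaller quaternary twist and
slightly positive polar tilt; the collapsed preset shows a ≈ 2 Å constriction
at 9′, a dewetted gate, a larger twist, and tense inter-subunit hydrogen
bonds formed >60 % of the time — the discrimination logic used to tell the
two states apart.

The same operations are exposed on the command line:

```bash
porescope synth pentamer --preset open --seed 4 --out open.pdb --truth truth.yaml
porescope pore crossed open.pdb --prime 13 -o crossed.csv
porescope restraint calibrate open.pdb -o restraint.yaml
porescope report --output-dir report_out --seed 1
```

## Layout

| module | contents |
|---|---|
| `porescope.model` / `porescope.io` | StructureFrame / Trajectory / DescriptorSeries containers; PDB/DCD/CSV readers and writers (MDAnalysis-backed) |
| `porescope.topology` | chains, prime-index ring map, loop spans (α7 default shipped as YAML) |
| `porescope.geometry` | centers of mass, channel axis frame, Kabsch superposition, RMSD/RMSF |
| `porescope.pore` | crossed distances, pore-radius profile, tilt, twist, distributions |
| `porescope.hydration` | water counts, ring-proximity counts, H-bonds, wetting events |
| `porescope.interface` | interface/ligand/ion descriptors |
| `porescope.restraint` | flat-bottom restraint energy, forces, calibration, activity log |
| `porescope.synthetic` | pentamer/trajectory/H-bond fixtures with ground truth |
| `porescope.report` / `porescope.cli` | end-to-end descriptor report and the `porescope` CLI |
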