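# Methods

This note documents the models, conventions and numerical choices behind
porescope, and what the synthetic fixtures do and do not establish about real
simulation data.

## Coordinate frames and conventions

All coordinates are in Å, times in ns, energies in kcal/mol, angles in
degrees.  Residue spans are closed intervals in author numbering; prime
indices are closed integer ranges −2′…20′ along the M2 helix, anchored in the
shipped α7 map at Val246 = 13′ (residue = 233 + prime index).  The M2 span is
taken as −2′…20′ inclusive — 23 residues — which is the only reading
consistent with both a 23-residue helix and a glycine ring at −2′.

The **channel axis frame** is built per structure: z is the unit vector from
the Cα-ring center of mass at −2′ to the one at 20′ (a ring chord is robust
when the extracellular domain is asymmetric; a PCA axis over all M2 Cα is
available as an option), oriented intracellular → extracellular; the origin
is the center of mass of all M2 Cα.  Each helix carries a local frame at its
M2 center of mass: x radial outward from the axis, y = z × x.

Angle sign conventions (chosen once, documented so literature comparisons
keep their signs):

* **polar tilt** = atan2(vx, vz) of the helix axis v in the local frame —
  positive when the helix top leans radially outward;
* **azimuthal tilt** = atan2(vy, vx) — positive toward tangential +y; when
  the xy-projection norm is < 1e-8 the azimuth is reported as 0 with a
  degeneracy flag (a helix parallel to z has no azimuth).  Note that the
  (polar, azimuthal) pair cannot represent a purely tangential tilt with
  nonzero magnitude: azimuth ±90° forces the xz-projection, hence the polar
  angle, to zero.  The generator rejects such prescriptions.
* **twist** = signed angle from the LBD center-of-mass projection to the TMD
  one in the plane ⊥ z, positive counter-clockwise viewed from the
  extracellular side; both signed and absolute values can be derived, the
  signed one is reported.

## Descriptor definitions

**Crossed distances.** One distance per non-adjacent chain pair, stable order
P1–P3, P2–P4, P3–P5, P4–P1, P5–P2.  The default selection is the
whole-residue mass-weighted center of mass (matching the restraint
definition); a Cα mode is provided, and on synthetic data both modes order
the open/collapsed presets identically.  Distributions are computed by
pooling the per-pair time series before binning, so individual-subunit
transitions are not blurred by averaging; histogram masses sum to 1.

**Pore radius.** Axis-sampling minimal clearance: at stations spaced every
0.5 Å (configurable), r(z) = min over protein atoms in the slab of half-width
spacing/2 of (distance to the axis line − Bondi vdW radius), floored at 0.
Stations with no atoms report a configured maximum radius and are flagged.
The probe center stays on the symmetry axis — a straight-pore simplification
of sphere-tracing profile algorithms, adequate for the M2 lumen; off-axis
corridor search is out of scope.  The profile abscissa is relative to the
axis-frame origin; ring positions are located by their Cα-ring COM.

**Helix axis.** The raw first principal component of 23 Cα positions is
biased when the helix covers a non-integer number of turns (23 × 100° = 6.4
turns): the Cα wheel is over-represented on one side.  The axis is therefore
refined by least-squares cylinder fitting — minimize the variance of the Cα
radial distances over axis direction and offset (Levenberg–Marquardt, PCA
initialization).  For an ideal helix this is exact regardless of phase;
noise-free tilt recovery on the construction grid is ≲ 1e-13 degrees, and at
σ = 0.3 Å positional noise the subunit-averaged angles are recovered within
2° (the single-helix azimuth at small polar tilt is information-limited: the
xy-projection it is measured from has norm sin(polar)).

**Hydration.** A water's position is its oxygen.  Pore regions are axial
slabs [z_lo, z_hi) — half-open at the top — with a lateral cylinder bound
(default 8 Å; the physical lumen is bounded by the helices, not by a number,
so the bound is configurable).  The constriction-point region defaults to a
10 Å slab centered on the 13′ ring COM; an anchor at the Leu9′–Leu16′ span is
available.  Ring-proximity counts use a 3 Å cutoff from any atom of the five
ring residues to any water atom, each water counted once (KD-tree).

**Hydrogen bonds.** Purely distance-based, no angular criterion.
Water–residue: formed when the minimum H···heavy-acceptor distance over all
donor/acceptor combinations is < 2.0 Å (a 2.0 Å heavy–heavy bond would be
sterically impossible, so the cutoff is read as hydrogen-to-heavy-atom).
Intra-protein: heavy donor–acceptor distance < 3.0 Å, same-residue pairs
excluded.  Donor/acceptor typing ships as an editable YAML table (backbone
N–H/O defaults plus side-chain entries).  Persistence is 100 × (frames
formed)/(frames analyzed); the field convention for "persistently formed" is
> 60 %.

**Wetting/dewetting events.** Hysteresis threshold crossing on a water-count
series: a dewetting event is a run of ≥ min_duration frames below `low`
entered from the wet state (previously above `high`); rewetting is symmetric.
Defaults low = 10, high = 30 waters, min_duration = 5 frames — the event
thresholds are this package's own operational choice; the qualitative
phenomenon they detect (sudden emptying/refilling of the hydrophobic gate) is
what matters.

**Ligand orientation.** The unit vector from the ligand centroid to a
reference atom (the chlorine for an epibatidine-like agonist) is classified
against the channel axis: within 45° of +z → axial_up, of −z → axial_down;
more than 67.5° from both poles with the radial-inward component dominating
the tangential one → equatorial; otherwise intermediate.  The cone
half-angles operationalize a qualitative distinction and are configurable;
classes partition every frame.

**Interface monitors.** Pro256 Cα ↔ Cys-loop (122–136) Cα COM and ↔ Lys40
Cα per subunit; dCintra = C-loop (179–188) Cα COM ↔ backwall (139–140) Cα
COM.  Ligand contact monitors are named atom-pair or ring-centroid–to–
ring-centroid distances resolved per binding site; summaries are mean ± s.d.
pooled over subunits and frames.  Ion axial distributions pool z-coordinates
over frames within a 10 Å lateral bound (the vestibule is wider than the
lumen); occupancy series count ions per frame in a region and report the
maximum simultaneous occupancy.

## The restraint

U_i = ½ k (d_i − d0_i)² for d_i < d0_i, else 0, summed over the five
non-adjacent pairs at each of the 16′ and 13′ rings; k defaults to
10 kcal/mol/Å².  The ½ convention is chosen so that k carries the stated
units with the restoring force at a 1 Å violation equal to k exactly; a
`k_full` switch selects U = k(d−d0)².  Thresholds are calibrated as the pair
distances in a reference (open) structure, so U ≡ 0 on the calibration frame.
COM groups are mass-weighted (the weighting of the original engine-side
implementation is not documented; mass weighting is assumed) and forces are
distributed onto group atoms by mass fraction — the standard COM-restraint
chain rule — so each pair obeys Newton's third law and the net force and
torque vanish identically.  Analytic forces agree with central finite
differences (step 1e-5 Å) to relative error < 1e-6 on randomized
configurations.  The activity log records per-frame per-pair distance,
energy and active flag, and exposes the frames where no pair is active (used
to seed unbiased trajectories from a restrained one).

## Synthetic fixtures: what they emulate

The generator builds five ideal α-helices (rise 1.5 Å/residue, 100°/residue,
Cα wheel radius 2.3 Å — fixed, to keep ground truth closed-form) on a circle,
with the local helix coordinates centered so each helix COM sits exactly on
the circle.  Each residue carries one side-chain proxy atom placed exactly at
a prescribed radial distance from the pore axis at its ring; these proxies
form the pore wall, so the pore radius at ring p is ring_radii[p] − 1.7 Å by
construction.  A rigid ideal helix cannot simultaneously satisfy arbitrary
per-ring Cα radii and prescribed tilts, which is why the ring radii live on
the proxies (this also reproduces the side-chain-swing mechanism by which
gate aperture changes without large backbone motion).  Ser/Thr rings
additionally carry a hydroxyl oxygen so water–residue hydrogen bonding is
exercisable.

A sparse LBD proxy cloud (β1-β2, Cys-loop, backwall, C-loop, binding-pocket
residues with aromatic-ring proxies, complementary-side leucines) supports
twist, dCintra, interface and ligand monitors; it is rotated by −twist
relative to the TMD.  Because the cloud is intentionally not azimuthally
uniform, the realized twist differs from the prescribed offset by a constant
geometric shift; the ground-truth record therefore stores the twist computed
by direct arithmetic on the noise-free construction (exact by C5 symmetry)
alongside the prescribed value.  dCintra is exact by construction (the C-loop
COM is placed at the prescribed distance from the backwall COM).

Waters are 3-site (0.957 Å, 104.5°), placed uniformly in a pore cylinder
with exact counts in the gate slab (13′ ± 5 Å) and the rest of the lumen,
with a 0.2 Å margin off every counting boundary so counts are
boundary-robust.  Ions follow simple z-placement laws (cations below the
gate, anions in the cytoplasmic vestibule).  A 15-atom ligand proxy per site
(two hexagonal rings, two amine nitrogens, one chlorine) has its non-chlorine
atoms symmetric about the pocket center, so the centroid→chlorine vector
realizes the prescribed orientation class exactly.

Trajectories linearly interpolate two noise-free constructions and add
i.i.d. Gaussian noise per protein/ligand atom per frame.  Waters are
re-placed each frame at the linearly interpolated occupancy; the water atom
allocation is fixed at the maximum occupancy and surplus waters are parked in
a bulk shell 30 Å off-axis — outside every counting region — so the
trajectory keeps a constant atom count while counted occupancy tracks the
schedule exactly.  When the occupancy is constant the frame-0 placement is
kept, so noise-free equal-endpoint trajectories have strictly constant
descriptors.  A scripted inter-subunit N···O pair at the M2-M3 loops is
placed at 2.8 Å in the collapsed preset (formed, "tense") and 4.5 Å in the
open one (broken), giving the hydrogen-bond persistence discriminator a known
answer.

**Presets.**  The `open` preset has gate (9′–16′) pore radius 5.0 Å, a 3 Å
constriction at the intracellular −2′ entrance, 115 lumen / 40 gate waters,
twist 21°, polar tilt +1.1°, dCintra 15.5 Å.  The `collapsed` preset has a
2.0 Å constriction at 9′ (3 Å at 13′/16′), 60 / 4 waters, twist 24°, polar
tilt −2°, dCintra 14.6 Å, tense contacts formed, and a slightly smaller
helix-circle radius.  The `free` preset is open-like at 95 / 30 waters.
These values are the qualitative geometry and hydration levels that
distinguish putative-open from collapsed α7 conformations in the literature
the package is built around.

**What passing tests do not show.**  The fixtures have no sterics, membrane,
electrostatics or dynamics; noise is i.i.d. Gaussian, not thermal; waters are
re-placed, not propagated.  Tests on them establish that the descriptors
measure what they claim on known geometry — not that any particular real
receptor model is open or collapsed.

## Numerical choices

* Superposition: Kabsch via SVD with the determinant correction; RMSF uses
  the standard two-pass align-to-average iteration.
* Principal-axis orientation ties are broken by positive dot product with the
  global z (or a supplied direction).
* Degenerate inputs raise typed errors (empty selections, < 3 fit atoms,
  coincident ring COMs, zero-length projections) rather than returning NaN;
  the two deliberate flagged cases are empty pore-profile slabs and the
  azimuth of an axis-parallel helix.
* Descriptor CSVs store full-precision floats (shortest round-trip repr) and
  re-parse bit-exactly (`float_precision="round_trip"`).
* Report problem sizes: the shipped report and acceptance script use 25-frame
  trajectories with σ = 0.15 Å noise and ~4000-atom fixtures — ample for the
  exact/analytic properties being checked, and the whole suite runs in well
  under a minute.

## Known limitations

* The pore profile is measured along the symmetry axis only; strongly bent or
  off-axis pores would need a corridor search, which is out of scope.
* M2 bending/kink analysis is deliberately absent (the helices are treated as
  rigid rods for tilt purposes).
* Hydrogen-bond criteria are distance-only by design; no angular term.
* The default α7 ring map ships only the residues and spans needed by the
  descriptors; full-sequence numbering differences between author and UniProt
  conventions are handled by supplying a topology YAML.
* Interaction-energy monitors (force-field energetics) are out of scope; the
  restraint is an energy/force provider and analysis tool, not an MD plug-in.
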