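# Models and methods

This note documents the science inside `abgas`: the models each stage
implements, the parameters that matter, what the synthetic fixtures do and do
not emulate, and the numerical choices made where the design was genuinely
open.

## Projection-approximation CCS

The model CCS convention throughout the package is `CCS = 1.14 × PA`. PA is
the orientation-averaged area of the union of disks obtained by projecting
every atom (radius = element collision radius + probe radius) onto a plane
perpendicular to the viewing direction. The 1.14 factor is the standard
empirical scaling that maps the bare projection approximation onto measured
CCS values of protein-sized ions in nitrogen; it is applied exactly and never
refitted. The projection approximation ignores multiple scattering and
long-range ion–neutral interactions, which is adequate for relative,
stage-to-stage comparisons of large ions; absolute CCS values carry a
few-percent parameterisation uncertainty through the radii set.

* **Radii**: H 1.2, C 1.7, N 1.55, O 1.52, S 1.8 Å (standard van der Waals
  values); probe radius 1.0 Å. Fully user-configurable; coarse-grained
  fixtures register their bead pseudo-element ("X") with the bead radius.
* **Orientations**: uniform random rotations from normalised 4-dimensional
  Gaussian quaternions, seeded. Default 300 orientations give a Monte-Carlo
  standard error well below 1 % on antibody-sized structures.
* **Per-orientation area**: the default Monte-Carlo estimator samples points
  uniformly in the disk-union bounding box (default 40 000) with a cell-list
  membership test; a grid rasteriser (default 0.5 Å cells, 0.2 Å in oracle
  mode) provides the independent cross-check, and the two agree to ≲0.1 % on
  random clusters. The one-disk case is evaluated analytically (π r²), making
  the single-atom CCS exact for any orientation count.
* **Trajectory CCS** reuses one orientation set and sampling stream for every
  frame, so CCS *differences* along a trajectory reflect structural change
  rather than independent Monte-Carlo noise.

## Antibody topology

An antibody is partitioned into three rigid bodies — Fab1, Fab2 (each the
heavy-chain Fab portion plus its nearest light chain) and Fc core (everything
C-terminal of the most N-terminal hinge disulfide cysteine, which the
disulfide bonding makes effectively rigid) — plus the flexible upper-hinge
residues between the Fab and that cysteine. Hinge spans are user-supplied
per subclass (they come from sequence annotation databases, which the package
does not fetch); disulfides are detected from SG–SG distances (cutoff 2.5 Å,
canonical bond 2.05 Å plus slack, greedy nearest pairing so each SG bonds at
most once). PDB dialect: of alternate locations only blank or "A" is kept;
HETATM records are retained and flagged; residues are keyed by
(chain, number, insertion code) so numbering is traceable to the source.

## Fab-arm sampling (RRT)

Sampled degrees of freedom are the backbone φ/ψ torsions of the upper-hinge
residues — side chains stay rigid, which captures arm reorientation at
minimal dimensionality. Rotating a torsion moves everything on the Fab side
of the bond as one rigid unit, so rigid-body internal geometry is preserved
to machine precision and the Fc core never moves.

The rapidly-exploring random tree starts at the input conformation. Each
iteration draws a uniform random target vector in torsion space, finds the
nearest tree node under the wrapped-Euclidean metric (ties broken by lowest
node index for determinism), steps toward the target, and accepts the new
node iff the realised structure passes the clash check. Sampling is
deliberately non-energetic: it maps the sterically reachable space, not the
Boltzmann ensemble.

* **Step size** is specified per torsion (default 15°); the Euclidean step in
  the full space is `step × √dim`. This keeps per-torsion exploration
  comparable across hinges of different lengths — with a fixed Euclidean
  step, high-dimensional (long-hinge) trees would explore proportionally
  less, inverting the physically expected flexibility ordering.
* **Clash check**: any inter-body atom pair closer than
  `0.7 × (r_i + r_j)` rejects a pose. Pairs within one rigid body or one
  flexible segment, sequence-adjacent residues, and disulfide-bonded pairs
  are exempt. Candidate pairs come from a k-d tree; the test suite holds the
  verdicts against a brute-force all-pairs oracle.
* **Budget**: the attempt budget is 50 × n_samples; if it runs out the
  partial ensemble is returned with a warning flag.
* **Ensemble descriptors**: ΔCCS = max − min conformer CCS (flexibility
  metric); Fab-centroid clouds per arm with an overlap fraction computed by
  voxel occupancy (Jaccard). The voxel edge adapts to sampling density
  (2.5 × cloud RMS extent / n^⅓, floor 2 Å) so the fraction measures shared
  *region* rather than point coincidences — with a fixed voxel, larger
  clouds at fixed n would look spuriously disjoint.
* **Compact selection**: the lowest-CCS conformer plus further next-lowest
  picks whose backbone RMSD (no superposition; all conformers share the
  fixed Fc frame) to every earlier pick exceeds 5 Å, so the collapse stage
  starts from genuinely distinct compact models. CCS during sampling uses
  reduced settings (100 orientations, 3000 points); selected conformers are
  re-scored at full settings.

## Charged vacuum collapse

The collapse stage models the dry, multiply protonated ion in the
spectrometer vacuum with one bead per residue (the Cα, or the native bead of
coarse fixtures; bead mass 110 Da):

* **Chain bonds**: harmonic (k = 500 kJ mol⁻¹ Å⁻²) between consecutive
  residues, rest length from the input geometry; gaps larger than 2.5 × the
  nominal 3.8 Å virtual bond are treated as chain breaks.
* **Elastic network**: harmonic pairs (k = 50 kJ mol⁻¹ Å⁻²) within 8 Å
  inside each rigid body preserve domain shape (radius of gyration drifts
  < 5 % over a run).
* **Cohesion**: a soft generalised Lennard-Jones 6-3 well,
  `U = ε[(σ/r)⁶ − 2(σ/r)³]`, depth ε = 25 kJ/mol at r = σ = 6 Å, cutoff
  30 Å, acting only between beads of *different* bodies (domain interiors are
  the elastic network's job). A residue-scale bead aggregates the dispersion,
  hydrogen-bonding and dipolar attraction of a whole residue, so the
  effective well is deeper and longer-ranged than an atomic 12-6; the 6-3
  tail is what lets an arm feel a surface a domain-diameter away, which an
  atomic r⁻⁶ cannot. ε was calibrated on the standard fixture so that the
  rigid control stays within 2 % and the extended fixture collapses at the
  experimental charge state — the two properties the stage exists to exhibit.
* **Coulomb**: unscreened repulsion (k = 1389.35 kJ Å mol⁻¹ e⁻², dielectric
  1 — vacuum) between the unit protonation sites, no cutoff. Charge placement
  is greedy farthest-point over solvent-exposed sites (exposure proxied by
  neighbour count within 10 Å; sites at or below the median count are
  eligible), deterministic for a given structure; a `basic_residues` rule
  restricts eligibility to Arg/Lys/His side-chain tips for atomistic inputs.
* **Integrator**: BAOAB Langevin splitting, dt = 10 fs, friction 1 ps⁻¹,
  300 K, seeded; short-range pair forces are capped at 2000 kJ mol⁻¹ Å⁻¹ for
  stability. Default 200 000 steps (2 ns of coarse-grained dynamics) reach a
  collapsed plateau on the standard fixture. Non-finite coordinates abort
  with the step index and a suggestion to reduce dt.
* **Reporting**: CCS every `report_stride` steps; the "final window" is the
  last 10 % of reported frames (the coarse-grained generalisation of a fixed
  final-nanosecond window), and its CCS max − min quantifies how narrow a
  range the collapsed ion occupies. Replicates run per selected conformer
  with distinct seeds; the spread is the maximum pairwise relative difference
  of final CCS.

Charge behaviour on the standard fixture: the collapse survives the
experimental charge state (21), while high charge (40) splays the arms and
raises the final CCS — final CCS is monotone non-decreasing over net charges
{0, 10, 21, 40} within run-to-run noise.

## IM-MS utilities

* **Mass inference** assigns consecutive charges to adjacent ladder peaks:
  for neighbours m₁ > m₂, `z = round((m₂ − m_p)/(m₁ − m₂))` with
  m_p = 1.00728 Da, and the mass is the mean of `z(m/z − m_p)` over peaks.
  Ladders whose per-peak masses disagree by more than 0.1 % are rejected
  with per-peak diagnostics. Exact on noiseless synthetic ladders.
* **TWIMS calibration**: reference CCS values are corrected by
  `√μ / z` (μ = reduced mass with the drift gas, default nitrogen
  28.006 Da), drift times by a configurable dead time (default 0), and
  `ln CCS'` is fit to `ln t'` by least squares — the standard power-law
  protocol. `apply_calibration` is its exact inverse. Calibrant tables are
  user-supplied; none are bundled as authoritative.
* **Averaging** over wave velocities uses the arithmetic mean and the
  sample (n−1) standard deviation, flagged in the output.
* **Comparison** conventions are explicit: differences are quoted relative
  to the experimental mean for agreement-band statements (default ±6 %, the
  customary IM-MS reproducibility band) and relative to the model CCS when
  quoting how far an uncollapsed model overestimates the ion.

## Synthetic fixtures

The synthetic antibody is a Y of three capsule-shaped bead domains (two Fab
arms, one Fc stem; deterministic lattice packing, bead radius 1.9 Å) joined
by per-arm flexible linkers, with four chains (two heavy, two light) and a
hinge cysteine pair whose SG beads sit 2.05 Å apart. Linker residues carry a
three-bead N/Cα/C backbone with standard peptide bond lengths (~3.6 Å rise
per residue), so φ/ψ torsions are genuine and one kinematics code path serves
coarse and atomistic inputs while residue counts stay comparable to real
upper-hinge counts (IgG2-like 3 … IgG3-like 12). Calibrant tables follow a
protein-like CCS–mass scaling with drift times constructed from the known
power law; charge ladders are exact.

What the fixtures do **not** emulate: sequence and side-chain chemistry,
realistic domain packing and interface complementarity, glycans, solvent, and
the actual size of an antibody (the standard fixture is roughly a tenth of an
IgG by residue count, carrying the full experimental charge — hence the
calibrated cohesion above). Passing tests therefore demonstrate the
*mechanisms* (sampling coverage, steric restriction, collapse direction,
charge opposition, estimator correctness), not absolute antibody CCS values,
which require prepared atomistic models as input.

## Problem sizes and determinism

The test suite runs entirely on synthetic fixtures at desk scale: sampler
invariants at n = 500, the hinge-length response (3/5/7/12 flexible residues)
at n = 1000, and collapse properties on a 32-bead-per-domain fixture with 20
seeded replicate runs. Every stochastic component (orientation sets,
Monte-Carlo point streams, RRT targets, Langevin noise, fixture jitter) is
driven by an explicit integer seed, and identical inputs with identical seeds
reproduce results bit for bit; the workflow report records all stage seeds
and a config hash.

## Known limitations

* The collapse stage is a coarse-grained stand-in: it answers at the CCS
  level and cannot resolve side-chain packing, proton mobility, or
  temperature effects; its force field is calibrated, not transferable.
* The degenerate "pass-through" workflow (one sample, zero collapse steps)
  reports stage CCS values that agree only to estimator tolerance, because
  the collapse stage scores the one-bead-per-residue model while earlier
  stages score all atoms.
* The projection approximation underestimates CCS for very concave shapes;
  exact hard-sphere scattering and trajectory-method CCS are out of scope.
* Homology modelling, missing-residue reconstruction and mmCIF input are out
  of scope; prepared PDB models are assumed.
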