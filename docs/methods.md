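# Methods

## Scope and data model

`synbind` post-processes conformational ensembles of a single disordered
protein chain with one small ligand, stored as one trajectory per replica
with a uniform frame spacing in ns. Coordinates are kept in nm; PDB
angstroms are converted on read/write. Ensembles are assumed
whole-molecule (pre-unwrapped): no periodic-boundary imaging is applied
anywhere. Replica identity is positional and binding events never span
replica boundaries — no replica-exchange demultiplexing is attempted, so
"continuous binding" means continuity within one stored trajectory.
Residues are numbered 1..N; the NAC region defaults to residues 61–95 and
is configurable (its exact bounds are not standardised).

## Binding analysis

* Contact criterion: minimum heavy-atom distance strictly below the cutoff
  (default 0.35 nm). Equality at the cutoff is *not* a contact.
* Events are maximal runs of contact frames per (replica, residue);
  `duration = frames × spacing`. "Stable for at least t ns" means
  duration ≥ t, inclusive; thresholds must be positive multiples of the
  frame spacing (defaults 3, 5, 15 ns).
* Profiles report, per residue: total contact frames, frames belonging to
  events ≥ t, event counts ≥ t, and the number of replicas containing at
  least one such event. Ranking sorts by the chosen statistic, ties broken
  by lower residue index for reproducibility; zero-score residues are
  dropped.
* Ion pairs: opposite-sign (protein group, ligand group) pairs whose
  minimum member-atom distance is below 0.45 nm, a conventional
  salt-bridge heavy-atom criterion (configurable).
* RDF normalisation uses the finite analysis sphere of radius `r_max`
  rather than a periodic box (the data model carries no box vectors), so
  g(r) → 1 for uncorrelated placement *within that sphere* and absolute
  scales are comparable only between profiles sharing `r_max`.

## Compaction observables and free-energy surfaces

R_g is mass-weighted over heavy atoms by default (CA-only available), for
the full chain or a region; the end-to-end distance uses terminal CA
atoms. The free-energy surface is −ln of the normalised 2D histogram
(default 50×50 bins spanning the pooled data range), global minimum
shifted to 0 so surfaces are comparable across systems; empty cells are
masked (NaN), not +∞, which keeps CSV round-trips exact. The stored shift
makes the transform invertible: `exp(−(value + shift))` reproduces the
normalised histogram. A degenerate axis (all values equal) collapses to a
single bin with value 0. No thermodynamic reweighting across replica
temperatures is applied; replica selection is explicit and configurable
instead.

## Secondary structure

Assignment implements the Kabsch–Sander hydrogen-bond model: amide H
placed geometrically when absent (0.101 nm from N along the bisector of
the N→C(prev) and N→CA directions), bond energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol (distances in
Å), bond if E < −0.5 kcal/mol. Helix needs two consecutive 4-turns; strand
(E) needs a ladder of ≥ 2 consecutive bridges; an isolated bridge is B;
turns mark the bracketed residues; priority H > E > B > T > C. Terminal
residues are never strands (a bridge requires both sequence neighbours).
The reduced alphabet is {H, E, B, T, C}; `to_simplified` maps it onto
{H, E, C} for comparison with mdtraj's DSSP port, which the test suite
uses as an independent oracle (≥ 95% interior agreement on ideal helix,
hairpin, and coil structures; small divergences near termini and at
borderline H-bond energies are expected because the reference places the
amide H along the previous carbonyl direction instead of the bisector).

## Hairpin scan and contact maps

A 12-residue window slides (step 1) over the scanned region; at each
position the hairpin probability is the fraction of frames whose backbone
(N, CA, C, O; CA-only mode available) RMSD to a reference hairpin after
optimal superposition is below a threshold. Superposition is closed-form
Kabsch via SVD with a determinant correction so reflections are never
used. The default threshold is 0.25 nm, chosen to tolerate thermal
distortion in real data; on synthetic data, planted windows reproduce the
template to ~1e-7 nm, so validation uses a tighter 0.15 nm threshold that
suppresses the small coil false-positive background without affecting
recovery. Users supply their own reference hairpin PDB (e.g. a 12-residue
fragment of an experimentally determined hairpin) for production runs;
reference coordinates are not bundled.

Contact maps count frames whose per-residue-pair minimum heavy-atom
distance lies strictly between 0.15 and 0.5 nm, sampled at a stride
(default 1 ns, implemented as frame striding, not averaging). Pairs with
|i−j| < 3 are zeroed so covalent neighbours do not saturate the map. The
differential map is an elementwise difference of two maps with identical
parameters (antisymmetric under swap); the pipeline computes bound-minus-
unbound within one ensemble by splitting frames on ligand contact.

## The synthetic-ensemble generator

The generator exists to give every analysis stage exact ground truth; it
is *not* a physical model. What it emulates, and how:

* **Coil backbone.** Per-frame, per-residue (phi, psi) are drawn iid from
  a 4-basin Ramachandran mixture — beta (−135, 135), polyproline II
  (−75, 145), alpha_R (−63, −43), alpha_L (57, 47), Gaussian scatter of
  10–25° — and the N/CA/C/O backbone is built by sequential
  internal-to-Cartesian (NeRF) placement with ideal bond lengths/angles
  and trans peptide bonds (CA–CA virtual bond 0.3804 nm). At the default
  `compaction = 1.0` the extended basins carry 62% of the weight; the
  mean R_g measured in a 10,000-frame pilot at 140 residues fixes the
  recorded Flory-type calibration `R_g ≈ 0.161 · N^0.588` nm, and frames
  show the broad R_g and end-to-end distributions characteristic of a
  disordered chain. Lowering `compaction` shifts weight toward turn-like
  basins, shrinking the chain monotonically.
* **Ligand kinetics.** Bound/unbound alternation is a two-state Markov
  chain in discrete frame time with per-frame hazards
  `p_off = spacing/mean_residence` and `p_on = spacing/mean_unbound`
  (clamped to [0,1]), started from its stationary distribution. Episode
  lengths are geometric with mean `mean_residence/spacing` frames; the
  stationary bound fraction is `mean_residence/(mean_residence +
  mean_unbound)`. Each episode binds one target residue sampled by the
  configured preference weights. During bound frames the rigid 5-atom
  ligand (a spermine-like rod, two cationic termini, 0.125 nm spacing) is
  placed within the contact distance of exactly one residue and clear of
  all others; unbound frames put it ≥ 2× the contact distance from the
  whole chain. `decoy_rate` converts unbound frames into one-frame
  contacts at uniform random non-target residues. When the chain buries a
  residue so that no single-residue pose exists (≈ 1–2% of frames), the
  generator redraws that frame's coil conformation (re-planting any
  hairpin episode) rather than perturbing the kinetics — episode durations
  therefore follow the geometric law exactly. Everything placed is
  recorded in a truth log (episodes with replica/residue/frames/kind,
  hairpin frame lists).
* **Hairpin episodes.** In a Bernoulli(`episode_fraction`) subset of
  frames the 12-residue window around the chosen centre is rebuilt with a
  frozen template: two 5-residue strands (−120, 130) joined by a
  (60, 45)/(80, 5) turn, tuned once so a DSSP analysis of the built
  geometry yields two 4-residue strand runs flanking the turn
  ('CEEEECCEEEEC'). Downstream atoms are rigidly re-attached, preserving
  their internal geometry. The window's first residue must be ≥ 2 (the
  rebuild needs the preceding carbonyl as a dihedral anchor).
* **Charged groups.** The backbone-only chain has no side chains, so the
  synthetic topology marks the backbone carbonyl O of each target residue
  as a −1 group (a stand-in for side-chain carboxylates) and the ligand's
  terminal nitrogens as +1 groups, giving the ion-pair and RDF analyses
  physically sensible selections.

What it does **not** emulate: sterics between non-adjacent residues (only
the ligand placement is clash-checked), side chains, solvent, energetics,
temperature dependence across replicas, or any correlation between
successive frames of the chain (frames are independent draws, while the
ligand state is Markov). Passing tests therefore demonstrate that the
analysis machinery recovers planted statistical structure exactly at
realistic problem sizes — not that the generator reproduces any real
protein's ensemble.

## Validation scenario and problem sizes

The reference validation scenario uses 4 replicas × 2000 frames at 1 ns
spacing, a 140-residue chain, C-terminal targets {125, 130, 133, 134,
136}, 5 ns mean residence / 15 ns mean unbound (bound fraction ≈ 0.25
before decoys), 10% decoys, and a hairpin at residue 84 in 30% of frames
— the sample sizes a desk-scale re-analysis can process in seconds while
keeping binomial confidence intervals tight. Calibration runs use longer
single-replica chains (30,000–50,000 frames on 20–40 residues) so that
event counts exceed 1000 and the stationary bound fraction is measured to
±0.01. `validate_recovery` scores binding-site Jaccard (≥ 0.8), the bound
fraction against the stationary law (3σ over completed on/off cycles),
hairpin peak position (±1 residue) and height (exact 99% binomial
interval), and the min-run-4 strand fraction (binomial interval plus a
0.05 allowance for coil background strands).

## Determinism and outputs

A single `numpy` Generator seeded from the config is threaded through
generation; analyses are deterministic. Rerunning `synth` + `analyze`
with the same config and seed reproduces every CSV byte-for-byte. All
tables round-trip exactly (floats serialised with shortest round-trip
repr; masked matrix cells as empty fields). `run_log.json` records
package versions, the seed, and every threshold so paper-faithful
settings (0.35 nm cutoff; 3/5/15 ns filters; 0.15–0.5 nm map band; 1 ns
stride; 12-residue window) are auditable.

## Known limitations

* The DSSP subset omits 3_10/pi helices and bends (G, I, S); strand/helix
  fractions on real trajectories may differ slightly from full DSSP.
* RDFs lack periodic-box normalisation; only relative shapes should be
  compared with literature g(r).
* The ideal-geometry hairpin template caps strand runs at 4 residues, so
  the min-run-6 strand fraction is near zero on synthetic data; it is
  meaningful only on real ensembles.
* Binding analyses assume exactly one ligand molecule.
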