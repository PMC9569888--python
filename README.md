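# synbind

Binding-site prediction and conformational-ensemble analysis for
intrinsically disordered proteins (IDPs) from replica-exchange molecular
dynamics (REMD) output.

## The problem

Small molecules that bind a fully disordered protein such as alpha-synuclein
do not dock into a pocket: the ligand drifts among a set of preferred
residues while the chain keeps exchanging conformations. Given an ensemble
of trajectories (one per replica) of a protein + single-ligand system,
`synbind` answers the questions such a simulation is run for:

* **Where does the ligand bind?** For every residue *i* and frame *t*, a
  contact is recorded when the minimum heavy-atom distance between the
  ligand and the residue is < 0.35 nm. Maximal runs of contact frames are
  *binding events* with duration `(frames × spacing)` ns; events shorter
  than a residence threshold *t* ∈ {3, 5, 15} ns are discarded as
  transient. Per-residue profiles (total frames, stable frames, event
  counts, replicas with a stable event) rank the preferred binding
  residues. Ion-pair counts and radial distribution functions g(r) of
  charged ligand groups around oppositely charged protein groups probe the
  electrostatics of the binding.
* **What does binding do to the chain?** Free-energy surfaces
  F(x, y) = −ln P(x, y) (units of kT, minimum shifted to 0) over the radius
  of gyration R_g and the end-to-end distance; per-frame observables split
  into ligand-bound and unbound sub-ensembles.
* **Does it push the chain toward amyloid-like structure?** Kabsch–Sander
  (DSSP-style) secondary structure and the fraction of frames with strand
  runs ≥ 4 or ≥ 6 residues in the NAC region (residues 61–95 by default); a
  sliding 12-residue window scanned against a reference beta-hairpin with
  Kabsch superposition, thresholded RMSD giving a per-position hairpin
  probability; residue–residue contact maps (min heavy-atom distance
  between 0.15 and 0.5 nm, |i−j| ≥ 3) and differential maps between
  bound/unbound or ligand/free ensembles.

Because real REMD trajectories of this kind are rarely redistributable, the
package ships a **seeded synthetic-ensemble generator** (`synbind.synth`)
that builds coil backbones from a Ramachandran-basin mixture and plants
ground truth: two-state (bound/unbound) ligand kinetics with geometric
residence times at chosen target residues, one-frame decoy contacts, and
beta-hairpin episodes at a chosen position. Every analysis stage can
therefore be validated against an exact truth log. See
`docs/methods.md` for the model details and its limitations.

## Worked example

```python
import json
from synbind import synth, pipeline

scfg = synth.SynthConfig(
    n_residues=60, n_replicas=2, n_frames=300,
    binding=synth.BindingConfig(target_residues=(20, 30, 40, 45, 50), decoy_rate=0.1),
    hairpin=synth.HairpinConfig(position=30, episode_fraction=0.3),
    seed=7,
)
top, trajs, truth = synth.write_synthetic_data(scfg, "demo")
cfg = pipeline.RunConfig(
    topology_path=str(top), trajectory_paths=tuple(map(str, trajs)),
    nac_start=15, nac_end=45, out_dir="demo_out",
)
print(json.dumps(pipeline.run_full_analysis(cfg), indent=1, sort_keys=True))
```

prints

```json
{
 "beta_fraction_4": 0.31666666666666665,
 "beta_fraction_6": 0.0033333333333333335,
 "bound_fraction": 0.36,
 "diff_map_max_abs": 0.08478009259259259,
 "hairpin_peak_position": 30,
 "hairpin_peak_probability": 0.31166666666666665,
 "n_frames_total": 600,
 "n_replicas": 2,
 "n_residues": 60,
 "top_binding_residues": [40, 50, 30, 45, 20]
}
```

The five top-ranked binding residues are exactly the planted targets
{20, 30, 40, 45, 50}; the hairpin scan peaks at the planted centre
(residue 30) with probability ≈ the planted episode fraction 0.3; the
bound fraction 0.36 matches the two-state stationary value
5/(5+15) + 0.75 × 0.1 ≈ 0.325 up to sampling noise; and ~32% of frames
show a ≥4-residue strand run in the scanned region (the planted hairpin
contributes two 4-residue strands). `demo_out/` holds the per-stage CSVs
(binding profile and events, observables, FES grids, hairpin profile,
contact and differential maps) plus `summary.json` and `run_log.json`
with every threshold, seed, and package version used.

The same workflow is available from the shell:

```bash
synbind synth --config synth.yaml --out demo
synbind analyze --config run.yaml
synbind validate --seed 3 --out report.json
```

plus per-stage subcommands (`contacts`, `profile`, `rank`, `ionpairs`,
`rdf`, `observables`, `fes`, `ss`, `betafrac`, `hairpin`, `cmap`).

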