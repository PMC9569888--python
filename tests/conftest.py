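"""Shared fixtures: small synthetic ensembles and programmatically written
PDB inputs (no stored data files)."""
from __future__ import annotations

import mdtraj as md
import numpy as np
import pytest

from synbind import synth
from synbind.core import Atom, Residue, Topology


@pytest.fixture(scope="session")
def small_planted():
    """60-residue, 2x300-frame ensemble with planted binding (targets
    spread along the chain, decoys on) and a hairpin at residue 30."""
    cfg = synth.SynthConfig(
        n_residues=60,
        n_replicas=2,
        n_frames=300,
        binding=synth.BindingConfig(
            target_residues=(20, 30, 40, 45, 50),
            mean_residence_ns=5.0,
            mean_unbound_ns=15.0,
            decoy_rate=0.1,
        ),
        hairpin=synth.HairpinConfig(position=30, episode_fraction=0.3),
        seed=7,
    )
    ensemble, truth = synth.generate_ensemble(cfg)
    return cfg, ensemble, truth


@pytest.fixture(scope="session")
def coil_small():
    """Plain 40-residue coil ensemble, 1 replica x 200 frames, no ligand."""
    cfg = synth.SynthConfig(n_residues=40, n_replicas=1, n_frames=200, seed=11)
    ensemble, _ = synth.generate_ensemble(cfg)
    return ensemble


def _build_pdb(tmp_path, name, residue_specs, ligand_spec=None):
    """Write a PDB from (resname, [atom names]) specs via mdtraj."""
    top = md.Topology()
    chain = top.add_chain()
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
                "N1": "N", "N2": "N", "N3": "N", "N4": "N", "C1": "C"}
    for i, (resname, atom_names) in enumerate(residue_specs, start=1):
        res = top.add_residue(resname, chain, resSeq=i)
        for an in atom_names:
            top.add_atom(an, md.element.get_by_symbol(elements[an]), res)
    if ligand_spec is not None:
        lchain = top.add_chain()
        resname, atom_names = ligand_spec
        res = top.add_residue(resname, lchain, resSeq=len(residue_specs) + 1)
        for an in atom_names:
            top.add_atom(an, md.element.get_by_symbol(elements[an]), res)
    n = top.n_atoms
    rng = np.random.default_rng(0)
    xyz = rng.uniform(0, 2, size=(1, n, 3))
    path = tmp_path / name
    md.Trajectory(xyz, top).save_pdb(str(path))
    return path


@pytest.fixture()
def aga_pdb(tmp_path):
    """Three-residue Ala-Gly-Ala PDB, backbone only."""
    bb = ["N", "CA", "C", "O"]
    return _build_pdb(tmp_path, "aga.pdb", [("ALA", bb), ("GLY", bb), ("ALA", bb)])


@pytest.fixture()
def aga_spm_pdb(tmp_path):
    """Ala-Gly-Ala plus a spermine-like ligand with four amine nitrogens."""
    bb = ["N", "CA", "C", "O"]
    return _build_pdb(
        tmp_path,
        "aga_spm.pdb",
        [("ALA", bb), ("GLY", bb), ("ALA", bb)],
        ligand_spec=("SPM", ["N1", "N2", "N3", "N4"]),
    )


@pytest.fixture()
def broken_pdb(tmp_path):
    """Residue 2 lacks its backbone C."""
    bb = ["N", "CA", "C", "O"]
    return _build_pdb(
        tmp_path, "broken.pdb", [("ALA", bb), ("GLY", ["N", "CA", "O"]), ("ALA", bb)]
    )


def random_system(rng, n_frames=10, n_atoms_total=50):
    """Random topology (variable residue sizes, some hydrogens, small ligand)
    plus coordinates — for oracle-equivalence checks."""
    n_lig = int(rng.integers(3, 7))
    n_prot = n_atoms_total - n_lig
    sizes = []
    while sum(sizes) < n_prot:
        sizes.append(int(rng.integers(3, 8)))
    sizes[-1] -= sum(sizes) - n_prot
    if sizes[-1] < 1:
        sizes.pop()
    residues, atoms = [], []
    serial = 0
    for r, size in enumerate(sizes, start=1):
        residues.append(Residue(r, "UNK", "X"))
        for a in range(size):
            serial += 1
            is_h = a > 0 and rng.random() < 0.25
            atoms.append(
                Atom(serial, r, f"A{a}", "H" if is_h else "C", is_h, False)
            )
        # every residue keeps at least one heavy atom (atom 0 above)
    ligand_atoms = []
    for a in range(n_lig):
        serial += 1
        is_h = a > 0 and rng.random() < 0.2
        ligand_atoms.append(Atom(serial, 0, f"L{a}", "H" if is_h else "C", is_h, False))
    top = Topology(residues, atoms, ligand_atoms)
    xyz = rng.uniform(0, 1.5, size=(n_frames, top.n_atoms, 3))
    return top, xyz
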