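"""Domain types and structure/trajectory I/O shared by all analysis stages.

Conventions
-----------
* Residues are numbered 1..N throughout (matching the usual residue labels
  for alpha-synuclein such as K6, Y39, Y136).
* Coordinates are stored in nanometres; PDB angstroms are converted on read
  and write.
* Ensembles are assumed whole-molecule: no periodic-boundary imaging is
  performed, so trajectories must be pre-unwrapped.
* Replica identity is positional (the order trajectories are supplied);
  no replica-exchange demultiplexing is attempted, so contact continuity is
  defined within each stored trajectory.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import mdtraj as md
import numpy as np
import pandas as pd

BACKBONE_NAMES = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Residue:
    index: int  # 1-based
    name: str   # 3-letter code
    one_letter: str


@dataclass(frozen=True)
class Atom:
    serial: int
    residue_index: int  # 1-based protein residue; 0 for ligand atoms
    name: str
    element: str
    is_hydrogen: bool
    is_backbone: bool


@dataclass(frozen=True)
class ChargedGroup:
    label: str
    member_serials: tuple[int, ...]
    sign: int  # +1 or -1
    molecule: str  # "protein" or "ligand"


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive 1-based residue range, e.g. the NAC domain."""

    label: str
    start: int
    end: int

    def validate(self, n_residues: int) -> None:
        if not (1 <= self.start <= self.end <= n_residues):
            raise ValueError(
                f"region {self.label!r} [{self.start}, {self.end}] outside 1..{n_residues}"
            )

    def residues(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


#: Default bounds used for the non-amyloid-beta component (NAC) region.
NAC_DEFAULT = RegionSpec("NAC", 61, 95)


class Topology:
    """Residue/atom catalogue for one protein chain plus an optional ligand.

    Atom order in coordinate arrays is protein atoms first (in `atoms`
    order) followed by ligand atoms.
    """

    def __init__(
        self,
        residues: Sequence[Residue],
        atoms: Sequence[Atom],
        ligand_atoms: Sequence[Atom] = (),
        charged_groups: Sequence[ChargedGroup] = (),
    ):
        self.residues = list(residues)
        self.atoms = list(atoms)
        self.ligand_atoms = list(ligand_atoms)
        self.charged_groups = list(charged_groups)
        self._validate()
        self._index()

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        idx = [r.index for r in self.residues]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("residue indices must be contiguous 1..N")
        res_set = set(idx)
        for a in self.atoms:
            if a.residue_index not in res_set:
                raise ValueError(f"atom serial {a.serial} references unknown residue")
        serials = [a.serial for a in self.atoms] + [a.serial for a in self.ligand_atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials")
        known = set(serials)
        prot = {a.serial for a in self.atoms}
        for g in self.charged_groups:
            for s in g.member_serials:
                if s not in known:
                    raise ValueError(f"charged group {g.label!r}: unknown atom serial {s}")
            in_prot = {s in prot for s in g.member_serials}
            if len(in_prot) > 1:
                raise ValueError(f"charged group {g.label!r} mixes protein and ligand atoms")

    def _index(self) -> None:
        n_prot = len(self.atoms)
        self._serial_to_global = {a.serial: i for i, a in enumerate(self.atoms)}
        self._serial_to_global.update(
            {a.serial: n_prot + i for i, a in enumerate(self.ligand_atoms)}
        )
        self.n_residues = len(self.residues)
        by_res: list[list[int]] = [[] for _ in range(self.n_residues)]
        by_res_heavy: list[list[int]] = [[] for _ in range(self.n_residues)]
        bb = np.full((self.n_residues, 4), -1, dtype=np.int64)
        for i, a in enumerate(self.atoms):
            by_res[a.residue_index - 1].append(i)
            if not a.is_hydrogen:
                by_res_heavy[a.residue_index - 1].append(i)
            if a.is_backbone and a.name in BACKBONE_NAMES:
                bb[a.residue_index - 1, BACKBONE_NAMES.index(a.name)] = i
        self.residue_atom_indices = [np.array(v, dtype=np.int64) for v in by_res]
        self.residue_heavy_indices = [np.array(v, dtype=np.int64) for v in by_res_heavy]
        self.backbone_indices = bb  # (n_res, 4) global indices of N, CA, C, O
        self.ca_indices = bb[:, 1].copy()
        self.protein_heavy_indices = np.array(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=np.int64
        )
        self.ligand_heavy_indices = np.array(
            [n_prot + i for i, a in enumerate(self.ligand_atoms) if not a.is_hydrogen],
            dtype=np.int64,
        )

    # -- basic queries ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms) + len(self.ligand_atoms)

    def global_index(self, serial: int) -> int:
        return self._serial_to_global[serial]

    def group_indices(self, group: ChargedGroup) -> np.ndarray:
        return np.array([self.global_index(s) for s in group.member_serials], dtype=np.int64)

    def protein_groups(self, sign: int | None = None) -> list[ChargedGroup]:
        return [
            g for g in self.charged_groups
            if g.molecule == "protein" and (sign is None or g.sign == sign)
        ]

    def ligand_groups(self, sign: int | None = None) -> list[ChargedGroup]:
        return [
            g for g in self.charged_groups
            if g.molecule == "ligand" and (sign is None or g.sign == sign)
        ]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    # -- interop -----------------------------------------------------------
    def to_mdtraj(self) -> md.Topology:
        """Equivalent mdtraj topology (protein chain + ligand chain)."""
        top = md.Topology()
        chain = top.add_chain()
        for r in self.residues:
            res = top.add_residue(r.name, chain, resSeq=r.index)
            for a in self.atoms:
                if a.residue_index == r.index:
                    top.add_atom(
                        a.name,
                        md.element.get_by_symbol(a.element) if a.element != "X"
                        else md.element.virtual,
                        res,
                        serial=a.serial,
                    )
        if self.ligand_atoms:
            lchain = top.add_chain()
            lres = top.add_residue("LIG", lchain, resSeq=self.n_residues + 1)
            for a in self.ligand_atoms:
                top.add_atom(
                    a.name,
                    md.element.get_by_symbol(a.element) if a.element != "X"
                    else md.element.virtual,
                    lres,
                    serial=a.serial,
                )
        return top


@dataclass
class Replica:
    """One stored trajectory: frames × atoms × 3 coordinates in nm."""

    replica_id: int
    xyz: np.ndarray  # (n_frames, n_atoms, 3)
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[0] < 1 or self.xyz.shape[2] != 3:
            raise ValueError("replica coordinates must have shape (frames>=1, atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"replica {self.replica_id}: non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]


@dataclass
class Ensemble:
    """A set of replicas sharing a topology and a fixed frame spacing."""

    replicas: list[Replica]
    frame_spacing_ns: float
    topology: Topology

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("no replicas")
        if self.frame_spacing_ns <= 0:
            raise ValueError("frame_spacing_ns must be positive")
        n = self.topology.n_atoms
        for rep in self.replicas:
            if rep.xyz.shape[1] != n:
                raise ValueError(
                    f"replica {rep.replica_id}: {rep.xyz.shape[1]} atoms, topology has {n}"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames_total(self) -> int:
        return sum(r.n_frames for r in self.replicas)

    def select_replicas(self, replica_ids: Iterable[int] | None) -> "Ensemble":
        """Restrict to a subset of replicas (None keeps everything)."""
        if replica_ids is None:
            return self
        wanted = set(replica_ids)
        reps = [r for r in self.replicas if r.replica_id in wanted]
        if not reps:
            raise ValueError(f"no replicas match ids {sorted(wanted)}")
        return dataclasses.replace(self, replicas=reps)

    def to_mdtraj(self, replica: int = 0) -> md.Trajectory:
        rep = self.replicas[replica]
        return md.Trajectory(rep.xyz.copy(), self.topology.to_mdtraj())


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _charged_groups_from_config(
    config: Sequence[dict] | None,
    serial_lookup: dict,
    name_lookup: dict,
    protein_serials: set[int],
) -> list[ChargedGroup]:
    groups: list[ChargedGroup] = []
    for entry in config or ():
        label = entry["label"]
        sign = {"+": 1, "-": -1, 1: 1, -1: -1}.get(entry["sign"])
        if sign is None:
            raise ValueError(f"charged group {label!r}: sign must be '+' or '-'")
        serials = []
        for member in entry["atoms"]:
            if isinstance(member, int):
                if member not in serial_lookup:
                    raise ValueError(f"charged group {label!r}: unknown atom serial {member}")
                serials.append(member)
            else:
                key = str(member)
                if key not in name_lookup:
                    raise ValueError(f"charged group {label!r}: unknown atom {key!r}")
                serials.append(name_lookup[key])
        molecule = "protein" if serials[0] in protein_serials else "ligand"
        groups.append(ChargedGroup(label, tuple(serials), sign, molecule))
    return groups


def read_topology(
    pdb_path: str | Path,
    ligand_resnames: Iterable[str] = (),
    charged_group_config: Sequence[dict] | None = None,
) -> Topology:
    """Parse a PDB file into a Topology.

    Residues whose name is in ``ligand_resnames`` become the ligand; all
    others are protein. Backbone atoms are flagged by name (N, CA, C, O);
    hydrogens by element. ``charged_group_config`` is a list of entries
    ``{"label": str, "sign": "+"|"-", "atoms": [serial | "resSeq:NAME", ...]}``.
    """
    ligand_set = {s.upper() for s in ligand_resnames}
    traj = md.load(str(pdb_path))
    mtop = traj.topology

    residues: list[Residue] = []
    atoms: list[Atom] = []
    ligand_atoms: list[Atom] = []
    serial_lookup: dict[int, int] = {}
    name_lookup: dict[str, int] = {}

    next_index = 0
    for res in mtop.residues:
        is_ligand = res.name.upper() in ligand_set or res.name.upper() in ("HOH", "WAT")
        if res.name.upper() in ("HOH", "WAT"):
            continue
        if not is_ligand:
            next_index += 1
            residues.append(
                Residue(next_index, res.name.upper(), THREE_TO_ONE.get(res.name.upper(), "X"))
            )
        for a in res.atoms:
            serial = a.serial if a.serial is not None else a.index + 1
            element = a.element.symbol if a.element is not None else "X"
            atom = Atom(
                serial=serial,
                residue_index=0 if is_ligand else next_index,
                name=a.name,
                element=element,
                is_hydrogen=element == "H",
                is_backbone=(not is_ligand) and a.name in BACKBONE_NAMES,
            )
            (ligand_atoms if is_ligand else atoms).append(atom)
            serial_lookup[serial] = serial
            name_lookup[f"{res.resSeq}:{a.name}"] = serial

    for res in residues:
        present = {a.name for a in atoms if a.residue_index == res.index and a.is_backbone}
        missing = set(BACKBONE_NAMES) - present
        if missing:
            raise ValueError(
                f"residue {res.index} ({res.name}) missing backbone atom(s) {sorted(missing)}"
            )

    protein_serials = {a.serial for a in atoms}
    groups = _charged_groups_from_config(
        charged_group_config, serial_lookup, name_lookup, protein_serials
    )
    return Topology(residues, atoms, ligand_atoms, groups)


def read_ensemble(
    topology: Topology,
    trajectory_paths: Sequence[str | Path],
    frame_spacing_ns: float,
    temperatures_K: Sequence[float] | None = None,
) -> Ensemble:
    """Load one trajectory file per replica (multi-model PDB, DCD, XTC, ...).

    Binary formats are read against the given topology; atom counts are
    checked against it for every file.
    """
    if not trajectory_paths:
        raise ValueError("no replicas: empty trajectory path list")
    mtop = topology.to_mdtraj()
    replicas = []
    for i, path in enumerate(trajectory_paths):
        path = str(path)
        if path.endswith(".pdb"):
            traj = md.load(path)
        else:
            traj = md.load(path, top=mtop)
        if traj.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: trajectory has {traj.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        temp = temperatures_K[i] if temperatures_K is not None else 300.0
        replicas.append(Replica(i, np.asarray(traj.xyz, dtype=np.float64), temp))
    return Ensemble(replicas, frame_spacing_ns, topology)


# ---------------------------------------------------------------------------
# Result tables and matrices (CSV round-trip)
# ---------------------------------------------------------------------------

def write_profile_table(profile, path: str | Path) -> None:
    """Write any result exposing ``to_frame() -> DataFrame`` (or a DataFrame)
    as CSV with a header row."""
    frame = profile.to_frame() if hasattr(profile, "to_frame") else profile
    frame.to_csv(path, index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(matrix: np.ndarray, path: str | Path, indices: Sequence[int] | None = None) -> None:
    """Dense CSV with residue indices as first row and column.

    NaN cells (masked) are written as empty fields and restored as NaN.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n_rows, n_cols = matrix.shape
    if indices is None:
        indices = range(1, n_cols + 1)
    idx = list(indices)
    if len(idx) != n_cols:
        raise ValueError("index length does not match matrix width")
    with open(path, "w") as fh:
        fh.write("," + ",".join(str(i) for i in idx) + "\n")
        for r in range(n_rows):
            cells = ("" if np.isnan(v) else repr(float(v)) for v in matrix[r])
            fh.write(str(idx[r] if r < len(idx) else r + 1) + "," + ",".join(cells) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of write_matrix: returns (matrix with NaN for masked cells,
    residue indices)."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return frame.to_numpy(dtype=np.float64), frame.columns.to_numpy(dtype=np.int64)
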