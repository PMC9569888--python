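"""Chain-compaction observables and free-energy surfaces.

The free-energy surface over two order parameters (typically radius of
gyration and end-to-end distance) is -ln of the normalised 2D histogram in
units of kT, with the global minimum shifted to zero. No thermodynamic
reweighting across replica temperatures is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import ContactSeries
from .core import Ensemble, RegionSpec

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class FreeEnergySurface:
    """-ln(P) grid; empty cells are masked (NaN), not +inf.

    ``exp(-(values + shift))`` recovers the normalised probability P on
    occupied cells (sums to 1).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # (nx, ny), NaN on empty cells
    mask: np.ndarray  # True where empty
    shift: float
    x_label: str = "x"
    y_label: str = "y"

    def probability(self) -> np.ndarray:
        p = np.exp(-(self.values + self.shift))
        return np.where(self.mask, 0.0, p)


@dataclass
class ScalarSeries:
    """Per-replica per-frame scalar observable (nm)."""

    label: str
    values: list[np.ndarray]
    region_label: str = "full"

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, v in enumerate(self.values):
            rows.append(
                pd.DataFrame(
                    {"replica": rid, "frame": np.arange(len(v)), self.label: v}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _selection_masses(ensemble: Ensemble, selection: np.ndarray) -> np.ndarray:
    atoms = ensemble.topology.atoms + ensemble.topology.ligand_atoms
    return np.array([ATOMIC_MASSES.get(atoms[i].element, 12.011) for i in selection])


def radius_of_gyration(
    frame: np.ndarray, selection: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Rg of the selected atoms: sqrt(sum w |r - rbar|^2 / sum w).

    ``frame`` may carry leading batch dimensions. Unit masses when
    ``masses`` is None.
    """
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise ValueError("empty selection")
    xyz = np.asarray(frame)[..., selection, :]
    w = np.ones(len(selection)) if masses is None else np.asarray(masses, dtype=np.float64)
    com = (xyz * w[:, None]).sum(axis=-2) / w.sum()
    sq = ((xyz - com[..., None, :]) ** 2).sum(axis=-1)
    out = np.sqrt((sq * w).sum(axis=-1) / w.sum())
    return float(out) if out.ndim == 0 else out


def rg_series(
    ensemble: Ensemble,
    region: RegionSpec | None = None,
    mass_weighted: bool = True,
    ca_only: bool = False,
) -> ScalarSeries:
    """Radius of gyration per frame over heavy atoms (default) or CA atoms
    of the full chain or a residue region."""
    top = ensemble.topology
    if region is not None:
        region.validate(top.n_residues)
        res_range = range(region.start - 1, region.end)
    else:
        res_range = range(top.n_residues)
    if ca_only:
        sel = top.ca_indices[list(res_range)]
    else:
        sel = np.concatenate([top.residue_heavy_indices[i] for i in res_range])
    masses = _selection_masses(ensemble, sel) if mass_weighted else None
    values = [radius_of_gyration(rep.xyz, sel, masses) for rep in ensemble.replicas]
    return ScalarSeries("Rg", values, region.label if region else "full")


def end_to_end(frame: np.ndarray, ca_first: int, ca_last: int):
    """Distance between the terminal C-alpha atoms; batches over leading dims."""
    d = np.linalg.norm(
        np.asarray(frame)[..., ca_last, :] - np.asarray(frame)[..., ca_first, :], axis=-1
    )
    return float(d) if d.ndim == 0 else d


def end_to_end_series(ensemble: Ensemble, region: RegionSpec | None = None) -> ScalarSeries:
    top = ensemble.topology
    first, last = (0, top.n_residues - 1) if region is None else (region.start - 1, region.end - 1)
    ca_first, ca_last = int(top.ca_indices[first]), int(top.ca_indices[last])
    if ca_first < 0 or ca_last < 0:
        raise ValueError("terminal residue lacks a CA atom")
    values = [end_to_end(rep.xyz, ca_first, ca_last) for rep in ensemble.replicas]
    return ScalarSeries("end_to_end", values, region.label if region else "full")


def free_energy_surface(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 50,
    x_label: str = "x",
    y_label: str = "y",
) -> FreeEnergySurface:
    """-ln(P_xy) over a uniform n_bins x n_bins grid spanning the data range,
    minimum shifted to 0. A degenerate (constant) axis collapses to one bin."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be equal-length, non-empty")

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi <= lo:  # all values equal: single bin
            return np.array([lo - 0.5, lo + 0.5])
        return np.linspace(lo, hi, n_bins + 1)

    xe, ye = _edges(x), _edges(y)
    H, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    P = H / H.sum()
    mask = P == 0
    with np.errstate(divide="ignore"):
        neglog = -np.log(P, where=~mask, out=np.full_like(P, np.nan))
    shift = np.nanmin(neglog)
    values = neglog - shift
    values[mask] = np.nan
    return FreeEnergySurface(xe, ye, values, mask, float(shift), x_label, y_label)


def split_bound_unbound(
    ensemble: Ensemble, contacts: ContactSeries
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-replica frame index sets: bound = frames with >= 1 residue in
    contact; unbound = complement. Disjoint and exhaustive."""
    if len(contacts.series) != ensemble.n_replicas:
        raise ValueError("contact series does not match ensemble replicas")
    bound, unbound = [], []
    for rep, mat in zip(ensemble.replicas, contacts.series):
        if mat.shape[1] != rep.n_frames:
            raise ValueError("contact series frame count does not match ensemble")
        any_contact = mat.any(axis=0)
        bound.append(np.flatnonzero(any_contact))
        unbound.append(np.flatnonzero(~any_contact))
    return bound, unbound
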