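"""Ligand-residue contact detection, residence-time filtering, binding
profiles and site ranking, ion pairs and radial distribution functions.

The contact criterion is a minimum heavy-atom distance strictly below a
cutoff (default 0.35 nm); a contact at exactly the cutoff does not count.
"Continuous binding for at least t ns" means a maximal run of contact
frames whose duration (frames x spacing) is >= t, inclusive. Runs never
span replica boundaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ChargedGroup, Ensemble, Topology

DEFAULT_CONTACT_CUTOFF_NM = 0.35
DEFAULT_THRESHOLDS_NS = (3.0, 5.0, 15.0)
DEFAULT_ION_PAIR_CUTOFF_NM = 0.45

_CHUNK_FRAMES = 256


class ContactSeries:
    """Per-replica boolean matrices (residues x frames) of ligand contact."""

    def __init__(
        self,
        series: Sequence[np.ndarray],
        frame_spacing_ns: float,
        replica_ids: Sequence[int] | None = None,
    ):
        mats = []
        for m in series:
            m = np.ascontiguousarray(m, dtype=bool)
            if m.ndim != 2:
                raise ValueError("each contact matrix must be residues x frames")
            m.flags.writeable = False
            mats.append(m)
        if not mats:
            raise ValueError("empty contact series")
        if len({m.shape[0] for m in mats}) != 1:
            raise ValueError("replicas disagree on residue count")
        self.series = tuple(mats)
        self.frame_spacing_ns = float(frame_spacing_ns)
        self.replica_ids = tuple(
            replica_ids if replica_ids is not None else range(len(mats))
        )

    @property
    def n_residues(self) -> int:
        return self.series[0].shape[0]

    @property
    def n_frames_total(self) -> int:
        return sum(m.shape[1] for m in self.series)


@dataclass(frozen=True)
class BindingEvent:
    """Maximal run of consecutive contact frames for one (replica, residue)."""

    replica_id: int
    residue_index: int  # 1-based
    start_frame: int
    end_frame: int  # inclusive
    duration_ns: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class BindingProfile:
    """Per-residue binding statistics at a set of stability thresholds."""

    residue_indices: np.ndarray  # 1-based
    total_frames: np.ndarray
    stable_frames: dict[float, np.ndarray]
    n_events: dict[float, np.ndarray]
    n_replicas_stable: dict[float, np.ndarray]
    thresholds_ns: tuple[float, ...]
    frame_spacing_ns: float

    def to_frame(self) -> pd.DataFrame:
        cols = {"residue": self.residue_indices, "total_frames": self.total_frames}
        for t in self.thresholds_ns:
            key = f"{t:g}"
            cols[f"stable_frames_{key}"] = self.stable_frames[t]
            cols[f"events_{key}"] = self.n_events[t]
            cols[f"replicas_{key}"] = self.n_replicas_stable[t]
        return pd.DataFrame(cols)


@dataclass
class RDFProfile:
    """Radial distribution function on uniform shells [r, r + bin_width)."""

    bin_centers_nm: np.ndarray
    g: np.ndarray
    bin_width_nm: float
    r_max_nm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.bin_centers_nm, "g": self.g})


# ---------------------------------------------------------------------------
# Distances and contact detection
# ---------------------------------------------------------------------------


def min_heavy_distance(
    frame: np.ndarray, ligand_idx: np.ndarray, residue_idx: np.ndarray
) -> float:
    """Minimum pairwise distance between two heavy-atom index sets in one frame."""
    if len(ligand_idx) == 0 or len(residue_idx) == 0:
        raise ValueError("atom selection empty after hydrogen exclusion")
    d = np.linalg.norm(
        frame[ligand_idx][:, None, :] - frame[residue_idx][None, :, :], axis=-1
    )
    return float(d.min())


def detect_contacts(
    ensemble: Ensemble, cutoff_nm: float = DEFAULT_CONTACT_CUTOFF_NM
) -> ContactSeries:
    """Boolean contact matrix per replica: contact[res, frame] is True when
    the minimum ligand-residue heavy-atom distance is strictly below the
    cutoff."""
    top = ensemble.topology
    lig = top.ligand_heavy_indices
    if len(lig) == 0:
        raise ValueError("ensemble has no ligand heavy atoms")
    res_idx = top.residue_heavy_indices
    for i, idx in enumerate(res_idx):
        if len(idx) == 0:
            raise ValueError(f"residue {i + 1} has no heavy atoms")
    # uniform residue sizes permit one vectorised reshape; otherwise pad
    sizes = {len(idx) for idx in res_idx}
    mats = []
    for rep in ensemble.replicas:
        nf = rep.n_frames
        out = np.empty((top.n_residues, nf), dtype=bool)
        if len(sizes) == 1:
            k = len(res_idx[0])
            flat = np.concatenate(res_idx)
            for s in range(0, nf, _CHUNK_FRAMES):
                e = min(s + _CHUNK_FRAMES, nf)
                pxyz = rep.xyz[s:e][:, flat]  # (c, n_res*k, 3)
                lxyz = rep.xyz[s:e][:, lig]  # (c, n_lig, 3)
                d = np.linalg.norm(pxyz[:, :, None, :] - lxyz[:, None, :, :], axis=-1)
                dmin = d.min(axis=2).reshape(e - s, top.n_residues, k).min(axis=2)
                out[:, s:e] = (dmin < cutoff_nm).T
        else:
            for f in range(nf):
                for r, idx in enumerate(res_idx):
                    out[r, f] = (
                        min_heavy_distance(rep.xyz[f], lig, idx) < cutoff_nm
                    )
        mats.append(out)
    return ContactSeries(
        mats, ensemble.frame_spacing_ns, [r.replica_id for r in ensemble.replicas]
    )


# ---------------------------------------------------------------------------
# Events and profiles
# ---------------------------------------------------------------------------


def _run_bounds(row: np.ndarray) -> np.ndarray:
    """(k, 2) array of [start, end] inclusive for maximal True runs."""
    padded = np.concatenate([[False], row, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2] - 1
    return np.stack([starts, ends], axis=1)


def extract_events(contacts: ContactSeries) -> list[BindingEvent]:
    """Maximal runs of consecutive contact frames per (replica, residue)."""
    spacing = contacts.frame_spacing_ns
    events = []
    for rid, mat in zip(contacts.replica_ids, contacts.series):
        for r in range(mat.shape[0]):
            for start, end in _run_bounds(mat[r]):
                events.append(
                    BindingEvent(rid, r + 1, int(start), int(end), (end - start + 1) * spacing)
                )
    return events


def _check_thresholds(thresholds_ns: Iterable[float], spacing: float) -> tuple[float, ...]:
    out = []
    for t in thresholds_ns:
        if t <= 0 or t < spacing:
            raise ValueError(f"threshold {t} ns must be positive and >= frame spacing")
        ratio = t / spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"threshold {t} ns is not a multiple of spacing {spacing} ns")
        out.append(float(t))
    return tuple(out)


def binding_profile(
    contacts: ContactSeries, thresholds_ns: Iterable[float] = DEFAULT_THRESHOLDS_NS
) -> BindingProfile:
    """Per-residue totals, stability-filtered frame counts, continuous-binding
    event counts, and the number of replicas where a stable event occurs."""
    thresholds = _check_thresholds(thresholds_ns, contacts.frame_spacing_ns)
    n_res = contacts.n_residues
    total = np.zeros(n_res, dtype=np.int64)
    for mat in contacts.series:
        total += mat.sum(axis=1)
    stable = {t: np.zeros(n_res, dtype=np.int64) for t in thresholds}
    nev = {t: np.zeros(n_res, dtype=np.int64) for t in thresholds}
    nrep = {t: np.zeros(n_res, dtype=np.int64) for t in thresholds}
    events = extract_events(contacts)
    by_rep_res: dict[float, set[tuple[int, int]]] = {t: set() for t in thresholds}
    for ev in events:
        r = ev.residue_index - 1
        for t in thresholds:
            if ev.duration_ns >= t:
                stable[t][r] += ev.n_frames
                nev[t][r] += 1
                by_rep_res[t].add((ev.replica_id, r))
    for t in thresholds:
        for _, r in by_rep_res[t]:
            nrep[t][r] += 1
    return BindingProfile(
        residue_indices=np.arange(1, n_res + 1),
        total_frames=total,
        stable_frames=stable,
        n_events=nev,
        n_replicas_stable=nrep,
        thresholds_ns=thresholds,
        frame_spacing_ns=contacts.frame_spacing_ns,
    )


def rank_binding_site(
    profile: BindingProfile,
    mode: str = "stable_frames",
    threshold_ns: float = 3.0,
    top_k: int = 5,
) -> list[tuple[int, float]]:
    """Residues sorted descending by the chosen statistic; ties broken by
    lower residue index. Zero-score residues are dropped (an all-zero
    profile yields an empty ranking with a warning)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if mode == "stable_frames":
        scores = profile.stable_frames[threshold_ns]
    elif mode == "n_events":
        scores = profile.n_events[threshold_ns]
    elif mode == "total_frames":
        scores = profile.total_frames
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    order = np.lexsort((profile.residue_indices, -scores.astype(np.float64)))
    ranked = [
        (int(profile.residue_indices[i]), float(scores[i]))
        for i in order
        if scores[i] > 0
    ]
    if not ranked:
        warnings.warn("all-zero binding profile: empty ranking", stacklevel=2)
    return ranked[:top_k]


def bound_fraction(contacts: ContactSeries) -> float:
    """Fraction of (replica, frame) pairs with at least one residue in contact."""
    bound = sum(int(mat.any(axis=0).sum()) for mat in contacts.series)
    return bound / contacts.n_frames_total


# ---------------------------------------------------------------------------
# Ion pairs and RDF
# ---------------------------------------------------------------------------


def count_ion_pairs(
    ensemble: Ensemble,
    protein_groups: Sequence[ChargedGroup] | None = None,
    ligand_groups: Sequence[ChargedGroup] | None = None,
    cutoff_nm: float = DEFAULT_ION_PAIR_CUTOFF_NM,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Count opposite-sign (protein group, ligand group) pairs whose minimum
    member-atom distance is below the cutoff.

    Returns (per-replica per-frame counts, histogram over pair counts).
    """
    top = ensemble.topology
    pg = list(protein_groups) if protein_groups is not None else top.protein_groups()
    lg = list(ligand_groups) if ligand_groups is not None else top.ligand_groups()
    if not pg or not lg:
        raise ValueError("need at least one charged group on each molecule")
    pairs = [
        (top.group_indices(p), top.group_indices(l))
        for p in pg
        for l in lg
        if p.sign * l.sign < 0
    ]
    per_replica = []
    for rep in ensemble.replicas:
        counts = np.zeros(rep.n_frames, dtype=np.int64)
        for pi, li in pairs:
            d = np.linalg.norm(
                rep.xyz[:, pi][:, :, None, :] - rep.xyz[:, li][:, None, :, :], axis=-1
            )
            counts += d.reshape(rep.n_frames, -1).min(axis=1) < cutoff_nm
        per_replica.append(counts)
    allc = np.concatenate(per_replica) if per_replica else np.zeros(0, dtype=np.int64)
    hist = np.bincount(allc, minlength=(allc.max() + 1) if len(allc) else 1)
    return per_replica, hist


def rdf(
    ensemble: Ensemble,
    center_idx: np.ndarray,
    around_idx: np.ndarray,
    bin_width_nm: float = 0.01,
    r_max_nm: float = 2.0,
) -> RDFProfile:
    """g(r) of ``around`` atoms in shells about ``center`` atoms.

    Normalisation uses the finite analysis sphere of radius ``r_max``: the
    ideal density is the mean pair concentration inside that sphere, so
    g -> 1 for uncorrelated placement within it. There is no periodic box
    in the data model, so the absolute scale is comparable only between
    profiles computed with the same r_max.
    """
    center_idx = np.asarray(center_idx, dtype=np.int64)
    around_idx = np.asarray(around_idx, dtype=np.int64)
    if len(center_idx) == 0 or len(around_idx) == 0:
        raise ValueError("empty atom selection")
    if bin_width_nm <= 0 or bin_width_nm >= r_max_nm:
        raise ValueError("need 0 < bin_width < r_max")
    n_bins = int(np.ceil(r_max_nm / bin_width_nm))
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts = np.zeros(n_bins, dtype=np.float64)
    n_obs = 0
    for rep in ensemble.replicas:
        d = np.linalg.norm(
            rep.xyz[:, center_idx][:, :, None, :] - rep.xyz[:, around_idx][:, None, :, :],
            axis=-1,
        ).ravel()
        d = d[d < edges[-1]]
        counts += np.histogram(d, bins=edges)[0]
        n_obs += rep.n_frames * len(center_idx)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    sphere_vol = 4.0 / 3.0 * np.pi * edges[-1] ** 3
    mean_density = counts.sum() / (n_obs * sphere_vol) if counts.sum() > 0 else np.nan
    with np.errstate(invalid="ignore"):
        g = counts / (n_obs * shell_vol * mean_density)
    g = np.nan_to_num(g, nan=0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(centers, g, bin_width_nm, float(edges[-1]))
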