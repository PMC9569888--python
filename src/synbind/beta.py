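"""Secondary-structure propensity, positional beta-hairpin scanning, and
residue-residue contact maps.

Secondary structure is assigned with the Kabsch-Sander hydrogen-bond model:
an electrostatic bond energy computed from backbone N, H, C, O positions
(amide H placed geometrically when absent), a -0.5 kcal/mol bond cutoff,
and the standard pattern rules for helix (two consecutive 4-turns), strand
(ladders of >= 2 consecutive bridges), isolated bridge, and turn. The
reduced alphabet is {H, E, B, T, C} with priority H > E > B > T > C.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _geometry as geom
from .core import Ensemble, RegionSpec, Topology

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_COUPLING = 27.888  # 0.084 e^2 * 332, kcal/mol * angstrom
NH_BOND_NM = 0.101
HAIRPIN_WINDOW = 12
DEFAULT_RMSD_THRESHOLD_NM = 0.25

SS_SYMBOLS = ("H", "E", "B", "T", "C")


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure
# ---------------------------------------------------------------------------


def _amide_hydrogens(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Geometric amide H for residues 2..n: N-H along the bisector of the
    N->C(prev) and N->CA directions, 0.101 nm. First residue has no donor
    (NaN)."""
    u1 = N[..., 1:, :] - C[..., :-1, :]
    u1 = u1 / np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = N[..., 1:, :] - CA[..., 1:, :]
    u2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    b = u1 + u2
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    H = np.full(N.shape, np.nan)
    H[..., 1:, :] = N[..., 1:, :] + NH_BOND_NM * b
    return H


def _hbond_co(frames_bb: np.ndarray) -> np.ndarray:
    """Boolean (..., n_res, n_res) matrix: [i, j] True when the carbonyl of
    residue i accepts a hydrogen bond from the amide of residue j
    (Kabsch-Sander energy < -0.5 kcal/mol)."""
    N, CA, C, O = (frames_bb[..., k, :] for k in range(4))
    H = _amide_hydrogens(N, CA, C)
    n_res = N.shape[-2]

    def dist(a, b):  # a: acceptor-site atoms, b: donor-site atoms
        return np.linalg.norm(a[..., :, None, :] - b[..., None, :, :], axis=-1)

    # distances in nm; the 332 coupling expects angstroms, hence /10
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = lambda d: 1.0 / (10.0 * d)  # noqa: E731
        energy = _KS_COUPLING * (
            inv(dist(O, N)) + inv(dist(C, H)) - inv(dist(O, H)) - inv(dist(C, N))
        )
    hb = energy < HBOND_ENERGY_CUTOFF
    hb &= ~np.isnan(energy)
    i = np.arange(n_res)
    near = np.abs(i[:, None] - i[None, :]) < 2
    hb &= ~near
    return hb


def _shift2(mat: np.ndarray, di: int, dj: int) -> np.ndarray:
    """mat shifted so out[..., i, j] = mat[..., i+di, j+dj] (False outside)."""
    out = np.zeros_like(mat)
    n = mat.shape[-1]
    si = slice(max(0, -di), min(n, n - di))
    sj = slice(max(0, -dj), min(n, n - dj))
    ti = slice(max(0, di), min(n, n + di))
    tj = slice(max(0, dj), min(n, n + dj))
    out[..., si, sj] = mat[..., ti, tj]
    return out


def _assign_from_hbonds(hb: np.ndarray) -> np.ndarray:
    """Symbols (..., n_res) from the carbonyl->amide bond matrix."""
    n_res = hb.shape[-1]
    shape = hb.shape[:-2] + (n_res,)
    helix = np.zeros(shape, dtype=bool)
    turn = np.zeros(shape, dtype=bool)

    turn_n = {}
    for n in (3, 4, 5):
        tn = np.zeros(shape, dtype=bool)
        idx = np.arange(n_res - n)
        tn[..., idx] = hb[..., idx, idx + n]
        turn_n[n] = tn
        for k in range(1, n):  # bracketed residues are turn
            turn[..., idx + k] |= tn[..., idx]
    # two consecutive 4-turns (at i and i+1) make residues i+1..i+4 helical
    t4 = turn_n[4]
    core = t4[..., :-1] & t4[..., 1:]
    for k in range(4):
        helix[..., 1 + k :] |= core[..., : n_res - 1 - k]

    par = (_shift2(hb, -1, 0) & np.swapaxes(_shift2(hb, 0, 1), -1, -2)) | (
        np.swapaxes(_shift2(hb, -1, 0), -1, -2) & _shift2(hb, 0, 1)
    )
    anti = (hb & np.swapaxes(hb, -1, -2)) | (
        _shift2(hb, -1, 1) & np.swapaxes(_shift2(hb, -1, 1), -1, -2)
    )
    i = np.arange(n_res)
    valid = (np.abs(i[:, None] - i[None, :]) > 2) & (i[:, None] > 0) & (i[:, None] < n_res - 1)
    valid &= (i[None, :] > 0) & (i[None, :] < n_res - 1)
    par &= valid
    anti &= valid
    ladder = (par & (_shift2(par, 1, 1) | _shift2(par, -1, -1))) | (
        anti & (_shift2(anti, 1, -1) | _shift2(anti, -1, 1))
    )
    strand = ladder.any(axis=-1)
    bridge = (par | anti).any(axis=-1) & ~strand

    symbols = np.full(shape, "C", dtype="U1")
    symbols[turn] = "T"
    symbols[bridge] = "B"
    symbols[strand] = "E"
    symbols[helix] = "H"
    return symbols


def assign_secondary_structure(frame: np.ndarray, topology: Topology) -> np.ndarray:
    """Per-residue symbols in {H, E, B, T, C} for one frame (or a batch of
    frames with a leading dimension)."""
    bb = topology.backbone_indices
    if (bb < 0).any():
        missing = int(np.argwhere((bb < 0).any(axis=1))[0, 0]) + 1
        raise ValueError(f"residue {missing} missing a backbone atom")
    frames_bb = np.asarray(frame)[..., bb, :]  # (..., n_res, 4, 3)
    return _assign_from_hbonds(_hbond_co(frames_bb))


def secondary_structure(
    ensemble: Ensemble, frame_stride: int = 1, chunk: int = 64
) -> list[np.ndarray]:
    """Secondary-structure symbols per replica: arrays (n_frames_sampled, n_res)."""
    out = []
    for rep in ensemble.replicas:
        frames = rep.xyz[::frame_stride]
        rows = [
            assign_secondary_structure(frames[s : s + chunk], ensemble.topology)
            for s in range(0, len(frames), chunk)
        ]
        out.append(np.concatenate(rows, axis=0))
    return out


def to_simplified(symbols: np.ndarray) -> np.ndarray:
    """Map {H,E,B,T,C} onto the 3-letter alphabet {H, E, C} (B counts as E)."""
    out = np.full(symbols.shape, "C", dtype="U1")
    out[symbols == "H"] = "H"
    out[(symbols == "E") | (symbols == "B")] = "E"
    return out


def beta_element_fraction(
    assignments: list[np.ndarray] | np.ndarray,
    region: RegionSpec,
    min_run: int = 4,
    per_residue: bool = False,
):
    """Fraction of frames containing at least one run of >= min_run
    consecutive strand (E) residues inside the region.

    With ``per_residue=True``, returns instead the fraction of
    (frame, region residue) cells that belong to such runs.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    mats = assignments if isinstance(assignments, list) else [assignments]
    hits = 0
    cells = 0
    total = 0
    width = region.end - region.start + 1
    if width < min_run:
        raise ValueError("region narrower than min_run")
    for mat in mats:
        sub = mat[:, region.start - 1 : region.end] == "E"
        padded = np.zeros((sub.shape[0], sub.shape[1] + 2), dtype=np.int8)
        padded[:, 1:-1] = sub
        d = np.diff(padded, axis=1)
        for row_d, row_e in zip(d, sub):
            starts = np.flatnonzero(row_d == 1)
            ends = np.flatnonzero(row_d == -1)
            lengths = ends - starts
            if (lengths >= min_run).any():
                hits += 1
                cells += int(lengths[lengths >= min_run].sum())
        total += sub.shape[0]
        # cells accumulated above; frame count in total
    if per_residue:
        return cells / (total * width)
    return hits / total


# ---------------------------------------------------------------------------
# Hairpin scan
# ---------------------------------------------------------------------------


@dataclass
class HairpinProfile:
    """Per-position probability that a sliding 12-residue window lies within
    an RMSD threshold of the reference hairpin."""

    positions: np.ndarray  # window centre residues (1-based)
    probability: np.ndarray
    rmsd_threshold_nm: float
    window_length: int = HAIRPIN_WINDOW

    def peak(self) -> tuple[int, float]:
        i = int(np.argmax(self.probability))
        return int(self.positions[i]), float(self.probability[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "probability": self.probability})


def hairpin_rmsd(window_coords: np.ndarray, reference_coords: np.ndarray):
    """Minimal RMSD (nm) after optimal rigid superposition (Kabsch, no
    reflection). Accepts batches in the leading dimensions."""
    return geom.superposed_rmsd(window_coords, reference_coords)


def _window_backbone(ensemble: Ensemble, start_res: int, ca_only: bool) -> list[np.ndarray]:
    top = ensemble.topology
    res0 = start_res - 1
    if ca_only:
        idx = top.ca_indices[res0 : res0 + HAIRPIN_WINDOW]
    else:
        idx = top.backbone_indices[res0 : res0 + HAIRPIN_WINDOW].ravel()
    return [rep.xyz[:, idx] for rep in ensemble.replicas]


def hairpin_probability_profile(
    ensemble: Ensemble,
    reference_coords: np.ndarray,
    region: RegionSpec,
    rmsd_threshold_nm: float = DEFAULT_RMSD_THRESHOLD_NM,
    ca_only: bool = False,
) -> HairpinProfile:
    """Slide a 12-residue window (step 1) across the region; at each position
    the probability is the fraction of frames whose backbone RMSD to the
    reference hairpin is below the threshold."""
    top = ensemble.topology
    region.validate(top.n_residues)
    if region.end - region.start + 1 < HAIRPIN_WINDOW:
        raise ValueError(f"region narrower than {HAIRPIN_WINDOW} residues")
    ref = np.asarray(reference_coords, dtype=np.float64)
    expected = HAIRPIN_WINDOW if ca_only else 4 * HAIRPIN_WINDOW
    if ref.shape != (expected, 3):
        raise ValueError(f"reference must be ({expected}, 3), got {ref.shape}")
    starts = np.arange(region.start, region.end - HAIRPIN_WINDOW + 2)
    positions = starts + 5  # centre residue of the 12-residue window
    prob = np.empty(len(starts))
    total = ensemble.n_frames_total
    for k, s in enumerate(starts):
        below = 0
        for wxyz in _window_backbone(ensemble, int(s), ca_only):
            r = hairpin_rmsd(wxyz, ref)
            below += int((r < rmsd_threshold_nm).sum())
        prob[k] = below / total
    return HairpinProfile(positions, prob, rmsd_threshold_nm)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Symmetric residue-pair contact frequencies in [0, 1]."""

    frequencies: np.ndarray
    d_min_nm: float
    d_max_nm: float
    exclude_window: int
    n_frames: int

    def params(self) -> tuple[float, float, int]:
        return (self.d_min_nm, self.d_max_nm, self.exclude_window)


def _residue_starts(topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous heavy-atom segments per residue for reduceat reduction."""
    heavy = topology.protein_heavy_indices
    res_of = np.array([topology.atoms[i].residue_index for i in heavy])
    if not np.all(np.diff(res_of) >= 0):
        raise ValueError("atoms are not ordered by residue")
    starts = np.flatnonzero(np.diff(np.concatenate([[0], res_of])) > 0)
    return heavy, starts


def contact_map(
    ensemble: Ensemble,
    frame_stride_ns: float = 1.0,
    d_min_nm: float = 0.15,
    d_max_nm: float = 0.5,
    exclude_window: int = 3,
) -> ContactMap:
    """Residue-residue contact frequencies: the fraction of sampled frames in
    which the minimum heavy-atom distance falls strictly between d_min and
    d_max. Frames are sampled by striding at ``frame_stride_ns``; pairs with
    |i - j| < exclude_window are zeroed."""
    if d_min_nm >= d_max_nm:
        raise ValueError("d_min must be < d_max")
    spacing = ensemble.frame_spacing_ns
    step = frame_stride_ns / spacing
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError(
            f"stride {frame_stride_ns} ns is not a positive multiple of spacing {spacing} ns"
        )
    step = int(round(step))
    top = ensemble.topology
    heavy, starts = _residue_starts(top)
    n_res = top.n_residues
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    n_frames = 0
    for rep in ensemble.replicas:
        for f in range(0, rep.n_frames, step):
            xyz = rep.xyz[f, heavy]
            d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
            dmin = np.minimum.reduceat(np.minimum.reduceat(d, starts, axis=0), starts, axis=1)
            counts += (dmin > d_min_nm) & (dmin < d_max_nm)
            n_frames += 1
    freq = counts / n_frames
    i = np.arange(n_res)
    freq[np.abs(i[:, None] - i[None, :]) < exclude_window] = 0.0
    return ContactMap(freq, d_min_nm, d_max_nm, exclude_window, n_frames)


def differential_contact_map(map_a: ContactMap, map_b: ContactMap) -> np.ndarray:
    """Elementwise map_a - map_b (antisymmetric under argument swap). Both
    maps must share distance band and exclusion window."""
    if map_a.params() != map_b.params():
        raise ValueError(
            f"contact-map parameters differ: {map_a.params()} vs {map_b.params()}"
        )
    if map_a.frequencies.shape != map_b.frequencies.shape:
        raise ValueError("contact maps differ in size")
    return map_a.frequencies - map_b.frequencies
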