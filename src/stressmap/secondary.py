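"""Minimal Kabsch-Sander hydrogen bonding and beta-strand assignment.

Only the extended (E) state matters for the analyses in this package, so the
assignment implements exactly the backbone H-bond energy

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

(a bond exists iff E < -0.5), the parallel / antiparallel bridge patterns
built from those bonds, and the ladder rule (>= 2 consecutive bridges) that
promotes bridge residues to strand residues.  Helices, turns, bends and the
isolated-bridge state are all mapped to "other".  Amide hydrogens, absent
from a heavy-atom model, are reconstructed on the donor nitrogen along the
previous residue's C=O direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .structure_io import StrandMap, Structure, Trajectory
from .superposition import mean_sem

__all__ = [
    "HBondParams",
    "place_amide_hydrogens",
    "hbond_energy",
    "assign_beta",
    "beta_occupancy",
    "strand_occupancy_change",
]

#: Kabsch-Sander coupling constant q1*q2*f in kcal*A/mol.
KS_COUPLING = 27.888
#: H-bond energy cutoff, kcal/mol (bond iff E strictly below).
KS_CUTOFF = -0.5
#: Reconstructed N-H bond length, Angstrom.
NH_BOND = 1.00
#: Energy assigned on a steric clash (any of the four distances < 0.5 A).
KS_CLASH_ENERGY = -9.9
#: CA-CA prefilter distance; the KS energy at 9 A is far above the cutoff.
CA_PREFILTER = 9.0
#: A peptide C-N bond longer than this is treated as a chain break.
PEPTIDE_BREAK = 2.5


@dataclass(frozen=True)
class HBondParams:
    coupling: float = KS_COUPLING
    cutoff: float = KS_CUTOFF
    nh_bond: float = NH_BOND

    def __post_init__(self) -> None:
        if not self.cutoff < 0:
            raise ValueError("energy cutoff must be negative")


# ---------------------------------------------------------------------------
# Backbone bookkeeping
# ---------------------------------------------------------------------------

class _Backbone:
    """Per-residue backbone coordinate arrays for one frame."""

    def __init__(self, structure: Structure, coords: np.ndarray):
        resids = structure.residue_ids
        n = resids.size
        self.resids = resids
        self.n = n
        self.atoms = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
        self.has = {name: np.zeros(n, bool) for name in ("N", "CA", "C", "O")}
        self.chain = np.empty(n, dtype=object)
        self.is_pro = np.zeros(n, bool)
        res_index = {int(r): k for k, r in enumerate(resids)}
        for a in range(structure.n_atoms):
            nm = str(structure.names[a])
            if nm in ("N", "CA", "C", "O"):
                k = res_index[int(structure.resseq[a])]
                self.atoms[nm][k] = coords[a]
                self.has[nm][k] = True
        for k, r in enumerate(resids):
            idx = structure.atoms_of_residue(int(r))
            self.chain[k] = str(structure.chains[idx[0]])
            self.is_pro[k] = str(structure.resnames[idx[0]]).upper() == "PRO"
        self.complete = (self.has["N"] & self.has["CA"]
                         & self.has["C"] & self.has["O"])

    def prev_index(self, k: int) -> Optional[int]:
        """Index of the sequence-predecessor residue, or None at chain starts.

        Requires consecutive numbering, the same chain id and a peptide-bond
        C-N distance below the break threshold.
        """
        if k == 0:
            return None
        if self.resids[k - 1] != self.resids[k] - 1:
            return None
        if self.chain[k - 1] != self.chain[k]:
            return None
        if not (self.has["C"][k - 1] and self.has["N"][k]):
            return None
        d = np.linalg.norm(self.atoms["C"][k - 1] - self.atoms["N"][k])
        if d > PEPTIDE_BREAK:
            return None
        return k - 1


def place_amide_hydrogens(
    structure: Structure,
    coords: Optional[np.ndarray] = None,
    params: HBondParams = HBondParams(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Reconstructed backbone amide H per residue.

    H sits 1.00 A from N along the previous residue's C->O direction
    reversed (i.e. along unit(C_prev - O_prev)).  Chain-initial residues and
    prolines carry no H.  Returns (h_coords (n_res, 3), has_h (n_res,)).
    """
    if coords is None:
        coords = structure.coords
    bb = _Backbone(structure, np.asarray(coords, float))
    h = np.full((bb.n, 3), np.nan)
    has_h = np.zeros(bb.n, bool)
    for k in range(bb.n):
        if bb.is_pro[k] or not bb.has["N"][k]:
            continue
        p = bb.prev_index(k)
        if p is None:
            continue
        if not (bb.has["C"][p] and bb.has["O"][p]):
            warnings.warn(f"residue {int(bb.resids[p])} lacks backbone C/O; "
                          f"H skipped for {int(bb.resids[k])}", stacklevel=2)
            continue
        direction = bb.atoms["C"][p] - bb.atoms["O"][p]
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        h[k] = bb.atoms["N"][k] + params.nh_bond * direction / norm
        has_h[k] = True
    return h, has_h


def hbond_energy(
    donor_n: np.ndarray,
    donor_h: np.ndarray,
    acceptor_c: np.ndarray,
    acceptor_o: np.ndarray,
    params: HBondParams = HBondParams(),
) -> float:
    """Kabsch-Sander electrostatic H-bond energy for one donor/acceptor pair.

    Distances below 0.5 A flag a clash and return the conventional -9.9.
    """
    r_on = float(np.linalg.norm(donor_n - acceptor_o))
    r_ch = float(np.linalg.norm(donor_h - acceptor_c))
    r_oh = float(np.linalg.norm(donor_h - acceptor_o))
    r_cn = float(np.linalg.norm(donor_n - acceptor_c))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        warnings.warn("steric clash in H-bond geometry; energy set to -9.9",
                      stacklevel=2)
        return KS_CLASH_ENERGY
    return params.coupling * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(bb: _Backbone, h: np.ndarray, has_h: np.ndarray,
                  params: HBondParams) -> np.ndarray:
    """Boolean (n, n): entry [i, j] true iff N-H of i donates to C=O of j."""
    n = bb.n
    hb = np.zeros((n, n), bool)
    ca_ok = bb.has["CA"]
    idx_ok = np.flatnonzero(ca_ok)
    if idx_ok.size == 0:
        return hb
    tree = cKDTree(bb.atoms["CA"][idx_ok])
    pairs = tree.query_pairs(CA_PREFILTER, output_type="ndarray")
    for a_loc, b_loc in pairs:
        i, j = int(idx_ok[a_loc]), int(idx_ok[b_loc])
        for don, acc in ((i, j), (j, i)):
            if abs(don - acc) < 1:
                continue
            if not (has_h[don] and bb.has["C"][acc] and bb.has["O"][acc]
                    and bb.has["N"][don]):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e = hbond_energy(bb.atoms["N"][don], h[don],
                                 bb.atoms["C"][acc], bb.atoms["O"][acc], params)
            if e < params.cutoff:
                hb[don, acc] = True
    return hb


def _adjacent(bb: _Backbone, a: int, b: int) -> bool:
    """Whether residues at indices a, b are chain-contiguous (a = b - 1)."""
    if a < 0 or b >= bb.n:
        return False
    return bb.prev_index(b) == a


def assign_beta(
    structure: Structure,
    coords: Optional[np.ndarray] = None,
    params: HBondParams = HBondParams(),
) -> Dict[int, str]:
    """Beta-strand (E) assignment per residue for one frame.

    A bridge between non-adjacent residues i, j exists when the
    Kabsch-Sander bond pattern is parallel
    [Hb(i-1 -> j) and Hb(j -> i+1)] or [Hb(j-1 -> i) and Hb(i -> j+1)]
    or antiparallel
    [Hb(i -> j) and Hb(j -> i)] or [Hb(i-1 -> j+1) and Hb(j-1 -> i+1)].
    Residues in ladders of >= 2 consecutive bridges are labelled E; isolated
    bridges are not.  Residues with incomplete backbone are "other".
    """
    if coords is None:
        coords = structure.coords
    bb = _Backbone(structure, np.asarray(coords, float))
    h, has_h = place_amide_hydrogens(structure, coords, params)
    hb = _hbond_matrix(bb, h, has_h, params)
    n = bb.n

    def bond(a: int, b: int) -> bool:
        if a < 0 or b < 0 or a >= n or b >= n:
            return False
        return bool(hb[a, b])

    parallel: set = set()
    antiparallel: set = set()
    for i in range(n):
        for j in range(i + 3, n):
            im1_ok = _adjacent(bb, i - 1, i)
            ip1_ok = _adjacent(bb, i, i + 1)
            jm1_ok = _adjacent(bb, j - 1, j)
            jp1_ok = _adjacent(bb, j, j + 1)
            if ((im1_ok and ip1_ok and bond(i - 1, j) and bond(j, i + 1))
                    or (jm1_ok and jp1_ok and bond(j - 1, i) and bond(i, j + 1))):
                parallel.add((i, j))
            if ((bond(i, j) and bond(j, i))
                    or (im1_ok and jp1_ok and jm1_ok and ip1_ok
                        and bond(i - 1, j + 1) and bond(j - 1, i + 1))):
                antiparallel.add((i, j))

    is_e = np.zeros(n, bool)
    for bridges, step in ((parallel, +1), (antiparallel, -1)):
        for (i, j) in bridges:
            nxt = (i + 1, j + step)
            if nxt in bridges and _adjacent(bb, i, i + 1) and (
                    _adjacent(bb, min(j, j + step), max(j, j + step))):
                for (a, b) in ((i, j), nxt):
                    is_e[a] = True
                    is_e[b] = True

    codes: Dict[int, str] = {}
    for k, r in enumerate(bb.resids):
        codes[int(r)] = "E" if (is_e[k] and bb.complete[k]) else "-"
    return codes


# ---------------------------------------------------------------------------
# Occupancy over trajectories
# ---------------------------------------------------------------------------

def beta_occupancy(traj: Trajectory, params: HBondParams = HBondParams(),
                   frame_stride: int = 1) -> Dict[int, float]:
    """Percentage of (sampled) frames in which each residue is labelled E."""
    if traj.n_frames < 1:
        raise DegenerateInputError("empty trajectory")
    frames = range(0, traj.n_frames, frame_stride)
    counts: Dict[int, int] = {}
    total = 0
    for k in frames:
        codes = assign_beta(traj.topology, traj.frames[k], params)
        total += 1
        for res, code in codes.items():
            if code == "E":
                counts[res] = counts.get(res, 0) + 1
    return {int(r): 100.0 * counts.get(int(r), 0) / total
            for r in traj.topology.residue_ids}


def _strand_occupancies(trajs: Sequence[Trajectory], strand_map: StrandMap,
                        params: HBondParams, frame_stride: int) -> np.ndarray:
    """(n_replicates, n_strands) mean E-occupancy %, residue-averaged."""
    labels = list(strand_map.strands)
    out = np.empty((len(trajs), len(labels)))
    for r, traj in enumerate(trajs):
        occ = beta_occupancy(traj, params, frame_stride)
        for s, label in enumerate(labels):
            lo, hi = strand_map.strands[label]
            vals = [occ[res] for res in range(lo, hi + 1) if res in occ]
            out[r, s] = float(np.mean(vals)) if vals else np.nan
    return out


def strand_occupancy_change(
    stress: Sequence[Trajectory],
    reference: Sequence[Trajectory],
    strand_map: StrandMap,
    params: HBondParams = HBondParams(),
    relative: bool = True,
    frame_stride: int = 1,
) -> pd.DataFrame:
    """Per-strand beta-occupancy change between conditions.

    ``relative`` (default) reports 100 * (occ_stress - occ_ref) / occ_ref per
    replicate pairing; with ``relative=False`` the change is the absolute
    percentage-point difference.  Strands never beta in the reference yield a
    missing (NaN) relative change with a warning, not +/- infinity.
    Columns: strand, domain, occ_ref, occ_stress, change, sem, n.
    """
    labels = list(strand_map.strands)
    occ_s = _strand_occupancies(stress, strand_map, params, frame_stride)
    occ_r = _strand_occupancies(reference, strand_map, params, frame_stride)
    n = min(occ_s.shape[0], occ_r.shape[0])
    if occ_s.shape[0] != occ_r.shape[0]:
        warnings.warn("replicate counts differ between conditions; pairing "
                      f"first {n} of each", stacklevel=2)
    occ_s, occ_r = occ_s[:n], occ_r[:n]

    rows = []
    for s, label in enumerate(labels):
        ref_vals = occ_r[:, s]
        stress_vals = occ_s[:, s]
        if relative:
            if np.any(ref_vals == 0):
                warnings.warn(f"strand {label} has zero reference occupancy in "
                              f"some replicate; relative change undefined",
                              stacklevel=2)
                change = np.full(n, np.nan)
            else:
                change = 100.0 * (stress_vals - ref_vals) / ref_vals
        else:
            change = stress_vals - ref_vals
        valid = change[np.isfinite(change)]
        if valid.size:
            cmean, csem = mean_sem(valid)
        else:
            cmean, csem = np.nan, np.nan
        rows.append({
            "strand": label,
            "domain": strand_map.domain_of_strand(label),
            "occ_ref": float(np.nanmean(ref_vals)),
            "occ_stress": float(np.nanmean(stress_vals)),
            "change": float(cmean) if np.ndim(cmean) == 0 else cmean,
            "sem": float(csem) if np.ndim(csem) == 0 else csem,
            "n": int(n),
            "mode": "relative" if relative else "absolute",
        })
    return pd.DataFrame(rows)
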