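"""Native-contact extraction and soft-cutoff contact fractions.

A native contact is a heavy-atom pair within ``ref_radius`` in the reference
structure.  Along a trajectory the fraction of native contacts retained is
scored with the smooth logistic switch

    Q = (1/N) * sum_ij 1 / (1 + exp[beta * (r_ij - lam * r0_ij)])

so a pair at its native distance counts ~1, a pair stretched past
``lam * r0`` counts ~0, and the crossover is soft rather than a hard
threshold.  The defaults beta = 5 / A, lam = 1.8, ref_radius = 4.5 A are the
standard soft-cutoff constants for heavy-atom contact analysis and are
config-exposed, never hard-coded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, RegionError, ShapeError
from .structure_io import DomainMap, Structure, Trajectory, select_region

__all__ = [
    "ContactParams",
    "ContactSet",
    "QSeries",
    "build_reference_contacts",
    "soft_cut_fraction",
    "contact_series",
    "residue_fraction",
    "count_total_contacts",
]


@dataclass(frozen=True)
class ContactParams:
    """Soft-cutoff parameters.

    beta : logistic steepness, 1/Angstrom
    lam : dimensionless scale on the native distance (crossover at lam*r0)
    ref_radius : contact-definition radius in the reference, Angstrom
    min_seq_sep : minimum |res_i - res_j| for intra-region pairs; interfaces
        keep all cross-domain pairs (sequence separation is meaningless
        across chains)
    """

    beta: float = 5.0
    lam: float = 1.8
    ref_radius: float = 4.5
    min_seq_sep: int = 3

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not self.lam >= 1:
            raise ValueError("lam must be >= 1")
        if not self.ref_radius > 0:
            raise ValueError("ref_radius must be > 0")


@dataclass
class ContactSet:
    """Reference atom pairs (i < j) with native distances r0, plus residue ids."""

    region: str
    i: np.ndarray                # (m,) atom indices into the topology
    j: np.ndarray
    r0: np.ndarray               # (m,) native distances, Angstrom
    res_i: np.ndarray            # (m,) residue numbers
    res_j: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.r0)
        for name in ("i", "j", "r0", "res_i", "res_j"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (m,):
                raise ShapeError(f"ContactSet field {name} misaligned")
            setattr(self, name, arr)

    @property
    def n_pairs(self) -> int:
        return int(len(self.r0))


@dataclass
class QSeries:
    region: str
    times_ns: np.ndarray
    q: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.times_ns = np.asarray(self.times_ns, float)
        if self.q.shape != self.times_ns.shape:
            raise ShapeError("times and q must align")
        if self.q.size and (self.q.min() < -1e-12 or self.q.max() > 1 + 1e-12):
            raise ShapeError("Q must lie in [0, 1]")


# ---------------------------------------------------------------------------

def build_reference_contacts(
    reference: Structure,
    region: str,
    domain_map: DomainMap,
    params: ContactParams = ContactParams(),
) -> ContactSet:
    """All heavy-atom pairs within ``ref_radius`` in the reference.

    Intra-domain sets exclude pairs closer than ``min_seq_sep`` in sequence;
    interface sets keep every cross-domain pair.
    """
    sel = select_region(reference, domain_map, region)
    coords = reference.coords
    resseq = reference.resseq
    if isinstance(sel, tuple):
        idx_a, idx_b = sel
        if idx_a.size == 0 or idx_b.size == 0:
            raise RegionError(f"interface {region} has an empty side")
        tree_b = cKDTree(coords[idx_b])
        pairs_i, pairs_j = [], []
        hits = tree_b.query_ball_point(coords[idx_a], params.ref_radius)
        for a_local, blist in enumerate(hits):
            for b_local in blist:
                pairs_i.append(idx_a[a_local])
                pairs_j.append(idx_b[b_local])
        i = np.asarray(pairs_i, dtype=int)
        j = np.asarray(pairs_j, dtype=int)
    else:
        if sel.size == 0:
            raise RegionError(f"region {region} is empty in the reference")
        tree = cKDTree(coords[sel])
        local_pairs = np.array(sorted(tree.query_pairs(params.ref_radius)), dtype=int)
        if local_pairs.size == 0:
            i = j = np.empty(0, dtype=int)
        else:
            i = sel[local_pairs[:, 0]]
            j = sel[local_pairs[:, 1]]
            keep = np.abs(resseq[i] - resseq[j]) >= params.min_seq_sep
            i, j = i[keep], j[keep]
    # normalise orientation i < j and drop duplicates
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    order = np.lexsort((hi, lo))
    lo, hi = lo[order], hi[order]
    r0 = np.linalg.norm(coords[lo] - coords[hi], axis=1)
    return ContactSet(region, lo, hi, r0, resseq[lo], resseq[hi])


def _pair_distances(frame: np.ndarray, contacts: ContactSet) -> np.ndarray:
    return np.linalg.norm(frame[contacts.i] - frame[contacts.j], axis=1)


def _soft_scores(r: np.ndarray, r0: np.ndarray, params: ContactParams) -> np.ndarray:
    arg = np.clip(params.beta * (r - params.lam * r0), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(arg))


def soft_cut_fraction(
    frame: np.ndarray,
    contacts: ContactSet,
    params: ContactParams = ContactParams(),
) -> float:
    """Soft-cutoff native-contact fraction Q of one frame."""
    if contacts.n_pairs == 0:
        raise DegenerateInputError(
            f"contact set for {contacts.region} is empty; Q is undefined")
    frame = np.asarray(frame, float)
    if contacts.i.max() >= frame.shape[0] or contacts.j.max() >= frame.shape[0]:
        raise ShapeError("contact atom index out of range for this frame")
    return float(_soft_scores(_pair_distances(frame, contacts), contacts.r0,
                              params).mean())


def contact_series(
    traj: Trajectory,
    contacts: ContactSet,
    params: ContactParams = ContactParams(),
    replicate: int = 0,
) -> QSeries:
    """Q per frame, in frame order."""
    if contacts.n_pairs == 0:
        raise DegenerateInputError(
            f"contact set for {contacts.region} is empty; Q is undefined")
    if contacts.i.max() >= traj.topology.n_atoms:
        raise ShapeError("contact atom indices do not fit this topology")
    q = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        q[k] = soft_cut_fraction(traj.frames[k], contacts, params)
    return QSeries(contacts.region, traj.times_ns, q, replicate)


def residue_fraction(
    frame: np.ndarray,
    contacts: ContactSet,
    params: ContactParams = ContactParams(),
) -> Dict[int, float]:
    """Per-residue mean soft-cutoff score over all pairs involving the residue.

    Residues with no native pairs are absent from the map.
    """
    if contacts.n_pairs == 0:
        raise DegenerateInputError("empty contact set")
    scores = _soft_scores(_pair_distances(np.asarray(frame, float), contacts),
                          contacts.r0, params)
    sums: Dict[int, float] = {}
    counts: Dict[int, int] = {}
    for res_arr in (contacts.res_i, contacts.res_j):
        for res, s in zip(res_arr, scores):
            res = int(res)
            sums[res] = sums.get(res, 0.0) + float(s)
            counts[res] = counts.get(res, 0) + 1
    return {res: sums[res] / counts[res] for res in sums}


def count_total_contacts(
    frame: np.ndarray,
    region_pair: Tuple[np.ndarray, np.ndarray],
    cutoff: float = 6.0,
) -> int:
    """Number of cross-set heavy-atom pairs within ``cutoff`` (native and
    non-native alike)."""
    idx_a, idx_b = (np.asarray(x, dtype=int) for x in region_pair)
    if np.intersect1d(idx_a, idx_b).size:
        raise ShapeError("the two atom sets overlap")
    frame = np.asarray(frame, float)
    tree_b = cKDTree(frame[idx_b])
    hits = tree_b.query_ball_point(frame[idx_a], cutoff)
    return int(sum(len(h) for h in hits))
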