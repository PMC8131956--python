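"""Salt-bridge detection, occurrence statistics and per-region counting.

A salt bridge is scored at residue level: an (acidic, basic) residue pair is
"formed" in a frame when ANY qualifying side-chain O-N atom pair is within
the cutoff (3.2 A between carboxylate O and amine/guanidinium N by default).
Occurrence is the percentage of frames in which the pair is formed; replicate
tables are aggregated as mean +/- SEM and thresholded on the replicate mean
(10% by default).  Histidine participates only when explicitly enabled,
since its charge is protonation-state dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .structure_io import DomainMap, Structure, Trajectory

__all__ = [
    "SaltBridgeParams",
    "OccurrenceTable",
    "detect_salt_bridges",
    "bridge_occurrence",
    "aggregate_occurrence",
    "count_by_region",
]

_ACIDIC_ATOMS: Dict[str, Tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
_BASIC_ATOMS: Dict[str, Tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
_HIS_ATOMS: Tuple[str, ...] = ("ND1", "NE2")


@dataclass(frozen=True)
class SaltBridgeParams:
    cutoff: float = 3.2          # Angstrom, O-N distance
    include_his: bool = False    # treat His imidazole N as basic

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class OccurrenceTable:
    """Occurrence table: one row per (acidic, basic) residue pair.

    ``table`` columns: acid_res, base_res, rep0..rep{n-1}, mean, sem.
    Rows are retained iff mean >= ``threshold`` (percent).
    """

    table: pd.DataFrame
    threshold: float = 10.0
    n_replicates: int = field(default=0)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        return [(int(a), int(b)) for a, b in
                zip(self.table["acid_res"], self.table["base_res"])]


def _charged_atom_indices(structure: Structure, params: SaltBridgeParams):
    """(acid_idx, acid_res), (base_idx, base_res) heavy-atom index arrays."""
    names = structure.names
    resnames = structure.resnames
    acid_mask = np.zeros(structure.n_atoms, bool)
    base_mask = np.zeros(structure.n_atoms, bool)
    for k in range(structure.n_atoms):
        rn = str(resnames[k])
        nm = str(names[k])
        if rn in _ACIDIC_ATOMS and nm in _ACIDIC_ATOMS[rn]:
            acid_mask[k] = True
        elif rn in _BASIC_ATOMS and nm in _BASIC_ATOMS[rn]:
            base_mask[k] = True
        elif params.include_his and rn == "HIS" and nm in _HIS_ATOMS:
            base_mask[k] = True
    return np.flatnonzero(acid_mask), np.flatnonzero(base_mask)


def detect_salt_bridges(
    frame: np.ndarray,
    structure: Structure,
    params: SaltBridgeParams = SaltBridgeParams(),
) -> Set[Tuple[int, int]]:
    """Residue pairs (acidic_res, basic_res) bridged in this frame.

    The any-atom rule applies: one qualifying O-N pair within the cutoff is
    enough.  Structures without charged residues yield an empty set.
    """
    acid_idx, base_idx = _charged_atom_indices(structure, params)
    if acid_idx.size == 0 or base_idx.size == 0:
        return set()
    frame = np.asarray(frame, float)
    tree = cKDTree(frame[base_idx])
    hits = tree.query_ball_point(frame[acid_idx], params.cutoff)
    found: Set[Tuple[int, int]] = set()
    for a_local, blist in enumerate(hits):
        if not blist:
            continue
        a_res = int(structure.resseq[acid_idx[a_local]])
        for b_local in blist:
            found.add((a_res, int(structure.resseq[base_idx[b_local]])))
    return found


def bridge_occurrence(
    traj: Trajectory,
    params: SaltBridgeParams = SaltBridgeParams(),
) -> Dict[Tuple[int, int], float]:
    """Occurrence percentage per residue pair over the trajectory.

    Pairs never formed are absent from the map (sparse representation), so
    downstream aggregation treats missing as 0.
    """
    if traj.n_frames < 1:
        raise DegenerateInputError("empty trajectory")
    counts: Dict[Tuple[int, int], int] = {}
    for k in range(traj.n_frames):
        for pair in detect_salt_bridges(traj.frames[k], traj.topology, params):
            counts[pair] = counts.get(pair, 0) + 1
    return {pair: 100.0 * c / traj.n_frames for pair, c in counts.items()}


def aggregate_occurrence(
    tables: Sequence[Dict[Tuple[int, int], float]],
    threshold: float = 10.0,
) -> OccurrenceTable:
    """Union of pairs across replicates (missing = 0%), mean and SEM per
    pair, rows retained iff mean >= threshold."""
    if not tables:
        raise DegenerateInputError("no replicate tables")
    n = len(tables)
    pairs = sorted(set().union(*[set(t) for t in tables]))
    rows = []
    for pair in pairs:
        occ = np.array([t.get(pair, 0.0) for t in tables])
        mean = occ.mean()
        sem = 0.0 if n == 1 else occ.std(ddof=1) / np.sqrt(n)
        rows.append((pair[0], pair[1], *occ, mean, sem))
    cols = (["acid_res", "base_res"] + [f"rep{k}" for k in range(n)]
            + ["mean", "sem"])
    df = pd.DataFrame(rows, columns=cols)
    df = df[df["mean"] >= threshold].reset_index(drop=True)
    df = df.sort_values("mean", ascending=False, kind="mergesort").reset_index(drop=True)
    return OccurrenceTable(df, threshold=threshold, n_replicates=n)


def count_by_region(
    table: OccurrenceTable,
    domain_map: DomainMap,
) -> Dict[str, int]:
    """Count retained bridges per domain / interface.

    Intra-domain when both partners share a domain; interface when the two
    partners occupy the paired domains of a named interface; every other
    combination (including hinge residues outside all domains) lands in the
    "other" bucket.
    """
    counts: Dict[str, int] = {name: 0 for name in domain_map.region_names}
    counts["other"] = 0
    for a_res, b_res in table.pairs:
        da = domain_map.domain_of(a_res)
        db = domain_map.domain_of(b_res)
        if da is not None and da == db:
            counts[da] += 1
            continue
        bucket = "other"
        for iname, (x, y) in domain_map.interfaces.items():
            if {da, db} == {x, y}:
                bucket = iname
                break
        counts[bucket] += 1
    return counts
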