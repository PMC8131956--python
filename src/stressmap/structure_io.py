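"""Structures, trajectories and the Fab-style coordinate model.

Reads and writes fixed-width PDB v3.3 ATOM records and multi-model PDB
trajectories, holds the domain / strand / APR interval maps used throughout
the analysis, and projects per-residue scores back onto structures through
the temperature-factor column.

Residue numbering convention
----------------------------
All analyses use a single continuous numbering across chains: the first
chain (light chain in a Fab) keeps its author numbering, and every
subsequent chain is offset so that its first residue continues where the
previous chain ended (heavy-chain residue 1 becomes 215 in a Fab with a
214-residue light chain).  Hydrogens are dropped on read unless explicitly
retained; every metric downstream is heavy-atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .errors import PDBParseError, RegionError, ShapeError

__all__ = [
    "Structure",
    "Trajectory",
    "DomainMap",
    "StrandMap",
    "AprSet",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_score_projection",
    "select_region",
    "default_domain_map",
    "default_strand_map",
    "default_apr_set",
]

# B-factor column is %6.2f: printable range.
_BFACTOR_MIN = -9.99
_BFACTOR_MAX = 999.99


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A protein structure as ordered heavy-atom records.

    Coordinates are in Angstrom.  Atom order is stable and is the contract
    shared with every Trajectory frame derived from the same topology.
    """

    serials: np.ndarray          # (n,) int
    names: np.ndarray            # (n,) str  e.g. "CA", "OE1"
    elements: np.ndarray         # (n,) str  e.g. "C"
    resseq: np.ndarray           # (n,) int  continuous 1-based numbering
    resnames: np.ndarray         # (n,) str  3-letter codes
    chains: np.ndarray           # (n,) str
    coords: np.ndarray           # (n, 3) float, Angstrom
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        for name in ("serials", "names", "elements", "resseq", "resnames", "chains"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ShapeError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if n and not np.isfinite(self.coords).all():
            raise ShapeError("non-finite coordinates in Structure")
        if n and int(self.resseq.min()) < 1:
            raise ShapeError("residue numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue numbers present in the structure."""
        return np.unique(self.resseq)

    def atoms_of_residue(self, resid: int) -> np.ndarray:
        return np.flatnonzero(self.resseq == resid)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure carrying different coordinates."""
        return replace(self, coords=np.asarray(coords, dtype=float).copy())


@dataclass
class Trajectory:
    """Ordered frames sharing the topology's atom order.

    ``frames`` has shape (n_frames, n_atoms, 3); the frame interval is in
    nanoseconds (0.1 ns is the conventional MD save cadence).
    """

    topology: Structure
    frames: np.ndarray
    frame_interval_ns: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not self.frame_interval_ns > 0:
            raise ShapeError("frame_interval_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns

    @property
    def duration_ns(self) -> float:
        """Time spanned from the first to the last frame."""
        return (self.n_frames - 1) * self.frame_interval_ns


@dataclass
class DomainMap:
    """Named inclusive residue intervals plus named interface pairings."""

    domains: Dict[str, Tuple[int, int]]
    interfaces: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        taken: List[Tuple[int, int, str]] = []
        for name, (lo, hi) in self.domains.items():
            if lo > hi:
                raise RegionError(f"domain {name}: interval start {lo} > end {hi}")
            for plo, phi, pname in taken:
                if lo <= phi and plo <= hi:
                    raise RegionError(f"domains {name} and {pname} overlap")
            taken.append((lo, hi, name))
        for iname, (a, b) in self.interfaces.items():
            for d in (a, b):
                if d not in self.domains:
                    raise RegionError(f"interface {iname} references unknown domain {d}")

    @property
    def region_names(self) -> List[str]:
        return list(self.domains) + list(self.interfaces)

    def domain_of(self, resid: int) -> Optional[str]:
        for name, (lo, hi) in self.domains.items():
            if lo <= resid <= hi:
                return name
        return None


@dataclass
class StrandMap:
    """Strand label (domain + letter) -> inclusive residue interval."""

    strands: Dict[str, Tuple[int, int]]
    domain_map: Optional[DomainMap] = None

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.strands.items():
            if lo > hi:
                raise RegionError(f"strand {label}: start {lo} > end {hi}")
            if self.domain_map is not None:
                d_lo = self.domain_map.domain_of(lo)
                d_hi = self.domain_map.domain_of(hi)
                if d_lo is None or d_lo != d_hi:
                    raise RegionError(f"strand {label} does not lie inside one domain")

    def __len__(self) -> int:
        return len(self.strands)

    def domain_of_strand(self, label: str) -> Optional[str]:
        if self.domain_map is None:
            return None
        return self.domain_map.domain_of(self.strands[label][0])


@dataclass
class AprSet:
    """Named aggregation-prone-region residue intervals."""

    regions: Dict[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise RegionError(f"APR {name}: start {lo} > end {hi}")
            if lo < 1:
                raise RegionError(f"APR {name}: residues must be >= 1")

    def residues(self, name: str) -> np.ndarray:
        lo, hi = self.regions[name]
        return np.arange(lo, hi + 1)

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# Default coordinate model (442-residue Fab)
# ---------------------------------------------------------------------------

def default_domain_map() -> DomainMap:
    """Fab domain intervals on the continuous 1-442 numbering.

    Hinge residues 430-442 belong to no domain: they are excluded from
    domain-level metrics but retained in whole-protein metrics.
    """
    return DomainMap(
        domains={
            "VL": (1, 108),
            "CL": (109, 214),
            "VH": (215, 334),
            "CH1": (335, 429),
        },
        interfaces={
            "VL-VH": ("VL", "VH"),
            "CL-CH1": ("CL", "CH1"),
        },
    )


#: Nominal default strand layout: 9 + 7 + 10 + 8 = 34 strands.  The handful
#: of strands with published residue anchors are fixed (VL A, VL H, CL K/M/P,
#: VH B/E, CH1 N); the remaining intervals are a regular nominal layout, not
#: a crystallographic assignment, and are expected to be replaced from config
#: when a real structure is analysed.
_DEFAULT_STRANDS: Dict[str, Tuple[int, int]] = {
    # VL: strands A-I in 1-108
    "VL-A": (4, 7), "VL-B": (10, 14), "VL-C": (19, 25), "VL-D": (33, 38),
    "VL-E": (45, 50), "VL-F": (62, 66), "VL-G": (70, 75), "VL-H": (84, 90),
    "VL-I": (97, 102),
    # CL: strands J-P in 109-214
    "CL-J": (112, 118), "CL-K": (129, 139), "CL-L": (145, 150),
    "CL-M": (159, 163), "CL-N": (170, 176), "CL-O": (190, 196),
    "CL-P": (205, 210),
    # VH: strands A-J in 215-334
    "VH-A": (218, 221), "VH-B": (224, 226), "VH-C": (232, 238),
    "VH-D": (246, 252), "VH-E": (261, 265), "VH-F": (272, 277),
    "VH-G": (285, 291), "VH-H": (300, 306), "VH-I": (314, 319),
    "VH-J": (322, 327),
    # CH1: strands K-R in 335-429
    "CH1-K": (338, 343), "CH1-L": (350, 356), "CH1-M": (362, 368),
    "CH1-N": (381, 383), "CH1-O": (390, 396), "CH1-P": (404, 410),
    "CH1-Q": (414, 418), "CH1-R": (422, 426),
}


def default_strand_map() -> StrandMap:
    return StrandMap(dict(_DEFAULT_STRANDS), domain_map=default_domain_map())


def default_apr_set() -> AprSet:
    """The seven consensus aggregation-prone regions of the default Fab model."""
    return AprSet({
        "31-36": (31, 36),
        "47-51": (47, 51),
        "114-118": (114, 118),
        "129-139": (129, 139),
        "261-265": (261, 265),
        "325-329": (325, 329),
        "387-402": (387, 402),
    })


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    """Element from the atom-name field when columns 77-78 are absent."""
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # Two-letter elements relevant to heavy-atom protein models.
            if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA") and len(stripped) <= 2:
                return stripped[:2].capitalize()
            return ch.upper()
    return "C"


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17]
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    return serial, name, altloc, resname, chain, resseq, icode, x, y, z, element


def _records_to_structure(records, title: str, keep_h: bool, renumber: bool) -> Structure:
    if not records:
        raise PDBParseError("no ATOM/HETATM records found (empty input)")
    seen = set()          # (chain, resseq, name) for altloc handling: keep first
    rows = []
    for rec in records:
        serial, name, altloc, resname, chain, resseq, icode, x, y, z, element = rec
        if icode:
            raise PDBParseError(
                f"insertion code {icode!r} at residue {chain}{resseq} is not supported"
            )
        if not keep_h and element in ("H", "D"):
            continue
        key = (chain, resseq, name)
        if key in seen:
            if altloc:      # alternate location of an atom already kept
                continue
            raise PDBParseError(f"duplicate atom {name} in residue {chain}{resseq}")
        seen.add(key)
        rows.append((serial, name, element, resseq, resname, chain, x, y, z))
    if not rows:
        raise PDBParseError("no heavy atoms left after filtering")

    serials = np.array([r[0] for r in rows], dtype=int)
    names = np.array([r[1] for r in rows], dtype=object)
    elements = np.array([r[2] for r in rows], dtype=object)
    resseq = np.array([r[3] for r in rows], dtype=int)
    resnames = np.array([r[4] for r in rows], dtype=object)
    chains = np.array([r[5] for r in rows], dtype=object)
    coords = np.array([[r[6], r[7], r[8]] for r in rows], dtype=float)

    if renumber:
        resseq = _renumber_continuous(chains, resseq)

    return Structure(serials, names, elements, resseq, resnames, chains, coords, title)


def _renumber_continuous(chains: np.ndarray, resseq: np.ndarray) -> np.ndarray:
    """Offset each chain after the first so numbering is continuous.

    The first chain keeps its author numbering; chain k starts at
    (last residue number assigned so far) + 1 relative to its own first
    residue.  For a Fab with light chain 1-214 and heavy chain 1-228 this
    maps heavy residue 1 to 215.
    """
    out = resseq.copy()
    order: List[str] = []
    for c in chains:
        if c not in order:
            order.append(c)
    running_max = 0
    for c in order:
        mask = chains == c
        chain_res = resseq[mask]
        offset = running_max - int(chain_res.min()) + 1 if running_max else 0
        if running_max == 0:
            offset = 0
        out[mask] = chain_res + offset
        running_max = int(out[mask].max())
    return out


def read_structure(pdb_text: str, keep_h: bool = False, renumber: bool = True) -> Structure:
    """Parse PDB text into a Structure.

    Hydrogens are dropped unless ``keep_h``; chains are renumbered onto one
    continuous 1-based axis unless ``renumber`` is False.  TER / END /
    REMARK records are tolerated; insertion codes are rejected; for
    alternate locations the first occurrence is kept.
    """
    records = []
    title = ""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            records.append(_parse_atom_line(line, lineno))
        elif rec == "TITLE ":
            title = (title + " " + line[10:].strip()).strip()
        elif rec.startswith("ENDMDL") or rec.startswith("MODEL"):
            raise PDBParseError(
                "multi-model input passed to read_structure; use read_trajectory"
            )
    return _records_to_structure(records, title, keep_h, renumber)


def read_trajectory(
    multi_model_pdb_text: str,
    keep_h: bool = False,
    renumber: bool = True,
    frame_interval_ns: float = 0.1,
) -> Trajectory:
    """Parse a multi-model PDB into a Trajectory.

    The topology (atom names, residues) is taken from the first MODEL; every
    model must present the same atom count in the same order.  A file with
    no MODEL records is read as a single-frame trajectory.
    """
    blocks: List[List] = []
    current: Optional[List] = None
    loose: List = []
    title = ""
    for lineno, line in enumerate(multi_model_pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            current = []
        elif rec.startswith("ENDMDL"):
            if current is None:
                raise PDBParseError(f"ENDMDL without MODEL at line {lineno}")
            blocks.append(current)
            current = None
        elif rec in ("ATOM  ", "HETATM"):
            target = current if current is not None else loose
            target.append(_parse_atom_line(line, lineno))
        elif rec == "TITLE ":
            title = (title + " " + line[10:].strip()).strip()
    if current is not None and current:
        blocks.append(current)
    if not blocks:
        if not loose:
            raise PDBParseError("no ATOM records found in trajectory input")
        blocks = [loose]

    topology = _records_to_structure(blocks[0], title, keep_h, renumber)
    n = topology.n_atoms
    frames = np.empty((len(blocks), n, 3), dtype=float)
    frames[0] = topology.coords
    for k, block in enumerate(blocks[1:], start=1):
        struct_k = _records_to_structure(block, title, keep_h, renumber)
        if struct_k.n_atoms != n:
            raise ShapeError(
                f"model {k + 1} has {struct_k.n_atoms} atoms but model 1 has {n}"
            )
        frames[k] = struct_k.coords
    return Trajectory(topology, frames, frame_interval_ns=frame_interval_ns)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(i: int, structure: Structure, coords: np.ndarray,
                      bfactor: float) -> str:
    name = str(structure.names[i])
    # PDB atom-name alignment: 1-3 char names start in column 14.
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {int(structure.serials[i]) % 100000:5d} {name_field}"
        f" {str(structure.resnames[i]):<3s} {str(structure.chains[i])[:1]:1s}"
        f"{int(structure.resseq[i]) % 10000:4d}    "
        f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
        f"{1.00:6.2f}{bfactor:6.2f}          "
        f"{str(structure.elements[i]):>2s}"
    )


def write_structure(structure: Structure, bfactors: Optional[np.ndarray] = None) -> str:
    """Serialize a Structure as fixed-width PDB v3.3 text."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    b = np.zeros(structure.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    for i in range(structure.n_atoms):
        lines.append(_format_atom_line(i, structure, structure.coords, b[i]))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a Trajectory as multi-model PDB text."""
    lines = []
    if traj.topology.title:
        lines.append(f"TITLE     {traj.topology.title}")
    for k in range(traj.n_frames):
        lines.append(f"MODEL     {k + 1:4d}")
        for i in range(traj.topology.n_atoms):
            lines.append(_format_atom_line(i, traj.topology, traj.frames[k], 0.0))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_score_projection(structure: Structure,
                           per_residue_scores: Mapping[int, float]) -> str:
    """Write per-residue scores into the B-factor column of a PDB.

    Every atom of a scored residue carries the residue's score, clamped to
    the printable column range [-9.99, 999.99]; unscored residues get 0.00.
    A round-trip read recovers scores to 2 decimals.
    """
    b = np.zeros(structure.n_atoms)
    for resid, score in per_residue_scores.items():
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for residue {resid}")
        clamped = float(np.clip(score, _BFACTOR_MIN, _BFACTOR_MAX))
        if clamped != score:
            warnings.warn(
                f"score {score} for residue {resid} clamped to {clamped} "
                f"(B-factor column range)", stacklevel=2)
        b[structure.resseq == resid] = clamped
    return write_structure(structure, bfactors=b)


def read_bfactors(pdb_text: str) -> Dict[int, float]:
    """Per-residue B-factor (first atom of each residue) from PDB text."""
    out: Dict[int, float] = {}
    for line in pdb_text.splitlines():
        if line[:6] in ("ATOM  ", "HETATM"):
            resid = int(line[22:26])
            if resid not in out:
                out[resid] = float(line[60:66])
    return out


# ---------------------------------------------------------------------------
# Region selection
# ---------------------------------------------------------------------------

def _interval_indices(structure: Structure, lo: int, hi: int) -> np.ndarray:
    return np.flatnonzero((structure.resseq >= lo) & (structure.resseq <= hi))


def select_region(structure: Structure, domain_map: DomainMap, region: str):
    """Atom indices of a named domain, or the pair of index sets of an interface.

    For a domain the return value is a 1-D integer array; for an interface
    (name like "VL-VH") it is the ordered pair of the two domains' arrays.
    """
    if region in domain_map.domains:
        lo, hi = domain_map.domains[region]
        idx = _interval_indices(structure, lo, hi)
        if idx.size == 0:
            warnings.warn(f"region {region} covers no residues present in the "
                          f"structure", stacklevel=2)
        return idx
    if region in domain_map.interfaces:
        a, b = domain_map.interfaces[region]
        return (select_region(structure, domain_map, a),
                select_region(structure, domain_map, b))
    raise RegionError(
        f"unknown region {region!r}; valid names: {domain_map.region_names}")
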