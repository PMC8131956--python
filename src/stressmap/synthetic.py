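"""Synthetic mini-Fab structures and stress trajectories with known ground truth.

The generator emulates the statistical structure of three MD condition
classes on an idealized four-domain protein:

* ``reference``   - stationary Gaussian jitter about the native structure,
  designed salt bridges held formed;
* ``low_ph_like`` - same jitter plus a ramped deformation localized in one
  constant-region domain and scheduled elimination of designated
  Glu-containing salt bridges;
* ``high_temp_like`` - globally increased jitter plus progressive rigid-body
  separation of the heavy-chain block, stressing both inter-chain
  interfaces at once.

Each domain is a small beta-sandwich (two stacked two-stranded antiparallel
sheets) built from ideal backbone geometry; designed salt-bridge partners
carry pseudo side-chain O/N atoms placed at controlled distances, and
designated APR segments sit between the sheets with inward pseudo-CB shells
so they start buried.  The jitter is i.i.d. per-atom Gaussian noise - a
deliberately non-physical but cheap stand-in for thermal fluctuation that
preserves every metric contract under test.  Atoms whose positions encode a
designed schedule (bridge N/O pseudo-atoms, scheduled APR segments) are
exempt from jitter so the schedules are exact ground truth.

Every trajectory is reproducible: replicate seeds derive from the master
seed via ``numpy.random.SeedSequence(master).spawn``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .structure_io import (AprSet, DomainMap, StrandMap, Structure, Trajectory,
                           write_trajectory)

__all__ = [
    "ToyFabSpec",
    "StressProfile",
    "DesignedBridge",
    "build_backbone",
    "build_toy_fab",
    "simulate_stress_trajectory",
    "toy_domain_map",
    "toy_strand_map",
    "toy_apr_set",
    "default_profiles",
    "write_fixture",
]

# Ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
PHI_BETA = -139.0
PSI_BETA = 135.0
OMEGA_TRANS = 180.0


# ---------------------------------------------------------------------------
# Internal-coordinate construction
# ---------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d given a-b-c with |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise DegenerateInputError("collinear reference atoms in placement")
    n /= n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    n_residues: int,
    dihedrals: Optional[Sequence[Tuple[float, float, float]]] = None,
    first_resid: int = 1,
    chain: str = "A",
    resname: str = "ALA",
) -> Structure:
    """Backbone N, CA, C, O for ``n_residues`` by sequential construction.

    ``dihedrals`` gives per-residue (phi, psi, omega); the default is an
    ideal beta strand (-139, +135, 180).  Two consecutive CA atoms land
    3.80 +/- 0.05 A apart for trans peptides.
    """
    if n_residues < 2:
        raise DegenerateInputError("need at least 2 residues")
    if dihedrals is None:
        dihedrals = [(PHI_BETA, PSI_BETA, OMEGA_TRANS)] * n_residues
    dihedrals = list(dihedrals)
    if len(dihedrals) != n_residues:
        raise ConfigError("one (phi, psi, omega) triple per residue required")
    for trip in dihedrals:
        if not all(np.isfinite(x) for x in trip):
            raise ConfigError("non-finite dihedral")

    n_xyz = np.zeros((n_residues, 3))
    ca_xyz = np.zeros((n_residues, 3))
    c_xyz = np.zeros((n_residues, 3))
    o_xyz = np.zeros((n_residues, 3))

    # first residue: N at origin, CA along +x, C in the xy-plane
    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    c_xyz[0] = ca_xyz[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_residues):
        phi_i = dihedrals[i][0]
        psi_prev = dihedrals[i - 1][1]
        omega_i = dihedrals[i][2]
        n_xyz[i] = _place(n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_xyz[i] = _place(ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
                           BOND_N_CA, ANGLE_C_N_CA, omega_i)
        c_xyz[i] = _place(c_xyz[i - 1], n_xyz[i], ca_xyz[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi_i)
        # carbonyl O of the previous residue, trans to the new N
        o_xyz[i - 1] = _place(n_xyz[i], ca_xyz[i - 1], c_xyz[i - 1],
                              BOND_C_O, ANGLE_CA_C_O, 180.0)
    # last residue's O from its own psi
    o_xyz[-1] = _place(n_xyz[-1], ca_xyz[-1], c_xyz[-1],
                       BOND_C_O, ANGLE_CA_C_O, dihedrals[-1][1] + 180.0)

    coords, serials, names, elements, resseq, resnames, chains = \
        [], [], [], [], [], [], []
    serial = 1
    for i in range(n_residues):
        for nm, el, xyz in (("N", "N", n_xyz[i]), ("CA", "C", ca_xyz[i]),
                            ("C", "C", c_xyz[i]), ("O", "O", o_xyz[i])):
            coords.append(xyz)
            serials.append(serial)
            names.append(nm)
            elements.append(el)
            resseq.append(first_resid + i)
            resnames.append(resname)
            chains.append(chain)
            serial += 1
    return Structure(
        np.array(serials), np.array(names, object), np.array(elements, object),
        np.array(resseq), np.array(resnames, object), np.array(chains, object),
        np.array(coords), title=f"synthetic backbone n={n_residues}")


# ---------------------------------------------------------------------------
# Sheet and toy-Fab construction
# ---------------------------------------------------------------------------

#: Frozen antiparallel pairing transforms per strand length:
#: (separation y, shift x, shift z, tilt about x deg, tilt about z deg)
#: applied to the mirrored partner strand.  Obtained once by the same
#: deterministic optimization `_solve_pair_transform` runs for lengths
#: outside this table (objective: total Kabsch-Sander H-bond energy between
#: the strands, subject to a 2.7 A clash floor).
_PAIR_TRANSFORMS: Dict[int, Tuple[float, float, float, float, float]] = {
    5: (4.042, -3.467, -0.011, -8.265, -0.020),
    6: (4.094, 0.231, 0.004, -8.813, -8.168),
    8: (3.785, 0.169, 0.004, -7.841, -6.292),
    10: (3.702, 0.120, 0.008, -8.109, -5.027),
}

_MIRROR_Y = np.diag([-1.0, 1.0, -1.0])


def _canonical_strand(n: int) -> Structure:
    """Ideal beta strand centered at the CA centroid, axis along +x."""
    s = build_backbone(n)
    ca = s.coords[np.asarray(s.names) == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    c = float(axis @ x)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return s.with_coords((s.coords - ca.mean(axis=0)) @ rot.T)


def _apply_pair_transform(strand_coords: np.ndarray,
                          params: Tuple[float, float, float, float, float]
                          ) -> np.ndarray:
    """Mirrored, tilted and translated partner-strand coordinates."""
    ysep, dx, dz, tilt_x, tilt_z = params
    c = strand_coords @ _MIRROR_Y.T
    cen = c.mean(axis=0)
    tx, tz = np.radians(tilt_x), np.radians(tilt_z)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(tx), -np.sin(tx)],
                   [0, np.sin(tx), np.cos(tx)]])
    rz = np.array([[np.cos(tz), -np.sin(tz), 0],
                   [np.sin(tz), np.cos(tz), 0],
                   [0, 0, 1]])
    return (c - cen) @ (rx @ rz).T + cen + np.array([dx, ysep, dz])


def _cross_strand_energy(strand: Structure, partner_coords: np.ndarray) -> float:
    """Total Kabsch-Sander energy of favourable cross-strand H-bonds."""
    from .secondary import hbond_energy, place_amide_hydrogens
    n = int(strand.residue_ids.size)
    combined = Structure(
        np.arange(1, 2 * strand.n_atoms + 1),
        np.concatenate([strand.names] * 2),
        np.concatenate([strand.elements] * 2),
        np.concatenate([strand.resseq, strand.resseq + n]),
        np.concatenate([strand.resnames] * 2),
        np.concatenate([strand.chains] * 2),
        np.vstack([strand.coords, partner_coords]))
    h, has_h = place_amide_hydrogens(combined)
    names = np.asarray(combined.names)
    n_xyz = combined.coords[names == "N"]
    c_xyz = combined.coords[names == "C"]
    o_xyz = combined.coords[names == "O"]
    total = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for don in range(2 * n):
            if not has_h[don]:
                continue
            for acc in range(2 * n):
                if (don < n) == (acc < n):
                    continue
                if np.linalg.norm(n_xyz[don] - o_xyz[acc]) > 6.0:
                    continue
                e = hbond_energy(n_xyz[don], h[don], c_xyz[acc], o_xyz[acc])
                if e < 0:
                    total += max(e, -4.0)
    return total


def _solve_pair_transform(strand_len: int
                          ) -> Tuple[float, float, float, float, float]:
    """Deterministic optimization of the partner-strand placement."""
    if strand_len in _PAIR_TRANSFORMS:
        return _PAIR_TRANSFORMS[strand_len]
    from scipy.optimize import minimize
    from scipy.spatial.distance import cdist
    strand = _canonical_strand(strand_len)

    def objective(params):
        partner = _apply_pair_transform(strand.coords, tuple(params))
        penalty = max(0.0, 2.7 - cdist(strand.coords, partner).min()) * 20.0
        return _cross_strand_energy(strand, partner) + penalty

    best = None
    for ysep in (4.6, 4.8, 5.0):
        for tilt_x in (-15.0, 0.0, 15.0):
            for tilt_z in (-10.0, 0.0, 10.0):
                res = minimize(objective,
                               np.array([ysep, -1.0, 0.0, tilt_x, tilt_z]),
                               method="Nelder-Mead",
                               options=dict(maxiter=400, xatol=1e-3, fatol=1e-3))
                if best is None or res.fun < best.fun:
                    best = res
    assert best is not None
    return tuple(float(v) for v in best.x)


@dataclass(frozen=True)
class DesignedBridge:
    """A designed salt bridge between pseudo side-chain O and N atoms.

    The pseudo-atoms arc over the +z face of the sandwich (``arc_height``
    above the CA-CA midpoint), clear of the packed core, with the designed
    O-N distance along the CA-CA direction.
    """

    name: str
    acid_res: int
    acid_type: str               # "GLU" or "ASP"
    base_res: int
    base_type: str               # "LYS" or "ARG"
    distance: float = 2.8        # designed O-N distance, Angstrom
    arc_height: float = 3.2      # Angstrom above the CA-CA midpoint, +z


@dataclass
class ToyFabSpec:
    """Construction parameters of the synthetic four-domain mini-Fab.

    Four 24-residue beta-sandwich domains (VL, CL, VH, CH1 analogs) on a
    continuous numbering 1-96; light chain = VL+CL, heavy chain = VH+CH1.
    """

    strand_len: int = 6
    strands_per_domain: int = 4          # two 2-strand sheets
    stack_sep: float = 5.5               # sheet-to-sheet z offset, Angstrom
    domain_gap_x: float = 5.0            # VL-CL / VH-CH1 spacing, Angstrom
    interface_gap: float = 1.8           # light-heavy spacing margin, Angstrom
    cb_length: float = 1.53              # pseudo-CB bond length, Angstrom
    phi: float = PHI_BETA
    psi: float = PSI_BETA
    omega: float = OMEGA_TRANS
    bridges: Tuple[DesignedBridge, ...] = (
        # intra-CL Glu bridge (lost under the low-pH-like stress)
        DesignedBridge("E30-K33", 30, "GLU", 33, "LYS"),
        # cross-domain CL-VL Glu bridge (also lost at low pH)
        DesignedBridge("E25-K6", 25, "GLU", 6, "LYS"),
        # Asp bridges survive the low-pH-like stress
        DesignedBridge("D28-R35", 28, "ASP", 35, "ARG"),
        DesignedBridge("D74-K81", 74, "ASP", 81, "LYS"),
    )
    apr_segments: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"VL_core": (15, 17), "CL_core": (39, 41),
                                 "VH_core": (63, 65)})
    deformation_pairs: Tuple[Tuple[int, int], ...] = ((31, 43), (32, 44), (34, 46))

    @property
    def residues_per_domain(self) -> int:
        return self.strand_len * self.strands_per_domain


def toy_domain_map(spec: Optional[ToyFabSpec] = None) -> DomainMap:
    spec = spec or ToyFabSpec()
    m = spec.residues_per_domain
    return DomainMap(
        domains={"VL": (1, m), "CL": (m + 1, 2 * m),
                 "VH": (2 * m + 1, 3 * m), "CH1": (3 * m + 1, 4 * m)},
        interfaces={"VL-VH": ("VL", "VH"), "CL-CH1": ("CL", "CH1")})


def toy_strand_map(spec: Optional[ToyFabSpec] = None) -> StrandMap:
    spec = spec or ToyFabSpec()
    n = spec.strand_len
    strands: Dict[str, Tuple[int, int]] = {}
    letters = "ABCD"
    for d, dom in enumerate(("VL", "CL", "VH", "CH1")):
        base = d * spec.residues_per_domain
        for s in range(spec.strands_per_domain):
            lo = base + s * n + 1
            strands[f"{dom}-{letters[s]}"] = (lo, lo + n - 1)
    return StrandMap(strands, domain_map=toy_domain_map(spec))


def toy_apr_set(spec: Optional[ToyFabSpec] = None) -> AprSet:
    spec = spec or ToyFabSpec()
    return AprSet(dict(spec.apr_segments))


def _domain_coords(spec: ToyFabSpec):
    """Coordinates and per-residue atom lists for one sandwich domain at the
    origin.  Returns (list over residues of (resname, [(atom, element, xyz)]))."""
    n = spec.strand_len
    strand = _canonical_strand(n)
    partner = _apply_pair_transform(strand.coords, _solve_pair_transform(n))
    sheets = [
        (strand.coords, -1.0),                 # sheet A, CB points -z
        (partner, -1.0),
        (strand.coords + np.array([0.0, 0.0, -spec.stack_sep]), +1.0),
        (partner + np.array([0.0, 0.0, -spec.stack_sep]), +1.0),
    ]
    residues = []
    for coords, cb_dir in sheets:
        for i in range(n):
            atoms = []
            for j, (nm, el) in enumerate((("N", "N"), ("CA", "C"),
                                          ("C", "C"), ("O", "O"))):
                atoms.append((nm, el, coords[4 * i + j].copy()))
            ca = coords[4 * i + 1]
            cb = ca + np.array([0.0, 0.0, cb_dir * spec.cb_length])
            atoms.append(("CB", "C", cb))
            residues.append(("ALA", atoms))
    return residues


_ACID_ATOM_NAMES = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
_BASE_ATOM_NAMES = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}


def build_toy_fab(spec: Optional[ToyFabSpec] = None) -> Structure:
    """The idealized four-domain mini-Fab with designed bridges and APRs.

    Domain layout: light chain VL (origin) and CL (+x); heavy chain VH and
    CH1 stacked above (+y) so that VL-VH and CL-CH1 form the two inter-chain
    interfaces.  Designed salt-bridge residues carry pseudo side-chain O/N
    atoms at the designed distance; every other residue is alanine with an
    inward-pointing pseudo-CB that packs the sandwich core.
    """
    from scipy.spatial.distance import cdist
    spec = spec or ToyFabSpec()
    domain_res = _domain_coords(spec)
    m = spec.residues_per_domain

    # domain placements
    xs = np.array([a[2][0] for _, atoms in domain_res for a in atoms])
    ys = np.array([a[2][1] for _, atoms in domain_res for a in atoms])
    width_x = xs.max() - xs.min()
    shift_cl = np.array([width_x + spec.domain_gap_x, 0.0, 0.0])
    y_span = ys.max() - ys.min()
    shift_h = np.array([0.0, y_span + spec.interface_gap, 0.0])

    placements = [
        ("L", np.zeros(3)),                   # VL: residues 1..m
        ("L", shift_cl),                      # CL: m+1..2m
        ("H", shift_h),                       # VH: 2m+1..3m
        ("H", shift_cl + shift_h),            # CH1: 3m+1..4m
    ]

    resnames: List[str] = []
    chains: List[str] = []
    atom_lists: List[List[Tuple[str, str, np.ndarray]]] = []
    for chain, offset in placements:
        for resname, atoms in domain_res:
            atom_lists.append([(nm, el, xyz + offset) for nm, el, xyz in atoms])
            resnames.append(resname)
            chains.append(chain)

    # designed salt bridges: rename residues, append pseudo side-chain atoms
    ca_pos = {r + 1: next(xyz for nm, _, xyz in atom_lists[r] if nm == "CA")
              for r in range(4 * m)}
    for bridge in spec.bridges:
        a, b = bridge.acid_res, bridge.base_res
        if not (1 <= a <= 4 * m and 1 <= b <= 4 * m):
            raise ConfigError(f"bridge {bridge.name} outside residue range")
        v = ca_pos[b] - ca_pos[a]
        d_ca = float(np.linalg.norm(v))
        if not 4.0 <= d_ca <= 14.0:
            raise ConfigError(
                f"bridge {bridge.name}: CA separation {d_ca:.1f} A outside "
                f"the constructible 4-14 A range")
        u = v / d_ca
        mid = 0.5 * (ca_pos[a] + ca_pos[b]) + np.array([0.0, 0.0, bridge.arc_height])
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        o_main = mid - 0.5 * bridge.distance * u
        n_main = mid + 0.5 * bridge.distance * u
        resnames[a - 1] = bridge.acid_type
        resnames[b - 1] = bridge.base_type
        o_names = _ACID_ATOM_NAMES[bridge.acid_type]
        atom_lists[a - 1].append((o_names[0], "O", o_main))
        atom_lists[a - 1].append((o_names[1], "O", o_main + 1.1 * perp))
        for k, nname in enumerate(_BASE_ATOM_NAMES[bridge.base_type]):
            atom_lists[b - 1].append((nname, "N", n_main + 1.0 * k * perp))

    serials, names, elements, resseq, out_resnames, out_chains, coords = \
        [], [], [], [], [], [], []
    serial = 1
    for r, atoms in enumerate(atom_lists):
        for nm, el, xyz in atoms:
            serials.append(serial)
            names.append(nm)
            elements.append(el)
            resseq.append(r + 1)
            out_resnames.append(resnames[r])
            out_chains.append(chains[r])
            coords.append(xyz)
            serial += 1
    structure = Structure(
        np.array(serials), np.array(names, object), np.array(elements, object),
        np.array(resseq), np.array(out_resnames, object),
        np.array(out_chains, object), np.array(coords),
        title="synthetic mini-Fab")

    # designed-placement clash check: bridge pseudo-atoms vs other residues
    pseudo_names = {"OE1", "OE2", "OD1", "OD2", "NZ", "NE", "NH1", "NH2"}
    pseudo = np.array([str(nm) in pseudo_names for nm in structure.names])
    for k in np.flatnonzero(pseudo):
        others = structure.resseq != structure.resseq[k]
        d = cdist(structure.coords[k:k + 1], structure.coords[others]).min()
        if d < 1.5:
            raise ConfigError(
                f"designed placement clash at atom {structure.names[k]} of "
                f"residue {int(structure.resseq[k])}: {d:.2f} A")
    return structure


def _designed_atom_mask(structure: Structure, spec: ToyFabSpec) -> np.ndarray:
    """Atoms whose positions encode a designed schedule (no jitter)."""
    mask = np.zeros(structure.n_atoms, bool)
    pseudo = {"OE1", "OE2", "OD1", "OD2", "NZ", "NE", "NH1", "NH2"}
    for k in range(structure.n_atoms):
        if str(structure.names[k]) in pseudo:
            mask[k] = True
    for lo, hi in spec.apr_segments.values():
        mask |= (structure.resseq >= lo) & (structure.resseq <= hi)
    return mask


# ---------------------------------------------------------------------------
# Stress trajectories
# ---------------------------------------------------------------------------

_MODES = ("reference", "low_ph_like", "high_temp_like")

#: Displacement of a broken bridge's N atoms (out of the bridge plane).
_BRIDGE_OFF_SHIFT = np.array([0.0, 0.0, 4.0])


@dataclass
class StressProfile:
    """Condition recipe for the trajectory generator.

    ``bridge_occupancy`` maps designed-bridge names to the fraction of
    frames in which the bridge is formed (formed in the first
    round(f * n_frames) frames, eliminated afterwards - a deterministic,
    progressive schedule).  ``apr_exposure`` maps designed APR names to the
    fraction of frames in which the segment is displaced out of the sandwich
    (the last round(f * n_frames) frames).  ``deformation_amplitude`` is the
    final extra separation (Angstrom) of the designed residue pairs in the
    target domain; ``separation_amplitude`` is the final rigid translation
    of the heavy-chain block away from the light chain.
    """

    mode: str
    jitter_sigma: float = 0.15           # Angstrom, i.i.d. per coordinate
    target_domain: str = "CL"
    deformation_amplitude: float = 0.0   # Angstrom, ramped 0 -> amp
    separation_amplitude: float = 0.0    # Angstrom, ramped 0 -> amp
    apr_displacement: float = 8.0        # Angstrom, -z, exposed state
    bridge_occupancy: Dict[str, float] = field(default_factory=dict)
    apr_exposure: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; one of {_MODES}")
        if self.jitter_sigma < 0:
            raise ConfigError("jitter sigma must be >= 0")
        for name, f in {**self.bridge_occupancy, **self.apr_exposure}.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"schedule fraction for {name} outside [0, 1]")


def default_profiles(seed: int = 0) -> Dict[str, StressProfile]:
    """The three study conditions at their default settings."""
    ref_occ = {"E30-K33": 0.9, "E25-K6": 0.8, "D28-R35": 0.7, "D74-K81": 0.6}
    return {
        "reference": StressProfile(
            "reference", jitter_sigma=0.15, bridge_occupancy=dict(ref_occ),
            apr_exposure={}, seed=seed),
        "low_ph_like": StressProfile(
            "low_ph_like", jitter_sigma=0.15, target_domain="CL",
            deformation_amplitude=2.0,
            bridge_occupancy={"E30-K33": 0.0, "E25-K6": 0.0,
                              "D28-R35": 0.55, "D74-K81": 0.5},
            apr_exposure={"CL_core": 0.4}, seed=seed),
        "high_temp_like": StressProfile(
            "high_temp_like", jitter_sigma=0.45,
            separation_amplitude=6.0,
            bridge_occupancy={"E30-K33": 0.4, "E25-K6": 0.35,
                              "D28-R35": 0.3, "D74-K81": 0.25},
            apr_exposure={"VH_core": 0.5}, seed=seed),
    }


def _bridge_atom_indices(structure: Structure, spec: ToyFabSpec):
    """Per designed bridge: (acid O atom indices, base N atom indices, unit u)."""
    out = {}
    for bridge in spec.bridges:
        o_names = _ACID_ATOM_NAMES[bridge.acid_type]
        n_names = _BASE_ATOM_NAMES[bridge.base_type]
        o_idx = np.flatnonzero(
            (structure.resseq == bridge.acid_res)
            & np.isin(np.asarray(structure.names, dtype=object), list(o_names)))
        n_idx = np.flatnonzero(
            (structure.resseq == bridge.base_res)
            & np.isin(np.asarray(structure.names, dtype=object), list(n_names)))
        if o_idx.size == 0 or n_idx.size == 0:
            raise ConfigError(f"bridge {bridge.name} atoms missing from structure")
        u = structure.coords[n_idx[0]] - structure.coords[o_idx[0]]
        u /= np.linalg.norm(u)
        out[bridge.name] = (o_idx, n_idx, u)
    return out


def _deformation_design(structure: Structure, spec: ToyFabSpec,
                        domain_map: DomainMap, target_domain: str):
    """Atom groups, unit axes and the closed-form RMSD coefficient.

    Each designed residue pair (a, b) is displaced +/- alpha along the unit
    vector between the two residues' centroids.  Because the displacement
    field is centroid-balanced and its cross-covariance perturbation is
    symmetric, the optimal superposition of a noiseless deformed frame onto
    the reference stays the identity, so the fitted region RMSD has the
    closed form alpha * sqrt(2 * n_displaced_atoms / n_region_atoms).
    """
    lo, hi = domain_map.domains[target_domain]
    region_atoms = int(np.sum((structure.resseq >= lo) & (structure.resseq <= hi)))
    pairs = []
    n_disp = 0
    for a, b in spec.deformation_pairs:
        if not (lo <= a <= hi and lo <= b <= hi):
            raise ConfigError(
                f"deformation pair ({a}, {b}) outside target domain {target_domain}")
        ia = np.flatnonzero(structure.resseq == a)
        ib = np.flatnonzero(structure.resseq == b)
        if ia.size != ib.size:
            raise ConfigError(
                f"deformation pair ({a}, {b}) has unequal atom counts")
        u = structure.coords[ia].mean(axis=0) - structure.coords[ib].mean(axis=0)
        u /= np.linalg.norm(u)
        pairs.append((ia, ib, u))
        n_disp += ia.size + ib.size
    coeff = float(np.sqrt(n_disp / region_atoms))
    return pairs, coeff


def _schedule_on(n_frames: int, fraction: float) -> np.ndarray:
    """Boolean per-frame mask: formed in the first round(f*n) frames."""
    k = int(round(fraction * n_frames))
    mask = np.zeros(n_frames, bool)
    mask[:k] = True
    return mask


def _schedule_late(n_frames: int, fraction: float) -> np.ndarray:
    """Boolean per-frame mask: active in the last round(f*n) frames."""
    k = int(round(fraction * n_frames))
    mask = np.zeros(n_frames, bool)
    if k:
        mask[n_frames - k:] = True
    return mask


def simulate_stress_trajectory(
    base: Structure,
    profile: StressProfile,
    n_frames: int = 101,
    n_replicates: int = 6,
    spec: Optional[ToyFabSpec] = None,
    frame_interval_ns: float = 1.0,
) -> Tuple[List[Trajectory], Dict]:
    """Replicate trajectories for one condition, plus the ground truth.

    Replicate r uses ``SeedSequence(profile.seed).spawn()[r]`` so replicate
    sets are reproducible independently.  The returned ground-truth dict
    records every designed schedule: exact bridge occupancences, the
    closed-form deformation RMSD, the noiseless final interface Q, and the
    two-state APR exposure prediction.
    """
    if n_frames < 2:
        raise DegenerateInputError("need at least 2 frames")
    spec = spec or ToyFabSpec()
    domain_map = toy_domain_map(spec)
    bridge_idx = _bridge_atom_indices(base, spec)
    jitter_free = _designed_atom_mask(base, spec)
    jitter_idx = np.flatnonzero(~jitter_free)
    heavy_idx = np.flatnonzero(
        np.asarray([str(c) == "H" for c in base.chains]))

    # schedules
    bridge_sched = {
        name: _schedule_on(n_frames, profile.bridge_occupancy.get(name, 1.0))
        for name in bridge_idx}
    apr_sched = {
        name: _schedule_late(n_frames, profile.apr_exposure.get(name, 0.0))
        for name in spec.apr_segments}
    apr_idx = {
        name: np.flatnonzero((base.resseq >= lo) & (base.resseq <= hi))
        for name, (lo, hi) in spec.apr_segments.items()}
    apr_dir = np.array([0.0, 0.0, -1.0])

    deformation = None
    if profile.deformation_amplitude > 0:
        pairs, coeff = _deformation_design(base, spec, domain_map,
                                           profile.target_domain)
        deformation = (pairs, coeff)

    sep_u = None
    if profile.separation_amplitude > 0:
        light_idx = np.flatnonzero(
            np.asarray([str(c) == "L" for c in base.chains]))
        sep_u = (base.coords[heavy_idx].mean(axis=0)
                 - base.coords[light_idx].mean(axis=0))
        sep_u /= np.linalg.norm(sep_u)

    ramp = np.arange(n_frames) / (n_frames - 1)

    children = np.random.SeedSequence(profile.seed).spawn(n_replicates)
    trajectories: List[Trajectory] = []
    for r in range(n_replicates):
        rng = np.random.default_rng(children[r])
        frames = np.empty((n_frames, base.n_atoms, 3))
        for k in range(n_frames):
            coords = base.coords.copy()
            if deformation is not None:
                alpha = profile.deformation_amplitude * ramp[k]
                for ia, ib, u in deformation[0]:
                    coords[ia] += 0.5 * alpha * u
                    coords[ib] -= 0.5 * alpha * u
            if sep_u is not None:
                coords[heavy_idx] += profile.separation_amplitude * ramp[k] * sep_u
            for name, sched in apr_sched.items():
                if sched[k]:
                    coords[apr_idx[name]] += profile.apr_displacement * apr_dir
            for name, sched in bridge_sched.items():
                if not sched[k]:
                    # broken state: lift the basic N atoms off the +z face,
                    # clear of every other designed bridge's O atoms
                    o_idx, n_idx, u = bridge_idx[name]
                    coords[n_idx] += _BRIDGE_OFF_SHIFT
            if profile.jitter_sigma > 0:
                coords[jitter_idx] += rng.normal(
                    0.0, profile.jitter_sigma, (jitter_idx.size, 3))
            frames[k] = coords
        trajectories.append(Trajectory(base, frames,
                                       frame_interval_ns=frame_interval_ns))

    ground_truth = _ground_truth(base, profile, spec, n_frames, n_replicates,
                                 frame_interval_ns, bridge_sched, apr_sched,
                                 apr_idx, apr_dir, deformation, sep_u,
                                 heavy_idx)
    return trajectories, ground_truth


def _ground_truth(base, profile, spec, n_frames, n_replicates,
                  frame_interval_ns, bridge_sched, apr_sched, apr_idx,
                  apr_dir, deformation, sep_u, heavy_idx) -> Dict:
    from .contacts import ContactParams, build_reference_contacts, soft_cut_fraction
    from .surface import SasaParams, residue_sasa

    gt: Dict = {
        "mode": profile.mode,
        "seed": int(profile.seed),
        "n_frames": int(n_frames),
        "n_replicates": int(n_replicates),
        "frame_interval_ns": float(frame_interval_ns),
        "jitter_sigma": float(profile.jitter_sigma),
    }
    gt["bridges"] = {
        name: {
            "occupancy_pct": 100.0 * int(sched.sum()) / n_frames,
            "on_frames": int(sched.sum()),
        } for name, sched in bridge_sched.items()}

    if deformation is not None:
        pairs, coeff = deformation
        amp = profile.deformation_amplitude
        gt["deformation"] = {
            "target_domain": profile.target_domain,
            "amplitude": float(amp),
            "rmsd_coefficient": coeff,
            "final_rmsd": 0.5 * amp * coeff,
            "pairs": [[int(a), int(b)] for a, b in spec.deformation_pairs],
        }

    if sep_u is not None:
        # noiseless final frame -> exact final interface Q from the formula
        final = base.coords.copy()
        final[heavy_idx] += profile.separation_amplitude * sep_u
        domain_map = toy_domain_map(spec)
        params = ContactParams()
        final_q = {}
        for iface in domain_map.interfaces:
            contacts = build_reference_contacts(base, iface, domain_map, params)
            final_q[iface] = soft_cut_fraction(final, contacts, params)
        gt["separation"] = {
            "amplitude": float(profile.separation_amplitude),
            "predicted_final_q": final_q,
        }

    apr_truth = {}
    sasa_params = SasaParams()
    for name, sched in apr_sched.items():
        frac = float(sched.mean())
        resids = [int(r) for r in range(spec.apr_segments[name][0],
                                        spec.apr_segments[name][1] + 1)]
        s_bur = sum(residue_sasa(base.coords, base, sasa_params,
                                 residues=resids).values())
        exposed = base.coords.copy()
        exposed[apr_idx[name]] += profile.apr_displacement * apr_dir
        s_exp = sum(residue_sasa(exposed, base, sasa_params,
                                 residues=resids).values())
        apr_truth[name] = {
            "exposed_fraction": frac,
            "sasa_buried": float(s_bur),
            "sasa_exposed": float(s_exp),
            "predicted_change_pct": 100.0 * frac * (s_exp - s_bur) / s_bur,
        }
    gt["apr_exposure"] = apr_truth
    return gt


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(
    outdir,
    seed: int = 0,
    n_frames: int = 101,
    n_replicates: int = 6,
    conditions: Sequence[str] = _MODES,
    spec: Optional[ToyFabSpec] = None,
) -> Dict:
    """Write the synthetic fixture set: reference structure, per-condition
    multi-model PDB replicates, and the ground-truth JSON.

    Returns the manifest dict (paths plus ground truth per condition).
    """
    from pathlib import Path
    from .structure_io import write_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or ToyFabSpec()
    base = build_toy_fab(spec)
    (outdir / "reference_structure.pdb").write_text(write_structure(base))

    profiles = default_profiles(seed)
    manifest: Dict = {"seed": int(seed), "conditions": {},
                      "reference_structure": "reference_structure.pdb"}
    for cond in conditions:
        profile = profiles[cond]
        trajs, gt = simulate_stress_trajectory(
            base, profile, n_frames=n_frames, n_replicates=n_replicates,
            spec=spec)
        paths = []
        for r, traj in enumerate(trajs):
            path = outdir / f"{cond}_rep{r}.pdb"
            path.write_text(write_trajectory(traj))
            paths.append(path.name)
        manifest["conditions"][cond] = {"trajectories": paths,
                                        "ground_truth": gt}
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def recover_exposure_fraction(change_pct: float, sasa_buried: float,
                              sasa_exposed: float) -> float:
    """Invert a measured APR %-SASA change to the implied exposed-time fraction.

    Under the generator's two-state exposure model the condition-mean SASA is
    (1 - f) * S_buried + f * S_exposed, so the percent change against an
    always-buried reference is 100 * f * (S_exposed - S_buried) / S_buried.
    This inverts that relation; the result is the recovered schedule fraction
    (compare with the designed ``exposed_fraction``).
    """
    if sasa_exposed == sasa_buried:
        raise DegenerateInputError("degenerate two-state model: equal areas")
    return (change_pct / 100.0) * sasa_buried / (sasa_exposed - sasa_buried)
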