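"""Shrake-Rupley SASA, APR exposure change, and occluded-surface packing.

SASA uses quasi-uniform (golden-spiral) dots on each atom's expanded sphere
(r_vdw + probe): the accessible area is the dot fraction outside every
neighbour's expanded sphere times the sphere area.  OSP casts the outward
normal ray from each dot on the bare van der Waals sphere; a ray that meets
a neighbouring vdW surface within one water diameter contributes a weight
that decays linearly with the ray length, giving a 0-1 packing score
(0 = fully exposed, 1 = fully occluded at contact).

The OSP ray origin here is the vdW sphere itself (not a molecular surface),
a simpler bounded variant: values are comparable within this tool only.
All computations are heavy-atom; hydrogens never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, RegionError
from .structure_io import AprSet, Structure, Trajectory
from .superposition import mean_sem

__all__ = [
    "SasaParams",
    "OspParams",
    "residue_sasa",
    "apr_sasa_change",
    "occluded_surface_packing",
    "sphere_dots",
]

#: van der Waals radii (Angstrom) for heavy-atom protein models.
VDW_RADII: Dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_DEFAULT_RADIUS = VDW_RADII["C"]


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4    # Angstrom (water probe)
    n_dots: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_dots < 60:
            raise ValueError("need at least 60 dots per atom")


@dataclass(frozen=True)
class OspParams:
    max_ray_length: float = 2.8  # Angstrom, one water diameter
    n_dots: int = 960

    def __post_init__(self) -> None:
        if not self.max_ray_length > 0:
            raise ValueError("max ray length must be > 0")


def sphere_dots(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors via the golden-spiral construction."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack((np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)))


def _radii(structure: Structure) -> np.ndarray:
    out = np.empty(structure.n_atoms)
    unknown = set()
    for k, el in enumerate(structure.elements):
        r = VDW_RADII.get(str(el))
        if r is None:
            unknown.add(str(el))
            r = _DEFAULT_RADIUS
        out[k] = r
    if unknown:
        warnings.warn(f"unknown elements {sorted(unknown)} assigned carbon "
                      f"vdW radius", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def residue_sasa(
    frame: np.ndarray,
    structure: Structure,
    params: SasaParams = SasaParams(),
    residues: Optional[Sequence[int]] = None,
) -> Dict[int, float]:
    """Solvent-accessible surface area per residue, Angstrom^2.

    ``residues`` restricts the dot computation (neighbours still come from
    the whole structure), which makes trajectory-scale APR tracking cheap.
    """
    frame = np.asarray(frame, float)
    if structure.n_atoms == 0:
        raise DegenerateInputError("structure has no atoms")
    radii = _radii(structure)
    expanded = radii + params.probe_radius
    dots = sphere_dots(params.n_dots)
    tree = cKDTree(frame)
    max_exp = expanded.max()

    if residues is None:
        atom_sel = np.arange(structure.n_atoms)
    else:
        wanted = set(int(r) for r in residues)
        atom_sel = np.flatnonzero(
            np.fromiter((int(r) in wanted for r in structure.resseq),
                        bool, structure.n_atoms))

    out: Dict[int, float] = {}
    for a in atom_sel:
        ra = expanded[a]
        neigh = tree.query_ball_point(frame[a], ra + max_exp)
        neigh = [b for b in neigh if b != a]
        pts = frame[a] + ra * dots
        exposed = np.ones(params.n_dots, bool)
        for b in neigh:
            rb2 = expanded[b] ** 2
            d2 = np.sum((pts - frame[b]) ** 2, axis=1)
            exposed &= d2 > rb2
            if not exposed.any():
                break
        area = 4.0 * np.pi * ra * ra * exposed.mean()
        res = int(structure.resseq[a])
        out[res] = out.get(res, 0.0) + float(area)
    return out


def _apr_traj_means(trajs: Sequence[Trajectory], aprs: AprSet,
                    params: SasaParams, frame_stride: int) -> np.ndarray:
    """(n_replicates, n_aprs) time-mean summed SASA per APR."""
    names = list(aprs.regions)
    out = np.empty((len(trajs), len(names)))
    for r, traj in enumerate(trajs):
        all_res = sorted(set(int(x) for name in names for x in aprs.residues(name)))
        present = set(int(x) for x in traj.topology.residue_ids)
        missing = [x for x in all_res if x not in present]
        if missing:
            raise RegionError(f"APR residues {missing[:5]} not in the structure")
        sums = np.zeros(len(names))
        count = 0
        for k in range(0, traj.n_frames, frame_stride):
            per_res = residue_sasa(traj.frames[k], traj.topology, params,
                                   residues=all_res)
            for s, name in enumerate(names):
                sums[s] += sum(per_res[int(x)] for x in aprs.residues(name))
            count += 1
        out[r] = sums / count
    return out


def apr_sasa_change(
    stress: Sequence[Trajectory],
    reference: Sequence[Trajectory],
    aprs: AprSet,
    params: SasaParams = SasaParams(),
    frame_stride: int = 1,
) -> pd.DataFrame:
    """Percent SASA change of each APR between conditions.

    Per replicate pairing: 100 * (mean_stress - mean_ref) / mean_ref, then
    mean +/- SEM over replicates.  Columns: apr, sasa_ref, sasa_stress,
    change_pct, sem, n.
    """
    names = list(aprs.regions)
    ms = _apr_traj_means(stress, aprs, params, frame_stride)
    mr = _apr_traj_means(reference, aprs, params, frame_stride)
    n = min(ms.shape[0], mr.shape[0])
    if ms.shape[0] != mr.shape[0]:
        warnings.warn("replicate counts differ between conditions; pairing "
                      f"first {n} of each", stacklevel=2)
    ms, mr = ms[:n], mr[:n]
    rows = []
    for s, name in enumerate(names):
        change = 100.0 * (ms[:, s] - mr[:, s]) / mr[:, s]
        cmean, csem = mean_sem(change)
        rows.append({
            "apr": name,
            "sasa_ref": float(mr[:, s].mean()),
            "sasa_stress": float(ms[:, s].mean()),
            "change_pct": float(cmean),
            "sem": float(csem),
            "n": int(n),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Occluded-surface packing
# ---------------------------------------------------------------------------

def occluded_surface_packing(
    structure: Structure,
    params: OspParams = OspParams(),
    frame: Optional[np.ndarray] = None,
) -> Dict[int, float]:
    """Occluded-surface packing score per residue, in [0, 1].

    For each dot on an atom's vdW sphere the outward normal ray is cast; if
    it enters a neighbour's vdW sphere at ray length RL < RL_max the dot
    contributes weight (1 - RL/RL_max), else 0.  An atom's OSP is its mean
    dot weight; a residue's OSP is the vdW-area-weighted mean of its atoms.
    """
    coords = structure.coords if frame is None else np.asarray(frame, float)
    radii = _radii(structure)
    dots = sphere_dots(params.n_dots)
    tree = cKDTree(coords)
    reach = radii.max() * 2 + params.max_ray_length

    atom_osp = np.zeros(structure.n_atoms)
    for a in range(structure.n_atoms):
        ra = radii[a]
        neigh = [b for b in tree.query_ball_point(coords[a], ra + reach) if b != a]
        if not neigh:
            continue
        origins = coords[a] + ra * dots          # (d, 3)
        best_rl = np.full(params.n_dots, np.inf)
        for b in neigh:
            rb = radii[b]
            oc = origins - coords[b]             # (d, 3)
            bq = np.sum(oc * dots, axis=1)       # u . (p - c_b)
            cq = np.sum(oc * oc, axis=1) - rb * rb
            disc = bq * bq - cq
            valid = disc >= 0
            rl = np.full(params.n_dots, np.inf)
            sq = np.sqrt(np.clip(disc, 0, None))
            t_enter = -bq - sq
            inside = cq < 0                      # dot already inside neighbour
            rl[valid] = t_enter[valid]
            rl[inside] = 0.0
            rl[rl < 0] = np.inf                  # sphere behind the dot
            rl[inside] = 0.0
            best_rl = np.minimum(best_rl, rl)
        weights = np.clip(1.0 - best_rl / params.max_ray_length, 0.0, 1.0)
        weights[~np.isfinite(best_rl)] = 0.0
        atom_osp[a] = weights.mean()

    out: Dict[int, float] = {}
    for res in structure.residue_ids:
        idx = structure.atoms_of_residue(int(res))
        w = radii[idx] ** 2                      # proportional to vdW area
        out[int(res)] = float(np.sum(w * atom_osp[idx]) / np.sum(w))
    return out
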