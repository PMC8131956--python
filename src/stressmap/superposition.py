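"""Rigid-body superposition and deformation metrics: RMSD, windowed RMSF, Rg.

All metrics operate on heavy atoms ("all-atom" here means all heavy atoms,
side chains included).  Domain metrics superpose each frame onto the
reference using only the domain's own atoms, so inter-domain motion never
inflates intra-domain deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError, RegionError, ShapeError
from .structure_io import DomainMap, Structure, Trajectory, select_region

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "AggregatedSeries",
    "kabsch_superpose",
    "domain_rmsd_series",
    "windowed_rmsf",
    "radius_of_gyration",
    "aggregate_replicates",
    "atom_masses",
]

#: Standard atomic masses (u) for the elements of a heavy-atom protein model.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "Se": 78.971,
}
_DEFAULT_MASS = ATOMIC_MASSES["C"]


def atom_masses(elements: Sequence[str]) -> np.ndarray:
    """Per-atom masses from a fixed element table; unknown elements get the
    carbon mass with a warning."""
    out = np.empty(len(elements))
    unknown = set()
    for i, el in enumerate(elements):
        m = ATOMIC_MASSES.get(str(el))
        if m is None:
            unknown.add(str(el))
            m = _DEFAULT_MASS
        out[i] = m
    if unknown:
        warnings.warn(f"unknown elements {sorted(unknown)} assigned carbon mass",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------

@dataclass
class RmsdSeries:
    region: str
    times_ns: np.ndarray
    values: np.ndarray           # Angstrom, one per frame
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, float)
        self.values = np.asarray(self.values, float)
        if self.times_ns.shape != self.values.shape:
            raise ShapeError("times and values must align")
        if self.values.size and self.values.min() < -1e-12:
            raise ShapeError("RMSD values must be >= 0")


@dataclass
class RmsfProfile:
    region: str
    window_index: int
    window_start_ns: float
    window_end_ns: float
    residues: np.ndarray         # residue numbers
    values: np.ndarray           # Angstrom, per residue
    replicate: int = 0


@dataclass
class AggregatedSeries:
    """Per-time replicate statistics (mean and SEM over replicates)."""

    region: str
    times_ns: np.ndarray
    mean: np.ndarray
    sem: np.ndarray              # sample sd / sqrt(n); 0 when n == 1
    n_replicates: int
    single_replicate: bool = field(default=False)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the (weighted) RMSD to
    ``reference``.  The rotation is proper (determinant +1) via the standard
    sign correction of the smallest singular direction.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ShapeError(
            f"mobile {mobile.shape} and reference {reference.shape} differ")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError("coordinates must be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError("need >= 3 atoms for a unique superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,):
            raise ShapeError("weights must be one per atom")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm

    fitted = x @ rotation.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - y) ** 2)))
    return rotation, translation, rmsd


def _fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    return kabsch_superpose(mobile, reference)[2]


# ---------------------------------------------------------------------------
# Trajectory metrics
# ---------------------------------------------------------------------------

def domain_rmsd_series(
    traj: Trajectory,
    reference: Structure,
    region: str,
    domain_map: DomainMap,
    replicate: int = 0,
) -> RmsdSeries:
    """All-heavy-atom RMSD of a region per frame, each frame superposed onto
    the reference using that region's atoms only."""
    idx = select_region(reference, domain_map, region)
    if isinstance(idx, tuple):
        idx = np.concatenate(idx)
    if idx.size == 0:
        raise RegionError(f"region {region} is empty in the reference")
    if traj.topology.n_atoms != reference.n_atoms:
        raise ShapeError("trajectory topology and reference atom counts differ")
    ref = reference.coords[idx]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        values[k] = _fit_rmsd(traj.frames[k][idx], ref)
    return RmsdSeries(region, traj.times_ns, values, replicate)


def _window_slices(n_frames: int, interval_ns: float, window_ns: float) -> List[np.ndarray]:
    """Partition frame indices into consecutive non-overlapping time windows.

    A frame landing exactly on a window boundary joins the preceding window,
    so 0..100 ns at 0.1 ns/frame gives exactly 10 windows.
    """
    t = np.arange(n_frames) * interval_ns
    # small epsilon guards against float noise pushing an exact boundary up
    w = np.ceil(t / window_ns - 1e-9).astype(int) - 1
    w[w < 0] = 0
    return [np.flatnonzero(w == k) for k in range(int(w.max()) + 1)]


def windowed_rmsf(
    traj: Trajectory,
    region: str,
    domain_map: DomainMap,
    window_ns: float = 10.0,
    reference: Optional[Structure] = None,
    replicate: int = 0,
) -> List[RmsfProfile]:
    """Per-residue RMSF in consecutive non-overlapping time windows.

    Each frame is superposed onto the (static) reference using the region's
    atoms; fluctuations are taken about the window-mean coordinates, then
    averaged over each residue's atoms.
    """
    if window_ns < 2 * traj.frame_interval_ns:
        raise DegenerateInputError(
            f"window of {window_ns} ns holds fewer than two frames at "
            f"{traj.frame_interval_ns} ns/frame")
    if reference is None:
        reference = traj.topology
    idx = select_region(reference, domain_map, region)
    if isinstance(idx, tuple):
        idx = np.concatenate(idx)
    if idx.size == 0:
        raise RegionError(f"region {region} is empty")
    ref = reference.coords[idx]
    resids = traj.topology.resseq[idx]
    residues = np.unique(resids)

    profiles: List[RmsfProfile] = []
    for wi, frames_in_window in enumerate(_window_slices(
            traj.n_frames, traj.frame_interval_ns, window_ns)):
        fitted = np.empty((frames_in_window.size, idx.size, 3))
        for j, k in enumerate(frames_in_window):
            mob = traj.frames[k][idx]
            rot, trans, _ = kabsch_superpose(mob, ref)
            fitted[j] = mob @ rot.T + trans
        mean_coords = fitted.mean(axis=0)
        per_atom = np.sqrt(np.mean(np.sum((fitted - mean_coords) ** 2, axis=2), axis=0))
        per_res = np.array([per_atom[resids == r].mean() for r in residues])
        t0 = float(frames_in_window[0] * traj.frame_interval_ns)
        t1 = float(frames_in_window[-1] * traj.frame_interval_ns)
        profiles.append(RmsfProfile(region, wi, t0, t1, residues, per_res, replicate))
    return profiles


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the center of mass, in Angstrom."""
    coords = np.asarray(coords, float)
    masses = np.asarray(masses, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ShapeError("coords must be (n, 3)")
    if coords.shape[0] < 1:
        raise DegenerateInputError("need at least one atom")
    if masses.shape != (coords.shape[0],):
        raise ShapeError("one mass per atom required")
    total = masses.sum()
    if not total > 0:
        raise DegenerateInputError("total mass must be > 0")
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((masses * np.sum((coords - com) ** 2, axis=1)).sum() / total))


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

def aggregate_replicates(series_list: Sequence[RmsdSeries]) -> AggregatedSeries:
    """Per-time mean and SEM (sample sd / sqrt(n)) over replicate series.

    All series must share region and time axis.  With a single replicate the
    SEM is 0 and the result is flagged.
    """
    if not series_list:
        raise DegenerateInputError("no series to aggregate")
    first = series_list[0]
    for s in series_list[1:]:
        if s.region != first.region:
            raise ShapeError(f"regions differ: {s.region} vs {first.region}")
        if s.times_ns.shape != first.times_ns.shape or not np.allclose(
                s.times_ns, first.times_ns):
            raise ShapeError("replicate series have mismatched time axes")
    values = np.stack([s.values for s in series_list])
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n == 1:
        warnings.warn("single replicate: SEM reported as 0", stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
    return AggregatedSeries(first.region, first.times_ns, mean, sem, n,
                            single_replicate=(n == 1))


def mean_sem(values: np.ndarray, axis: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and SEM (n-1 sd) along an axis; SEM is 0 for a single sample."""
    values = np.asarray(values, float)
    n = values.shape[axis]
    mean = values.mean(axis=axis)
    if n == 1:
        return mean, np.zeros_like(mean)
    return mean, values.std(axis=axis, ddof=1) / np.sqrt(n)
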