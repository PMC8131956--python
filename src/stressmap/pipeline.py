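"""Config-driven orchestration of the comparative stress analysis.

``run_comparison`` reads one structured config (YAML or a dict), loads the
reference structure and every condition's replicate trajectories, and writes
the full comparative report as CSV tables plus score-projected PDBs:

* per-domain RMSD and per-region native-contact Q time series with
  replicate mean +/- SEM,
* windowed per-residue RMSF profiles,
* salt-bridge occurrence tables and per-region counts,
* per-strand beta-occupancy change versus the reference condition,
* per-APR SASA change versus the reference condition,
* per-residue delta maps (stress - reference) for RMSF and Q, also
  projected onto the structure's B-factor column.

The delta convention is always stress - reference (positive = increase
under stress).  Replicates are paired by index when counts match; otherwise
unpaired means are differenced and SEMs combine in quadrature.  Outputs are
deterministic: floats are written with 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (ContactParams, build_reference_contacts, contact_series,
                       residue_fraction)
from .errors import ConfigError
from .saltbridges import (SaltBridgeParams, aggregate_occurrence,
                          bridge_occurrence, count_by_region)
from .secondary import HBondParams, strand_occupancy_change
from .structure_io import (AprSet, DomainMap, StrandMap, Structure, Trajectory,
                           default_apr_set, default_domain_map,
                           default_strand_map, read_structure, read_trajectory,
                           write_score_projection)
from .superposition import (aggregate_replicates, domain_rmsd_series,
                            mean_sem, windowed_rmsf)
from .surface import SasaParams, apr_sasa_change

logger = logging.getLogger("stressmap")

_FLOAT_FORMAT = "%.6g"

__all__ = ["RunConfig", "ConditionReport", "run_comparison", "load_config"]


@dataclass
class ConditionData:
    name: str
    role: str                    # "reference" | "stress"
    trajectories: List[Trajectory]


@dataclass
class RunConfig:
    reference_structure: Structure
    conditions: List[ConditionData]
    domain_map: DomainMap
    strand_map: StrandMap
    apr_set: AprSet
    contact_params: ContactParams = field(default_factory=ContactParams)
    saltbridge_params: SaltBridgeParams = field(default_factory=SaltBridgeParams)
    sasa_params: SasaParams = field(default_factory=SasaParams)
    hbond_params: HBondParams = field(default_factory=HBondParams)
    rmsf_window_ns: float = 10.0
    occurrence_threshold: float = 10.0
    relative_strand_change: bool = True
    frame_stride: int = 1        # for the per-frame SS / SASA passes
    seed: int = 0
    raw: Dict = field(default_factory=dict)

    @property
    def reference_condition(self) -> ConditionData:
        refs = [c for c in self.conditions if c.role == "reference"]
        if len(refs) != 1:
            raise ConfigError("config must name exactly one reference condition")
        return refs[0]

    @property
    def stress_conditions(self) -> List[ConditionData]:
        return [c for c in self.conditions if c.role != "reference"]


@dataclass
class ConditionReport:
    """Pointers to every table computed for one stress (or reference) condition."""

    condition: str
    tables: Dict[str, pd.DataFrame]
    delta_residue: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def _region_maps(regions_cfg) -> Tuple[DomainMap, StrandMap, AprSet]:
    if regions_cfg in (None, "default", "fab"):
        return default_domain_map(), default_strand_map(), default_apr_set()
    if regions_cfg == "toy":
        from .synthetic import toy_apr_set, toy_domain_map, toy_strand_map
        return toy_domain_map(), toy_strand_map(), toy_apr_set()
    domains = {k: tuple(v) for k, v in regions_cfg["domains"].items()}
    interfaces = {k: tuple(v) for k, v in
                  regions_cfg.get("interfaces", {}).items()}
    dmap = DomainMap(domains, interfaces)
    smap = StrandMap({k: tuple(v) for k, v in
                      regions_cfg.get("strands", {}).items()}, domain_map=dmap)
    aprs = AprSet({k: tuple(v) for k, v in regions_cfg.get("aprs", {}).items()})
    return dmap, smap, aprs


def load_config(path) -> RunConfig:
    """Load and validate a run configuration (YAML file or dict).

    Fails fast: every referenced file must exist before any computation.
    """
    if isinstance(path, dict):
        cfg = path
        base_dir = Path(cfg.get("base_dir", "."))
    else:
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base_dir = Path(cfg.get("base_dir", path.parent))

    if "reference_structure" not in cfg:
        raise ConfigError("config missing reference_structure")
    ref_path = base_dir / cfg["reference_structure"]
    if not ref_path.exists():
        raise ConfigError(f"reference structure not found: {ref_path}")

    conditions_cfg = cfg.get("conditions", [])
    if not conditions_cfg:
        raise ConfigError("config lists no conditions")
    # fail-fast file check before reading anything
    for cond in conditions_cfg:
        for tp in cond.get("trajectories", []):
            if not (base_dir / tp).exists():
                raise ConfigError(f"trajectory file not found: {base_dir / tp}")

    reference = read_structure(ref_path.read_text(), renumber=False)
    interval = float(cfg.get("frame_interval_ns", 0.1))
    conditions: List[ConditionData] = []
    for cond in conditions_cfg:
        trajs = [read_trajectory((base_dir / tp).read_text(), renumber=False,
                                 frame_interval_ns=interval)
                 for tp in cond.get("trajectories", [])]
        if not trajs:
            raise ConfigError(f"condition {cond['name']} has no trajectories")
        conditions.append(ConditionData(cond["name"],
                                        cond.get("role", "stress"), trajs))

    dmap, smap, aprs = _region_maps(cfg.get("regions"))
    params = cfg.get("parameters", {})
    return RunConfig(
        reference_structure=reference,
        conditions=conditions,
        domain_map=dmap, strand_map=smap, apr_set=aprs,
        contact_params=ContactParams(**params.get("contact", {})),
        saltbridge_params=SaltBridgeParams(**params.get("saltbridge", {})),
        sasa_params=SasaParams(**params.get("sasa", {})),
        hbond_params=HBondParams(**params.get("hbond", {})),
        rmsf_window_ns=float(params.get("rmsf_window_ns", 10.0)),
        occurrence_threshold=float(params.get("occurrence_threshold", 10.0)),
        relative_strand_change=bool(params.get("relative_strand_change", True)),
        frame_stride=int(params.get("frame_stride", 1)),
        seed=int(cfg.get("seed", 0)),
        raw=cfg,
    )


# ---------------------------------------------------------------------------
# Per-condition metric tables
# ---------------------------------------------------------------------------

def _rmsd_tables(cond: ConditionData, reference: Structure, dmap: DomainMap):
    rows = []
    agg_rows = []
    for region in dmap.region_names:
        series = [domain_rmsd_series(t, reference, region, dmap, replicate=r)
                  for r, t in enumerate(cond.trajectories)]
        for s in series:
            for t_ns, v in zip(s.times_ns, s.values):
                rows.append((region, s.replicate, t_ns, v))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            agg = aggregate_replicates(series)
        for t_ns, m, e in zip(agg.times_ns, agg.mean, agg.sem):
            agg_rows.append((region, t_ns, m, e, agg.n_replicates))
    per_rep = pd.DataFrame(rows, columns=["region", "replicate", "time_ns", "value"])
    agg_df = pd.DataFrame(agg_rows,
                          columns=["region", "time_ns", "mean", "sem", "n"])
    return per_rep, agg_df


def _q_tables(cond: ConditionData, reference: Structure, dmap: DomainMap,
              params: ContactParams):
    rows, agg_rows = [], []
    contact_sets = {}
    for region in dmap.region_names:
        contacts = build_reference_contacts(reference, region, dmap, params)
        if contacts.n_pairs == 0:
            logger.warning("region %s has no native contacts; skipped", region)
            continue
        contact_sets[region] = contacts
        qseries = [contact_series(t, contacts, params, replicate=r)
                   for r, t in enumerate(cond.trajectories)]
        for s in qseries:
            for t_ns, v in zip(s.times_ns, s.q):
                rows.append((region, s.replicate, t_ns, v))
        values = np.stack([s.q for s in qseries])
        m, e = mean_sem(values)
        for k, t_ns in enumerate(qseries[0].times_ns):
            agg_rows.append((region, t_ns, m[k], e[k], values.shape[0]))
    per_rep = pd.DataFrame(rows, columns=["region", "replicate", "time_ns", "q"])
    agg_df = pd.DataFrame(agg_rows,
                          columns=["region", "time_ns", "mean", "sem", "n"])
    return per_rep, agg_df, contact_sets


def _rmsf_table(cond: ConditionData, reference: Structure, dmap: DomainMap,
                window_ns: float) -> pd.DataFrame:
    rows = []
    for region in dmap.domains:
        for r, traj in enumerate(cond.trajectories):
            for prof in windowed_rmsf(traj, region, dmap, window_ns,
                                      reference=reference, replicate=r):
                for res, v in zip(prof.residues, prof.values):
                    rows.append((region, r, prof.window_index,
                                 prof.window_start_ns, prof.window_end_ns,
                                 int(res), v))
    return pd.DataFrame(rows, columns=["region", "replicate", "window",
                                       "t_start_ns", "t_end_ns", "residue",
                                       "rmsf"])


def _saltbridge_tables(cond: ConditionData, params: SaltBridgeParams,
                       dmap: DomainMap, threshold: float):
    reps = [bridge_occurrence(t, params) for t in cond.trajectories]
    table = aggregate_occurrence(reps, threshold=threshold)
    counts = count_by_region(table, dmap)
    counts_df = pd.DataFrame(sorted(counts.items()),
                             columns=["region", "count"])
    return table.table, counts_df


# ---------------------------------------------------------------------------
# Residue-level deltas
# ---------------------------------------------------------------------------

def _final_window_rmsf(cond: ConditionData, reference: Structure,
                       dmap: DomainMap, window_ns: float) -> Dict[int, float]:
    """Replicate-mean RMSF of the final time window, per residue."""
    acc: Dict[int, List[float]] = {}
    for region in dmap.domains:
        for traj in cond.trajectories:
            prof = windowed_rmsf(traj, region, dmap, window_ns,
                                 reference=reference)[-1]
            for res, v in zip(prof.residues, prof.values):
                acc.setdefault(int(res), []).append(float(v))
    return {res: float(np.mean(vs)) for res, vs in acc.items()}


def _final_residue_q(cond: ConditionData, contact_sets, reference: Structure,
                     params: ContactParams) -> Dict[int, float]:
    """Replicate-mean residue-level Q of the final frame, per residue."""
    acc: Dict[int, List[float]] = {}
    for contacts in contact_sets.values():
        for traj in cond.trajectories:
            rf = residue_fraction(traj.frames[-1], contacts, params)
            for res, v in rf.items():
                acc.setdefault(int(res), []).append(float(v))
    return {res: float(np.mean(vs)) for res, vs in acc.items()}


def _delta_map(stress: Dict[int, float], ref: Dict[int, float]) -> Dict[int, float]:
    return {res: stress[res] - ref[res] for res in stress if res in ref}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def run_comparison(config, outdir) -> Dict[str, ConditionReport]:
    """Run the full comparative analysis and write all outputs to ``outdir``.

    ``config`` is a YAML path or a config dict (see ``load_config``).
    Returns the per-condition reports keyed by condition name.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference_cond = cfg.reference_condition
    ref_struct = cfg.reference_structure

    reports: Dict[str, ConditionReport] = {}
    per_cond_cache: Dict[str, Dict] = {}

    for cond in cfg.conditions:
        logger.info("analysing condition %s (%d replicates)", cond.name,
                    len(cond.trajectories))
        cdir = outdir / cond.name
        cdir.mkdir(exist_ok=True)
        tables: Dict[str, pd.DataFrame] = {}

        rmsd_rep, rmsd_agg = _rmsd_tables(cond, ref_struct, cfg.domain_map)
        tables["rmsd"] = rmsd_rep
        tables["rmsd_agg"] = rmsd_agg
        _write_csv(rmsd_rep, cdir / "rmsd.csv")
        _write_csv(rmsd_agg, cdir / "rmsd_agg.csv")

        q_rep, q_agg, contact_sets = _q_tables(cond, ref_struct,
                                               cfg.domain_map,
                                               cfg.contact_params)
        tables["q"] = q_rep
        tables["q_agg"] = q_agg
        _write_csv(q_rep, cdir / "native_contacts.csv")
        _write_csv(q_agg, cdir / "native_contacts_agg.csv")

        rmsf_df = _rmsf_table(cond, ref_struct, cfg.domain_map,
                              cfg.rmsf_window_ns)
        tables["rmsf"] = rmsf_df
        _write_csv(rmsf_df, cdir / "rmsf.csv")

        sb_df, sb_counts = _saltbridge_tables(cond, cfg.saltbridge_params,
                                              cfg.domain_map,
                                              cfg.occurrence_threshold)
        tables["saltbridges"] = sb_df
        tables["saltbridge_counts"] = sb_counts
        _write_csv(sb_df, cdir / "saltbridges.csv")
        _write_csv(sb_counts, cdir / "saltbridge_counts.csv")

        per_cond_cache[cond.name] = {
            "contact_sets": contact_sets,
            "cond": cond,
        }
        reports[cond.name] = ConditionReport(cond.name, tables)

    # cross-condition deltas (stress - reference)
    ref_cache = per_cond_cache[reference_cond.name]
    ref_rmsf = _final_window_rmsf(reference_cond, ref_struct, cfg.domain_map,
                                  cfg.rmsf_window_ns)
    ref_q = _final_residue_q(reference_cond, ref_cache["contact_sets"],
                             ref_struct, cfg.contact_params)

    for cond in cfg.stress_conditions:
        cdir = outdir / cond.name
        report = reports[cond.name]

        if len(cond.trajectories) != len(reference_cond.trajectories):
            warnings.warn(
                f"condition {cond.name} has {len(cond.trajectories)} replicates "
                f"vs {len(reference_cond.trajectories)} in the reference; "
                f"pairing falls back to unpaired statistics", stacklevel=2)

        strand_df = strand_occupancy_change(
            cond.trajectories, reference_cond.trajectories, cfg.strand_map,
            cfg.hbond_params, relative=cfg.relative_strand_change,
            frame_stride=cfg.frame_stride)
        report.tables["strand_occupancy"] = strand_df
        _write_csv(strand_df, cdir / "strand_occupancy.csv")

        if len(cfg.apr_set):
            apr_df = apr_sasa_change(
                cond.trajectories, reference_cond.trajectories, cfg.apr_set,
                cfg.sasa_params, frame_stride=cfg.frame_stride)
            report.tables["apr_sasa"] = apr_df
            _write_csv(apr_df, cdir / "apr_sasa.csv")

        stress_rmsf = _final_window_rmsf(cond, ref_struct, cfg.domain_map,
                                         cfg.rmsf_window_ns)
        stress_q = _final_residue_q(cond, ref_cache["contact_sets"],
                                    ref_struct, cfg.contact_params)
        d_rmsf = _delta_map(stress_rmsf, ref_rmsf)
        d_q = _delta_map(stress_q, ref_q)
        delta_df = pd.DataFrame(
            [(res, d_rmsf.get(res, np.nan), d_q.get(res, np.nan))
             for res in sorted(set(d_rmsf) | set(d_q))],
            columns=["residue", "delta_rmsf", "delta_q"])
        report.delta_residue = delta_df
        _write_csv(delta_df, cdir / "delta_residue.csv")
        (cdir / "delta_rmsf_projection.pdb").write_text(
            write_score_projection(ref_struct, d_rmsf))
        (cdir / "delta_q_projection.pdb").write_text(
            write_score_projection(ref_struct, d_q))

    manifest = {
        "stressmap_version": __version__,
        "seed": cfg.seed,
        "reference_condition": reference_cond.name,
        "conditions": {c.name: {"role": c.role,
                                "n_replicates": len(c.trajectories),
                                "n_frames": c.trajectories[0].n_frames}
                       for c in cfg.conditions},
        "parameters": {
            "contact": vars(cfg.contact_params),
            "saltbridge": vars(cfg.saltbridge_params),
            "sasa": vars(cfg.sasa_params),
            "rmsf_window_ns": cfg.rmsf_window_ns,
            "occurrence_threshold": cfg.occurrence_threshold,
            "strand_change_mode": ("relative" if cfg.relative_strand_change
                                   else "absolute"),
            "frame_stride": cfg.frame_stride,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return reports
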