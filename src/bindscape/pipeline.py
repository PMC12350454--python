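"""End-to-end comparative workflow: stability → FEL → crucial interval →
representative frame → DCCM → MM/GBSA → decomposition → interactions,
with machine-readable outputs per system and a pairwise comparison
report when two systems are given.

Outputs are deterministic for a fixed config and seed; every CSV/JSON
carries a header block with the package version, a config hash and the
seed, and a MANIFEST records which stages completed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import BindscapeError, StageError, ValidationError
from .essential import dccm, fit_pca, region_correlation_summary, smallest_k_for_variance
from .energetics import GBSAParams, mmgbsa, per_residue_decomposition
from .geometry import (
    average_replicas,
    com_distance_series,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    select_stable_replica,
)
from .interactions import (
    detect_contacts,
    detect_hbonds,
    detect_pi_stacking,
    fingerprint_diff,
)
from .io import read_pdb, read_topology_json, read_trajectory, write_pdb
from .landscape import (
    compute_fel,
    crucial_interval,
    find_ground_basin,
    frame_basin_membership,
    representative_frame,
)
from .topology import select

logger = logging.getLogger(__name__)

__all__ = ["SystemConfig", "RunConfig", "run_pipeline", "load_config"]


@dataclass
class SystemConfig:
    """Input files and selections for one simulated system."""

    name: str
    topology_pdb: str
    topology_json: str
    trajectories: list[str]
    frame_spacing_ps: Optional[float] = None
    protein_selection: str = "segment:protein"
    ligand_selection: str = "segment:ligand"
    cv_residue_selection: str = ""          # e.g. "resid:11" — the CV anchor
    probe_pair: Optional[list[str]] = None  # two queries for a COM-distance probe
    region_p: list[int] = field(default_factory=list)  # pocket residue ids
    region_c: list[int] = field(default_factory=list)  # C-terminal residue ids


@dataclass
class RunConfig:
    """Full pipeline configuration (one or two systems)."""

    systems: list[SystemConfig]
    output_dir: str = "bindscape_out"
    seed: int = 0
    temperature_K: float = 310.0
    n_bins: int = 50
    basin_cutoff_kcal: Optional[float] = None   # default: 1 kT
    window_frames: int = 100
    stability_window_frames: Optional[int] = None  # default: window_frames
    pc_variance_threshold: float = 0.5
    gbsa: dict = field(default_factory=dict)       # GBSAParams overrides
    interactions: dict = field(default_factory=dict)
    occupancy_min: float = 0.5

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs land is
        excluded, so re-running into another directory is comparable)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON document."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    systems = [SystemConfig(**s) for s in doc.pop("systems")]
    return RunConfig(systems=systems, **doc)


def _header_lines(config: RunConfig) -> list[str]:
    return [
        f"# bindscape {__version__}",
        f"# config {config.config_hash()}",
        f"# seed {config.seed}",
    ]


def _write_csv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"_meta": {"package": f"bindscape {__version__}",
                         "config": config.config_hash(),
                         "seed": config.seed}, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _record_stage(manifest: dict, stage: str, status: str, **info) -> None:
    manifest["stages"].append({"stage": stage, "status": status, **info})


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for each system; returns the MANIFEST dict.

    Any stage error aborts with a :class:`StageError` naming the stage;
    outputs produced so far stay on disk and the MANIFEST notes the
    incomplete state.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "complete": False,
        "stages": [],
        "systems": {},
    }
    per_system: dict[str, dict] = {}
    try:
        for system in config.systems:
            per_system[system.name] = _run_system(system, config, out_root, manifest)
        if len(config.systems) == 2:
            _compare_systems(config, out_root, per_system, manifest)
        manifest["complete"] = True
    finally:
        _write_json(out_root / "MANIFEST.json", manifest, config)
    return manifest


def _run_system(system: SystemConfig, config: RunConfig, out_root: Path,
                manifest: dict) -> dict:
    out = out_root / system.name
    out.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
                _record_stage(manifest, f"{system.name}:{name}", "ok")
            except BindscapeError as exc:
                _record_stage(manifest, f"{system.name}:{name}", "failed",
                              error=str(exc))
                raise StageError(f"{system.name}:{name}", exc) from exc
        return deco

    @stage("load")
    def _load():
        topology, ref = read_pdb(system.topology_pdb)
        topology = read_topology_json(system.topology_json, topology)
        state["topology"] = topology
        state["reference"] = ref
        state["replicas"] = [
            read_trajectory(p, topology, system.frame_spacing_ps)
            for p in system.trajectories
        ]
        state["protein"] = select(topology, system.protein_selection)
        state["ligand"] = select(topology, system.ligand_selection)
        if len(state["protein"]) == 0 or len(state["ligand"]) == 0:
            raise ValidationError(
                f"empty protein/ligand selection for system {system.name}"
            )

    @stage("stability")
    def _stability():
        top, prot, lig = state["topology"], state["protein"], state["ligand"]
        rows = {}
        prot_series = []
        for r, traj in enumerate(state["replicas"]):
            p_rmsd = rmsd_series(traj, top, prot, fit_selection=prot,
                                 label=f"protein_rmsd_rep{r}")
            l_rmsd = rmsd_series(traj, top, lig, fit_selection=prot,
                                 label=f"ligand_rmsd_rep{r}")
            rog = radius_of_gyration(traj, top, prot, label=f"rog_rep{r}")
            prot_series.append(p_rmsd)
            rows[p_rmsd.label] = p_rmsd.values
            rows[l_rmsd.label] = l_rmsd.values
            rows[rog.label] = rog.values
        if len(prot_series) > 1:
            rows["protein_rmsd_mean"] = average_replicas(*prot_series).values
        window = config.stability_window_frames or config.window_frames
        chosen = select_stable_replica(prot_series, window)
        state["replica"] = state["replicas"][chosen]
        state["chosen_replica"] = chosen
        df = pd.DataFrame(rows)
        df.insert(0, "time_ps", state["replicas"][0].times_ps)
        _write_csv(out / "stability.csv", df, config)
        prof = rmsf(state["replica"], top, prot)
        _write_csv(out / "rmsf.csv",
                   pd.DataFrame({"residue": np.arange(len(prof)) + 1,
                                 "rmsf": prof.values}), config)

    @stage("cv")
    def _cv():
        top, lig = state["topology"], state["ligand"]
        traj = state["replica"]
        anchor = select(top, system.cv_residue_selection)
        if len(anchor) == 0:
            raise ValidationError(
                f"cv_residue_selection {system.cv_residue_selection!r} empty"
            )
        dist = com_distance_series(traj, top, lig, anchor, label="cv_com_distance")
        lig_rmsd = rmsd_series(traj, top, lig, fit_selection=state["protein"],
                               label="cv_ligand_rmsd")
        state["cv_x"] = dist.values
        state["cv_y"] = lig_rmsd.values
        df = pd.DataFrame({"time_ps": traj.times_ps, "com_distance": dist.values,
                           "ligand_rmsd": lig_rmsd.values})
        if system.probe_pair:
            a = select(top, system.probe_pair[0])
            b = select(top, system.probe_pair[1])
            probe = com_distance_series(traj, top, a, b, label="probe_distance")
            df["probe_distance"] = probe.values
        _write_csv(out / "cv.csv", df, config)

    @stage("fel")
    def _fel():
        fel = compute_fel(state["cv_x"], state["cv_y"], config.n_bins,
                          config.temperature_K)
        basin = find_ground_basin(fel, config.basin_cutoff_kcal)
        state["fel"], state["basin"] = fel, basin
        state["membership"] = frame_basin_membership(
            state["cv_x"], state["cv_y"], fel, basin)
        xc = 0.5 * (fel.x_edges[:-1] + fel.x_edges[1:])
        yc = 0.5 * (fel.y_edges[:-1] + fel.y_edges[1:])
        ii, jj = np.meshgrid(np.arange(len(xc)), np.arange(len(yc)), indexing="ij")
        df = pd.DataFrame({
            "x_center": xc[ii.ravel()], "y_center": yc[jj.ravel()],
            "count": fel.counts.ravel(), "G_kcal": fel.G.ravel(),
            "in_basin": [(i, j) in basin.member_bins
                         for i, j in zip(ii.ravel(), jj.ravel())],
        })
        _write_csv(out / "fel.csv", df, config)

    @stage("crucial")
    def _crucial():
        interval = crucial_interval(state["membership"], config.window_frames)
        rep = representative_frame(interval, state["membership"])
        state["interval"] = interval
        _write_json(out / "crucial.json", {
            "start_frame": interval.start_frame,
            "end_frame": interval.end_frame,
            "in_basin_count": interval.in_basin_count,
            "representative_frame": rep,
        }, config)
        write_pdb(out / "representative.pdb", state["topology"],
                  state["replica"].coordinates[rep])

    @stage("dccm")
    def _dccm():
        from .essential import _site_indices
        from .topology import Selection

        top, prot = state["topology"], state["protein"]
        traj = state["replica"]
        sites, _ = _site_indices(top, prot)
        site_sel = Selection(indices=tuple(sites))
        model = fit_pca(traj, top, site_sel)
        k = smallest_k_for_variance(model, config.pc_variance_threshold)
        window = (state["interval"].start_frame, state["interval"].end_frame)
        mat = dccm(traj, top, prot, frame_window=window, pc_subset=k, model=model)
        state["dccm"] = mat
        df = pd.DataFrame(mat.matrix, columns=[str(r) for r in mat.residue_ids])
        df.insert(0, "residue", mat.residue_ids)
        _write_csv(out / "dccm.csv", df, config)
        summaries = {"pc_subset": k,
                     "variance_explained": float(sum(
                         model.eigenvalues[:k]) / max(model.eigenvalues.sum(), 1e-300))}
        regions = {"P": system.region_p, "C": system.region_c}
        for label, region in regions.items():
            if len(region) >= 2:
                mean, frac_pos = region_correlation_summary(mat, region, region)
                summaries[f"{label}-{label}"] = {"mean": mean,
                                                 "fraction_positive": frac_pos}
        state["region_summaries"] = summaries
        _write_json(out / "regions.json", summaries, config)

    @stage("gbsa")
    def _gbsa():
        window = (state["interval"].start_frame, state["interval"].end_frame)
        params = GBSAParams(**config.gbsa)
        comps = mmgbsa(state["replica"], state["topology"], state["protein"],
                       state["ligand"], frame_window=window, params=params)
        state["energy"] = comps
        summary = comps.summary()
        df = pd.DataFrame({
            "quantity": ["dE_vdW", "dE_eel", "dG_GB", "dE_Surf",
                         "dG_gas", "dG_solv", "dG_binding"],
            "mean": [summary[k][0] for k in
                     ("vdw", "eel", "gb", "surf", "gas", "solv", "total")],
            "sd": [summary[k][1] for k in
                   ("vdw", "eel", "gb", "surf", "gas", "solv", "total")],
        })
        _write_csv(out / "energy.csv", df, config)

    @stage("decomp")
    def _decomp():
        window = (state["interval"].start_frame, state["interval"].end_frame)
        params = GBSAParams(**config.gbsa)
        decomp = per_residue_decomposition(
            state["replica"], state["topology"], state["protein"],
            state["ligand"], frame_window=window, params=params)
        rows = []
        for (seg, rid, rname), means in decomp.residue_means().items():
            rows.append({"segment": seg, "residue_id": rid, "residue_name": rname,
                         **means})
        lig_means = {c: float(np.mean(v)) for c, v in decomp.ligand_term.items()}
        lig_means["total"] = float(np.mean(sum(decomp.ligand_term.values())))
        lig_means["total_sd"] = float(np.std(sum(decomp.ligand_term.values())))
        rows.append({"segment": "ligand", "residue_id": 0, "residue_name": "LIG",
                     **lig_means})
        _write_csv(out / "decomposition.csv", pd.DataFrame(rows), config)

    @stage("interactions")
    def _interactions():
        window = (state["interval"].start_frame, state["interval"].end_frame)
        kw = dict(config.interactions)
        traj, top = state["replica"], state["topology"]
        records = []
        records += detect_hbonds(
            traj, top, window,
            **{k: kw[k] for k in ("d_max", "angle_min") if k in kw})
        records += detect_contacts(
            traj, top, window, **{k: kw[k] for k in ("pad",) if k in kw})
        pi_kw = {}
        if "pi_d_max" in kw:
            pi_kw["d_max"] = kw["pi_d_max"]
        if "tilt_max" in kw:
            pi_kw["tilt_max"] = kw["tilt_max"]
        records += detect_pi_stacking(traj, top, window, **pi_kw)
        state["interactions"] = records
        rows = [{
            "kind": r.kind, "partner_residue_id": r.partner_residue_id,
            "ligand_atoms": ";".join(map(str, r.ligand_atoms)),
            "occupancy": r.occupancy, "mean_distance": r.mean_distance,
            "mean_angle": r.mean_angle,
        } for r in records]
        _write_csv(out / "interactions.csv", pd.DataFrame(rows), config)

    return state


def _compare_systems(config: RunConfig, out_root: Path,
                     per_system: dict[str, dict], manifest: dict) -> None:
    a, b = config.systems
    try:
        sa, sb = per_system[a.name], per_system[b.name]
        diff = fingerprint_diff(sa["interactions"], sb["interactions"],
                                config.occupancy_min)
        delta_regions = {}
        for label in ("P-P", "C-C"):
            ra = sa["region_summaries"].get(label)
            rb = sb["region_summaries"].get(label)
            if ra and rb:
                delta_regions[label] = {
                    "mean_a": ra["mean"], "mean_b": rb["mean"],
                    "delta_mean": ra["mean"] - rb["mean"],
                }
        payload = {
            "system_a": a.name, "system_b": b.name,
            "fingerprint_diff": diff,
            "delta_region_correlation": delta_regions,
            "delta_binding_total":
                sa["energy"].mean()["total"] - sb["energy"].mean()["total"],
        }
        _write_json(out_root / "comparison.json", payload, config)
        _record_stage(manifest, "compare", "ok")
    except BindscapeError as exc:
        _record_stage(manifest, "compare", "failed", error=str(exc))
        raise StageError("compare", exc) from exc
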