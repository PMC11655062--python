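"""End-to-end orchestration: trajectory -> PCA -> landscape -> basins ->
pose clusters -> descriptors -> pocket volume -> state energies -> efficiency.

A single key-value config drives every stage; all defaults that the method
itself does not pin down live in :data:`DEFAULTS`.  Stage outputs are pure
functions of (inputs, config, seed) and the summary embeds a config hash so
reruns are verifiable.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import energy as energy_mod
from . import geometry as geom
from . import landscape as fel_mod
from . import pca as pca_mod
from . import pocket as pocket_mod
from . import poses as poses_mod
from . import synth, thermo, traj

__all__ = ["DEFAULTS", "load_config", "config_hash", "run_all", "PipelineError"]

#: Every tunable the pipeline accepts, with its default.
DEFAULTS = {
    "seed": 0,
    "ca_selection": "name CA",
    "ligand_selection": "ligand",
    "site_selection": "name CA and resid 1:20",
    "pocket_center_selection": "resid 1 2 3 and name CA",
    "head_selection": "ligand and name N1",
    "tail_selection": None,            # default: last ligand atom
    "nbins": 50,
    "kT": fel_mod.DEFAULT_KT,
    "smooth_sigma": 2.0,
    "max_depth_cut": 2.0,
    "well_window": 0.5,                # kcal/mol around each basin minimum
    "rmsd_threshold": 1.0,             # A, pose-cluster rule
    "top_clusters": 3,
    "pocket_radius": 10.0,             # A
    "pocket_spacing": 0.5,             # A
    "pocket_stride": 2,
    "water_cutoff": 8.0,               # A
    "max_cluster_frames": 60,          # frames per basin fed to pose clustering
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    config = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(DEFAULTS) - {
            "trajectory", "apo", "energies_csv", "experimental_csv", "synthetic",
        }
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    if overrides:
        config.update(overrides)
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _validate(config: dict, trajectory: traj.Trajectory) -> None:
    for key in ("ca_selection", "ligand_selection", "site_selection"):
        expr = config.get(key)
        if not expr:
            raise ValueError(f"config is missing required selection {key!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj.select(trajectory.topology, expr)  # parses or raises


def run_all(config: dict, outdir: str | Path,
            trajectory: traj.Trajectory | None = None,
            apo: traj.Trajectory | None = None,
            labels_true=None) -> dict:
    """Execute the full analysis and write per-stage artifacts plus a summary.

    The trajectory may be passed in directly, named in the config under
    ``trajectory`` (a multi-model PDB path), or generated synthetically when
    the config carries a ``synthetic`` block.  Returns the summary dict
    (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config_hash(config), "seed": config.get("seed", 0)}
    energies_df = None

    stage = "ingest"
    try:
        if trajectory is None:
            if "synthetic" in config:
                spec = synth.SyntheticSpec(seed=int(config.get("seed", 0)),
                                           **(config["synthetic"] or {}))
                trajectory, labels_true, schedule = synth.generate_system(spec)
                apo = synth.generate_apo_reference(spec)
                energies_df = synth.generate_energy_table(spec, labels_true)
                summary["planted"] = {
                    k: v for k, v in schedule.items() if k != "energy_mean"
                }
            elif config.get("trajectory"):
                trajectory = traj.read_structure(config["trajectory"])
                if config.get("apo"):
                    apo = traj.read_structure(config["apo"])
            else:
                raise ValueError("no trajectory given: set 'trajectory' or 'synthetic'")
        if energies_df is None and config.get("energies_csv"):
            energies_df = energy_mod.read_energy_csv(config["energies_csv"])
        _validate(config, trajectory)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    try:
        stage = "pca"
        model = pca_mod.fit_pca(trajectory, config["ca_selection"])
        proj = pca_mod.project(trajectory, model, k=2)
        traj.write_table(
            [{"frame": int(f), "pc1": float(p[0]), "pc2": float(p[1])}
             for f, p in enumerate(proj)],
            outdir / "proj.csv",
        )
        summary["variance_explained_2"] = pca_mod.variance_explained(model, 2)

        stage = "fel"
        fel = fel_mod.build_fel(proj, nbins=int(config["nbins"]), kT=float(config["kT"]))
        occupied = np.argwhere(~fel.mask)
        traj.write_table(
            [{"pc1_bin": int(i), "pc2_bin": int(j),
              "count": int(fel.counts[i, j]), "G": float(fel.G[i, j])}
             for i, j in occupied],
            outdir / "fel.csv",
        )

        stage = "basins"
        basins = fel_mod.find_minima(
            fel, smooth_sigma=float(config["smooth_sigma"]),
            max_depth_cut=float(config["max_depth_cut"]),
        )
        if not basins:
            raise ValueError("no basin found below the depth cut")
        frame_labels_idx = fel_mod.assign_frames(proj, fel, basins)
        fel_mod.label_basins_temporal(basins, trajectory.times)
        frame_labels = np.array(
            [basins[i].label if i >= 0 else None for i in frame_labels_idx],
            dtype=object,
        )
        basin_table = [{
            "label": b.label,
            "pc1_min": float(b.minimum[0]),
            "pc2_min": float(b.minimum[1]),
            "g_min": b.g_min,
            "depth": None if not np.isfinite(b.depth) else b.depth,
            "occupancy": b.occupancy,
            "n_frames": int(len(b.frames)),
            "positional_variance": b.positional_variance,
            "shallow": bool(b.shallow),
        } for b in basins]
        with open(outdir / "basins.json", "w") as fh:
            json.dump(basin_table, fh, indent=2)
        summary["basins"] = basin_table

        stage = "clusters"
        lig_idx = trajectory.select(config["ligand_selection"])
        site_idx = trajectory.select(config["site_selection"])
        cluster_report = {}
        accepted: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(int(config.get("seed", 0)))
        for b in basins:
            bottom = fel_mod.well_bottom_frames(
                b, fel, proj, window=float(config["well_window"])
            )
            if bottom.size == 0:
                continue
            if bottom.size > int(config["max_cluster_frames"]):
                keep = np.sort(rng.choice(
                    bottom.size, int(config["max_cluster_frames"]), replace=False
                ))
                bottom = bottom[keep]
            cs = poses_mod.cluster_poses(
                trajectory, bottom, lig_idx, site_idx,
                threshold=float(config["rmsd_threshold"]), basin_label=b.label,
            )
            poses_mod.select_top_clusters(cs, k=int(config["top_clusters"]))
            accepted[b.label] = cs.accepted_frames
            cluster_report[b.label] = {
                "n_clusters": len(cs.clusters),
                "cluster_sizes": [c.size for c in cs.clusters],
                "accepted_fraction": cs.accepted_fraction,
                "n_accepted": int(len(cs.accepted_frames)),
            }
        with open(outdir / "clusters.json", "w") as fh:
            json.dump(cluster_report, fh, indent=2)
        summary["clusters"] = cluster_report

        stage = "geometry"
        head = trajectory.select(config["head_selection"])
        tail_sel = config.get("tail_selection")
        tail = trajectory.select(tail_sel) if tail_sel else np.array([lig_idx[-1]])
        series = [
            geom.pivot_angle(trajectory, head, tail, site_idx),
            geom.count_pocket_waters(
                trajectory, config["pocket_center_selection"],
                cutoff=float(config["water_cutoff"]),
            ),
        ]
        if apo is not None:
            series.append(geom.loop_displacement(
                trajectory, apo,
                tip_sel=config.get("loop_tip_selection", _default_loop_tip(trajectory)),
                anchor_sel=config.get("loop_anchor_selection",
                                      _default_loop_anchor(trajectory)),
            ))
        geom.state_summaries(series, frame_labels)
        rows = []
        for s in series:
            for state, (mean, sd) in s.per_state.items():
                rows.append({"descriptor": s.name, "state": state,
                             "mean": mean, "sd": sd, "units": s.units})
        traj.write_table(rows, outdir / "descriptors.csv")
        summary["descriptors"] = rows

        stage = "pocket"
        grid = pocket_mod.GridSpec(
            center=config["pocket_center_selection"],
            radius=float(config["pocket_radius"]),
            spacing=float(config["pocket_spacing"]),
        )
        frames_v, vols, per_state_vol = pocket_mod.volume_series(
            trajectory, grid, stride=int(config["pocket_stride"]), labels=frame_labels,
        )
        traj.write_table(
            [{"frame": int(f), "volume_A3": float(v)} for f, v in zip(frames_v, vols)],
            outdir / "volume.csv",
        )
        summary["pocket_volume_per_state"] = per_state_vol

        stage = "energy"
        state_rows = []
        states: dict[str, energy_mod.StateEnergy] = {}
        if energies_df is not None:
            evals = energies_df["energy_kcal"].to_numpy()
            for label, frames in accepted.items():
                se = energy_mod.state_energy(label, evals, frames=frames)
                states[label] = se
                state_rows.append({
                    "state": label, "dH": se.dH, "TdS": se.TdS, "dG": se.dG,
                    "sd": se.sd, "sem": se.sem, "n_frames": se.n_frames,
                })
            traj.write_table(state_rows, outdir / "states.csv")
            summary["state_energies"] = state_rows
            if "m1" in states and "m3" in states:
                summary["eta_calc"] = energy_mod.efficiency_from_states(
                    states["m1"].dG, states["m3"].dG
                )

        stage = "compare"
        if config.get("experimental_csv"):
            table = thermo.read_energetics_csv(config["experimental_csv"])
            summary["eta_experimental"] = {e.agonist_id: e.eta for e in table}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _default_loop_tip(trajectory: traj.Trajectory) -> str:
    """Last loop residue of the synthetic system (stand-in for the loop C tip)."""
    top = trajectory.topology
    loop_resids = top.resid[(top.resname == "GLY") & (top.name == "CA")]
    if loop_resids.size == 0:
        raise ValueError("no default loop tip: set 'loop_tip_selection' in the config")
    return f"name CA and resid {int(loop_resids.max())}"


def _default_loop_anchor(trajectory: traj.Trajectory) -> str:
    top = trajectory.topology
    core_resids = top.resid[(top.resname == "ALA") & (top.name == "CA")]
    if core_resids.size == 0:
        raise ValueError("no default anchor: set 'loop_anchor_selection' in the config")
    return f"name CA and resid {int(core_resids.min())}:{int(core_resids.max())}"
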