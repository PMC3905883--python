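"""End-to-end orchestration: simulate or ingest, reconstruct, analyze.

A single YAML configuration drives the staged workflow

    simulate | ingest -> truncate at escape -> FES reconstruction
    -> minima / basins / frame assignment -> minimum-energy path
    -> per-state structure tables

and a JSON run report records seeds, parameters and every output file.
Rerunning the same configuration and seed reproduces every output
byte for byte.

State naming: among the "major" minima of the reconstructed FES
(topographic prominence above the hill-noise scale and energy within
the state cutoff of the global minimum -- hill roughness always carves
a scatter of shallow pockets that are not states), the one at the
smallest distance CV is the bound state B, the others are
intermediates I, I2, ...; the transition state Ts is the saddle of the
B -> I minimum-energy path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cvs, engine, fes as fes_mod, landscape, structure, synthetic, system

__all__ = ["RunConfig", "run_pipeline", "load_config", "write_structure_tables", "read_states_table"]

log = logging.getLogger("metafes.pipeline")

# a minimum counts as a state only if its escape barrier (topographic
# prominence) exceeds this, i.e. it is not a pocket carved by hill noise
MIN_PROMINENCE_KJ = 2.0


@dataclass
class RunConfig:
    """Validated run configuration (exactly one of inputs / synthetic)."""

    outdir: str
    inputs: dict | None = None  # hills, colvar, topology, trajectory
    synthetic: dict | None = None  # landscape, meta, run, mock blocks
    grid: tuple[int, int] = (500, 500)
    stop_distance: float = 4.0  # nm
    state_cutoff: float = 20.0  # kJ/mol
    hbond: dict = field(default_factory=dict)
    cluster_cutoff: float = 0.1  # nm
    max_cluster_frames: int = 60  # stride-subsample cap for pairwise RMSD
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'inputs' and 'synthetic' must be configured"
            )
        if self.stop_distance <= 0 or self.state_cutoff <= 0 or self.cluster_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        self.grid = tuple(self.grid)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: v for k, v in vars(cfg).items()}, sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate(cfg: RunConfig, seed: int):
    syn = cfg.synthetic
    land = syn.get("landscape", {})
    pot = synthetic.make_unbinding_landscape(
        depths={"B": land.get("depth_B", 45.0), "I": land.get("depth_I", 40.0)},
        barrier_BTs=land.get("barrier_BTs", 20.0),
        barrier_out=land.get("barrier_out", 35.0),
    )
    meta_kwargs = dict(syn.get("meta", {}))
    meta_kwargs.setdefault("height", 0.25)
    meta_kwargs.setdefault("widths", (0.05, 50.0))
    params = engine.MetaParams(**meta_kwargs)
    run_kwargs = dict(syn.get("run", {}))
    run_kwargs.setdefault("dt", 0.005)
    run_kwargs.setdefault("friction", 1.0)
    run_kwargs.setdefault("n_steps", 500_000)
    run_kwargs.setdefault("masses", (1.0, 0.0005))
    result = engine.run_metadynamics(
        pot, params, seed=seed, **run_kwargs
    )
    return pot, params, result


def _major_minima(
    fes, basins: landscape.BasinMap, cutoff: float,
    min_prominence: float = MIN_PROMINENCE_KJ,
) -> list[landscape.Minimum]:
    """Minima that are genuine states: prominent (escape barrier above
    the hill-noise scale) and within the state cutoff of the global
    minimum, ordered by the distance CV."""
    prom = landscape.prominences(fes, basins)
    emin = min(m.energy for m in basins.minima)
    out = [
        m
        for m in basins.minima
        if prom[m.label] >= min_prominence and m.energy - emin < cutoff
    ]
    return sorted(out, key=lambda m: m.coords[0])


def _state_names(major: list[landscape.Minimum]) -> dict[str, str]:
    """Map internal minimum labels to B / I / I2 ... by distance CV."""
    names = {}
    for k, m in enumerate(major):
        names[m.label] = "B" if k == 0 else ("I" if k == 1 else f"I{k}")
    return names


def read_states_table(path, cutoff: float = 20.0) -> landscape.StateAssignment:
    """Read a states.tsv written by the pipeline back into a
    :class:`~metafes.landscape.StateAssignment`."""
    df = pd.read_csv(path, sep="\t", dtype={"state": str})
    labels = [
        (s if isinstance(s, str) and s else None) for s in df["state"].fillna("")
    ]
    delta = pd.to_numeric(df["delta_F"], errors="coerce").to_numpy()
    return landscape.StateAssignment(
        labels=labels, delta_f=delta, cutoff=cutoff,
        times=df["time"].to_numpy(dtype=float),
    )


def write_structure_tables(
    topology: system.Topology,
    trajectory: system.Trajectory,
    states: landscape.StateAssignment,
    outdir: Path,
    hbond: dict | None = None,
    cluster_cutoff: float = 0.1,
    max_cluster_frames: int = 60,
) -> dict[str, str]:
    """Per-state H-bond / RMSF / cluster / nick-width tables; returns
    the mapping of table names to written paths."""
    if len(states.labels) != trajectory.n_frames:
        raise ValueError(
            f"state assignment covers {len(states.labels)} frames but the "
            f"trajectory has {trajectory.n_frames}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    hb = structure.hbond_percentages(
        trajectory, topology, states,
        criteria=structure.HBondCriteria(**(hbond or {})),
    )
    hb_path = outdir / "hbonds_by_state.tsv"
    hb.to_csv(hb_path, sep="\t", index=False)
    paths["hbonds_by_state"] = str(hb_path)

    state_labels = sorted(states.counts())
    rmsf_rows: list[dict] = []
    nick_rows: list[dict] = []
    lig = topology.ligand_indices()
    for s in state_labels:
        idx = states.frames_of(s)
        if idx.size < 2:
            continue
        sub = system.Trajectory(
            coords=trajectory.coords[idx], times=trajectory.times[idx]
        )
        r = structure.rmsf(sub, topology)
        for row in r.itertuples(index=False):
            rmsf_rows.append(
                {"state": s, "resid": row.resid, "resname": row.resname,
                 "rmsf_nm": round(row.rmsf, 4)}
            )
        widths = [structure.nick_width(fr, topology) for fr in sub.coords]
        nick_rows.append(
            {"state": s, "mean_nm": round(float(np.mean(widths)), 4),
             "sd_nm": round(float(np.std(widths, ddof=1)), 4)}
        )
        # pairwise RMSD is quadratic in frames: stride-subsample
        stride = max(1, int(np.ceil(idx.size / max_cluster_frames)))
        cl_idx = idx[::stride]
        cl_sub = system.Trajectory(
            coords=trajectory.coords[cl_idx], times=trajectory.times[cl_idx]
        )
        cl = structure.gromos_cluster(
            cl_sub, selection=lig, masses=topology.masses,
            cutoff=cluster_cutoff,
        )
        cl_path = outdir / f"clusters_{s}.tsv"
        with open(cl_path, "w") as fh:
            fh.write("cluster\tsize\trepresentative\tmembers\n")
            for ci, members in enumerate(cl.clusters):
                fh.write(
                    f"{ci}\t{len(members)}\t{cl_idx[cl.representatives[ci]]}\t"
                    + ",".join(str(cl_idx[m]) for m in members) + "\n"
                )
        paths[f"clusters_{s}"] = str(cl_path)
    pd.DataFrame(rmsf_rows).to_csv(
        outdir / "rmsf_by_state.tsv", sep="\t", index=False
    )
    pd.DataFrame(nick_rows).to_csv(
        outdir / "nickwidth_by_state.tsv", sep="\t", index=False
    )
    paths["rmsf_by_state"] = str(outdir / "rmsf_by_state.tsv")
    paths["nickwidth_by_state"] = str(outdir / "nickwidth_by_state.tsv")
    log.info("stage structure: tables for states %s", state_labels)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    seed_sim, seed_mock = (int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2))
    report: dict = {
        "package": "metafes",
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stage_seeds": {"simulate": seed_sim, "mock": seed_mock},
        "outputs": {},
    }

    # --- stage 1: simulate or ingest ------------------------------------
    mock_states = None
    topology = trajectory = None
    if config.synthetic is not None:
        log.info("stage simulate: synthetic metadynamics run")
        pot, params, result = _simulate(config, seed_sim)
        colvar, hills = result.colvar, result.hills
        report["simulate"] = {
            "potential": pot.name,
            "n_hills": len(hills),
            "mode": params.mode,
            "barrier_BTs_true": pot.info.get("barrier_BTs"),
        }
        mode, gamma = params.mode, params.bias_factor
        hills_path = outdir / "hills.txt"
        colvar_path = outdir / "colvar.tsv"
        engine.write_hills(hills, hills_path,
                           bias_factor=gamma if mode == "well_tempered" else 1.0)
        cvs.write_colvar(colvar, colvar_path)
        report["outputs"]["hills"] = str(hills_path)
        report["outputs"]["colvar"] = str(colvar_path)
        mock_cfg = (config.synthetic or {}).get("mock", {})
        if mock_cfg.get("enabled", True):
            spec = synthetic.default_mock_spec(
                seed=seed_mock, state_counts=mock_cfg.get("state_counts")
            )
            n_frames = int(mock_cfg.get("n_frames", len(spec.state_sequence)))
            topology, trajectory = synthetic.generate_mock_trajectory(spec, n_frames)
            mock_states = landscape.StateAssignment(
                labels=list(spec.state_sequence[:n_frames]),
                delta_f=np.zeros(n_frames),
                cutoff=config.state_cutoff,
                times=trajectory.times,
            )
            top_path = outdir / "mock_topology.pdb"
            xyz_path = outdir / "mock_trajectory.xyz"
            system.write_topology(topology, top_path, frame=trajectory.coords[0])
            system.write_xyz(topology, trajectory, xyz_path)
            report["outputs"]["topology"] = str(top_path)
            report["outputs"]["trajectory"] = str(xyz_path)
            mock_states_path = outdir / "mock_states.tsv"
            with open(mock_states_path, "w") as fh:
                fh.write("frame\ttime\tstate\tdelta_F\n")
                for k, lab in enumerate(mock_states.labels):
                    fh.write(f"{k}\t{trajectory.times[k]:.6g}\t{lab}\t0\n")
            report["outputs"]["mock_states"] = str(mock_states_path)
    else:
        log.info("stage ingest: reading hills/colvar/topology/trajectory")
        inp = config.inputs
        hills = engine.read_hills(inp["hills"])
        colvar = cvs.read_colvar(inp["colvar"])
        mode, gamma = inp.get("mode", "standard"), inp.get("bias_factor", 10.0)
        if "topology" in inp:
            topology = system.read_topology(inp["topology"])
            trajectory = system.read_xyz(inp["trajectory"])
        report["simulate"] = {"ingested": True, "n_hills": len(hills)}

    # --- stage 2: stop criterion ----------------------------------------
    kept = fes_mod.truncate_at_escape(colvar, hills, config.stop_distance)
    log.info("stage truncate: kept %d of %d hills (stop at %.2f nm)",
             len(kept), len(hills), config.stop_distance)
    report["truncate"] = {"n_hills_kept": len(kept), "n_hills_total": len(hills),
                          "stop_distance_nm": config.stop_distance}

    # --- stage 3: FES -----------------------------------------------------
    spec_grid = fes_mod.grid_from_hills(kept, n_points=config.grid)
    fes = fes_mod.reconstruct_fes(
        kept, spec_grid, mode=mode,
        bias_factor=gamma if mode == "well_tempered" else None,
    )
    fes_path = outdir / "fes.tsv"
    fes_mod.write_fes(fes, fes_path)
    report["outputs"]["fes"] = str(fes_path)
    log.info("stage fes: %s grid, range %.2f kJ/mol",
             "x".join(map(str, fes.spec.shape)), float(fes.values.max()))

    # --- stage 4: minima, basins, states ---------------------------------
    minima = landscape.find_minima(fes)
    basins = landscape.basin_assign(fes, minima)
    major = _major_minima(fes, basins, config.state_cutoff)
    names = _state_names(major)
    report["landscape"] = {
        "n_minima_raw": len(minima),
        "n_minima_major": len(major),
        "states": {
            names[m.label]: {"coords": list(m.coords), "F": m.energy}
            for m in major
        },
    }
    basins_path = outdir / "basins.tsv"
    with open(basins_path, "w") as fh:
        fh.write("node_i\tnode_j\tlabel\n")
        bi = basins.basin_index
        for i in range(bi.shape[0]):
            for j in range(bi.shape[1]):
                k = bi[i, j]
                lab = basins.minima[k].label if k >= 0 else ""
                fh.write(f"{i}\t{j}\t{names.get(lab, lab)}\n")
    report["outputs"]["basins"] = str(basins_path)

    assignment = landscape.assign_frames(colvar, fes, basins, config.state_cutoff)
    states_path = outdir / "states.tsv"
    with open(states_path, "w") as fh:
        fh.write("frame\ttime\tstate\tdelta_F\n")
        for k, lab in enumerate(assignment.labels):
            nm = names.get(lab, "") if lab is not None else ""
            dfv = assignment.delta_f[k]
            fh.write(
                f"{k}\t{assignment.times[k]:.6g}\t{nm}\t"
                f"{'' if np.isnan(dfv) else format(dfv, '.6g')}\n"
            )
    report["outputs"]["states"] = str(states_path)
    log.info("stage landscape: %d major minima, %s",
             len(major), {names[m.label]: round(m.energy, 2) for m in major})

    # --- stage 5: minimum-energy path ------------------------------------
    if len(major) >= 2:
        mep = landscape.minimum_energy_path(
            fes, basins, major[0].label, major[1].label
        )
        profile = landscape.profile_along_path(mep)
        prof_path = outdir / "mep_profile.tsv"
        profile.to_csv(prof_path, sep="\t", index=False, float_format="%.6g")
        report["outputs"]["mep_profile"] = str(prof_path)
        report["mep"] = {
            "from": "B",
            "to": names[major[1].label],
            "activation_energy_B_Ts": mep.activation_energy,
            "saddle_coords": [float(c) for c in mep.coords[mep.saddle_index]],
        }
        log.info("stage mep: dG(B->Ts) = %.2f kJ/mol", mep.activation_energy)

    # --- stage 6: per-state structure tables ------------------------------
    if topology is not None and trajectory is not None:
        states_for_structure = mock_states if mock_states is not None else assignment
        paths = write_structure_tables(
            topology, trajectory, states_for_structure, outdir,
            hbond=config.hbond, cluster_cutoff=config.cluster_cutoff,
            max_cluster_frames=config.max_cluster_frames,
        )
        report["outputs"].update(paths)

    report_path = outdir / "run.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["outputs"]["report"] = str(report_path)
    return report
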