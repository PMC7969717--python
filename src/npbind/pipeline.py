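"""Run configuration, provenance and the end-to-end demo pipeline.

The pipeline chains every analysis stage on synthetic inputs: generate the
two-state references, lambda-targeted trajectories and charged particles;
compute lambda series, distance-fluctuation matrices, clusterings and normal
modes; run MM/PBSA with per-residue decomposition and an alanine scan on the
complex fixture; characterize the particle surfaces; and write a summary
report.  Every stage reads and writes files only, every output starts with a
provenance header (tool version, config hash, seed), and a fixed config+seed
reproduces every byte.
"""

from __future__ import annotations

import copy
import hashlib
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conformation import (CALPHA, cluster_trajectory, distance_fluctuation,
                           lambda_series)
from .energetics import (EnergyModelConfig, alanine_scan_table, mmpbsa)
from .io_model import (ParameterTable, SelectionSpec, write_matrix,
                       write_parameters, write_report, write_trajectory,
                       write_structure, Trajectory)
from .normal_modes import build_enm, compute_modes, mode_overlap
from .surface import (accessible_area, classify_patches, electrostatic_map,
                      patch_summary, size_series_density, surface_points)
from .synthetic import (ParticleSpec, TrajectorySpec, TwoStateSpec,
                        make_complex, make_particle, make_trajectory,
                        make_two_state_references, merge_structures,
                        particle_as_structure)

log = logging.getLogger("npbind")


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


# the fully resolved default configuration; unknown keys are rejected
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "npbind_run",
    "log_level": "INFO",
    "selection": "calpha",
    "two_state": {
        "n_residues_N_domain": 20,
        "n_residues_C_domain": 12,
        "rotation_angle": 35.0,
        "translation": 3.0,
    },
    "trajectories": {
        # the three regimes: unbound, needle-bound, sphere-bound
        "apo": {"lambda_target": 0.24, "positional_noise_sd": 0.5,
                "n_frames": 60},
        "needle_bound": {"lambda_target": 0.32, "positional_noise_sd": 0.5,
                         "n_frames": 60},
        "sphere_bound": {"lambda_target": 0.65, "positional_noise_sd": 0.5,
                         "n_frames": 60},
    },
    "cluster": {"cutoff": 1.5},
    "nma": {"cutoff": 15.0, "n_modes": 5},
    "energetics": {"pb_grid_spacing": 1.0, "solute_dielectric": 2.0,
                   "solvent_dielectric": 80.0, "ionic_strength_mM": 150.0},
    "alascan": {"n_top_single": 1, "n_top_multi": 4},
    "particles": {
        "shapes": ["sphere", "rod", "needle"],
        "sphere_series_nm": [1.926, 2.6, 3.2],
        "lattice_spacing": 3.0,
    },
    "surface": {"threshold": 0.5, "density": 0.4},
}


def _validate(user: dict, defaults: dict, path: str = "") -> None:
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + str(key)!r}")
        if isinstance(defaults[key], dict) and key != "trajectories":
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path + str(key)!r} must be a block")
            _validate(value, defaults[key], path + f"{key}.")


def resolve_config(user: dict | None = None) -> dict:
    """Merge a partial user config over the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if user:
        _validate(user, DEFAULT_CONFIG)
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict) \
                    and key != "trajectories":
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return resolve_config(user)


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location and log level
    excluded, so reruns into different directories are comparable)."""
    payload = {k: v for k, v in cfg.items() if k not in ("outdir", "log_level")}
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def version_and_provenance(cfg: dict) -> list[str]:
    """Header lines embedded in every output file."""
    return [
        f"npbind {__version__}",
        f"config sha256:{config_hash(cfg)}",
        f"seed {cfg['seed']}",
    ]


def provenance_selfcheck(path: str | Path) -> bool:
    """True if the file begins with an npbind provenance header."""
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("# npbind ")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


def _selection(cfg: dict) -> SelectionSpec:
    return SelectionSpec(cfg["selection"])


def run_pipeline(cfg: dict, only: list[str] | None = None) -> dict:
    """Execute the pipeline stages; returns {stage: [artifact paths]} plus
    the collected report rows under ``report_rows``.

    ``only`` restricts the run to the named stages (the ``simulate`` stage is
    always included, every other stage consumes its outputs).  Any stage
    failure raises PipelineError naming the stage and the artifacts written
    so far.
    """
    cfg = resolve_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    header = version_and_provenance(cfg)
    artifacts: dict[str, list[str]] = {}
    report_rows: list[dict] = []
    sel = _selection(cfg)
    state: dict = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            artifacts[name] = fn()
        except Exception as exc:
            done = [p for paths in artifacts.values() for p in paths]
            raise PipelineError(
                f"stage {name!r} failed: {exc}; artifacts so far: {done}"
            ) from exc
        log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)

    def _write_tsv(df: pd.DataFrame, path: Path) -> str:
        write_report(df, path, header)
        return str(path)

    def simulate() -> list[str]:
        seed = cfg["seed"]
        refs = make_two_state_references(
            TwoStateSpec(seed=seed, **cfg["two_state"]), selection=sel)
        state["refs"] = refs
        paths = []
        for name, s in (("open", refs.v1), ("locked", refs.v2)):
            p = outdir / f"{name}.pdb"
            write_structure(s, p)
            paths.append(str(p))
        state["trajs"] = {}
        for k, (name, block) in enumerate(cfg["trajectories"].items()):
            traj = make_trajectory(refs, TrajectorySpec(seed=seed + 1 + k,
                                                        **block))
            state["trajs"][name] = traj
            p = outdir / f"traj_{name}.pdb"
            write_trajectory(traj, p)
            paths.append(str(p))
        state["particles"] = {}
        for k, shape in enumerate(cfg["particles"]["shapes"]):
            particle = make_particle(ParticleSpec(
                shape=shape, seed=seed + 100 + k,
                lattice_spacing=cfg["particles"]["lattice_spacing"]))
            state["particles"][shape] = particle
            ps = particle_as_structure(particle)
            p_xyz = outdir / f"particle_{shape}.xyz"
            p_prm = outdir / f"particle_{shape}.prm"
            write_structure(ps, p_xyz)
            write_parameters(ParameterTable.from_structure(ps), p_prm, header)
            paths.extend([str(p_xyz), str(p_prm)])
        return paths

    def lam() -> list[str]:
        paths = []
        for name, traj in state["trajs"].items():
            series = lambda_series(traj, state["refs"])
            proj = lambda_series(traj, state["refs"], projection=True)
            df = pd.DataFrame({"frame": np.arange(len(series.values)),
                               "lambda": series.values,
                               "lambda_projection": proj.values})
            paths.append(_write_tsv(df, outdir / f"lambda_{name}.tsv"))
            report_rows.append({"quantity": f"lambda_mean[{name}]",
                                "value": series.mean})
            report_rows.append({"quantity": f"lambda_mean_projection[{name}]",
                                "value": proj.mean})
        return paths

    def dfmat() -> list[str]:
        paths = []
        for name, traj in state["trajs"].items():
            fm = distance_fluctuation(traj, sel)
            p = outdir / f"tau_{name}.tsv"
            write_matrix(fm.tau, fm.labels, p, header)
            paths.append(str(p))
        return paths

    def cluster() -> list[str]:
        paths = []
        for name, traj in state["trajs"].items():
            res = cluster_trajectory(traj, cfg["cluster"]["cutoff"], sel)
            df = pd.DataFrame({"cluster": np.arange(len(res.populations)),
                               "population": res.populations,
                               "centroid_frame": res.centroids})
            paths.append(_write_tsv(df, outdir / f"clusters_{name}.tsv"))
            for cid, pop in enumerate(res.populations):
                report_rows.append(
                    {"quantity": f"cluster_population[{name}:{cid}]",
                     "value": pop})
        return paths

    def nma() -> list[str]:
        refs = state["refs"]
        model = build_enm(refs.v1, cutoff=cfg["nma"]["cutoff"], sel=sel)
        modes = compute_modes(model, cfg["nma"]["n_modes"])
        overlaps = mode_overlap(modes, refs)
        rows = []
        for m in range(len(modes.eigenvalues)):
            amp = modes.node_amplitudes(m)
            rows.append({"mode": m + 1, "eigenvalue": modes.eigenvalues[m],
                         "overlap_with_transition": overlaps[m],
                         "max_amplitude_residue":
                             model.node_residues[int(np.argmax(amp))]})
        return [_write_tsv(pd.DataFrame(rows), outdir / "modes.tsv")]

    def energetics() -> list[str]:
        seed = cfg["seed"]
        protein, particle, table = make_complex(seed)
        comp = merge_structures(protein, particle_as_structure(particle))
        ecfg = EnergyModelConfig(**cfg["energetics"])
        result = mmpbsa(comp, "chain:A", "chain:X", cfg=ecfg)
        terms = {"e_bonded": result.delta.e_bonded,
                 "e_vdw": result.delta.e_vdw, "e_elec": result.delta.e_elec,
                 "g_polar": result.delta.g_polar,
                 "g_nonpolar": result.delta.g_nonpolar,
                 "g_total": result.delta.g_total}
        df = pd.DataFrame([{"term": k, "delta_kcal_mol": v}
                           for k, v in terms.items()])
        paths = [_write_tsv(df, outdir / "energies.tsv")]
        pr = result.per_residue.reset_index()
        pr.columns = ["residue", "delta_G_kcal_mol"]
        paths.append(_write_tsv(pr, outdir / "per_residue.tsv"))
        report_rows.append({"quantity": "delta_G_binding",
                            "value": result.delta.g_total})
        for res_label, val in result.per_residue.head(3).items():
            report_rows.append({"quantity": f"top_contributor[{res_label}]",
                                "value": val})
        # alanine scan: the top single contributor and the top-n multi mutant,
        # protein residues only, skipping residues without a C-beta tail
        protein_rows = pr[pr["residue"].str.startswith("A:")]
        mutable = [r for r in protein_rows["residue"]
                   if r.split(":")[2] not in ("ALA", "GLY", "PRO")]
        def _key(label):
            _, rid, _ = label.split(":")
            return ("A", int(rid))
        mutants = {}
        if mutable:
            mutants[f"single_{mutable[0]}"] = [_key(mutable[0])]
            multi = mutable[:cfg["alascan"]["n_top_multi"]]
            if len(multi) > 1:
                mutants["multi_" + "_".join(m.split(":")[1] for m in multi)] = \
                    [_key(m) for m in multi]
        _, scan_df = alanine_scan_table(comp, mutants, "chain:A", "chain:X",
                                        cfg=ecfg)
        paths.append(_write_tsv(scan_df, outdir / "alascan.tsv"))
        state["binding"] = result
        return paths

    def npsurf() -> list[str]:
        paths = []
        dens = cfg["surface"]["density"]
        for shape, particle in state["particles"].items():
            pts = surface_points(particle, density=dens)
            emap = electrostatic_map(particle, pts, density=dens)
            table = classify_patches(emap, cfg["surface"]["threshold"])
            p = outdir / f"eps_{shape}.tsv"
            paths.append(_write_tsv(table, p))
            summary = patch_summary(table, emap.area)
            paths.append(_write_tsv(summary, outdir / f"patches_{shape}.tsv"))
            report_rows.append({"quantity": f"particle_area_nm2[{shape}]",
                                "value": emap.area})
            report_rows.append({"quantity": f"particle_charge_e[{shape}]",
                                "value": emap.total_charge})
            report_rows.append(
                {"quantity": f"particle_charge_density_e_nm2[{shape}]",
                 "value": emap.charge_density})
        sizes = cfg["particles"]["sphere_series_nm"]
        series = [ParticleSpec(shape="sphere", characteristic_size=s,
                               lattice_spacing=cfg["particles"][
                                   "lattice_spacing"],
                               seed=cfg["seed"] + 200)
                  for s in sizes]
        df = size_series_density(series)
        report_rows.append({"quantity": "sphere_density_relative_spread",
                            "value": df.attrs["relative_spread"]})
        paths.append(_write_tsv(df, outdir / "sphere_size_series.tsv"))
        return paths

    def report() -> list[str]:
        p = outdir / "report.tsv"
        _write_tsv(pd.DataFrame(report_rows), p)
        cfg_path = outdir / "config_resolved.yaml"
        with open(cfg_path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return [str(p), str(cfg_path)]

    for name, fn in [("simulate", simulate), ("lambda", lam),
                     ("dfmat", dfmat), ("cluster", cluster), ("nma", nma),
                     ("energetics", energetics), ("npsurf", npsurf),
                     ("report", report)]:
        if only is not None and name != "simulate" and name not in only:
            continue
        _stage(name, fn)
    artifacts["report_rows"] = report_rows
    return artifacts
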