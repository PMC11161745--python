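"""Config schema, validation and pipeline orchestration.

A single human-editable mapping (YAML on disk) drives every stage; the
defaults encode the reference study conditions — material constants, the
0.91/0.72 um grain, 3-grain chain at 40 nm gap, 20-step growth series,
20-direction 250 mT field protocol, and the organism model — so an empty
config reproduces the standard setup.  Heavy micromagnetic stages are
opt-in via ``stages``; the closed-form magnetotaxis stage runs by default.
"""

from __future__ import annotations

import copy
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .barriers import (
    RelaxationModel,
    mirrored_state,
    neb_path,
    refine_between_minima,
    relaxation_time,
)
from .core import LEMSolver, grow_chain_states, minimize_lem, run_scenario
from .geometry import (
    ChainSpec,
    GrainSpec,
    GrowthSeriesSpec,
    build_chain,
    build_grain,
    build_growth_series,
)
from .io import (
    sha256sum,
    write_assembly_vtk,
    write_field_checkpoint,
    write_json,
)
from .materials import get_material
from .postprocess import classify_domain_state, normalized_helicity, vorticity
from .protocols import FieldProtocol, fibonacci_directions, hysteresis_loop
from .taxis import THREE_GRAIN_MOMENTS, uturn_sweep

__all__ = ["DEFAULTS", "validate_config", "load_config", "run_pipeline"]

DEFAULTS: dict = {
    "seed": 0,
    "stages": {
        "geometry": True,
        "lem": False,
        "loop": False,
        "growth": False,
        "barrier": False,
        "uturn": True,
    },
    "grain": {
        "long_axis_nm": 910.0,
        "short_axis_nm": 720.0,
        "shape": "rounded_cuboid",
        "exponent": 2.3,
        "mineral": "magnetite",
    },
    "chain": {"n": 3, "gap_nm": 40.0, "axis": "X"},
    "grid": {"cell_nm": 20.0},
    "solver": {"tol": 1e-7, "max_evals": 100000},
    "scenario": {"which": "I", "n_repeats": 10},
    "growth": {
        "n_steps": 20,
        "min_long_axis_nm": 86.0,
        "max_long_axis_nm": 823.0,
        "proportional_gap": True,
        "cells_per_long_axis": None,
    },
    "protocol": {
        "n_directions": 20,
        "B_start_mT": 250.0,
        "B_end_mT": -250.0,
        "B_step_mT": 2.0,
        "start_state": "saturated",
    },
    "barrier": {"n_images": 15, "rotation_axis": "Z", "neb_tol": 1e-4},
    "relaxation": {"C_s": 1e-9, "T_K": 293.15},
    "organism": {
        "b_um": 2.0,
        "eta": 1e-3,
        "T_K": 293.15,
        "N_min": 3,
        "N_max": 20,
        "B_uT": [6.0, 10.0, 15.0, 25.0, 40.0, 55.0, 80.0],
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, given: dict, path: str, errors: list) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (given or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(f"unknown key {here}")
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here, errors)
        else:
            out[key] = value
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a partial config into the defaults and check its values.

    Returns ``{"ok": bool, "errors": [...], "resolved": full_config}``;
    errors name the offending key.
    """
    errors: list[str] = []
    resolved = _merge(DEFAULTS, config or {}, "", errors)

    def bad(cond, msg):
        if cond:
            errors.append(msg)

    bad(resolved["chain"]["gap_nm"] < 0, "chain.gap_nm must be >= 0")
    bad(resolved["chain"]["n"] < 1, "chain.n must be >= 1")
    bad(resolved["grid"]["cell_nm"] <= 0, "grid.cell_nm must be > 0")
    bad(
        resolved["grain"]["long_axis_nm"] < resolved["grain"]["short_axis_nm"],
        "grain.long_axis_nm must be >= grain.short_axis_nm",
    )
    bad(
        resolved["grain"]["mineral"] not in ("magnetite", "maghemite"),
        "grain.mineral must be magnetite or maghemite",
    )
    bad(resolved["chain"]["axis"] not in ("X", "Z"), "chain.axis must be X or Z")
    bad(
        resolved["scenario"]["which"] not in ("I", "II"),
        "scenario.which must be I or II",
    )
    bad(resolved["organism"]["b_um"] <= 0, "organism.b_um must be > 0")
    bad(resolved["organism"]["eta"] <= 0, "organism.eta must be > 0")
    bad(
        resolved["organism"]["N_min"] > resolved["organism"]["N_max"],
        "organism.N_min must be <= organism.N_max",
    )
    return {"ok": not errors, "errors": errors, "resolved": resolved}


def load_config(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data)}")
    return data


def _specs_from(cfg: dict):
    g = cfg["grain"]
    grain = GrainSpec(
        long_axis=g["long_axis_nm"] * 1e-9,
        short_axis=g["short_axis_nm"] * 1e-9,
        shape=g["shape"],
        exponent=g["exponent"],
        mineral=g["mineral"],
    )
    c = cfg["chain"]
    chain = ChainSpec(n_grains=c["n"], gap=c["gap_nm"] * 1e-9, axis=c["axis"])
    return grain, chain


def run_pipeline(config: dict | None, outdir, seed: int | None = None) -> dict:
    """Execute the requested stages and write artifacts plus a manifest.

    The manifest echoes the resolved config, records every seed, per-stage
    wall times, convergence flags and an artifact registry with SHA-256
    checksums; re-running with the same config and seed is bit-identical
    for the deterministic stages.
    """
    report = validate_config(config)
    if not report["ok"]:
        raise ConfigError("; ".join(report["errors"]))
    cfg = report["resolved"]
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "software": {"name": "magnetofossil", "version": __version__},
        "config": cfg,
        "seed": cfg["seed"],
        "stages": {},
        "artifacts": [],
        "errors": [],
    }

    def register(path):
        manifest["artifacts"].append(
            {"path": str(Path(path).relative_to(outdir)),
             "sha256": sha256sum(path)}
        )

    grain, chain = _specs_from(cfg)
    material = get_material(cfg["grain"]["mineral"])
    cell = cfg["grid"]["cell_nm"] * 1e-9
    tol = cfg["solver"]["tol"]
    max_evals = cfg["solver"]["max_evals"]
    stages = cfg["stages"]
    assembly = None

    def stage(name):
        return stages.get(name, False)

    try:
        if stage("geometry") or stage("lem") or stage("loop") or stage("barrier"):
            t0 = time.perf_counter()
            assembly = build_chain(grain, chain, cell_size=cell)
            p = write_assembly_vtk(outdir / "assembly.vtk", assembly)
            register(p)
            register(Path(str(p) + ".json"))
            manifest["stages"]["geometry"] = {
                "seconds": time.perf_counter() - t0,
                "n_cells": assembly.n_cells,
                "V_m3": assembly.V,
            }

        if stage("lem"):
            t0 = time.perf_counter()
            summary = run_scenario(
                assembly, material, cfg["scenario"]["which"],
                n_repeats=cfg["scenario"]["n_repeats"], seed=cfg["seed"],
                tol=tol, max_evals=max_evals,
            )
            rows = []
            for i, res in enumerate(summary.results):
                w = vorticity(res.field)
                H = normalized_helicity(res.field, w)
                state = classify_domain_state(res.field)
                p = write_field_checkpoint(
                    outdir / f"lem_{i:02d}.vtk", res, helicity=H, vorticity=w,
                    extra_meta={"domain_state": state.label,
                                "n_cores": state.n_cores},
                )
                register(p)
                register(Path(str(p) + ".json"))
                rows.append({
                    "repeat": i, "seed": summary.seeds[i],
                    "Msc_fAm2": res.Msc * 1e15, "Mr_over_Ms": res.Mr_over_Ms,
                    "converged": res.converged, "state": state.label,
                })
            manifest["stages"]["lem"] = {
                "seconds": time.perf_counter() - t0,
                "scenario": cfg["scenario"]["which"],
                "seeds": summary.seeds,
                "Msc_mean_fAm2": summary.Msc_mean * 1e15,
                "Msc_sd_fAm2": summary.Msc_sd * 1e15,
                "Mr_over_Ms_mean": summary.Mr_over_Ms_mean,
                "Mr_over_Ms_sd": summary.Mr_over_Ms_sd,
                "repeats": rows,
                "all_converged": all(r["converged"] for r in rows),
            }

        if stage("loop"):
            t0 = time.perf_counter()
            pr = cfg["protocol"]
            proto = FieldProtocol(
                directions=fibonacci_directions(pr["n_directions"],
                                                seed=cfg["seed"]),
                B_start=pr["B_start_mT"] * 1e-3,
                B_end=pr["B_end_mT"] * 1e-3,
                B_step=pr["B_step_mT"] * 1e-3,
                start_state=pr["start_state"],
            )
            loop = hysteresis_loop(assembly, material, proto,
                                   tol=max(tol, 1e-5), max_evals=max_evals)
            import pandas as pd

            tables = []
            for di in range(len(proto.directions)):
                tables.append(pd.DataFrame({
                    "direction_id": di,
                    "B_mT": loop.B_grid * 1e3,
                    "m": loop.per_direction[di],
                }))
            p = outdir / "loop_directions.csv"
            pd.concat(tables).to_csv(p, index=False)
            register(p)
            p = outdir / "loop_averaged.csv"
            pd.DataFrame({"B_mT": loop.B_grid * 1e3,
                          "m_desc": loop.averaged,
                          "m_asc": loop.averaged_asc[::-1]}).to_csv(
                p, index=False)
            register(p)
            manifest["stages"]["loop"] = {
                "seconds": time.perf_counter() - t0,
                "coercivity_mT": loop.coercivity_mT,
                "n_flagged_steps": len(loop.flagged_steps),
            }

        if stage("growth"):
            t0 = time.perf_counter()
            gr = cfg["growth"]
            series_spec = GrowthSeriesSpec(
                n_steps=gr["n_steps"],
                min_long_axis=gr["min_long_axis_nm"] * 1e-9,
                max_long_axis=gr["max_long_axis_nm"] * 1e-9,
                proportional_gap=gr["proportional_gap"],
            )
            cells = gr["cells_per_long_axis"]
            cell_fn = (None if cells is None
                       else (lambda L: max(L / cells, 9e-9)))
            series = build_growth_series(grain, chain, series_spec,
                                         cell_size_fn=cell_fn)
            results = grow_chain_states(
                series, material, tol=tol, max_evals=max_evals,
                classify=classify_domain_state,
            )
            steps = []
            for asm, res in zip(series, results):
                state = res.domain_state
                steps.append({
                    "long_axis_nm": asm.meta["growth_long_axis_m"] * 1e9,
                    "cell_nm": asm.cell_size * 1e9,
                    "state": state.label,
                    "n_cores": state.n_cores,
                    "Mr_over_Ms": res.Mr_over_Ms,
                    "converged": res.converged,
                })
            manifest["stages"]["growth"] = {
                "seconds": time.perf_counter() - t0,
                "steps": steps,
            }

        if stage("barrier"):
            t0 = time.perf_counter()
            # isolated single grain, per the reference protocol
            single = build_grain(grain, cell_size=cell)
            solver = LEMSolver(single, material)
            base = minimize_lem(single, material, init="uniform",
                                direction=[1, 0, 0], tol=tol,
                                max_evals=max_evals, solver=solver)
            mirror_init = mirrored_state(
                base.field, axis=cfg["barrier"]["rotation_axis"],
                seed=cfg["seed"])
            mirror = solver.minimize(mirror_init, tol=tol,
                                     max_evals=max_evals)
            path_ = neb_path(base.field, mirror.field, solver,
                             n_images=cfg["barrier"]["n_images"],
                             tol=cfg["barrier"]["neb_tol"])
            path_ = refine_between_minima(path_, solver,
                                          tol=cfg["barrier"]["neb_tol"],
                                          n_images=cfg["barrier"]["n_images"])
            model = RelaxationModel(C=cfg["relaxation"]["C_s"],
                                    T=cfg["relaxation"]["T_K"])
            import pandas as pd

            p = outdir / "barrier_path.csv"
            pd.DataFrame({
                "path_index": path_.path_index,
                "energy_J": path_.energies,
                "energy_over_kT": path_.energies / model.ET,
            }).to_csv(p, index=False)
            register(p)
            manifest["stages"]["barrier"] = {
                "seconds": time.perf_counter() - t0,
                "Em_J": path_.Em,
                "Em_over_kT": path_.Em / model.ET,
                "tau_s": relaxation_time(path_.Em, model),
                "endpoint_energy_mismatch": abs(
                    path_.energies[0] - path_.energies[-1]
                ) / max(abs(path_.energies[0]), 1e-300),
                "converged": path_.converged,
                "refined": path_.refined,
            }

        if stage("uturn"):
            t0 = time.perf_counter()
            org = cfg["organism"]
            df = uturn_sweep(
                moments=THREE_GRAIN_MOMENTS,
                N_range=range(org["N_min"], org["N_max"] + 1),
                B_values_uT=org["B_uT"],
                b=org["b_um"] * 1e-6,
                eta=org["eta"],
                T=org["T_K"],
            )
            p = outdir / "uturn_sweep.csv"
            df.to_csv(p, index=False)
            register(p)
            manifest["stages"]["uturn"] = {
                "seconds": time.perf_counter() - t0,
                "n_rows": len(df),
            }
    except Exception as exc:  # partial manifest with the error recorded
        manifest["errors"].append(f"{type(exc).__name__}: {exc}")
        write_json(outdir / "manifest.json", manifest)
        raise

    write_json(outdir / "manifest.json", manifest)
    return manifest
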