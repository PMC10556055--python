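"""End-to-end orchestration: structures -> landscape -> tetramer -> pore -> residues.

A run is driven by a structured config (YAML or dict), validated
field-by-field before any compute.  Outputs land in a run directory with a
manifest (config hash, package version, seeds) and a single summary JSON;
rerunning the same config reproduces the deterministic outputs byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .electrophysiology import apparent_permeability, biionic_ratio, dilution_ratio
from .energy import EnergyParams
from .panel_landscape import compute_landscape, stable_states
from .pore_profile import profile_pore
from .pore_residues import NoPoreError, pore_lining_report
from .structures import (
    align_to_membrane_frame,
    load_structure,
    truncate_cterm,
    write_pdb,
)
from .synthetic_data import make_ephys_record, make_flux_series, make_toy_monomer
from .tetramer_assembly import CisDimer, build_tetramer, refine_tetramer

__all__ = ["run_pipeline", "validate_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 1729,
    "monomers": {
        "a": {"kind": "toy", "n_tm": 8,
              "ecl_charges": [["ECS1", 2, 1], ["ECS1", 7, -1]]},
        "b": {"kind": "toy", "n_tm": 8,
              "ecl_charges": [["ECS1", 3, -1], ["ECS2", 1, 1]]},
    },
    "energy": {"sigma": 4.7, "epsilon": 2.0, "eps_r": 15.0, "cutoff": 12.0},
    "panel": {"increment": 30.0, "contact_gap": 0.5, "percentile": 10.0},
    "assembly": {"gap": 2.0, "refine": True},
    "pore": {"z_step": 0.5, "probe_threshold": 0.9},
    "residues": {"cutoff": 6.0, "mode": "surface"},
    "ephys": {
        "true_p_na": 1.0e-5, "true_p_cl": 5.0e-6, "true_p_li": 1.2e-5,
        "noise_sd_mv": 0.0, "true_papp": 2.0e-7, "noise_frac": 0.0,
    },
}


class ConfigError(ValueError):
    """Config schema violations, reported field-by-field."""


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> dict:
    """Merge over defaults and check every field; collect all violations."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    errors = []
    if not isinstance(cfg["seed"], int):
        errors.append("seed: must be an integer")
    for name in ("a", "b"):
        mon = cfg["monomers"].get(name)
        if not isinstance(mon, dict):
            errors.append(f"monomers.{name}: missing")
            continue
        kind = mon.get("kind")
        if kind not in ("toy", "pdb"):
            errors.append(f"monomers.{name}.kind: must be 'toy' or 'pdb'")
        if kind == "pdb" and not mon.get("path"):
            errors.append(f"monomers.{name}.path: required for kind 'pdb'")
        if kind == "toy" and mon.get("n_tm", 8) <= 0:
            errors.append(f"monomers.{name}.n_tm: must be positive")
    for field in ("sigma", "epsilon", "eps_r", "cutoff"):
        if cfg["energy"].get(field, 1) <= 0:
            errors.append(f"energy.{field}: must be positive")
    inc = cfg["panel"].get("increment", 1.0)
    if inc <= 0 or not float(360.0 / inc).is_integer():
        errors.append("panel.increment: 360 must be divisible by the increment")
    if cfg["panel"].get("contact_gap", 0.5) < 0:
        errors.append("panel.contact_gap: must be non-negative")
    if not 0 < cfg["panel"].get("percentile", 10.0) <= 100:
        errors.append("panel.percentile: must be in (0, 100]")
    if cfg["assembly"].get("gap", 2.0) < 0:
        errors.append("assembly.gap: must be non-negative")
    if cfg["pore"].get("z_step", 0.5) <= 0:
        errors.append("pore.z_step: must be positive")
    if cfg["residues"].get("cutoff", 6.0) <= 0:
        errors.append("residues.cutoff: must be positive")
    if cfg["residues"].get("mode", "surface") not in ("surface", "centerline"):
        errors.append("residues.mode: must be 'surface' or 'centerline'")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _load_monomer(spec: dict, seed: int, label: str):
    if spec["kind"] == "toy":
        model = make_toy_monomer(
            n_tm_residues_per_helix=spec.get("n_tm", 8),
            ecl_charges=[tuple(c) for c in spec.get("ecl_charges", [])],
            seed=seed,
            label=spec.get("label", label),
        )
    else:
        model = load_structure(spec["path"], chain=spec.get("chain"),
                               label=spec.get("label", label))
        if "cterm_boundary" in spec:
            model = truncate_cterm(model, spec["cterm_boundary"])
        model = align_to_membrane_frame(model)
    return model


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config, out_dir) -> Path:
    """Run the full analysis chain; returns the run directory path."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    events = []

    def log(stage, **info):
        event = {"stage": stage, **info}
        events.append(event)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(event, sort_keys=True) + "\n")

    t0 = time.time()
    seed = cfg["seed"]
    params = EnergyParams(**cfg["energy"])

    # --- structures -------------------------------------------------------
    mono_a = _load_monomer(cfg["monomers"]["a"], seed, "A")
    mono_b = _load_monomer(cfg["monomers"]["b"], seed + 1, "B")
    (out / "structures").mkdir(exist_ok=True)
    write_pdb(mono_a, out / "structures" / "monomer_a.pdb")
    write_pdb(mono_b, out / "structures" / "monomer_b.pdb")
    log("structures", n_beads_a=len(mono_a), n_beads_b=len(mono_b),
        wall_s=round(time.time() - t0, 3))

    # --- PANEL landscape --------------------------------------------------
    t_stage = time.time()
    landscape = compute_landscape(
        mono_a, mono_b,
        increment=cfg["panel"]["increment"],
        params=params,
        contact_gap=cfg["panel"]["contact_gap"],
    )
    (out / "panel").mkdir(exist_ok=True)
    landscape.to_csv(out / "panel" / "landscape.csv")
    states = stable_states(landscape, cfg["panel"]["percentile"])
    summary_panel = landscape.summary()
    _json_dump(summary_panel, out / "panel" / "summary.json")
    log("panel", n_cells=landscape.n_cells, stable_states=states.count,
        wall_s=round(time.time() - t_stage, 3))

    # --- tetramer assembly ------------------------------------------------
    t_stage = time.time()
    theta1, theta2, _ = landscape.min_cell()
    asm = cfg["assembly"]
    theta1 = asm.get("theta1", theta1)
    theta2 = asm.get("theta2", theta2)
    dimer = CisDimer.from_thetas(mono_a, mono_b, theta1, theta2,
                                 cfg["panel"]["contact_gap"])
    tetramer = build_tetramer(dimer, dimer, gap=asm["gap"], params=params)
    if asm.get("refine", True):
        tetramer = refine_tetramer(tetramer, params=params)
    e_lj, e_coul, e_total = tetramer.energies
    tetramer.write_pdb(out / "tetramer.pdb")
    _json_dump(
        {"e_lj_kj_mol": e_lj, "e_coul_kj_mol": e_coul, "e_total_kj_mol": e_total,
         "theta1": theta1, "theta2": theta2, "gap": tetramer.gap},
        out / "tetramer_energies.json",
    )
    log("assembly", e_total=e_total, wall_s=round(time.time() - t_stage, 3))

    # --- pore profile -----------------------------------------------------
    t_stage = time.time()
    combined = tetramer.combined_model()
    ecs_lo = float(np.min(tetramer.dimer_bottom.positions[
        tetramer.dimer_bottom.ecs_mask(), 2]))
    ecs_hi = float(np.max(tetramer.dimer_top.positions[
        tetramer.dimer_top.ecs_mask(), 2]))
    pore_cfg = cfg["pore"]
    profile = profile_pore(
        combined,
        z_range=pore_cfg.get("z_range", (ecs_lo, ecs_hi)),
        z_step=pore_cfg["z_step"],
        probe_threshold=pore_cfg["probe_threshold"],
    )
    (out / "pore").mkdir(exist_ok=True)
    profile.to_csv(out / "pore" / "profile.csv")
    _json_dump(profile.summary(), out / "pore" / "summary.json")
    log("pore", min_diameter=profile.min_diameter,
        pore_exists=profile.pore_exists, wall_s=round(time.time() - t_stage, 3))

    # --- pore-lining residues --------------------------------------------
    t_stage = time.time()
    residues_summary = None
    try:
        report = pore_lining_report(
            combined, profile,
            cutoff=cfg["residues"]["cutoff"],
            mode=cfg["residues"]["mode"],
        )
        residues_summary = report.summary()
        report.to_frame().to_csv(out / "pore" / "lining_residues.csv", index=False)
    except NoPoreError:
        pass
    log("residues",
        net_charge=None if residues_summary is None
        else residues_summary["net_charge"],
        wall_s=round(time.time() - t_stage, 3))

    # --- electrophysiology side-chain ------------------------------------
    t_stage = time.time()
    eph = cfg["ephys"]
    record = make_ephys_record(
        eph["true_p_na"], eph["true_p_cl"], eph["true_p_li"],
        noise_sd_mv=eph["noise_sd_mv"], seed=seed,
    )
    beta = dilution_ratio(record.dilution_potential_mv,
                          record.apical, record.basal_dilution)
    li_over_na = biionic_ratio(record.biionic_potential_mv,
                               record.apical, record.basal_biionic, beta=beta)
    flux = make_flux_series(eph["true_papp"], noise_frac=eph["noise_frac"],
                            seed=seed)
    papp = apparent_permeability(flux)
    ephys_summary = {
        "beta_p_na_over_p_cl": beta,
        "p_li_over_p_na": li_over_na,
        "p_app_cm_s": papp,
        "dilution_potential_mv": record.dilution_potential_mv,
        "biionic_potential_mv": record.biionic_potential_mv,
    }
    _json_dump(ephys_summary, out / "ephys_summary.json")
    log("ephys", beta=beta, wall_s=round(time.time() - t_stage, 3))

    # --- manifest + summary -----------------------------------------------
    cfg_canonical = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_canonical.encode()).hexdigest(),
        "package_version": __version__,
        "seed": seed,
    }
    _json_dump(manifest, out / "manifest.json")
    summary = {
        "stable_state_count": states.count,
        "stable_state_mean_kj_mol": states.mean,
        "landscape_min_kj_mol": summary_panel["min_cell"]["e_total_kj_mol"],
        "trans_interface": {
            "e_lj_kj_mol": e_lj, "e_coul_kj_mol": e_coul,
            "e_total_kj_mol": e_total,
        },
        "min_pore_diameter_a": profile.min_diameter,
        "pore_exists": profile.pore_exists,
        "pore_lining": residues_summary
        if residues_summary is not None else "no pore-lining report",
        "ephys": ephys_summary,
    }
    _json_dump(summary, out / "summary.json")
    log("done", wall_s=round(time.time() - t0, 3))
    return out
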