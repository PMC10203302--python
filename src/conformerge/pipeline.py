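"""End-to-end pipeline: configuration, orchestration, reporting.

``run_all`` executes the integrative workflow on one peptide: conformer
sampling -> energy scoring -> per-conformer CCS -> FRET distance from
photophysics -> constraint cascade -> microsolvation of the selected
structures -> optional DMS shift summary. A single master seed fans out to
per-stage seeds through NumPy SeedSequence spawn keys, so any stage can be
re-run reproducibly in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ccs as ccs_mod
from . import conformers as conf_mod
from . import dms as dms_mod
from . import fret as fret_mod
from . import refine as refine_mod
from . import solvation as solv_mod

logger = logging.getLogger("conformerge")

__all__ = ["RunConfig", "validate_config", "run_all", "stage_seed"]


_SCHEMA: dict = {
    "seed": 0,
    "output_dir": "conformerge_out",
    "peptide": {
        "sequence": "AAAAKAAAAKAAAAKAAAAKAAAA",
        "conformation": "extended",
        "marker_residues": [0, 23],
        "charge_residues": [4, 9, 14, 19],
    },
    "photophysics": {
        "J_nm4_M_cm": 3.848e15,
        "phi_D": 0.63,
        "kappa2": 2.0 / 3.0,
        "refractive_index": 1.0,
        "tau_D_ns": 6.80,
        "tau_DA_ns": 1.46,
    },
    "ccs": {
        "probe_radius_A": 1.0,
        "n_orientations": 50,
        "n_points": 4000,
        "scale_factor": 1.0,
    },
    "sampling": {
        "heat_steps": 20,
        "plateau_steps": 200,
        "cool_steps": 60,
        "hold_steps": 40,
        "t_max_K": 1500.0,
        "n_roots": 10,
        "n_children": 5,
        "minimize_max_evals": 400,
        "minimize_switch_after": 150,
    },
    "constraints": {
        "peaks": [],  # list of {label, ccs_A2, tolerance_fraction}
        "r_da_A": None,  # default: computed from photophysics lifetimes
        "selection_rule": "closest",
        "k_select": 5,
        "energy_fraction": 0.2,
    },
    "microsolvation": {
        "enabled": True,
        "spacing_A": 0.75,
        "margin_A": 3.0,
        "n_orient": 12,
        "threshold_kcal": -1.5,
        "min_separation_A": 3.5,
    },
    "dms": {
        "enabled": False,
        "base_cv_V": 8.0,
        "shift_slope_V_per_molpct": 12.0,
        "width_V": 0.4,
        "height": 1000.0,
        "noise_sd": 5.0,
        "concentrations_mol_percent": [0.0, 0.2, 0.4],
    },
}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration (see ``_SCHEMA`` for keys)."""

    data: dict
    defaults_applied: list[str] = field(default_factory=list)

    def __getitem__(self, key):
        return self.data[key]


def _merge(schema: dict, user: dict, path: str, errors: list, defaults: list) -> dict:
    out = {}
    for key, default in schema.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            val = user[key]
            if isinstance(default, dict) and isinstance(val, dict):
                out[key] = _merge(default, val, here, errors, defaults)
            else:
                out[key] = val
        else:
            out[key] = json.loads(json.dumps(default)) if isinstance(default, (dict, list)) else default
            defaults.append(here)
    for key in user:
        if key not in schema:
            errors.append(f"unknown key: {path + '.' if path else ''}{key}")
    return out


def validate_config(path_or_dict) -> RunConfig:
    """Parse, default, and validate a YAML run configuration.

    All problems (unknown keys, invariant violations, missing files) are
    collected and reported in a single error."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    defaults: list[str] = []
    data = _merge(_SCHEMA, raw, "", errors, defaults)

    seed = data["seed"]
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")
    pep = data["peptide"]
    if not isinstance(pep["sequence"], str) or len(pep["sequence"]) < 2:
        errors.append("peptide.sequence must be a string of >= 2 residues")
    if len(pep["marker_residues"]) != 2:
        errors.append("peptide.marker_residues must list exactly 2 residues")
    cons = data["constraints"]
    for i, pk in enumerate(cons["peaks"]):
        for req in ("label", "ccs_A2"):
            if req not in pk:
                errors.append(f"constraints.peaks[{i}] missing key {req!r}")
    if cons["selection_rule"] not in ("closest", "closest_below"):
        errors.append(f"constraints.selection_rule invalid: {cons['selection_rule']!r}")
    ms = data["microsolvation"]
    if not 0.25 <= ms["spacing_A"] <= 1.0:
        errors.append("microsolvation.spacing_A must be in [0.25, 1.0]")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    for d in defaults:
        logger.debug("config default applied: %s", d)
    logger.info("configuration validated: seed=%s, peptide=%s", seed, pep["sequence"])
    return RunConfig(data=data, defaults_applied=defaults)


def stage_seed(master: int, stage: int) -> int:
    """Derive a per-stage seed from the master seed (documented scheme:
    SeedSequence(master, spawn_key=(stage,)) -> first 31-bit word)."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(data: dict) -> str:
    return hashlib.sha256(json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    ``report.json``, a text summary, and selected-structure PDB files to the
    configured output directory. Idempotent for identical configurations."""
    data = cfg.data
    outdir = Path(data["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = data["seed"]
    seeds = {name: stage_seed(master, k) for k, name in enumerate(["sampling", "ccs", "fret", "solvation", "dms"])}
    report: dict = {
        "schema_version": 1,
        "provenance": {"config_hash": _config_hash(data), "master_seed": master, "stage_seeds": seeds},
    }

    # --- photophysics -> experimental distance constraint
    ph = data["photophysics"]
    photo = fret_mod.DyePhotophysics(
        J=ph["J_nm4_M_cm"], phi_D=ph["phi_D"], kappa2=ph["kappa2"], n=ph["refractive_index"]
    )
    r0 = fret_mod.forster_radius(photo)
    eff = fret_mod.fret_efficiency(ph["tau_DA_ns"], ph["tau_D_ns"])
    r_da_fret = fret_mod.distance_from_efficiency(eff, r0) if 0 < eff < 1 else None
    report["fret"] = {
        "R0_A": r0,
        "efficiency": eff,
        "r_DA_A": r_da_fret,
        "tau_D_ns": ph["tau_D_ns"],
        "tau_DA_ns": ph["tau_DA_ns"],
    }
    logger.info("Förster radius R0 = %.1f Å; E = %.4f", r0, eff)

    # --- conformer sampling
    pep = data["peptide"]
    try:
        start = conf_mod.build_peptide(
            pep["sequence"],
            pep["conformation"],
            seed=seeds["sampling"],
            marker_residues=tuple(pep["marker_residues"]),
            charge_residues=tuple(pep["charge_residues"]),
        )
        sm = data["sampling"]
        schedule = conf_mod.AnnealingSchedule(
            heat_steps=sm["heat_steps"],
            plateau_steps=sm["plateau_steps"],
            cool_steps=sm["cool_steps"],
            hold_steps=sm["hold_steps"],
            t_max_K=sm["t_max_K"],
            n_roots=sm["n_roots"],
            n_children=sm["n_children"],
        )
        ensemble = conf_mod.anneal_sample(
            start,
            schedule,
            seed=seeds["sampling"],
            minimize_max_evals=sm["minimize_max_evals"],
            minimize_switch_after=sm["minimize_switch_after"],
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'sampling' failed: {exc}") from exc
    energies = [c.energy_kcal for c in ensemble]
    r_das = [conf_mod.marker_distance(c) for c in ensemble]
    report["ensemble"] = {
        "n_conformers": len(ensemble),
        "energy_min_kcal": float(np.min(energies)),
        "energy_max_kcal": float(np.max(energies)),
        "r_DA_min_A": float(np.min(r_das)),
        "r_DA_max_A": float(np.max(r_das)),
    }

    # --- CCS
    cc = data["ccs"]
    try:
        results = ccs_mod.ccs_distribution(
            ensemble,
            probe_radius_A=cc["probe_radius_A"],
            n_orientations=cc["n_orientations"],
            seed=seeds["ccs"],
            n_points=cc["n_points"],
            scale_factor=cc["scale_factor"],
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'ccs' failed: {exc}") from exc
    ccs_vals = [r.ccs_A2 for r in results if r is not None]
    report["ccs"] = {
        "n_computed": len(ccs_vals),
        "ccs_min_A2": float(np.min(ccs_vals)),
        "ccs_max_A2": float(np.max(ccs_vals)),
        "ccs_mean_A2": float(np.mean(ccs_vals)),
    }

    # --- refinement cascade
    cons = data["constraints"]
    peaks_cfg = cons["peaks"]
    if not peaks_cfg:
        # default: windows around the observed CCS distribution tails
        lo, hi = np.percentile(ccs_vals, [20, 80])
        peaks_cfg = [
            {"label": "C1", "ccs_A2": float(lo), "tolerance_fraction": 0.05},
            {"label": "C2", "ccs_A2": float(hi), "tolerance_fraction": 0.05},
        ]
        logger.warning("no CCS peaks configured; falling back to ensemble percentiles")
        warnings.warn("no CCS peaks configured; falling back to ensemble percentiles", stacklevel=2)
    peaks = [
        refine_mod.CCSPeak(p["label"], p["ccs_A2"], p.get("tolerance_fraction", 0.02))
        for p in peaks_cfg
    ]
    r_exp = cons["r_da_A"] if cons["r_da_A"] is not None else r_da_fret
    if r_exp is None:
        raise RuntimeError("stage 'cascade' failed: no experimental r_DA available")
    constraints = refine_mod.ExperimentalConstraints(
        ccs_peaks=peaks,
        r_da_A=float(r_exp),
        selection_rule=cons["selection_rule"],
        k_select=cons["k_select"],
    )
    try:
        cascade = refine_mod.run_cascade(ensemble, constraints, cons["energy_fraction"])
    except Exception as exc:
        raise RuntimeError(f"stage 'cascade' failed: {exc}") from exc
    report["cascade"] = {
        "stage_counts": cascade.stage_counts,
        "r_exp_A": float(r_exp),
        "mean_r_calc_A": cascade.mean_r_calc_A,
        "overestimation_percent": cascade.overestimation_percent,
        "selected_labels": {k: [c.label for c in v] for k, v in cascade.selected.items()},
    }

    # --- microsolvation of selected structures
    ms = data["microsolvation"]
    if ms["enabled"]:
        probe = solv_mod.SolventProbe.acetonitrile()
        groups: dict[str, list] = {}
        try:
            for label, confs in cascade.selected.items():
                complexes = []
                for c in confs:
                    m = solv_mod.energy_map(
                        c, probe, spacing_A=ms["spacing_A"], margin_A=ms["margin_A"],
                        n_orient=ms["n_orient"], seed=seeds["solvation"],
                    )
                    sites = solv_mod.find_sites(m, ms["threshold_kcal"], ms["min_separation_A"])
                    complexes.append(solv_mod.place_probes(c, sites, probe))
                groups[label] = complexes
        except Exception as exc:
            raise RuntimeError(f"stage 'microsolvation' failed: {exc}") from exc
        report["microsolvation"] = {
            label: {
                "n_sites": [x.n_sites for x in cx],
                "e_interaction_kcal": [x.e_interaction_kcal for x in cx],
            }
            for label, cx in groups.items()
        }
        labels = list(groups)
        if len(labels) == 2 and all(groups[label] for label in labels):
            report["microsolvation"]["comparison"] = solv_mod.compare_ensembles(
                groups[labels[0]], groups[labels[1]]
            )

    # --- DMS summary
    dm = data["dms"]
    if dm["enabled"]:
        series = [
            dms_mod.simulate_ionogram(
                base_cv_V=dm["base_cv_V"],
                shift_slope_V_per_molpct=dm["shift_slope_V_per_molpct"],
                width_V=dm["width_V"],
                height=dm["height"],
                noise_sd=dm["noise_sd"],
                concentration_mol_percent=c,
                seed=seeds["dms"] + i,
                species_label="pipeline",
            )
            for i, c in enumerate(dm["concentrations_mol_percent"])
        ]
        report["dms"] = dms_mod.cv_shift_series(series)

    # --- outputs
    for label, confs in cascade.selected.items():
        for c in confs:
            safe = c.label.replace("/", "_")
            conf_mod.write_pdb(c, outdir / f"selected_{label}_{safe}.pdb")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_text_report(report, outdir / "report.txt")
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report


def _write_text_report(report: dict, path) -> None:
    lines = ["conformerge pipeline report", "=" * 30]
    fr = report["fret"]
    lines.append(f"R0 = {fr['R0_A']:.1f} Å; E_FRET = {fr['efficiency']:.3f}; r_DA = "
                 + (f"{fr['r_DA_A']:.1f} Å" if fr["r_DA_A"] else "n/a"))
    en = report["ensemble"]
    lines.append(f"ensemble: {en['n_conformers']} conformers, "
                 f"E in [{en['energy_min_kcal']:.1f}, {en['energy_max_kcal']:.1f}] kcal/mol, "
                 f"r_DA in [{en['r_DA_min_A']:.1f}, {en['r_DA_max_A']:.1f}] Å")
    cs = report["ccs"]
    lines.append(f"CCS: mean {cs['ccs_mean_A2']:.1f} Å² (range {cs['ccs_min_A2']:.1f}-{cs['ccs_max_A2']:.1f})")
    ca = report["cascade"]
    for label, over in ca["overestimation_percent"].items():
        lines.append(
            f"peak {label}: mean r_calc = {ca['mean_r_calc_A'][label]:.1f} Å vs "
            f"r_exp = {ca['r_exp_A']:.1f} Å -> overestimation {over:+.1f}%"
        )
    if "microsolvation" in report:
        for label, d in report["microsolvation"].items():
            if label == "comparison":
                continue
            ns = d["n_sites"]
            es = d["e_interaction_kcal"]
            if ns:
                lines.append(
                    f"microsolvation {label}: {np.mean(ns):.1f} sites, "
                    f"E_int mean {np.mean(es):.1f} kcal/mol"
                )
    if "dms" in report:
        lines.append(f"DMS CV-shift slope: {report['dms']['slope_V_per_molpct']:.2f} V per mol%")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
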