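"""End-to-end analysis pipeline: plate kinetics → van 't Hoff → docking
→ dopachrome offset, with machine-readable JSON outputs and a
human-readable summary."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .constants import KELVIN_OFFSET, ROOM_TEMPERATURE_K
from .dcshift import DCShift
from .docking import (
    attach_ligand_coordinates,
    best_pose_per_temperature,
    binding_energy_to_kd,
    docking_vant_hoff_points,
    filter_correct_poses,
    load_active_site,
    parse_docking_table,
)
from .exceptions import DopathermError, PipelineStageError
from .kinetics import (
    aggregate_replicates,
    estimate_initial_velocity,
    fit_michaelis_menten,
    read_plate_csv,
    subtract_baseline,
)
from .vanthoff import VantHoff, build_vant_hoff_points, gibbs_energy

__all__ = ["run_pipeline"]

log = logging.getLogger("dopatherm")


def _sig6(x):
    """Round floats to 6 significant digits recursively (JSON hygiene)."""
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return None
        return float(f"{float(x):.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.bool_):
        return bool(x)
    return x


def _write_json(obj, path):
    Path(path).write_text(json.dumps(_sig6(obj), indent=2) + "\n")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DopathermError as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


@_stage("kinetics")
def _kinetics_stage(config: PipelineConfig, plate_csv):
    traces = read_plate_csv(plate_csv)
    blanks = {t.temperature_C: t for t in traces if t.is_blank}
    fits = []
    per_fit_records = []
    by_group: dict[tuple[float, str], list] = {}
    for tr in traces:
        if tr.is_blank:
            continue
        blank = blanks.get(tr.temperature_C)
        corrected = subtract_baseline(tr, blank) if blank is not None else tr
        by_group.setdefault((tr.temperature_C, tr.replicate_id), []).append(corrected)
    if not by_group:
        raise DopathermError(f"{plate_csv}: no reaction traces found")
    for (temp, rep), group in sorted(by_group.items()):
        rates = [
            estimate_initial_velocity(tr, config.window_s,
                                      config.epsilon_M_cm, config.path_cm)
            for tr in sorted(group, key=lambda g: g.substrate_mM)
        ]
        fit = fit_michaelis_menten(rates)
        fits.append(fit)
        per_fit_records.append({"temperature_C": temp, "replicate": rep,
                                **asdict(fit)})
    mean_fits = aggregate_replicates(fits)
    return mean_fits, per_fit_records


@_stage("vant_hoff")
def _vant_hoff_stage(config: PipelineConfig, mean_fits):
    points = build_vant_hoff_points(mean_fits, config.enzyme_conc_M)
    signature = VantHoff(points).fit()
    return points, signature


@_stage("docking")
def _docking_stage(config: PipelineConfig, docking_tsv, receptor_pdb):
    runs = parse_docking_table(docking_tsv)
    if receptor_pdb is not None:
        site = load_active_site(receptor_pdb)
        runs = attach_ligand_coordinates(runs, receptor_pdb)
        kept, counts = filter_correct_poses(runs, site, config.pose_cutoff_A)
    elif runs and "in_site_truth" in getattr(runs[0], "extra", {}):
        log.warning("no receptor PDB given; using the table's in_site_truth column")
        kept = [r for r in runs if str(r.extra["in_site_truth"]) == "True"]
        counts = {}
        for r in runs:
            counts.setdefault(r.temperature_C, 0)
        for r in kept:
            counts[r.temperature_C] += 1
    else:
        warnings.warn("docking runs carry no coordinates or truth labels; "
                      "all poses retained", stacklevel=2)
        kept, counts = runs, {}
    best, missing = best_pose_per_temperature(kept, config.temperatures_C)
    if missing:
        log.warning("temperatures with no correctly docked pose: %s", missing)
    points = docking_vant_hoff_points(best)
    signature = VantHoff(points).fit()
    affinities = [
        binding_energy_to_kd(r.binding_energy_kJ_mol,
                             t + KELVIN_OFFSET, temperature_C=t)
        for t, r in sorted(best.items())
    ]
    return best, counts, points, signature, affinities


def run_pipeline(
    config: PipelineConfig,
    plate_csv,
    docking_tsv=None,
    receptor_pdb=None,
    out_dir=None,
) -> dict:
    """Run kinetics → van 't Hoff → docking → DC shift and write the
    report bundle (fits.json, thermo.json, dcshift.json, summary.txt,
    vanthoff_plot.csv, provenance.json) into ``out_dir``.

    Without a docking table the DC stage is skipped and a kinetics-only
    report is produced.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"complete": False, "stages": []}

    mean_fits, per_fit_records = _kinetics_stage(config, plate_csv)
    report["stages"].append("kinetics")
    fits_payload = {
        "per_temperature_means": [asdict(f) for f in mean_fits],
        "per_replicate_fits": per_fit_records,
    }
    _write_json(fits_payload, out / "fits.json")

    kin_points, kin_sig = _vant_hoff_stage(config, mean_fits)
    report["stages"].append("vant_hoff")
    thermo_payload = {
        "normalization": "ln([E]/Km), association convention; "
                         "entropy intercept depends on enzyme_conc_M",
        "enzyme_conc_M": config.enzyme_conc_M,
        "kinetics_signature": asdict(kin_sig),
        "kinetics_points": [asdict(p) for p in kin_points],
        "gibbs_kJ_mol_by_T": [
            {"temperature_K": p.temperature_K,
             "dG_kJ_mol": gibbs_energy(kin_sig, p.temperature_K).dG_kJ_mol}
            for p in kin_points
        ],
    }

    dc_result = None
    dock_sig = None
    if docking_tsv is not None:
        best, counts, dock_points, dock_sig, affinities = _docking_stage(
            config, docking_tsv, receptor_pdb)
        report["stages"].append("docking")
        thermo_payload["docking_signature"] = asdict(dock_sig)
        thermo_payload["docking_points"] = [asdict(p) for p in dock_points]
        thermo_payload["correctly_docked_counts"] = {
            f"{t:g}": n for t, n in sorted(counts.items())}
        thermo_payload["best_pose_affinities"] = [asdict(a) for a in affinities]

        try:
            model = DCShift(kin_points, dock_sig)
            dc_result = model.fit()
        except DopathermError as exc:
            raise PipelineStageError("dc_shift", exc) from exc
        report["stages"].append("dc_shift")
        _write_json({
            "dc": dc_result.dc,
            "se_dc": dc_result.se_dc,
            "dG_dc_kJ_mol_at_298p15K": dc_result.free_energy(ROOM_TEMPERATURE_K),
            "dG_dc_by_T": [{"temperature_K": t, "dG_dc_kJ_mol": g}
                           for t, g in dc_result.dg_dc_by_T],
            "dG_m_by_T": [{"temperature_K": t, "dG_m_kJ_mol": g}
                          for t, g in dc_result.dg_m_by_T],
            "dG_assoc_by_T": [{"temperature_K": t, "dG_kJ_mol": g}
                              for t, g in dc_result.dg_assoc_by_T],
        }, out / "dcshift.json")
        model.plot_table(dc_result).to_csv(out / "vanthoff_plot.csv", index=False)
    else:
        log.warning("no docking table supplied; DC stage skipped")

    _write_json(thermo_payload, out / "thermo.json")

    summary = _render_summary(mean_fits, kin_sig, dock_sig, dc_result,
                              thermo_payload)
    (out / "summary.txt").write_text(summary)

    config_json = json.dumps(_sig6(asdict(config)), sort_keys=True)
    provenance = {
        "package": "dopatherm",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "seed": config.seed,
        "stages_completed": report["stages"],
    }
    _write_json(provenance, out / "provenance.json")

    report.update({
        "complete": True,
        "out_dir": str(out),
        "mean_fits": mean_fits,
        "kinetics_signature": kin_sig,
        "docking_signature": dock_sig,
        "dc_result": dc_result,
    })
    return report


def _render_summary(mean_fits, kin_sig, dock_sig, dc_result, thermo_payload) -> str:
    lines = ["Temperature-dependent diphenol-oxidase analysis", ""]
    lines.append("Michaelis-Menten kinetics (per-temperature means ± SEM)")
    lines.append(f"{'T (°C)':>8} {'Km (mM)':>16} {'Vmax (mM/min)':>18} {'adj R²':>8} {'n':>3}")
    for f in mean_fits:
        lines.append(f"{f.temperature_C:8.1f} {f.km_mM:8.3f} ± {f.se_km:5.3f} "
                     f"{f.vmax_mM_min:9.4f} ± {f.se_vmax:6.4f} {f.adj_r2:8.3f} {f.n_rates:3d}")
    lines.append("")
    lines.append("Apparent thermodynamic signature (association convention)")

    def sig_row(label, sig):
        return (f"  {label:<22} ΔH = {sig.dH_kJ_mol:8.2f} ± {sig.se_dH:5.2f} kJ/mol   "
                f"ΔS = {sig.dS_kJ_K_mol:7.4f} ± {sig.se_dS:6.4f} kJ/(K·mol)   "
                f"r = {sig.pearson_r:6.3f}   adj R² = {sig.adj_r2:6.3f}")

    lines.append(sig_row("Michaelis-Menten:", kin_sig))
    if dock_sig is not None:
        lines.append(sig_row("Docking:", dock_sig))
        if "best_pose_affinities" in thermo_payload:
            lines.append("")
            lines.append("Best-pose binding energies and affinities")
            for a in thermo_payload["best_pose_affinities"]:
                lines.append(f"  {a['temperature_C']:5.1f} °C: "
                             f"E = {a['source_energy_kJ_mol']:6.2f} kJ/mol, "
                             f"Kd = {a['kd_mM']:.4g} mM")
    if dc_result is not None:
        lines.append("")
        lines.append(dc_result.summary())
    lines.append("")
    return "\n".join(lines)
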