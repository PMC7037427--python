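"""Synthetic assay data with known ground truth.

Every downstream stage of the pipeline is exercised against data from
this module: dopachrome progress curves obeying Michaelis-Menten
substrate depletion with Beer-Lambert absorbance and Gaussian
plate-reader noise; docking-energy ensembles scattered about a van 't
Hoff line, with a controllable fraction of out-of-site decoy poses;
minimal PDB pose fixtures for the copper-proximity filter; and
ITC-style rate/absorbance pairs with a known proportionality.

The generator emulates the study conditions of the temperature-
dependent diphenol-oxidase assay: four temperatures (25/31/37/43 °C), a
twofold L-DOPA dilution series from 6 mM down to 0.09375 mM, dopachrome
read at 475 nm with ε = 3700 M⁻¹cm⁻¹ over a 0.3 cm path, duplicate
measurements repeated three times, and 200 docking runs per
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_ITC_SUBSTRATE_UM,
    DEFAULT_PATH_CM,
    DEFAULT_SUBSTRATE_SERIES_MM,
    DEFAULT_TEMPERATURES_C,
    EPSILON_DOPACHROME_M_CM,
    KELVIN_OFFSET,
    R_GAS,
)
from .exceptions import DegenerateDataError, DopathermError, InvalidGridError
from .kinetics import AbsorbanceTrace, RatePair, write_plate_csv

__all__ = [
    "SimulationParams",
    "DEFAULT_KM_BY_T_MM",
    "DEFAULT_VMAX_BY_T_MM_MIN",
    "DEFAULT_CU_POSITIONS",
    "gen_progress_curves",
    "gen_docking_table",
    "gen_pose_pdb_fixture",
    "gen_itc_rate_pairs",
    "write_simulation_bundle",
]

#: Ground-truth Michaelis constants per temperature, mM (study-condition
#: magnitudes: weaker apparent binding at higher temperature).
DEFAULT_KM_BY_T_MM = {25.0: 0.41, 31.0: 0.52, 37.0: 0.70, 43.0: 0.62}

#: Ground-truth maximal velocities per temperature, mM/min.
DEFAULT_VMAX_BY_T_MM_MIN = {25.0: 0.029, 31.0: 0.032, 37.0: 0.038, 43.0: 0.057}

#: Canonical binuclear-copper positions for fixtures, Å (Cu–Cu ≈ 3.6 Å).
DEFAULT_CU_POSITIONS = ((0.0, 0.0, 0.0), (3.6, 0.0, 0.0))


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters for progress-curve simulation.

    Concentrations are mM, velocities mM/min, times seconds, absorbance
    noise mOD. ``km_by_T_mM`` and ``vmax_by_T_mM_min`` must cover every
    requested temperature.
    """

    temperatures_C: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    substrate_series_mM: tuple[float, ...] = DEFAULT_SUBSTRATE_SERIES_MM
    km_by_T_mM: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_KM_BY_T_MM))
    vmax_by_T_mM_min: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_VMAX_BY_T_MM_MIN))
    epsilon_M_cm: float = EPSILON_DOPACHROME_M_CM
    path_cm: float = DEFAULT_PATH_CM
    duration_s: float = 1200.0
    step_s: float = 5.0
    noise_sigma_mOD: float = 2.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.step_s >= self.duration_s:
            raise InvalidGridError(
                f"step_s ({self.step_s}) must be smaller than duration_s ({self.duration_s})"
            )
        for name in ("epsilon_M_cm", "path_cm", "duration_s", "step_s"):
            if getattr(self, name) <= 0:
                raise DopathermError(f"{name} must be strictly positive")
        if self.noise_sigma_mOD < 0:
            raise DopathermError("noise_sigma_mOD must be non-negative")
        if self.n_replicates < 1:
            raise DopathermError("n_replicates must be >= 1")
        if len(set(self.temperatures_C)) != len(self.temperatures_C):
            raise DopathermError("temperatures must be distinct")
        if any(s <= 0 for s in self.substrate_series_mM):
            raise DopathermError("substrate concentrations must be strictly positive")
        for t in self.temperatures_C:
            if t not in self.km_by_T_mM or t not in self.vmax_by_T_mM_min:
                raise DopathermError(f"no ground-truth Km/Vmax for {t} °C")
            if self.km_by_T_mM[t] <= 0 or self.vmax_by_T_mM_min[t] <= 0:
                raise DopathermError("ground-truth Km and Vmax must be positive")

    @classmethod
    def from_thermo_signature(
        cls,
        dH_kJ_mol: float,
        dS_kJ_K_mol: float,
        enzyme_conc_M: float,
        vmax_by_T_mM_min: Mapping[float, float] | None = None,
        temperatures_C: Sequence[float] = DEFAULT_TEMPERATURES_C,
        **kwargs,
    ) -> "SimulationParams":
        """Derive Km(T) from a thermodynamic signature by inverting the
        van 't Hoff line: Km = [E]·exp(ΔH/(R·T) − ΔS/R) (molar → mM)."""
        if enzyme_conc_M <= 0:
            raise DopathermError("enzyme concentration must be positive")
        km = {}
        for t in temperatures_C:
            t_K = t + KELVIN_OFFSET
            km[t] = enzyme_conc_M * np.exp(
                dH_kJ_mol * 1e3 / (R_GAS * t_K) - dS_kJ_K_mol * 1e3 / R_GAS
            ) * 1e3
        vmax = dict(vmax_by_T_mM_min) if vmax_by_T_mM_min is not None else {
            t: DEFAULT_VMAX_BY_T_MM_MIN.get(t, 0.04) for t in temperatures_C
        }
        return cls(temperatures_C=tuple(temperatures_C), km_by_T_mM=km,
                   vmax_by_T_mM_min=vmax, **kwargs)


def _rk4_depletion(s0_mM: np.ndarray, km_mM: float, vmax_mM_s: float,
                   t_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of dS/dt = −Vmax·S/(Km+S), dP/dt = +….

    Vectorized over initial substrate concentrations; returns (S, P) of
    shape (len(s0), len(t)). The paired increments cancel exactly, so
    S + P = S₀ holds to machine precision at every step.
    """
    def rate(s):
        s = np.maximum(s, 0.0)
        return vmax_mM_s * s / (km_mM + s)

    n_t = t_s.size
    S = np.empty((s0_mM.size, n_t))
    P = np.empty_like(S)
    S[:, 0], P[:, 0] = s0_mM, 0.0
    for i in range(n_t - 1):
        h = t_s[i + 1] - t_s[i]
        s = S[:, i]
        k1 = -rate(s)
        k2 = -rate(s + 0.5 * h * k1)
        k3 = -rate(s + 0.5 * h * k2)
        k4 = -rate(s + h * k3)
        ds = (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        S[:, i + 1] = s + ds
        P[:, i + 1] = P[:, i] - ds
    return S, P


def gen_progress_curves(params: SimulationParams) -> list[AbsorbanceTrace]:
    """Simulate dopachrome progress curves for every (temperature,
    substrate, replicate) condition, plus a substrate-free blank per
    temperature.

    Product concentration follows Michaelis-Menten substrate depletion;
    absorbance is ε·L·P (mOD, for P in mM) plus i.i.d. Gaussian noise.
    Output is bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration_s + params.step_s / 2, params.step_s)
    s0 = np.asarray(params.substrate_series_mM, dtype=float)
    traces: list[AbsorbanceTrace] = []
    for temp in params.temperatures_C:
        km = params.km_by_T_mM[temp]
        vmax_s = params.vmax_by_T_mM_min[temp] / 60.0
        _, P = _rk4_depletion(s0, km, vmax_s, t)
        clean = params.epsilon_M_cm * params.path_cm * P  # mOD (P in mM)
        for j, sub in enumerate(params.substrate_series_mM):
            for rep in range(1, params.n_replicates + 1):
                noise = (rng.normal(0.0, params.noise_sigma_mOD, size=t.size)
                         if params.noise_sigma_mOD > 0 else 0.0)
                traces.append(AbsorbanceTrace(
                    time_s=t.copy(),
                    absorbance_mOD=clean[j] + noise,
                    temperature_C=temp,
                    substrate_mM=sub,
                    replicate_id=str(rep),
                    is_blank=False,
                ))
        blank_noise = (rng.normal(0.0, params.noise_sigma_mOD, size=t.size)
                       if params.noise_sigma_mOD > 0 else np.zeros(t.size))
        traces.append(AbsorbanceTrace(
            time_s=t.copy(),
            absorbance_mOD=np.asarray(blank_noise, dtype=float),
            temperature_C=temp,
            substrate_mM=0.0,
            replicate_id="1",
            is_blank=True,
        ))
    return traces


def gen_docking_table(
    dH_dock_kJ_mol: float,
    dS_dock_kJ_K_mol: float,
    temperatures_C: Sequence[float] = DEFAULT_TEMPERATURES_C,
    n_runs: int = 200,
    decoy_fraction: float = 0.0,
    energy_noise_kJ: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Docking-run table whose in-site energies scatter about the van 't
    Hoff line |ΔH − T·ΔS|.

    Columns: temperature_C, run_id, binding_energy_kJ_mol, in_site_truth,
    o_cu_offset_A. In-site poses carry ligand-oxygen-to-copper offsets of
    2–4 Å, decoys 10–20 Å, so any first-shell cutoff separates them.
    """
    if n_runs < 1:
        raise DopathermError("n_runs must be >= 1")
    if not (0.0 <= decoy_fraction < 1.0):
        raise DopathermError("decoy_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for temp in temperatures_C:
        t_K = temp + KELVIN_OFFSET
        mean_energy = abs(dH_dock_kJ_mol - t_K * dS_dock_kJ_K_mol)
        decoy = rng.random(n_runs) < decoy_fraction
        energies = mean_energy + (
            rng.normal(0.0, energy_noise_kJ, size=n_runs)
            if energy_noise_kJ > 0 else np.zeros(n_runs)
        )
        energies = np.clip(energies, 0.0, None)
        offsets = np.where(decoy,
                           rng.uniform(10.0, 20.0, size=n_runs),
                           rng.uniform(2.0, 4.0, size=n_runs))
        for i in range(n_runs):
            rows.append({
                "temperature_C": temp,
                "run_id": f"T{temp:g}_r{i + 1:04d}",
                "binding_energy_kJ_mol": energies[i],
                "in_site_truth": bool(~decoy[i]),
                "o_cu_offset_A": offsets[i],
            })
    return pd.DataFrame(rows)


def gen_pose_pdb_fixture(
    cu_positions: Sequence[Sequence[float]] = DEFAULT_CU_POSITIONS,
    pose_offsets_A: Sequence[float] = (),
    seed: int = 0,
) -> str:
    """Minimal PDB text: two copper HETATM records plus one catechol-like
    ligand residue per requested pose offset.

    Each pose's nearest oxygen sits exactly ``offset`` Å from the first
    copper (and no closer to the second), so a distance filter at any
    cutoff classifies the fixture deterministically. Poses are residues
    LDP 1..n on chain L.
    """
    cu = np.asarray(cu_positions, dtype=float)
    if cu.shape != (2, 3):
        raise DopathermError("exactly two 3-D copper positions are required")
    offsets = np.asarray(pose_offsets_A, dtype=float)
    if np.any(offsets < 0):
        raise DopathermError("pose offsets must be non-negative")
    rng = np.random.default_rng(seed)

    # Unit vector pointing from CuB through CuA, away from the site.
    axis = cu[0] - cu[1]
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)

    def fmt(serial, name, resname, chain, resseq, xyz, element):
        return (f"HETATM{serial:5d} {name:<4s}{'':1s}{resname:<3s} {chain:1s}"
                f"{resseq:4d}{'':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")

    lines = [
        "REMARK   1 SYNTHETIC POSE FIXTURE: TWO CU SITES PLUS CATECHOL-LIKE POSES",
        fmt(1, "CU", "CU", "A", 501, cu[0], "CU"),
        fmt(2, "CU", "CU", "A", 502, cu[1], "CU"),
    ]
    serial = 3
    for i, offset in enumerate(offsets, start=1):
        # small random tilt keeps poses distinct but preserves the exact
        # nearest-O distance to CuA
        tilt = rng.uniform(-0.15, 0.15)
        direction = axis + tilt * perp
        direction = direction / np.linalg.norm(direction)
        o1 = cu[0] + offset * direction
        atoms = [("O1", o1, "O"), ("O2", o1 + 1.30 * direction, "O")]
        for k in range(6):  # catechol ring placeholder carbons
            pos = o1 + (1.4 + 0.5 * k) * direction + 0.4 * ((-1) ** k) * perp
            atoms.append((f"C{k + 1}", pos, "C"))
        for name, xyz, elem in atoms:
            lines.append(fmt(serial, name, "LDP", "L", i, xyz, elem))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def gen_itc_rate_pairs(
    true_ratio: float,
    substrate_points_uM: Sequence[float] = DEFAULT_ITC_SUBSTRATE_UM,
    noise_rel: float = 0.0,
    seed: int = 0,
    km_uM: float = 700.0,
    amax_mOD: float = 100.0,
) -> list[RatePair]:
    """Matched UV/ITC rate pairs with a known proportionality constant.

    UV absorbances follow a Michaelis-Menten curve; ITC rates are the UV
    values divided by ``true_ratio``, with optional relative noise.
    """
    if true_ratio <= 0:
        raise DopathermError("true_ratio must be positive")
    rng = np.random.default_rng(seed)
    s = np.asarray(substrate_points_uM, dtype=float)
    uv = amax_mOD * s / (km_uM + s)
    if np.all(uv == 0):
        raise DegenerateDataError("generated UV signal is identically zero")
    rate = uv / true_ratio
    if noise_rel > 0:
        rate = rate * (1.0 + rng.normal(0.0, noise_rel, size=s.size))
    return [RatePair(substrate_uM=float(si), itc_rate_uM_s=float(ri),
                     uv_absorbance_mOD=float(ui))
            for si, ri, ui in zip(s, rate, uv)]


def write_simulation_bundle(
    out_dir,
    params: SimulationParams | None = None,
    # docking-line defaults reproduce best-pose energies near 26 kJ/mol,
    # the scale the study's docking outputs report
    dH_dock_kJ_mol: float = -21.34,
    dS_dock_kJ_K_mol: float = 0.0161,
    n_runs: int = 200,
    decoy_fraction: float = 0.3,
    energy_noise_kJ: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Write a complete synthetic input bundle (plate CSV, docking TSV,
    pose PDB) and return the paths with the ground truth used."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = SimulationParams(seed=seed if seed is not None else 0)
    elif seed is not None:
        params = SimulationParams(**{**params.__dict__, "seed": seed})

    plate_path = out / "plate.csv"
    write_plate_csv(gen_progress_curves(params), plate_path)

    table = gen_docking_table(dH_dock_kJ_mol, dS_dock_kJ_K_mol,
                              params.temperatures_C, n_runs=n_runs,
                              decoy_fraction=decoy_fraction,
                              energy_noise_kJ=energy_noise_kJ,
                              seed=params.seed + 1)
    docking_path = out / "docking.tsv"
    table.to_csv(docking_path, sep="\t", index=False)

    pdb_text = gen_pose_pdb_fixture(DEFAULT_CU_POSITIONS,
                                    table["o_cu_offset_A"].to_numpy(),
                                    seed=params.seed + 2)
    pdb_path = out / "poses.pdb"
    pdb_path.write_text(pdb_text)

    return {
        "plate_csv": str(plate_path),
        "docking_tsv": str(docking_path),
        "poses_pdb": str(pdb_path),
        "params": params,
        "dH_dock_kJ_mol": dH_dock_kJ_mol,
        "dS_dock_kJ_K_mol": dS_dock_kJ_K_mol,
    }
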