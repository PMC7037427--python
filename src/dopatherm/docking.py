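"""Docking-output analysis: pose classification against the binuclear
copper site, best-pose selection, and Boltzmann conversion of binding
energies to dissociation constants.

The package never runs a docking engine; it consumes tabulated docking
results (TSV) and, optionally, pose coordinates in PDB format. A pose
counts as "correctly docked" when a catechol oxygen of the ligand sits
within a cutoff distance of either catalytic copper — the geometry
required for diphenol oxidation chemistry.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .constants import DEFAULT_POSE_CUTOFF_A, R_GAS
from .exceptions import (
    DopathermError,
    InsufficientDataError,
    NotClassifiableError,
    SchemaError,
)
from .vanthoff import VantHoffPoint

__all__ = [
    "DockingRun",
    "ActiveSite",
    "AffinityEstimate",
    "parse_docking_table",
    "write_docking_tsv",
    "load_active_site",
    "load_pose_coordinates",
    "attach_ligand_coordinates",
    "filter_correct_poses",
    "best_pose_per_temperature",
    "binding_energy_to_kd",
    "kd_to_binding_energy",
    "docking_vant_hoff_points",
]

DOCKING_COLUMNS = ["temperature_C", "run_id", "binding_energy_kJ_mol"]


@dataclass
class DockingRun:
    """One docking pose: temperature, id, binding-energy magnitude and
    optional ligand coordinates (Å) with element labels."""

    temperature_C: float
    run_id: str
    binding_energy_kJ_mol: float
    ligand_elements: list[str] | None = None
    ligand_coords: np.ndarray | None = None

    def __post_init__(self):
        if self.binding_energy_kJ_mol < 0:
            raise DopathermError("binding energy is stored as a magnitude (>= 0)")
        if self.ligand_coords is not None:
            self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
            if self.ligand_coords.ndim != 2 or self.ligand_coords.shape[1] != 3:
                raise DopathermError("ligand_coords must be (n_atoms, 3)")
            if self.ligand_elements is None or len(self.ligand_elements) != len(self.ligand_coords):
                raise DopathermError("ligand_elements must label every coordinate")


@dataclass(frozen=True)
class ActiveSite:
    """The two catalytic copper positions of the tyrosinase active site (Å)."""

    cu_a: tuple[float, float, float]
    cu_b: tuple[float, float, float]

    def __post_init__(self):
        if np.allclose(self.cu_a, self.cu_b):
            raise DopathermError("the two copper positions must be distinct")

    @property
    def coppers(self) -> np.ndarray:
        return np.array([self.cu_a, self.cu_b], dtype=float)


@dataclass(frozen=True)
class AffinityEstimate:
    """Dissociation constant derived from a docking binding energy."""

    temperature_C: float
    kd_mM: float
    source_energy_kJ_mol: float

    def __post_init__(self):
        if self.kd_mM <= 0:
            raise DopathermError("Kd must be positive")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def parse_docking_table(path) -> list[DockingRun]:
    """Read a docking TSV (temperature_C, run_id, binding_energy_kJ_mol).

    Extra columns (e.g. a generator's in_site_truth) are preserved on the
    returned records as the attribute ``extra``. Malformed numeric fields
    raise :class:`SchemaError` naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DOCKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: docking table missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: docking table has no rows", stacklevel=2)
        return []
    runs = []
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after the header line
        try:
            temp = float(row["temperature_C"])
            energy = float(row["binding_energy_kJ_mol"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: non-numeric value on line {line_no}: {exc}") from exc
        run = DockingRun(temperature_C=temp, run_id=str(row["run_id"]),
                         binding_energy_kJ_mol=energy)
        run.extra = {c: row[c] for c in df.columns if c not in DOCKING_COLUMNS}
        runs.append(run)
    ids = pd.DataFrame({"t": [r.temperature_C for r in runs],
                        "id": [r.run_id for r in runs]})
    if ids.duplicated().any():
        raise SchemaError(f"{path}: duplicate run_id within a temperature")
    return runs


def write_docking_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pose geometry
# ---------------------------------------------------------------------------

def _parse_structure(pdb_source):
    parser = PDBParser(QUIET=True)
    if isinstance(pdb_source, str) and "\n" in pdb_source:
        handle = io.StringIO(pdb_source)
    else:
        handle = open(pdb_source)
    with handle:
        return parser.get_structure("poses", handle)


def load_active_site(pdb_source) -> ActiveSite:
    """Locate the two copper HETATM records in a receptor/pose PDB."""
    structure = _parse_structure(pdb_source)
    coppers = [a.coord for a in structure.get_atoms() if a.element == "CU"]
    if len(coppers) != 2:
        raise SchemaError(f"expected exactly 2 copper atoms, found {len(coppers)}")
    return ActiveSite(cu_a=tuple(map(float, coppers[0])),
                      cu_b=tuple(map(float, coppers[1])))


def load_pose_coordinates(pdb_source, ligand_resname: str = "LDP") -> dict[int, tuple[list[str], np.ndarray]]:
    """Extract ligand poses keyed by residue number from a pose PDB."""
    structure = _parse_structure(pdb_source)
    poses: dict[int, tuple[list[str], list]] = {}
    for residue in structure.get_residues():
        if residue.get_resname().strip() != ligand_resname:
            continue
        resseq = residue.get_id()[1]
        elements = [a.element for a in residue.get_atoms()]
        coords = np.array([a.coord for a in residue.get_atoms()], dtype=float)
        poses[resseq] = (elements, coords)
    return {k: (els, np.asarray(xyz)) for k, (els, xyz) in sorted(poses.items())}


def attach_ligand_coordinates(
    runs: Sequence[DockingRun],
    pdb_source,
    ligand_resname: str = "LDP",
) -> list[DockingRun]:
    """Attach pose coordinates to runs, pairing the i-th table row with the
    i-th ligand residue (ascending residue number) of the pose PDB."""
    poses = load_pose_coordinates(pdb_source, ligand_resname)
    if len(poses) != len(runs):
        raise SchemaError(
            f"pose count mismatch: {len(runs)} table rows, {len(poses)} PDB poses"
        )
    out = []
    for run, (els, xyz) in zip(runs, poses.values()):
        new = DockingRun(run.temperature_C, run.run_id, run.binding_energy_kJ_mol,
                         ligand_elements=list(els), ligand_coords=xyz)
        if hasattr(run, "extra"):
            new.extra = run.extra
        out.append(new)
    return out


def min_oxygen_copper_distance(run: DockingRun, site: ActiveSite) -> float:
    """Smallest distance (Å) from any ligand oxygen to either copper."""
    if run.ligand_coords is None:
        raise NotClassifiableError(
            f"run {run.run_id}: no ligand coordinates; pose cannot be classified"
        )
    oxy = np.array([xyz for el, xyz in zip(run.ligand_elements, run.ligand_coords)
                    if el.upper().startswith("O")])
    if oxy.size == 0:
        raise NotClassifiableError(
            f"run {run.run_id}: ligand has no oxygen atoms to test against the site"
        )
    d = np.linalg.norm(oxy[:, None, :] - site.coppers[None, :, :], axis=-1)
    return float(d.min())


def filter_correct_poses(
    runs: Sequence[DockingRun],
    site: ActiveSite,
    cutoff_A: float = DEFAULT_POSE_CUTOFF_A,
) -> tuple[list[DockingRun], dict[float, int]]:
    """Keep poses whose nearest ligand oxygen lies within ``cutoff_A`` of a
    copper; returns (kept runs, per-temperature kept counts)."""
    kept = [r for r in runs if min_oxygen_copper_distance(r, site) <= cutoff_A]
    counts: dict[float, int] = {}
    for r in runs:
        counts.setdefault(r.temperature_C, 0)
    for r in kept:
        counts[r.temperature_C] += 1
    return kept, counts


def best_pose_per_temperature(
    runs: Sequence[DockingRun],
    temperatures_C: Sequence[float] | None = None,
) -> tuple[dict[float, DockingRun], list[float]]:
    """Strongest-binding pose per temperature.

    Selection maximizes the binding-energy magnitude; ties break to the
    lexicographically smallest run_id. Returns (best-by-temperature,
    requested temperatures with no kept pose). Missing temperatures are
    reported, never filled in.
    """
    best: dict[float, DockingRun] = {}
    for run in sorted(runs, key=lambda r: (r.temperature_C, -r.binding_energy_kJ_mol, r.run_id)):
        best.setdefault(run.temperature_C, run)
    wanted = list(temperatures_C) if temperatures_C is not None else sorted(best)
    missing = [t for t in wanted if t not in best]
    return {t: best[t] for t in wanted if t in best}, missing


# ---------------------------------------------------------------------------
# Energy ↔ affinity conversion
# ---------------------------------------------------------------------------

def binding_energy_to_kd(energy_kJ_mol: float, temperature_K: float,
                         temperature_C: float | None = None) -> AffinityEstimate:
    """Boltzmann conversion of a binding-energy magnitude to Kd (mM).

    Kd = exp(−E/(R·T)) relative to the 1 M reference state, returned in mM.
    """
    if energy_kJ_mol < 0:
        raise DopathermError("binding energy magnitude must be non-negative")
    if temperature_K <= 0:
        raise DopathermError("temperature must be positive")
    kd_M = float(np.exp(-energy_kJ_mol * 1e3 / (R_GAS * temperature_K)))
    return AffinityEstimate(
        temperature_C=temperature_C if temperature_C is not None else temperature_K - 273.15,
        kd_mM=kd_M * 1e3,
        source_energy_kJ_mol=energy_kJ_mol,
    )


def kd_to_binding_energy(kd_mM: float, temperature_K: float) -> float:
    """Inverse of :func:`binding_energy_to_kd`; returns kJ/mol."""
    if kd_mM <= 0 or temperature_K <= 0:
        raise DopathermError("Kd and temperature must be positive")
    return float(-R_GAS * temperature_K * np.log(kd_mM * 1e-3) / 1e3)


def docking_vant_hoff_points(best_by_T: dict[float, DockingRun]) -> list[VantHoffPoint]:
    """Van 't Hoff points from best poses: ln K_assoc = E/(R·T) (molar units)."""
    if len(best_by_T) < 2:
        raise InsufficientDataError("docking van 't Hoff needs >= 2 temperatures")
    points = []
    for temp_C in sorted(best_by_T):
        run = best_by_T[temp_C]
        t_K = temp_C + 273.15
        points.append(VantHoffPoint(
            temperature_K=t_K,
            ln_k_norm=run.binding_energy_kJ_mol * 1e3 / (R_GAS * t_K),
            sigma_ln_k=0.0,
            source="docking",
        ))
    return points


def mean_pose_energy_per_temperature(runs: Iterable[DockingRun]) -> dict[float, float]:
    """Arithmetic-mean binding energy per temperature (averaging mode for
    temperatures reporting several comparable best poses)."""
    acc: dict[float, list[float]] = {}
    for r in runs:
        acc.setdefault(r.temperature_C, []).append(r.binding_energy_kJ_mol)
    return {t: float(np.mean(v)) for t, v in sorted(acc.items())}
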