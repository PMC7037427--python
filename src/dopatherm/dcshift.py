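"""Dopachrome-offset (DC) model.

On a shared van 't Hoff plot, the association line derived from docking
(the first, binding step of the reaction) and the points derived from
Michaelis-Menten kinetics (read out at the last, dopachrome step) are
parallel descriptions of the same interaction separated by a vertical
offset DC — the dopachrome effect:

    ln K_kinetics(1/T) = ln K_docking(1/T) + DC.

DC is fitted as a pure vertical shift (the slope, i.e. the apparent
enthalpy, is shared from the docking line). Its free-energy equivalent

    ΔG_dc(T) = R·T·|DC|

is the extra free energy separating the apparent binding seen through
dopachrome formation from the direct association, positive when the
kinetics-apparent binding is the weaker of the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import R_GAS, ROOM_TEMPERATURE_K
from .exceptions import DopathermError, InsufficientDataError
from .vanthoff import ThermoSignature, VantHoff, VantHoffPoint

__all__ = ["DCShiftResult", "DCShift", "fit_dc_offset", "dopachrome_free_energy"]


@dataclass(frozen=True)
class DCShiftResult:
    """Fitted dopachrome offset and its free-energy decomposition.

    ``dg_m_by_T`` holds the apparent (kinetics-side) free energy from the
    shifted docking line, ``dg_assoc_by_T`` the direct-association free
    energy from the unshifted line; their difference is ``dg_dc_by_T`` and
    equals R·T·|DC| at every listed temperature.
    """

    dc: float
    se_dc: float
    dg_dc_by_T: tuple[tuple[float, float], ...]
    dg_m_by_T: tuple[tuple[float, float], ...]
    dg_assoc_by_T: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if np.isfinite(self.se_dc) and self.se_dc < 0:
            raise DopathermError("se_dc must be non-negative")

    def free_energy(self, temperature_K: float) -> float:
        """ΔG_dc at an arbitrary temperature, kJ/mol."""
        return R_GAS * temperature_K * abs(self.dc) / 1e3

    def summary(self) -> str:
        lines = [
            "Dopachrome-offset fit (vertical shift of the docking association line)",
            f"  DC = {self.dc:.4f} ± {self.se_dc:.4f} (dimensionless)",
            f"  ΔG_dc(298.15 K) = {self.free_energy(ROOM_TEMPERATURE_K):.3f} kJ/mol",
        ]
        for (t, g_dc), (_, g_m), (_, g_a) in zip(
            self.dg_dc_by_T, self.dg_m_by_T, self.dg_assoc_by_T
        ):
            lines.append(
                f"  T = {t:7.2f} K: ΔG_m = {g_m:8.3f}, ΔG = {g_a:8.3f}, "
                f"ΔG_dc = {g_dc:7.3f} kJ/mol"
            )
        return "\n".join(lines)


class DCShift:
    """Model of the vertical offset between kinetics points and docking line.

    Parameters
    ----------
    kinetics_points : sequence of VantHoffPoint
        Kinetics-derived (1/T, ln K) points.
    docking_line : ThermoSignature
        Docking-derived association signature supplying slope and intercept.
    """

    def __init__(self, kinetics_points: Sequence[VantHoffPoint],
                 docking_line: ThermoSignature):
        self.points = list(kinetics_points)
        if len(self.points) < 2:
            raise InsufficientDataError("DC fit needs >= 2 kinetics points")
        if not (np.isfinite(docking_line.dH_kJ_mol) and np.isfinite(docking_line.dS_kJ_K_mol)):
            raise DopathermError("docking signature must be finite")
        self.docking_line = docking_line

    def fit(self, use_trendline: bool = False) -> DCShiftResult:
        """Least-squares vertical offset of the docking line to the kinetics
        data.

        With ``use_trendline`` the kinetics points are first replaced by
        their own fitted line evaluated at the same temperatures (identical
        result when the points are collinear).
        """
        t_K = np.array([p.temperature_K for p in self.points])
        ln_kin = np.array([p.ln_k_norm for p in self.points])
        if use_trendline:
            ln_kin = VantHoff(self.points).fit().predict_ln_k(t_K)
        ln_dock = self.docking_line.predict_ln_k(t_K)
        resid = ln_kin - ln_dock
        dc = float(resid.mean())
        n = resid.size
        se = float(np.std(resid, ddof=1) / np.sqrt(n)) if n > 1 else np.nan

        dg_assoc = -R_GAS * t_K * ln_dock / 1e3
        dg_m = -R_GAS * t_K * (ln_dock + dc) / 1e3
        dg_dc = dg_m - dg_assoc
        return DCShiftResult(
            dc=dc,
            se_dc=se,
            dg_dc_by_T=tuple(zip(t_K.tolist(), dg_dc.tolist())),
            dg_m_by_T=tuple(zip(t_K.tolist(), dg_m.tolist())),
            dg_assoc_by_T=tuple(zip(t_K.tolist(), dg_assoc.tolist())),
        )

    def plot_table(self, result: DCShiftResult) -> "pd.DataFrame":
        """Four plot-ready series: kinetics points, kinetics trendline,
        docking line, and the DC-shifted docking line."""
        import pandas as pd

        t_K = np.array([p.temperature_K for p in self.points])
        kin_line = VantHoff(self.points).fit().predict_ln_k(t_K)
        dock_line = self.docking_line.predict_ln_k(t_K)
        return pd.DataFrame({
            "inv_temperature_K": 1.0 / t_K,
            "ln_k_kinetics": [p.ln_k_norm for p in self.points],
            "ln_k_kinetics_trend": kin_line,
            "ln_k_docking_line": dock_line,
            "ln_k_docking_shifted": dock_line + result.dc,
        })


def fit_dc_offset(kinetics_points: Sequence[VantHoffPoint],
                  docking_line: ThermoSignature,
                  use_trendline: bool = False) -> DCShiftResult:
    """Fit the dopachrome offset DC; see :class:`DCShift`."""
    return DCShift(kinetics_points, docking_line).fit(use_trendline=use_trendline)


def dopachrome_free_energy(result_or_dc, temperature_K: float = ROOM_TEMPERATURE_K) -> float:
    """ΔG_dc = R·T·|DC| in kJ/mol.

    Accepts either a :class:`DCShiftResult` or a bare DC value.
    """
    dc = result_or_dc.dc if isinstance(result_or_dc, DCShiftResult) else float(result_or_dc)
    if not np.isfinite(dc):
        raise DopathermError("DC must be finite")
    if temperature_K <= 0:
        raise DopathermError("temperature must be positive")
    return R_GAS * temperature_K * abs(dc) / 1e3
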