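"""Van 't Hoff analysis: apparent thermodynamic signature from
temperature-indexed association constants.

The linearized van 't Hoff relation regresses the log of a normalized
association constant on reciprocal absolute temperature,

    ln(K/[E]) = (−ΔH/R)·(1/T) + ΔS/R,

so the slope yields the apparent enthalpy change and the intercept the
apparent entropy change of substrate association. For enzyme kinetics
the association constant is taken from the Michaelis constant under the
rapid-equilibrium assumption (product formation much slower than
complex dissociation, so Km ≈ Kd); the dimensionless normalized form
used here is [E]/Km, whose choice of enzyme concentration [E] shifts
only the entropy intercept, never the enthalpy slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .constants import KELVIN_OFFSET, R_GAS
from .exceptions import DopathermError, InsufficientDataError
from .kinetics import MichaelisMentenFit

__all__ = [
    "VantHoffPoint",
    "ThermoSignature",
    "GibbsEnergy",
    "VantHoff",
    "build_vant_hoff_points",
    "fit_vant_hoff",
    "gibbs_energy",
]


@dataclass(frozen=True)
class VantHoffPoint:
    """One point of a van 't Hoff plot: (1/T, ln normalized K)."""

    temperature_K: float
    ln_k_norm: float
    sigma_ln_k: float = 0.0
    source: str = "kinetics"

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise DopathermError("temperature_K must be positive")
        if self.sigma_ln_k < 0:
            raise DopathermError("sigma_ln_k must be non-negative")


@dataclass(frozen=True)
class ThermoSignature:
    """Apparent thermodynamic signature of an association reaction.

    Signs follow the association convention: a binding that strengthens
    on cooling has ΔH < 0; a positive ΔS indicates net disordering
    (e.g. dehydration of the interacting surfaces). Standard errors are
    propagated from the regression slope/intercept and are NaN when the
    fit is an exact two-point interpolation.
    """

    dH_kJ_mol: float
    dS_kJ_K_mol: float
    se_dH: float
    se_dS: float
    pearson_r: float
    adj_r2: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("a thermodynamic signature needs n >= 2")
        if np.isfinite(self.pearson_r) and abs(self.pearson_r) > 1 + 1e-12:
            raise DopathermError("|Pearson r| cannot exceed 1")

    def predict_ln_k(self, temperature_K):
        """Value of the fitted line at the given temperature(s)."""
        t = np.asarray(temperature_K, dtype=float)
        return (-self.dH_kJ_mol * 1e3 / R_GAS) / t + self.dS_kJ_K_mol * 1e3 / R_GAS


@dataclass(frozen=True)
class GibbsEnergy:
    temperature_K: float
    dG_kJ_mol: float

    def __post_init__(self):
        if not np.isfinite(self.dG_kJ_mol):
            raise DopathermError("ΔG must be finite")


def build_vant_hoff_points(
    fits: Sequence[MichaelisMentenFit],
    enzyme_conc_M: float,
) -> list[VantHoffPoint]:
    """Normalized association points from per-temperature Km means.

    ln K_norm = ln([E]/Km) with Km in molar units; the uncertainty of the
    log follows from the delta method, sigma_ln = SE(Km)/Km.
    """
    if enzyme_conc_M <= 0:
        raise DopathermError("enzyme concentration must be positive")
    points = []
    for fit in fits:
        km_M = fit.km_mM * 1e-3
        if km_M <= 0:
            raise DopathermError("Km must be positive for the log transform")
        points.append(VantHoffPoint(
            temperature_K=fit.temperature_C + KELVIN_OFFSET,
            ln_k_norm=float(np.log(enzyme_conc_M / km_M)),
            sigma_ln_k=float(fit.se_km / fit.km_mM),
            source="kinetics",
        ))
    return points


class VantHoff:
    """Linear van 't Hoff model of ln K_norm against 1/T."""

    def __init__(self, points: Sequence[VantHoffPoint]):
        self.points = list(points)
        if len(self.points) < 2:
            raise InsufficientDataError("van 't Hoff fit needs >= 2 points")
        self.temperature_K = np.array([p.temperature_K for p in self.points])
        self.ln_k = np.array([p.ln_k_norm for p in self.points])
        self.sigma = np.array([p.sigma_ln_k for p in self.points])
        if np.unique(self.temperature_K).size < 2:
            raise DopathermError("all points share one temperature; design is singular")

    def fit(self, weighted: bool = False) -> ThermoSignature:
        """OLS (default) or inverse-variance WLS line through the points."""
        x = 1.0 / self.temperature_K
        X = sm.add_constant(x)
        # errstate: a two-point fit has zero residual df and would warn
        with np.errstate(divide="ignore", invalid="ignore"):
            if weighted:
                if np.any(self.sigma <= 0):
                    raise DopathermError(
                        "weighted fit requires strictly positive sigma_ln_k for every point"
                    )
                res = sm.WLS(self.ln_k, X, weights=1.0 / self.sigma**2).fit()
            else:
                res = sm.OLS(self.ln_k, X).fit()
            intercept, slope = res.params
            se_int, se_slope = res.bse
        n = len(self.points)
        if n <= 2:
            se_int, se_slope = np.nan, np.nan
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(x, self.ln_k)[0, 1]) if n > 1 else np.nan
        # two points interpolate exactly; R² diagnostics are undefined there
        adj_r2 = float(res.rsquared_adj) if n > 2 else np.nan
        return ThermoSignature(
            dH_kJ_mol=float(-R_GAS * slope / 1e3),
            dS_kJ_K_mol=float(R_GAS * intercept / 1e3),
            se_dH=float(R_GAS * se_slope / 1e3),
            se_dS=float(R_GAS * se_int / 1e3),
            pearson_r=r,
            adj_r2=adj_r2,
            n=n,
        )


def fit_vant_hoff(points: Sequence[VantHoffPoint], weighted: bool = False) -> ThermoSignature:
    """Straight-line van 't Hoff fit; see :class:`VantHoff`."""
    return VantHoff(points).fit(weighted=weighted)


def gibbs_energy(sig: ThermoSignature, temperature_K: float) -> GibbsEnergy:
    """Gibbs free energy ΔG = ΔH − T·ΔS at the requested temperature."""
    return GibbsEnergy(
        temperature_K=temperature_K,
        dG_kJ_mol=sig.dH_kJ_mol - temperature_K * sig.dS_kJ_K_mol,
    )


def summary(sig: ThermoSignature, temperatures_K: Sequence[float] = ()) -> str:
    """Human-readable signature table (association convention)."""
    lines = [
        "Apparent thermodynamic signature (association convention; the",
        "entropy intercept depends on the enzyme-concentration normalization)",
        f"  ΔH = {sig.dH_kJ_mol:.3f} ± {sig.se_dH:.3f} kJ/mol",
        f"  ΔS = {sig.dS_kJ_K_mol:.4f} ± {sig.se_dS:.4f} kJ/(K·mol)",
        f"  Pearson r = {sig.pearson_r:.3f}   adj R² = {sig.adj_r2:.3f}   n = {sig.n}",
    ]
    for t in temperatures_K:
        lines.append(f"  ΔG({t:.2f} K) = {gibbs_energy(sig, t).dG_kJ_mol:.3f} kJ/mol")
    return "\n".join(lines)
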