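"""Plate-reader kinetics: dopachrome absorbance traces to Michaelis-Menten
parameters, plus the UV↔ITC proportional-rate calibration.

The workflow mirrors a standard diphenol-oxidase assay: raw 475 nm
absorbance traces are blank-subtracted, converted to dopachrome
concentration with the Beer-Lambert law, reduced to initial velocities
over an early linear window, and the velocity-vs-substrate profile is
fitted with the Michaelis-Menten rate law

    v(S) = Vmax · S / (Km + S)

by nonlinear least squares in log-parameter space (which enforces
Km, Vmax > 0). Replicate fits at the same temperature are averaged with
their SEM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .constants import (
    DEFAULT_PATH_CM,
    DEFAULT_WINDOW_S,
    EPSILON_DOPACHROME_M_CM,
)
from .exceptions import (
    DegenerateDataError,
    DopathermError,
    FitFailureError,
    InsufficientDataError,
    SchemaError,
    UnidentifiableFitError,
)

__all__ = [
    "AbsorbanceTrace",
    "InitialRate",
    "MichaelisMentenFit",
    "RatePair",
    "RatioFit",
    "MichaelisMenten",
    "MichaelisMentenResults",
    "ProportionalRatio",
    "absorbance_to_concentration",
    "subtract_baseline",
    "estimate_initial_velocity",
    "fit_michaelis_menten",
    "aggregate_replicates",
    "fit_proportional_ratio",
    "read_plate_csv",
    "write_plate_csv",
    "read_plate_wide",
]

PLATE_COLUMNS = [
    "time_s",
    "temperature_C",
    "substrate_mM",
    "replicate",
    "absorbance_mOD",
    "is_blank",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AbsorbanceTrace:
    """One dopachrome absorbance time series at fixed conditions.

    Parameters
    ----------
    time_s : array
        Sample times, seconds, strictly increasing.
    absorbance_mOD : array
        Absorbance at 475 nm in milli-optical-density units.
    temperature_C : float
        Assay temperature, °C.
    substrate_mM : float
        Initial L-DOPA concentration, mM (0 for blanks).
    replicate_id : str
        Replicate label.
    is_blank : bool
        True for substrate-free baseline wells.
    baseline_corrected : bool
        Set by :func:`subtract_baseline`.
    """

    time_s: np.ndarray
    absorbance_mOD: np.ndarray
    temperature_C: float
    substrate_mM: float
    replicate_id: str = "1"
    is_blank: bool = False
    baseline_corrected: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance_mOD = np.asarray(self.absorbance_mOD, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.absorbance_mOD.shape:
            raise DopathermError("time and absorbance must be 1-D and equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise DopathermError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance_mOD)):
            raise DopathermError("absorbance values must be finite")
        if self.substrate_mM < 0:
            raise DopathermError("substrate_mM must be non-negative")


@dataclass(frozen=True)
class InitialRate:
    """Initial velocity of dopachrome formation at one (T, S₀) condition."""

    substrate_mM: float
    temperature_C: float
    v_initial_mM_min: float
    se_mM_min: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise InsufficientDataError("initial rate requires n_points >= 3")
        if self.se_mM_min < 0:
            raise DopathermError("standard error must be non-negative")


@dataclass(frozen=True)
class MichaelisMentenFit:
    """Per-temperature Michaelis-Menten estimates with uncertainties.

    For single fits ``n_rates`` counts velocity points; for replicate
    aggregates it counts the contributing fits and the SE fields hold the
    SEM across replicates.
    """

    temperature_C: float
    km_mM: float
    vmax_mM_min: float
    se_km: float
    se_vmax: float
    adj_r2: float
    n_rates: int

    def __post_init__(self):
        if not (self.km_mM > 0 and self.vmax_mM_min > 0):
            raise DopathermError("Km and Vmax must be strictly positive")
        if np.isfinite(self.adj_r2) and self.adj_r2 > 1 + 1e-12:
            raise DopathermError("adjusted R² cannot exceed 1")


@dataclass(frozen=True)
class RatePair:
    """Matched ITC rate and UV absorbance at one substrate concentration."""

    substrate_uM: float
    itc_rate_uM_s: float
    uv_absorbance_mOD: float

    def __post_init__(self):
        if self.substrate_uM <= 0:
            raise DopathermError("substrate_uM must be positive")


@dataclass(frozen=True)
class RatioFit:
    """UV/ITC proportionality: mean absorbance-to-rate ratio and fit quality."""

    mean_ratio: float
    adj_r2: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("ratio fit requires n >= 2 pairs")


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------

def absorbance_to_concentration(
    a_mOD,
    epsilon_M_cm: float = EPSILON_DOPACHROME_M_CM,
    path_cm: float = DEFAULT_PATH_CM,
):
    """Beer-Lambert conversion of absorbance (mOD) to concentration (mM).

    c[M] = A[OD] / (ε·L); with A in mOD and c in mM the two factors of
    1000 cancel, leaving ``a_mOD / (ε·L)``.
    """
    if epsilon_M_cm <= 0 or path_cm <= 0:
        raise DopathermError("epsilon and path length must be positive")
    return np.asarray(a_mOD, dtype=float) / (epsilon_M_cm * path_cm)


def subtract_baseline(trace: AbsorbanceTrace, blank: AbsorbanceTrace) -> AbsorbanceTrace:
    """Subtract a substrate-free blank from a reaction trace.

    Points are paired by nearest time within half the sampling step; trace
    points with no blank sample that close are dropped. Temperatures must
    match and the blank must be flagged as such.
    """
    if not blank.is_blank:
        raise DopathermError("baseline trace must have is_blank=True")
    if not np.isclose(trace.temperature_C, blank.temperature_C):
        raise DopathermError(
            f"temperature mismatch: trace at {trace.temperature_C} °C, "
            f"blank at {blank.temperature_C} °C"
        )
    step = np.median(np.diff(trace.time_s)) if trace.time_s.size > 1 else 1.0
    idx = np.searchsorted(blank.time_s, trace.time_s)
    idx_lo = np.clip(idx - 1, 0, blank.time_s.size - 1)
    idx_hi = np.clip(idx, 0, blank.time_s.size - 1)
    nearer = np.where(
        np.abs(blank.time_s[idx_lo] - trace.time_s)
        <= np.abs(blank.time_s[idx_hi] - trace.time_s),
        idx_lo,
        idx_hi,
    )
    dt = np.abs(blank.time_s[nearer] - trace.time_s)
    keep = dt <= step / 2
    if not np.any(keep):
        raise DopathermError("trace and blank share no overlapping time range")
    return AbsorbanceTrace(
        time_s=trace.time_s[keep],
        absorbance_mOD=trace.absorbance_mOD[keep] - blank.absorbance_mOD[nearer[keep]],
        temperature_C=trace.temperature_C,
        substrate_mM=trace.substrate_mM,
        replicate_id=trace.replicate_id,
        is_blank=False,
        baseline_corrected=True,
    )


def estimate_initial_velocity(
    trace: AbsorbanceTrace,
    window_s: float = DEFAULT_WINDOW_S,
    epsilon_M_cm: float = EPSILON_DOPACHROME_M_CM,
    path_cm: float = DEFAULT_PATH_CM,
) -> InitialRate:
    """Initial velocity from the early linear portion of a progress curve.

    Absorbance is converted to dopachrome concentration and an ordinary
    least-squares line is fitted over ``t ∈ [0, window_s]``; the slope is
    the initial velocity in mM/min with its standard error.
    """
    mask = trace.time_s <= window_s
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"initial-velocity window holds {n} points; at least 3 required"
        )
    t_min = trace.time_s[mask] / 60.0
    conc = absorbance_to_concentration(trace.absorbance_mOD[mask], epsilon_M_cm, path_cm)
    model = sm.OLS(conc, sm.add_constant(t_min))
    res = model.fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se):
        se = 0.0
    return InitialRate(
        substrate_mM=trace.substrate_mM,
        temperature_C=trace.temperature_C,
        v_initial_mM_min=slope,
        se_mM_min=se,
        n_points=n,
    )


# ---------------------------------------------------------------------------
# Michaelis-Menten model
# ---------------------------------------------------------------------------

class MichaelisMenten:
    """Michaelis-Menten rate-law model v(S) = Vmax·S/(Km+S).

    Parameters
    ----------
    substrate_mM : array
        Substrate concentrations, mM.
    rate_mM_min : array
        Observed initial velocities, mM/min.
    temperature_C : float, optional
        Temperature tag carried into the results.

    The fit is performed on (log Km, log Vmax), which keeps both
    parameters strictly positive; standard errors are mapped back to the
    natural scale with the delta method.
    """

    #: identifiability guard: Km outside [min(S)/RANGE, max(S)·RANGE] is
    #: treated as divergence of the estimate.
    KM_RANGE_FACTOR = 1e5

    def __init__(self, substrate_mM, rate_mM_min, temperature_C: float | None = None):
        self.substrate_mM = np.asarray(substrate_mM, dtype=float)
        self.rate_mM_min = np.asarray(rate_mM_min, dtype=float)
        self.temperature_C = temperature_C
        if self.substrate_mM.shape != self.rate_mM_min.shape:
            raise DopathermError("substrate and rate arrays must match in length")
        if np.any(self.substrate_mM <= 0):
            raise DopathermError("substrate concentrations must be positive")
        if np.unique(self.substrate_mM).size < 3:
            raise UnidentifiableFitError(
                "Michaelis-Menten fit needs at least 3 distinct substrate concentrations"
            )

    @classmethod
    def from_rates(cls, rates: Sequence[InitialRate]) -> "MichaelisMenten":
        if not rates:
            raise InsufficientDataError("no initial rates supplied")
        temps = {r.temperature_C for r in rates}
        if len(temps) != 1:
            raise DopathermError(f"rates span multiple temperatures: {sorted(temps)}")
        return cls(
            [r.substrate_mM for r in rates],
            [r.v_initial_mM_min for r in rates],
            temperature_C=rates[0].temperature_C,
        )

    def _start_values(self) -> tuple[float, float]:
        # Vmax₀ = largest observed rate; Km₀ = substrate at half Vmax₀ by
        # interpolation of the mean rate profile.
        order = np.argsort(self.substrate_mM)
        s, v = self.substrate_mM[order], self.rate_mM_min[order]
        s_u = np.unique(s)
        v_u = np.array([v[s == x].mean() for x in s_u])
        vmax0 = max(float(v.max()), 1e-12)
        half = vmax0 / 2.0
        km0 = float(np.interp(half, v_u, s_u)) if v_u[-1] >= half else float(s_u[-1])
        km0 = min(max(km0, s_u[0] / 10.0), s_u[-1] * 10.0)
        return km0, vmax0

    def fit(self, start: tuple[float, float] | None = None, n_restarts: int = 5,
            seed: int = 0) -> "MichaelisMentenResults":
        """Fit by nonlinear least squares with jittered restarts on failure."""
        s, v = self.substrate_mM, self.rate_mM_min
        km0, vmax0 = start if start is not None else self._start_values()

        def residual(theta):
            km, vmax = np.exp(theta)
            return vmax * s / (km + s) - v

        rng = np.random.default_rng(seed)
        x0 = np.log([km0, vmax0])
        best = None
        attempts = []
        for attempt in range(n_restarts + 1):
            x_init = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.5, size=2)
            sol = least_squares(residual, x_init, method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            attempts.append({"x0": x_init.tolist(), "cost": float(sol.cost),
                             "status": int(sol.status)})
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitFailureError(
                "Michaelis-Menten fit did not converge", {"attempts": attempts}
            )

        km, vmax = np.exp(best.x)
        if km < s.min() / self.KM_RANGE_FACTOR or km > s.max() * self.KM_RANGE_FACTOR:
            raise UnidentifiableFitError(
                f"Km estimate {km:.3g} mM diverges from the sampled substrate "
                f"range [{s.min():.3g}, {s.max():.3g}] mM; the design is "
                "uninformative (rates do not saturate or do not vary)"
            )

        n, p = s.size, 2
        resid = residual(best.x)
        ssr = float(resid @ resid)
        dof = n - p
        s2 = ssr / dof if dof > 0 else 0.0
        jtj = best.jac.T @ best.jac
        try:
            cov_log = s2 * np.linalg.inv(jtj)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        except np.linalg.LinAlgError:
            se_log = np.full(2, np.nan)
        se_km, se_vmax = se_log * np.array([km, vmax])  # delta method

        sst = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else np.nan
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if (dof > 0 and np.isfinite(r2)) else np.nan

        return MichaelisMentenResults(
            model=self, km_mM=float(km), vmax_mM_min=float(vmax),
            se_km=float(se_km), se_vmax=float(se_vmax),
            adj_r2=float(adj_r2) if adj_r2 is not None else np.nan,
            ssr=ssr, n=n,
        )


@dataclass
class MichaelisMentenResults:
    """Fitted Michaelis-Menten parameters with uncertainties and diagnostics."""

    model: MichaelisMenten
    km_mM: float
    vmax_mM_min: float
    se_km: float
    se_vmax: float
    adj_r2: float
    ssr: float
    n: int

    @property
    def params(self) -> dict:
        return {"km_mM": self.km_mM, "vmax_mM_min": self.vmax_mM_min}

    @property
    def bse(self) -> dict:
        return {"km_mM": self.se_km, "vmax_mM_min": self.se_vmax}

    def predict(self, substrate_mM):
        s = np.asarray(substrate_mM, dtype=float)
        return self.vmax_mM_min * s / (self.km_mM + s)

    def to_fit(self) -> MichaelisMentenFit:
        return MichaelisMentenFit(
            temperature_C=self.model.temperature_C if self.model.temperature_C is not None else np.nan,
            km_mM=self.km_mM, vmax_mM_min=self.vmax_mM_min,
            se_km=self.se_km, se_vmax=self.se_vmax,
            adj_r2=self.adj_r2, n_rates=self.n,
        )

    def summary(self) -> str:
        t = self.model.temperature_C
        lines = [
            "Michaelis-Menten fit" + (f" at {t:g} °C" if t is not None else ""),
            f"  Km   = {self.km_mM:.4g} ± {self.se_km:.2g} mM",
            f"  Vmax = {self.vmax_mM_min:.4g} ± {self.se_vmax:.2g} mM/min",
            f"  adj R² = {self.adj_r2:.4f}   n = {self.n}   SSR = {self.ssr:.3g}",
        ]
        return "\n".join(lines)


def fit_michaelis_menten(rates: Sequence[InitialRate], **fit_kwargs) -> MichaelisMentenFit:
    """Fit the rate law to a single temperature's initial velocities."""
    return MichaelisMenten.from_rates(rates).fit(**fit_kwargs).to_fit()


def aggregate_replicates(fits: Iterable[MichaelisMentenFit]) -> list[MichaelisMentenFit]:
    """Average replicate fits per temperature; SE fields become the SEM.

    Returns one fit per temperature, sorted by temperature. With a single
    replicate the SEM is 0 by convention and n_rates records 1.
    """
    fits = list(fits)
    if not fits:
        raise InsufficientDataError("no fits to aggregate")
    out = []
    for temp in sorted({f.temperature_C for f in fits}):
        group = [f for f in fits if f.temperature_C == temp]
        km = np.array([f.km_mM for f in group])
        vmax = np.array([f.vmax_mM_min for f in group])
        n = len(group)
        sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(MichaelisMentenFit(
            temperature_C=temp,
            km_mM=float(km.mean()),
            vmax_mM_min=float(vmax.mean()),
            se_km=sem(km),
            se_vmax=sem(vmax),
            adj_r2=float(np.mean([f.adj_r2 for f in group])),
            n_rates=n,
        ))
    return out


# ---------------------------------------------------------------------------
# UV ↔ ITC proportional calibration
# ---------------------------------------------------------------------------

class ProportionalRatio:
    """Proportional model uv = ratio · rate linking UV absorbance to ITC rates."""

    def __init__(self, pairs: Sequence[RatePair]):
        self.pairs = list(pairs)
        if len(self.pairs) < 2:
            raise InsufficientDataError("ratio fit requires at least 2 pairs")
        self.rate = np.array([p.itc_rate_uM_s for p in self.pairs])
        self.uv = np.array([p.uv_absorbance_mOD for p in self.pairs])
        if np.any(self.rate == 0):
            raise DegenerateDataError("ITC rate of exactly zero cannot enter a ratio")
        if np.all(self.uv == 0):
            raise DegenerateDataError("all UV absorbances are zero; ratio undefined")

    def fit(self) -> RatioFit:
        ratios = self.uv / self.rate
        mean_ratio = float(ratios.mean())
        pred = mean_ratio * self.rate
        ss_res = float(np.sum((self.uv - pred) ** 2))
        ss_tot = float(np.sum((self.uv - self.uv.mean()) ** 2))
        n = len(self.pairs)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if (n > 2 and np.isfinite(r2)) else r2
        return RatioFit(mean_ratio=mean_ratio, adj_r2=float(adj), n=n)


def fit_proportional_ratio(pairs: Sequence[RatePair]) -> RatioFit:
    """Mean UV/ITC ratio and adjusted R² of the proportional model."""
    return ProportionalRatio(pairs).fit()


# ---------------------------------------------------------------------------
# Plate CSV I/O
# ---------------------------------------------------------------------------

def write_plate_csv(traces: Iterable[AbsorbanceTrace], path) -> None:
    """Write traces in the long plate dialect (one row per time point)."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.time_s,
            "temperature_C": tr.temperature_C,
            "substrate_mM": tr.substrate_mM,
            "replicate": tr.replicate_id,
            "absorbance_mOD": tr.absorbance_mOD,
            "is_blank": tr.is_blank,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plate_csv(path) -> list[AbsorbanceTrace]:
    """Read the long plate dialect back into traces."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required plate columns {missing}")
    traces = []
    keys = ["temperature_C", "substrate_mM", "replicate", "is_blank"]
    for (temp, sub, rep, blank), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_s")
        traces.append(AbsorbanceTrace(
            time_s=grp["time_s"].to_numpy(),
            absorbance_mOD=grp["absorbance_mOD"].to_numpy(),
            temperature_C=float(temp),
            substrate_mM=float(sub),
            replicate_id=str(rep),
            is_blank=bool(blank),
        ))
    return traces


def read_plate_wide(path, mapping_path) -> list[AbsorbanceTrace]:
    """Read a wide plate export (time column + one column per well).

    ``mapping_path`` is a CSV with columns well, temperature_C,
    substrate_mM, replicate, is_blank assigning conditions to wells.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: wide plate export needs a time_s column")
    mapping = pd.read_csv(mapping_path)
    needed = {"well", "temperature_C", "substrate_mM", "replicate", "is_blank"}
    if not needed.issubset(mapping.columns):
        raise SchemaError(f"{mapping_path}: mapping needs columns {sorted(needed)}")
    traces = []
    for _, row in mapping.iterrows():
        well = str(row["well"])
        if well not in df.columns:
            raise SchemaError(f"{path}: well column {well!r} absent from export")
        traces.append(AbsorbanceTrace(
            time_s=df["time_s"].to_numpy(),
            absorbance_mOD=df[well].to_numpy(),
            temperature_C=float(row["temperature_C"]),
            substrate_mM=float(row["substrate_mM"]),
            replicate_id=str(row["replicate"]),
            is_blank=bool(row["is_blank"]),
        ))
    return traces
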