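# Methods

## Model and assumptions

The pipeline treats one enzymatic readout — dopachrome absorbance at
475 nm — as a window onto the thermodynamics of L-DOPA association with
tyrosinase.

**Kinetic layer.** Each progress curve is modelled as single-step
Michaelis-Menten substrate depletion with 1:1 L-DOPA → dopachrome
stoichiometry:

    dS/dt = −Vmax·S/(Km + S),   dP/dt = +Vmax·S/(Km + S),   A = ε·L·P

The dopaquinone intermediate is not modelled: only dopachrome absorbs at
the readout wavelength, so a two-step scheme would be unidentifiable from
this signal. Initial velocities are ordinary-least-squares slopes of
concentration over the first analysis window (default 480 s), and the
velocity-vs-substrate profile is fitted with v = Vmax·S/(Km+S) by
nonlinear least squares.

**Thermodynamic layer.** Under rapid equilibrium (product formation much
slower than complex dissociation) Km approximates the dissociation
constant, so ln([E]/Km) is a log association constant up to a
normalization. Regressed on 1/T it yields apparent ΔH (slope × −R) and
ΔS (intercept × R). Docking binding-energy magnitudes E convert to molar
association constants via ln K = E/(R·T) (Boltzmann, 1 M reference
state). The dopachrome offset DC is the least-squares vertical shift
aligning the docking association line with the kinetics points; its
free-energy equivalent is ΔG_dc = R·T·|DC|.

**Normalization caveat.** The kinetics axis uses the dimensionless
association form ln([E]/Km), the docking axis the molar form E/RT. The
enzyme concentration [E] is a pure normalization: it shifts the kinetics
intercept (ΔS) and therefore DC, but never ΔH, Pearson r, or any
difference between temperatures. Outputs state this prominently; choose
[E] deliberately when DC magnitudes are to be compared across studies.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ε (dopachrome, 475 nm) | 3700 | M⁻¹cm⁻¹ | standard molar absorptivity of dopachrome |
| path length L | 0.3 | cm | plate-well optical path |
| analysis window | 480 | s | first eight minutes of reaction |
| temperatures | 25, 31, 37, 43 | °C | assay grid spanning physiological range |
| substrate series | 0.09375–6 (×2) | mM | exact twofold dilution ladder; the ladder brackets Km from ~Km/6 to ~10·Km |
| enzyme conc. [E] | 2·10⁻⁶ | M | 0.1 mg/mL of the ~52 kDa truncated enzyme (the calorimetry cell concentration); normalization only |
| pose cutoff | 6.0 | Å | ligand-oxygen-to-copper distance bounding the first coordination shell |
| gas constant R | 8.314 | J/(K·mol) | CODATA value, pinned in config |
| RK4 step | 5 | s | matches a plate-reader sampling interval; integration error ≪ 10⁻⁶ |
| plate noise σ | 2 | mOD | typical well-to-well photometric scatter |
| replicates | 3 | — | independent repeats per condition |
| docking runs | 200 | per T | ensemble size of a docking screen |

Ground-truth generator values (Km 0.41/0.52/0.70/0.62 mM, Vmax
0.029/0.032/0.038/0.057 mM/min across 25–43 °C) reproduce the magnitudes
and temperature trend of the assay the package models. The
docking-energy line defaults (ΔH = −21.34 kJ/mol, ΔS = 0.0161 kJ/K/mol)
are chosen so generated best-pose energies fall near 26 kJ/mol, the
scale a docking screen of this system reports.

## What the generator does and does not emulate

It emulates: Michaelis-Menten depletion with Beer-Lambert readout,
i.i.d. Gaussian photometric noise, substrate-free blanks, docking-energy
ensembles scattered about a van 't Hoff line with a controllable decoy
fraction, pose geometry with exact oxygen-copper offsets, and
proportional UV/ITC rate pairs.

It does not emulate: the monophenolase lag phase, enzyme inactivation at
elevated temperature, substrate inhibition, absorbance saturation,
melanin polymerization, drift or spatial plate gradients, or ITC heat
pulses. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to these
real-data pathologies.

## Numerical choices

- **MM fit**: optimization over (log Km, log Vmax) enforces positivity;
  starts at Vmax₀ = max observed rate and Km₀ = interpolated substrate at
  half Vmax₀, with five jittered restarts; convergence tolerances 10⁻¹⁴ on
  step and objective; standard errors from the Jacobian at the optimum
  mapped back by the delta method. Km estimates escaping the sampled
  substrate range by more than 10⁵× are flagged unidentifiable rather
  than reported.
- **Regressions**: initial velocities and van 't Hoff lines use OLS
  (statsmodels); inverse-variance weighting is available when every point
  carries a positive σ. Two-point van 't Hoff fits interpolate exactly
  and flag their standard errors as undefined (NaN).
- **Best-pose ties**: equal energies break to the lexicographically
  smallest run id, making selection permutation-invariant.
- **Baseline pairing**: nearest-time matching within half the sampling
  step; disjoint grids are an error, not an empty result.
- **Integration**: fixed-step RK4 on the paired (S, P) system; the paired
  increments cancel exactly, so S+P is conserved to machine precision,
  and halving the step changes the final product by < 10⁻⁶ relative.
- **JSON outputs**: six significant digits, fixed key order — byte-stable
  for a fixed seed.

## Design decisions taken where the design was open

- DC is a pure vertical offset (slope shared from the docking line),
  fitted to the kinetics points by default; a trendline-based variant is
  available and identical when points are collinear.
- Replicate bookkeeping: one MM fit per (temperature, replicate) on that
  replicate's rates, then unweighted per-temperature means with SEM.
- ΔG_dc is reported per temperature with "room temperature" fixed at
  298.15 K; the decomposition uses the shifted docking line as the
  kinetics-side model so that ΔG_dc(T) = ΔG_m(T) − ΔG(T) = R·T·|DC| holds
  as an exact identity.
- Energies are stored as printed magnitudes (positive); thermodynamic
  sign is applied at conversion time.

## Known limitations

**Windowed-velocity depletion bias.** With the default rate constants the
lowest substrate points (0.09375–0.375 mM) lose 20–45% of their substrate
within the 480 s window, so the OLS slope under-reads the true initial
velocity most strongly at low S and Km̂ is biased upward — by ~18–30%
per temperature even at zero noise, a median relative error near 0.20
across the default grid (the recovery tests and the acceptance script's
`synthetic_median_km_rel_error` compute this figure). The bias is
temperature-dependent, so it also tilts the fitted ΔH by 2–3 kJ/mol and
shifts DC by ~0.2 in a way the residual-scatter standard error does not
capture. It is a property of the estimator, not of the optimizer:
the same fit recovers exact rates to better than 10⁻⁹. Shortening the
window or raising the lowest substrate concentrations reduces the bias
at the cost of noise sensitivity; both are configurable.

**Best-pose extreme-value shift.** Selecting the maximal energy among
~10² noisy poses inflates the best-pose energy by roughly 2.8 standard
deviations of the pose noise, and the docking signature inherits that
shift. With real docking engines the best-pose score is the estimator of
interest, so this matters mainly when interpreting recovery tests against
the generator line; the averaging mode (`mean_pose_energy_per_temperature`)
avoids it.

**Tabulated inconsistencies are reported, not reconciled.** Dissociation
constants tabulated alongside binding energies in this system's
literature are consistent with Kd = exp(−E/RT) at 25 °C but not at the
higher temperatures, and no single [E] reproduces the per-temperature
ΔG values tabulated with the Km means via −RT·ln([E]/Km). The package
always reports its own computed conversions.
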