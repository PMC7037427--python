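# dopatherm

Temperature-dependent analysis of tyrosinase diphenol-oxidase kinetics:
from dopachrome absorbance progress curves to an apparent thermodynamic
signature of L-DOPA binding, with docking-derived affinities and the
dopachrome-offset (DC) model tying the two together.

## The problem

Tyrosinase oxidizes L-DOPA to dopaquinone, which cyclizes to dopachrome —
an orange product read at 475 nm on a plate reader. Measuring
Michaelis-Menten constants at several temperatures turns an ordinary
activity assay into a thermodynamic probe: under the rapid-equilibrium
assumption (k₂ ≪ k₋₁, so Km ≈ Kd), the temperature dependence of the
association constant follows the van 't Hoff relation

    ln(K/[E]) = (−ΔH/R)·(1/T) + ΔS/R

whose slope and intercept give the apparent enthalpy and entropy of
substrate association. Docking outputs at the same temperatures provide an
independent association line via the Boltzmann conversion
Kd = exp(−E/RT). On a shared van 't Hoff plot the two descriptions differ
by a vertical offset — the dopachrome effect DC:

    ln K_kinetics(1/T) = ln K_docking(1/T) + DC,     ΔG_dc = R·T·|DC|

quantifying the free-energy penalty separating apparent binding read out
at the dopachrome step from the direct association step.

The package is for enzymologists and structural-bioinformatics users who
have plate-reader kinetic tables, tabulated docking results (the package
never runs a docking engine), and optionally ITC-derived rate tables. A
synthetic-data generator with known ground truth stands in for all three
inputs, so the entire pipeline is testable without any external data.

## What it does

- `synthetic` — progress curves from Michaelis-Menten substrate depletion
  (fixed-step RK4) with Beer-Lambert absorbance and Gaussian plate noise;
  docking-energy tables scattered about a van 't Hoff line with decoy
  poses; minimal PDB pose fixtures; UV/ITC rate pairs.
- `kinetics` — Beer-Lambert conversion, blank subtraction, windowed
  initial velocities (first 8 min), `MichaelisMenten` model →
  `MichaelisMentenResults` (Km, Vmax, SEs, adjusted R², `summary()`),
  replicate aggregation, and the UV↔ITC proportional-ratio fit.
- `vanthoff` — `VantHoff` model → `ThermoSignature` (ΔH, ΔS, SEs,
  Pearson r, adjusted R²) and ΔG(T) = ΔH − TΔS.
- `docking` — TSV/PDB ingestion, "correctly docked" classification by
  ligand-oxygen-to-copper distance, best-pose selection, energy ↔ Kd
  conversion, docking van 't Hoff points.
- `dcshift` — `DCShift` model → `DCShiftResult` (DC, se, ΔG_dc(T) and the
  ΔG_m/ΔG decomposition).
- `pipeline`/`cli` — the end-to-end `dopatherm` command with JSON outputs
  and a provenance record.

## Worked example

Simulate a full input bundle and run the pipeline:

```sh
dopatherm --seed 7 --out-dir demo simulate --n-runs 200 --decoy-fraction 0.3
dopatherm --seed 7 --out-dir demo/results run \
    --plate demo/plate.csv --docking-table demo/docking.tsv \
    --receptor demo/poses.pdb
```

`demo/results/summary.txt` then reads (abridged):

```
Michaelis-Menten kinetics (per-temperature means ± SEM)
  T (°C)          Km (mM)      Vmax (mM/min)   adj R²   n
    25.0    0.490 ± 0.001    0.0296 ± 0.0000    0.999   3
    31.0    0.612 ± 0.001    0.0326 ± 0.0000    0.999   3
    37.0    0.828 ± 0.003    0.0388 ± 0.0000    1.000   3
    43.0    0.811 ± 0.001    0.0589 ± 0.0000    0.999   3

Apparent thermodynamic signature (association convention)
  Michaelis-Menten:      ΔH =   -23.77 ±  5.99 kJ/mol   ΔS = -0.1258 ± 0.0195 kJ/(K·mol)   r =  0.942   adj R² =  0.831

Best-pose binding energies and affinities
   25.0 °C: E =  28.50 kJ/mol, Kd = 0.01017 mM
```

Reading the numbers: Km rises with temperature (weaker apparent binding
when warm), which is exactly what a negative association enthalpy means —
the fitted ΔH ≈ −24 kJ/mol says binding is enthalpy-driven. The recovered
Km values sit 15–30% above the generator's ground truth (0.41–0.70 mM):
initial velocities fitted over the first eight minutes systematically
under-read the true initial slope because the lowest substrate
concentrations are substantially depleted within the window. This is a
property of the windowed-velocity estimator itself, quantified in
`docs/methods.md`. The entropy intercept (and hence DC) depends on the
enzyme-concentration normalization `enzyme_conc_M`; ΔH does not.

Library use follows the same objects:

```python
from dopatherm import MichaelisMenten, binding_energy_to_kd

res = MichaelisMenten([0.09375, 0.375, 1.5, 6.0],
                      [0.0045, 0.0133, 0.0259, 0.0340], temperature_C=37.0).fit()
print(res.summary())                       # Km, Vmax with standard errors
print(binding_energy_to_kd(25.71, 298.15).kd_mM)  # 0.0313 mM
```

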