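"""Physical constants and assay defaults shared across the package."""

#: Gas constant, J/(K·mol).
R_GAS = 8.314

#: Celsius → Kelvin offset.
KELVIN_OFFSET = 273.15

#: "Room temperature" used for single-temperature free-energy summaries, K.
ROOM_TEMPERATURE_K = 298.15

#: Molar absorptivity of dopachrome at 475 nm, M⁻¹ cm⁻¹.
EPSILON_DOPACHROME_M_CM = 3700.0

#: Optical path length of the plate well, cm.
DEFAULT_PATH_CM = 0.3

#: Assay temperatures, °C.
DEFAULT_TEMPERATURES_C = (25.0, 31.0, 37.0, 43.0)

#: L-DOPA doubling series for plate kinetics, mM (lowest point 0.09375 mM,
#: i.e. an exact twofold dilution ladder down from 6 mM).
DEFAULT_SUBSTRATE_SERIES_MM = (0.09375, 0.1875, 0.375, 0.75, 1.5, 3.0, 6.0)

#: ITC-tandem UV substrate points, µM (the plate series divided by ten,
#: quoted to three figures by the instrument software).
DEFAULT_ITC_SUBSTRATE_UM = (10.9, 21.9, 43.8, 87.5, 175.0, 350.0)

#: Initial-velocity analysis window, s (first eight minutes of reaction).
DEFAULT_WINDOW_S = 480.0

#: Default enzyme concentration for association-constant normalization, M.
#: Matches 0.1 mg/mL of the ~52 kDa truncated tyrosinase used in ITC; the
#: plate-assay concentration is not independently known. Only the entropy
#: intercept of the van 't Hoff fit depends on this choice.
DEFAULT_ENZYME_CONC_M = 2.0e-6

#: Ligand-oxygen-to-copper distance cutoff for "correctly docked" poses, Å.
DEFAULT_POSE_CUTOFF_A = 6.0


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + KELVIN_OFFSET
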