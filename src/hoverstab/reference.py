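"""Reference multilinear-regression coefficients for hovering energetics.

Two fitted models relate seven morphological predictors to the metabolic
cost of hovering in near-neutrally buoyant fishes:

* ``MO2NET_COEFFS`` — response is MO2net = MO2hover - MO2rest
  (mg O2 kg^-1 h^-1, mass-corrected with allometric exponent 0.9).
* ``RATIO_COEFFS`` — response is the dimensionless ratio MO2hover/MO2rest.

Predictor conventions (see :mod:`hoverstab.morphometry`):

* ``mass`` — body mass in kg.
* ``fineness_depth`` — total length / maximum body depth (TL/MBD).
* ``comcob_ap`` — COM-COB offset along the anterior-posterior axis as a
  signed proportion of body length.
* ``comcob_dv`` — COM-COB offset along the dorsal-ventral axis as a signed
  proportion of body depth, dorsal-most point as origin, so a COB lying
  ventral of the COM gives a negative value.
* ``fineness_width`` — total length / maximum body width (TL/MBW).
* ``pect_fin_ap``, ``caud_fin_ap`` — fin positions along the
  anterior-posterior axis as proportions of body length.

These vectors serve both as the generative ground truth for the synthetic
species generator and as the packaged reference against which refits are
compared.
"""

from __future__ import annotations

PREDICTORS: tuple[str, ...] = (
    "mass",
    "fineness_depth",
    "comcob_ap",
    "comcob_dv",
    "fineness_width",
    "pect_fin_ap",
    "caud_fin_ap",
)

#: Full seven-predictor model for MO2net (mg O2 kg^-1 h^-1).
MO2NET_COEFFS: dict[str, float] = {
    "intercept": 1501.05,
    "mass": -440.24,
    "fineness_depth": 201.28,
    "comcob_ap": -114.18,
    "comcob_dv": -116.80,
    "fineness_width": 194.16,
    "pect_fin_ap": -1297.36,
    "caud_fin_ap": -1297.60,
}

#: Full seven-predictor model for the ratio MO2hover/MO2rest (dimensionless).
RATIO_COEFFS: dict[str, float] = {
    "intercept": 9.35,
    "mass": -2.91,
    "fineness_depth": 0.63,
    "comcob_ap": -0.34,
    "comcob_dv": -0.80,
    "fineness_width": 0.21,
    "pect_fin_ap": -3.94,
    "caud_fin_ap": -6.97,
}

#: Default sampling ranges (low, high) for the synthetic species generator.
#: Chosen to be anatomically plausible for small laboratory fishes: masses of
#: a few grams to ~50 g, moderately elongate bodies, COB ventral of COM in
#: most draws, pectoral fins in the anterior third and the caudal-fin tip
#: slightly beyond the snout-peduncle span.
DEFAULT_PREDICTOR_RANGES: dict[str, tuple[float, float]] = {
    "mass": (0.002, 0.05),
    "fineness_depth": (2.0, 5.0),
    "comcob_ap": (-0.06, 0.06),
    "comcob_dv": (-0.18, -0.02),
    "fineness_width": (2.5, 6.0),
    "pect_fin_ap": (0.20, 0.45),
    "caud_fin_ap": (1.00, 1.20),
}

#: Oxy-calorific equivalent: energy released per mg O2 consumed (cal/mg O2).
OXYCALORIFIC_CAL_PER_MG_O2 = 3.25

#: Thermodynamic calorie in joules.
JOULES_PER_CAL = 4.184

#: Allometric mass-scaling exponent applied when normalising MO2 by mass.
MASS_SCALING_EXPONENT = 0.9
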