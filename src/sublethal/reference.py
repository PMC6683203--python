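"""Published posterior summaries for the two-generation deltamethrin experiment.

These are the reported posterior means, standard deviations and 95% credible
bounds from the original Colorado potato beetle study this package models
(gen-1 n = 245 second-instar larvae split between water control and a
sublethal 1.59 mg/l deltamethrin exposure; 14 control sires x 4 dams = 56
split-brood families; gen-2 n = 842 re-randomised offspring).  They serve two
roles:

* as the default "true" parameter values of the synthetic-cohort generator,
  so that inference can be tested by parameter recovery under realistic
  effect sizes; and
* as inputs for the deterministic derived quantities reported alongside the
  fits (survival odds ratios and their interval endpoints).

Residual scales (sigma) and beta precisions (phi) were not reported; the
defaults below are the generator's own choices (see docs/methods.md).
Entries reported only as "<0.001" are stored as 0.0.
"""

from __future__ import annotations

import pandas as pd

from .blocks import BLOCKS, ParameterSet, param_name

# block -> [(term, mean, sd, lo2.5, hi97.5), ...] in published row order
REFERENCE_TABLE: dict[str, list[tuple[str, float, float, float, float]]] = {
    # (a) survival, first generation (mortality-logit scale, death = 1)
    "g1_surv_24h": [
        ("intercept", -1.06, 1.972, -4.689, 2.979),
        ("within", 0.42, 0.696, -0.896, 1.807),
        ("larval_mass", -0.73, 0.584, -1.980, 0.278),
    ],
    "g1_surv_larval": [
        ("intercept", -0.96, 0.211, -1.382, -0.555),
        ("within", 0.07, 0.292, -0.502, 0.641),
    ],
    "g1_surv_pupal": [
        ("intercept", -1.62, 0.298, -2.231, -1.057),
        ("within", -0.03, 0.419, -0.861, 0.791),
    ],
    "g1_surv_adult": [
        ("intercept", -1.95, 0.371, -2.722, -1.271),
        ("within", -1.35, 0.741, -2.890, 0.024),
    ],
    # (b) development time and body mass, first generation
    "g1_devtime": [
        ("intercept", 3.38, 0.006, 3.369, 3.393),
        ("within", -0.002, 0.007, -0.015, 0.012),
        ("male", -0.02, 0.007, -0.032, -0.005),
    ],
    "g1_mass_emergence": [
        ("intercept", 122.77, 1.906, 119.075, 126.568),
        ("within", -0.39, 2.205, -4.660, 3.953),
        ("male", -18.38, 2.258, -22.888, -13.963),
    ],
    "g1_mass_day10": [
        ("intercept", 164.93, 2.900, 159.289, 170.493),
        ("within", 7.00, 3.388, 0.364, 13.690),
        ("male", -31.83, 3.401, -38.483, -25.129),
    ],
    # (c) survival, second generation
    "g2_surv_24h": [
        ("intercept", -6.66, 1.762, -10.203, -3.222),
        ("within", 2.06, 0.874, 0.582, 4.011),
        ("trans", 1.02, 0.947, -0.680, 3.057),
        ("maternal_mass", 0.01, 0.009, -0.007, 0.027),
        ("within_x_trans", -1.70, 1.073, -3.954, 0.291),
    ],
    "g2_surv_larval": [
        ("intercept", 0.51, 0.596, -0.670, 1.689),
        ("within", 0.29, 0.199, -0.096, 0.682),
        ("trans", -0.56, 0.210, -0.975, -0.152),
        ("maternal_mass", -0.004, 0.003, -0.010, 0.003),
        ("within_x_trans", -0.32, 0.293, -0.898, 0.259),
    ],
    "g2_surv_pupal": [
        ("intercept", 0.52, 0.589, -0.641, 1.668),
        ("within", 0.18, 0.196, -0.201, 0.565),
        ("trans", -0.58, 0.207, -0.986, -0.175),
        ("maternal_mass", -0.004, 0.003, -0.010, 0.003),
        ("within_x_trans", -0.22, 0.290, -0.799, 0.336),
    ],
    "g2_surv_adult": [
        ("intercept", -7.26, 4.126, -15.692, 0.522),
        ("within", 1.00, 0.971, -0.774, 3.083),
        ("trans", -1.48, 1.043, -3.792, 0.398),
        ("maternal_mass", 0.02, 0.023, -0.027, 0.061),
    ],
    # (d) development time and body mass, second generation
    "g2_devtime": [
        ("intercept", 3.37, 0.025, 3.317, 3.413),
        ("within", 0.0, 0.009, -0.019, 0.018),
        ("male", -0.03, 0.009, -0.045, -0.008),
        ("male_x_trans", 0.04, 0.013, 0.012, 0.061),
        ("trans", -0.02, 0.011, -0.042, 0.0),
        ("within_x_trans", -0.005, 0.013, -0.030, 0.019),
        ("maternal_mass", 0.0, 0.0, 0.0, 0.0),
    ],
    "g2_mass_emergence": [
        ("intercept", 107.83, 4.973, 98.018, 117.455),
        ("within", 1.35, 1.922, -2.373, 5.135),
        ("male", -12.16, 1.907, -15.885, -8.429),
        ("male_x_trans", -2.76, 2.512, -7.738, 2.145),
        ("trans", 4.85, 2.167, 0.625, 9.109),
        ("within_x_trans", -1.99, 2.525, -6.845, 2.983),
        ("maternal_mass", 0.03, 0.027, -0.021, 0.084),
    ],
    "g2_mass_day7": [
        ("intercept", 176.37, 8.760, 159.017, 193.616),
        ("within", 3.02, 3.355, -3.543, 9.624),
        ("male", -28.31, 3.351, -34.988, -21.657),
        ("male_x_trans", -7.98, 4.448, -16.644, 0.829),
        ("trans", 7.36, 3.763, -0.002, 14.525),
        ("within_x_trans", -1.10, 4.434, -9.815, 7.519),
        ("maternal_mass", 0.01, 0.047, -0.083, 0.102),
    ],
    "g2_mass_day14": [
        ("intercept", 142.12, 6.435, 129.316, 154.637),
        ("within", -0.37, 2.471, -5.260, 4.602),
        ("male", -15.55, 2.478, -20.440, -10.663),
        ("male_x_trans", -3.21, 3.301, -9.737, 3.357),
        ("trans", 4.06, 2.806, -1.499, 9.458),
        ("within_x_trans", 0.91, 3.258, -5.293, 7.389),
        ("maternal_mass", 0.03, 0.035, -0.042, 0.094),
    ],
    # (e) composition fractions, second generation (logit-mean scale)
    "g2_lipid": [
        ("intercept", -1.42, 0.119, -1.650, -1.187),
        ("within", -0.03, 0.046, -0.118, 0.062),
        ("male", 0.06, 0.030, 0.004, 0.122),
        ("trans", -0.04, 0.042, -0.118, 0.047),
        ("within_x_trans", 0.06, 0.060, -0.054, 0.181),
        ("maternal_mass", 0.0, 0.001, -0.001, 0.002),
    ],
    "g2_water": [
        ("intercept", 0.07, 0.073, -0.070, 0.213),
        ("within", 0.006, 0.028, -0.050, 0.062),
        ("male", -0.02, 0.019, -0.057, 0.016),
        ("trans", 0.003, 0.026, -0.049, 0.054),
        ("within_x_trans", -0.02, 0.038, -0.090, 0.058),
        ("maternal_mass", 0.0, 0.0, -0.001, 0.0),
    ],
    "g2_drymass": [
        ("intercept", -0.89, 0.038, -0.963, -0.815),
        ("within", 0.01, 0.014, -0.017, 0.040),
        ("male", -0.02, 0.009, -0.041, -0.004),
        ("trans", 0.005, 0.013, -0.021, 0.030),
        ("within_x_trans", -0.01, 0.019, -0.047, 0.028),
        ("maternal_mass", 0.0, 0.0, 0.0, 0.0),
    ],
}

#: Generator defaults for the unreported nuisance scales:
#: residual SD of log development time (log-days), residual SDs of body masses
#: (mg) and beta precisions of the composition fractions.
DEFAULT_SCALES: dict[str, float] = {
    "g1_devtime": 0.08,
    "g1_mass_emergence": 12.0,
    "g1_mass_day10": 18.0,
    "g2_devtime": 0.08,
    "g2_mass_emergence": 12.0,
    "g2_mass_day7": 18.0,
    "g2_mass_day14": 18.0,
    "g2_lipid": 100.0,
    "g2_water": 100.0,
    "g2_drymass": 100.0,
}


def reference_frame() -> pd.DataFrame:
    """Published summaries as a tidy frame (parameter, block, term, mean, sd, lo, hi)."""
    rows = []
    for block, entries in REFERENCE_TABLE.items():
        for term, mean, sd, lo, hi in entries:
            rows.append({"parameter": param_name(block, term), "block": block,
                         "term": term, "mean": mean, "sd": sd, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def reference_parameters(scales: dict[str, float] | None = None) -> ParameterSet:
    """Published posterior means as a complete :class:`ParameterSet`.

    Parameters
    ----------
    scales
        Optional overrides for the unreported nuisance scales, keyed by block
        name; merged over :data:`DEFAULT_SCALES`.
    """
    sc = dict(DEFAULT_SCALES)
    if scales:
        sc.update(scales)
    blocks: dict[str, dict[str, float]] = {}
    for name, entries in REFERENCE_TABLE.items():
        blocks[name] = {term: mean for term, mean, *_ in entries}
        st = BLOCKS[name].scale_term
        if st is not None:
            blocks[name][st] = sc[name]
    params = ParameterSet(blocks)
    params.validate(list(BLOCKS))
    return params


def reference_intervals() -> dict[str, tuple[float, float]]:
    """Published 95% credible bounds keyed by flat parameter name."""
    out = {}
    for block, entries in REFERENCE_TABLE.items():
        for term, _mean, _sd, lo, hi in entries:
            out[param_name(block, term)] = (lo, hi)
    return out
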