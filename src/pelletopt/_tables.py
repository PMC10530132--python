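"""Embedded reference data for the published screening/optimization study.

These are the printed factor settings and per-trial results that the
package's analyses are validated against: the ten-factor two-level
screening layout with triplicate dry-cell-weight (DCW) outcomes, and the
four-factor L9 optimization layout with per-trial biomass and
signal-to-noise values.  Access them through
:func:`pelletopt.synthetic.load_fixture`.
"""

from __future__ import annotations

from .designs import FactorSpec, l9_matrix, pb12_matrix

# Two-level screening factors; first level value is the +1 setting.
# Units are per 100 mL of medium.
PB_FACTORS = [
    FactorSpec("X1", "Lignin", (1.0, 0.0), "mL"),
    FactorSpec("X2", "Inoculation", (2.0, 1.0), "pieces"),
    FactorSpec("X3", "Yeast extract", (0.5, 0.25), "g"),
    FactorSpec("X4", "CaCO3", (0.5, 0.0), "g"),
    FactorSpec("X5", "Olive oil", (2.0, 0.0), "mL"),
    FactorSpec("X6", "Yolk powder", (0.5, 0.25), "g"),
    FactorSpec("X7", "Soy powder", (0.5, 0.25), "g"),
    FactorSpec("X8", "Tween 80", (1.0, 0.0), "mL"),
    FactorSpec("X9", "KH2PO4", (2.0, 1.0), "g"),
    FactorSpec("X10", "Mung bean powder", (0.5, 0.0), "g"),
]

PB_DUMMY = "X11"

# Three-level optimization factors (levels 1, 2, 3), per 100 mL.
L9_FACTORS = [
    FactorSpec("A", "Olive oil", (0.0, 2.0, 4.0), "mL"),
    FactorSpec("B", "CaCO3", (0.0, 0.25, 0.5), "g"),
    FactorSpec("C", "Yeast extract", (0.25, 0.50, 0.75), "g"),
    FactorSpec("D", "Soy powder", (0.00, 0.25, 0.50), "g"),
]

# Screening outcomes: per-trial DCW mean +- SD (g/dL), triplicate cultures.
PB_DCW_MEANS = [
    0.50, 2.35, 1.64, 2.25, 2.48, 2.81, 1.19, 4.12, 3.73, 0.58, 1.77, 0.94,
]
PB_DCW_SDS = [
    0.23, 0.07, 0.91, 0.19, 0.31, 0.18, 1.01, 0.30, 1.28, 0.30, 0.38, 0.19,
]

# Published per-column statistics (computed from unrounded replicate data,
# printed to 2-3 decimals); keyed X1..X11.
PB_PRINTED_EFFECTS = {
    "X1": -0.401, "X2": 0.021, "X3": 0.111, "X4": 1.313, "X5": 1.06,
    "X6": 0.049, "X7": -0.514, "X8": 1.031, "X9": -0.729, "X10": 0.176,
    "X11": 0.062,
}
PB_PRINTED_SS = {
    "X1": 0.483, "X2": 0.001, "X3": 0.037, "X4": 5.173, "X5": 3.37,
    "X6": 0.007, "X7": 0.791, "X8": 3.19, "X9": 1.593, "X10": 0.093,
    "X11": 0.012,
}
PB_PRINTED_F = {
    "X1": 41.95, "X2": 0.11, "X3": 3.2, "X4": 449.6, "X5": 292.9,
    "X6": 0.63, "X7": 68.78, "X8": 277.3, "X9": 138.5, "X10": 8.11,
    "X11": 1.0,
}
PB_PRINTED_P = {
    "X1": 0.098, "X2": 0.793, "X3": 0.325, "X4": 0.030, "X5": 0.037,
    "X6": 0.573, "X7": 0.076, "X8": 0.038, "X9": 0.054, "X10": 0.215,
    "X11": 0.5,
}
PB_SIGNIFICANT = {"X4", "X5", "X8"}

# Optimization outcomes: per-trial biomass mean +- SD (g/dL) and the
# published per-trial larger-the-better S/N (dB), trials L1..L9.
L9_BIOMASS_MEANS = [0.65, 1.36, 1.71, 1.61, 2.11, 1.66, 1.27, 1.52, 1.81]
L9_BIOMASS_SDS = [0.16, 0.09, 0.22, 0.28, 0.37, 0.14, 0.21, 0.31, 0.29]
L9_SN = [-4.52, 2.61, 4.47, 3.75, 6.03, 4.29, 1.68, 3.03, 4.78]

# Published factor-level mean S/N (rows: level 1..3; columns A..D).
L9_PRINTED_LEVEL_MEANS = {
    "A": (0.85, 4.69, 3.16),
    "B": (0.30, 3.89, 4.51),
    "C": (0.93, 3.71, 4.06),
    "D": (2.10, 2.86, 3.75),
}
L9_PRINTED_SS = {"A": 22.38, "B": 30.97, "C": 17.63, "D": 4.09}
L9_PRINTED_CONTRIBUTIONS = {"A": 30, "B": 41, "C": 23, "D": 5}
L9_PRINTED_SST = 75.06
L9_OPTIMUM = "A2B3C3D3"

# Confirmation cultures under the basal and the optimized formulation.
CONFIRMATION_BASELINE_MEAN = 0.92   # g/dL
CONFIRMATION_BASELINE_SD = 0.15
CONFIRMATION_OPTIMIZED_MEAN = 1.99  # g/dL
CONFIRMATION_OPTIMIZED_SD = 0.11


def fixture(table_id: str) -> dict:
    """Assemble the named fixture; see ``synthetic.load_fixture``."""
    key = table_id.strip().lower().replace(" ", "")
    if key in ("table1", "pb_factors"):
        return {"factors": list(PB_FACTORS), "dummy": PB_DUMMY}
    if key in ("table2", "l9_factors"):
        return {"factors": list(L9_FACTORS)}
    if key in ("table3", "pb_screen"):
        return {
            "design": pb12_matrix(),
            "factors": list(PB_FACTORS),
            "dummy": PB_DUMMY,
            "means": list(PB_DCW_MEANS),
            "sds": list(PB_DCW_SDS),
            "printed_effects": dict(PB_PRINTED_EFFECTS),
            "printed_ss": dict(PB_PRINTED_SS),
            "printed_f": dict(PB_PRINTED_F),
            "printed_p": dict(PB_PRINTED_P),
            "significant": set(PB_SIGNIFICANT),
        }
    if key in ("table4", "l9_results"):
        return {
            "design": l9_matrix(),
            "factors": list(L9_FACTORS),
            "means": list(L9_BIOMASS_MEANS),
            "sds": list(L9_BIOMASS_SDS),
            "sn": list(L9_SN),
            "printed_level_means": dict(L9_PRINTED_LEVEL_MEANS),
            "printed_ss": dict(L9_PRINTED_SS),
            "printed_contributions": dict(L9_PRINTED_CONTRIBUTIONS),
            "printed_sst": L9_PRINTED_SST,
            "optimum": L9_OPTIMUM,
        }
    raise KeyError(f"unknown fixture id {table_id!r}")
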