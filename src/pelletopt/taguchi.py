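"""Taguchi larger-the-better signal-to-noise analysis on the L9 array.

The quality characteristic here is biomass yield, so the
larger-the-better signal-to-noise (S/N) ratio is used:

    S/N = -10 * log10( (1/n) * sum_i 1 / y_i**2 )   [dB]

For n identical replicates y this reduces to 20*log10(y).  Factor-level
mean S/N values, the optimum level combination (arg-max per factor),
factor sums of squares and contribution ratios, and the additive-model
prediction at an arbitrary combination are all computed from the
per-trial S/N values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import DesignMatrix, validate_oa3

__all__ = [
    "TaguchiError",
    "sn_larger_better",
    "sn_from_mean",
    "SNTable",
    "sn_level_table",
    "pick_optimum",
    "parse_combination",
    "TaguchiAnova",
    "taguchi_anova",
    "predict_additive_sn",
    "ConfirmationSummary",
    "confirmation_summary",
]


class TaguchiError(ValueError):
    """Raised for invalid responses or undefined S/N statistics."""


def sn_larger_better(replicates) -> float:
    """Larger-the-better S/N ratio in dB.

    All replicate values must be strictly positive (the statistic
    diverges at zero).
    """
    y = np.asarray(replicates, dtype=float)
    if y.size == 0:
        raise TaguchiError("at least one replicate required")
    if (y <= 0).any():
        raise TaguchiError("larger-the-better S/N needs strictly positive values")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def sn_from_mean(mean: float) -> float:
    """Identical-replicate approximation ``20*log10(mean)``.

    Used when only a per-trial mean is available; ignores replicate
    spread, so it is labelled approximate in reports.
    """
    if mean <= 0:
        raise TaguchiError("mean must be strictly positive")
    return float(20.0 * np.log10(mean))


@dataclass(frozen=True)
class SNTable:
    """Factor-level mean S/N values for an L9 analysis.

    ``level_means`` is a factors x levels DataFrame (index = factor
    symbols in design order, columns = levels 1..3); ``grand_mean`` is the
    mean S/N over all nine trials; ``sn`` holds the per-trial values the
    table was built from, in trial order.
    """

    level_means: pd.DataFrame
    grand_mean: float
    sn: tuple[float, ...]


def sn_level_table(design: DesignMatrix, sn) -> SNTable:
    """Mean S/N of the trials run at each level of each factor."""
    validate_oa3(design)
    values = np.asarray(sn, dtype=float)
    if values.shape != (design.n_trials,):
        raise TaguchiError(
            f"{design.n_trials} per-trial S/N values required, got "
            f"shape {values.shape}"
        )
    means = pd.DataFrame(
        index=pd.Index(design.symbols, name="factor"),
        columns=pd.Index([1, 2, 3], name="level"),
        dtype=float,
    )
    for sym in design.symbols:
        col = design.column(sym)
        for level in (1, 2, 3):
            means.loc[sym, level] = values[col == level].mean()
    return SNTable(
        level_means=means,
        grand_mean=float(values.mean()),
        sn=tuple(float(v) for v in values),
    )


def pick_optimum(table: SNTable) -> str:
    """Per-factor arg-max level, concatenated into a combination label.

    Ties break to the lowest level index.  With symbols A..D and optimum
    levels (2, 3, 3, 3) the label is ``"A2B3C3D3"``.
    """
    parts = []
    for sym in table.level_means.index:
        row = table.level_means.loc[sym]
        level = int(row.idxmax())  # first (lowest) level wins exact ties
        parts.append(f"{sym}{level}")
    return "".join(parts)


def parse_combination(label: str, symbols) -> dict[str, int]:
    """Parse ``"A2B3C3D3"``-style labels into a symbol -> level mapping."""
    found = dict(re.findall(r"([A-Za-z]+?)(\d)", label))
    out = {}
    for sym in symbols:
        if sym not in found:
            raise TaguchiError(f"combination {label!r} is missing factor {sym}")
        out[sym] = int(found[sym])
    return out


@dataclass(frozen=True)
class TaguchiAnova:
    """Factor sums of squares, total SS, and contribution percentages."""

    ss: pd.Series
    sst: float
    contributions: pd.Series  # percent, summing to 100 before rounding


def taguchi_anova(table: SNTable) -> TaguchiAnova:
    """Decompose S/N variation into per-factor sums of squares.

    ``SS_i = r * sum_levels (levelMean - grandMean)**2`` with r trials per
    level (3 for the L9), and ``SST = sum_trials (S/N_t - grandMean)**2``.
    Contribution_i = SS_i / SST * 100.  For the saturated L9 the factor
    SS sum to SST exactly (up to floating point) when computed from the
    same unrounded S/N values; SST is nevertheless computed from the
    trial deviations, so contributions of rounded inputs stay faithful to
    that definition.
    """
    sn = np.asarray(table.sn, dtype=float)
    g = table.grand_mean
    r = len(sn) // table.level_means.shape[1]
    ss = ((table.level_means - g) ** 2).sum(axis=1) * r
    ss.name = "SS"
    sst = float(((sn - g) ** 2).sum())
    if sst == 0.0:
        raise TaguchiError("total S/N variation is zero: contributions undefined")
    contributions = ss / sst * 100.0
    contributions.name = "contribution_pct"
    return TaguchiAnova(ss=ss, sst=sst, contributions=contributions)


def predict_additive_sn(table: SNTable, combination) -> float:
    """Additive-model S/N prediction at a level combination.

    ``grandMean + sum_factors (selectedLevelMean - grandMean)``; the
    combination may be a label string or a symbol -> level mapping and may
    use any levels, not only the arg-max ones.
    """
    if isinstance(combination, str):
        combination = parse_combination(combination, table.level_means.index)
    pred = table.grand_mean
    for sym, level in combination.items():
        if sym not in table.level_means.index:
            raise TaguchiError(f"unknown factor {sym!r}")
        if level not in table.level_means.columns:
            raise TaguchiError(f"factor {sym}: invalid level {level}")
        pred += float(table.level_means.loc[sym, level]) - table.grand_mean
    return float(pred)


@dataclass(frozen=True)
class ConfirmationSummary:
    """Comparison of baseline vs optimized confirmation cultures."""

    baseline_mean: float
    optimized_mean: float
    fold_change: float
    baseline_sn: float
    optimized_sn: float
    delta_sn: float


def confirmation_summary(baseline, optimized) -> ConfirmationSummary:
    """Fold change and S/N gain of the optimized over the baseline medium."""
    b = np.asarray(baseline, dtype=float)
    o = np.asarray(optimized, dtype=float)
    if b.size == 0 or o.size == 0:
        raise TaguchiError("both replicate sets must be non-empty")
    if b.mean() == 0.0:
        raise TaguchiError("baseline mean is zero: fold change undefined")
    b_sn = sn_larger_better(b)
    o_sn = sn_larger_better(o)
    return ConfirmationSummary(
        baseline_mean=float(b.mean()),
        optimized_mean=float(o.mean()),
        fold_change=float(o.mean() / b.mean()),
        baseline_sn=b_sn,
        optimized_sn=o_sn,
        delta_sn=o_sn - b_sn,
    )
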