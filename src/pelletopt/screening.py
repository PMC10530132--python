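"""Plackett-Burman screening statistics.

Main effects are estimated on per-trial *means* (replicates are collapsed
first): for each column the effect is the mean response of the trials at
the high (+1) level minus the mean at the low (-1) level.  Because the
12-run design is saturated, no residual degrees of freedom remain, so the
error variance is estimated from the unassigned ("dummy") column: each
factor's mean square is tested against the dummy's mean square with a
one-tailed F test on (1, 1) degrees of freedom.

With a single dummy column the error estimate has one degree of freedom
and the F(1, 1) critical value at alpha = 0.05 is about 161, so only very
large effects are declared significant -- the intended behaviour of a
screening stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix, validate_pb

__all__ = [
    "ScreeningError",
    "ResponseSet",
    "trial_means",
    "factor_effects",
    "anova_vs_dummy",
    "critical_f",
    "flag_significant",
    "effect_shares",
    "run_screening",
    "ScreeningReport",
]


class ScreeningError(ValueError):
    """Raised for invalid responses or undefined screening statistics."""


@dataclass(frozen=True)
class ResponseSet:
    """Per-trial replicate responses (biomass, g/dL).

    ``replicates`` holds one tuple of values per trial; trials may have
    different replicate counts but never zero.  Means and standard
    deviations are always recomputed from the replicate values.
    """

    trials: tuple[str, ...]
    replicates: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(str(t) for t in self.trials))
        reps = tuple(tuple(float(v) for v in r) for r in self.replicates)
        object.__setattr__(self, "replicates", reps)
        if len(self.trials) != len(reps):
            raise ScreeningError("one replicate list per trial required")
        if len(set(self.trials)) != len(self.trials):
            raise ScreeningError("trial labels must be unique")
        for t, r in zip(self.trials, reps):
            if len(r) == 0:
                raise ScreeningError(f"trial {t!r} has no replicates")
            if any(v < 0 for v in r):
                raise ScreeningError(f"trial {t!r} has a negative response")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def means(self) -> np.ndarray:
        return np.array([np.mean(r) for r in self.replicates])

    def sds(self) -> np.ndarray:
        """Sample SD (n-1 denominator); 0.0 for a single replicate."""
        return np.array(
            [np.std(r, ddof=1) if len(r) > 1 else 0.0 for r in self.replicates]
        )

    @classmethod
    def from_means(cls, trials, means) -> "ResponseSet":
        """Wrap per-trial means as single-replicate responses."""
        return cls(tuple(trials), tuple((float(m),) for m in means))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseSet":
        """Build from a table with a ``trial`` column and replicate columns.

        Any column whose name starts with ``replicate`` is treated as a
        replicate; missing entries (NaN) allow ragged replicate counts.
        """
        if "trial" not in df.columns:
            raise ScreeningError("responses table needs a 'trial' column")
        rep_cols = [c for c in df.columns if str(c).startswith("replicate")]
        if not rep_cols:
            raise ScreeningError("no replicate_* columns found")
        trials, reps = [], []
        for _, row in df.iterrows():
            vals = [row[c] for c in rep_cols if pd.notna(row[c])]
            trials.append(str(row["trial"]))
            reps.append(tuple(float(v) for v in vals))
        return cls(tuple(trials), tuple(reps))

    @classmethod
    def from_csv(cls, path) -> "ResponseSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        k = max(len(r) for r in self.replicates)
        data = {"trial": list(self.trials)}
        for j in range(k):
            data[f"replicate_{j + 1}"] = [
                r[j] if j < len(r) else np.nan for r in self.replicates
            ]
        return pd.DataFrame(data)


def trial_means(responses: ResponseSet) -> pd.DataFrame:
    """Per-trial mean and sample SD, indexed by trial label."""
    return pd.DataFrame(
        {"mean": responses.means(), "sd": responses.sds()},
        index=pd.Index(responses.trials, name="trial"),
    )


def factor_effects(design: DesignMatrix, means) -> pd.Series:
    """Main effect of every design column, dummy included.

    ``effect = mean(responses at +1) - mean(responses at -1)`` with the
    two groups of equal size (enforced by design validation).

    Parameters
    ----------
    design : DesignMatrix
        A validated two-level design (any matrix passing the balance and
        orthogonality checks, not only the canonical 12-run layout).
    means : array-like or ResponseSet
        Per-trial mean responses in design row order.
    """
    if isinstance(means, ResponseSet):
        means = means.means()
    y = np.asarray(means, dtype=float)
    if y.shape != (design.n_trials,):
        raise ScreeningError(
            f"{design.n_trials} trial means required, got shape {y.shape}"
        )
    validate_pb(design)  # guarantees equal-size +/- groups per column
    half = design.n_trials // 2
    effects = (design.codes.T @ y) / half
    return pd.Series(effects, index=list(design.symbols), name="effect")


def anova_vs_dummy(
    effects: pd.Series, n_trials: int, dummy_symbol: str = "X11",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dummy-referenced ANOVA for a saturated two-level screening design.

    Per column: ``SS = n * effect**2 / 4`` (n = number of trials), one
    degree of freedom each, ``MS = SS``, and ``F = MS / MS_dummy``.  The
    p-value is the one-tailed upper-tail F probability at (1, 1) df; the
    dummy column tests against itself, so its F is 1 and its p is 0.5.
    """
    if dummy_symbol not in effects.index:
        raise ScreeningError(f"dummy column {dummy_symbol!r} not in effects")
    ss = n_trials * effects.astype(float) ** 2 / 4.0
    ms = ss / 1.0
    ms_dummy = float(ms[dummy_symbol])
    if ms_dummy == 0.0:
        raise ScreeningError(
            "dummy mean square is exactly zero: the error variance is "
            "unmeasurable and significance is undefined"
        )
    f = ms / ms_dummy
    p = stats.f.sf(f, 1, 1)
    crit = critical_f(alpha, 1, 1)
    table = pd.DataFrame(
        {
            "effect": effects,
            "SS": ss,
            "df": 1,
            "MS": ms,
            "F": f,
            "p": p,
            "significant": (f > crit) & (effects.index != dummy_symbol),
        }
    )
    table.index.name = "factor"
    return table


def critical_f(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F distribution."""
    if not 0.0 < alpha < 1.0:
        raise ScreeningError(f"alpha must be in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ScreeningError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df1, df2))


def flag_significant(
    anova: pd.DataFrame, alpha: float = 0.05, dummy_symbol: str = "X11"
) -> set[str]:
    """Factors whose F exceeds the (1, 1) critical value; never the dummy."""
    crit = critical_f(alpha, 1, 1)
    hits = anova.index[(anova["F"] > crit) & (anova.index != dummy_symbol)]
    return set(hits)


def effect_shares(
    effects: pd.Series, dummy_symbol: str | None = "X11"
) -> pd.Series:
    """Percent share of each assigned factor in the total absolute effect.

    ``share_i = |effect_i| / sum_j |effect_j| * 100`` over the assigned
    (non-dummy) columns only; the dummy is excluded from both numerator
    and denominator.  Shares sum to 100 before rounding.
    """
    real = effects.drop(dummy_symbol) if dummy_symbol in effects.index else effects
    if len(real) == 0:
        raise ScreeningError("no assigned factors to share over")
    total = real.abs().sum()
    if total == 0.0:
        raise ScreeningError("all effects are zero: shares are undefined")
    shares = real.abs() / total * 100.0
    shares.name = "share_pct"
    return shares


@dataclass(frozen=True)
class ScreeningReport:
    """Full screening result: ANOVA table, significance calls, shares."""

    anova: pd.DataFrame
    significant: set[str]
    shares: pd.Series
    alpha: float
    critical_f: float


def run_screening(
    design: DesignMatrix,
    responses: ResponseSet,
    alpha: float = 0.05,
    dummy_symbol: str = "X11",
) -> ScreeningReport:
    """Effects -> dummy ANOVA -> significance -> shares, in one call."""
    if responses.n_trials != design.n_trials:
        raise ScreeningError(
            f"design has {design.n_trials} trials but responses have "
            f"{responses.n_trials}"
        )
    effects = factor_effects(design, responses.means())
    anova = anova_vs_dummy(effects, design.n_trials, dummy_symbol, alpha)
    return ScreeningReport(
        anova=anova,
        significant=flag_significant(anova, alpha, dummy_symbol),
        shares=effect_shares(effects, dummy_symbol),
        alpha=alpha,
        critical_f=critical_f(alpha, 1, 1),
    )
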