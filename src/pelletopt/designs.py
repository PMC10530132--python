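"""Construction and validation of screening and optimization designs.

Two designs are supported:

* the 12-run, 11-column two-level Plackett-Burman array (PB12), used to
  screen main effects of up to ten medium components plus at least one
  unassigned ("dummy") column that estimates experimental error, and
* the Taguchi L9(3^4) orthogonal array, used to tune the levels of the
  four components retained after screening.

Level coding conventions
------------------------
PB12 columns are coded ``+1`` / ``-1``; by convention the *first* entry of a
:class:`FactorSpec` level list is the ``+1`` ("level 1", high) setting and
the second entry is the ``-1`` setting.  L9 columns are coded ``1..3`` and
index directly into the three-entry level list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "FactorSpec",
    "DesignMatrix",
    "pb12_matrix",
    "pb12_cyclic",
    "l9_matrix",
    "apply_factor_levels",
    "infer_codes",
    "validate_pb",
    "validate_oa3",
]


class DesignError(ValueError):
    """Raised when a design matrix or factor specification is invalid."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its concrete level settings.

    Parameters
    ----------
    symbol : str
        Short identifier used in design matrices, e.g. ``"X4"`` or ``"B"``.
    name : str
        Human-readable name, e.g. ``"CaCO3"``.
    levels : tuple of float
        Concrete settings, per 100 mL of medium.  Two entries for a
        two-level (Plackett-Burman) factor, three for a three-level
        (orthogonal-array) factor.  For two-level factors the first entry
        is the ``+1`` setting.
    units : str
        Unit of the level values (``"g"`` or ``"mL"`` per 100 mL).
    """

    symbol: str
    name: str
    levels: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) not in (2, 3):
            raise DesignError(
                f"factor {self.symbol!r}: need 2 or 3 levels, got {len(levels)}"
            )
        if any(v < 0 for v in levels):
            raise DesignError(f"factor {self.symbol!r}: negative level value")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def value_for_code(self, code: int) -> float:
        """Concrete setting for an integer level code (+1/-1 or 1..3)."""
        if self.n_levels == 2:
            if code == 1:
                return self.levels[0]
            if code == -1:
                return self.levels[1]
        else:
            if 1 <= code <= 3:
                return self.levels[code - 1]
        raise DesignError(
            f"factor {self.symbol!r}: code {code} outside the level range"
        )

    def code_for_value(self, value: float) -> int:
        """Inverse of :meth:`value_for_code`; exact match required."""
        for i, v in enumerate(self.levels):
            if v == value:
                return 1 if (self.n_levels == 2 and i == 0) else (
                    -1 if self.n_levels == 2 else i + 1
                )
        raise DesignError(
            f"factor {self.symbol!r}: value {value} is not one of its levels"
        )


@dataclass(frozen=True)
class DesignMatrix:
    """A trials x factors array of integer level codes.

    ``codes`` holds ``+1/-1`` for two-level designs and ``1..3`` for
    three-level orthogonal arrays.  Factor symbols and trial labels are
    carried alongside; the array itself is immutable.
    """

    codes: np.ndarray
    symbols: tuple[str, ...]
    trials: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int).copy()
        codes.setflags(write=False)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))
        object.__setattr__(self, "trials", tuple(str(t) for t in self.trials))
        if codes.ndim != 2:
            raise DesignError("codes must be a 2-D array")
        if codes.shape != (len(self.trials), len(self.symbols)):
            raise DesignError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.trials)} trials x {len(self.symbols)} factors"
            )
        if len(set(self.symbols)) != len(self.symbols):
            raise DesignError("factor symbols must be unique")

    @property
    def n_trials(self) -> int:
        return self.codes.shape[0]

    @property
    def n_factors(self) -> int:
        return self.codes.shape[1]

    def column(self, symbol: str) -> np.ndarray:
        try:
            j = self.symbols.index(symbol)
        except ValueError:
            raise DesignError(f"unknown factor symbol {symbol!r}") from None
        return self.codes[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes, index=pd.Index(self.trials, name="trial"),
            columns=list(self.symbols),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "symbols": list(self.symbols),
            "trials": list(self.trials),
            "codes": self.codes.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "DesignMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            codes=df.to_numpy(dtype=int),
            symbols=tuple(df.columns),
            trials=tuple(str(t) for t in df.index),
        )


# ---------------------------------------------------------------------------
# canonical matrices
# ---------------------------------------------------------------------------

# 12-run Plackett-Burman arrangement used throughout the screening stage,
# coded with the "level 1 = +1" convention.  Column X11 is the unassigned
# dummy; it is the unique +-1 column (up to sign) that is balanced and
# orthogonal to the ten assigned columns, with the sign fixed so that the
# reference screening data yield a positive dummy effect.
_PB12_CODES = np.array([
    # X1  X2  X3  X4  X5  X6  X7  X8  X9 X10 X11
    [+1, -1, +1, -1, -1, -1, +1, +1, +1, -1, +1],
    [+1, +1, -1, +1, -1, -1, -1, +1, +1, +1, -1],
    [-1, +1, +1, -1, +1, -1, -1, -1, +1, +1, +1],
    [+1, -1, +1, +1, -1, +1, -1, -1, -1, +1, +1],
    [+1, +1, -1, +1, +1, -1, +1, -1, -1, -1, +1],
    [+1, +1, +1, -1, +1, +1, -1, +1, -1, -1, -1],
    [-1, +1, +1, +1, -1, +1, +1, -1, +1, -1, -1],
    [-1, -1, +1, +1, +1, -1, +1, +1, -1, +1, -1],
    [-1, -1, -1, +1, +1, +1, -1, +1, +1, -1, +1],
    [+1, -1, -1, -1, +1, +1, +1, -1, +1, +1, -1],
    [-1, +1, -1, -1, -1, +1, +1, +1, -1, +1, +1],
    [-1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1],
])

# First row of the standard cyclic generator for the 12-run design.
_PB12_GENERATOR = (+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1)

# Standard L9(3^4) orthogonal array.
_L9_CODES = np.array([
    [1, 1, 1, 1],
    [1, 2, 2, 2],
    [1, 3, 3, 3],
    [2, 1, 2, 3],
    [2, 2, 3, 1],
    [2, 3, 1, 2],
    [3, 1, 3, 2],
    [3, 2, 1, 3],
    [3, 3, 2, 1],
])


def pb12_matrix() -> DesignMatrix:
    """The canonical 12-run Plackett-Burman screening matrix.

    Ten assigned factor columns ``X1``..``X10`` plus the dummy column
    ``X11``.  Trial labels are ``"1"``..``"12"``.
    """
    return DesignMatrix(
        codes=_PB12_CODES,
        symbols=tuple(f"X{i}" for i in range(1, 12)),
        trials=tuple(str(i) for i in range(1, 13)),
    )


def pb12_cyclic(symbols: tuple[str, ...] | None = None) -> DesignMatrix:
    """A 12-run Plackett-Burman matrix from the standard cyclic generator.

    Row ``i`` (0-based, first 11 rows) is the generator cyclically shifted
    right by ``i``; the 12th row is all ``-1``.  Any matrix built this way
    passes :func:`validate_pb`; analyses accept it interchangeably with
    :func:`pb12_matrix`.
    """
    if symbols is None:
        symbols = tuple(f"X{i}" for i in range(1, 12))
    if len(symbols) != 11:
        raise DesignError("pb12_cyclic needs exactly 11 factor symbols")
    rows = [np.roll(_PB12_GENERATOR, i) for i in range(11)]
    rows.append(-np.ones(11, dtype=int))
    return DesignMatrix(
        codes=np.array(rows, dtype=int),
        symbols=symbols,
        trials=tuple(str(i) for i in range(1, 13)),
    )


def l9_matrix(symbols: tuple[str, ...] = ("A", "B", "C", "D")) -> DesignMatrix:
    """The standard Taguchi L9(3^4) orthogonal array (trials L1..L9)."""
    if len(symbols) != 4:
        raise DesignError("l9_matrix needs exactly 4 factor symbols")
    return DesignMatrix(
        codes=_L9_CODES,
        symbols=tuple(symbols),
        trials=tuple(f"L{i}" for i in range(1, 10)),
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_pb(design: DesignMatrix) -> None:
    """Check two-level balance and pairwise orthogonality.

    Every column must contain equally many ``+1`` and ``-1`` entries and
    every pair of columns must have zero inner product (equivalently, each
    of the four sign combinations occurs n/4 times).  Raises
    :class:`DesignError` on the first violation.
    """
    codes = design.codes
    if not np.isin(codes, (-1, 1)).all():
        raise DesignError("two-level design must be coded +1/-1")
    n = design.n_trials
    if n % 4:
        raise DesignError("run count must be a multiple of 4")
    sums = codes.sum(axis=0)
    if (sums != 0).any():
        bad = design.symbols[int(np.flatnonzero(sums)[0])]
        raise DesignError(f"column {bad} is not balanced")
    gram = codes.T @ codes
    off = gram - n * np.eye(design.n_factors, dtype=int)
    if off.any():
        i, j = np.argwhere(off)[0]
        raise DesignError(
            f"columns {design.symbols[i]} and {design.symbols[j]} "
            "are not orthogonal"
        )


def validate_oa3(design: DesignMatrix) -> None:
    """Check three-level orthogonal-array balance.

    Each column must contain each of levels 1..3 equally often, and for
    every pair of columns each of the nine ordered level pairs must occur
    equally often (exactly once for the L9).
    """
    codes = design.codes
    if not np.isin(codes, (1, 2, 3)).all():
        raise DesignError("three-level design must be coded 1..3")
    n = design.n_trials
    if n % 9:
        raise DesignError("run count must be a multiple of 9")
    for j, sym in enumerate(design.symbols):
        counts = np.bincount(codes[:, j], minlength=4)[1:4]
        if not (counts == n // 3).all():
            raise DesignError(f"column {sym} has unbalanced level counts")
    for (i, si), (j, sj) in combinations(enumerate(design.symbols), 2):
        pair = codes[:, i] * 3 + codes[:, j]  # 4..12 encodes the 9 pairs
        counts = np.bincount(pair, minlength=13)[4:13]
        if not (counts == n // 9).all():
            raise DesignError(
                f"columns {si} and {sj} do not balance all level pairs"
            )


# ---------------------------------------------------------------------------
# level mapping
# ---------------------------------------------------------------------------

def apply_factor_levels(
    design: DesignMatrix, specs: list[FactorSpec]
) -> pd.DataFrame:
    """Decode a design into a recipe table of concrete concentrations.

    Every design column must have a matching :class:`FactorSpec` (matched
    by symbol) whose level count fits the coding; spare design columns
    without a spec (dummy columns) are omitted from the output.

    Returns a DataFrame indexed by trial label with one column per
    specified factor, in the units of each spec.
    """
    by_symbol = {s.symbol: s for s in specs}
    unknown = set(by_symbol) - set(design.symbols)
    if unknown:
        raise DesignError(f"specs for symbols not in the design: {sorted(unknown)}")
    out = {}
    for sym, spec in by_symbol.items():
        col = design.column(sym)
        out[sym] = [spec.value_for_code(int(c)) for c in col]
    df = pd.DataFrame(out, index=pd.Index(design.trials, name="trial"))
    return df[[s.symbol for s in specs]]


def infer_codes(recipe: pd.DataFrame, specs: list[FactorSpec]) -> DesignMatrix:
    """Re-code a concrete recipe table back into integer level codes.

    Inverse of :func:`apply_factor_levels`: each concentration must match
    one of its factor's levels exactly.
    """
    by_symbol = {s.symbol: s for s in specs}
    missing = [c for c in recipe.columns if c not in by_symbol]
    if missing:
        raise DesignError(f"no FactorSpec for recipe columns: {missing}")
    codes = np.empty((len(recipe), len(recipe.columns)), dtype=int)
    for j, sym in enumerate(recipe.columns):
        spec = by_symbol[sym]
        codes[:, j] = [spec.code_for_value(v) for v in recipe[sym]]
    return DesignMatrix(
        codes=codes,
        symbols=tuple(recipe.columns),
        trials=tuple(str(t) for t in recipe.index),
    )
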