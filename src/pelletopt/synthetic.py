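"""Synthetic inputs with known ground truth.

Two generators replace the wet-lab stages of the workflow:

* :func:`simulate_doe` draws replicate biomass responses for a screening
  or optimization design from an additive effects model with Gaussian
  replicate noise, returning the planted truth alongside;
* :func:`draw_pellet_image` renders near-circular pellets as filled disks
  on a contrasting background (no anti-aliasing), optionally with
  additive Gaussian pixel noise, returning the true centers and
  diameters.

Both are deterministic given a seed (NumPy ``default_rng``, i.e. the
PCG64 bit generator; seeds are portable across runs of this package).

:func:`load_fixture` exposes the embedded published reference tables
(factor settings and per-trial outcomes) keyed ``"table1"``..``"table4"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _tables
from .designs import DesignMatrix
from .screening import ResponseSet

__all__ = [
    "SyntheticError",
    "SyntheticDOESpec",
    "simulate_doe",
    "SyntheticImageSpec",
    "draw_pellet_image",
    "load_fixture",
]


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class SyntheticDOESpec:
    """Additive-model response generator settings.

    For a two-level (+1/-1) design, ``effects`` maps factor symbols to a
    coefficient per coded unit: a trial's expected response is
    ``baseline + sum_j code_j * effects[j]``, so the recovered
    (+)-minus-(-) effect of a planted factor is exactly twice its
    coefficient.  For a three-level design, ``effects`` maps symbols to a
    three-entry per-level offset sequence.

    Defaults mirror the reference study's conditions: triplicate
    cultures, a basal-medium biomass of 0.92 g/dL, and a replicate noise
    SD of 0.15 g/dL (the basal culture's observed SD).  Simulated
    responses are kept strictly positive by resampling (not clipping)
    non-positive draws.
    """

    design: DesignMatrix
    baseline: float = 0.92
    effects: Mapping = field(default_factory=dict)
    noise_sd: float = 0.15
    replicates: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SyntheticError("noise SD must be >= 0")
        if self.replicates < 1:
            raise SyntheticError("at least one replicate per trial required")
        unknown = set(self.effects) - set(self.design.symbols)
        if unknown:
            raise SyntheticError(f"effects for unknown factors: {sorted(unknown)}")


def _expected_means(spec: SyntheticDOESpec) -> np.ndarray:
    design = spec.design
    mu = np.full(design.n_trials, float(spec.baseline))
    two_level = bool(np.isin(design.codes, (-1, 1)).all())
    for sym, eff in spec.effects.items():
        col = design.column(sym)
        if two_level:
            mu = mu + col * float(eff)
        else:
            offsets = np.asarray(eff, dtype=float)
            if offsets.shape != (3,):
                raise SyntheticError(
                    f"factor {sym}: three-level design needs 3 per-level "
                    "offsets"
                )
            mu = mu + offsets[col - 1]
    return mu


def simulate_doe(spec: SyntheticDOESpec) -> tuple[ResponseSet, pd.DataFrame]:
    """Draw replicate responses and return them with the planted truth.

    Returns ``(responses, truth)`` where ``truth`` has one row per factor
    with the planted parameters and, for two-level designs, the expected
    (+)-minus-(-) effect (``2 * coefficient``).
    """
    rng = np.random.default_rng(spec.seed)
    mu = _expected_means(spec)
    draws = rng.normal(
        mu[:, None], spec.noise_sd, size=(len(mu), spec.replicates)
    )
    # strictly positive responses: resample offending entries
    bad = draws <= 0
    while bad.any():
        draws[bad] = rng.normal(
            np.broadcast_to(mu[:, None], draws.shape)[bad], spec.noise_sd
        )
        bad = draws <= 0
    responses = ResponseSet(
        trials=spec.design.trials,
        replicates=tuple(tuple(row) for row in draws),
    )
    two_level = bool(np.isin(spec.design.codes, (-1, 1)).all())
    rows = []
    for sym in spec.design.symbols:
        eff = spec.effects.get(sym, 0.0 if two_level else (0.0, 0.0, 0.0))
        if two_level:
            rows.append(
                {"factor": sym, "coefficient": float(eff),
                 "expected_effect": 2.0 * float(eff)}
            )
        else:
            o = tuple(float(v) for v in np.asarray(eff, dtype=float))
            rows.append(
                {"factor": sym, "offset_level1": o[0], "offset_level2": o[1],
                 "offset_level3": o[2]}
            )
    return responses, pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Pellet-image generator settings.

    Diameters (mm) are drawn from ``diameter_dist``: ``"normal"`` with
    ``(mean, sd)`` truncated strictly positive by resampling,
    ``"lognormal"`` with ``(mu, sigma)`` of the underlying normal, or
    ``"fixed"`` with ``(value,)``.  Defaults follow the reference pellet
    preparation: mean diameter 2.10 mm, SD 0.52 mm, dark pellets on a
    light background at 0.05 mm/px.

    With ``overlap=False`` disks are rejection-sampled to be pairwise
    disjoint (1 px clearance); placement failure after ``max_attempts``
    per disk raises an error instead of silently dropping particles.
    ``shape="square"`` renders axis-aligned squares whose side equals the
    drawn diameter, for roundness-filter tests.
    """

    shape_px: tuple[int, int] = (1024, 1024)
    scale: float = 0.05  # mm per pixel
    count: int = 100
    diameter_dist: str = "normal"
    diameter_params: tuple[float, ...] = (2.10, 0.52)
    overlap: bool = False
    foreground: int = 60
    background: int = 200
    noise_sd: float = 0.0
    shape: str = "disk"
    margin_px: int = 2
    max_attempts: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise SyntheticError("count must be >= 0")
        if self.scale <= 0:
            raise SyntheticError("pixel scale must be positive")
        if not (0 <= self.foreground <= 255 and 0 <= self.background <= 255):
            raise SyntheticError("gray levels must fit 8-bit depth")
        if self.noise_sd < 0:
            raise SyntheticError("noise SD must be >= 0")
        if self.shape not in ("disk", "square"):
            raise SyntheticError(f"unknown shape {self.shape!r}")
        if self.diameter_dist not in ("normal", "lognormal", "fixed"):
            raise SyntheticError(
                f"unknown diameter distribution {self.diameter_dist!r}"
            )


def _draw_diameters(spec: SyntheticImageSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.diameter_dist == "fixed":
        return np.full(spec.count, float(spec.diameter_params[0]))
    if spec.diameter_dist == "lognormal":
        mu, sigma = spec.diameter_params
        return rng.lognormal(mu, sigma, spec.count)
    mean, sd = spec.diameter_params
    d = rng.normal(mean, sd, spec.count)
    bad = d <= 0
    while bad.any():  # truncate by resampling, no point mass near zero
        d[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = d <= 0
    return d


def draw_pellet_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the image and return it with a ground-truth particle table.

    Returns ``(image, truth)``: an 8-bit grayscale array and a DataFrame
    with columns ``id, row_px, col_px, diameter_mm, diameter_px``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    diam_mm = _draw_diameters(spec, rng)
    radii_px = diam_mm / spec.scale / 2.0
    # place largest first: makes disjoint packing far easier
    order = np.argsort(radii_px)[::-1]
    placed: list[tuple[float, float, float, int]] = []  # (r0, c0, radius, idx)
    for idx in order:
        r = radii_px[idx]
        lo = r + spec.margin_px
        if h - 2 * lo <= 0 or w - 2 * lo <= 0:
            raise SyntheticError(
                f"particle {idx}: diameter {diam_mm[idx]:.2f} mm does not "
                "fit in the image"
            )
        for _ in range(spec.max_attempts):
            r0 = rng.uniform(lo, h - lo)
            c0 = rng.uniform(lo, w - lo)
            # 2.5 px clearance: rendered disks stay separated even under
            # 8-connected labelling (diagonal adjacency spans sqrt(2) px,
            # plus digitization slack on both boundaries)
            if spec.overlap or all(
                np.hypot(r0 - pr, c0 - pc) > r + pradius + 2.5
                for pr, pc, pradius, _ in placed
            ):
                placed.append((r0, c0, r, int(idx)))
                break
        else:
            raise SyntheticError(
                f"could not place {spec.count} disjoint particles in a "
                f"{h}x{w} px image after {spec.max_attempts} attempts each"
            )
    mask = np.zeros((h, w), dtype=bool)
    for r0, c0, r, _ in placed:
        # paint only the particle's bounding box
        rlo, rhi = int(np.floor(r0 - r)) - 1, int(np.ceil(r0 + r)) + 2
        clo, chi = int(np.floor(c0 - r)) - 1, int(np.ceil(c0 + r)) + 2
        rlo, clo = max(rlo, 0), max(clo, 0)
        rhi, chi = min(rhi, h), min(chi, w)
        yy, xx = np.mgrid[rlo:rhi, clo:chi]
        if spec.shape == "disk":
            patch = (yy - r0) ** 2 + (xx - c0) ** 2 <= r**2
        else:
            patch = (np.abs(yy - r0) <= r) & (np.abs(xx - c0) <= r)
        mask[rlo:rhi, clo:chi] |= patch
    img = np.full((h, w), float(spec.background))
    img[mask] = float(spec.foreground)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    placed.sort(key=lambda t: t[3])  # back to draw order
    truth = pd.DataFrame(
        {
            "id": [i for *_, i in placed],
            "row_px": [r0 for r0, *_ in placed],
            "col_px": [c0 for _, c0, *_ in placed],
            "diameter_mm": [diam_mm[i] for *_, i in placed],
            "diameter_px": [2.0 * r for _, _, r, _ in placed],
        }
    )
    return img, truth


def load_fixture(table_id: str) -> dict:
    """Embedded published reference tables.

    ``"table1"``: two-level screening factor settings; ``"table2"``:
    three-level optimization factor settings; ``"table3"``: screening
    design + per-trial DCW outcomes + printed statistics; ``"table4"``:
    L9 design + biomass + per-trial S/N + printed level means, SS and
    contributions.  Raises ``KeyError`` for unknown ids.
    """
    return _tables.fixture(table_id)
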