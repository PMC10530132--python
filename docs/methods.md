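# Methods

## Screening statistics (Plackett–Burman)

The screening stage uses the standard 12-run, 11-column two-level
Plackett–Burman array: every column is balanced (six runs at each level)
and every pair of columns is orthogonal. Two constructions are provided:
the canonical embedded arrangement whose rows match the reference
experiment's trial order, and a cyclic-Hadamard generator
(`pb12_cyclic`). All analysis functions accept *any* matrix that passes
the balance/orthogonality validator, so other 11-column arrangements can
be analysed unchanged. The canonical matrix's dummy column is the unique
(up to sign) ±1 vector orthogonal to the ten assigned columns; its sign
is fixed so the reference data give a positive dummy effect.

Effects are computed on per-trial **means** — replicates are collapsed
first, matching how the reference experiment reported one dry-cell-weight
mean per trial — not by replicate-level ANOVA. Replicate spread enters
only as the reported per-trial SD (sample SD, n−1 denominator, the
convention for triplicate mean ± SD reporting).

The design is saturated (11 columns, 11 degrees of freedom after the
grand mean), so the error variance comes from the unassigned dummy
column: `SS = n·effect²/4`, one df per column, `F = MS/MS_dummy`,
p-values one-tailed from F(1, 1). The dummy tested against itself gives
F = 1, p = 0.5 by construction. A dummy mean square of exactly zero makes
significance undefined and raises rather than returning infinities. Note
the single error df makes this test extremely conservative *and* noisy:
the critical value at α = 0.05 is ≈ 161, and the empirical per-factor
type-I rate over simulations is only loosely centred on 5% (the test
suite asserts a wide 0.5–15% sanity band, not a calibration claim).

Effect shares are `|effect| / Σ|effect| · 100` over the **assigned**
factors only; the dummy is excluded from numerator and denominator. This
convention reproduces all four published share percentages at integer
rounding; including the dummy would not.

Tolerances against the published table: effects ±0.005, SS ±0.01, since
the source computed from unrounded replicate data but printed 2–3
decimals (e.g. its F 449.6 vs 448.7 recomputed from printed means).

## Optimization statistics (Taguchi L9)

Larger-the-better S/N: `−10·log₁₀(mean(1/y²))` in dB, requiring strictly
positive responses. For identical replicates this reduces to
`20·log₁₀(y)`; when only a per-trial mean is available (fixture mode),
that identical-replicate approximation is used and flagged
`sn_approximate` in reports, because the replicate spread behind the
published per-trial S/N values is unpublished and cannot be recovered.

Level means average the three trials at each factor level. The optimum
takes the arg-max level per factor; exact ties break to the lowest level
index (deterministic, documented). Sums of squares:
`SS_i = 3·Σ_levels (levelMean − grandMean)²`, with
`SST = Σ_trials (S/N − grandMean)²` computed from trial deviations — for
the saturated L9 the factor SS sum to SST exactly in full precision (an
invariant the tests assert at 1e−9 relative), but SST is deliberately
*not* computed as ΣSS_i so that rounded published inputs propagate
faithfully. Contributions are SS_i/SST·100 and sum to 100% before
rounding. The additive-model prediction is the grand mean plus the
selected levels' deviations from it; on the published level means the
A2B3C3D3 prediction is 8.31 dB. Rescaling all replicates by c adds
exactly 20·log₁₀(c) to every S/N and leaves level-mean differences, SS,
contributions and the optimum unchanged (property-tested).

## Morphometry conventions

Segmentation: global threshold (Otsu by default, fixed value
selectable), dark objects on a light background by default (values equal
to the threshold belong to the dark class, matching the scikit-image
convention that the bright class is `img > thr`), optional hole filling,
8-connected foreground labelling (4-connected background). A constant
image yields zero particles with a warning, not an error. Touching
pellets are **not** declumped — the imaging protocol this emulates
dilutes samples to avoid overlap — so merged blobs count as one
particle; this is a documented limitation, not a defect.

Per-particle measures, all scaled by the mm/px calibration:

* **area** — pixel count · scale²;
* **perimeter** — Crofton four-direction estimator (default), accurate
  to ~1% on digitized disks of radius ≥ 10 px; the weighted
  boundary-step estimator is selectable but runs ~5% high on disks,
  which depresses circularity to ~0.90;
* **circularity** — `4πA/p²`, clamped at 1.0 because digitization noise
  can push near-perfect disks slightly above 1;
* **Feret diameter** — maximal caliper distance over the convex hull of
  *pixel centers*. Sub-pixel boundary outlines (as in
  `feret_diameter_max`-style estimators) carry a constant ≈ +1.6 px
  offset — 7% at radius 10 px — whereas pixel centers stay within
  −1.4%…0% of the true diameter for radii ≥ 10 px. A single-pixel
  particle has Feret = one pixel width by convention. Feret may
  undershoot the equivalent-circle diameter on digitized shapes by at
  most 5% (config constant `FERET_DIGITIZATION_TOL`).

Size/roundness filtering mirrors interactive particle-analyzer
semantics: minimum area 0.01 in calibrated units (mm²) and an inclusive
circularity band of 0.1–1.0 by default; the area unit is calibrated
rather than pixel-based because that is the "Size" semantics of the tool
the workflow emulates, and both settings are plain arguments.

Distribution summaries of Feret diameters: Christiansen uniformity
coefficient `CU = 1 − Σ|xᵢ − x̄|/(n·x̄)` (1 iff all equal,
scale-invariant, can go negative for very dispersed samples); quartiles
by linear interpolation between order statistics (the common spreadsheet
rule); outliers outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`.

## Synthetic generators

`simulate_doe` draws `y = baseline + structure + N(0, σ)` per replicate:
for two-level designs the structure is `Σ codeⱼ·coefⱼ` (so the recovered
(+)−(−) effect of a planted factor is exactly 2·coef — an identity the
tests assert at zero noise), for three-level designs a per-level offset.
Defaults are the reference study's conditions: triplicate cultures,
baseline 0.92 g/dL (the basal-medium biomass), noise SD 0.15 g/dL (the
basal culture's printed SD). Responses are kept strictly positive by
resampling non-positive draws, not clipping, to avoid a point mass at
zero.

`draw_pellet_image` renders anti-aliasing-free disks (a pixel is
foreground iff its center lies inside the circle) at 0.05 mm/px by
default with diameters from a positive-truncated Normal(2.10, 0.52²) mm,
dark pellets (gray 60) on a light background (gray 200), optional
additive Gaussian pixel noise. When overlap is disallowed, placement is
rejection-sampled largest-first with a 2.5 px clearance — enough that
8-connected labelling can never bridge two disks across a diagonal —
and failure to place all particles raises rather than silently dropping
some. The truth table (centers, diameters) is returned alongside.

All randomness flows through NumPy `default_rng` (PCG64), so seeds are
portable and identical seeds give bit-identical outputs.

What the generator does **not** emulate: hyphal "burr" texture,
irregular or fragmented pellets, illumination gradients, camera noise
beyond additive Gaussian, or overlapping-pellet declumping. Passing the
recovery tests therefore demonstrates correctness of the measurement
chain on idealised near-circular particles, not segmentation robustness
on difficult real photographs.

## Problem sizes and numerical choices

The simulation-based tests use 12×3 or 9×3 response draws over 20–2000
seeds and one 2048×2048 px, 500-disk image — sizes chosen so the whole
suite runs in well under a minute while leaving Monte-Carlo standard
errors far below the asserted bounds. Statistical tests over seeds are
derandomised (fixed seed lists; hypothesis `derandomize=True`).
F quantiles and tail probabilities come from `scipy.stats.f`; the test
suite cross-checks the quantile against direct quadrature of the F
density. Degenerate inputs follow explicit conventions documented above
(zero dummy MS, zero SST, empty particle sets, constant images,
single-pixel particles).

## Known limitations

* The dummy-referenced F(1, 1) test has a single error df; its power and
  calibration are poor by construction, and no alternative effect
  screening (half-normal plots, Lenth's method) is provided.
* Only max-caliper Feret is implemented (no MinFeret); "roundness"
  filtering is applied to the circularity value.
* Published image-derived values (uniformity 0.85, pellet diameters
  2.10 ± 0.52 mm) depend on photographs that were never deposited; they
  serve as generator parameters here and are validated only through
  synthetic-recovery properties, not reproduced from real images.
* No run-order randomization, interaction effects, fold-over designs,
  other PB run sizes, or larger orthogonal arrays.
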