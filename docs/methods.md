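# Methods

## The single-filament detachment model

A lamin-B filament of in-situ length `L_fil` and persistence length `ℓ_p`
is treated as a two-state system: attached to, or detached from, the inner
nuclear membrane.  Relative to the detached state (energy 0), the attached
state at a membrane of Gaussian-curvature radius `R` has energy

```
E_attached = −E + a·(1/R) + ½·k·(1/R)²
```

with `E` the binding energy, `a` a contact coefficient capturing the
curvature-induced loss of filament–membrane contact area, and
`k = ℓ_p · L_fil` the bending constant (the filament's bending stiffness
`ℓ_p·k_BT` integrated over its length).  The Boltzmann weight of the two
states gives the detachment probability

```
P_detached(κ) = 1 / (1 + exp(E − a·κ − ½·k·κ²)),    κ = 1/R .
```

All energies are expressed in `k_BT` units so temperature never appears;
curvature is passed as `κ = 1/R` (µm⁻¹) so the flat limit is exactly
representable.  With the measured geometry `ℓ_p = 0.5` µm and
`L_fil = 0.38` µm, `k = 0.19 k_BT·µm²`; at curvatures up to 1 µm⁻¹ the
bending term contributes at most `½·0.19 ≈ 0.1 k_BT`, which moves the
probability by under 0.03 anywhere on the logistic, so fits routinely drop
it (`include_bending=False`).

Model assumptions worth keeping in mind: a mean-field single filament
stands in for a cross-linked meshwork; attachment is binary (no partial
peeling); curvature enters only through the local Gaussian-curvature
radius, and only sites where both principal curvatures share a sign
(positive Gaussian curvature — poles, tips, not the pipette-wall cusp) are
in scope, which is why `gaussian_sign` gates downstream dilution analysis.

## The sigmoidal response and its fitting

Response data (rupture percentages, intensity ratios) are fitted with

```
y(x) = B / (1 + exp(ε − α·x)) ,
```

the detachment probability rescaled by an amplitude `B` that carries the
response's units.  `ε` (k_BT) and `α` (k_BT·µm) are the binding and
interaction energies; they were calibrated in prior work and are therefore
*required inputs* with no package default — `B_only` mode fits the
amplitude alone by the closed-form weighted ratio
`B = Σ w·f·y / Σ w·f²` with `f` the unit logistic, and `full` mode fits
all three by nonlinear least squares.

Numerical choices for `full` mode: five deterministic multi-starts with
`α₀` log-spaced over `[0.5, 50]/span(x)` (gentle to steep transitions),
`ε₀ = α₀·median(x)`, `B₀ = max(y)`; best residual kept, ties broken toward
the smallest `α`.  `B ≥ 0` is enforced as a bound.  Rows may carry trial
counts; binomial weighting (`w = n`) is the default but can be disabled,
since figure-level fits of percentage data do not state their weighting.
The logistic exponent is clipped at ±700 before exponentiation: saturated
probabilities are physically meaningful and must not overflow.  The
reported `residual_norm` is `‖r‖_w / ‖y‖_w`, making fits scale-equivariant
in the response.  All-zero responses yield `B = 0` with zero residual
rather than an error.

## Curvature estimation

Local curvature on a contour (ordered (x, y) points in µm, closed contours
normalised to counter-clockwise orientation) is the inverse radius of an
osculating circle fitted over an arc window of nominal total length 2 µm
centred on the query point.  The window is centred rather than one-sided
because symmetric windows are unbiased exactly where curvature is measured
— at extrema (poles).  The circle fit is algebraic (Kåsa) least squares
refined by one geometric Gauss–Newton step: deterministic and adequate at
this noise scale.

One refinement matters for sharp poles: a *fixed* 2 µm window spanning a
feature whose radius is smaller than the window averages over rapidly
varying curvature and underestimates it (by ~16% at the pole of a
10 × 3 µm ellipse, where R = 0.9 µm).  The estimator therefore shrinks the
window iteratively until the fitted arc subtends at most half a radian of
the fitted circle (never below the 5 nearest points, never above the
nominal window).  Constant-curvature arcs are unaffected — circles from
0.5–10 µm radius are recovered to well under 1% at 256 points — while the
ellipse pole error drops to ~1.4%.  The nominal window is additionally
capped at half the contour perimeter so small contours remain measurable.
Exactly collinear windows return curvature 0 (infinite radius), signed
curvature is positive where the contour bulges outward, and windows holding
fewer than 3 points raise an estimation error.

Pore and pipette curvature is simply `2/D` for diameter `D`.  Regime
classification (low/medium/high) uses explicit, user-supplied thresholds —
the boundaries are presentation choices, not model constants — with
boundary values assigned upward and negative (concave) curvature mapped to
`low` with a warning.

## Intensity metrics

Profiles are min–max normalized, `(v − min)/(max − min)`, which is
invariant to affine intensity transforms; pole means average the first
1 µm of a profile by trapezoidal integration over distance (robust to
non-uniform sampling; the raw measurements averaged uniform pixel grids).
Tip dilution is `φ = inside/tip − 1` on background-subtracted intensities
(so `φ = 0` means no loss at the tip), and the relative tip intensity
`tip/inside = 1/(1+φ)`.  Spindle-pole dilution reuses the same measure with
(center, pole) in place of (inside, tip) from 2 × 2 µm boxes.

## Rupture statistics

**Independence model.** The multi-site prediction `p^k` is interpreted as
`P(N ≥ k) = p₁^k`: a k-th rupture occurs with probability `p₁` given that
k−1 occurred.  This is self-consistent with pooled "2" and "3+" classes,
whereas a fixed-site binomial would predict `3p²(1−p)` for two sites and
contradict the stated power law.  Class probabilities are then
`{1−p₁, p₁−p₁², p₁²−p₁³, p₁³}` for {0, 1, 2, 3+}.

**Goodness-of-fit.** The formal test is an extension (the original analysis
judged agreement by fit quality).  Tail classes with expected counts below
5 are pooled; cohorts under 200 cells get an exact multinomial test (total
probability of all outcomes no more likely than the observed one, with the
outcome table cached per (n, probs)), larger cohorts a Pearson chi-square.
Degenerate `p₁ ∈ {0, 1}` with conforming data reports statistic 0, with
nonconforming data p-value 0.  Across several pore diameters, Holm
adjustment is applied and both raw and adjusted p-values reported.

**Regime enrichment** is the ratio of the fraction of rupture sites in a
curvature regime to the fraction of perimeter samples in that regime —
density-based, hence invariant to duplicating the perimeter sample list —
with per-regime medians taken over perimeter samples.  Regimes absent from
the perimeter are flagged undefined rather than raising.

**Hinge fit.** `φ = c·max(0, rate − r_crit)` is fitted by a deterministic
coarse grid over `r_crit ∈ [0, max rate]` (201 knots; the slope `c` has a
closed form at fixed `r_crit`), refined by bounded scalar minimisation
between the best knot's neighbours, then snapped to a data rate when that
does at least as well.  Grid-plus-refinement was chosen over joint gradient
descent because the objective is only piecewise smooth in `r_crit` and the
grid avoids both local minima and seed dependence.  Data with no positive
dilution return `r_crit = max(rate)` flagged "no dilution detected".

## Synthetic-data generators

The generators emulate the *statistical structure* of each input class;
they are not image simulators.  A single frozen `GeneratorConfig` drives
everything, and a fixed config (seed included) produces byte-identical
CSVs; each generator draws from its own named sub-stream of the seed.

Default study conditions: pore diameters (2.25, 3, 4, 5, 6, 8) µm — i.e.
imposed curvatures 0.25–0.89 µm⁻¹ — with 500 migrated cells per pore;
response sigmoid `B = 34` (percent), `ε = 4`, `α = 8`, placing the
midpoint at `ε/α = 0.5 µm⁻¹`, the pipette curvature at which rupture
becomes frequent; filament energies `(E, a) = (ε, α)` with the geometric
`k = 0.19`; additive Gaussian intensity noise sd 0.05; lamin-A hinge slope
1.0 per (µm/s) with critical rate 0.2 µm/s inside a 0.05–1 µm/s aspiration
range.  Amplitudes above 1 are interpreted as percentages and divided by
100 for simulation (logged).

* **Contours** are parametric circles, ellipses, or "spindles" — modelled
  as capsules: two semicircular pole caps of radius `r` joined tangentially
  by straight sides, so pole curvature is exactly `1/r` and side curvature
  exactly 0.  Analytic pole/side/axial curvature is attached as metadata.
* **Profiles**: lamin-B (and DNA) intensity at axial distance `d` is
  `1 − P_detached(κ(d))`; lamin-A is reduced by the same shape scaled by
  the hinge factor `clip(c·max(0, rate − r_crit), 0, 1)`, so below the
  critical rate lamin-A stays flat while lamin-B dilutes.  The
  proportionality between detachment probability and fractional intensity
  loss is an explicit generator assumption (single filament vs meshwork
  density is not resolved by the model).
* **Migration cohorts** draw site counts from the independence model with
  `p` given by the (percent-converted) sigmoid of pore curvature; myosin
  inhibition multiplies `p` by 0.5 — an approximation knob reflecting the
  observed roughly two-fold suppression, not a fitted constant; the
  hypotonic condition tags records and scales aspiration rates.
* **Aspiration traces** have `ΔL(t) = rate·t`; tip lamin-B dilutes
  instantaneously and elastically (`φ_B = slope_B·rate`), lamin-A by the
  hinge law, DNA like lamin-B.  At long times lamin-A relaxes exponentially
  toward lamin-B's dilution (time constant `relaxation_tau`, default 300 s
  — an explicit config parameter with no claim of measured realism), with
  the relaxation clock starting at the standard readout time (default
  60 s) so the early readout reflects the hinge law exactly.  Noise is
  added to tip intensities; note that intensity noise of sd σ maps to
  dilution noise ≈ (1+φ)²·σ, so φ estimates at high rates are noisier than
  the raw σ suggests.

What the generators deliberately omit — segmentation error, uneven
illumination, photobleaching, cell-to-cell parameter variability, 3-D
projection effects — bounds what passing tests show: they validate the
estimators against the model's own structure, not against raw-microscopy
artefacts.

## Problem sizes and determinism

The test and acceptance suites run at the default study conditions: 20
replicate cohorts of 6 × 500 cells for sigmoid recovery; one 10,000-cell
cohort plus 500 null replicates of 100 cells for the independence
calibration (exact multinomial, cached outcome table); 20,000 perimeter /
5,000 rupture samples for the enrichment null; 30 aspiration traces for
hinge recovery.  The full suite completes in well under a minute.  All
randomness flows through explicit seeds; hypothesis property tests run
derandomized.

## Known limitations

* 2-D contours provide one principal curvature; Gaussian-sign
  classification needs the second supplied or assumed (equal at a pole of
  revolution).
* `ε` and `α` must come from prior calibration; the package can estimate
  them in `full` mode but offers no defaults for analysis of real data.
* The independence test conditions on an externally supplied `p₁`; using
  the same cohort's measured single-site fraction as `p₁` makes the test
  mildly conservative.
* No image segmentation, no 3-D surface reconstruction, no intranuclear
  pressure model: contours, profiles and cohort tables are inputs.
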