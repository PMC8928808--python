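# lamincurv

Curvature-driven dilution of the nuclear lamina, as a reusable analysis
pipeline.

The nuclear lamina — juxtaposed meshworks of lamin-A and lamin-B filaments
lining the inner nuclear membrane — locally thins ("dilutes") wherever the
nuclear envelope is forced into high positive Gaussian curvature: at the
poles of elongating nuclei, in constricting migration pores, and at the
leading tip of micropipette-aspirated nuclei.  Lamin-B loss marks the sites
where the envelope subsequently ruptures.  `lamincurv` implements the
quantitative machinery used to analyse this phenomenon:

* a **two-state Boltzmann model** of a single lamin filament that is either
  attached to or detached from a membrane of curvature `1/R`.  With binding
  energy `E`, contact coefficient `a` and bending constant
  `k = ℓ_p · L_fil` (all in units of `k_B T`), the attached-state energy is

  `E_attached = −E + a/R + k/(2R²)`

  and the detachment probability is the logistic

  `P_detached = 1 / (1 + exp(E − a/R − k/(2R²)))`,

  rising sigmoidally from ≈0 on flat membranes (`E ≫ k_B T`) to 1 at high
  curvature;
* **osculating-circle curvature estimation** on nuclear contours (ordered
  2-D point lists in µm), plus pore/pipette curvature `2/D`;
* **intensity metrics**: min–max profile normalization, 1 µm pole means,
  lamin-B-to-A ratios, and tip dilution `φ = inside/tip − 1`;
* **rupture statistics**: bleb/scar count distributions with the
  independence prediction `P(N ≥ k) = p^k`, an exact goodness-of-fit test,
  curvature-regime enrichment, and the hinge fit
  `φ = c · max(0, ΔL/t − (ΔL/t)_crit)` that separates rate-independent
  (elastic, lamin-B) from critical-rate (viscous, lamin-A) dilution;
* a **seeded synthetic-data generator** for every input class, so the whole
  pipeline is testable end to end without microscope data.

It is intended for quantitative cell biologists and biophysicists analysing
nuclear-envelope mechanics, and as a worked reference implementation of the
model.

## Worked example

```python
import numpy as np
from lamincurv import (FilamentParams, GeneratorConfig, bending_constant,
                       detach_probability, fit_sigmoid, simulate_migration_cohort)

# Bending constant from measured lamin-filament geometry:
bending_constant(0.5, 0.38)          # -> 0.19  (k_BT um^2)

# Detachment probability at pore-imposed curvatures (E=4, a=8 in k_BT units):
params = FilamentParams(binding_energy_E=4.0, contact_coeff_a=8.0)
detach_probability(2/8.0, params)    # -> 0.120   (8 um pore, kappa=0.25/um)
detach_probability(2/2.25, params)   # -> 0.960   (2.25 um pore, kappa=0.89/um)

# Simulate migration cohorts (6 pore sizes x 500 cells) and refit the sigmoid:
cfg = GeneratorConfig(seed=1)
records = simulate_migration_cohort(cfg)
pts = []
for D in cfg.pore_diameters:
    kappa = 2.0 / D
    sub = [r for r in records if abs(r.imposed_curvature - kappa) < 1e-9]
    pts.append((kappa, 100.0 * np.mean([r.n_sites >= 1 for r in sub]), len(sub)))
fit = fit_sigmoid(pts, mode="full")
print(fit.amplitude_B, fit.epsilon, fit.alpha)
# -> 33.9 4.41 9.19   (generating values were B=34, eps=4, alpha=8)
```

The measured rupture percentages rise from 3.0% at κ = 0.25 µm⁻¹ (8 µm
pores) to 32.4% at κ = 0.89 µm⁻¹ (2.25 µm pores), and the refitted
amplitude B = 33.9% recovers the generating plateau of 34%.  A noiseless
aspiration round trip recovers the lamin-A hinge exactly
(`slope_c = 1.000`, `critical_rate = 0.200` µm/s with the default
configuration).

The same pipeline is scriptable from the shell:

```sh
lamincurv simulate --seed 1 --out out/sim
lamincurv fit --points out/sim/rupture_vs_curvature.csv --out out/fit
lamincurv rupture-stats --cohort out/sim/cohort.csv --out out/stats
lamincurv report --inputs out/sim --out out/report
```

Every run writes a `manifest.json` (seed, config hash, version) next to its
outputs; identical manifests reproduce identical data files.

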