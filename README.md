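# oleokin

Kinetic and mass-transfer analysis of solid–liquid (solvent) oil extraction,
built around the hexane extraction of *Attalea tessmannii* (an Amazonian
palm) kernel oil. The package is for process engineers and natural-product
chemists who need to turn bench extraction curves into rate constants,
activation energies and effective diffusivities — and to check that an
analysis pipeline of this kind actually recovers known parameters before
trusting it on real data.

## What it computes

**Extraction kinetics.** Cumulative yield curves, normalised by the kernel's
total lipid basis m_tl to an extracted fraction f(t) = m_l/m_tl, are fitted
by Levenberg–Marquardt to two models (t in minutes):

- pseudo-first-order: f(t) = 1 − exp(−k₁t)
- Brimberg:           f(t) = 1 − exp(−k₂tⁿ)

Each fit reports SSE, R², adjusted R² = 1 − (1 − R²)(n − 1)/(n − p), and RMSE
in both common conventions (√(SSE/N) and √(SSE/(N − p))). Models are ranked
by adjusted R², ties broken by RMSE.

**Activation energy.** Rate constants across temperature are regressed on
the Arrhenius plot, ln k vs 1/T: k = k₀ exp(−Eₐ/RT), with R = 8.314
J mol⁻¹ K⁻¹. The fit is applied to the pseudo-first-order constants, which
increase with temperature as the law requires.

**Effective diffusivity.** The slow stage is modelled by Fick diffusion in a
sphere, M_t/M_∞ = 1 − (6/π²) Σ n⁻² exp(−n²π²D_e t/R²) (t in seconds), whose
long-time one-term form 1 − A·exp(−Bt) is fitted to normalised curves. The
diffusivity follows from the decay coefficient: D_e = B·R²/π². When the
particle radius is unreported it can be back-calculated from a published
(D_e, B) anchor pair as R = π√(D_e/B).

**Oil characterisation.** FAME (fatty-acid methyl ester) profiles are
classified by the Cx:y shorthand into SFA/MUFA/PUFA and summed, and
carbohydrate content is computed by difference from a proximate composition.

**Synthetic experiments.** A seeded generator emulates the bench design
(6 samples over 15–240 min at 25/50/60 °C, additive Gaussian noise on the
fraction scale, optional Arrhenius-consistent rate constants), so every
stage of the pipeline is testable against known ground truth.

Reference coefficient tables for the *A. tessmannii* system (fitted kinetic
and diffusion parameters, the FAME profile, oil quality indices, proximate
composition) ship with the package under `oleokin.reference`.

## Worked example

```python
import oleokin as ok
from oleokin.reference import (
    kinetic_fits, diffusion_fits, fame_records, DE_ANCHOR_25C_M2_PER_S,
)

# activation energy from the fitted first-order rate constants
pfo = kinetic_fits().query("model == 'pseudo_first_order'")
arr = ok.fit_arrhenius(pfo["k"], pfo["temperature_C"])
print(f"Ea = {arr.activation_energy_kj:.2f} kJ/mol, R2 = {arr.r_squared:.4f}")

# diffusivities with the particle radius anchored at 25 degC
d = diffusion_fits().set_index("temperature_C")
radius = ok.radius_from_anchor(DE_ANCHOR_25C_M2_PER_S, d.loc[25, "B_per_s"])
for T in (25, 50, 60):
    de = ok.effective_diffusivity(d.loc[T, "B_per_s"], radius)
    print(f"De({T} C) = {de:.2e} m2/s")

# saturation totals of the 60 degC FAME profile
s = ok.aggregate_saturation(fame_records(60.0))
print(f"SFA {s.sfa_total:.2f}  MUFA {s.mufa_total:.2f}  PUFA {s.pufa_total:.2f}")
```

prints

```
Ea = 27.52 kJ/mol, R2 = 0.9930
De(25 C) = 1.80e-11 m2/s
De(50 C) = 4.13e-11 m2/s
De(60 C) = 5.77e-11 m2/s
SFA 89.70  MUFA 8.28  PUFA 2.02
```

i.e. a moderate activation energy (diffusion-controlled extraction), a
three-fold rise in effective diffusivity from 25 to 60 °C with a
back-calculated particle radius of 1.227 mm, and an oil that is ~90 %
saturated (dominated by lauric acid).

A shell interface wraps the same stages:

```sh
oleokin simulate --seed 1 --out kinetics.csv
oleokin fit-kinetics kinetics.csv --basis 64.19
oleokin arrhenius --k 0.00703 --k 0.01782 --k 0.02197 --temp 25 --temp 50 --temp 60
oleokin run-all --kinetics kinetics.csv --basis 64.19 --out report.json
```

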