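# pdtmon

Light dosimetry and dual-wavelength fluorescence monitoring for
photodynamic therapy (PDT) with chlorin-based photosensitizers.

Chlorin e6 has two absorption peaks, near 402 nm (blue) and 662 nm (red).
Because tissue absorbs blue light much more strongly than red, the two
bands deposit their energy at very different depths, and exciting the
photosensitizer's fluorescence alternately at 405 and 660 nm probes its
distribution over depth. `pdtmon` packages the quantitative core of this
monitoring approach for researchers running or simulating low-dose PDT
protocols on layered tissue (the built-in model is a 1-mm rabbit ear:
skin 0.4 mm / cartilage 0.2 mm / skin 0.4 mm):

* **`pdtmon.layered_mc`** — weighted-packet Monte Carlo photon transport in
  a planar layered slab: depth-resolved absorbed dose A(z) (per unit volume
  per photon launched per unit area, mm⁻¹), plus specular/diffuse
  reflectance and transmittance fractions. Isotropic scattering at μs′
  (similarity rule), continuous absorption along paths, Fresnel boundaries
  with total internal reflection, Russian roulette termination.
* **`pdtmon.fluor_kinetics`** — photobleaching quantification: ROI
  segmentation of the fluorescing area, dose-indexed mean intensities,
  photobleaching efficiency `PE = (If1 − If2)/If1 · 100%`, nonlinear
  least-squares fit of the decay `If(D) = If1·exp(−αD)` (α in (J/cm²)⁻¹),
  and the red-to-blue ratio series `R = If660/If405`.
* **`pdtmon.depth_inference`** — Monte Carlo forward model of the detected
  fluorescence `I = ∫ Φ_exc(z)·C(z)·E(z) dz` and monotone inversion of
  R into a photosensitizer penetration depth.
* **`pdtmon.synthetic_data`** — synthetic decay series, dual-wavelength
  image sessions, and ordinal edema-outcome tables with the qualitative
  structure the analysis assumes.
* **`pdtmon.pipeline` / the `pdtmon` CLI** — end-to-end runs with
  provenance, and regime × timepoint outcome summaries.

## Worked example

```python
from pdtmon import RunConfig, run_monitoring_pipeline

cfg = RunConfig(seed=1, synth_preset="pdt_b", regime="PDT_b50",
                mc_photons=200_000)
rep = run_monitoring_pipeline(cfg)
```

On the synthetic blue-light 50 J/cm² session this prints (see
`pipeline.RunReport`):

```text
regime          : PDT_b50
PE 405 / 660 nm : 42.3% / 36.2%
alpha 405 nm    : 0.0110 (J/cm2)^-1
alpha 660 nm    : 0.0090 (J/cm2)^-1
ratio trend     : rising  (R: 0.90 -> 0.99)
depth estimate  : 0.10 mm (out of curve range: True)
absorbed total  : 405 nm 0.801, 660 nm 0.512
top-skin share  : 405 nm 0.86, 660 nm 0.68
```

Reading: after 50 J/cm² the 405-nm-excited signal dropped 42.3% (the ~40%
level regarded as a successful procedure), the fitted rates recover the
generating preset (0.011/0.009 (J/cm²)⁻¹), and the red-to-blue ratio rises
— the signature of superficial bleaching under blue light. 86% of the
absorbed 405-nm energy stays in the top skin layer versus 68% at 660 nm.
The depth estimate is clamped and flagged because the uncalibrated forward
curve (instrument constant κ = 1) sits above the measured ratio range; see
`docs/methods.md`.

The same run from the shell:

```bash
pdtmon run --config run.yaml --out results/
pdtmon mc --wavelength 405 --photons 1000000 --seed 1 --out dose405
pdtmon synth images --preset pdt_r --seed 3 --out session/
pdtmon bleach --images session/manifest.csv --out fit
```

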