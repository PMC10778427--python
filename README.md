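# tumoxmap

Quantitative MRI mapping of brain-tumor hypoxia and microvasculature,
packaged as a fully testable pipeline driven by a synthetic ground-truth
phantom.

Brain tumors outgrow their vascular supply and become hypoxic, which
drives aggressiveness and treatment resistance. Two MRI approaches probe
this non-invasively:

* **sqBOLD (streamlined quantitative BOLD)** fits FLAIR-ASE data — an
  asymmetric-spin-echo acquisition with shifts
  τ ∈ {0, 16, 20, …, 60} ms — to a piecewise log-signal model

  ```
  ln S(τ) = ln S₀ − R₂·TE − 0.3·(R₂′·τ)²/DBV      τ < τc
  ln S(τ) = ln S₀ − R₂·TE + DBV − R₂′·τ           τ ≥ τc   (τc = 16 ms)
  ```

  yielding the reversible relaxation rate R₂′ and deoxygenated blood
  volume DBV, and from them the oxygen extraction fraction

  ```
  OEF = 3·R₂′ / (4π·γ·B₀·Δχ₀·Hct·DBV)
  ```

  (γ = 267.5×10⁶ rad T⁻¹ s⁻¹, B₀ = 3 T, Δχ₀ = 0.264 ppm, Hct = 0.4).

* **DSC vessel-size imaging** converts paired gradient-echo/spin-echo
  bolus-passage series into ΔR₂*(t) and ΔR₂(t), integrates ΔR₂* over the
  bolus (trapezoid, normalized to contralateral white matter) for CBV,
  applies the Boxerman–Schmainda–Weisskoff leakage correction where the
  blood–brain barrier is disrupted, and estimates mean vessel caliber
  with the Kiselev model:

  ```
  vessel size = 0.867·(CBV·ADC)^½ · ΔR₂*peak / ΔR₂peak^(3/2)
  ```

Downstream, the package selects biopsy targets as percentile-defined
clusters (above the 80th / below the 20th percentile, ≥ 9 voxels,
edema excluded), quantifies histology (vessel density, mean vessel
diameter, HIF-1α H-score), and compares MRI with histology using
Kruskal–Wallis, Mann–Whitney and Spearman tests.

Because clinical scans of this kind are rarely shareable, every raw
input is generated by the `phantom` module with known ground truth, so
each stage is verified by parameter recovery. See `docs/methods.md` for
model assumptions and design choices.

## Worked example

```python
import numpy as np
from tumoxmap import phantom, qbold, dsc_vsi

# build a ground-truth phantom and simulate a FLAIR-ASE acquisition
truth = phantom.build_phantom(phantom.PhantomSpec(seed=1))
ase = phantom.simulate_flair_ase(truth)

# fit the sqBOLD model and flag failure voxels
maps = qbold.fit_qbold(ase, method="loglinear")
for name in ("contra_GM", "enhancing", "necrosis"):
    m = truth.region_mask(name) & ~maps.error_mask
    print(f"{name:10s}  R2' = {np.median(maps.R2prime[m]):5.2f} /s   "
          f"DBV = {100*np.median(maps.DBV[m]):5.2f} %   "
          f"OEF = {100*np.median(maps.OEF[m]):6.2f} %")

# DSC -> leakage-corrected CBV and vessel size
dsc = phantom.simulate_dsc(truth)
dwi = phantom.simulate_dwi(truth)
perf = dsc_vsi.perfusion_pipeline(
    dsc, dwi, np.array([0., 10., 1000.]), truth.region_mask("contra_WM"),
    brain_mask=truth.brain_mask)
enh = truth.region_mask("enhancing")
print(f"enhancing   CBV = {np.median(perf.CBV[enh]):.2f}  "
      f"vessel size = {np.nanmedian(perf.vessel_size[enh]):.1f} um  "
      f"K2 = {np.median(perf.K2[enh]):.3f}")
```

Output:

```
contra_GM   R2' =  5.13 /s   DBV =  4.30 %   OEF =  33.61 %
enhancing   R2' =  7.90 /s   DBV =  6.44 %   OEF =  34.56 %
necrosis    R2' =  7.36 /s   DBV =  6.72 %   OEF =  30.85 %
enhancing   CBV = 1.78  vessel size = 25.7 um  K2 = 0.020
```

On this noiseless phantom every recovered value equals its ground truth:
the gray-matter R₂′ = 5.13 s⁻¹ and DBV = 4.30 % are exactly the painted
region parameters, the OEF values follow from the formula above, the
enhancing-region CBV of 1.78 (relative to contralateral WM) and vessel
size of 25.7 µm are recovered despite the injected contrast-leakage term,
whose coefficient K₂ = 0.020 s⁻¹ the BSW fit returns exactly.

The full chain also runs from the shell:

```bash
tumoxmap run --out runs/demo --seed 5
```

which writes NIfTI maps (`R2prime`, `DBV`, `OEF`, `CBV`, `vessel_size`,
`error_mask`, `K2`, `ADC`), `targets.csv`, `histology.csv`,
`stats.json`, plots, and a provenance manifest. Subcommands
`simulate`, `qbold-fit`, `vsi`, `histology-quant` and `stats` expose the
individual stages for externally supplied data.

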