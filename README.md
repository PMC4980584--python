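# icaperf

Automatic arterial-input-function (AIF) determination and quantitative
cerebral blood flow (CBF) for dynamic susceptibility contrast (DSC) MRI.

Quantitative perfusion from a DSC bolus passage stands or falls with the
AIF. Sampling it *inside* a large artery suffers flow artifacts, signal
saturation and a relaxivity that differs from tissue; sampling it by hand
in the tissue *around* the artery is subjective and confounded by partial
volume. `icaperf` implements the data-driven alternative: spatial
independent component analysis (ICA) of the dynamic series separates the
arterial, perivascular and parenchymal responses into component maps; the
map of interest is standardized into a z-map, the 50 voxels of largest z
form the AIF region, and the AIF is their z-weighted average,

    AIF(t) = (1/n) Σᵢ Qᵢ·Sᵢ(t),   Qᵢ ∝ zᵢ,  mean(Q) = 1,

which reduces to the plain region average under uniform weights. CBF then
follows from truncated-SVD deconvolution of the dilution relation
`C_t = F·(C_a ⊛ R)` with an adaptive truncation threshold chosen by a
residue-smoothness (oscillation-index) criterion, and the standard
hematocrit/density scaling to mL/100 g/min.

The package ships a physics-based synthetic phantom (three compartments
with 0.5 partial-volume strips, static-dephasing and diffusional-narrowing
relaxation regimes, CNR-controlled noise) so the whole chain is testable
end to end with ground truth. See `docs/methods.md` for the models,
parameter defaults and their rationale.

## Worked example

```python
import numpy as np
from icaperf import PerfusionICA, PhantomSpec, build_phantom

series, truth = build_phantom(PhantomSpec(cnr=50.0, seed=1))
model = PerfusionICA(series, n_components=10)
results = model.fit(seed=1)
print(results.summary())

maps = results.perfusion(source="surround", mask=truth.mask_tissue)
print("parenchymal CBF (surround AIF): %.1f +/- %.1f mL/100g/min"
      % (np.nanmean(maps.cbf), np.nanstd(maps.cbf)))
```

prints

```
   PerfusionICA results
==========================
      quantity       value
--------------------------
         time points    80
              voxels   189
      ICA components    10
                seed     1
    artery component     0
  surround component     2
      artery TTP (s) 16.02
    artery onset (s) 10.50
     artery FWHM (s) 17.17
  artery peak height 517.9
    surround TTP (s) 18.09
  surround onset (s) 10.50
   surround FWHM (s) 19.27
surround peak height 162.7
--------------------------
parenchymal CBF (surround AIF): 469.5 +/- 63.9 mL/100g/min
```

The summary reads as a candidate-AIF feature table: the arterial component
peaks earlier, narrower and three times higher than the perivascular one —
the hemodynamic signature used to rank components. The CBF number carries
the phantom's arbitrary relaxivity scale (the susceptibility phantom does
not fix a true flow; quantitative flow recovery is validated on the linear
dilution forward model, where known flows are recovered within 5%
noise-free).

Clinical-style 4D NIfTI series are loaded with
`PerfusionICA.from_nifti("series.nii.gz", te=0.06)` (TR from the header,
first dummy frames dropped via `read_dynamic_series(..., discard_first=3)`),
with `variance_fraction=0.99` selecting the component count from the
eigenvalue spectrum.

## Command line

```bash
icaperf simulate --cnr 30 --seed 7 --out phantom.nii.gz --truth truth.json
icaperf extract-aif --config run.yaml        # ICA, AIFs, features, CBF maps
icaperf quantify    --config run.yaml
icaperf evaluate    --n-realizations 50      # ideal-AIF flow sensitivity
icaperf sweep       --cnrs 30,40,50,60,70    # segmentation accuracy grid
```

Every run writes AIF curves (CSV + JSON provenance), a bolus-feature
table, CBF maps (NIfTI) and a report embedding the configuration hash; a
YAML config with a single seed drives all stages, and unknown keys are
rejected.

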