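# ivimprefmap

Voxel-wise intra-voxel incoherent motion (IVIM) and apparent diffusion
coefficient (ADC) model fitting for diffusion-weighted MRI, with
corrected-Akaike (AICc) model-preference mapping, the `p_IVIM` biomarker,
the perfusion-bias statistic δADC, and the repeatability/longitudinal
statistics needed to validate these biomarkers (within-subject CV,
repeated-measures correlation, repeated-measures ANOVA).

It is written for quantitative-imaging researchers who want a tested,
reproducible implementation of the whole analysis chain — from a 4D DWI
stack plus b-value table to per-ROI biomarker tables and statistics —
together with digital phantoms that make every stage testable without
any clinical data.

## Models

The DW signal at diffusion weighting *b* (s/mm²) is modelled either as a
mono-exponential decay

    S(b) = S0 · exp(−b · ADC · 10⁻³)

or as the bi-exponential IVIM decay

    S(b) = S0 · [ f · exp(−b · D* · 10⁻³) + (1 − f) · exp(−b · D · 10⁻³) ]

with tissue diffusivity *D*, perfusion signal fraction *f* and
pseudo-diffusion coefficient *D\**, all diffusivities in µm²/ms.  IVIM is
fitted with a segmented approach: a log-linear fit on b ≥ b\* gives *D*
and, via the extrapolated intercept, *f*; a bounded 1-D least squares
then estimates *D\**; the cut-off b\* is swept over candidates and the
fit with the lowest full-curve sum of squared residuals wins.  Two ADC
maps are produced: ADC_b0 (all b) and ADC_b150 (b ≥ 150 s/mm², which
suppresses perfusion).

Per voxel the two models are compared through

    AICc = n ln(SSR/n) + 2k + 2k(k+1)/(n−k−1)

(k = 2 for ADC, 4 for IVIM), and the model with the lower AICc is
"preferred".  Derived biomarkers per region of interest: medians of
D, f, ADC_b0, ADC_b150 (whole-ROI and preference-conditioned subsets),
`p_IVIM` — the fraction of valid ROI voxels preferring IVIM — and
δADC = median voxel-wise (ADC_b0 − ADC_b150), which grows with perfusion.

## Worked example

```python
from ivimprefmap.synthetic_phantom import two_region_spec, generate_phantom
from ivimprefmap.voxel_fitting import fit_volume
from ivimprefmap.model_selection import build_preference_map
from ivimprefmap.roi_biomarkers import summarize_roi

spec = two_region_spec((16, 16, 2), snr_b0=50, noise_model="rician", seed=7)
vol, mask, truth = generate_phantom(spec)
maps = fit_volume(vol)
pref = build_preference_map(maps)
for label, name in [(1, "fluid"), (2, "tissue")]:
    s = summarize_roi(maps, pref, mask, label,
                      voxel_volume_mm3=vol.voxel_volume_mm3, roi_name=name)
    print(f"{name:7s} p_IVIM={s.p_ivim:.3f}  D={s.median_D:.3f}  "
          f"f={s.median_f:.3f}  ADC_b0={s.median_ADC_b0:.3f}  "
          f"ADC_b150={s.median_ADC_b150:.3f}  dADC={s.median_delta_adc:.3f}")
```

prints

```
fluid   p_IVIM=0.000  D=2.996  f=0.005  ADC_b0=3.001  ADC_b150=3.014  dADC=-0.013
tissue  p_IVIM=0.996  D=1.311  f=0.190  ADC_b0=1.616  ADC_b150=1.307  dADC=0.304
```

The free-water region (true f = 0, D = 3.0) is almost never assigned the
IVIM model and shows no ADC bias, while the perfused-tissue region
(true f = 0.19, D = 1.3, D\* = 30) prefers IVIM in essentially all
voxels, recovers D and f closely, and shows the perfusion-driven
elevation of ADC_b0 over ADC_b150.

## Command line

```bash
ivimprefmap simulate --preset two_region --shape 32,32,4 --snr 50 \
    --noise rician --seed 314 --out-dir phantom/
ivimprefmap fit --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
    --mask phantom/mask.nii.gz --out-dir maps/
ivimprefmap summarize --maps-dir maps/ --dwi phantom/dwi.nii.gz \
    --bval phantom/dwi.bval --mask phantom/mask.nii.gz --out-dir summary/
ivimprefmap stats --table summary/biomarkers.csv --out-dir stats/
```

Each stage writes a `manifest.json` (config echo, seed, version, input
checksums); reruns with the same seed are byte-identical.

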