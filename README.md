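# mmseg — semi-automatic myeloma lesion segmentation on whole-body DWI

Multiple myeloma (MM) seeds dozens of focal lesions throughout the
skeleton. On whole-body diffusion-weighted MRI (WB-DWI) they are bright at
high b-value; on T1-weighted imaging they sit at or below muscle signal.
Manually outlining every lesion across a whole-body stack is so slow and
variable that inter-reader agreement is poor, yet total lesion burden and
its apparent diffusion coefficient (ADC) are exactly the quantities one
wants for treatment-response assessment.

`mmseg` implements an atlas-guided, semi-automatic detector of MM lesions
for that setting, aimed at imaging scientists and radiology research
groups working with WB-MRI:

1. **Search region** — a population DWI template with pre-drawn masks of
   the normally hyperintense organs (spleen, kidneys, spinal cord,
   bladder, testes) and of a band around the skeleton is registered to the
   patient (rigid → affine → B-spline free-form deformation, mutual
   information); the warped skeleton band dilated by 6 mm minus the warped
   organs dilated by 4 mm is where lesions are searched.
2. **Outlier threshold** — inside that region, candidate voxels satisfy

   `I ≥ Q3 + k·(Q3 − Q1)`

   with Q1, Q3 the region's intensity quartiles and `k` a per-patient dial
   (default 4, typical range 2.5–7.5). Candidates are grouped into 3-D
   connected components, one per putative lesion; no size criterion is
   ever applied.
3. **T1 false-positive filter** — the T1w volume is rigidly aligned to the
   b0 DWI; any component whose voxels are, at a fraction ≥ `pct_cutoff`
   (default 0.90), brighter than the mean psoas-muscle intensity is
   discarded (MM lesions are T1-hypointense relative to low-fat muscle).
4. **Quantification & validation** — per-lesion ADC
   (`ADC = −ln(S_i/S_0)/(b_i − b_0)`, mm²/s) histogram metrics (median,
   mean, 5th/25th/75th/95th percentiles, skewness, kurtosis) and volume;
   Dice agreement; lesion-level sensitivity and PPV against a 3-of-4
   majority-vote reader gold standard; ICC(2,1) for paired measurements.

The package also contains the iterative mean-template atlas builder
(register-all → average → repeat, with a representative first template and
mean-displacement re-centering) and a synthetic whole-body phantom
generator — paired DWI/b0/T1 volumes with ground-truth masks, Rician
noise, and an exact mono-exponential ADC forward model — so the complete
pipeline is testable without any imaging data. See `docs/methods.md` for
the full model description and conventions.

## Worked example

Everything below runs on synthetic data generated on the fly. First make
an atlas bundle — in production `mmseg build-atlas` constructs the mean
template from a cohort and bundles it with the organ/skeleton drawings;
for a quick demo the lesion-free phantom anatomy and its truth masks serve
directly:

```sh
mmseg phantom --out-dir demo/anatomy --seed 0 --n-lesions 0 --noise-sigma 0
mkdir -p demo/atlas
cp demo/anatomy/dwi_high.nii.gz      demo/atlas/template.nii.gz
cp demo/anatomy/organ_mask.nii.gz    demo/atlas/organs.nii.gz
cp demo/anatomy/skeleton_mask.nii.gz demo/atlas/skeleton.nii.gz
```

Then make a subject with four planted lesions and run the detector (the
`desk` preset uses the reduced registration settings appropriate for these
small volumes):

```sh
mmseg phantom --out-dir demo/patient --seed 11 --n-lesions 4
mmseg run --dwi-high demo/patient/dwi_high.nii.gz \
          --dwi-b0   demo/patient/dwi_b0.nii.gz \
          --t1       demo/patient/t1.nii.gz \
          --atlas-dir demo/atlas --psoas demo/patient/psoas_mask.nii.gz \
          --k 4.0 --preset desk --out-dir demo/out
```

    4 lesions (threshold 132.2) -> demo/out

`demo/out/provenance.json` records what happened: the search region held
12336 voxels with quartiles Q1 = 96.4 and Q3 = 103.5, so the k = 4 outlier
rule put the threshold at 132.2; 4 candidate components survived the T1
filter (psoas reference mean 164.7). Scoring the result against the
ground-truth lesion mask:

```sh
mmseg validate --pred demo/out/lesions.nii.gz \
    --readers demo/patient/lesion_mask.nii.gz --readers demo/patient/lesion_mask.nii.gz \
    --readers demo/patient/lesion_mask.nii.gz --readers demo/patient/lesion_mask.nii.gz \
    --out demo/out/metrics.json
```

(here the four "reader" masks are all the ground-truth mask, so the
majority vote is the truth itself; with real reader files each `--readers`
argument is one radiologist's segmentation)

    sensitivity=1.0 ppv=1.0 (4/4 GS detected, 4/4 predictions correct)

i.e. all four planted lesions were found and every predicted component was
a true lesion. `mmseg adc` then writes the ADC map and the per-lesion
histogram report, and `mmseg build-atlas` / `mmseg build-search-region`
expose the atlas stages individually.

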