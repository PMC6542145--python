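# liverdki

Quantitative diffusion analysis of multi-b-value liver DWI for small
hepatocellular carcinomas (HCC) treated by radiofrequency ablation (RFA):
simulation of realistic two-timepoint patient cohorts, voxel-wise fitting of
diffusion-kurtosis and mono-exponential signal models, lesion ROI
measurement under a radiologist-style protocol, and ROC-based evaluation of
the resulting imaging markers as predictors of tumour recurrence.

## Who this is for

Researchers developing or validating quantitative diffusion biomarkers
(ADC, MD, MK) for treatment-response prediction who need a fully synthetic,
seeded test bed: no patient data is required — the package generates
digital phantoms whose ground truth is known, runs the entire measurement
chain on them, and evaluates how well each marker separates recurring from
non-recurring lesions.

## The models

Diffusion kurtosis imaging (DKI) describes non-Gaussian water diffusion by
a quadratic correction to the log-signal decay:

    S(b) = S0 · exp(−b·D + b²·D²·K/6)

where `b` is the diffusion weighting (s/mm²), `D` the corrected diffusivity
(mm²/s; reported as mean diffusivity MD at lesion level) and `K` the
apparent kurtosis (unitless; reported as mean kurtosis MK, an index of
microstructural complexity).  The conventional apparent diffusion
coefficient comes from the mono-exponential model

    S(b) = S0 · exp(−b·ADC)

fitted from b = 0 and 800 s/mm² only.  On noiseless kurtosis-model signal
the two-point ADC obeys the exact identity `ADC = D·(1 − b·D·K/6)`, hence
ADC < MD whenever K > 0.

The default acquisition is the four-shell scheme b = 0, 800, 1500,
2000 s/mm².  Estimation is a log-domain quadratic least-squares fit (exact
on noiseless data) with an optional box-constrained non-linear refinement
in the signal domain; estimates are kept in a physiological box
(D ∈ (1e−6, 5e−3) mm²/s, K ∈ [0, 3]) with every clamp flagged.

Marker evaluation uses the empirical ROC curve, its trapezoidal AUC
(= concordant-pair fraction), the Youden index J = sensitivity +
specificity − 1 for cutoff selection, Hanley–McNeil standard errors with
normal 95% CIs, DeLong's paired test for comparing two markers' AUCs on the
same patients, and paired / Welch t-tests for group comparisons.
Recurrence is defined by strict >20% growth of the longest lesion diameter
after ablation; recurrent lesions show lower ADC/MD and higher MK one month
after treatment.

## Worked example

Simulate a 107-patient cohort (71 recurrences), fit parameter maps from
the Rician-noise signal stacks, extract the three-ROI lesion means, and
evaluate the post-ablation markers:

```python
from liverdki.pipeline import RunConfig, run_pipeline
from liverdki.phantom import CohortSpec

cfg = RunConfig(seed=42, out_dir="results/example",
                cohort=CohortSpec(n_patients=107, seed=42))
report = run_pipeline(cfg)
s = report["statistics"]
print(f"patients: {s['n']}  recurrence: {s['n_recurrence']}  "
      f"non-recurrence: {s['n_nonrecurrence']}")
for marker in ("adc", "md", "mk"):
    roc = s["roc"]["post"][marker]
    y = roc["youden"]
    print(f"post-RFA {marker.upper():3s}  AUC {roc['auc']:.3f} "
          f"(95% CI {roc['ci'][0]:.3f}-{roc['ci'][1]:.3f})  "
          f"J {y['j']:.3f}  sens {y['sensitivity']:.3f}  spec {y['specificity']:.3f}")
```

prints

```
patients: 107  recurrence: 71  non-recurrence: 36
post-RFA ADC  AUC 0.991 (95% CI 0.976-1.000)  J 0.944  sens 0.972  spec 0.972
post-RFA MD   AUC 0.986 (95% CI 0.967-1.000)  J 0.902  sens 0.930  spec 0.972
post-RFA MK   AUC 0.951 (95% CI 0.913-0.990)  J 0.859  sens 0.859  spec 1.000
```

Each post-ablation marker separates the groups strongly (pre-ablation AUCs
hover near 0.5, as intended — the groups are configured to differ only
after treatment).  The ROC block also carries the Youden-optimal cutoff on
the marker's own scale; `results/example/` holds the per-patient cohort
table (CSV), the ROI definitions (JSON) and the full report (JSON).  Note
that the simulated ADC inherits most of the MD/MK information through the
kurtosis model (see `docs/methods.md`), so its in-silico AUC is optimistic
relative to a separately acquired clinical ADC.

The same pipeline runs from the command line:

```bash
liverdki run --config configs/default.yaml --seed 42 --out results/example
liverdki simulate --n 4 --seed 1 --out results/sim     # cohort + NIfTI stacks
liverdki fit --volume dwi.nii --bvals bvals --out maps/  # maps from your own data
liverdki validate --config configs/default.yaml
```

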