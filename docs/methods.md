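# Methods

## Signal models and estimation

Per voxel, the diffusion signal over the b-value scheme (default 0, 800,
1500, 2000 s/mm²) follows the kurtosis representation
`S(b) = S0·exp(−b·D + b²·D²·K/6)`; the mono-exponential ADC is defined from
the b = 0 and b = 800 points of the same acquisition.  Kurtosis here is
isotropic — one D and one K per voxel from trace-weighted signal; no
directional (tensor) kurtosis is modelled.

The reference estimator is unweighted least squares on
`ln S(b) = c0 − c1·b + c2·b²`, mapping `S0 = exp(c0)`, `D = c1`,
`K = 6·c2/D²`.  It is exact on noiseless data (the three coefficients are
identified by three distinct shells; the fourth shell is redundant without
noise) and has a closed form, which makes round-trip testing sharp.  An
optional refinement minimises the signal-domain residual
`Σ_b (S_obs − S_model)²` by box-constrained Levenberg–Marquardt
(`scipy.optimize.least_squares`), started from the log-linear solution; it
never returns a worse objective than its start (the start is returned,
flagged, if the optimiser fails to improve).

Numerical safeguards, all flagged and never silent:

* signals ≤ 0 are clipped to `1e−6·S(0)` before the log (`noise_floor`);
* a non-positive fitted diffusivity marks the voxel invalid
  (`nonphysical_d`), as does a non-positive two-point ADC
  (`nonpositive_adc`) — invalid voxels are NaN in the maps and excluded
  from the validity mask, never zeroed;
* estimates are clamped to the physiological liver box
  D ∈ (1e−6, 5e−3) mm²/s, K ∈ [0, 3], chosen to stop noise-driven
  blow-up of `K = 6c2/D²` at small D.

### Known estimator behaviour

At clinically realistic SNR (≈50 at b = 0 against the liver background),
the voxel-wise kurtosis estimate is left-skewed: its median is nearly
unbiased (within ~2%), but its mean — and therefore the mean over an ROI
of the MK map — reads roughly 4–9% low depending on the tissue regime
(the effect grows as the b = 2000 signal approaches the noise floor, i.e.
at high D).  Diffusivity and ADC means are unbiased to well under 1%.  The
non-linear refinement roughly halves the kurtosis skew (to ≲3.5% across
the regimes used here).  This is a property of the estimator under
magnitude (Rician) noise, not a bug; analyses that compare group means of
MK should expect it, and the end-to-end recovery test uses the refined fit
for that reason.

## Synthetic phantoms and cohorts

A phantom is a piecewise-constant sphere (disk in the default planar mode)
of diameter 1–3 cm — the inclusion window for early-stage single HCC — in
a liver-like background (S0 = 1000, D = 1.4×10⁻³ mm²/s, K = 0.9), with an
optional concentric necrotic core (D = 2.2×10⁻³, K = 0.2) representing the
ablation zone at the post-treatment timepoint.  Signal is generated by the
kurtosis forward model; Rician noise forms
`sqrt((S+n₁)² + n₂²)` with `n₁,n₂ ~ N(0, σ)`, `σ = background S0 / SNR`
(default SNR 50); Gaussian and noise-free modes exist for testing.

A cohort draws, per patient and timepoint, lesion MD and MK from
truncated normal distributions around group means; the defaults are the
published post-ablation separation (recurrence: ADC 1.092, MD 1.251
×10⁻³ mm²/s, MK 0.678; non-recurrence: 1.486, 1.837, 0.424) and the
near-identical pre-ablation values.  Group standard deviations are not
published; the default is 15% of each mean, which yields the imperfect
sensitivities/specificities typical of the clinical setting.  Group sizes
are quota-sampled (`round(n·fraction)` recurrences) so the canonical
107-patient cohort splits exactly 71/36.

The synthetic "true ADC" follows the model link `MD·(1 − b·MD·MK/6)` at
b = 800, rescaled per group so its mean equals the configured ADC mean,
plus 2% independent relative jitter.  This preserves the model-implied
ADC < MD ordering and a realistic ADC–MD–MK correlation while matching the
published group means.  One caveat follows: because image stacks are
generated from the kurtosis model alone, the *measured* two-point ADC is
exactly the link value — the pipeline's in-silico ADC therefore carries
most of the MD/MK information and its AUC is optimistic compared with an
ADC from a separate DWI acquisition.  Cohort-level marker comparisons
(e.g. the MK-vs-ADC replicate test) are made on the drawn marker values,
where the calibrated means apply.

Baseline diameters are truncated-normal (1.81 ± 0.83 cm within [1, 3] cm);
follow-up diameters multiply the baseline by a uniform growth ratio of
1.25–1.80 (recurrence) or 0.50–1.15 (non-recurrence), so the strict >20%
growth rule reproduces the simulated labels exactly.  Post-treatment
phantoms clip the follow-up diameter back into the grid-safe [1, 3] cm
window and carry a necrotic core of half the lesion diameter.  All
randomness descends from one master seed via `numpy` seed sequences; equal
spec + seed gives bit-identical output.

What the generator does **not** emulate: liver texture, partial-volume
edges, respiratory motion, field inhomogeneity, vessels/bile ducts, and a
separate ADC acquisition.  Passing tests therefore validate the estimation
and evaluation machinery, not robustness to those real-data effects.

## ROI protocol

Three planar circular ROIs per lesion, each nominally 1.0–2.5 cm², placed
in viable tissue only (lesion minus necrosis); per marker the reported
value is the average of the three ROI means of the voxel-wise map.  The
automatic placement computes an exact Euclidean distance transform of the
viable region per slice; the common radius is the largest allowed by the
area window that still admits three distinct centres (third-largest
distance value), and centres are chosen greedily for spread with seeded
tie-breaking.  If even 1.0 cm² does not fit — common for small lesions or
large cores — the radius shrinks to the largest feasible one and the
measurement is flagged as a protocol deviation rather than rejected.
ROI membership uses voxel centres strictly inside the radius, which
together with the distance-transform bound guarantees no ROI voxel touches
necrosis or leaves the lesion.  Exclusion of tissue "adjacent to vessels
or bile ducts" has no synthetic analogue and is not modelled; the
two-reader protocol is reduced to one seeded placement (a second seed can
stand in for a second reader).  The lesion diameter is the maximum caliper
extent of the mask (convex-hull pairwise distance plus one voxel pitch).

Open choice resolved: the per-lesion value is the mean of the three ROI
means (not the pooled-voxel mean); for equal-sized ROIs the two coincide.

## Statistics

Markers are oriented by fixed polarity — MK greater-is-positive, ADC and
MD smaller-is-positive, per the known biology — rather than auto-detected
(auto-detection exists behind `infer_polarity`).  The empirical ROC
enumerates every distinct cutoff with ties grouped; AUC is the trapezoidal
area, identical to the Mann–Whitney concordant-pair fraction with half
credit for ties.  The Youden-optimal cutoff maximises J; ties break toward
the higher-specificity operating point (conservative recurrence calling).
Single-AUC uncertainty uses the Hanley–McNeil variance with
`Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)` and a normal 95% CI clipped to [0, 1];
paired AUC comparison uses DeLong placement values with midranks.  These
choices mirror common clinical-statistics defaults; the source analyses do
not specify their methods.  Paired (pre vs post) and Welch two-sample
t-tests delegate to scipy with explicit zero-variance handling (t = 0,
p = 1 for all-zero differences; t = ±∞, p = 0 for zero-variance nonzero
shifts).  No multiple-testing correction is applied, matching the original
analysis design.

## Pipeline

`run_pipeline` executes simulate (or load) → fit → ROI → statistics and
writes `cohort.csv`, `rois.json` and `report.json` under the output
directory; the report embeds the full configuration, a short SHA-256
config hash, package versions and the master seed, and contains no
timestamps, so a rerun with the same config and seed is byte-identical.
Map fitting inside the pipeline is restricted to the lesion mask (the only
voxels the ROI statistics consume); the standalone `fit` CLI fits whole
volumes.  Load mode consumes a `manifest.csv` of NIfTI volume/mask paths
with group labels and diameters plus an FSL-style `bvals` file.  The
follow-up schedule is collapsed to two timepoints (baseline and one month
post-ablation) because those are the ones the evaluation uses; further
timepoints would enter as extra `timepoint` values in the cohort table.
A stage failure aborts with a stage-tagged error after writing the report
with `status: incomplete:<stage>`.

Default problem sizes — a 64×64 planar grid at 1.5 mm spacing, 107
patients, and a single axial slice per scan — keep a full cohort run
around a second while leaving ≥20 voxels per ROI; the 3-D mode exists for
geometry realism where needed.

## Limitations

* Isotropic kurtosis only; no tensor metrics, no registration, no motion
  or eddy-current correction.
* The synthetic ADC is model-linked (see above): in-silico ADC performance
  is an upper bound, not a clinical estimate.
* Published pre-ablation operating points in the source table are
  internally inconsistent (sensitivity + specificity − 1 does not equal
  the printed Youden index for any reading of the pre rows); only the
  self-consistent post-ablation arithmetic is used as a reference.
* Group SDs, marker correlations and the ADC acquisition's own noise are
  unreported in the source setting; their defaults here are explicit
  synthetic choices, not estimates.
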