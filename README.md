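# y90dose

CT-based voxel dosimetry for yttrium-90 (⁹⁰Y) radioembolization with
radiopaque microspheres.

⁹⁰Y radioembolization delivers beta-emitting microspheres into the
hepatic arterial tree; the absorbed-dose distribution they produce is
conventionally estimated from ⁹⁰Y PET, whose 5–10 mm resolution smooths
away the extreme dose heterogeneity known from histology.  Radiopaque
microspheres make the deposit directly visible on CT at sub-millimetre
resolution.  This package implements the full CT-based dosimetry chain
and the PET-based chain beside it, for medical physicists and imaging
scientists who want to quantify, compare, or simulate both:

* **Calibration** — fit the linear HU–concentration relation
  `HU = m_cal·MS_con + b_cal` on a multi-post calibration phantom
  (ordinary least squares with confidence and prediction intervals),
  with the per-subject intercept `b_cal = μ_bkg + 1.645·σ_bkg` acting as
  a one-sided 95 % detection threshold.
* **Quantification** — invert the calibration per voxel and scale by the
  microspheres-per-milligram, per-sphere activity and voxel volume:
  `A = MS_con · MS_mg · A_MS · V`, giving a Bq activity map and recovery
  coefficients `RC = 100·ΣA/A₀`.
* **Kernels** — ⁹⁰Y dose-voxel kernels (absorbed dose per decay) for any
  voxel geometry by reduced condensed-history Monte-Carlo beta transport
  in water, with a deterministic dose-point-kernel integration as an
  independent cross-check.
* **Dosimetry** — cumulated activity `Ã = A·τ` (permanent implant,
  τ = T½/ln 2, T½ = 64.1 h), zero-padded FFT convolution `D = Ã ⊗ DVK`,
  and the MIRD mono-compartment reference `D = A₀·50·(1−R)/M`.
* **Metrics & statistics** — D_med/D_max/D_μ/σ/COV, cumulative DVHs and
  D70, limit-of-blank/limit-of-detection/minimum-detectable-activity,
  boundary-activity fractions, linear regression, Bland–Altman, ANOVA.
* **Synthetic data** — a first-class generator for the calibration
  phantom and for virtual subjects (ground-truth deposition with paired
  CT and PET), so the whole chain is testable without image downloads.

## Worked example

Calibrate on the synthetic 27-post phantom, quantify a virtual subject,
and run convolution dosimetry (a coarsened 1 × 1 × 2 mm CT grid keeps
this quick; drop `ct_spacing_mm` for the full 0.313 mm grid):

```python
from y90dose import (PhantomSpec, generate_phantom_ct, generate_virtual_subject,
                     fit_calibration, compute_intercept, segment_posts,
                     ct_to_concentration, concentration_to_activity,
                     recovery_coefficient, simulate_dvk, cumulated_activity,
                     convolve_dose, dose_stats, mird_mean_dose)
from y90dose.calibration import BackgroundStats, post_mean_table

spec = PhantomSpec(seed=7)                      # 0.313 x 0.313 x 2.0 mm grid
phantom, posts = generate_phantom_ct(spec)
table = post_mean_table(segment_posts(posts, phantom), phantom)
p15 = table[table.diameter_mm == 15]
curve = fit_calibration(list(zip(p15.concentration_mg_ml, p15.mean_hu)))
print(f"calibration slope: {curve.slope_hu_per_mg_ml:.2f} HU/mg/mL "
      f"(r^2 = {curve.r_squared:.4f})")

subj = generate_virtual_subject(liver_volume_ml=79.0,
                                administered_activity_bq=144.2e6,
                                ct_spacing_mm=(1.0, 1.0, 2.0), seed=3)
bkg = BackgroundStats.from_region(subj.ct, subj.masks["L_bkg"])
b_cal = compute_intercept(bkg)
conc = ct_to_concentration(subj.ct, curve.slope_hu_per_mg_ml, b_cal,
                           mask=subj.masks["L"])
activity = concentration_to_activity(conc, subj.record)
rc = recovery_coefficient(activity, subj.masks["L"], 144.2e6)
print(f"intercept b_cal: {b_cal:.1f} HU;  CT recovery coefficient: {rc:.1f}%")

kernel = simulate_dvk(subj.ct.spacing, histories=100_000, seed=1)
dose = convolve_dose(cumulated_activity(activity), kernel)
rep = dose_stats(dose, subj.masks["L"])
liver_mass_kg = subj.masks["L"].volume_ml * 1.03e-3
d_mird = mird_mean_dose(144.2e-3, 0.0, liver_mass_kg)
print(f"liver dose: mean {rep.d_mean_gy:.1f} Gy, median {rep.d_med_gy:.1f} Gy, "
      f"D70 {rep.d70_gy:.1f} Gy, COV {rep.cov:.2f}")
print(f"MIRD mono-compartment dose: {d_mird:.1f} Gy")
```

Output:

```
calibration slope: 14.12 HU/mg/mL (r^2 = 1.0000)
intercept b_cal: 95.6 HU;  CT recovery coefficient: 81.5%
liver dose: mean 67.8 Gy, median 4.2 Gy, D70 2.0 Gy, COV 2.63
MIRD mono-compartment dose: 88.6 Gy
```

Reading the numbers: the fitted slope recovers the generator's ground
truth (14.13 HU per mg/mL) from noisy, blurred data; the intercept is
the subject's liver background mean plus 1.645 standard deviations;
81.5 % of the administered 144.2 MBq is recovered inside the liver
contour (diffuse deposit below the detection threshold accounts for the
remainder).  The voxel dose distribution is extremely heterogeneous —
median 4 Gy against a mean of 68 Gy (COV 2.6) — which is exactly the
structure the uniform MIRD estimate (88.6 Gy) cannot represent, and the
reason D70 is far below the mean.

A command-line interface mirrors the library:

```bash
y90dose phantom-sim --seed 1 --out phantom.nii.gz --geometry posts.json
y90dose calibrate --volume phantom.nii.gz --geometry posts.json --curve-out curve.json
y90dose subject-sim --seed 1 --out-dir subj/
y90dose quantify --ct subj/ct.nii.gz --curve curve.json \
    --subject subj/subject.json --structures subj/structures.json \
    --activity-out a_ct.nii.gz
y90dose make-kernel --spacing 2.039 2.039 2.039 --histories 1000000 --seed 1 --out dvk.nii.gz
y90dose dose --activity a_ct.nii.gz --kernel dvk.nii.gz --out dose.nii.gz
y90dose metrics --dose dose.nii.gz --structures subj/structures.json --out metrics.csv
y90dose run-all --seed 1 --out-dir study/
```

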