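# Methods

`y90dose` implements CT-based voxel dosimetry for yttrium-90
radioembolization with radiopaque microspheres, alongside the conventional
PET-based route, so the two can be compared on common ground truth.  This
note records the models, the conventions that were genuinely open, and the
limits of what the synthetic tests demonstrate.

## Calibration model

Radiopaque microspheres raise CT attenuation linearly with their mass
concentration over the clinically relevant range:

    HU = m_cal * MS_con + b_cal

`fit_calibration` estimates `m_cal` (HU per mg/mL) by unweighted ordinary
least squares on the mean HU of calibration-phantom posts versus nominal
concentration, with t-based 95% confidence intervals on the slope and 95%
prediction intervals for new posts.  Post means are taken over structures
eroded by 1 mm radially and 5 mm longitudinally to suppress partial-volume
contamination at the post-background and background-air interfaces; 2-mm
posts, which a 1-mm radial erosion would eliminate, are instead replaced
by a centered 1-mm-diameter cylinder.  By default the calibration uses the
15-mm posts only; `slope_by_diameter` exposes the per-diameter analysis,
where imaging blur visibly biases the 2-mm-post slope low.

The intercept is *not* taken from the fit when mapping a subject: it is
the one-sided 95% detection threshold

    b_cal = mu_bkg + 1.645 * sigma_bkg

of a non-embolized background region of that subject's liver, so that a
voxel above `b_cal` has a 95% probability of containing microspheres.
Two different intercepts therefore circulate deliberately:

* **activity mapping** (`ct_to_concentration`) uses the detection
  threshold and clamps sub-threshold voxels to zero concentration — the
  only convention under which structure-level activity sums are stable
  against background noise (the clamp can be disabled for sensitivity
  studies);
* **mass integration** (`recovered_mass_mg`) uses the *fitted* intercept
  and no clamp: a signed enhancement integral is unbiased because
  background noise averages to zero, which is what makes the mass of even
  a 2-mm structure recoverable to ~1% once the contour is expanded beyond
  the blurred boundary.  Using the detection threshold here would bias the
  integral low by ~1.645*sigma per voxel of contour.

## Activity quantification

Concentration maps convert to activity via two microsphere scalar factors
and the voxel volume: `A = MS_con * MS_mg * A_MS * V_voxel`, with defaults
`MS_mg` = 24,460 spheres/mg and `A_MS` = 156 Bq/sphere.  Recovery
coefficients are structure sums divided by the administered activity A0
(assumed net of residuals; a residual fraction field exists for
assay-based A0).  PET concentration grids are post-filtered with a
separable Gaussian (default 4 mm FWHM) and converted to per-voxel Bq by
the voxel volume.  Masks drawn on the CT grid are evaluated on the PET
grid by nearest-center resampling; fractional-volume weighting is not
implemented.

## Dose-voxel kernels

The Y-90 dose-voxel kernel (DVK) is the lattice of absorbed dose per decay
around a source voxel in uniform water, computed by a reduced class-II
condensed-history Monte Carlo:

* **Spectrum** — allowed-shape beta spectrum with the relativistic
  Coulomb (Fermi) correction for the Zr-90 daughter; endpoint 2.28 MeV,
  mean 0.928 MeV (reference value 0.9337 MeV, i.e. within 1%).  The
  internal-pair-production branch (~3e-5) is ignored.
* **Continuous loss** — ESTAR collision stopping powers for liquid water
  (log-log interpolated), restricted by subtracting the Moller tail above
  the 10 keV delta-ray threshold; radiative losses are removed from the
  electron but not scored (bremsstrahlung photons deposit far outside the
  kernel support; ~1% of emitted energy).
* **Delta rays** — explicit Moller secondaries above 10 keV, sampled from
  the leading 1/eps^2 term and transported like primaries.  Electrons
  below 10 keV are deposited locally (residual range 2.5 um).
* **Scattering** — Gaussian multiple scattering per step (Highland), with
  the logarithmic correction evaluated at the electron's residual-range
  scale (applying it per sub-millimetre step would understate the total
  deflection about two-fold), plus a screened-Rutherford single-scattering
  tail for rare large-angle deflections.
* **Scoring** — each step's restricted loss is deposited at a uniformly
  random point along the step (unbiased voxel attribution); source
  positions are uniform in the origin voxel; voxel centers beyond 25 mm
  are zeroed, which also enforces a spherically symmetric support.
  Lattices are odd-sized so the source voxel is the exact center.
* **Uncertainty** — per-voxel relative standard error from the variance
  across independent history batches (default 20).

Validation against published physical constants: the CSDA range
integrates to 11.0 mm at the endpoint, total deposited energy per decay
equals the spectrum mean within 0.1% (bounded above by it), and X90 — the
radius containing 90% of the absorbed dose around a point source — comes
out at ~5.05 mm versus the reference 5.4 mm.

A deterministic cross-check (`dvk_from_dpk`) integrates a radial
dose-point kernel over the voxel lattice.  The default table is the
straight-ahead CSDA kernel computed from the same stopping powers and
spectrum: exact in the r -> 0 limit, energy-conserving by construction,
but with no path detours.  Because the integrand is radial, the energy a
ray deposits between two radii is an exact difference of the cumulative
radial energy, so the integrator has no 1/r^2 singularity at the self
voxel.  Monte-Carlo and oracle central voxels agree to within ~7%
(2.039 mm cube) and ~2% (0.313 x 0.313 x 2.0 mm), which is the expected
model difference, far above Monte-Carlo noise.

**Thin-voxel caveat.**  The central value of a kernel with
sub-millimetre transverse voxel dimensions is pinned from below by
geometry: the mean escape path of an isotropic uniform source in a
0.313 x 0.313 x 2.0 mm voxel is 0.204 mm, and the collision stopping
power of water is never below 0.185 MeV/mm, so any transport model that
deposits restricted collision losses locally yields at least ~38 keV per
decay in that voxel (~3.1e-8 Gy/history).  Delta-ray export, radiative
loss, and scattering-tail ejection adjust this by at most ~15% combined.
Published central-voxel values from full-physics toolkits that fall
substantially below this bound are therefore sensitive to sub-voxel
energy-transport and scoring-attribution detail that a condensed-history
model cannot reproduce; our 2.039-mm-cube kernel, by contrast, matches
the corresponding reference value to a few percent because at that scale
the bound and the reference coincide.

## Convolution dosimetry

Microspheres are permanent implants, so cumulated activity is
`A_tilde = A * tau` with `tau = T_half / ln 2` and `T_half` = 64.1 h
(tau ~ 3.329e5 s); imaging at a single time point suffices.  Dose is the
linear convolution of cumulated activity with the DVK of matching voxel
geometry, computed by zero-padded FFT — *not* circular convolution, since
embolized livers sit near grid edges and wrap-around would alias dose
across the volume.  CT-grid doses use the CT-geometry kernel and PET-grid
doses the PET-geometry kernel; doses are never resampled across grids
(metrics use masks resampled to each grid instead).

The MIRD mono-compartment reference is `D = A0[GBq] * 50 * (1 - R) /
M[kg]`, with the constant kept at its clinical value 50.  The physically
derived value `tau * E_mean * 1.602e-13 * 1e9` is 49.8 Gy kg/GBq, and the
kernel reproduces it: a large uniform activity region converges to
~49.5-49.8 Gy per GBq/kg at the center, the small deficit being the
kernel's unscored radiative energy.  Doses are computed in water
everywhere (the DVK medium); no density scaling is applied.

## Dose metrics and detectability

Conventions fixed where the field leaves them open: voxel-population
standard deviations divide by n (across-subject summaries use n-1); D_x
is the exact order statistic — the largest dose d such that at least x%
of the structure volume receives >= d — with no interpolation, so D70 <=
D_med <= D_max always holds and the cumulative DVH evaluated at D70
returns >= 70%.  Boundary-activity fractions measure, via a physical-unit
distance transform, the activity within a given depth of the structure's
exterior boundary (nearest outside voxel; grid edges count as outside).

Detectability follows the limit-of-blank / limit-of-detection
construction: `LOB = mu + 1.645 sigma` of the background (mu = 0 in
difference-image mode), `LOD_HU = LOB + 1.645 sigma_low` using replicates
of a known low-concentration sample, inverted through the calibration
line and scaled by the microsphere factors to a minimum detectable
activity concentration (MDA, Bq/mL).

## Synthetic data

No image data are distributed with the study this package
operationalizes, so a first-class generator provides ground truth.

The **phantom** reproduces the 27-post geometry (diameters 2-9 mm plus
15 mm; concentrations 0.5 / 5.0 / 25.0 mg/mL; posts 40 mm long on a
100-mm circle in a 150-mm resin background) on the 0.313 x 0.313 x 2.0 mm
acquisition grid.  Post discs are anti-aliased by 4x4 sub-voxel occupancy
sampling (the partial-volume behaviour a reconstruction would show), then
blurred with a Gaussian PSF (default 1 mm FWHM) and given additive
Gaussian noise (default 4 HU, matching observed liver-background
standard deviations of 3-6 HU).

**Virtual subjects** place a branching-tree deposition inside an
ellipsoidal liver (default 79 mL; plausible range of the animal model
65-97 mL; administered activity 128-171 MBq).  Tree segments carry
cumulative lognormal concentration multipliers (sigma 0.5) and the
vessel-bound weight is spread into the surrounding perfusion territory by
a 4-mm Gaussian — microspheres lodge in the capillary bed around
arterial branches, not in the vessel lumen.  These deposition parameters
are the one deliberate calibration in the generator: they were set once
so the quantified CT-grid liver dose COV is ~2-3.5 and the recovery
coefficient ~80-90% (the heterogeneity and recovery scales reported for
this animal model), and are not revisited.  The CT is the forward
calibration model plus a smooth contrast-nonuniformity field (1 HU RMS)
and Gaussian noise; the background region L_bkg is a union of up to three deposit-free
5-mm spheres, because a single region makes the intercept sensitive to
where it lands in the nonuniformity field.  The PET is the truth activity
binned conservatively to a 2.039-mm grid, expressed as Bq/mL, blurred
(default 7 mm FWHM within the reported 5-10 mm system range), and
averaged over a uniform cranial-caudal displacement window (default 5 mm;
observed liver excursions reach 10 mm).  An optional noise term with
positivity truncation mimics the positive bias of low-count PET
reconstruction; it is off by default.

What the generator does **not** emulate: projection-domain CT physics
(beam hardening, artifacts), sinogram-level PET reconstruction (the noise
is neither Poisson nor spatially correlated), real vascular anatomy, and
co-registration error between modalities.  Passing tests therefore
demonstrate the correctness and internal consistency of the quantification
and dosimetry chain on known ground truth — not the clinical accuracy of
CT-based dosimetry on real scans.

## Agreement statistics

Cross-modality comparisons pair the CT mean dose over the liver L with
the PET mean dose over the 1-cm-expanded liver L_shell (the margin
compensates PET resolution and respiratory smearing).  Regression is OLS
with t-based slope CIs; Bland-Altman reports the mean difference and
limits of agreement `bias +/- 1.96 * SD(differences)` (SD with n-1);
ANOVA is the standard one-way decomposition across the CT, PET and MIRD
mean-dose groups.

## Problem sizes

The test suite runs reduced problem sizes chosen for tight feedback:
kernels at 1.2e5 histories (central-voxel relative SE ~0.3%), subjects on
1-1.5 mm grids, the full-geometry phantom once per session.  The
acceptance script uses 1e6 histories per kernel and the full phantom
geometry.  All random draws flow through seeded NumPy generators; results
are bit-reproducible for a given seed.

## Known limitations

* The transport model omits energy-loss straggling, spin-dependent
  scattering corrections, and photon (bremsstrahlung) dose; kernels are
  water-only, with no tissue-heterogeneity correction.
* Thin-voxel kernel central values carry the model-difference budget
  described above; dose distributions convolved from them are dominated
  by the kernel's integral properties, which are conserved to <0.1%.
* The delta-HU calibration variant (difference of registered pre/post
  volumes, background mean forced to zero) is exercised only on synthetic
  data where registration is exact.
* Nearest-center mask resampling can shift structure volumes by up to one
  voxel layer on the coarse grid; recovery coefficients over small
  structures on the PET grid inherit that granularity.
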