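# Methods

`qqoef` implements oxygen-extraction-fraction (OEF) mapping from multi-echo
gradient-echo (mGRE) MRI by the joint QSM+qBOLD ("QQ") model, together with
the synthetic data that exercises it and the cohort-level statistics used to
relate regional OEF to white-matter-hyperintensity (WMH) burden and
cognition in a two-group (AD vs non-AD dementia) design.

## Biophysical models

Each voxel contains a venous blood compartment (volume fraction `v`) and a
non-blood tissue compartment (susceptibility `chi_nb`, ppm). The two routes
of the mGRE signal constrain the same physiology:

**Susceptibility (phase route).**
`chi = (1 - v) chi_nb + v (chi_oxy + OEF * dchi0 * Hct)` — blood becomes
more paramagnetic as more oxygen is extracted. Defaults: `dchi0 = 3.39` ppm
per unit hematocrit (fully deoxygenated minus fully oxygenated blood, SI),
`chi_oxy = -0.03` ppm, `Hct = 0.3567`; all configurable through
`PhysioConstants`. Only the hematocrit is fixed by the in-vivo protocol the
package emulates; the other two are standard literature values.

**Magnitude (qBOLD route), static dephasing regime.**
`S(TE) = S0 exp(-R2 TE) exp(-v f_s(delta_omega TE))` with the
characteristic frequency `delta_omega = (1/3) gamma B0 dchi0 Hct OEF` and

```
f_s(x) = (1/3) * Int_0^1 (2+u) sqrt(1-u) u^-2 [1 - J0(1.5 x u)] du,
```

quadratic (`~0.3 x^2`) for small `x` and asymptotically linear for large
`x`. Because `f_s` sits in the inner loop of the joint fit, it is evaluated
from a cached 2048-knot cubic spline on `x in [0, 50]` (Gauss–Legendre
quadrature at the knots, linear extension above 50). The spline agrees with
adaptive quadrature and a 10^6-panel Riemann sum to better than 1e-5; an
independent quadrature path (`fs_integral_quad`) is kept for verification.

**Phase convention.** `phase = +2*pi*gamma_bar*B0*field_ppm*1e-6*TE + phi0`,
declared once and used by both the simulator and the field fitter. Vendor
sign and `phi0` handling are exposed as arguments rather than guessed.

## Synthetic data

`make_phantom` builds a parametric ellipsoidal brain (matrix >= 32^3):
central CSF ventricles, thalamus/putamen/pallidum nuclei, a cortical
ribbon, WM filler, and WMH lesions seeded half on the ventricle surface
(periventricular) and half in deep WM, grown as spheres until the requested
lesion load (fraction of brain volume) is reached. Tissue parameters are
piecewise constant (per-tissue means: OEF 0.35, v 0.03, R2 12–20 1/s,
chi_nb -0.05…+0.05 ppm, CSF v = 0 and R2 = 1 1/s) and overridable per
tissue. Geometry is deliberately schematic: recovery tests need labels and
known truth, not anatomical realism. The default grid is 48^3 at 2 mm
isotropic — the smallest size that holds all structures with realistic
proportions; acquisition timing follows a 3 T protocol (10 echoes, TE1
6.68 ms, spacing 4.06 ms).

What the phantom does **not** emulate: air-sinus geometry, coil
combination, k-space undersampling, flow, within-tissue parameter texture,
and Rician magnitude statistics at fit time (complex Gaussian noise is
added per channel). Passing recovery tests therefore demonstrate numerical
correctness of the inversion chain under its own forward model, not
robustness to the full physics of patient data.

`simulate_cohort` draws a subject table (defaults 16 AD / 15 non-AD) with
age ~ N(72, 9), MoCA ~ N(19, 4) clipped to [0, 30], log-normal PWMH/DWMH
fractions (their sum is the WMH fraction), and per-ROI OEF generated by the
same linear interaction structure the analysis fits:
`OEF = b0 + b_pred*X + b_group*G + b_int*X*G + b_age*age + eps`. `X` is
MoCA or log WMH per configuration; `tie_to_pwmh` routes the effect through
the periventricular component only, for sensitivity analyses.

## Reconstruction chain

1. **Field mapping.** Temporal unwrapping of echo-to-echo phase increments
   (valid while per-spacing phase advance stays below pi, i.e. |field| <
   ~0.96 ppm at the default spacing; a quality flag reports residual
   spatial wraps); per-voxel WLS slope of phase vs TE (first-echo
   magnitude-squared weights, intercept discarded) converted to ppm. R2*
   by magnitude-squared-weighted log-linear fit; CSF identified as R2* <
   2.5 1/s inside the 3 mm-eroded brain mask. Erosion uses an ellipsoidal
   structuring element with half-axes rounded to voxels, so mm radii work
   on anisotropic grids.
2. **Background removal (PDF).** Susceptibility sources supported outside
   the brain are fitted by CG on the weighted normal equations on a grid
   zero-padded by 40 voxels, capped at 30 iterations. The printed stopping
   "tolerance 0.1" is unitless in the protocol description; it is read
   here as a stagnation ratio — iteration stops once the residual improves
   by less than 10% — because a literal relative-residual reading stops
   after ~3 iterations and leaves ~10% of the background in place.
3. **SMV.** A 5 mm spherical-mean filter removes residual harmonic fields;
   the mask shrinks by the radius. Constants and linear ramps are
   annihilated (<= 1% of range); genuine interior dipole fields retain
   ~45% of their RMS, which downstream inversion accounts for explicitly.
4. **Dipole inversion.** Edge-weighted smoothed-L1 inversion with CSF zero
   referencing: `lambda ||W(D_s * chi - f)||^2 + ||M_G grad chi||_1 +
   lambda_csf ||M_CSF (chi - mean)||^2`, with `lambda = 1000` multiplying
   the data term, `lambda_csf = 100`, `M_G` releasing the strongest 30% of
   magnitude gradients from the TV penalty, and `|x|` smoothed as
   `sqrt(x^2 + 1e-12)`. Two numerical choices matter: the forward operator
   is the **SMV-composed kernel** `D_s = (1 - S) D`, keeping the model
   consistent with the filtered data (inverting the bare kernel shrinks
   recovered contrast by ~half); and Gauss–Newton starts from the
   early-stopped un-regularized least-squares iterate so the IRLS weights
   see realistic gradients (from a zero start the uniform `1/eps` weight
   freezes the solution). Outer iterations cap at 30 with early stop at 1%
   relative step; inner CG at 100 iterations. Because `D(0) = 0`, adding a
   constant to chi never changes the data term, so the final map is
   referenced by subtracting its CSF mean.
5. **VSF.** Macroscopic field variation is modeled as linear within each
   voxel: the across-voxel angular-frequency difference per axis
   (central differences; `order3` averages them over the 3x3x3
   neighbourhood, the least-squares plane-fit gradient) attenuates each
   echo by `prod_axis |sinc(dw TE/2)|`. The correction divides magnitude
   by this factor, floored at 0.1 to bound noise amplification. On the
   phantom the *uncorrected* fit is biased low (the concave log-attenuation
   is absorbed by lowering v·OEF), and the correction restores the true
   mean; the sign of the uncorrected bias is a property of the fit
   parametrization, not of the correction.
6. **QQ-CCTV.** Voxels are clustered by tissue class (GM, WM, WMH from the
   labels) crossed with k-means (default 8 temporal clusters) on
   first-echo-normalized decay curves. The clustering input is smoothed
   spatially by a 1-voxel Gaussian — on piecewise-constant truth, k-means
   on raw noisy curves partitions identical voxels by their noise
   realization, and those noise-selected cluster means bias OEF by several
   points; the fit itself always uses raw data. Per cluster, bounded
   nonlinear least squares runs over (OEF, v) with `chi_nb` and the
   voxel-wise (S0, R2) profiled in closed form (log-domain weighted
   regression after moving the blood-dephasing term across), minimizing
   `w * sum (chi_obs - chi_model)^2 + sum (m_obs - model)^2`. OEF, v and
   chi_nb are shared per cluster; S0 and R2 stay voxel-wise. Stage 2
   alternates a Chambolle TV proximal step on the OEF map (weight `auto`:
   ~10% of the *magnitude* misfit per unit TV at initialization — the QSM
   term carries an irreducible within-cluster floor and is excluded) with
   voxel-wise S0/R2 refits, for 3 rounds. `w` is chosen by L-curve
   (maximum Menger curvature on the log-log residual curve over a 7-point
   grid, ties to the smaller w, geometric mean on degenerate curves) or
   fixed; with per-voxel-normalized scales, `w = 1e7` balances the two
   terms at SNR ~100 and is used by the pipeline default. OEF is reported
   in percent, CSF voxels carry no value.

## ROI and cohort statistics

ROI means erode deep-gray regions by one voxel (face-connected by default)
and skip excluded/NaN voxels. WMH burden is `100 * #WMH / #brain`; the
periventricular/deep split labels 26-connected components and calls a
component periventricular if any voxel is 26-adjacent to the ventricle
surface. Dice is `2|A∩B|/(|A|+|B|)` with the both-empty convention 1.

Regressions build the design `[1, X, G, X*G, age (, mch)]` with G = 1 for
AD, fitted by QR; within-group simple slopes are linear contrasts of the
combined fit (non-AD: `b_pred`; AD: `b_pred + b_int`) with t-based
p-values. Influence uses exact leave-one-out identities — leverage `h_i`,
Cook's `D_i = e_i^2 h_i / (k s^2 (1-h_i)^2)`, DFBETAS with the deleted
variance `s_(i)` — with flags at 4/n, 2(p+1)/n and 2/sqrt(n); flagged rows
are excluded and the model refitted. Natural logs are used for WMH; a zero
WMH fraction under a log predictor raises an explicit error advising an
offset or exclusion. Benjamini–Hochberg is applied across the ROI family
separately per reported p-value column. Wilcoxon rank-sum enumerates the
exact null for combined n <= 12 and otherwise uses the tie-corrected
normal approximation with continuity correction; Fisher's exact test sums
hypergeometric probabilities no larger than the observed table's.

## Problem sizes and tolerances

Reconstruction experiments run at 48^3 (2 mm isotropic); statistical
batteries use 1000 simulated cohorts for the null family-rejection rate,
500 for CI coverage, and 200 for outlier detection and power — sizes at
which the checked proportions have standard errors well inside the asserted
bands. Noiseless closed-loop recovery is asserted to 0.03 OEF per cluster
and 0.05 per tier end-to-end; dipole inversion to 10–15% of the chi dynamic
range; PDF background removal to >= 95% RMS.

## Known limitations

- Cluster-shared (OEF, v, chi_nb) is one defensible reading of
  composition clustering; per-cluster-voxel-wise mixtures are not modeled.
- The L-curve weight is computed per dataset from stage-1 fits only.
- The phantom's piecewise-constant truth favors TV regularization; real
  tissue texture would be smoothed.
- Magnitude bias (Rician) is not modeled at fit time; at SNR >= 100 the
  later-echo bias is negligible for the default protocol.
- Registration, brain extraction and anatomical segmentation are external
  to this package: real-data inputs must arrive co-registered with labels.
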