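# Methods

This note records the models, numerical choices, and known limitations of
`dotdiff`. It is the design rationale a maintainer needs; empirical
claims below are limited to what the test suite and `scripts/acceptance.py`
compute.

## Forward model

Light propagation is modelled by the frequency-domain diffusion equation
in a semi-infinite homogeneous medium. The photon-density wave of a point
source is the image-source solution with an extrapolated boundary:

    g(r, r') = [exp(−k·d1)/d1 − exp(−k·d2)/d2] / (4πD)

with `D = 1/(3(μa+μs′))` (cm), `k² = (μa − iω/c)/D`, `Re(k) > 0`,
`d1` the direct distance, and `d2` the distance to the image of `r'`
mirrored about the plane `z = −zb`. Surface source fibers are replaced by
isotropic sources buried at `z0 = 1/μs′`; the extrapolated distance is
`zb = 2D(1+Reff)/(1−Reff)` with the Fresnel-polynomial
`Reff ≈ 0.493` for `n = 1.333`. The sign convention `Im(k) < 0` makes
unwrapped phase increase with propagation distance; phases are unwrapped
per source along increasing source–detector separation.

Absorbing structures enter through the first-order Born kernel,

    p = − Σ_j g(s, r_j) · g(r_j, d) · δμa_j · V_j / g(s, d),

which is simultaneously the forward perturbation operator and the
reconstruction sensitivity matrix `W` — simulation and inversion share
one kernel by construction (`simulate_with_inclusions(...,
composition="born")` equals `W @ δμa` to machine precision on the same
voxelization).

**Composition.** At the lesion and chest-wall contrasts of the corpus the
Born sums reach magnitudes of 2–3, where the linear composition
`U = U0(1 + Σp)` produces non-physical measurements (negative amplitudes,
relative perturbations below −1). Scene measurements therefore use the
exponential (Rytov) composition `U = U0·exp(Σp)` of the same kernel: it
agrees with Born to first order, keeps amplitudes positive, bounds the
matched perturbation's real part in (−1, 0] (up to a ≤1e-3 AC
interference allowance discussed below), and lets structures shared by
the lesion and reference sides cancel exactly in their ratio.

**Probe.** The clinical probe's source count and coordinates are not
public; the package uses 9 sources (3×3 grid, x ∈ [−3.3, −1.5] cm) and
14 detectors (2×7 grid, x ∈ [1.5, 3.9] cm) on a ~9 cm face with a
central gap for the ultrasound transducer, giving 126 pairs, minimum
separation 3.0 cm, and the 252-wide network interface. Coordinates are
configurable; units are cm, cm⁻¹, radians, Hz, depth = +z.

## Scene corpus

Scenes are drawn uniformly from: target radius 0.375–1.5 cm, center depth
0.6–2.7 cm (strictly buried), target μa 0.08–0.30 cm⁻¹, background μa
0.01–0.06 cm⁻¹, μs′ 4–8 cm⁻¹; optional chest wall (probability 0.5) at
depth 1.6–5 cm, tilt ±10°, μa 0.1–0.2 cm⁻¹; lesion centered in the
ultrasound scan plane (y jitter ±0.25 cm, x ±1 cm). Irregular lesions
perturb a sphere's radius with random `l ≤ 2` spherical harmonics
(amplitude ≤ 25%). Background heterogeneity is a smooth Gaussian random
μa field (correlation ~1.5 cm, peak amplitude uniform in 0–20% of the
background μa), a parametric stand-in for anatomically realistic digital
breasts. Scattering contrast of lesions and wall is *not* modelled — the
forward operator and the inversion are absorption-only.

Measurement noise is 2% multiplicative Gaussian on amplitude plus
0.02 rad additive Gaussian phase noise, applied to the lesion-side
measurement only; the matched reference (the training label's source) is
noise-free. The supervised pair is (noisy normalized `Ul`, noise-free
matched perturbation).

Training inputs are offset-normalized: `log(A·ρ²)` shifted so its maximum
is 0 and the unwrapped phase shifted so its minimum is 0, per measurement
set. Only additive offsets are used, so any global gain (coupling
coefficient, source power) is absorbed without distorting the shape of
either channel.

## Network and training

A 252–256–128–256–252 MLP with ReLU after every affine layer except the
last, implemented directly in numpy (the model is small enough that a CPU
trains it in about a minute; full determinism under a seed is part of the
contract). Initialization is seeded uniform fan-in,
`U(±1/√fan_in)`. Training: MSE loss, Adam (β = 0.9/0.999, ε = 1e-8) with
coupled weight decay 1e-5, learning rate 1e-4, batch 64, 200 epochs; the
learning rate is multiplied by 0.2 whenever the validation loss has not
improved for three consecutive epochs; the returned parameters are the
best-validation checkpoint. A single wavelength-agnostic model is
trained: the corpus property ranges span all four wavelengths' plausible
tissue values, and nothing in the input layout is wavelength-specific.

## Reconstruction

The inverse problem is the Tikhonov-regularized Born system
`min ‖data − Wδμa‖² + λ²‖Sδμa‖²`, solved on the stacked real/imaginary
normal equations by conjugate gradient (zero start, max 200 iterations,
relative tolerance 1e-8; tightened from the conventional 1e-6 so the CG
solution matches the dense closed form to ≤1e-6 relative error).

- **Data.** The inversion consumes the Rytov-linearized data
  `log(1+pert) = log(Al/Ar) + j(φl−φr)`. With saturating perturbations
  (|pert| approaching 1) a linear fit of `pert` itself systematically
  mislocates shallow strong absorbers; the log transform removes the
  saturation and reduces to `pert` in the small-perturbation limit. The
  amplitude ratio is floored at 1e-3 and the phase clipped to ±π/2 —
  no-ops for measured data, guards for network predictions that stray
  past −1.
- **Depth compensation.** `S = diag(‖W column‖^0.5)`. Reflection probes
  concentrate sensitivity directly beneath the optodes; without partial
  column compensation the minimum-norm solution places all absorption at
  the surface. The exponent 0.5 is the standard partial compensation;
  1.0 over-boosts low-sensitivity corners.
- **Regularization.** `λ = 0.02·σmax` of the compensated operator by
  default, configurable. No rule is claimed beyond stability across the
  corpus; it was chosen on inverse-crime localization behaviour.
- **Dual mesh.** Fine voxels 0.25×0.25×0.5 cm inside the lesion ROI
  (snapped outward to the coarse lattice), coarse 1 cm³ voxels elsewhere,
  over an 8×8×4 cm volume under the probe. The ROI comes from the known
  target bounding box + 0.5 cm margin — the synthetic stand-in for
  coregistered ultrasound guidance.
- **δμa** is real-valued (absorption-only); the reported maximum μa is
  `background μa + max δμa` over the fine voxels.

**Background estimation.** `fit_background` estimates bulk (μa, μs′) from
a single measurement by fitting the homogeneous semi-infinite model to
the *shapes* of `log(A·ρ²)` and phase versus separation (per-channel
offsets removed, so coupling coefficients drop out; bounds μa ∈
[0.001, 0.5] cm⁻¹, μs′ ∈ [2, 15] cm⁻¹). On a homogeneous medium it
recovers the true properties to ~1e-4 relative error; on structured
media it deliberately reproduces the bias of real practice — a shallow
chest wall inflates the effective bulk μa, which is precisely how a
mismatched reference corrupts the reconstruction operator. In the
mismatch evaluation each pathway reconstructs with the background its
workflow supplies: matched and mismatched difference imaging fit the
bulk from their respective reference measurements; the reference-free
pathway fits it from the lesion-side measurement itself. The held-out
simulation summary instead uses the known scene background for both of
its pathways, since both share one operator there and the comparison
isolates the perturbation source.

Hemoglobin: per-voxel nonnegative least squares of μa at
730/785/808/830 nm against ln(10)-scaled molar extinction coefficients of
HbO₂/Hb (embedded table from the standard compiled hemoglobin spectra:
730 nm: 390/1102.2, 785 nm: 740/957.2, 808 nm: 866/732.0, 830 nm:
974/693.04 cm⁻¹/M); tHb = HbO₂ + Hb in μM.

## Metrics

- **SSIM** between a reconstructed depth layer and the rendered truth:
  uniform 7×7 window, K1 = 0.01, K2 = 0.03, dynamic range from the truth
  layer; per-layer values, reported as their mean when aggregated.
- **Target-to-artifact ratio**: peak of the negative-clipped map inside
  the lesion footprint widened 3× laterally, over the peak outside it;
  `inf` when the outside is empty of signal.
- **Centroid distance**: the reconstructed lesion is the
  above-half-maximum blob of the negative-clipped map; its volume-weighted
  center of mass is compared with the true centroid at (x, 0, z) — the
  lesion's y-centroid is taken as 0, consistent with the probe being
  centered on the lesion. Whole-map centers of mass (blob_fraction=0) are
  available but are dragged by diffuse artifact mass that the
  target-to-artifact ratio already scores.
- **Simulation summary**: per held-out scene,
  |max μa(predicted pert) − max μa(matched pert)|, aggregated as mean
  with a seeded 1,000-resample bootstrap 95% CI. Per-scene noise derives
  from the scene's own seed, making the summary invariant to case order.

## Problem sizes

The default study conditions are desk-scale: a 6,000-scene training
corpus (80/20 train/validation split; a 2,000-scene corpus is used for
the training-gate benchmark), 60–65 held-out evaluation scenes, and 20
chest-wall-mismatch scenes (lesion-side wall 3 cm, reference wall 2 cm,
lesions at the demonstration scale of radius 0.75–1.5 cm so the
sub-radius localization gate stays above the fine-mesh diagonal of
0.61 cm, and scenes kept when matched-reference imaging localizes the
lesion — the premise of the rescue comparison). The corpus generator
reproduces the full-scale study (tens of thousands of scenes) by
changing a single argument; prediction accuracy, and with it the
matched-vs-predicted agreement, improves steadily with corpus size.

## Known limitations

- The analytic Rytov/Born forward is a declared substitute for
  finite-element and Monte Carlo transport: absolute accuracy at high
  contrast is limited, and reconstructed μa underestimates the true
  lesion μa substantially (a generic property of linearized DOT that the
  matched-vs-predicted comparison is insensitive to).
- At 140 MHz the first-order kernel can predict a tiny (≤ ~3e-4)
  amplitude *increase* for the deepest targets at the shortest
  separation, so the matched perturbation's real part can exceed 0 by that
  allowance; the bound is exact at DC.
- Chest walls at maximal contrast over dark backgrounds rotate the
  complex perturbation strongly; in ~10% of mismatch scenes the real
  part shifts negative rather than positive (the imaginary part shifts
  positive throughout).
- Heterogeneity and chest wall are shared exactly between lesion and
  matched reference, so matched-reference cancellation is idealized;
  real contralateral breasts differ anatomically.
- One wavelength-agnostic model; no uncertainty quantification; no
  scattering reconstruction; no ingestion of real ultrasound segmentations.
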