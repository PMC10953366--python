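# Methods

## The reconstruction model

Free-breathing MRI acquires k-space line by line over minutes while the
anatomy moves; uncorrected reconstruction smears each motion state's
contribution into ghosting and blur. `pygrics` implements a joint inversion
for a motion-corrected image and a motion model:

    rho0, alpha = argmin || E(u) rho0 - m ||^2 + lambda ||rho0||^2
                           + mu ||grad alpha||^2,
    u(x, y, t) = alpha(x, y) * s(t),

where `m` is the acquired multi-coil Cartesian k-space, `s(t)` is a
respiratory-belt signal recorded simultaneously, `alpha(x, y)` is a
per-pixel pair of coefficients (pixels of in-plane displacement per unit
sensor amplitude), and `E(u)` composes, per motion state: a backward
bilinear warp, coil-sensitivity weighting, a centered unitary 2D FFT and
phase-encode row sampling. The belt signal is low-pass filtered at 3 Hz
(zero-phase 4th-order Butterworth), drift-corrected by subtracting a
least-squares quadratic in time (air-leak drift), and re-binned into `Ns`
amplitude states (equal-width bins over the robust 1st–99th percentile
range); all lines acquired in one state share one displacement field.

Two conventions are worth stating once:

* **Reference position.** State amplitudes are shifted so the lowest
  motion state maps to `s = 0`; the reconstructed `rho0` is therefore the
  anatomy at end-expiration, not at the time-averaged position. A constant
  (breath-hold or disconnected) sensor trace degenerates to a single state
  with `s = 0`, so the pipeline then reduces *exactly* to a plain
  Tikhonov-regularized parallel-imaging reconstruction.
* **Warping and its adjoint.** The backward warp is realized as an explicit
  sparse matrix (4 bilinear weights per row, zero outside the FOV); the
  adjoint used in the normal equations is the literal transpose of that
  matrix — not the inverse warp. This keeps the operator/adjoint pair exact
  to machine precision, which conjugate gradients requires.

## The alternating solver

Each *fixed-point iteration* alternates:

1. **Image step.** CG on `(E^H E + lambda_eff I) rho = E^H m`, capped at
   `maxit_recon = 10` iterations, relative-residual tolerance `1e-3`,
   started from zero.
2. **Model step.** A Gauss–Newton update of `alpha`. The warp is
   linearized through the spatial gradient of the warped image: perturbing
   `alpha` by `d` shifts state k's image by `s_k * (grad W_k rho) . d`.
   The resulting real-linear operator `L` feeds a CG solve (cap
   `maxit_motion = 10`, tolerance `1e-2`) of the *reduced* normal
   equations described below; the returned increment is applied through a
   backtracking line search (step 1, 1/2, 1/4, 1/8) on the true
   data-consistency norm, so the per-level residual trace is monotone.

`n_fixed_point = 4` iterations form one *level*; after each non-final
level the coil maps are re-estimated motion-compensated (next section) and
the data renormalized; the final level performs the image step only. The
default is `n_levels = 4` (three model levels plus the final
reconstruction). The "uncorrected" comparator is the identical final image
solve with a zero motion model.

### Why the reduced (variable-projection) model step

With the image freshly solved, the residual `eps = m - E rho` has had the
bulk of the motion signature absorbed into `rho` as ghosting: only the
part that no single image can explain — the inter-coil (parallel-imaging)
inconsistency — survives, empirically about 5% of the raw signature for
4 smooth coils. Plain Gauss–Newton on `L` then measures curvature with the
*full* operator but receives only the *reduced* residual, and its steps
come out ~20x too small; the iteration creeps and stalls far from the
optimum. The model step therefore solves

    ( L^H (I-P) L + mu_eff G^T G ) d = L^H (I-P) eps - mu_eff G^T G alpha,

where `P = E (E^H E + 1e-4 I)^{-1} E^H` projects onto the encoding
operator's range (applied through a short inner CG, 8 iterations at
tolerance 1e-3) and `G` is the forward-difference gradient. This is the
Gauss–Newton step of the variable-projection functional
`J(alpha) = min_rho ||E(alpha) rho - m||^2 + lambda ||rho||^2`, whose
steps are correctly scaled. The line search guards the approximation.

An earlier design ran the alternation on a dyadic spatial pyramid with
coarse k-space obtained by central cropping. At 64x64 this was abandoned
after measurement: cropping does not commute with coil weighting and
warping, and the resulting modeling error (relative residual floor ~0.045
at 16x16 on *static* data) exceeds the coarse-scale motion contrast
(~0.003), so the coarse levels feed noise to the model step. Full-grid
levels with exact operators proved both simpler and better conditioned at
this problem size.

### Regularizer scales

The raw weights `lambda = 1` and `mu = 0.5` are kept as the interface, and
made dimensionless internally:

* k-space is normalized so the zero-motion adjoint image has unit peak
  magnitude;
* `lambda_eff = lambda * nu_recon` with `nu_recon = 1e-4`. The Tikhonov
  term only needs to stabilize near-null modes (background pixels under
  low coil sensitivity). A larger weight is actively harmful: its
  shrinkage residual `~lambda * m` enters the model step's right-hand side
  and can anti-correlate with the true motion direction, reversing the
  Gauss–Newton sign at small amplitudes.
* `mu_eff = mu * nu_motion * mean-diag(L^H L)` with `nu_motion = 0.5`.
  Scaling by the data term's mean diagonal makes `mu` independent of image
  contrast and state occupancy. The gradient penalty is not cosmetic: image
  gradients vanish inside homogeneous tissue, so motion there is
  unobservable (the aperture problem), and it is this term that propagates
  displacement from edges into flat regions. Under-weighting it caps the
  recovered-field fidelity well below what the data support.

Both `nu` values are configuration fields, not constants.

## Coil sensitivities

Initial maps come from the central k-space band (32 lines for the fully
sampled protocol, 24 calibration lines when undersampled by 2):
Hann-apodized, zero-filled, inverse-transformed, divided by the
root-sum-of-squares image, then magnitude and phase smoothed with a
penalized (smoothing-spline) filter of roughness weight
`lambda_smooth = 1000`, solved in the DCT domain with Laplacian
eigenvalues normalized to [0, 1] (cutoff roughly a tenth of the FOV,
independent of grid size). Phase is smoothed through the real/imaginary
parts of the unit-phase field — no unwrapping. The fit is weighted by
signal confidence (squared RSS, saturating at 15% of peak) so background
garbage cannot drag the support boundary, and the result is RSS-normalized.

Maps estimated this way from a *moving* acquisition absorb motion ghosts
— the central band mixes lines from different states, and the leakage
masquerades as coil structure. This is not a small effect: it nearly
flattens the data-consistency contrast between the true model and no
model, making the motion model unidentifiable. Between solver levels the
maps are therefore *re-estimated motion-compensated*
(`coils.refine_coil_maps`): each coil's image is reconstructed by a small
CG solve of `min_x sum_k ||S_k F W_k x - m_ck||^2` using the current
displacements, and the coil ratio of those images — which cancels the
shared anatomy exactly — is smoothed as above. Two to three such cycles
restore most of the clean-calibration accuracy (max in-support error ~2-7%
against ground-truth maps in the bundled simulations).

## Image-quality metrics

* **Sharpness index (SI).** The image's total variation (periodic
  finite differences, L1) is compared against the phase-randomized null:
  random-phase fields with the same power spectrum are asymptotically
  Gaussian, and the null mean and variance of TV follow in closed form
  from the circular autocorrelations and cross-correlation of the two
  gradient fields (`Cov(|a|,|b|) = (2 sa sb / pi)(sqrt(1-r^2) + r asin r - 1)`).
  `SI = -log10 Phi((TV_obs - mu_TV) / sigma_TV)`, computed through the
  normal log-CDF for numerical range. Scale-invariant by construction;
  white noise scores ~log10 2; sharper structure scores higher.
* **Average edge strength (AES).** Mean gradient magnitude over Canny edge
  pixels (sigma 1 px, hysteresis thresholds at the 70th/90th gradient
  quantiles, so detection — and hence the metric's ratio behaviour — is
  scale-invariant). Zero when no edge is detected.
* **Enhancement.** `2 (a - b) / (a + b)` between corrected and
  uncorrected values of either metric (SE for SI, AEE for AES), bounded in
  (-2, 2), antisymmetric.
* **Background masking.** k-means (k = 3) on lightly smoothed intensities;
  the lowest-centroid cluster is background unless the centroid spread is
  within 20% of the brightest centroid (then the image is all foreground);
  morphological closing tidies the mask. Fixed k-means seeding keeps it
  deterministic. Residual aliasing lives outside the anatomy, so metric
  evaluation can be restricted to the object's bounding region.

## The synthetic test bed

The simulator emulates a supine breast-like acquisition at desk scale:

* **Phantom** (default 64x64): two half-elliptical lobes with smooth
  "glandular" ellipsoidal texture hanging from a chest-wall band;
  intensities normalized to [0, 1]; support fraction 0.2–0.6.
* **Breathing** : raised cosine with inhale/exhale phase asymmetry,
  period ~4 s, optional quadratic drift and white sensor noise.
* **Motion models**: `vertical` (dominant y-displacement growing away from
  the chest wall, the common no-holder regime), `expansion` and `shear`,
  all tapered to zero outside a chest-attached support so the object never
  slides rigidly; amplitudes up to 8 px.
* **Coils**: Gaussian-lobe complex sensitivities ringing the FOV,
  RSS-normalized to 1.
* **Acquisition**: shot-by-shot Cartesian sampling (optionally uniformly
  undersampled with a fully sampled central band), each shot warping the
  phantom by `alpha * s(t)` at its timestamp. In *binned* mode `s` is
  quantized to the state grid the reconstruction assumes (exact model
  family, used for the efficacy benchmarks, so they measure the solver and
  not binning error); *continuous* mode injects the binning mismatch
  deliberately and is used for the state-count saturation sweep and
  robustness checks. Noiseless binned simulation agrees with the
  `EncodingOperator` applied to the phantom to ~1e-12 — the consistency
  oracle tying the simulator to the reconstruction operators.

The standard benchmark (150 s acquisition, 64 single-line shots, 4 coils,
6 states, 5 px peak vertical displacement) is small enough to run in
seconds yet exhibits the full pathology: ghosting in the uncorrected
image, identifiability only through coil inconsistency, motion leakage
into calibration. What the synthetic bed does *not* model: through-plane
motion, relaxation weighting and B0/B1 effects, non-rigid intra-state
motion, realistic noise correlations between coils, and the 10-fold larger
matrices/coil counts of clinical data — passing here demonstrates the
machinery's correctness and the method's behaviour under its own
assumptions, not clinical performance.

## Numerical choices and degenerate inputs

* Unitary centered FFTs everywhere; DC at `N//2`.
* CG always starts from zero; with a constant sensor trace the corrected
  and uncorrected paths are then bit-identical by construction.
* Empty motion states (no lines) are skipped.
* `sos_normalize` floors its denominator at 1e-6 of the peak
  sum-of-squares.
* Binning refuses constant signals (`degenerate amplitude range`); the
  pipeline-level fallback maps such traces to a single zero-amplitude
  state. Degeneracy is detected relative to the *raw* signal scale, since
  drift removal reduces a constant trace to numerical residue.
* Timestamp-to-state lookup resolves exact midpoints to the earlier
  sample.
* `interpolate_alpha` resamples in physical millimetres with grid centres
  aligned and rescales pixel-unit coefficients by the pixel-size ratio, so
  physical displacement is preserved across geometries (linear
  interpolation by default; order configurable).

## Known limitations

* Identifiability rests on coil diversity; with very few or very smooth
  coils the reduced Gauss–Newton signal weakens, and more
  states/iterations cannot fully compensate.
* The motion model is linear in a single sensor channel and 2D in-plane,
  per slice; hysteresis (different inhale/exhale paths at equal amplitude)
  folds into model error.
* The backtracking line search guarantees monotone residuals, not global
  optimality; pathological initializations can stall at a worse fit than
  the true model (not observed at the bundled amplitudes).
* `refine_coil_maps` assumes the current displacement model is at least
  directionally correct; it is run after, never before, model levels.
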