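# pygrics

Sensor-driven non-rigid motion-corrected MRI reconstruction, with a
synthetic multi-coil test bed and objective image-quality metrics.

Free-breathing acquisitions (e.g. supine breast MRI, where the breast is
not immobilized and moves with the chest wall) collect Cartesian k-space
line by line over minutes; respiratory motion smears the lines' mutually
inconsistent views of the anatomy into ghosting and blur. `pygrics`
implements the GRICS family of reconstructions: a **joint inversion** for
a motion-corrected image `ρ₀` and a **linear motion model** that maps the
respiratory-belt signal `s(t)` (recorded alongside the sequence) to a
pixelwise in-plane displacement field,

```
ρ₀, α = argmin ‖E(u) ρ₀ − m‖² + λ‖ρ₀‖² + μ‖∇α‖² ,      u(x, y, t) = α(x, y) · s(t)
```

where `m` is the multi-coil k-space and `E(u)` composes per-state
non-rigid warping, coil-sensitivity weighting, Fourier transform and
k-space sampling. The belt signal is low-pass filtered (3 Hz),
quadratic-drift corrected and re-binned into `Ns` motion states; the
coupled problem is solved by alternating conjugate-gradient image and
model steps, with motion-compensated coil-map re-estimation between
levels. The package is aimed at reconstruction researchers who want a
compact, fully testable implementation whose every operator has an exact
adjoint and whose efficacy is measurable against simulated ground truth —
no scanner data required.

## Worked example

Simulate a breast-like phantom deforming under a quasi-periodic breathing
drive (5 px peak displacement), acquire it shot-by-shot with 4 coils over
150 s, then reconstruct with and without motion correction:

```python
import numpy as np
import pygrics as pg

phantom, support = pg.make_phantom(64, seed=7)
alpha = pg.make_alpha(phantom.geometry, "vertical", amplitude_px=5.0, seed=7)
resp = pg.make_resp(duration_s=150.0, period_s=4.1, seed=7)
coils = pg.make_coils(4, phantom.geometry, seed=7)
protocol = pg.Protocol(lines_per_shot=1, shot_interval_s=150.0 / 64)
ks, truth = pg.simulate_acquisition(
    phantom, alpha, resp, coils, protocol, seed=7,
    support=support, binned_states=6,
)

result = pg.run_grics(ks, resp, pg.GricsConfig(n_states=6))

report = pg.evaluate_pair(result.corrected.magnitude(),
                          result.uncorrected.magnitude())
gt = phantom.data[0]
def rmse(img):
    a = np.abs(img); a = a / a.max() * gt.max()
    return np.sqrt(np.mean((a - gt) ** 2))

print(f"RMSE vs ground truth: corrected {rmse(result.corrected.data[0]):.4f}, "
      f"uncorrected {rmse(result.uncorrected.data[0]):.4f}")
print(f"sharpness index:      corrected {report.si_corrected[0]:.2f}, "
      f"uncorrected {report.si_uncorrected[0]:.2f}  (SE = {100*report.mean_se:.1f}%)")
print(f"average edge strength: corrected {report.aes_corrected[0]:.3f}, "
      f"uncorrected {report.aes_uncorrected[0]:.3f}  (AEE = {100*report.mean_aee:.1f}%)")
```

prints

```
RMSE vs ground truth: corrected 0.0167, uncorrected 0.0372
sharpness index:      corrected 6.90, uncorrected 4.38  (SE = 44.6%)
average edge strength: corrected 0.133, uncorrected 0.117  (AEE = 12.9%)
```

Motion correction here halves the error against the known ground truth
and raises both no-reference quality metrics: the **sharpness index**
(how improbably low the image's total variation is under a
phase-randomized null — higher is sharper) and the **average edge
strength** (mean gradient magnitude over detected edges). `SE` and `AEE`
are the symmetric relative enhancements `2(a−b)/(a+b)` of those metrics,
the same summary used to compare corrected against standard
reconstructions of in-vivo data. `result.alpha` holds the recovered
motion model; on this simulation its displacement field correlates with
the ground-truth field at r ≈ 0.95 inside the object.

## Command line

```sh
pygrics simulate --size 64 --n-coils 4 --amplitude-px 5 --seed 7 --out-dir data/
pygrics recon data/kspace.h5 --out-dir recon/ --ns 6
pygrics recon data/kspace.h5 --out-dir recon_t1/ --recon-only --alpha recon/alpha.h5
pygrics evaluate recon/corrected.nii.gz recon/uncorrected.nii.gz --mask
pygrics sweep data/kspace.h5 --ns-grid 2,4,6,12
```

`recon --recon-only --alpha` reuses a previously estimated motion model
(with geometry interpolation) and skips the model step — the pathway for
reconstructing a second sequence from the model of the first. `sweep`
tabulates sharpness against the number of motion states; on simulated
data the curve rises and then saturates, which is how the operating
number of states is chosen.

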