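# Methods

## Problem setting

PROPELLER MRI samples k-space as `N_b` rectangular "blades" of `W`
phase-encode lines x `L` readout points, each rotated by a uniform angle
increment of `180°/N_b`. The central k-space disk of radius `W/2` is
sampled by every blade, which is what makes per-blade rigid-motion
estimation possible. Parallel-imaging acceleration keeps every `R`-th
line of each blade, so each blade image is aliased into `R` replicas
spaced `FOV/R` apart along that blade's phase-encode axis.

The conventional reconstruction (simple single-blade SENSE, SSB)
unaliases each blade independently with the Moore-Penrose pseudoinverse
of the per-pixel coil-sensitivity matrix and then grids all blades into
a combined image. At high `R` individual blades are badly conditioned
and per-blade noise amplification dominates the result.

The multi-step joint-blade (MJB) reconstruction implemented here reduces
that amplification by letting the blades share information:

1. **Step 1 (SSB):** conventional per-blade SENSE, motion estimation,
   density-compensated blade combination.
2. **Step 2 (regularised single-blade SENSE):** *virtual blades* are
   resampled from the Step-1 combined image — the combined image is
   moved back to each blade's pose, multiplied by the coil maps, and
   band-limited to the blade width. Each pixel of each blade is then
   updated by one Jacobi sweep of the SENSE normal equations
   ("back-substitution"): the `R-1` aliasing partners are replaced by
   their virtual-blade values, and the update is the matched filter
   `rho = C_rho^H (S - sum_others) / ||C_rho||²`. Because the
   blade-combined image averages ~`N_b W / L` blades per k-sample, the
   virtual partners carry far less noise than a single blade, so the
   solve trades ill-conditioned inversion for a well-conditioned
   substitution.
3. **Step 3 (joint-blade SENSE):** "wide" virtual blades of full width
   `L` are resampled from the Step-2 combined image; their
   high-frequency comb lines are patched onto the acquired blades so all
   blades share one resolution. The widened blades are co-registered
   into the common frame and solved jointly: the matched-filter
   numerator and the sensitivity-energy denominator are accumulated
   over all blades and coils, with partners again back-substituted.
   Optionally Steps 2-3 are iterated by feeding the Step-3 image back
   as the Step-2 reference; the marginal gain of extra iterations is
   small compared with the Step-1 to Step-3 improvement.

Without back-substitution, Step 3 can instead solve the full stacked
per-pixel system (the shared pixel plus each blade's partners) by
truncated-SVD least squares — an ablation mode, much slower and noisier
at high `R`.

## Numerical conventions

* **Transforms.** All image/k-space transforms are centered (DC at index
  `N//2`) and orthonormal, so Parseval holds exactly and white noise
  keeps its per-component standard deviation in either domain.
* **Rotation.** One shared operator everywhere (synthesis, coil-map
  rotation, gridding, co-registration): an FFT three-shear rotation —
  an exact multiple of 90° applied as an index permutation plus a
  residual in (-45°, 45°] applied as three unitary shear passes. The
  operator conserves energy and `rot(θ)∘rot(-θ)` is an exact identity;
  compositions such as `rot(a)∘rot(b)` vs `rot(a+b)` agree only to
  interpolation accuracy (~1e-3 relative on smooth images), which sets
  the floor of several "exactness" checks. A bicubic-spline rotation is
  available (`interp="spline"`) so simulation and reconstruction can use
  different interpolators when probing inverse-crime sensitivity;
  the default uses the shear operator on both sides, which mirrors how
  the emulated protocol itself synthesises data by image rotation +
  FFT.
* **Working grid.** When `R` does not divide `L` (e.g. 5 ∤ 256), SENSE
  systems are solved on an `L' = R*ceil(L/R)` phase-encode grid reached
  by k-space zero-padding (sinc interpolation), where aliasing partners
  fall on exact integer offsets `L'/R`; results are cropped back to `L`.
* **Sampling comb.** Undersampling keeps band indices `0, R, 2R, ...`
  of the `W`-line band. For the standard `W = ETL*R` geometries with
  even ETL the comb contains the DC line. Odd-ETL combs are offset; the
  zero-filled images are then demodulated by a linear phase so replicas
  stay in phase, and the solved image is re-modulated.
* **Gridding.** Blade combination follows the rotation-based dialect:
  each unaliased blade image is motion-corrected and rotated to the
  common frame in a single merged rigid transform, its k-space is
  accumulated over the blade's band, and the accumulator is divided by
  the per-point band count. The rotated band indicator is rasterized
  analytically (half-plane test on rotated k-coordinates) rather than by
  rotating a mask array: the analytic rasterization is exact at angle 0,
  has no ringing, and its weights are strictly counts.
* **Solvers.** The SSB pseudoinverse uses truncated SVD with relative
  cutoff 1e-6 (pure least-squares semantics — the baseline is
  deliberately unregularised). Pixels whose root-sum-of-squares
  sensitivity falls below 5% of the maximum are excluded. Both
  thresholds are arguments. The per-geometry pseudoinverses are cached
  (`SenseKernel`), which makes Monte-Carlo replica loops ~7x faster; the
  cached path is bit-identical to the direct solve.
* **Step-3 partner lookup** happens in each blade's aligned frame where
  partners are integer offsets; the per-blade matched-filter fields are
  then rotated into the common frame. This is equivalent to rotated-axis
  lookup but avoids off-grid partner interpolation. Widened blades keep
  their virtual rows decimated to the acquired comb so the uniform
  `R`-replica aliasing model holds across the whole widened blade.

## Synthetic protocol (what the generator emulates)

The simulator reproduces the study conditions of the emulated protocol:
a 256x256 (tests and acceptance use the 128x128 fast mode) magnitude
phantom, 8 coil maps, 16 blades of width `10R` (ETL 10), even `R`-fold
line discarding at `R` = 4, 5, 6, complex Gaussian noise at target SNR
10 and 20, and per-blade rigid motion uniform in ±10° / ±5 px with
blade 0 motion-free as the reference pose.

* **Phantom.** Modified Shepp-Logan (plus a 4-fold-symmetric disk grid
  and a checkerboard disc), scaled to 86% of the FOV so rotations never
  clip, and apodised with a 0.9-px Gaussian PSF. The apodisation matters:
  an idealised piecewise-constant object carries unbounded out-of-band
  energy and imposes a 4-5% gridding/model floor that acquired reference
  images (which are themselves resolution-limited) do not have; with the
  PSF the noise-free floor drops below 1%.
* **Coil maps.** A ring of eight dipole-like elements,
  `C(r) = (dx + i dy)/(|r - r_coil|² + s²)` — smooth everywhere, ~1/r
  magnitude falloff and the phase vortex characteristic of loop
  elements, normalised to unit root-sum-of-squares. This reproduces
  head-coil-like SENSE conditioning (per-blade Cartesian mean g of
  roughly 2.2 / 3.1 / 5.0 at R = 4 / 5 / 6); Gaussian-magnitude profiles
  with polynomial phase were found to be drastically worse conditioned
  than any real array and were rejected.
* **Noise.** i.i.d. complex Gaussian per acquired sample,
  `sigma = mean(truth)/SNR` per real/imaginary component, identity coil
  covariance. Under the orthonormal convention this sigma is also the
  image-domain noise level of a fully sampled reconstruction.
* **What is *not* emulated:** relaxation contrast and echo-train
  amplitude modulation, off-resonance/distortion, through-plane or
  intra-blade motion, coil-map estimation error (ground-truth maps are
  used in reconstruction), noise correlation between coils. Passing
  tests therefore demonstrate the linear-algebraic and geometric
  correctness of the method and its noise behaviour, not robustness to
  these physical effects.

## Motion estimation

Rotation is estimated by a translation-invariant rotation search: both
images are restricted to the shared central k-space disk (radius
`W/2 - 1`), the reference is rotated over candidate angles (1° coarse
grid, ±15° window, 0.25° fine stage), and the sub-pixel-refined peak of
the magnitude cross-correlation scores each candidate; a parabolic fit
gives the final sub-degree estimate. The sub-pixel refinement of the
correlation *peak height* is essential — the discrete maximum depends on
the fractional part of the translation and biases the rotation by up to
a degree otherwise. A polar-resampled correlation of the k-space
magnitude was evaluated and rejected: on smooth phantoms the angular
structure of `|k|` in the shared disk is weak and oscillates at
sub-pixel scale, making the profile correlation unreliable even without
noise. Translation is then estimated by upsampled-DFT cross-correlation
(scikit-image) of the disk-low-passed images after rotation
compensation. `estimate_all` runs two passes, rebuilding the reference
from motion-corrected blades after the first pass; parameters are
reported relative to blade 0. Accuracy on the emulated protocol at
SNR 20, R = 4: ≤0.4° and ≤0.1 px worst-blade error.

The pose convention is `T(dx,dy) ∘ R(rot)` (rotate about the image
centre, then shift); correction applies the exact inverse. Step 2
re-estimates motion from its improved blade images and keeps the update
only if any parameter moved by ≥0.1° / 0.1 px.

## Evaluation

* **nRMS error** = `100 * || |recon| - truth ||₂ / || truth ||₂` over
  the full image. The normalisation convention (percent of the truth's
  l2 norm) affects absolute values, not orderings.
* **g-factor maps** use pseudo multiple replica: many complex-Gaussian
  noise realisations are added to the noise-free k-space, each replica
  is reconstructed, and `g = std_R / (std_1 * sqrt(R))` pixelwise, with
  `std_1` from a fully sampled PROPELLER acquisition (16 blades, width
  `2*ETL`) reconstructed by SSB under the identical per-sample noise.
  The experiment runner computes the reference noise map once and shares
  it. Default 100 replicas; the acceptance runs use 50 and the fast CI
  configurations 25 or fewer. Mean g is averaged over the object support
  (truth ≥ 5% of max).
* **Step-ablation runner** reproduces the step table (standard /
  no-back-substitution-in-Step-3 / Step-2-twice / Step-3-twice). At
  desk scale the robust findings are that back-substitution in Step 3
  never hurts and each standard step improves on the previous one; the
  finer trend (the back-substitution contribution growing with `R`) is
  not reliably visible at small matrices because the
  no-back-substitution mode's off-grid bilinear sampling adds an
  interpolation penalty of its own.

## Known limitations

* The band-limit and the coil-map multiplication do not commute, so even
  noise-free consistent data carry a ~1% nRMS floor through the
  band-limited solvers (exactness holds algebraically, and is tested, on
  full-width data). This same commutation limits "virtual blades equal
  ideal blades" checks to ~1% agreement.
* Rotations compose only to interpolation accuracy; the merged
  single-rotation motion correction in the gridder trades ~1e-3 relative
  exactness for one shear pass per blade.
* The shear rotation is circular: content within the central ~86% of
  the FOV never wraps, which the generator guarantees but arbitrary
  user-supplied objects must respect.
* Phase-map compensation (`estimate_blade_phase`, `phase_comp=True`)
  addresses smooth inter-shot phase only; it is off by default in
  simulations, which generate no inter-shot phase.
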