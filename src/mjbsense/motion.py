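"""Inter-blade rigid-motion estimation and correction.

PROPELLER's rotating blades all sample the same central k-space disk, so
each (unaliased) blade image is a low-resolution view of the object that
can be registered to a reference:

* rotation — the magnitude of the central k-space disk is invariant to
  translation and rotates with the object, so the blade rotation is found
  by correlating angular profiles of ``|k|`` on a polar resampling, with
  sub-degree refinement by a parabolic fit around the discrete peak;
* translation — after rotation compensation, the shift is found by
  cross-correlating the disk-low-passed images with sub-pixel refinement
  (upsampled DFT correlation).

The pose convention: motion parameters ``(rot, dx, dy)`` describe the
object's pose during a blade's acquisition, as the forward map
``T_(dx,dy) . R_rot`` applied to the reference-frame object (rotate about
the image centre, then shift).  ``apply_rigid(..., inverse=True)``
applies the exact inverse and is what "correction" means everywhere in
this package.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import MotionParams
from .transforms import fft2c, lowpass_disk, phase_shift, rotate_image

__all__ = [
    "apply_rigid",
    "estimate_rotation",
    "estimate_translation",
    "estimate_all",
]


def apply_rigid(
    img: np.ndarray,
    rot_deg: float,
    dx_px: float,
    dy_px: float,
    inverse: bool = False,
    interp: str = "shear",
) -> np.ndarray:
    """Apply (or undo) an in-plane rigid transform.

    Forward: rotate by ``rot_deg`` about the centre pixel, then shift by
    ``(dx, dy)`` (x = column, y = row) via a k-space linear phase.
    Inverse: shift by ``(-dx, -dy)``, then rotate by ``-rot_deg`` —
    the exact inverse of the forward map for the shear interpolator.
    """
    if not inverse:
        out = rotate_image(img, rot_deg, interp=interp)
        return phase_shift(out, dy_px, dx_px)
    out = phase_shift(img, -dy_px, -dx_px)
    return rotate_image(out, -rot_deg, interp=interp)


def estimate_rotation(
    blade_img: np.ndarray,
    reference: np.ndarray,
    search_deg: float = 15.0,
    disk_radius: float | None = None,
    step_deg: float = 1.0,
    interp: str = "shear",
) -> float:
    """Estimate the rotation of ``blade_img`` relative to ``reference``.

    Both images are restricted to the central k-space disk that all
    blades share (``disk_radius``, in k-space pixels — callers pass the
    common blade half-width).  The reference is rotated over a grid of
    candidate angles within ``+-search_deg``; for each candidate the
    peak of the magnitude cross-correlation against the blade image is
    evaluated (making the score translation-invariant), and the
    maximising angle is refined to sub-step precision by a parabolic fit.
    Returns the angle such that rotating ``reference`` by it best
    matches ``blade_img``.
    """
    n = blade_img.shape[-1]
    if disk_radius is None:
        disk_radius = 0.2 * n
    if disk_radius < 2:
        raise ValueError("central k-space overlap disk is empty")
    bl = np.abs(lowpass_disk(blade_img, disk_radius))
    F_blade = np.fft.fft2(bl - bl.mean())

    def _score(d: float) -> float:
        r = np.abs(lowpass_disk(rotate_image(reference, d, interp=interp), disk_radius))
        xc = np.fft.ifft2(F_blade * np.conj(np.fft.fft2(r - r.mean()))).real
        return _subpixel_peak_value(xc)

    cands = np.arange(-search_deg, search_deg + 1e-9, step_deg)
    scores = np.array([_score(d) for d in cands])
    best = int(np.argmax(scores))
    # fine stage around the coarse peak
    fine = np.arange(
        cands[best] - step_deg, cands[best] + step_deg + 1e-9, step_deg / 4.0
    )
    vf = np.array([_score(d) for d in fine])
    bf = int(np.argmax(vf))
    frac = 0.0
    if 0 < bf < len(vf) - 1:
        c0, c1, c2 = vf[bf - 1], vf[bf], vf[bf + 1]
        denom = c0 - 2 * c1 + c2
        if abs(denom) > 1e-30:
            frac = float(np.clip(0.5 * (c0 - c2) / denom, -1.0, 1.0))
    est = fine[bf] + frac * step_deg / 4.0
    return float(np.clip(est, -search_deg, search_deg))


def _subpixel_peak_value(xc: np.ndarray) -> float:
    """Height of the correlation peak refined by separable quadratic fits.

    The discrete maximum underestimates the true peak by an amount that
    depends on the sub-pixel offset of the registration shift; fitting
    parabolas along both axes around the argmax removes that dependence
    so peak heights are comparable across candidate rotations.
    """
    ny, nx = xc.shape
    iy, ix = np.unravel_index(int(np.argmax(xc)), xc.shape)
    val = xc[iy, ix]
    for axis_vals in (
        (xc[(iy - 1) % ny, ix], val, xc[(iy + 1) % ny, ix]),
        (xc[iy, (ix - 1) % nx], val, xc[iy, (ix + 1) % nx]),
    ):
        c0, c1, c2 = axis_vals
        denom = c0 - 2 * c1 + c2
        if denom < -1e-30:
            val += -((c0 - c2) ** 2) / (8.0 * denom)
    return float(val)


def estimate_translation(
    blade_img: np.ndarray,
    reference: np.ndarray,
    disk_radius: float | None = None,
    upsample: int = 20,
) -> tuple[float, float]:
    """Estimate (dx, dy) such that ``reference`` shifted by (dx, dy)
    matches ``blade_img``.  Rotation must already be compensated.

    Uses upsampled-DFT cross-correlation on the disk-low-passed magnitude
    images; a flat correlation surface (degenerate input) returns (0, 0).
    """
    n = blade_img.shape[-1]
    if disk_radius is None:
        disk_radius = 0.2 * n
    a = np.abs(lowpass_disk(blade_img, disk_radius))
    b = np.abs(lowpass_disk(reference, disk_radius))
    if a.std() < 1e-12 * (abs(a).max() + 1e-300) or b.std() < 1e-12 * (
        abs(b).max() + 1e-300
    ):
        return 0.0, 0.0
    shift, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample, normalization=None
    )
    dy, dx = float(shift[0]), float(shift[1])
    # resolve the half-FOV wrap ambiguity toward the smaller magnitude
    if dy > n / 2:
        dy -= n
    if dx > n / 2:
        dx -= n
    return dx, dy


def estimate_all(
    blade_images: Sequence[np.ndarray],
    angles_deg: Sequence[float],
    disk_radius: float | None = None,
    search_deg: float = 15.0,
    reference: np.ndarray | None = None,
    n_passes: int = 2,
    interp: str = "shear",
) -> MotionParams:
    """Estimate per-blade rigid motion from unaliased blade images.

    ``blade_images`` are in their blade-aligned frames; each is first
    rotated by its nominal blade angle into the common frame.  The
    registration reference defaults to the unweighted mean of the
    common-frame blade images (less biased than electing a single
    blade); after the first pass the reference is rebuilt from the
    motion-corrected blade images and the estimation repeated, which
    removes most of the bias the motion-blurred first reference causes.
    The returned parameters follow the forward-pose convention of
    :func:`apply_rigid` and are reported relative to blade 0 (the
    motion reference).
    """
    n_blades = len(blade_images)
    if n_blades != len(angles_deg):
        raise ValueError("one angle per blade image required")
    if n_blades == 1:
        return MotionParams.zero(1)
    common = [
        rotate_image(img, ang, interp=interp)
        for img, ang in zip(blade_images, angles_deg)
    ]
    est = MotionParams.zero(n_blades)
    fixed_reference = reference is not None
    for _ in range(max(1, n_passes)):
        if not fixed_reference:
            corrected = [
                apply_rigid(
                    img,
                    est.rotations_deg[i],
                    est.shifts_x_px[i],
                    est.shifts_y_px[i],
                    inverse=True,
                    interp=interp,
                )
                for i, img in enumerate(common)
            ]
            reference = np.mean(np.abs(np.stack(corrected)), axis=0)
        rots = np.zeros(n_blades)
        dxs = np.zeros(n_blades)
        dys = np.zeros(n_blades)
        for i, img in enumerate(common):
            rot = estimate_rotation(
                img,
                reference,
                search_deg=search_deg,
                disk_radius=disk_radius,
                interp=interp,
            )
            # blade content is T_d R_rot(object); compare against the
            # equally-rotated reference to read off the shift directly
            ref_rot = rotate_image(reference, rot, interp=interp)
            dx, dy = estimate_translation(img, ref_rot, disk_radius=disk_radius)
            rots[i], dxs[i], dys[i] = rot, dx, dy
        est = MotionParams(rots, dxs, dys).relative_to_blade0()
    return est
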