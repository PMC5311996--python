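"""PROPELLER geometry, blade <-> image transforms, rotation-based
gridding with density compensation, and image metrics.

Grids
-----
Reconstruction happens on two grids:

* the common ``L x L`` grid shared by the object, coil maps and final
  image;
* a per-acceleration *working grid* of ``L' x L`` pixels with
  ``L' = R * ceil(L / R)`` along the blade's phase-encode (row) axis.
  On the working grid the R-fold aliasing replicas of a comb-sampled
  blade fall exactly ``L'/R`` pixels apart, so SENSE pixel groups index
  integer positions even when R does not divide L.  Fields move between
  the grids by sinc resampling (:func:`mjbsense.transforms.resample_axis`).

Blade k-space rows live on a centered band: band index ``w`` of a
W-line blade is the centered k-space row ``w - W//2``.  When the
acquired comb is offset from the DC-aligned comb (i.e. the retained
centered rows are congruent to ``c != 0`` mod R), the zero-filled image
is demodulated by a linear phase so that replicas are in-phase; the
demodulation is undone on the solved image.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import BladeSet, CoilMaps, GroundTruthImage, MotionParams
from .transforms import fft2c, ifft2c, phase_shift, rotate_image

__all__ = [
    "working_pe_size",
    "comb_offset",
    "demod_ramp",
    "blade_to_images",
    "band_weight",
    "density_weights",
    "combine_blades",
    "correct_to_common",
    "rotate_vector",
    "nrms_error",
    "support_mask",
]


def working_pe_size(n_readout: int, R: int) -> int:
    """Phase-encode size of the SENSE working grid: ``R * ceil(L / R)``."""
    return R * int(np.ceil(n_readout / R))


def comb_offset(blades: BladeSet) -> int:
    """Residue class (mod R) of the acquired centered k-space rows."""
    if blades.accel_factor == 1:
        return 0
    k0 = int(blades.acquired_line_indices[0]) - blades.blade_width_lines // 2
    return k0 % blades.accel_factor


def demod_ramp(n_pe: int, c: int) -> np.ndarray:
    """Column phase ramp shifting the sampling comb by ``-c`` k-space rows."""
    y = np.arange(n_pe) - n_pe // 2
    return np.exp(-2j * np.pi * c * y / n_pe)[:, None]


def blade_to_images(blades: BladeSet, blade_index: int) -> np.ndarray:
    """Aliased multi-coil images of one blade on the working grid.

    Zero-fills the acquired lines into an ``L' x L`` grid (blade-aligned
    frame), inverse transforms, scales by R and demodulates any comb
    offset, so the result equals the plain sum of the R aliasing replicas
    of the blade's band-limited coil images:
    ``A(y) = sum_r img(y - r * L'/R)``.
    """
    L = blades.n_readout
    R = blades.accel_factor
    W = blades.blade_width_lines
    Lp = working_pe_size(L, R)
    ksp = np.zeros((blades.n_coils, Lp, L), dtype=complex)
    rows = Lp // 2 + (blades.acquired_line_indices - W // 2)
    ksp[:, rows, :] = blades.kspace[blade_index]
    imgs = ifft2c(ksp) * np.sqrt(Lp / L)  # value-preserving zero-pad scale
    if R == 1:
        return imgs
    imgs = imgs * R
    c = comb_offset(blades)
    if c:
        imgs = imgs * demod_ramp(Lp, c)
    return imgs


def band_weight(
    matrix: int, width: int, angle_deg: float = 0.0
) -> np.ndarray:
    """Indicator of a W-line blade band rotated by ``angle_deg`` on the
    ``matrix``-square k-space grid (analytic rasterization, hard edges).

    At angle 0 this is exactly the discrete band of rows
    ``matrix//2 - width//2 .. matrix//2 + (width-1)//2``.
    """
    n = matrix
    ky = (np.arange(n) - n // 2)[:, None].astype(float)
    kx = (np.arange(n) - n // 2)[None, :].astype(float)
    th = np.deg2rad(angle_deg)
    # row coordinate of each k-point in the band's own (unrotated) frame
    r = np.cos(th) * ky + np.sin(th) * kx
    eps = 1e-6
    return ((r >= -(width // 2) - 0.5 + eps) & (r < width - width // 2 - 0.5 + eps)).astype(
        float
    )


def density_weights(
    angles_deg: Sequence[float],
    widths: Sequence[int] | int,
    matrix: int,
) -> np.ndarray:
    """Sampling-density weights: per k-grid point, the number of blade
    bands covering it."""
    if np.isscalar(widths):
        widths = [int(widths)] * len(angles_deg)
    w = np.zeros((matrix, matrix))
    for ang, wid in zip(angles_deg, widths):
        w += band_weight(matrix, int(wid), ang)
    return w


def rotate_vector(dy: float, dx: float, angle_deg: float) -> tuple[float, float]:
    """Rotate an (y, x) offset by the same matrix convention as
    :func:`mjbsense.transforms.rotate_image`."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return c * dy - s * dx, s * dy + c * dx


def correct_to_common(
    img: np.ndarray,
    blade_angle_deg: float,
    rot_deg: float = 0.0,
    dx_px: float = 0.0,
    dy_px: float = 0.0,
    interp: str = "shear",
) -> np.ndarray:
    """Bring a blade-frame image into the motion-corrected common frame.

    Equivalent to rotating by the blade angle and then undoing the rigid
    motion, merged into a single rotation by ``theta - rot`` followed by
    a phase shift of the motion translation rotated into the corrected
    frame: ``T(-M(-rot) d) . R(theta - rot)``.
    """
    out = rotate_image(img, blade_angle_deg - rot_deg, interp=interp)
    if dx_px or dy_px:
        dy_c, dx_c = rotate_vector(dy_px, dx_px, -rot_deg)
        out = phase_shift(out, -dy_c, -dx_c)
    return out


def combine_blades(
    blade_images: Sequence[np.ndarray],
    angles_deg: Sequence[float],
    motion: MotionParams | None,
    widths: Sequence[int] | int,
    interp: str = "shear",
    weight_floor: float = 1e-3,
) -> np.ndarray:
    """Gridding by image rotation: density-compensated blade combination.

    Each (unaliased, blade-frame) blade image is motion-corrected and
    rotated into the common frame; its k-space is accumulated over the
    blade's rotated band and finally divided by the per-point band count.
    Unsampled k-space (weight below ``weight_floor``) is left at zero.
    """
    n_blades = len(blade_images)
    if len(angles_deg) != n_blades:
        raise ValueError("one angle per blade image required")
    if np.isscalar(widths):
        widths = [int(widths)] * n_blades
    if motion is None:
        motion = MotionParams.zero(n_blades)
    if motion.n_blades != n_blades:
        raise ValueError("one motion entry per blade required")
    L = blade_images[0].shape[-1]
    acc = np.zeros((L, L), dtype=complex)
    wsum = np.zeros((L, L))
    for i in range(n_blades):
        rot = motion.rotations_deg[i]
        common = correct_to_common(
            blade_images[i],
            angles_deg[i],
            rot,
            motion.shifts_x_px[i],
            motion.shifts_y_px[i],
            interp=interp,
        )
        w = band_weight(L, widths[i], angles_deg[i] - rot)
        acc += fft2c(common) * w
        wsum += w
    good = wsum > weight_floor
    acc[good] /= wsum[good]
    acc[~good] = 0.0
    return ifft2c(acc)


def nrms_error(recon: np.ndarray, truth: GroundTruthImage | np.ndarray) -> float:
    """Normalised RMS error in percent.

    ``100 * || |recon| - truth ||_2 / || truth ||_2`` over the full
    image, comparing magnitudes.
    """
    t = truth.pixels if isinstance(truth, GroundTruthImage) else np.asarray(truth)
    denom = np.linalg.norm(t)
    if denom == 0:
        raise ValueError("ground truth is identically zero")
    if recon.shape[-2:] != t.shape:
        raise ValueError("matrix size mismatch")
    return float(100.0 * np.linalg.norm(np.abs(recon) - t) / denom)


def support_mask(
    ref: CoilMaps | GroundTruthImage | np.ndarray, frac: float = 0.05
) -> np.ndarray:
    """Boolean mask where the reference magnitude exceeds ``frac`` of its
    maximum (RSS magnitude for coil maps)."""
    if isinstance(ref, CoilMaps):
        mag = ref.rss()
    elif isinstance(ref, GroundTruthImage):
        mag = ref.pixels
    else:
        mag = np.abs(np.asarray(ref))
    return mag >= frac * mag.max()
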