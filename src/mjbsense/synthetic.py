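"""Synthetic PROPELLER acquisition: phantoms, coil maps, blade k-space,
undersampling, calibrated noise and random rigid motion.

The generator mirrors a typical simulated multi-coil PROPELLER study: a
square magnitude phantom (object support kept inside ~86% of the FOV so
rotations never clip), a ring of smooth complex coil sensitivities, and
per-blade k-space obtained by *image rotation + 2D FFT* — the object
(optionally moved to its per-blade pose) is multiplied by each coil map,
rotated into the blade's frame, Fourier transformed, and cropped to the
blade's W-line band.  Acceleration discards every line whose band index
is not a multiple of R (offset 0, so the DC line is retained whenever
W/2 is a multiple of R, which holds for the W = ETL*R geometries used
throughout).  Noise is i.i.d. complex Gaussian per acquired sample with
per-component standard deviation sigma = mean(truth)/SNR; under the
orthonormal transform convention this is also the image-domain noise
level of a fully sampled reconstruction.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .containers import BladeSet, CoilMaps, GroundTruthImage, MotionParams
from .motion import apply_rigid
from .transforms import fft2c, rotate_image

__all__ = [
    "make_phantom",
    "make_csm",
    "blade_angles",
    "synthesize_blades",
    "undersample",
    "add_noise",
    "draw_motion",
]

#: fraction of the FOV diameter occupied by the object's bounding circle;
#: keeps three-shear rotations free of wrap-around for any angle
SUPPORT_FRACTION = 0.86


def make_phantom(
    matrix_size: int, kind: str = "shepp_logan", psf_sigma_px: float = 0.9
) -> GroundTruthImage:
    """Deterministic test object on a ``matrix_size`` square grid.

    Kinds: ``shepp_logan`` (modified Shepp-Logan head phantom),
    ``disk_grid`` (4-fold-symmetric grid of disks) and ``checker_disc``
    (checkerboard inside a disc — high-frequency content for resolution
    checks).  The object is scaled to ``SUPPORT_FRACTION`` of the FOV
    and lightly apodised with a Gaussian point-spread function
    (``psf_sigma_px`` pixels, 0 disables) so its spectrum resembles that
    of an acquired reference image rather than an idealised piecewise-
    constant object with unbounded high-frequency content.
    """
    if matrix_size < 32:
        raise ValueError("matrix_size must be at least 32")
    n = matrix_size
    inner = int(round(n * SUPPORT_FRACTION))
    if kind == "shepp_logan":
        base = shepp_logan_phantom()  # 400x400, values in [0, 1]
        img_inner = resize(base, (inner, inner), order=3, anti_aliasing=True)
        img_inner = np.clip(img_inner, 0.0, None)
    elif kind == "disk_grid":
        img_inner = _disk_grid(inner)
    elif kind == "checker_disc":
        img_inner = _checker_disc(inner)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    out = np.zeros((n, n))
    lo = n // 2 - inner // 2
    out[lo : lo + inner, lo : lo + inner] = img_inner
    if psf_sigma_px > 0:
        out = gaussian_filter(out, psf_sigma_px)
    m = out.max()
    if m > 0:
        out = out / m
    return GroundTruthImage(out)


def _disk_grid(n: int) -> np.ndarray:
    """4-fold symmetric grid of soft disks inside a circular support."""
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    img = np.zeros((n, n))
    pitch = n / 6.0
    r_disk = n / 18.0
    for iy in (-2, -1, 0, 1, 2):
        for ix in (-2, -1, 0, 1, 2):
            cy, cx = c + iy * pitch, c + ix * pitch
            d2 = (y - cy) ** 2 + (x - cx) ** 2
            img += np.exp(-(d2 / (2 * r_disk**2)) ** 2)
    support = ((y - c) ** 2 + (x - c) ** 2) <= (0.48 * n) ** 2
    return img * support


def _checker_disc(n: int) -> np.ndarray:
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    cell = max(4, n // 16)
    checker = (((y // cell) + (x // cell)) % 2).astype(float) * 0.7 + 0.3
    support = ((y - c) ** 2 + (x - c) ** 2) <= (0.45 * n) ** 2
    return checker * support


def make_csm(matrix_size: int, n_coils: int, seed: int = 0) -> CoilMaps:
    """Smooth complex coil sensitivities for a ring of receive elements.

    Each element is modelled as a 2D dipole-like field centred on a ring
    just outside the FOV: ``C(r) = (dx + i dy) / (|r - r_coil|^2 + s^2)``
    — an analytic (everywhere-smooth) complex field with ~1/r magnitude
    falloff and the characteristic phase vortex of a loop element, which
    is what gives a real phased array its SENSE encoding power.  The
    seed jitters element placement and adds a gentle low-order
    polynomial phase.  Maps are normalised to unit root-sum-of-squares
    (as sensitivity maps estimated from data conventionally are), so
    the RSS trivially exceeds any support threshold inside the object.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    n = matrix_size
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:n, 0:n].astype(float)
    c = n // 2
    yn, xn = (y - c) / (n / 2), (x - c) / (n / 2)  # roughly [-1, 1]
    maps = np.empty((n_coils, n, n), dtype=complex)
    ring_r = 1.1  # element centres just outside the unit FOV circle
    soft = 0.25  # softening of the near-field singularity
    for k in range(n_coils):
        ang = 2 * np.pi * k / n_coils + rng.uniform(-0.05, 0.05)
        cy = ring_r * np.sin(ang) + rng.uniform(-0.02, 0.02)
        cx = ring_r * np.cos(ang) + rng.uniform(-0.02, 0.02)
        dy, dx = yn - cy, xn - cx
        field = (dx + 1j * dy) / (dx**2 + dy**2 + soft**2)
        p = rng.uniform(-1.0, 1.0, size=3)
        poly_phase = 0.2 * np.pi * (p[0] * yn + p[1] * xn + p[2])
        maps[k] = field * np.exp(1j * (poly_phase - 2 * np.pi * k / n_coils))
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss
    return CoilMaps(maps)


def blade_angles(n_blades: int) -> np.ndarray:
    """Uniform blade angles spanning 180 degrees starting at 0."""
    return np.arange(n_blades) * (180.0 / n_blades)


def synthesize_blades(
    truth: GroundTruthImage,
    csm: CoilMaps,
    n_blades: int,
    width_lines: int,
    n_readout: int,
    motion: MotionParams | None = None,
    interp: str = "shear",
) -> BladeSet:
    """Noise-free fully sampled blade k-space from a ground-truth object.

    Per blade i at angle theta_i: move the object to its per-blade pose
    (if motion is given), multiply by each coil map, rotate the coil
    images by ``-theta_i`` into the blade frame, 2D-FFT, and keep the
    central ``width_lines`` rows of the ``n_readout``-square k-space.
    """
    if truth.matrix_size != n_readout or csm.matrix_size != n_readout:
        raise ValueError("truth/CSM matrix must equal n_readout")
    if width_lines > n_readout:
        raise ValueError("width_lines cannot exceed n_readout")
    if motion is not None and motion.n_blades != n_blades:
        raise ValueError("motion must carry one entry per blade")
    angles = blade_angles(n_blades)
    L, W = n_readout, width_lines
    lo = L // 2 - W // 2
    ksp = np.empty((n_blades, csm.n_coils, W, L), dtype=complex)
    obj = truth.pixels.astype(complex)
    for i, theta in enumerate(angles):
        if motion is not None:
            moved = apply_rigid(
                obj,
                motion.rotations_deg[i],
                motion.shifts_x_px[i],
                motion.shifts_y_px[i],
                interp=interp,
            )
        else:
            moved = obj
        coil_imgs = moved[None] * csm.maps
        blade_frame = rotate_image(coil_imgs, -theta, interp=interp)
        ksp[i] = fft2c(blade_frame)[:, lo : lo + W, :]
    return BladeSet(
        kspace=ksp,
        blade_angles_deg=angles,
        blade_width_lines=W,
        n_readout=L,
        accel_factor=1,
        acquired_line_indices=np.arange(W),
    )


def undersample(blades: BladeSet, R: int, offset: int = 0) -> BladeSet:
    """Keep every R-th line of each blade's W-line band (fixed offset).

    With the default offset 0 and the ``W = ETL*R`` geometries used here,
    the retained comb contains the DC line.  R = 1 returns the input
    unchanged.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > blades.blade_width_lines:
        raise ValueError("R cannot exceed the blade width")
    if R == 1:
        return blades
    if blades.accel_factor != 1:
        raise ValueError("blades are already undersampled")
    keep = np.arange(offset, blades.blade_width_lines, R)
    return blades.copy_with(
        kspace=blades.kspace[:, :, keep, :].copy(),
        accel_factor=R,
        acquired_line_indices=keep,
    )


def add_noise(
    blades: BladeSet,
    target_snr: float,
    noise_ref_mean: float,
    seed: int = 0,
) -> BladeSet:
    """Add i.i.d. complex Gaussian noise calibrated to a target SNR.

    SNR is defined as ``noise_ref_mean / sigma`` with ``noise_ref_mean``
    the mean magnitude of the ground-truth image(s) and ``sigma`` the
    per-component (real/imaginary) noise standard deviation; under the
    orthonormal transform convention sigma is preserved between k-space
    and image domain.  ``target_snr = inf`` returns the input unchanged.
    Coil noise covariance is identity (no inter-coil correlation).
    """
    if not target_snr > 0:
        raise ValueError("target_snr must be positive")
    if np.isinf(target_snr):
        return blades
    sigma = noise_ref_mean / target_snr
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=blades.kspace.shape + (2,))
    return blades.copy_with(
        kspace=blades.kspace + noise[..., 0] + 1j * noise[..., 1]
    )


def draw_motion(
    n_blades: int,
    rot_range_deg: float = 10.0,
    trans_range_px: float = 5.0,
    seed: int = 0,
) -> MotionParams:
    """Per-blade uniform rigid motion in +-rot_range / +-trans_range.

    Blade 0 is forced to zero motion so it anchors the reference frame
    and estimated parameters are directly comparable to injected ones.
    """
    if rot_range_deg < 0 or trans_range_px < 0:
        raise ValueError("motion ranges must be non-negative")
    rng = np.random.default_rng(seed)
    rot = rng.uniform(-rot_range_deg, rot_range_deg, size=n_blades)
    dx = rng.uniform(-trans_range_px, trans_range_px, size=n_blades)
    dy = rng.uniform(-trans_range_px, trans_range_px, size=n_blades)
    rot[0] = dx[0] = dy[0] = 0.0
    return MotionParams(rot, dx, dy)
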