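"""Simple single-blade (SSB) SENSE: the conventional baseline.

Each blade is unaliased independently by solving, at every pixel group of
R positions spaced ``L'/R`` apart along the blade's phase-encode axis,
the least-squares system ``S = C P`` with ``C`` the (n_coils x R) matrix
of rotated coil sensitivities.  The solve is the plain Moore-Penrose
pseudoinverse (truncated SVD, relative cutoff 1e-6) — deliberately
unregularised, as the baseline should be.  Pixels where the
root-sum-of-squares sensitivity falls below a support threshold are
excluded (set to zero) so the solution does not blow up outside the
object.  The unaliased blades are then motion-corrected and gridded into
the blade-combined image.

Noise prewhitening is assumed done (identity coil covariance); a
user-supplied covariance can be applied by prewhitening the blade
k-space and coil maps before entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BladeSet, CoilMaps, MotionParams
from .core import blade_to_images, comb_offset, combine_blades, demod_ramp, working_pe_size
from .motion import estimate_all
from .transforms import resample_axis, rotate_image

__all__ = ["rotate_csm", "sense_unalias", "SenseKernel", "SSBResult", "ssb_reconstruct"]

SUPPORT_FRAC = 0.05
SVD_RCOND = 1e-6


def rotate_csm(csm: CoilMaps, angle_deg: float, interp: str = "shear") -> CoilMaps:
    """Rotate every coil map by ``angle_deg`` with the shared operator."""
    return CoilMaps(rotate_image(csm.maps, angle_deg, interp=interp))


def sense_unalias(
    aliased: np.ndarray,
    csm_rot: np.ndarray,
    R: int,
    support_frac: float = SUPPORT_FRAC,
    rcond: float = SVD_RCOND,
) -> np.ndarray:
    """Unalias one blade by pixel-group pseudoinverse SENSE.

    ``aliased``: (n_coils, L', L) aliased coil images on the working grid
    (replica-sum scaling as produced by :func:`blade_to_images`);
    ``csm_rot``: blade-frame coil sensitivities on the same grid.
    Returns the (L', L) unaliased blade image.
    """
    n_coils, Lp, L = aliased.shape
    if Lp % R:
        raise ValueError("working grid must be divisible by R")
    delta = Lp // R
    rss = np.sqrt((np.abs(csm_rot) ** 2).sum(axis=0))
    mask = rss >= support_frac * rss.max()
    cm = csm_rot * mask  # zeroed columns drop out of the truncated-SVD solve
    # group layout: y = r * delta + y0
    C = cm.reshape(n_coils, R, delta, L).transpose(2, 3, 0, 1)  # (d, L, Nc, R)
    S = aliased.reshape(n_coils, R, delta, L)[:, 0].transpose(1, 2, 0)[..., None]
    pinv = np.linalg.pinv(C, rcond=rcond)  # (d, L, R, Nc)
    P = (pinv @ S)[..., 0]  # (d, L, R)
    out = P.transpose(2, 0, 1).reshape(Lp, L)
    return np.where(mask, out, 0.0)


@dataclass
class SenseKernel:
    """Cached per-geometry quantities for repeated reconstructions.

    Holds the blade-frame coil sensitivities on the common ``L x L``
    grid (``csm_common``) and on the ``L' x L`` working grid
    (``csm_work``) for one (blade angles, matrix, R) geometry, so
    Monte-Carlo replica loops and the MJB steps never re-rotate coil
    maps.  The working grid depends only on (L, R), so the same kernel
    serves the acquired W-line blades and the widened full-width blades.
    """

    csm_common: np.ndarray  # (n_blades, n_coils, L, L)
    csm_work: np.ndarray  # (n_blades, n_coils, L', L)
    angles_deg: np.ndarray
    R: int
    L: int
    Lp: int
    interp: str = "shear"
    _pinv_cache: dict = field(default_factory=dict, repr=False)

    def unalias_operator(
        self, support_frac: float = SUPPORT_FRAC, rcond: float = SVD_RCOND
    ) -> tuple[np.ndarray, np.ndarray]:
        """Cached per-blade pixel-group pseudoinverses and support mask.

        Returns ``(pinv, mask)`` with ``pinv`` of shape
        (n_blades, delta, L, R, n_coils) and ``mask`` (n_blades, L', L).
        The SVD depends only on the coil maps, so Monte-Carlo replica
        loops reuse it and each unaliasing becomes a batched matmul.
        """
        key = (support_frac, rcond)
        if key not in self._pinv_cache:
            n_blades, n_coils = self.csm_work.shape[:2]
            delta = self.Lp // self.R
            pinvs = np.empty(
                (n_blades, delta, self.L, self.R, n_coils), dtype=complex
            )
            masks = np.empty((n_blades, self.Lp, self.L), dtype=bool)
            for i in range(n_blades):
                cw = self.csm_work[i]
                rss = np.sqrt((np.abs(cw) ** 2).sum(axis=0))
                mask = rss >= support_frac * rss.max()
                cm = cw * mask
                C = cm.reshape(n_coils, self.R, delta, self.L).transpose(2, 3, 0, 1)
                pinvs[i] = np.linalg.pinv(C, rcond=rcond)
                masks[i] = mask
            self._pinv_cache[key] = (pinvs, masks)
        return self._pinv_cache[key]

    @classmethod
    def prepare(
        cls, blades: BladeSet, csm: CoilMaps, interp: str = "shear"
    ) -> "SenseKernel":
        L = blades.n_readout
        R = blades.accel_factor
        Lp = working_pe_size(L, R)
        common = np.stack(
            [
                rotate_image(csm.maps, -theta, interp=interp)
                for theta in blades.blade_angles_deg
            ]
        )
        work = (
            common
            if Lp == L
            else resample_axis(common, Lp, axis=-2)
        )
        return cls(
            csm_common=common,
            csm_work=np.asarray(work),
            angles_deg=np.asarray(blades.blade_angles_deg),
            R=R,
            L=L,
            Lp=Lp,
            interp=interp,
        )


@dataclass
class SSBResult:
    blade_images: list  # (L, L) complex blade-frame images
    motion: MotionParams
    combined: np.ndarray  # (L, L) complex, common frame


def ssb_reconstruct(
    blades: BladeSet,
    csm: CoilMaps,
    do_motion: bool = False,
    kernel: SenseKernel | None = None,
    interp: str = "shear",
    support_frac: float = SUPPORT_FRAC,
) -> SSBResult:
    """Step 1: per-blade SENSE, optional motion estimation, gridding.

    Returns the unaliased blade images (blade-aligned frames), the
    estimated motion (zeros when ``do_motion`` is off) and the
    density-compensated blade-combined image — the SSB final image when
    used standalone.
    """
    if kernel is None:
        kernel = SenseKernel.prepare(blades, csm, interp=interp)
    L = blades.n_readout
    R = blades.accel_factor
    delta = kernel.Lp // R
    c = comb_offset(blades)
    pinvs, masks = kernel.unalias_operator(support_frac)
    blade_images = []
    for i in range(blades.n_blades):
        aliased = blade_to_images(blades, i)
        n_coils = aliased.shape[0]
        S = aliased.reshape(n_coils, R, delta, L)[:, 0].transpose(1, 2, 0)[..., None]
        P = (pinvs[i] @ S)[..., 0]  # (delta, L, R)
        img = np.where(
            masks[i], P.transpose(2, 0, 1).reshape(kernel.Lp, L), 0.0
        )
        if c:
            img = img * np.conj(demod_ramp(kernel.Lp, c))
        blade_images.append(resample_axis(img, L, axis=-2))
    if do_motion and blades.n_blades > 1:
        motion = estimate_all(
            blade_images,
            blades.blade_angles_deg,
            disk_radius=max(3.0, blades.blade_width_lines / 2 - 1),
            interp=interp,
        )
    else:
        motion = MotionParams.zero(blades.n_blades)
    combined = combine_blades(
        blade_images,
        blades.blade_angles_deg,
        motion,
        blades.blade_width_lines,
        interp=interp,
    )
    return SSBResult(blade_images=blade_images, motion=motion, combined=combined)
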