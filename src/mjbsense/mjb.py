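"""Multi-step joint-blade (MJB) SENSE.

The procedure reduces the noise amplification of per-blade SENSE by
sharing information across blades through *virtual blades* resampled
from blade-combined images:

Step 1   Conventional per-blade (SSB) SENSE provides initial blade
         images, motion parameters and a blade-combined image.

Step 2   Regularised single-blade SENSE.  Virtual blades of the acquired
         width W are resampled from the Step-1 combined image (motion
         re-applied, coil maps multiplied, band-limited).  Each pixel of
         each blade is then re-estimated by one Jacobi sweep on the
         SENSE normal equations — "back-substitution": the aliasing
         partners are replaced by their (high-SNR) virtual-blade values,
         and the pixel update is the matched filter
         ``rho = C_rho^H (S - sum_others) / ||C_rho||^2``.

Step 3   Joint-blade SENSE.  "Wide" virtual blades of full width L are
         resampled from the Step-2 combined image; their high-frequency
         comb lines are patched onto the acquired blades so every blade
         has the same resolution.  All widened blades are co-registered
         into the common frame and solved jointly: the matched-filter
         numerator and sensitivity-energy denominator are accumulated
         over all blades and coils, with the aliasing partners again
         back-substituted from the wide virtual blades.  Without
         back-substitution the full stacked system is solved by least
         squares instead (ablation mode).

Partner lookup happens in each blade's aligned frame, where the R
aliasing partners sit at exact integer offsets of ``L'/R`` pixels; the
per-blade matched-filter fields are then rotated into the common frame.
This is mathematically equivalent to looking partners up along rotated
axes but avoids off-grid partner interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BladeSet, CoilMaps, MotionParams
from .core import (
    blade_to_images,
    comb_offset,
    combine_blades,
    correct_to_common,
    demod_ramp,
    nrms_error,
    working_pe_size,
)
from .motion import estimate_all
from .ssb import SUPPORT_FRAC, SenseKernel, ssb_reconstruct
from .transforms import fft2c, ifft2c, phase_shift, resample_axis, rotate_image

__all__ = [
    "make_virtual_blades",
    "regularized_blade_solve",
    "widen_blades",
    "joint_blade_backsub",
    "joint_blade_lstsq",
    "estimate_blade_phase",
    "MJBResult",
    "mjb_reconstruct",
]


def _group_others(imgs: np.ndarray, R: int) -> np.ndarray:
    """Per pixel, the summed values of its R-1 aliasing partners.

    ``imgs``: (..., L', L) with L' divisible by R; partners are spaced
    L'/R rows apart.
    """
    shp = imgs.shape
    Lp = shp[-2]
    delta = Lp // R
    g = imgs.reshape(shp[:-2] + (R, delta, shp[-1]))
    gsum = g.sum(axis=-3, keepdims=True)
    others = np.broadcast_to(gsum, g.shape) - g
    return others.reshape(shp)


def make_virtual_blades(
    combined: np.ndarray,
    csm: CoilMaps,
    motion: MotionParams | None,
    angles_deg: np.ndarray,
    width_lines: int,
    phase_maps: np.ndarray | None = None,
    kernel: SenseKernel | None = None,
    interp: str = "shear",
) -> np.ndarray:
    """Resample virtual blades from a blade-combined image.

    Per blade: re-apply the blade's rigid motion to the combined image
    (undoing the correction), rotate into the blade frame, multiply by
    the blade-frame coil maps (optionally by a per-blade phase map),
    and band-limit to ``width_lines`` phase-encode rows.  With
    ``width_lines = L`` this produces the "wide" virtual blades used for
    blade widening.

    Returns (n_blades, n_coils, L, L) blade-frame coil images.
    """
    L = combined.shape[-1]
    if width_lines > L:
        raise ValueError("width_lines cannot exceed the matrix size")
    n_blades = len(angles_deg)
    if motion is None:
        motion = MotionParams.zero(n_blades)
    n_coils = csm.n_coils
    lo = L // 2 - width_lines // 2
    out = np.empty((n_blades, n_coils, L, L), dtype=complex)
    for i, theta in enumerate(angles_deg):
        rot = motion.rotations_deg[i]
        dx, dy = motion.shifts_x_px[i], motion.shifts_y_px[i]
        # blade-frame object: R(-theta) T(d) R(rot) combined
        #                   = T(M(-theta) d) R(rot - theta) combined
        obj = rotate_image(combined, rot - theta, interp=interp)
        if dx or dy:
            th = np.deg2rad(-theta)
            dy_b = np.cos(th) * dy - np.sin(th) * dx
            dx_b = np.sin(th) * dy + np.cos(th) * dx
            obj = phase_shift(obj, dy_b, dx_b)
        if kernel is not None:
            csm_blade = kernel.csm_common[i]
        else:
            csm_blade = rotate_image(csm.maps, -theta, interp=interp)
        coil = obj[None] * csm_blade
        if phase_maps is not None:
            coil = coil * phase_maps[i][None]
        if width_lines < L:
            ksp = fft2c(coil)
            band = np.zeros_like(ksp)
            band[:, lo : lo + width_lines, :] = ksp[:, lo : lo + width_lines, :]
            coil = ifft2c(band)
        out[i] = coil
    return out


def regularized_blade_solve(
    aliased: np.ndarray,
    csm_rot: np.ndarray,
    virtual_blade: np.ndarray,
    R: int,
    support_frac: float = SUPPORT_FRAC,
) -> np.ndarray:
    """One Jacobi back-substitution sweep for a single blade.

    ``aliased``: (n_coils, L', L) aliased coil images (replica-sum
    scaling); ``csm_rot``: blade-frame sensitivities on the same grid;
    ``virtual_blade``: virtual-blade *coil* images on the same grid,
    providing the partner values ``C_others P_others`` directly.

    For each pixel: ``rho = C_rho^H (S - sum_partners(virtual)) /
    ||C_rho||^2`` — exactly one Jacobi iteration on the normal equations
    initialised at the virtual values.
    """
    others = _group_others(virtual_blade, R)
    residual = aliased - others
    num = (np.conj(csm_rot) * residual).sum(axis=0)
    den = (np.abs(csm_rot) ** 2).sum(axis=0)
    mask = den >= (support_frac**2) * den.max()
    out = np.zeros_like(num)
    out[mask] = num[mask] / den[mask]
    return out


def widen_blades(acquired: BladeSet, wide_virtual: np.ndarray) -> BladeSet:
    """Patch virtual high-frequency comb lines onto the acquired blades.

    ``wide_virtual``: (n_blades, n_coils, L, L) blade-frame coil images
    resampled at full width L.  The output blades have width L and remain
    uniformly R-undersampled: rows of the acquired comb keep the measured
    data, every other row of the same comb is filled from the virtual
    blade's k-space, eliminating the resolution inconsistency among
    blades.
    """
    L = acquired.n_readout
    W = acquired.blade_width_lines
    R = acquired.accel_factor
    if wide_virtual.shape[-2:] != (L, L) or wide_virtual.shape[0] != acquired.n_blades:
        raise ValueError("wide virtual blades must match acquired geometry")
    c = comb_offset(acquired)
    k_all = np.arange(L) - L // 2
    comb_rows = np.flatnonzero(np.mod(k_all, R) == c)  # band indices in [0, L)
    acq_band = (acquired.acquired_line_indices - W // 2) + L // 2
    slot = {b: j for j, b in enumerate(comb_rows)}
    acq_slots = np.array([slot[b] for b in acq_band])
    vk = fft2c(wide_virtual)
    ksp = vk[:, :, comb_rows, :].copy()
    ksp[:, :, acq_slots, :] = acquired.kspace
    return BladeSet(
        kspace=ksp,
        blade_angles_deg=acquired.blade_angles_deg,
        blade_width_lines=L,
        n_readout=L,
        accel_factor=R,
        acquired_line_indices=comb_rows,
    )


def joint_blade_backsub(
    widened: BladeSet,
    kernel: SenseKernel,
    motion: MotionParams | None,
    wide_virtual: np.ndarray,
    support_frac: float = SUPPORT_FRAC,
    blade_weights: np.ndarray | None = None,
    interp: str = "shear",
) -> np.ndarray:
    """Step-3 joint solve with back-substitution (one stacked Jacobi sweep).

    Per blade, the matched-filter numerator ``sum_k conj(C) (S - virtual
    others)`` and denominator ``sum_k |C|^2`` are formed in the blade
    frame (integer partner offsets), co-registered into the common frame
    (rotation + translation-phase correction), accumulated over blades,
    and divided:
    ``rho = C_rho^H (S_w - C_others P_others^virtual) / ||C_rho||^2``
    with ``C_rho`` stacked over all blades and coils.
    """
    L = widened.n_readout
    R = widened.accel_factor
    Lp = working_pe_size(L, R)
    n_blades = widened.n_blades
    if motion is None:
        motion = MotionParams.zero(n_blades)
    if blade_weights is None:
        blade_weights = np.ones(n_blades)
    c = comb_offset(widened)
    num = np.zeros((L, L), dtype=complex)
    den = np.zeros((L, L))
    for i in range(n_blades):
        aliased = blade_to_images(widened, i)
        virt = resample_axis(wide_virtual[i], Lp, axis=-2)
        if c:
            virt = virt * demod_ramp(Lp, c)
        csm_b = kernel.csm_work[i]
        residual = aliased - _group_others(virt, R)
        n_i = (np.conj(csm_b) * residual).sum(axis=0)
        if c:
            n_i = n_i * np.conj(demod_ramp(Lp, c))
        d_i = (np.abs(csm_b) ** 2).sum(axis=0)
        n_i = resample_axis(n_i, L, axis=-2)
        d_i = resample_axis(d_i, L, axis=-2).real
        n_c = correct_to_common(
            n_i,
            widened.blade_angles_deg[i],
            motion.rotations_deg[i],
            motion.shifts_x_px[i],
            motion.shifts_y_px[i],
            interp=interp,
        )
        d_c = correct_to_common(
            d_i,
            widened.blade_angles_deg[i],
            motion.rotations_deg[i],
            interp=interp,
        ).real
        num += blade_weights[i] * n_c
        den += blade_weights[i] * np.clip(d_c, 0.0, None)
    mask = den >= (support_frac**2) * den.max()
    out = np.zeros_like(num)
    out[mask] = num[mask] / den[mask]
    return out


def joint_blade_lstsq(
    widened: BladeSet,
    kernel: SenseKernel,
    motion: MotionParams | None,
    support_frac: float = SUPPORT_FRAC,
    rcond: float = 1e-6,
    interp: str = "shear",
) -> np.ndarray:
    """Step-3 joint solve *without* back-substitution (ablation mode).

    For every common-frame pixel the full stacked system over all blades
    and coils is assembled — unknowns are the pixel itself plus the R-1
    aliasing partners of every blade, treated as independent per blade —
    and solved by truncated-SVD least squares; only the shared pixel
    value is kept.  Per-blade rows are sampled in each blade's frame at
    the motion-mapped coordinates (bilinear off-grid interpolation).
    Substantially slower than the back-substituted solve; intended for
    small matrices and ablation studies.
    """
    from scipy import ndimage as _ndi

    L = widened.n_readout
    R = widened.accel_factor
    Lp = working_pe_size(L, R)
    delta = Lp // R
    n_blades, n_coils = widened.n_blades, widened.n_coils
    if motion is None:
        motion = MotionParams.zero(n_blades)
    c = comb_offset(widened)

    yy, xx = np.mgrid[0:L, 0:L].astype(float)
    cy = cx = L // 2
    n_unknowns = 1 + n_blades * (R - 1)
    rows_total = n_blades * n_coils
    A = np.zeros((L * L, rows_total, n_unknowns), dtype=complex)
    b = np.zeros((L * L, rows_total), dtype=complex)

    def _sample(fld: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        re = _ndi.map_coordinates(fld.real, [ys, xs], order=1, mode="grid-wrap")
        im = _ndi.map_coordinates(fld.imag, [ys, xs], order=1, mode="grid-wrap")
        return re + 1j * im

    for i in range(n_blades):
        aliased = blade_to_images(widened, i)  # demodulated if c != 0
        csm_b = kernel.csm_work[i]
        if c:
            # fold the comb demodulation into the sensitivities so the
            # shared unknown stays the unmodulated object
            csm_b = csm_b * demod_ramp(Lp, c)
        # common-frame pixel u -> blade-frame coordinate:
        # u_b = M(rot - theta) (u - centre) + M(-theta) d + centre
        th = np.deg2rad(motion.rotations_deg[i] - widened.blade_angles_deg[i])
        rot_y = np.cos(th) * (yy - cy) - np.sin(th) * (xx - cx)
        rot_x = np.sin(th) * (yy - cy) + np.cos(th) * (xx - cx)
        tb = np.deg2rad(-widened.blade_angles_deg[i])
        dy_b = np.cos(tb) * motion.shifts_y_px[i] - np.sin(tb) * motion.shifts_x_px[i]
        dx_b = np.sin(tb) * motion.shifts_y_px[i] + np.cos(tb) * motion.shifts_x_px[i]
        y_common = rot_y + dy_b  # offset from centre, common pixel units
        x_b = np.mod(rot_x + dx_b + cx, L)
        y_work = np.mod(y_common * (Lp / L) + Lp // 2, Lp)
        for r in range(R):
            ys = np.mod(y_work + r * delta, Lp)
            col = 0 if r == 0 else 1 + i * (R - 1) + (r - 1)
            for k in range(n_coils):
                A[:, i * n_coils + k, col] = _sample(csm_b[k], ys, x_b).ravel()
        for k in range(n_coils):
            b[:, i * n_coils + k] = _sample(aliased[k], y_work, x_b).ravel()

    rss = np.sqrt((np.abs(A[:, :, 0]) ** 2).sum(axis=1))
    mask = rss >= support_frac * rss.max()
    out = np.zeros(L * L, dtype=complex)
    idx = np.flatnonzero(mask)
    chunk = 2048
    for s in range(0, len(idx), chunk):
        sel = idx[s : s + chunk]
        pinv = np.linalg.pinv(A[sel], rcond=rcond)
        out[sel] = (pinv @ b[sel][..., None])[:, 0, 0]
    return out.reshape(L, L)


def estimate_blade_phase(
    blade_images: list[np.ndarray], kernel_width: int = 12
) -> np.ndarray:
    """Low-resolution unit-magnitude phase maps of the blade images.

    The phase of each blade image is extracted after windowing its
    k-space to a central square of ``kernel_width`` samples — the smooth
    inter-shot phase that virtual blades must carry to match the
    acquired data.  Off by default for simulations.
    """
    out = []
    for img in blade_images:
        img = np.asarray(img, dtype=complex)
        L = img.shape[-1]
        lo = L // 2 - kernel_width // 2
        full = fft2c(img)
        ksp = np.zeros_like(full)
        ksp[lo : lo + kernel_width, lo : lo + kernel_width] = full[
            lo : lo + kernel_width, lo : lo + kernel_width
        ]
        low = ifft2c(ksp)
        mag = np.abs(low)
        phase = np.where(
            mag > 1e-12 * mag.max(), low / np.maximum(mag, 1e-300), 1.0
        )
        out.append(phase)
    return np.stack(out)


@dataclass
class MJBResult:
    image: np.ndarray  # final complex image, common frame
    motion: MotionParams
    diagnostics: dict = field(default_factory=dict)


def _regularized_pass(
    blades: BladeSet,
    csm: CoilMaps,
    motion: MotionParams,
    reference: np.ndarray,
    kernel: SenseKernel,
    do_motion: bool,
    phase_maps: np.ndarray | None,
    interp: str,
    support_frac: float,
) -> tuple[list[np.ndarray], MotionParams, np.ndarray]:
    """Step 2: virtual blades at width W -> back-substituted blade solve
    -> optional motion update -> blade-combined image."""
    L = blades.n_readout
    W = blades.blade_width_lines
    Lp = kernel.Lp
    c = comb_offset(blades)
    virtual = make_virtual_blades(
        reference,
        csm,
        motion,
        blades.blade_angles_deg,
        W,
        phase_maps=phase_maps,
        kernel=kernel,
        interp=interp,
    )
    blade_images = []
    for i in range(blades.n_blades):
        aliased = blade_to_images(blades, i)
        virt = resample_axis(virtual[i], Lp, axis=-2)
        if c:
            virt = virt * demod_ramp(Lp, c)
        img = regularized_blade_solve(
            aliased, kernel.csm_work[i], virt, blades.accel_factor, support_frac
        )
        if c:
            img = img * np.conj(demod_ramp(Lp, c))
        blade_images.append(resample_axis(img, L, axis=-2))
    new_motion = motion
    if do_motion and blades.n_blades > 1:
        est = estimate_all(
            blade_images,
            blades.blade_angles_deg,
            disk_radius=max(3.0, W / 2 - 1),
            interp=interp,
        )
        change = np.max(np.abs(est.as_array() - motion.as_array()), initial=0.0)
        if change >= 0.1:
            new_motion = est
    combined = combine_blades(
        blade_images, blades.blade_angles_deg, new_motion, W, interp=interp
    )
    return blade_images, new_motion, combined


def _joint_pass(
    blades: BladeSet,
    csm: CoilMaps,
    motion: MotionParams,
    reference: np.ndarray,
    kernel: SenseKernel,
    use_backsub: bool,
    phase_maps: np.ndarray | None,
    interp: str,
    support_frac: float,
    blade_weights: np.ndarray | None,
) -> np.ndarray:
    """Step 3: wide virtual blades -> widen -> co-register -> joint solve."""
    L = blades.n_readout
    wide_virtual = make_virtual_blades(
        reference,
        csm,
        motion,
        blades.blade_angles_deg,
        L,
        phase_maps=phase_maps,
        kernel=kernel,
        interp=interp,
    )
    widened = widen_blades(blades, wide_virtual)
    if use_backsub:
        return joint_blade_backsub(
            widened,
            kernel,
            motion,
            wide_virtual,
            support_frac=support_frac,
            blade_weights=blade_weights,
            interp=interp,
        )
    return joint_blade_lstsq(
        widened, kernel, motion, support_frac=support_frac, interp=interp
    )


def mjb_reconstruct(
    blades: BladeSet,
    csm: CoilMaps,
    n_extra_iters: int = 0,
    use_backsub_s3: bool = True,
    variant: str = "standard",
    do_motion: bool = False,
    phase_comp: bool = False,
    truth=None,
    kernel: SenseKernel | None = None,
    interp: str = "shear",
    support_frac: float = SUPPORT_FRAC,
    blade_weights: np.ndarray | None = None,
) -> MJBResult:
    """Full multi-step joint-blade SENSE reconstruction.

    Variants mirror the step-ablation experiments: ``standard`` is
    Step 1 -> Step 2 -> Step 3; ``s2x2`` repeats the regularised
    single-blade pass instead of the joint pass; ``s3x2`` omits the
    regularised pass and runs the joint pass twice (the second seeded by
    the first's image).  ``n_extra_iters`` feeds the Step-3 image back
    into Step 2 (standard variant only).  ``use_backsub_s3=False``
    replaces the Step-3 back-substitution with the full stacked
    least-squares solve.  If ``truth`` is given, per-step nRMS errors
    are recorded in ``diagnostics``.
    """
    if variant not in ("standard", "s2x2", "s3x2"):
        raise ValueError(f"unknown variant {variant!r}")
    if kernel is None:
        kernel = SenseKernel.prepare(blades, csm, interp=interp)
    diags: dict = {}
    s1 = ssb_reconstruct(
        blades,
        csm,
        do_motion=do_motion,
        kernel=kernel,
        interp=interp,
        support_frac=support_frac,
    )
    motion = s1.motion
    phase_maps = estimate_blade_phase(s1.blade_images) if phase_comp else None
    diags["s1_combined"] = s1.combined
    if truth is not None:
        diags["nrms_s1"] = nrms_error(s1.combined, truth)

    if variant == "s2x2":
        _, motion, comb_a = _regularized_pass(
            blades, csm, motion, s1.combined, kernel, do_motion,
            phase_maps, interp, support_frac,
        )
        if truth is not None:
            diags["nrms_s2"] = nrms_error(comb_a, truth)
        _, motion, final = _regularized_pass(
            blades, csm, motion, comb_a, kernel, do_motion,
            phase_maps, interp, support_frac,
        )
        if truth is not None:
            diags["nrms_s3"] = nrms_error(final, truth)
        return MJBResult(final, motion, diags)

    if variant == "s3x2":
        img_a = _joint_pass(
            blades, csm, motion, s1.combined, kernel, use_backsub_s3,
            phase_maps, interp, support_frac, blade_weights,
        )
        if truth is not None:
            diags["nrms_s2"] = nrms_error(img_a, truth)
        final = _joint_pass(
            blades, csm, motion, img_a, kernel, use_backsub_s3,
            phase_maps, interp, support_frac, blade_weights,
        )
        if truth is not None:
            diags["nrms_s3"] = nrms_error(final, truth)
        return MJBResult(final, motion, diags)

    # standard: S1 -> S2 -> S3 (-> optionally S2 -> S3 again)
    reference = s1.combined
    final = None
    for it in range(1 + max(0, n_extra_iters)):
        _, motion, comb2 = _regularized_pass(
            blades, csm, motion, reference, kernel, do_motion,
            phase_maps, interp, support_frac,
        )
        if it == 0:
            diags["s2_combined"] = comb2
            if truth is not None:
                diags["nrms_s2"] = nrms_error(comb2, truth)
        final = _joint_pass(
            blades, csm, motion, comb2, kernel, use_backsub_s3,
            phase_maps, interp, support_frac, blade_weights,
        )
        if truth is not None:
            diags.setdefault("nrms_s3_per_iter", []).append(
                nrms_error(final, truth)
            )
        reference = final
    if truth is not None:
        diags["nrms_s3"] = diags["nrms_s3_per_iter"][0]
        diags["nrms_final"] = diags["nrms_s3_per_iter"][-1]
    return MJBResult(final, motion, diags)
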