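"""Virtual blades, back-substitution solves, blade widening and the full
multi-step reconstruction."""

import numpy as np
import pytest

from mjbsense import (
    BladeSet,
    CoilMaps,
    GroundTruthImage,
    make_csm,
    make_phantom,
    mjb_reconstruct,
    nrms_error,
    synthesize_blades,
    undersample,
)
from mjbsense.core import blade_to_images
from mjbsense.mjb import (
    estimate_blade_phase,
    joint_blade_backsub,
    joint_blade_lstsq,
    make_virtual_blades,
    regularized_blade_solve,
    widen_blades,
)
from mjbsense.motion import estimate_rotation
from mjbsense.ssb import SenseKernel
from mjbsense.synthetic import blade_angles, draw_motion
from mjbsense.transforms import fft2c, ifft2c, rotate_image


class TestMakeVirtualBlades:
    def test_full_width_consistency_limit(self, truth64, csm64):
        """combined = truth, zero motion, width = L: the virtual blades
        are exactly the rotated truth times the rotated coil maps."""
        angles = blade_angles(4)
        v = make_virtual_blades(truth64.pixels.astype(complex), csm64, None, angles, 64)
        for i, th in enumerate(angles):
            expect = (
                rotate_image(truth64.pixels.astype(complex), -th)[None]
                * rotate_image(csm64.maps, -th)
            )
            assert np.abs(v[i] - expect).max() < 1e-10

    def test_band_crop_matches_direct_oracle(self, truth64, csm64):
        """width = W virtual blade equals the explicit crop-in-k-space of
        the full-width virtual blade."""
        angles = blade_angles(4)
        wide = make_virtual_blades(
            truth64.pixels.astype(complex), csm64, None, angles, 64
        )
        narrow = make_virtual_blades(
            truth64.pixels.astype(complex), csm64, None, angles, 20
        )
        lo = 32 - 10
        for i in range(4):
            K = fft2c(wide[i])
            Kb = np.zeros_like(K)
            Kb[:, lo : lo + 20, :] = K[:, lo : lo + 20, :]
            assert np.abs(narrow[i] - ifft2c(Kb)).max() < 1e-10

    def test_motion_pose_matches_acquired_blade(self, truth128, csm128):
        """The virtual blade carries the acquired blade's pose: its
        rotation relative to a motion-free virtual blade matches the
        injected rotation."""
        angles = blade_angles(8)
        motion = draw_motion(8, 10, 5, seed=2)
        still = make_virtual_blades(
            truth128.pixels.astype(complex), csm128, None, angles, 40
        )
        moved = make_virtual_blades(
            truth128.pixels.astype(complex), csm128, motion, angles, 40
        )
        i = 3
        sos_still = np.sqrt((np.abs(still[i]) ** 2).sum(axis=0))
        sos_moved = np.sqrt((np.abs(moved[i]) ** 2).sum(axis=0))
        est = estimate_rotation(
            sos_moved.astype(complex), sos_still.astype(complex), disk_radius=19
        )
        assert est == pytest.approx(motion.rotations_deg[i], abs=0.5)

    def test_width_exceeding_matrix_rejected(self, truth64, csm64):
        with pytest.raises(ValueError):
            make_virtual_blades(
                truth64.pixels.astype(complex), csm64, None, [0.0], 65
            )


class TestRegularizedBladeSolve:
    def test_exact_backsubstitution_cartesian(self, rng):
        """With virtual partners equal to the true partner contributions
        (no band-limiting confound), the update returns the truth to
        numerical precision."""
        n_coils, R, delta, L = 4, 3, 5, 6
        Lp = R * delta
        csm = rng.normal(size=(n_coils, Lp, L)) + 1j * rng.normal(
            size=(n_coils, Lp, L)
        )
        truth = rng.normal(size=(Lp, L)) + 1j * rng.normal(size=(Lp, L))
        coil_imgs = csm * truth[None]
        aliased = sum(np.roll(coil_imgs, r * delta, axis=-2) for r in range(R))
        out = regularized_blade_solve(aliased, csm, coil_imgs, R, support_frac=0.0)
        assert np.abs(out - truth).max() < 1e-10

    def test_equals_one_jacobi_sweep(self, rng):
        """The solve equals one Jacobi iteration on the assembled normal
        equations initialised at the virtual values (dense oracle)."""
        n_coils, R, delta, L = 5, 4, 3, 3
        Lp = R * delta
        csm = rng.normal(size=(n_coils, Lp, L)) + 1j * rng.normal(
            size=(n_coils, Lp, L)
        )
        truth = rng.normal(size=(Lp, L)) + 1j * rng.normal(size=(Lp, L))
        virt_obj = truth + 0.3 * (
            rng.normal(size=(Lp, L)) + 1j * rng.normal(size=(Lp, L))
        )
        coil_true = csm * truth[None]
        virt_coil = csm * virt_obj[None]
        aliased = sum(np.roll(coil_true, r * delta, axis=-2) for r in range(R))
        out = regularized_blade_solve(aliased, csm, virt_coil, R, support_frac=0.0)
        # dense Jacobi sweep per pixel group
        for y0 in range(delta):
            for x in range(L):
                C = csm[:, y0::delta, x]  # (coils, R)
                S = aliased[:, y0, x]
                P_old = virt_obj[y0::delta, x]
                G = C.conj().T @ C
                b = C.conj().T @ S
                D = np.diag(G).real
                P_new = (b - (G - np.diag(D)) @ P_old) / D
                assert np.allclose(out[y0::delta, x], P_new, atol=1e-10)

    def test_r1_reduces_to_matched_filter(self, rng):
        n_coils, L = 4, 8
        csm = rng.normal(size=(n_coils, L, L)) + 1j * rng.normal(size=(n_coils, L, L))
        truth = rng.normal(size=(L, L)) + 1j * rng.normal(size=(L, L))
        coil = csm * truth[None]
        out = regularized_blade_solve(coil, csm, np.zeros_like(coil), 1, support_frac=0.0)
        mf = (np.conj(csm) * coil).sum(0) / (np.abs(csm) ** 2).sum(0)
        assert np.abs(out - mf).max() < 1e-12


class TestWidenBlades:
    def _setup(self, truth, csm, R=4, W=24, n_blades=4):
        L = truth.matrix_size
        full = synthesize_blades(truth, csm, n_blades, W, L)
        acq = undersample(full, R)
        wide = make_virtual_blades(
            truth.pixels.astype(complex), csm, None, full.blade_angles_deg, L
        )
        return acq, wide

    def test_measured_rows_preserved(self, truth64, csm64):
        acq, wide = self._setup(truth64, csm64)
        widened = widen_blades(acq, wide)
        assert widened.blade_width_lines == 64
        assert widened.accel_factor == 4
        # the acquired comb rows carry the measured data bit-for-bit
        W = acq.blade_width_lines
        acq_band = (acq.acquired_line_indices - W // 2) + 32
        slots = {b: j for j, b in enumerate(widened.acquired_line_indices)}
        idx = [slots[b] for b in acq_band]
        assert np.array_equal(widened.kspace[:, :, idx, :], acq.kspace)

    def test_uniform_comb(self, truth64, csm64):
        from mjbsense.core import comb_offset

        acq, wide = self._setup(truth64, csm64)
        widened = widen_blades(acq, wide)
        k = widened.acquired_line_indices - 32
        assert np.all(np.diff(widened.acquired_line_indices) == 4)
        assert np.all(k % 4 == comb_offset(acq))

    def test_offset_comb_preserved(self, truth64, csm64):
        """Odd-ETL geometry (comb not through DC): widening keeps the
        acquired comb's offset."""
        from mjbsense.core import comb_offset

        acq, wide = self._setup(truth64, csm64, W=20)
        assert comb_offset(acq) == 2
        widened = widen_blades(acq, wide)
        k = widened.acquired_line_indices - 32
        assert np.all(k % 4 == 2)

    def test_virtual_from_truth_matches_ideal_wide_blade(self, truth64, csm64):
        """Widening with truth-derived virtual data reproduces the ideal
        full-width undersampled blade."""
        acq, wide = self._setup(truth64, csm64)
        widened = widen_blades(acq, wide)
        ideal_full = undersample(synthesize_blades(truth64, csm64, 4, 64, 64), 4)
        rel = np.linalg.norm(widened.kspace - ideal_full.kspace) / np.linalg.norm(
            ideal_full.kspace
        )
        assert rel < 2e-2  # limited by the rotate/multiply commutation

    def test_zero_virtual_gives_zero_padded_blade(self, truth64, csm64):
        acq, wide = self._setup(truth64, csm64)
        widened = widen_blades(acq, np.zeros_like(wide))
        W = acq.blade_width_lines
        acq_band = (acq.acquired_line_indices - W // 2) + 32
        slots = {b: j for j, b in enumerate(widened.acquired_line_indices)}
        others = [j for b, j in slots.items() if b not in set(acq_band)]
        assert np.abs(widened.kspace[:, :, others, :]).max() == 0.0

    def test_geometry_mismatch_rejected(self, truth64, csm64):
        acq, wide = self._setup(truth64, csm64)
        with pytest.raises(ValueError):
            widen_blades(acq, wide[:, :, :32, :32])


class TestJointBladeSolve:
    def test_single_blade_degenerates_to_regularized_solve(self, truth64, csm64):
        """With one blade at angle 0 the joint solve is the per-blade
        back-substitution solve."""
        L = 64
        full = synthesize_blades(truth64, csm64, 1, L, L)
        acq = undersample(full, 4)
        wide = make_virtual_blades(
            truth64.pixels.astype(complex), csm64, None, full.blade_angles_deg, L
        )
        widened = widen_blades(acq, wide)
        kernel = SenseKernel.prepare(widened, csm64)
        joint = joint_blade_backsub(widened, kernel, None, wide)
        aliased = blade_to_images(widened, 0)
        single = regularized_blade_solve(aliased, kernel.csm_work[0], wide[0], 4)
        assert np.abs(joint - single).max() < 1e-10

    def test_noise_free_exact_virtual_reaches_truth(self, truth128, csm128):
        """Consistent noise-free data with truth-derived virtual blades
        reconstruct the object to the rotate/coil-multiply commutation
        floor (the band-limit and the coil weighting do not commute, so
        ~1% nRMS remains even with exact partners)."""
        L = 128
        acq = undersample(synthesize_blades(truth128, csm128, 16, 40, L), 4)
        wide = make_virtual_blades(
            truth128.pixels.astype(complex), csm128, None, acq.blade_angles_deg, L
        )
        widened = widen_blades(acq, wide)
        kernel = SenseKernel.prepare(widened, csm128)
        out = joint_blade_backsub(widened, kernel, None, wide)
        assert nrms_error(out, truth128) < 1.5

    def test_lstsq_matches_bruteforce_two_blade_toy(self):
        """8x8 two-orthogonal-blade toy at R=2: the no-back-substitution
        joint solve equals an independently assembled stacked
        least-squares solution at every pixel."""
        L, R, n_coils = 8, 2, 2
        rng = np.random.default_rng(5)
        y, x = np.mgrid[0:L, 0:L]
        c = L // 2
        # smooth low-order coil maps and a smooth object
        csm_maps = np.stack(
            [
                (0.8 + 0.4 * (x - c) / L + 0.25j * (y - c) / L),
                (0.7 - 0.35 * (y - c) / L + 0.2j * (x - c) / L),
            ]
        ).astype(complex)
        csm = CoilMaps(csm_maps)
        obj = np.exp(-((y - c) ** 2 + (x - c) ** 2) / 6.0)
        truth = GroundTruthImage(obj / obj.max())
        full = synthesize_blades(truth, csm, 2, L, L)  # angles 0 and 90
        acq = undersample(full, R)
        kernel = SenseKernel.prepare(acq, csm)
        out = joint_blade_lstsq(acq, kernel, None, support_frac=0.0)

        # independent brute force: for each pixel assemble rows from both
        # blades (exact quarter-turn geometry, no interpolation)
        aliased = [blade_to_images(acq, i) for i in range(2)]
        csm_b = [kernel.csm_work[i] for i in range(2)]
        delta = L // R
        expect = np.zeros((L, L), complex)
        for yy in range(L):
            for xx in range(L):
                rows = []
                rhs = []
                cols_per_blade = []
                for i in range(2):
                    if i == 0:
                        yb, xb = yy, xx
                    else:
                        # common pixel (yy, xx) in the 90-deg blade frame:
                        # invert the quarter-turn content map
                        yb, xb = xx, (2 * c - yy) % L
                    partner = [(yb + r * delta) % L for r in range(R)]
                    cols_per_blade.append(partner)
                    for k in range(n_coils):
                        rows.append(
                            [csm_b[i][k, p, xb] for p in partner]
                        )
                        rhs.append(aliased[i][k, yb, xb])
                # unknowns: shared pixel + one partner per blade
                A = np.zeros((4, 3), complex)
                for r_i in range(2):
                    for k in range(n_coils):
                        row = rows[r_i * n_coils + k]
                        A[r_i * n_coils + k, 0] = row[0]
                        A[r_i * n_coils + k, 1 + r_i] = row[1]
                sol, *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
                expect[yy, xx] = sol[0]
        assert np.abs(out - expect).max() < 1e-8


class TestEstimateBladePhase:
    """Windowed low-resolution phase extraction; checked on a smooth
    positive blob where the window introduces no sign flips."""

    @staticmethod
    def _blob():
        y, x = np.mgrid[0:64, 0:64]
        return np.exp(-((y - 32) ** 2 + (x - 32) ** 2) / 120.0)

    def test_real_image_zero_phase(self):
        img = self._blob()
        maps = estimate_blade_phase([img.astype(complex)])
        sup = img > 0.1
        assert np.abs(np.angle(maps[0])[sup]).max() < 1e-4

    def test_smooth_ramp_recovered(self):
        img = self._blob()
        y, x = np.mgrid[0:64, 0:64]
        ramp = 0.5 * (x - 32) / 64 + 0.3 * (y - 32) / 64
        maps = estimate_blade_phase([img * np.exp(1j * ramp)])
        sup = img > 0.1
        err = np.angle(maps[0] * np.exp(-1j * ramp))[sup]
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_conjugate_negates_phase(self):
        img = self._blob()
        y, x = np.mgrid[0:64, 0:64]
        z = img * np.exp(1j * 0.4 * (x - 32) / 64)
        m1 = estimate_blade_phase([z])[0]
        m2 = estimate_blade_phase([np.conj(z)])[0]
        sup = img > 0.1
        assert np.abs(np.angle(m1 * m2)[sup]).max() < 1e-4


class TestMJBReconstruct:
    def test_r1_end_to_end(self, truth128, csm128):
        blades = synthesize_blades(truth128, csm128, 16, 24, 128)
        res = mjb_reconstruct(blades, csm128, truth=truth128)
        assert res.diagnostics["nrms_s3"] < 2.0

    def test_noise_free_r4(self, blades128_r4, csm128, kernel128_r4, truth128):
        res = mjb_reconstruct(
            blades128_r4, csm128, kernel=kernel128_r4, truth=truth128
        )
        assert res.diagnostics["nrms_s3"] < 3.0

    def test_variants_run_and_report(self, truth64, csm64):
        blades = undersample(synthesize_blades(truth64, csm64, 8, 24, 64), 4)
        kernel = SenseKernel.prepare(blades, csm64)
        for variant in ("standard", "s2x2", "s3x2"):
            res = mjb_reconstruct(
                blades, csm64, variant=variant, kernel=kernel, truth=truth64
            )
            d = res.diagnostics
            assert {"nrms_s1", "nrms_s2", "nrms_s3"} <= set(d)

    def test_unknown_variant_rejected(self, blades128_r4, csm128):
        with pytest.raises(ValueError):
            mjb_reconstruct(blades128_r4, csm128, variant="bogus")
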