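"""Fourier-domain primitives shared by synthesis and reconstruction.

All image <-> k-space transforms in this package use a single convention:

* centered grids — the DC sample sits at index ``N // 2`` on both axes;
* orthonormal scaling (``norm="ortho"``) — Parseval holds exactly, so
  white noise keeps the same per-component standard deviation in either
  domain.

Rotation is implemented as an FFT three-shear decomposition: an angle is
split into an exact multiple of 90 degrees plus a residual in (-45, 45],
and the residual is applied as shear / shear / shear passes realised as
linear phase ramps in the conjugate domain.  Each shear is unitary on the
periodic grid, so ``rotate_image(theta)`` followed by
``rotate_image(-theta)`` is an exact inverse and energy is conserved.  A
bicubic-spline fallback (``interp="spline"``) is provided so that
simulation and reconstruction can deliberately use different
interpolators when probing inverse-crime sensitivity.

Coordinate convention: arrays are indexed ``(..., y, x)`` (row, column).
``rotate_image(img, theta)`` moves image content according to the
rotation matrix ``[[cos, -sin], [sin, cos]]`` acting on ``(y, x)``
offsets from the centre pixel ``(N//2, N//2)``; the direction is opaque
to callers as long as the same operator is used consistently, which it
is throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "fft2c",
    "ifft2c",
    "fft1c",
    "ifft1c",
    "resample_axis",
    "phase_shift",
    "rotate_image",
    "lowpass_disk",
]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def fft1c(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def ifft1c(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def resample_axis(img: np.ndarray, n_new: int, axis: int = -2) -> np.ndarray:
    """Sinc-resample one axis to ``n_new`` samples by k-space zero-pad/crop.

    The field of view along the axis is unchanged and smooth image values
    are preserved (a constant image stays at the same level).  Used to
    move between the common ``L`` grid and the SENSE working grid
    ``L' = R * ceil(L / R)`` on which aliasing replicas fall on integer
    pixels.
    """
    n_old = img.shape[axis]
    if n_new == n_old:
        return np.asarray(img, dtype=complex)
    ksp = fft1c(img, axis=axis)
    c_old, c_new = n_old // 2, n_new // 2
    shape = list(img.shape)
    shape[axis] = n_new
    if n_new > n_old:
        out = np.zeros(shape, dtype=complex)
        dst = [slice(None)] * img.ndim
        dst[axis] = slice(c_new - c_old, c_new - c_old + n_old)
        out[tuple(dst)] = ksp
    else:
        src = [slice(None)] * img.ndim
        src[axis] = slice(c_old - c_new, c_old - c_new + n_new)
        out = ksp[tuple(src)]
    return ifft1c(out, axis=axis) * np.sqrt(n_new / n_old)


def phase_shift(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Cyclically shift image content by (dy, dx) pixels via k-space phase.

    Positive ``dy``/``dx`` move content toward larger row/column index:
    the shifted image value at (y, x) is the original at (y-dy, x-dx).
    """
    img = np.asarray(img)
    if dy == 0.0 and dx == 0.0:
        return img.astype(complex, copy=False)
    ny, nx = img.shape[-2:]
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    ramp = np.exp(-2j * np.pi * (ky * dy + kx * dx))
    ksp = np.fft.fft2(img, axes=(-2, -1))
    return np.fft.ifft2(ksp * ramp, axes=(-2, -1))


def _shear(img: np.ndarray, amount: float, axis: int) -> np.ndarray:
    """Sub-pixel shear via a 1D FFT phase ramp.

    ``axis=-1``: each row ``y`` shifts horizontally by ``amount*(y-c)``,
    i.e. the coordinate map is ``x -> x + amount*(y-c)``.
    ``axis=-2``: each column ``x`` shifts vertically by ``amount*(x-c)``.
    Centre ``c = N//2`` matches the centered-FFT convention.  Shears are
    circular (unitary) on the periodic grid.
    """
    ny, nx = img.shape[-2:]
    if axis == -1:
        k = np.fft.fftfreq(nx)[None, :]
        coord = (np.arange(ny) - ny // 2)[:, None]
    else:
        k = np.fft.fftfreq(ny)[:, None]
        coord = (np.arange(nx) - nx // 2)[None, :]
    ramp = np.exp(-2j * np.pi * k * amount * coord)
    ksp = np.fft.fft(img, axis=axis)
    return np.fft.ifft(ksp * ramp, axis=axis)


def _quarter_turn(img: np.ndarray, k: int) -> np.ndarray:
    """Exact rotation by ``k*90`` degrees about the lattice point (N//2, N//2).

    Implemented as an index permutation (transpose / flip / roll) so it is
    lossless for any input and consistent with the shear path's fixed
    point on even grids.
    """
    k = k % 4
    out = np.asarray(img)
    n = out.shape[-1]
    if out.shape[-2] != n:
        raise ValueError("quarter turns require square arrays")
    roll = 1 if n % 2 == 0 else 0
    for _ in range(k):
        # single +90 step: out[y, x] = in[x, (2c - y) mod N]
        t = np.swapaxes(out, -2, -1)
        t = np.flip(t, axis=-2)
        out = np.roll(t, roll, axis=-2)
    return out


def rotate_image(
    img: np.ndarray,
    angle_deg: float,
    interp: str = "shear",
) -> np.ndarray:
    """Rotate image content by ``angle_deg`` about pixel ``(N//2, N//2)``.

    Works on the last two axes of arbitrarily stacked arrays.  Multiples
    of 90 degrees are applied exactly (index permutation) in either
    interpolation mode.
    """
    img = np.asarray(img)
    angle = float(angle_deg) % 360.0
    k = int(np.round(angle / 90.0))
    resid = angle - 90.0 * k
    out = _quarter_turn(img, k) if (k % 4) else img
    if abs(resid) < 1e-12:
        return out
    if interp == "shear":
        was_real = not np.iscomplexobj(out)
        out = np.asarray(out, dtype=complex)
        theta = np.deg2rad(resid)
        a = -np.tan(theta / 2.0)
        b = np.sin(theta)
        # M(theta) = V(a) H(b) V(a) with V a vertical (axis=-2) shear and
        # H a horizontal (axis=-1) shear; applied outside-in.
        out = _shear(out, a, axis=-2)
        out = _shear(out, b, axis=-1)
        out = _shear(out, a, axis=-2)
        return out.real if was_real else out
    if interp == "spline":
        return _spline_rotate(out, resid)
    raise ValueError(f"unknown interp {interp!r}")


def _spline_rotate(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bicubic rotation with the same fixed point and direction as the
    shear path."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    ny, nx = img.shape[-2:]
    centre = np.array([ny // 2, nx // 2], dtype=float)
    mat = np.array([[c, s], [-s, c]])  # inverse map M(-theta)
    off = centre - mat @ centre

    def _rot2d(a: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            a, mat, offset=off, order=3, mode="grid-wrap", prefilter=True
        )

    flat = img.reshape((-1, ny, nx))
    if np.iscomplexobj(img):
        out = np.stack([_rot2d(f.real) + 1j * _rot2d(f.imag) for f in flat])
    else:
        out = np.stack([_rot2d(f) for f in flat])
    return out.reshape(img.shape)


def lowpass_disk(img: np.ndarray, radius: float) -> np.ndarray:
    """Keep only the central k-space disk of the given pixel radius."""
    ny, nx = img.shape[-2:]
    ky = np.arange(ny) - ny // 2
    kx = np.arange(nx) - nx // 2
    mask = (ky[:, None] ** 2 + kx[None, :] ** 2) <= radius**2
    return ifft2c(fft2c(img) * mask)
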