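"""Real even-order spherical harmonics.

Fiber orientation distributions and diffusion signals are antipodally
symmetric spherical functions, so only even-degree harmonics are used.  The
basis here is the real symmetric basis: for degree ``l`` and order ``m``,

    m < 0 :  sqrt(2) * Im(Y_l^{|m|})
    m = 0 :  Y_l^0
    m > 0 :  sqrt(2) * Re(Y_l^m)

stored in the flat order ``(l, m) = (0,0), (2,-2) ... (2,2), (4,-4) ...``.
At maximum degree 8 this gives 45 coefficients.  The basis is orthonormal
over the sphere.  A conversion matrix between this convention and others
differing by per-coefficient sign/scale can be built with
:func:`basis_conversion`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "n_coeffs",
    "degrees",
    "sh_basis",
    "zonal_response",
    "convolution_factors",
    "rotate_zonal_to",
    "basis_conversion",
]

BASIS_TAG = "real-sym-mneg-im"


def n_coeffs(order: int) -> int:
    """Number of real even-SH coefficients up to ``order`` (45 for order 8)."""
    return (order + 1) * (order + 2) // 2


def degrees(order: int) -> np.ndarray:
    """Degree l of each flat coefficient index."""
    return np.concatenate(
        [np.full(2 * l + 1, l, dtype=int) for l in range(0, order + 1, 2)]
    )


def _to_angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    r = np.linalg.norm(d, axis=1)
    theta = np.arccos(np.clip(d[:, 2] / np.where(r == 0, 1, r), -1, 1))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def sh_basis(order: int, dirs: np.ndarray) -> np.ndarray:
    """Design matrix of the real even-SH basis evaluated at unit ``dirs``.

    Returns an (n_dirs, n_coeffs(order)) matrix.  ``order`` must be even.
    """
    if order % 2 != 0 or order < 0:
        raise ValueError("SH order must be a non-negative even integer")
    theta, phi = _to_angles(dirs)
    cols = []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.stack(cols, axis=1)


def zonal_response(profile, order: int, n_nodes: int = 64) -> np.ndarray:
    """Project an axially symmetric kernel onto zonal harmonics.

    ``profile`` maps cos(theta) (angle from the symmetry axis) to kernel
    amplitude.  Returns ``r_l`` for even ``l`` up to ``order`` such that the
    kernel equals ``sum_l r_l Y_l0`` on the sphere.  Uses Gauss-Legendre
    quadrature over cos(theta), exact for band-limited kernels.
    """
    if order % 2 != 0:
        raise ValueError("SH order must be even")
    t, w = np.polynomial.legendre.leggauss(max(n_nodes, order + 1))
    k = np.asarray(profile(t), dtype=float)
    ls = np.arange(0, order + 1, 2)
    # r_l = 2*pi * sqrt((2l+1)/(4*pi)) * int_-1^1 K(t) P_l(t) dt
    out = np.empty(len(ls))
    for i, l in enumerate(ls):
        out[i] = (
            2.0 * np.pi
            * np.sqrt((2 * l + 1) / (4.0 * np.pi))
            * np.sum(w * k * eval_legendre(l, t))
        )
    return out


def convolution_factors(r_l: np.ndarray, order: int) -> np.ndarray:
    """Per-coefficient factors turning FOD SH coefficients into signal SH
    coefficients for spherical convolution with a zonal kernel (Funk-Hecke):
    ``s_lm = sqrt(4*pi/(2l+1)) * r_l * f_lm``."""
    ls = degrees(order)
    lut = {l: r_l[i] for i, l in enumerate(range(0, order + 1, 2))}
    return np.array([np.sqrt(4 * np.pi / (2 * l + 1)) * lut[l] for l in ls])


def rotate_zonal_to(r_l: np.ndarray, order: int, axis: np.ndarray) -> np.ndarray:
    """SH coefficients of a zonal kernel re-oriented along ``axis``.

    By the addition theorem the rotated kernel at direction u is
    ``sum_l r_l sqrt((2l+1)/4pi) P_l(axis . u)``; its SH coefficients are
    obtained by convolving a unit delta at ``axis`` with the kernel.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # delta on the sphere at `axis` has SH coefficients Y_lm(axis); convolve.
    y = sh_basis(order, axis[None, :])[0]
    return convolution_factors(r_l, order) * y


def basis_conversion(signs: np.ndarray) -> np.ndarray:
    """Diagonal conversion matrix between real-SH conventions that differ by
    per-coefficient signs/scales; its inverse is the reciprocal diagonal."""
    signs = np.asarray(signs, dtype=float)
    if np.any(signs == 0):
        raise ValueError("conversion factors must be nonzero")
    return np.diag(signs)
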